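"""Shared record types: classified assembly differences and gene annotations."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["DifferenceRecord", "GeneAnnotation", "KINDS", "GENE_CLASSES"]

KINDS = ("insertion", "deletion", "substitution")
GENE_CLASSES = ("PCG", "tRNA", "rRNA", "other")


@dataclass(frozen=True)
class DifferenceRecord:
    """One classified difference between two assemblies, in reference coordinates.

    Coordinates are 0-based. For a substitution, ``ref_position`` is the first
    substituted base. For a deletion, the first deleted reference base. For an
    insertion, the reference position *before which* the query bases are
    inserted. Indels inside repeats are stored left-normalized (lowest
    reference coordinate among equivalent placements).

    ``hp_base``/``hp_len`` describe the homopolymer context at the locus
    (filled in by :func:`mitoqc.profiling.attribute_homopolymer`).
    """

    ref_position: int
    kind: str
    ref_bases: str = ""
    query_bases: str = ""
    hp_base: str | None = None
    hp_len: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown difference kind {self.kind!r}")
        if self.kind == "substitution":
            if len(self.ref_bases) != len(self.query_bases) or not self.ref_bases:
                raise ValueError(
                    "substitution needs equal-length non-empty ref/query bases"
                )
        elif self.kind == "insertion":
            if self.ref_bases or not self.query_bases:
                raise ValueError("insertion carries query bases only")
        elif self.kind == "deletion":
            if self.query_bases or not self.ref_bases:
                raise ValueError("deletion carries reference bases only")

    @property
    def size(self) -> int:
        return max(len(self.ref_bases), len(self.query_bases))

    @property
    def type_label(self) -> str:
        """Compact label in difference-string style: ``+A``, ``-T``, ``*CT``."""
        if self.kind == "insertion":
            return "+" + self.query_bases
        if self.kind == "deletion":
            return "-" + self.ref_bases
        return "*" + self.ref_bases + self.query_bases

    @property
    def is_indel(self) -> bool:
        return self.kind in ("insertion", "deletion")

    @property
    def indel_base(self) -> str | None:
        """The inserted/deleted base for single-base indels, else None."""
        if self.kind == "insertion" and len(self.query_bases) == 1:
            return self.query_bases
        if self.kind == "deletion" and len(self.ref_bases) == 1:
            return self.ref_bases
        return None


@dataclass(frozen=True)
class GeneAnnotation:
    """A named mitochondrial feature with 0-based half-open circular coordinates.

    ``end`` may be <= ``start`` only for features wrapping the origin of a
    circular sequence; ``length_on`` computes the span modulo genome length.
    """

    name: str
    gene_class: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {self.gene_class!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0:
            raise ValueError("negative start coordinate")

    @property
    def wraps(self) -> bool:
        return self.end <= self.start

    def length_on(self, genome_length: int) -> int:
        if self.wraps:
            return genome_length - self.start + self.end
        return self.end - self.start
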