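"""Core sequence container for circular mitogenome work.

A mitogenome is a circular molecule: any rotation and either strand of the
assembled contig represent the same genome. :class:`CircularSequence` carries
the base string together with a circularity flag and a record of any
normalization (rotation / strand flip) that has been applied, so the
normalization is invertible and comparisons between assemblies are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "CircularSequence",
    "reverse_complement",
    "minimal_rotation_index",
    "homopolymer_run",
    "homopolymer_mask",
]

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN" + "acgtryswkmbdhvn",
    "TGCAYRSWMKVHDBN" + "tgcayrswmkvhdbn",
)

IUPAC = frozenset("ACGTRYSWKMBDHVN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CircularSequence:
    """A nucleotide sequence with circular topology and normalization record.

    Parameters
    ----------
    name:
        Sequence identifier (FASTA header word).
    bases:
        Uppercase IUPAC nucleotide string.
    circular:
        Whether the molecule is circular (rotations are equivalent).
    applied_rotation:
        Rotation (in bp, in ``[0, len)``) applied relative to the original
        input, or ``None`` if the sequence was never normalized.
    applied_strand_flip:
        Whether the sequence was reverse-complemented during normalization.
    """

    name: str
    bases: str
    circular: bool = False
    applied_rotation: int | None = None
    applied_strand_flip: bool = False

    def __post_init__(self) -> None:
        self.bases = self.bases.upper()
        bad = set(self.bases) - IUPAC
        if bad:
            raise ValueError(
                f"sequence {self.name!r} contains non-nucleotide characters: "
                f"{sorted(bad)}"
            )
        if self.applied_rotation is not None and len(self.bases):
            self.applied_rotation %= len(self.bases)

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def normalized(self) -> bool:
        return self.applied_rotation is not None

    def rotate(self, offset: int) -> "CircularSequence":
        """Return the sequence rotated so original position ``offset`` is first.

        Only meaningful for circular sequences; the cumulative rotation is
        recorded so the operation can be inverted.
        """
        if not self.circular:
            raise ValueError(f"cannot rotate linear sequence {self.name!r}")
        n = len(self.bases)
        if n == 0:
            return replace(self)
        offset %= n
        prev = self.applied_rotation or 0
        return replace(
            self,
            bases=self.bases[offset:] + self.bases[:offset],
            applied_rotation=(prev + offset) % n,
        )

    def reverse_complement(self) -> "CircularSequence":
        return replace(
            self,
            bases=reverse_complement(self.bases),
            applied_rotation=self.applied_rotation
            if self.applied_rotation is not None
            else None,
            applied_strand_flip=not self.applied_strand_flip,
        )

    def denormalize(self) -> "CircularSequence":
        """Invert any recorded rotation/flip, recovering the input orientation."""
        seq = self
        if seq.applied_strand_flip:
            seq = seq.reverse_complement()
        rot = seq.applied_rotation or 0
        if rot:
            # applied_strand_flip toggling above keeps rotation bookkeeping:
            # undo by rotating the complementary amount.
            n = len(seq.bases)
            seq = replace(
                seq,
                bases=seq.bases[n - rot :] + seq.bases[: n - rot],
                applied_rotation=0,
            )
        return replace(seq, applied_rotation=None, applied_strand_flip=False)

    def at_fraction(self) -> float:
        """AT fraction over unambiguous bases (ambiguity codes excluded)."""
        at = sum(self.bases.count(b) for b in "AT")
        acgt = sum(self.bases.count(b) for b in "ACGT")
        return at / acgt if acgt else 0.0


def minimal_rotation_index(s: str) -> int:
    """Index of the lexicographically minimal rotation of ``s`` (Booth's algorithm)."""
    if not s:
        return 0
    ss = s + s
    n = len(ss)
    f = [-1] * n
    k = 0
    for j in range(1, n):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def homopolymer_run(seq: str, pos: int) -> tuple[str, int, int]:
    """Maximal identical-base run containing ``pos``.

    Returns ``(base, run_start, run_length)``.
    """
    n = len(seq)
    if not 0 <= pos < n:
        raise IndexError(f"position {pos} outside sequence of length {n}")
    base = seq[pos]
    start = pos
    while start > 0 and seq[start - 1] == base:
        start -= 1
    end = pos + 1
    while end < n and seq[end] == base:
        end += 1
    return base, start, end - start


def homopolymer_mask(seq: str, min_run: int = 3) -> list[bool]:
    """Per-position flags marking positions inside runs of length >= min_run."""
    n = len(seq)
    mask = [False] * n
    i = 0
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            for k in range(i, j):
                mask[k] = True
        i = j
    return mask
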