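"""Readers and writers for the formats the pipeline touches.

Internal coordinates are uniformly 0-based half-open; files keep their native
conventions (PAF and BED 0-based half-open, GFF-like tables 1-based
inclusive). Circularity of a FASTA record is carried as a ``circular=true``
token in the header description, keeping fixtures single-file.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import DifferenceRecord, GeneAnnotation
from .sequences import IUPAC, CircularSequence

__all__ = [
    "AlignmentRecord",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_paf",
    "write_paf",
    "read_annotations",
    "write_annotations",
    "read_differences_tsv",
    "write_differences_tsv",
    "write_window_track_tsv",
    "write_profile_json",
]


class FormatError(ValueError):
    """A file violated its format contract; message names the offending record."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One PAF alignment line, optionally carrying a cs difference string.

    Coordinates follow the PAF standard: 0-based half-open on both query and
    target. ``difference_string`` holds the raw ``cs:Z`` tag payload when
    present, else ``None`` (such records are flagged by ``has_cs``).
    """

    query_name: str
    query_length: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_length: int
    target_start: int
    target_end: int
    residue_matches: int
    block_length: int
    mapping_quality: int
    difference_string: str | None = None

    def __post_init__(self) -> None:
        for side, s, e, ln in (
            ("query", self.query_start, self.query_end, self.query_length),
            ("target", self.target_start, self.target_end, self.target_length),
        ):
            if not (0 <= s < e <= ln):
                raise FormatError(
                    f"{side} coordinates violate 0 <= {s} < {e} <= {ln} for "
                    f"{self.query_name}->{self.target_name}"
                )
        if self.strand not in "+-":
            raise FormatError(f"strand must be + or -, got {self.strand!r}")

    @property
    def has_cs(self) -> bool:
        return self.difference_string is not None


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[CircularSequence]:
    """Read FASTA records as uppercased :class:`CircularSequence` objects.

    A ``circular=true`` token anywhere in the header description marks the
    record circular. Non-nucleotide characters or an empty file raise
    :class:`FormatError` naming the record.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or headerless FASTA")
    out = []
    for rec in records:
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has no sequence")
        bad = set(seq) - IUPAC
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} has non-nucleotide characters {sorted(bad)}"
            )
        circular = any(
            tok.lower() == "circular=true" for tok in rec.description.split()
        )
        out.append(CircularSequence(name=rec.id, bases=seq, circular=circular))
    return out


def write_fasta(path: str | Path, seqs: Iterable[CircularSequence]) -> None:
    """Write sequences wrapped at 70 columns, encoding circularity in the header."""
    records = []
    for s in seqs:
        desc = "circular=true" if s.circular else "circular=false"
        records.append(SeqRecord(Seq(s.bases), id=s.name, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# PAF


def read_paf(path: str | Path) -> list[AlignmentRecord]:
    """Parse a PAF file; the cs difference string is taken from the cs:Z tag."""
    path = Path(path)
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 12 PAF columns, got {len(cols)}"
                )
            cs = None
            for tag in cols[12:]:
                if tag.startswith("cs:Z:"):
                    cs = tag[5:]
            try:
                rec = AlignmentRecord(
                    query_name=cols[0],
                    query_length=int(cols[1]),
                    query_start=int(cols[2]),
                    query_end=int(cols[3]),
                    strand=cols[4],
                    target_name=cols[5],
                    target_length=int(cols[6]),
                    target_start=int(cols[7]),
                    target_end=int(cols[8]),
                    residue_matches=int(cols[9]),
                    block_length=int(cols[10]),
                    mapping_quality=int(cols[11]),
                    difference_string=cs,
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            out.append(rec)
    if not out:
        raise FormatError(f"{path}: no PAF records")
    return out


def write_paf(path: str | Path, records: Iterable[AlignmentRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            cols = [
                r.query_name,
                str(r.query_length),
                str(r.query_start),
                str(r.query_end),
                r.strand,
                r.target_name,
                str(r.target_length),
                str(r.target_start),
                str(r.target_end),
                str(r.residue_matches),
                str(r.block_length),
                str(r.mapping_quality),
            ]
            if r.difference_string is not None:
                cols.append("cs:Z:" + r.difference_string)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Annotations

_CLASS_ALIASES = {
    "pcg": "PCG",
    "cds": "PCG",
    "trna": "tRNA",
    "rrna": "rRNA",
    "other": "other",
}


def _norm_class(raw: str) -> str:
    cls = _CLASS_ALIASES.get(raw.strip().lower())
    if cls is None:
        raise FormatError(f"unknown feature class {raw!r}")
    return cls


def read_annotations(
    path: str | Path,
    coordinates: str = "1-based",
    circular: bool = True,
    genome_length: int | None = None,
) -> list[GeneAnnotation]:
    """Read a tab-separated annotation table (name, class, start, end, strand).

    ``coordinates`` declares the file convention: ``"1-based"`` (inclusive,
    GFF-like; the package's own table format) or ``"0-based"`` (half-open,
    BED-like). Internally everything becomes 0-based half-open. Features may
    wrap the origin only when ``circular`` is true.
    """
    if coordinates not in ("1-based", "0-based"):
        raise ValueError(f"coordinates must be '1-based' or '0-based'")
    path = Path(path)
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise FormatError(
                    f"{path}:{lineno}: expected 5 columns "
                    "(name, class, start, end, strand)"
                )
            name, cls, start_s, end_s, strand = cols[:5]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if coordinates == "1-based":
                start -= 1  # end stays: 1-based inclusive end == 0-based open end
            wraps = end <= start
            if wraps and not circular:
                raise FormatError(
                    f"{path}:{lineno}: feature {name!r} has end <= start on a "
                    "linear sequence"
                )
            if genome_length is not None and (
                start >= genome_length or end > genome_length
            ):
                raise FormatError(
                    f"{path}:{lineno}: feature {name!r} exceeds genome length"
                )
            out.append(
                GeneAnnotation(
                    name=name,
                    gene_class=_norm_class(cls),
                    start=start,
                    end=end,
                    strand=strand,
                )
            )
    if not out:
        raise FormatError(f"{path}: no annotation records")
    return out


def write_annotations(path: str | Path, annotations: Iterable[GeneAnnotation]) -> None:
    """Write the 1-based inclusive tab-separated annotation table."""
    with open(path, "w") as fh:
        fh.write("#name\tclass\tstart\tend\tstrand\n")
        for a in annotations:
            fh.write(
                f"{a.name}\t{a.gene_class}\t{a.start + 1}\t{a.end}\t{a.strand}\n"
            )


# ---------------------------------------------------------------------------
# Report tables

_DIFF_COLUMNS = ["ref_pos", "kind", "ref_bases", "query_bases", "hp_base", "hp_len"]


def write_differences_tsv(path: str | Path, records: Iterable[DifferenceRecord]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_DIFF_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.ref_position,
                    r.kind,
                    r.ref_bases or ".",
                    r.query_bases or ".",
                    r.hp_base or ".",
                    r.hp_len,
                ]
            )


def read_differences_tsv(path: str | Path) -> list[DifferenceRecord]:
    path = Path(path)
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _DIFF_COLUMNS:
            raise FormatError(f"{path}: unexpected difference-table header {header}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != len(_DIFF_COLUMNS):
                raise FormatError(f"{path}:{lineno}: truncated row")
            pos, kind, ref_b, qry_b, hp_b, hp_len = cols
            out.append(
                DifferenceRecord(
                    ref_position=int(pos),
                    kind=kind,
                    ref_bases="" if ref_b == "." else ref_b,
                    query_bases="" if qry_b == "." else qry_b,
                    hp_base=None if hp_b == "." else hp_b,
                    hp_len=int(hp_len),
                )
            )
    return out


def write_window_track_tsv(path: str | Path, track) -> None:
    """Write a WindowTrack as a BED-like table (chrom, start, end, at, depth)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["chrom", "start", "end", "at_fraction", "depth"])
        for row in track.rows:
            depth = "" if row.depth is None else f"{row.depth:.4f}"
            w.writerow(
                [track.sequence_name, row.start, row.end, f"{row.at_fraction:.6f}", depth]
            )


def write_profile_json(path: str | Path, profile) -> None:
    with open(path, "w") as fh:
        json.dump(profile.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
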