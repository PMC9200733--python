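"""Windowed composition, structural segments, annotation QC and gene order.

Covers the comparative-structure side of mitogenome QC: AT-content and
coverage tracks in fixed windows, detection of assembly-specific (unaligned)
segments such as AT-rich control-region expansions, read-length N50,
completeness against the canonical metazoan gene complement (13 protein-coding
genes, 22 tRNAs, 2 rRNAs), premature-stop screening of protein-coding genes
under the invertebrate mitochondrial code, and breakpoint/inversion
comparison of circular gene orders treated as signed circular permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .align import DifferenceSet, Segment
from .records import GeneAnnotation
from .sequences import CircularSequence

__all__ = [
    "WindowRow",
    "WindowTrack",
    "UniqueSegment",
    "CompletenessReport",
    "window_stats",
    "detect_unique_segments",
    "n50",
    "completeness_check",
    "count_premature_stops",
    "gene_order_breakpoints",
    "control_region_length",
    "gene_order_string",
    "CANONICAL_PCGS",
    "CANONICAL_RRNAS",
    "CANONICAL_TRNAS",
]


# ---------------------------------------------------------------------------
# Windowed statistics


@dataclass(frozen=True)
class WindowRow:
    start: int
    end: int
    at_fraction: float
    depth: float | None = None


@dataclass
class WindowTrack:
    """Per-window AT fraction (and optional mean depth) tiling [0, L)."""

    sequence_name: str
    window: int
    rows: list[WindowRow] = field(default_factory=list)
    final_partial: bool = False

    def at_values(self) -> np.ndarray:
        return np.array([r.at_fraction for r in self.rows])

    def depth_values(self) -> np.ndarray:
        return np.array(
            [np.nan if r.depth is None else r.depth for r in self.rows]
        )


def window_stats(
    seq: CircularSequence | str,
    window: int,
    depth: np.ndarray | list[float] | None = None,
) -> WindowTrack:
    """AT fraction (and mean depth) in consecutive fixed-size windows.

    AT fraction is (A+T) / (A+C+G+T) within the window: ambiguity codes are
    excluded from both numerator and denominator so unknown bases do not bias
    composition estimates. A final partial window is included and flagged via
    ``final_partial``. ``depth``, when given, must hold one value per base.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    bases = seq.bases if isinstance(seq, CircularSequence) else seq.upper()
    name = seq.name if isinstance(seq, CircularSequence) else "seq"
    n = len(bases)
    if window > n:
        raise ValueError(f"window {window} exceeds sequence length {n}")
    if depth is not None:
        depth = np.asarray(depth, dtype=float)
        if len(depth) != n:
            raise ValueError(
                f"depth array length {len(depth)} != sequence length {n}"
            )
    rows = []
    for start in range(0, n, window):
        end = min(start + window, n)
        chunk = bases[start:end]
        at = sum(chunk.count(b) for b in "AT")
        acgt = at + sum(chunk.count(b) for b in "CG")
        frac = at / acgt if acgt else 0.0
        d = float(np.mean(depth[start:end])) if depth is not None else None
        rows.append(WindowRow(start, end, frac, d))
    return WindowTrack(
        sequence_name=name,
        window=window,
        rows=rows,
        final_partial=(n % window != 0),
    )


# ---------------------------------------------------------------------------
# Assembly-specific segments


@dataclass(frozen=True)
class UniqueSegment:
    """A stretch present in only one of the two compared assemblies."""

    owner: str  # "ref" | "query"
    start: int
    end: int
    length: int
    at_fraction: float
    flanking_genes: tuple[str | None, str | None] = (None, None)


def detect_unique_segments(
    diffs: DifferenceSet,
    min_length: int = 200,
    ref: CircularSequence | None = None,
    query: CircularSequence | None = None,
    annotations: list[GeneAnnotation] | None = None,
) -> list[UniqueSegment]:
    """Report unaligned segments of at least ``min_length`` bp.

    The default threshold sits below typical tRNA size and above
    alignment-gap noise. When the owning sequence is supplied its AT fraction
    is computed (segments bridging the origin of a circular sequence are read
    across the junction); when annotations for the reference are supplied,
    the nearest annotated genes flanking each segment are reported.
    """
    out = []
    seqs = {"ref": ref, "query": query}
    for seg in diffs.unaligned_segments:
        if seg.length < min_length:
            continue
        owner_seq = seqs[seg.owner]
        at = float("nan")
        if owner_seq is not None:
            if seg.end <= len(owner_seq):
                piece = owner_seq.bases[seg.start : seg.end]
            elif owner_seq.circular:  # wraps the origin
                over = seg.end - len(owner_seq)
                piece = owner_seq.bases[seg.start :] + owner_seq.bases[:over]
            else:
                raise ValueError("segment exceeds a linear sequence")
            at = CircularSequence("seg", piece).at_fraction()
        flank = (None, None)
        if annotations and seg.owner == "ref":
            before = [a for a in annotations if a.end <= seg.start]
            after = [a for a in annotations if a.start >= seg.end]
            flank = (
                max(before, key=lambda a: a.end).name if before else None,
                min(after, key=lambda a: a.start).name if after else None,
            )
        out.append(
            UniqueSegment(seg.owner, seg.start, seg.end, seg.length, at, flank)
        )
    return out


# ---------------------------------------------------------------------------
# Read-length statistics


def n50(lengths: list[int]) -> int:
    """N50: largest length such that reads at least that long hold >= half the bases."""
    if not lengths:
        raise ValueError("n50 of an empty length list is undefined")
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    target = sum(lengths) / 2
    acc = 0
    for l in sorted(lengths, reverse=True):
        acc += l
        if acc >= target:
            return l
    raise AssertionError("unreachable")  # pragma: no cover


# ---------------------------------------------------------------------------
# Completeness against the canonical metazoan complement

CANONICAL_PCGS = (
    "atp6", "atp8", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)
CANONICAL_RRNAS = ("rrnS", "rrnL")
#: one tRNA per amino acid plus the second leucine and serine isoacceptors
CANONICAL_TRNAS = tuple(
    f"trn{aa}" for aa in "ACDEFGHIKLMNPQRSTVWY"
) + ("trnL2", "trnS2")

_NAME_ALIASES = {
    "cytb": "cob", "cob": "cob", "co1": "cox1", "co2": "cox2", "co3": "cox3",
    "nad4l": "nad4L", "12s": "rrnS", "16s": "rrnL", "rrns": "rrnS", "rrnl": "rrnL",
    "trnl1": "trnL", "trns1": "trnS",
}


def _canonical_name(raw: str) -> str:
    low = raw.strip().lower()
    if low in _NAME_ALIASES:
        return _NAME_ALIASES[low]
    for known in CANONICAL_PCGS + CANONICAL_RRNAS + CANONICAL_TRNAS:
        if low == known.lower():
            return known
    return raw.strip()


@dataclass
class CompletenessReport:
    missing: list[str]
    duplicated: dict[str, int]
    unrecognized: list[str]

    @property
    def complete(self) -> bool:
        return not self.missing and not self.duplicated and not self.unrecognized

    def to_dict(self) -> dict:
        return {
            "complete": self.complete,
            "missing": self.missing,
            "duplicated": self.duplicated,
            "unrecognized": self.unrecognized,
        }


def completeness_check(annotations: list[GeneAnnotation]) -> CompletenessReport:
    """Compare an annotation set against the 37-gene metazoan complement.

    Leucine/serine tRNAs have two expected copies (the isoacceptors); copies
    may be labelled ``trnL``/``trnL1``/``trnL2`` interchangeably. Returns the
    missing names, duplicated names with copy counts, and unrecognized names.
    """
    expected = {name: 1 for name in CANONICAL_PCGS + CANONICAL_RRNAS}
    for aa in "ACDEFGHIKMNPQRTVWY":
        expected[f"trn{aa}"] = 1
    expected["trnL"] = 2
    expected["trnS"] = 2

    observed: dict[str, int] = {}
    unrecognized = []
    for a in annotations:
        name = _canonical_name(a.name)
        if name in ("trnL2", "trnS2"):
            name = name[:-1]
        if name not in expected:
            unrecognized.append(a.name)
            continue
        observed[name] = observed.get(name, 0) + 1

    missing = sorted(n for n, want in expected.items() if observed.get(n, 0) < want)
    duplicated = {
        n: c for n, c in sorted(observed.items()) if c > expected[n]
    }
    return CompletenessReport(missing, duplicated, sorted(set(unrecognized)))


# ---------------------------------------------------------------------------
# Premature stop codons

INVERTEBRATE_MITO_TABLE = 5


def count_premature_stops(
    cds: str, code: int = INVERTEBRATE_MITO_TABLE
) -> tuple[int, float]:
    """Internal stop-codon count and longest stop-free stretch of a CDS.

    The CDS is read in frame 0 from its annotated start on the coding strand
    and translated under the given NCBI genetic-code table (default 5,
    invertebrate mitochondrial, under which TGA is Trp). Stops strictly
    before the final codon are counted; the second value is the longest run
    of stop-free codons divided by the total codon count. A trailing partial
    codon is dropped.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    n_codons = len(cds) // 3
    aa = str(Seq(cds[: n_codons * 3]).translate(table=code))
    internal = aa[:-1].count("*")
    core = aa[:-1] if aa.endswith("*") else aa  # terminal stop is not an error
    if not core:
        return internal, 0.0
    longest = max(len(run) for run in core.split("*"))
    return internal, longest / len(core)


# ---------------------------------------------------------------------------
# Circular gene order


def gene_order_string(annotations: list[GeneAnnotation]) -> str:
    """One-line signed gene order, e.g. ``+cox1 -nad6 ...`` (by start coordinate)."""
    ordered = sorted(annotations, key=lambda a: a.start)
    return " ".join(f"{a.strand}{a.name}" for a in ordered)


def _signed_order(
    annotations: list[GeneAnnotation], keep: set[str]
) -> list[tuple[str, int]]:
    ordered = sorted(annotations, key=lambda a: a.start)
    return [
        (_canonical_name(a.name), 1 if a.strand == "+" else -1)
        for a in ordered
        if _canonical_name(a.name) in keep
    ]


def _adjacencies(order: list[tuple[str, int]]) -> set[frozenset]:
    """Orientation-aware circular adjacencies as extremity pairs.

    A signed gene ``+g`` exposes its tail on the left and head on the right
    (reversed for ``-g``); the adjacency between consecutive genes is the
    unordered pair of facing extremities, which is invariant under rotation
    and full reflection of the order.
    """
    adj = set()
    n = len(order)
    for i in range(n):
        g, sg = order[i]
        h, sh = order[(i + 1) % n]
        right = (g, "head" if sg > 0 else "tail")
        left = (h, "tail" if sh > 0 else "head")
        adj.add(frozenset([right, left]))
    return adj


def gene_order_breakpoints(
    a: list[GeneAnnotation], b: list[GeneAnnotation]
) -> tuple[int, int, list[list[str]]]:
    """Compare two circular gene orders as signed circular permutations.

    Returns ``(breakpoint_count, shared_adjacencies, inverted_blocks)``.
    Only genes present in both annotation sets are compared. A breakpoint is
    an adjacency of ``a`` absent from ``b``; an inverted block is a maximal
    run of consecutive genes of ``a`` that appear in ``b`` consecutively in
    reverse order with strands flipped. All quantities are invariant under
    rotation and full reflection of either circular order.
    """
    names_a = {_canonical_name(x.name) for x in a}
    names_b = {_canonical_name(x.name) for x in b}
    shared = names_a & names_b
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared genes between the two orders")
    order_a = _signed_order(a, shared)
    order_b = _signed_order(b, shared)
    if len(order_a) != len(shared) or len(order_b) != len(shared):
        raise ValueError("duplicated shared gene names; gene order is ambiguous")

    adj_a = _adjacencies(order_a)
    adj_b = _adjacencies(order_b)
    breakpoints = len(adj_a - adj_b)
    shared_adj = len(adj_a & adj_b)

    # inverted blocks: runs of a whose genes sit consecutively in b, reversed
    # in order and flipped in strand
    pos_b = {g: i for i, (g, _) in enumerate(order_b)}
    sign_b = {g: s for g, s in order_b}
    n = len(order_a)
    inverted = [sign_b[g] == -s for g, s in order_a]

    def b_prev(i: int, j: int) -> bool:
        """a-successor j sits directly before i in b (reversed order), circularly."""
        return pos_b[order_a[j][0]] == (pos_b[order_a[i][0]] - 1) % n

    blocks: list[list[str]] = []
    visited = [False] * n
    for start in range(n):
        if visited[start] or not inverted[start]:
            continue
        # extend forward while consecutive-in-a genes run backwards in b
        run = [start]
        j = start
        while True:
            nxt = (j + 1) % n
            if nxt == start or visited[nxt] or not inverted[nxt] or not b_prev(j, nxt):
                break
            run.append(nxt)
            j = nxt
        # extend backward
        j = start
        while True:
            prv = (j - 1) % n
            if prv == run[-1] or visited[prv] or not inverted[prv] or not b_prev(prv, j):
                break
            run.insert(0, prv)
            j = prv
        for i in run:
            visited[i] = True
        blocks.append([order_a[i][0] for i in run])
    return breakpoints, shared_adj, blocks


def control_region_length(
    annotations: list[GeneAnnotation], genome_length: int
) -> int:
    """Length of the control region: the circular gap from tRNA-Phe end to cox3 start.

    In gastropod mitogenomes the major non-coding (control) region lies
    between tRNA-Phe and cox3; its length is the plus-strand circular distance
    between those two features.
    """
    by_name = {_canonical_name(a.name): a for a in annotations}
    if "trnF" not in by_name or "cox3" not in by_name:
        raise ValueError("control region needs both trnF and cox3 annotated")
    start = by_name["trnF"].end % genome_length
    end = by_name["cox3"].start % genome_length
    return (end - start) % genome_length


def accession_report(seq: CircularSequence) -> dict:
    """Length and AT-content summary for a deposited assembly FASTA."""
    return {
        "name": seq.name,
        "length_bp": len(seq),
        "at_percent": round(100 * seq.at_fraction(), 1),
    }
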