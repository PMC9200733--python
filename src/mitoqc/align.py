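"""Circular assembly normalization and base-level difference calling.

Two assemblies of the same circular mitogenome may start anywhere on the
circle and on either strand. :func:`canonical_rotation` brings a sequence to
a reproducible canonical form (an anchor-defined start, or the
lexicographically minimal rotation over both strands). :func:`align_assemblies`
then computes a base-level difference stream between two assemblies via
unique-k-mer anchor chaining plus banded gap closure, and
:func:`differences_from_paf` derives the same difference stream from an
external aligner's PAF + cs output so the two routes can be cross-checked.

Indels inside repeats are left-normalized (shifted to the lowest reference
coordinate among equivalent placements) so difference counts are comparable
across aligners. Indel runs at or above ``segment_min`` are reported as
unaligned *segments* rather than difference records: multi-kilobase
technology-specific sequence (e.g. an AT-rich control-region expansion seen
only by one platform) is a structural feature, not a base error.
"""

from __future__ import annotations

import re
from bisect import bisect_left
from collections import Counter
from dataclasses import dataclass, field, replace

import edlib

from .io import AlignmentRecord, FormatError
from .records import DifferenceRecord
from .sequences import CircularSequence, minimal_rotation_index, reverse_complement

__all__ = [
    "AlignmentFailure",
    "AnchorNotFound",
    "DifferenceSet",
    "canonical_rotation",
    "align_assemblies",
    "differences_from_paf",
    "left_normalize",
    "apply_differences",
    "invert_records",
]

DEFAULT_SEGMENT_MIN = 200  # bp; indel runs this long become unaligned segments
BAND_LIMIT = 2500  # bp; refuse gap closure needing a wider band


class AnchorNotFound(ValueError):
    """The requested rotation anchor does not occur on either strand."""


class AlignmentFailure(RuntimeError):
    """No usable anchor chain between the two assemblies."""

    def __init__(self, message: str, degenerate: bool = False):
        super().__init__(message)
        self.degenerate = degenerate


@dataclass(frozen=True)
class Block:
    """One colinear aligned block (0-based half-open on both sequences)."""

    ref_start: int
    ref_end: int
    query_start: int
    query_end: int


@dataclass(frozen=True)
class Segment:
    """A sequence stretch present in only one assembly."""

    owner: str  # "ref" | "query"
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DifferenceSet:
    """Classified differences between a reference and a query assembly.

    ``aligned_blocks`` are non-overlapping and sorted on the reference; every
    difference record lies inside a block; ``unaligned_segments`` are the
    stretches of either assembly not covered by any block (structural,
    assembly-specific sequence).
    """

    reference_name: str
    query_name: str
    aligned_blocks: list[Block] = field(default_factory=list)
    records: list[DifferenceRecord] = field(default_factory=list)
    unaligned_segments: list[Segment] = field(default_factory=list)
    query_rotation: int = 0  # applied to the query before alignment (circular)

    @property
    def n_records(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Canonical rotation


def _find_anchor(bases: str, anchor: str, circular: bool, max_mismatches: int) -> int | None:
    """Start offset of ``anchor`` in (doubled, if circular) ``bases``; None if absent."""
    text = bases + bases[: len(anchor) - 1] if circular else bases
    if max_mismatches == 0:
        idx = text.find(anchor)
        return idx if idx >= 0 and idx < len(bases) else (None if idx < 0 else idx % len(bases))
    best = None
    m = len(anchor)
    for i in range(len(bases) if circular else len(bases) - m + 1):
        window = text[i : i + m]
        if len(window) < m:
            break
        mism = sum(a != b for a, b in zip(anchor, window))
        if mism <= max_mismatches:
            if best is None or mism < best[1]:
                best = (i, mism)
                if mism == 0:
                    break
    return best[0] if best else None


def canonical_rotation(
    seq: CircularSequence,
    anchor: str | None = None,
    max_mismatches: int = 0,
) -> CircularSequence:
    """Rotate (and possibly flip) a circular sequence to a canonical form.

    With an ``anchor`` (e.g. the first bases of cox1), the sequence is rotated
    so the anchor starts at position 0 on the plus strand; the anchor is
    searched on both strands allowing up to ``max_mismatches`` mismatches.
    Without an anchor, the canonical form is the lexicographically minimal
    rotation of the lexicographically smaller strand, which is reproducible
    with no biological input. The rotation and flip applied are recorded on
    the result so the normalization can be inverted.
    """
    if not seq.circular:
        raise ValueError(f"canonical_rotation requires a circular sequence, got {seq.name!r}")
    base = replace(seq, applied_rotation=seq.applied_rotation or 0)
    if anchor:
        anchor = anchor.upper()
        if len(anchor) > len(seq):
            raise ValueError("anchor longer than sequence")
        offset = _find_anchor(base.bases, anchor, True, max_mismatches)
        if offset is not None:
            return base.rotate(offset)
        flipped = base.reverse_complement()
        offset = _find_anchor(flipped.bases, anchor, True, max_mismatches)
        if offset is not None:
            return flipped.rotate(offset)
        raise AnchorNotFound(
            f"anchor {anchor[:20]!r}... not found on either strand of {seq.name!r}"
        )
    # minimal rotation over both strands (all 2L rotations); ties keep forward
    fwd_idx = minimal_rotation_index(base.bases)
    flipped = base.reverse_complement()
    rev_idx = minimal_rotation_index(flipped.bases)
    fwd_min = base.bases[fwd_idx:] + base.bases[:fwd_idx]
    rev_min = flipped.bases[rev_idx:] + flipped.bases[:rev_idx]
    if fwd_min <= rev_min:
        return base.rotate(fwd_idx)
    return flipped.rotate(rev_idx)


# ---------------------------------------------------------------------------
# Left normalization


def left_normalize(records: list[DifferenceRecord], ref: str) -> list[DifferenceRecord]:
    """Shift indels to their lowest equivalent reference coordinate.

    A deletion can move one base left when the reference base before it equals
    the last deleted base; an insertion when the reference base before the
    insertion point equals the last inserted base. The operation is idempotent
    and leaves substitutions untouched.
    """
    out = []
    for rec in records:
        if rec.kind == "deletion":
            pos, bases = rec.ref_position, rec.ref_bases
            while pos > 0 and ref[pos - 1] == bases[-1]:
                pos -= 1
                bases = ref[pos] + bases[:-1]
            rec = replace(rec, ref_position=pos, ref_bases=bases)
        elif rec.kind == "insertion":
            pos, bases = rec.ref_position, rec.query_bases
            while pos > 0 and ref[pos - 1] == bases[-1]:
                pos -= 1
                bases = ref[pos] + bases[:-1]
            rec = replace(rec, ref_position=pos, query_bases=bases)
        out.append(rec)
    out.sort(key=lambda r: (r.ref_position, r.kind, r.query_bases, r.ref_bases))
    return out


# ---------------------------------------------------------------------------
# Applying / inverting difference streams


def apply_differences(ref: str, records: list[DifferenceRecord]) -> str:
    """Rebuild the query sequence by replaying records onto the reference."""
    pieces = []
    pos = 0
    for rec in sorted(records, key=lambda r: r.ref_position):
        if rec.ref_position < pos:
            raise ValueError(
                f"overlapping records at reference position {rec.ref_position}"
            )
        pieces.append(ref[pos : rec.ref_position])
        pos = rec.ref_position
        if rec.kind == "insertion":
            pieces.append(rec.query_bases)
        elif rec.kind == "deletion":
            if ref[pos : pos + len(rec.ref_bases)] != rec.ref_bases:
                raise ValueError(f"deletion bases mismatch at {pos}")
            pos += len(rec.ref_bases)
        else:
            if ref[pos : pos + len(rec.ref_bases)] != rec.ref_bases:
                raise ValueError(f"substitution ref bases mismatch at {pos}")
            pieces.append(rec.query_bases)
            pos += len(rec.ref_bases)
    pieces.append(ref[pos:])
    return "".join(pieces)


def invert_records(records: list[DifferenceRecord]) -> list[DifferenceRecord]:
    """Re-express records in query coordinates so they map query back to ref.

    ``apply_differences(apply_differences(ref, R), invert_records(R)) == ref``.
    """
    out = []
    delta = 0  # query_pos - ref_pos so far
    for rec in sorted(records, key=lambda r: r.ref_position):
        qpos = rec.ref_position + delta
        if rec.kind == "insertion":
            out.append(
                DifferenceRecord(qpos, "deletion", ref_bases=rec.query_bases)
            )
            delta += len(rec.query_bases)
        elif rec.kind == "deletion":
            out.append(
                DifferenceRecord(qpos, "insertion", query_bases=rec.ref_bases)
            )
            delta -= len(rec.ref_bases)
        else:
            out.append(
                DifferenceRecord(
                    qpos,
                    "substitution",
                    ref_bases=rec.query_bases,
                    query_bases=rec.ref_bases,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Native alignment: unique-k-mer chaining + banded gap closure


def _unique_kmers(bases: str, k: int) -> dict[str, int]:
    counts: Counter[str] = Counter()
    for i in range(len(bases) - k + 1):
        counts[bases[i : i + k]] += 1
    return {
        bases[i : i + k]: i
        for i in range(len(bases) - k + 1)
        if counts[bases[i : i + k]] == 1
    }


def _chain_anchors(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest increasing subsequence on query position, ties leftmost-ref."""
    if not pairs:
        return []
    pairs.sort()  # by ref, then query: leftmost-ref tie-break is implicit
    tails: list[int] = []  # query positions
    tails_idx: list[int] = []
    prev = [-1] * len(pairs)
    for i, (_, q) in enumerate(pairs):
        j = bisect_left(tails, q)
        if j == len(tails):
            tails.append(q)
            tails_idx.append(i)
        else:
            tails[j] = q
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    i = tails_idx[-1]
    while i != -1:
        chain.append(pairs[i])
        i = prev[i]
    return chain[::-1]


_CIG_RE = re.compile(r"(\d+)([=XID])")


def _edlib_ops(ref_seg: str, qry_seg: str) -> list[tuple[int, str]]:
    """(length, op) list for a global alignment of the two segments."""
    if not ref_seg and not qry_seg:
        return []
    if not ref_seg:
        return [(len(qry_seg), "I")]
    if not qry_seg:
        return [(len(ref_seg), "D")]
    res = edlib.align(qry_seg, ref_seg, mode="NW", task="path")
    return [(int(n), op) for n, op in _CIG_RE.findall(res["cigar"])]


class _Builder:
    """Accumulates blocks, records and segments while walking an alignment."""

    def __init__(self, segment_min: int):
        self.segment_min = segment_min
        self.blocks: list[Block] = []
        self.records: list[DifferenceRecord] = []
        self.segments: list[Segment] = []
        self._open: list[int] | None = None  # [ref_start, query_start]
        self.ref_pos = 0
        self.query_pos = 0

    def open_block(self) -> None:
        if self._open is None:
            self._open = [self.ref_pos, self.query_pos]

    def close_block(self) -> None:
        if self._open is not None:
            rs, qs = self._open
            if self.ref_pos > rs or self.query_pos > qs:
                self.blocks.append(Block(rs, self.ref_pos, qs, self.query_pos))
            self._open = None

    def match(self, n: int) -> None:
        self.open_block()
        self.ref_pos += n
        self.query_pos += n

    def substitution(self, ref_bases: str, query_bases: str) -> None:
        self.open_block()
        # one record per substituted base, matching cs-token granularity
        for i, (r, q) in enumerate(zip(ref_bases, query_bases)):
            self.records.append(
                DifferenceRecord(self.ref_pos + i, "substitution", ref_bases=r, query_bases=q)
            )
        self.ref_pos += len(ref_bases)
        self.query_pos += len(query_bases)

    def insertion(self, bases: str) -> None:
        if len(bases) >= self.segment_min:
            self.close_block()
            self.segments.append(
                Segment("query", self.query_pos, self.query_pos + len(bases))
            )
        else:
            self.open_block()
            self.records.append(
                DifferenceRecord(self.ref_pos, "insertion", query_bases=bases)
            )
        self.query_pos += len(bases)

    def deletion(self, bases: str) -> None:
        if len(bases) >= self.segment_min:
            self.close_block()
            self.segments.append(
                Segment("ref", self.ref_pos, self.ref_pos + len(bases))
            )
        else:
            self.open_block()
            self.records.append(
                DifferenceRecord(self.ref_pos, "deletion", ref_bases=bases)
            )
        self.ref_pos += len(bases)

    def skip_unaligned(self, ref_len: int, query_len: int) -> None:
        self.close_block()
        if ref_len:
            self.segments.append(Segment("ref", self.ref_pos, self.ref_pos + ref_len))
        if query_len:
            self.segments.append(
                Segment("query", self.query_pos, self.query_pos + query_len)
            )
        self.ref_pos += ref_len
        self.query_pos += query_len

    def walk_ops(self, ref: str, query: str, ops: list[tuple[int, str]]) -> None:
        for n, op in ops:
            if op == "=":
                self.match(n)
            elif op == "X":
                self.substitution(
                    ref[self.ref_pos : self.ref_pos + n],
                    query[self.query_pos : self.query_pos + n],
                )
            elif op == "I":
                self.insertion(query[self.query_pos : self.query_pos + n])
            elif op == "D":
                self.deletion(ref[self.ref_pos : self.ref_pos + n])
            else:  # pragma: no cover
                raise ValueError(f"unexpected alignment op {op!r}")


def _best_rotation(pairs: list[tuple[int, int]], qlen: int) -> int:
    """Query rotation that maximizes the colinear anchor chain.

    Candidate rotations are zero plus the most-voted (ref_pos - query_pos)
    offsets over shared unique k-mers; the winner is whichever yields the
    longest increasing chain, so insertions or small indel drift (which split
    the offset votes without breaking colinearity) never trigger a spurious
    rotation. Equivalent to matching against a doubled reference and reducing
    hit positions modulo the length.
    """
    if not pairs:
        return 0
    votes = Counter((r - q) % qlen for r, q in pairs)
    candidates = {0} | {
        (-off) % qlen for off, _ in votes.most_common(5)
    }
    best_rot, best_len = 0, -1
    for rot in sorted(candidates):
        shifted = [(r, (q - rot) % qlen) for r, q in pairs]
        chain_len = len(_chain_anchors(shifted))
        if chain_len > best_len:
            best_rot, best_len = rot, chain_len
    return best_rot


def align_assemblies(
    ref: CircularSequence,
    query: CircularSequence,
    k: int = 15,
    segment_min: int = DEFAULT_SEGMENT_MIN,
    band_limit: int = BAND_LIMIT,
) -> DifferenceSet:
    """Base-level comparison of two assemblies of the same molecule.

    Anchors are k-mers unique in both sequences; the best colinear chain
    (longest increasing subsequence, leftmost-reference tie-break) defines
    aligned blocks, and inter-anchor gaps are closed by global alignment.
    Gaps whose length difference exceeds ``band_limit`` are reported as
    unaligned segments instead of being force-aligned, as are indel runs of
    ``segment_min`` bp or more. For circular inputs whose rotations differ,
    the query is first rotated by the modal anchor offset (equivalent to
    matching against a doubled reference and reducing positions modulo the
    length); the rotation used is recorded on the result.
    """
    if len(ref) == 0 or len(query) == 0:
        raise AlignmentFailure("empty input sequence", degenerate=True)
    if not (1 / 3 <= len(query) / len(ref) <= 3):
        raise AlignmentFailure(
            f"length ratio {len(query)/len(ref):.2f} outside [1/3, 3]", degenerate=True
        )

    ref_k = _unique_kmers(ref.bases, k)
    qry_k = _unique_kmers(query.bases, k)
    pairs = [(ref_k[m], qry_k[m]) for m in ref_k.keys() & qry_k.keys()]

    query_rotation = 0
    qbases = query.bases
    if ref.circular and query.circular and pairs:
        query_rotation = _best_rotation(pairs, len(qbases))
        if query_rotation:
            qbases = qbases[query_rotation:] + qbases[:query_rotation]
            qry_k = _unique_kmers(qbases, k)
            pairs = [
                (ref_k[m], qry_k[m]) for m in ref_k.keys() & qry_k.keys()
            ]
    if not pairs:
        raise AlignmentFailure(
            "no shared unique k-mer anchors (homology too low)", degenerate=False
        )
    chain = _chain_anchors(pairs)

    b = _Builder(segment_min)
    # walk gap-anchor-gap...; consecutive anchors may overlap by up to k-1 bp
    prev_r, prev_q = 0, 0
    for r, q in chain:
        d_r, d_q = r - prev_r, q - prev_q
        if d_r < 0 or d_q < 0:
            if d_r == d_q:  # same diagonal: extend the running match
                ext = r + k - prev_r
                if ext > 0:
                    b.match(ext)
                    prev_r += ext
                    prev_q += ext
            # off-diagonal overlap: drop the anchor, the gap logic handles it
            continue
        gap_r = ref.bases[prev_r:r]
        gap_q = qbases[prev_q:q]
        if gap_r or gap_q:
            if abs(len(gap_r) - len(gap_q)) > band_limit:
                b.skip_unaligned(len(gap_r), len(gap_q))
            else:
                b.walk_ops(ref.bases, qbases, _edlib_ops(gap_r, gap_q))
        b.match(k)
        prev_r, prev_q = r + k, q + k
    tail_r = ref.bases[prev_r:]
    tail_q = qbases[prev_q:]
    if tail_r or tail_q:
        if abs(len(tail_r) - len(tail_q)) > band_limit:
            b.skip_unaligned(len(tail_r), len(tail_q))
        else:
            b.walk_ops(ref.bases, qbases, _edlib_ops(tail_r, tail_q))
    b.close_block()

    records = left_normalize(b.records, ref.bases)
    return DifferenceSet(
        reference_name=ref.name,
        query_name=query.name,
        aligned_blocks=_merge_blocks(b.blocks),
        records=records,
        unaligned_segments=sorted(b.segments, key=lambda s: (s.owner, s.start)),
        query_rotation=query_rotation,
    )


def _merge_blocks(blocks: list[Block]) -> list[Block]:
    """Merge abutting colinear blocks (same diagonal, contiguous on both)."""
    merged: list[Block] = []
    for blk in sorted(blocks, key=lambda x: x.ref_start):
        if (
            merged
            and merged[-1].ref_end == blk.ref_start
            and merged[-1].query_end == blk.query_start
        ):
            last = merged.pop()
            blk = Block(last.ref_start, blk.ref_end, last.query_start, blk.query_end)
        merged.append(blk)
    return merged


# ---------------------------------------------------------------------------
# PAF + cs route

_CS_TOKEN = re.compile(r"(:\d+)|(\*[a-zA-Z]{2})|(\+[a-zA-Z]+)|(-[a-zA-Z]+)|(~[a-zA-Z0-9]+)")


def differences_from_paf(
    alignments: list[AlignmentRecord],
    ref: CircularSequence,
    query: CircularSequence,
    segment_min: int = DEFAULT_SEGMENT_MIN,
) -> DifferenceSet:
    """Convert PAF + cs alignments into the same DifferenceSet the native
    aligner produces, so the two routes are interchangeable.

    All alignments must pair the given reference (PAF target) and query, carry
    cs difference strings, and be on the plus strand (normalize both
    assemblies to the same canonical rotation/strand first). The cs token walk
    is validated against the stated start/end coordinates; regions of either
    sequence covered by no alignment become unaligned segments.
    """
    if not alignments:
        raise FormatError("no alignments supplied")
    b = _Builder(segment_min)
    all_records: list[DifferenceRecord] = []
    blocks: list[Block] = []
    segments: list[Segment] = []
    ref_cov: list[tuple[int, int]] = []
    qry_cov: list[tuple[int, int]] = []

    for aln in sorted(alignments, key=lambda a: a.target_start):
        if aln.target_name != ref.name or aln.query_name != query.name:
            raise FormatError(
                f"alignment pairs {aln.query_name}->{aln.target_name}, expected "
                f"{query.name}->{ref.name}"
            )
        if not aln.has_cs:
            raise FormatError("alignment lacks a cs difference string")
        if aln.strand != "+":
            raise FormatError(
                "minus-strand alignment: normalize both assemblies to the same "
                "strand before parsing differences"
            )
        b = _Builder(segment_min)
        b.ref_pos, b.query_pos = aln.target_start, aln.query_start
        consumed = 0
        for m in _CS_TOKEN.finditer(aln.difference_string):
            tok = m.group(0)
            if m.start() != consumed:
                raise FormatError(
                    f"unparseable cs content at offset {consumed}: "
                    f"{aln.difference_string[consumed:m.start()]!r}"
                )
            consumed = m.end()
            if tok[0] == ":":
                b.match(int(tok[1:]))
            elif tok[0] == "*":
                r, q = tok[1].upper(), tok[2].upper()
                if ref.bases[b.ref_pos] != r:
                    raise FormatError(
                        f"cs substitution base {r} != reference base "
                        f"{ref.bases[b.ref_pos]} at {b.ref_pos} (token offset {m.start()})"
                    )
                b.substitution(r, q)
            elif tok[0] == "+":
                b.insertion(tok[1:].upper())
            elif tok[0] == "-":
                b.deletion(tok[1:].upper())
            else:
                raise FormatError(f"intron cs token unsupported: {tok!r}")
        if consumed != len(aln.difference_string):
            raise FormatError(
                f"trailing cs content at offset {consumed}: "
                f"{aln.difference_string[consumed:]!r}"
            )
        b.close_block()
        if (b.ref_pos, b.query_pos) != (aln.target_end, aln.query_end):
            raise FormatError(
                f"cs walk ends at ({b.ref_pos}, {b.query_pos}), PAF states "
                f"({aln.target_end}, {aln.query_end})"
            )
        all_records.extend(b.records)
        blocks.extend(b.blocks)
        segments.extend(b.segments)
        ref_cov.append((aln.target_start, aln.target_end))
        qry_cov.append((aln.query_start, aln.query_end))

    segments.extend(_uncovered("ref", ref_cov, len(ref)))
    segments.extend(_uncovered("query", qry_cov, len(query)))
    records = left_normalize(all_records, ref.bases)
    return DifferenceSet(
        reference_name=ref.name,
        query_name=query.name,
        aligned_blocks=_merge_blocks(blocks),
        records=records,
        unaligned_segments=sorted(set(segments), key=lambda s: (s.owner, s.start)),
    )


def _uncovered(owner: str, spans: list[tuple[int, int]], length: int) -> list[Segment]:
    out = []
    pos = 0
    for s, e in sorted(spans):
        if s > pos:
            out.append(Segment(owner, pos, s))
        pos = max(pos, e)
    if pos < length:
        out.append(Segment(owner, pos, length))
    return out
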