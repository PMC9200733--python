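"""Error classification, homopolymer attribution and consensus QV arithmetic.

Nanopore consensus errors are dominated by single-base indels concentrated in
homopolymer runs. This module turns a stream of classified assembly
differences into the summary statistics that describe that error structure:
counts by error-type label, the single-base-indel and T/A-indel fractions,
the fraction of errors falling in homopolymer regions, an indel-count by
run-length table, and the Phred-scaled consensus quality

    QV = -10 * log10(n_errors / assembly_length)

whose inverse 10^(QV/10) is the mean spacing between errors in bp (QV 30 is
one error per 1,000 bp).
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, replace

from .records import DifferenceRecord
from .sequences import CircularSequence, homopolymer_run

__all__ = [
    "ErrorProfile",
    "DEFAULT_MIN_RUN",
    "attribute_homopolymer",
    "summarize_profile",
    "qv_from_errors",
    "compare_before_after",
]

#: Minimum identical-base run length that counts as a "homopolymer region".
#: Runs of 2 are so frequent in random sequence (~37% of positions) that they
#: would make the in-homopolymer fraction uninformative.
DEFAULT_MIN_RUN = 3


@dataclass
class ErrorProfile:
    """Aggregated error statistics for one draft-vs-truth comparison."""

    n_total: int
    assembly_length: int
    counts_by_label: dict[str, int]
    fraction_single_base_indel: float
    fraction_TA_single_indel: float
    fraction_in_homopolymer: float
    indel_by_runlength: dict[int, dict[str, int]]
    qv: float
    qv_is_lower_bound: bool
    min_run: int = DEFAULT_MIN_RUN

    @property
    def bases_per_error(self) -> float:
        return 10 ** (self.qv / 10)

    def plot_labels(self, min_count: int = 3) -> dict[str, int]:
        """Label counts with rare labels (count < min_count) dropped.

        This is a *view* for plotting; every fraction in the profile is
        computed over all records.
        """
        return {k: v for k, v in self.counts_by_label.items() if v >= min_count}

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "assembly_length": self.assembly_length,
            "counts_by_label": dict(sorted(self.counts_by_label.items())),
            "fraction_single_base_indel": self.fraction_single_base_indel,
            "fraction_TA_single_indel": self.fraction_TA_single_indel,
            "fraction_in_homopolymer": self.fraction_in_homopolymer,
            "indel_by_runlength": {
                str(k): dict(sorted(v.items()))
                for k, v in sorted(self.indel_by_runlength.items())
            },
            "qv": self.qv,
            "qv_is_lower_bound": self.qv_is_lower_bound,
            "bases_per_error": self.bases_per_error,
            "min_run": self.min_run,
        }


def attribute_homopolymer(
    seq: CircularSequence | str,
    record: DifferenceRecord,
    min_run: int = DEFAULT_MIN_RUN,
) -> DifferenceRecord:
    """Fill in the homopolymer context (``hp_base``, ``hp_len``) of a record.

    For a substitution the context is the maximal run containing the
    substituted position. For an indel it is the maximal run adjacent to the
    locus whose base equals the inserted/deleted base (an indel extends or
    shrinks that run). Records with no matching adjacent run get
    ``hp_len = 1``. A record is *in* a homopolymer iff ``hp_len >= min_run``.
    """
    bases = seq.bases if isinstance(seq, CircularSequence) else seq
    pos = record.ref_position
    if not 0 <= pos <= len(bases):
        raise IndexError(f"record position {pos} outside sequence")
    if record.kind == "substitution":
        base, _, run_len = homopolymer_run(bases, pos)
        return replace(record, hp_base=base, hp_len=run_len)
    # indel: the relevant base is the first inserted/deleted one
    b = (record.query_bases or record.ref_bases)[0]
    best = 1
    if pos < len(bases) and bases[pos] == b:
        best = max(best, homopolymer_run(bases, pos)[2])
    if pos > 0 and bases[pos - 1] == b:
        best = max(best, homopolymer_run(bases, pos - 1)[2])
    return replace(record, hp_base=b, hp_len=best)


def in_homopolymer(record: DifferenceRecord, min_run: int = DEFAULT_MIN_RUN) -> bool:
    return record.hp_len >= min_run


def qv_from_errors(
    n_errors: int, assembly_length: int
) -> tuple[float, float, bool]:
    """Consensus QV and mean error spacing from an error count.

    Returns ``(qv, bases_per_error, is_lower_bound)``. Zero errors cannot be
    distinguished from "fewer than one error in L bases", so the QV is capped
    at ``-10*log10(1/L)`` and flagged as a lower bound.
    """
    if assembly_length <= 0:
        raise ValueError("assembly_length must be positive")
    if n_errors < 0:
        raise ValueError("n_errors must be non-negative")
    if n_errors == 0:
        qv = -10 * math.log10(1 / assembly_length)
        return qv, float(assembly_length), True
    qv = -10 * math.log10(n_errors / assembly_length)
    return qv, assembly_length / n_errors, False


def summarize_profile(
    records: list[DifferenceRecord],
    assembly_length: int,
    min_run: int = DEFAULT_MIN_RUN,
    seq: CircularSequence | str | None = None,
) -> ErrorProfile:
    """Aggregate classified differences into an :class:`ErrorProfile`.

    If ``seq`` is given, homopolymer context is (re)computed for records that
    lack it. All fractions use ``n_total`` as denominator; the single-base
    indel fraction counts indels of size exactly 1, and the T/A fraction
    counts single-base indels whose base is T or A — both as shares of *all*
    errors.
    """
    if assembly_length <= 0:
        raise ValueError("assembly_length must be positive")
    if seq is not None:
        records = [
            attribute_homopolymer(seq, r, min_run) if r.hp_len == 0 else r
            for r in records
        ]
    n = len(records)
    counts: Counter[str] = Counter(r.type_label for r in records)
    single_indel = [r for r in records if r.is_indel and r.size == 1]
    ta = [r for r in single_indel if r.indel_base in ("T", "A")]
    in_hp = [r for r in records if r.hp_len >= min_run]
    by_run: dict[int, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for r in single_indel:
        by_run[max(r.hp_len, 1)][r.indel_base] += 1
    qv, _, lower = qv_from_errors(n, assembly_length)
    return ErrorProfile(
        n_total=n,
        assembly_length=assembly_length,
        counts_by_label=dict(counts),
        fraction_single_base_indel=len(single_indel) / n if n else 0.0,
        fraction_TA_single_indel=len(ta) / n if n else 0.0,
        fraction_in_homopolymer=len(in_hp) / n if n else 0.0,
        indel_by_runlength={k: dict(v) for k, v in sorted(by_run.items())},
        qv=qv,
        qv_is_lower_bound=lower,
        min_run=min_run,
    )


def compare_before_after(
    draft: CircularSequence,
    polished: CircularSequence,
    aligner=None,
) -> int:
    """Count modified sites between a draft and its polished assembly.

    Each difference record counts as one modified site regardless of size.
    Both sequences must carry a normalization record (same canonical
    rotation/strand) when circular, otherwise position-based comparison is
    meaningless and the call refuses.
    """
    from .align import align_assemblies

    if draft.circular and polished.circular:
        if not (draft.normalized and polished.normalized):
            raise ValueError(
                "circular inputs must be normalized to the same rotation/strand "
                "first (apply canonical_rotation with a shared anchor)"
            )
    align = aligner or align_assemblies
    diffs = align(draft, polished)
    return diffs.n_records
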