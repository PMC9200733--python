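import subprocess

import numpy as np
import pytest

from mitoqc import io as mio
from mitoqc.align import (
    AlignmentFailure,
    AnchorNotFound,
    align_assemblies,
    apply_differences,
    canonical_rotation,
    differences_from_paf,
    left_normalize,
)
from mitoqc.records import DifferenceRecord
from mitoqc.sequences import CircularSequence, reverse_complement

from .conftest import random_seq


def record_keys(diffset_or_records):
    records = getattr(diffset_or_records, "records", diffset_or_records)
    return {(r.ref_position, r.kind, r.ref_bases, r.query_bases) for r in records}


def spaced_edits(rng, seq, n, min_gap=12):
    """n random single-base edits at positions >= min_gap apart."""
    positions = np.sort(
        rng.choice(np.arange(50, len(seq) - 50, min_gap), size=n, replace=False)
    )
    records = []
    for p in positions:
        p = int(p)
        kind = int(rng.integers(3))
        if kind == 0:
            alt = "ACGT".replace(seq[p], "")[int(rng.integers(3))]
            records.append(
                DifferenceRecord(p, "substitution", ref_bases=seq[p], query_bases=alt)
            )
        elif kind == 1:
            records.append(DifferenceRecord(p, "insertion", query_bases=seq[p]))
        else:
            records.append(DifferenceRecord(p, "deletion", ref_bases=seq[p]))
    return left_normalize(records, seq)


class TestCanonicalRotation:
    def test_anchor_rotation(self):
        seq = CircularSequence("x", "GCAT", circular=True)
        out = canonical_rotation(seq, anchor="ATGC")
        assert out.bases == "ATGC" and out.applied_rotation == 2

    def test_reverse_complement_input_yields_same_form(self, rng):
        genome = CircularSequence("g", random_seq(rng, 3000), circular=True)
        anchor = genome.bases[500:525]
        fwd = canonical_rotation(genome, anchor=anchor)
        flipped_input = CircularSequence(
            "g_rc", reverse_complement(genome.bases), circular=True
        )
        rev = canonical_rotation(flipped_input, anchor=anchor)
        assert rev.bases == fwd.bases
        assert rev.applied_strand_flip != fwd.applied_strand_flip

    def test_minimal_rotation_example(self):
        out = canonical_rotation(CircularSequence("x", "CAAC", circular=True))
        assert out.bases == "AACC"  # revcomp GTTG also considered; AACC wins

    def test_minimal_rotation_matches_brute_force(self, rng):
        for _ in range(100):
            s = random_seq(rng, int(rng.integers(4, 30)))
            seq = CircularSequence("x", s, circular=True)
            out = canonical_rotation(seq)
            candidates = [
                t[i:] + t[:i]
                for t in (s, reverse_complement(s))
                for i in range(len(s))
            ]
            assert out.bases == min(candidates)

    def test_anchor_not_found_raises(self):
        seq = CircularSequence("x", "AAAACCCC", circular=True)
        with pytest.raises(AnchorNotFound):
            canonical_rotation(seq, anchor="GATC")  # absent on both strands

    def test_anchor_with_mismatch_allowance(self):
        seq = CircularSequence("x", "TTTTACGTACGT", circular=True)
        out = canonical_rotation(seq, anchor="ACGA", max_mismatches=1)
        assert out.bases.startswith("ACGT")


class TestAlignAssemblies:
    def test_identical_sequences_single_block(self, rng):
        s = random_seq(rng, 16_000)
        a = CircularSequence("a", s)
        b = CircularSequence("b", s)
        d = align_assemblies(a, b)
        assert d.records == [] and d.unaligned_segments == []
        assert len(d.aligned_blocks) == 1
        blk = d.aligned_blocks[0]
        assert (blk.ref_start, blk.ref_end) == (0, 16_000)

    def test_recovers_spaced_truth_exactly(self, rng):
        seq = random_seq(rng, 8000, at=0.66)
        truth = spaced_edits(rng, seq, 50)
        query = apply_differences(seq, truth)
        d = align_assemblies(
            CircularSequence("r", seq), CircularSequence("q", query)
        )
        assert record_keys(d) == record_keys(truth)

    def test_rotation_invariance_after_normalization(self, sim_pair):
        genome, corrupted, truth = sim_pair
        # anchor from a stretch free of injected errors so it exists verbatim
        # in both assemblies
        positions = sorted(r.ref_position for r in truth)
        start = next(
            s for s in range(100, len(genome) - 100, 50)
            if not any(s - 10 <= p <= s + 40 for p in positions)
        )
        anchor = genome.bases[start : start + 30]
        base = align_assemblies(
            canonical_rotation(genome, anchor), canonical_rotation(corrupted, anchor)
        )
        d = align_assemblies(
            canonical_rotation(genome, anchor),
            canonical_rotation(corrupted.rotate(4000), anchor),
        )
        assert record_keys(d) == record_keys(base)

    def test_auto_rotation_of_unnormalized_circular_query(self, sim_pair):
        """A grossly rotated circular query is detected and realigned; the
        recorded internal rotation makes the difference stream reconstruct it."""
        genome, corrupted, _ = sim_pair
        rotated = corrupted.rotate(4000)
        d = align_assemblies(genome, rotated)
        assert d.query_rotation != 0
        rebuilt = apply_differences(genome.bases, d.records)
        expected = rotated.bases[d.query_rotation :] + rotated.bases[: d.query_rotation]
        assert rebuilt == expected

    def test_rotated_identical_query_zero_records(self, sim_genome):
        genome, _ = sim_genome
        d = align_assemblies(genome, genome.rotate(4000))
        assert d.records == []

    def test_reconstruction_over_full_alignment(self, sim_pair):
        genome, corrupted, _ = sim_pair
        d = align_assemblies(genome, corrupted)
        assert apply_differences(genome.bases, d.records) == corrupted.bases

    def test_symmetry_of_indel_counts(self, rng):
        seq = random_seq(rng, 5000)
        truth = spaced_edits(rng, seq, 30)
        query = apply_differences(seq, truth)
        fwd = align_assemblies(CircularSequence("r", seq), CircularSequence("q", query))
        rev = align_assemblies(CircularSequence("q", query), CircularSequence("r", seq))
        n_ins_fwd = sum(r.kind == "insertion" for r in fwd.records)
        n_del_rev = sum(r.kind == "deletion" for r in rev.records)
        assert n_ins_fwd == n_del_rev

    def test_no_homology_fails_distinctly(self, rng):
        a = CircularSequence("a", "AT" * 2000)
        b = CircularSequence("b", "GC" * 2000)
        with pytest.raises(AlignmentFailure):
            align_assemblies(a, b)

    def test_length_ratio_guard(self):
        with pytest.raises(AlignmentFailure):
            align_assemblies(
                CircularSequence("a", "ACGT" * 1000), CircularSequence("b", "ACGT" * 10)
            )


class TestLeftNormalize:
    def test_shifts_deletion_to_run_start(self):
        #        0123456
        ref = "GGAAAAC"
        rec = DifferenceRecord(5, "deletion", ref_bases="A")
        (out,) = left_normalize([rec], ref)
        assert out.ref_position == 2

    def test_shifts_insertion_through_repeat(self):
        ref = "GGATATC"
        rec = DifferenceRecord(6, "insertion", query_bases="AT")
        (out,) = left_normalize([rec], ref)
        assert out.ref_position == 2 and out.query_bases == "AT"

    def test_idempotent(self, rng):
        seq = random_seq(rng, 2000)
        records = spaced_edits(rng, seq, 30)
        once = left_normalize(records, seq)
        assert left_normalize(once, seq) == once


class TestDifferencesFromPaf:
    def _aln(self, cs, target_end, query_end, tlen=100, qlen=100):
        return mio.AlignmentRecord(
            query_name="q", query_length=qlen, query_start=0, query_end=query_end,
            strand="+", target_name="r", target_length=tlen,
            target_start=0, target_end=target_end,
            residue_matches=90, block_length=100, mapping_quality=60,
            difference_string=cs,
        )

    def test_pure_match_token(self, rng):
        s = random_seq(rng, 100)
        ref = CircularSequence("r", s)
        qry = CircularSequence("q", s)
        d = differences_from_paf([self._aln(":100", 100, 100)], ref, qry)
        assert d.records == []
        assert len(d.aligned_blocks) == 1 and d.aligned_blocks[0].ref_end == 100

    def test_substitution_token_semantics(self):
        ref = CircularSequence("r", "G" * 10 + "A" + "C" * 5)
        qry = CircularSequence("q", "G" * 10 + "T" + "C" * 5)
        d = differences_from_paf([self._aln(":10*at:5", 16, 16, 16, 16)], ref, qry)
        (rec,) = d.records
        assert (rec.ref_position, rec.kind, rec.ref_bases, rec.query_bases) == (
            10, "substitution", "A", "T",
        )

    def test_inconsistent_walk_rejected(self):
        ref = CircularSequence("r", "G" * 20)
        qry = CircularSequence("q", "G" * 20)
        with pytest.raises(mio.FormatError, match="cs walk ends"):
            differences_from_paf([self._aln(":15", 20, 20, 20, 20)], ref, qry)

    def test_minus_strand_refused(self):
        aln = mio.AlignmentRecord(
            "q", 10, 0, 10, "-", "r", 10, 0, 10, 10, 10, 60, difference_string=":10"
        )
        ref = CircularSequence("r", "ACGTACGTAC")
        with pytest.raises(mio.FormatError, match="strand"):
            differences_from_paf([aln], ref, CircularSequence("q", "ACGTACGTAC"))


@pytest.mark.parametrize("seed", [0, 1])
def test_native_alignment_matches_external_aligner(tmp_path, seed):
    """Native difference calls equal minimap2 cs-derived calls after
    left-normalization on a simulated pair (deep version in acceptance)."""
    rng = np.random.default_rng(seed)
    seq = random_seq(rng, 5000, at=0.6)
    truth = spaced_edits(rng, seq, 30)
    query = apply_differences(seq, truth)
    ref = CircularSequence("ref", seq)
    qry = CircularSequence("qry", query)
    ref_fa, qry_fa = tmp_path / "r.fa", tmp_path / "q.fa"
    mio.write_fasta(ref_fa, [ref])
    mio.write_fasta(qry_fa, [qry])
    paf = tmp_path / "a.paf"
    with open(paf, "w") as out:
        subprocess.run(
            ["minimap2", "-x", "asm5", "--cs", str(ref_fa), str(qry_fa)],
            stdout=out, stderr=subprocess.DEVNULL, check=True,
        )
    external = differences_from_paf(mio.read_paf(paf), ref, qry)
    native = align_assemblies(ref, qry)
    assert record_keys(native) == record_keys(external) == record_keys(truth)
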