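import dataclasses

import numpy as np
import pytest

from mitoqc import (
    CircularSequence,
    align_assemblies,
    completeness_check,
    control_region_length,
    count_premature_stops,
    detect_unique_segments,
    gene_order_breakpoints,
    n50,
    window_stats,
)
from mitoqc.align import apply_differences
from mitoqc.records import GeneAnnotation
from mitoqc.sequences import reverse_complement
from mitoqc.structure import accession_report

from .conftest import make_order, random_seq


class TestWindowStats:
    def test_all_A(self):
        track = window_stats("A" * 100, window=50)
        assert [r.at_fraction for r in track.rows] == [1.0, 1.0]
        assert not track.final_partial

    def test_balanced_repeat(self):
        track = window_stats("ATGC" * 25, window=20)
        assert [r.at_fraction for r in track.rows] == [0.5] * 5

    def test_final_partial_window_flagged(self):
        track = window_stats("ATGC" * 30, window=50)
        assert track.final_partial and track.rows[-1].end - track.rows[-1].start == 20

    def test_matches_brute_force(self, rng):
        seq = random_seq(rng, 5000, at=0.66)
        track = window_stats(seq, window=50)
        for row in track.rows:
            chunk = seq[row.start : row.end]
            at = sum(c in "AT" for c in chunk)
            acgt = sum(c in "ACGT" for c in chunk)
            assert row.at_fraction == pytest.approx(at / acgt)

    def test_ambiguity_codes_excluded_both_sides(self):
        track = window_stats("AT" + "N" * 48, window=50)
        assert track.rows[0].at_fraction == 1.0

    def test_reverse_complement_symmetry(self, rng):
        seq = random_seq(rng, 2000, at=0.6)
        fwd = window_stats(seq, window=50).at_values()
        rev = window_stats(reverse_complement(seq), window=50).at_values()
        assert np.allclose(fwd, rev[::-1])

    def test_depth_averaging_and_length_check(self, rng):
        depth = np.arange(100, dtype=float)
        track = window_stats("A" * 100, window=50, depth=depth)
        assert [r.depth for r in track.rows] == [24.5, 74.5]
        with pytest.raises(ValueError, match="depth"):
            window_stats("A" * 100, window=50, depth=depth[:50])


class TestUniqueSegments:
    def test_identical_assemblies_empty(self, rng):
        s = random_seq(rng, 5000)
        d = align_assemblies(CircularSequence("a", s), CircularSequence("b", s))
        assert detect_unique_segments(d) == []

    def test_at_rich_insertion_recovered(self, sim_genome, rng):
        genome, _ = sim_genome
        insert = random_seq(rng, 2000, at=0.987)
        qbases = genome.bases[:8000] + insert + genome.bases[8000:]
        query = CircularSequence("q", qbases, circular=True)
        d = align_assemblies(genome, query)
        segs = detect_unique_segments(d, min_length=500, ref=genome, query=query)
        assert len(segs) == 1
        (seg,) = segs
        assert seg.owner == "query"
        assert abs(seg.start - 8000) <= 10 and abs(seg.end - 10_000) <= 10
        injected_at = sum(c in "AT" for c in insert) / len(insert)
        assert seg.at_fraction == pytest.approx(injected_at, abs=0.02)

    def test_min_length_threshold_filters(self, sim_genome, rng):
        genome, _ = sim_genome
        ins_a = random_seq(rng, 868, at=0.9)
        ins_b = random_seq(rng, 300, at=0.9)
        qbases = (
            genome.bases[:4000] + ins_a + genome.bases[4000:9000] + ins_b
            + genome.bases[9000:]
        )
        query = CircularSequence("q", qbases, circular=True)
        d = align_assemblies(genome, query)
        segs = detect_unique_segments(d, min_length=500, ref=genome, query=query)
        assert len(segs) == 1 and segs[0].length == pytest.approx(868, abs=10)

    def test_flanking_genes_reported(self, sim_genome, rng):
        genome, annotations = sim_genome
        # delete 500 bp from the reference's view: query lacks a ref chunk
        qbases = genome.bases[:6000] + genome.bases[6500:]
        query = CircularSequence("q", qbases, circular=True)
        d = align_assemblies(genome, query)
        segs = detect_unique_segments(
            d, min_length=300, ref=genome, query=query, annotations=annotations
        )
        assert len(segs) == 1 and segs[0].owner == "ref"
        left, right = segs[0].flanking_genes
        assert left is not None and right is not None


class TestN50:
    def test_single_read(self):
        assert n50([100]) == 100

    def test_half_total_reached_by_longest(self):
        assert n50([1, 1, 1, 1, 4]) == 4

    def test_matches_brute_force(self, rng):
        for _ in range(100):
            lengths = [int(x) for x in rng.integers(1, 500, size=rng.integers(1, 40))]
            total = sum(lengths)
            candidates = [
                l for l in lengths
                if sum(x for x in lengths if x >= l) >= total / 2
            ]
            assert n50(lengths) == max(candidates)

    @pytest.mark.parametrize("k,l", [(1, 7), (5, 123), (50, 1)])
    def test_uniform_lengths(self, k, l):
        assert n50([l] * k) == l

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            n50([])


class TestCompleteness:
    def test_full_complement_complete(self, full_annotation_set):
        report = completeness_check(full_annotation_set)
        assert report.complete
        assert report.missing == [] and report.duplicated == {}

    def test_cfl_style_missing_genes(self, full_annotation_set):
        reduced = [
            a for a in full_annotation_set if a.name not in ("nad5", "trnH", "trnF")
        ]
        report = completeness_check(reduced)
        assert report.missing == ["nad5", "trnF", "trnH"]
        assert report.duplicated == {}

    def test_duplicated_gene_counted(self, full_annotation_set):
        extra = full_annotation_set + [
            GeneAnnotation("cox1", "PCG", 15_000, 15_100, "+")
        ]
        report = completeness_check(extra)
        assert report.duplicated == {"cox1": 2}

    def test_unrecognized_name_listed(self, full_annotation_set):
        odd = full_annotation_set + [GeneAnnotation("orfX", "other", 0, 10, "+")]
        report = completeness_check(odd)
        assert report.unrecognized == ["orfX"]

    def test_leucine_isoacceptors_interchangeable(self, full_annotation_set):
        # dropping trnL1 while keeping trnL2 leaves one missing leucine copy
        reduced = [a for a in full_annotation_set if a.name != "trnL1"]
        report = completeness_check(reduced)
        assert report.missing == ["trnL"]


class TestPrematureStops:
    def test_clean_cds(self):
        assert count_premature_stops("ATGTTTTAA") == (0, 1.0)

    def test_tga_is_tryptophan_under_table5(self):
        cds = "ATGTGATTTTAA"
        assert count_premature_stops(cds, code=5)[0] == 0
        assert count_premature_stops(cds, code=1)[0] == 1

    def test_frameshift_creates_stops_matching_oracle(self, rng):
        from Bio.Seq import Seq

        # stop-free 300-codon CDS, then delete one base at codon 100
        codons = []
        while len(codons) < 298:
            c = random_seq(rng, 3, at=0.6)
            if c not in ("TAA", "TAG"):
                codons.append(c)
        cds = "ATG" + "".join(codons) + "TAA"
        mutated = cds[:300] + cds[301:]
        n_stops, frac = count_premature_stops(mutated, code=5)
        n_codons = len(mutated) // 3
        oracle_aa = str(Seq(mutated[: n_codons * 3]).translate(table=5))
        assert n_stops == oracle_aa[:-1].count("*")
        assert 0 < frac <= 1

    def test_short_cds_rejected(self):
        with pytest.raises(ValueError):
            count_premature_stops("AT")

    def test_simulated_pcgs_are_stop_free(self, sim_genome):
        genome, annotations = sim_genome
        for a in annotations:
            if a.gene_class != "PCG":
                continue
            cds = genome.bases[a.start : a.end]
            if a.strand == "-":
                cds = reverse_complement(cds)
            assert count_premature_stops(cds, code=5) == (0, 1.0), a.name


def brute_force_adjacencies(order):
    """Oracle: signed adjacency multiset via doubled-extremity encoding."""
    adj = set()
    n = len(order)
    for i in range(n):
        g, sg = order[i]
        h, sh = order[(i + 1) % n]
        left = (g, "h" if sg > 0 else "t")
        right = (h, "t" if sh > 0 else "h")
        adj.add(frozenset([left, right]))
    return adj


class TestGeneOrder:
    def test_identical_orders(self, full_annotation_set):
        bp, shared, blocks = gene_order_breakpoints(
            full_annotation_set, full_annotation_set
        )
        assert bp == 0 and blocks == []
        assert shared == len(full_annotation_set)

    def test_toy_inversion_single_block(self):
        names = [f"g{i}" for i in range(8)]
        # canonical-vocabulary names are irrelevant here; use real gene names
        genes = ["cox1", "cox2", "atp6", "atp8", "nad1", "nad2", "nad3", "cob"]
        a = make_order([(g, "+") for g in genes])
        flipped = genes[:1] + genes[1:5][::-1] + genes[5:]
        strands = ["+"] + ["-"] * 4 + ["+"] * 3
        b = make_order(list(zip(flipped, strands)))
        bp, _, blocks = gene_order_breakpoints(a, b)
        assert len(blocks) == 1
        assert sorted(blocks[0]) == sorted(genes[1:5])
        # brute-force adjacency comparison
        oa = [(g, +1) for g in genes]
        ob = [(g, +1 if s == "+" else -1) for g, s in zip(flipped, strands)]
        assert bp == len(brute_force_adjacencies(oa) - brute_force_adjacencies(ob))

    def test_patellogastropoda_style_inversion(self):
        rest = ["cox2", "atp8", "atp6", "nad1", "nad2", "nad3",
                "nad4", "nad4L", "nad5", "nad6", "cob"]
        a = make_order([("cox1", "+"), ("cox3", "+")] + [(g, "+") for g in rest])
        b = make_order(
            [("cox1", "+"), ("cox3", "+")] + [(g, "-") for g in reversed(rest)]
        )
        bp, _, blocks = gene_order_breakpoints(a, b)
        assert len(blocks) == 1 and len(blocks[0]) == 11
        assert "cox1" not in blocks[0] and "cox3" not in blocks[0]

    def test_breakpoints_symmetric_and_rotation_invariant(self, rng):
        genes = ["cox1", "cox2", "cox3", "atp6", "atp8", "nad1",
                 "nad2", "nad3", "nad4", "cob"]
        for _ in range(25):
            pa = list(rng.permutation(genes))
            pb = list(rng.permutation(genes))
            sa = ["+" if rng.random() < 0.5 else "-" for _ in genes]
            sb = ["+" if rng.random() < 0.5 else "-" for _ in genes]
            a = make_order(list(zip(pa, sa)))
            b = make_order(list(zip(pb, sb)))
            bp_ab = gene_order_breakpoints(a, b)[0]
            bp_ba = gene_order_breakpoints(b, a)[0]
            assert bp_ab == bp_ba
            # rotate b's circular order
            k = int(rng.integers(1, len(genes)))
            rot = make_order(list(zip(pb[k:] + pb[:k], sb[k:] + sb[:k])))
            assert gene_order_breakpoints(a, rot)[0] == bp_ab
            # full reflection (reverse order, flip all strands)
            refl = make_order(
                [(g, "+" if s == "-" else "-") for g, s in zip(pb[::-1], sb[::-1])]
            )
            assert gene_order_breakpoints(a, refl)[0] == bp_ab

    def test_too_few_shared_genes(self):
        a = make_order([("cox1", "+"), ("cox2", "+")])
        b = make_order([("nad1", "+"), ("cox1", "+")])
        with pytest.raises(ValueError, match="shared"):
            gene_order_breakpoints(a, b)


class TestControlRegion:
    def test_circular_gap_between_trnF_and_cox3(self, sim_genome):
        genome, annotations = sim_genome
        cr = next(a for a in annotations if a.name == "control_region")
        length = control_region_length(annotations, len(genome))
        # the trnF->cox3 gap is the control region plus short intergenic spacers
        assert cr.end - cr.start <= length <= cr.end - cr.start + 60

    def test_wrapping_gap(self):
        ann = [
            GeneAnnotation("cox3", "PCG", 100, 880, "+"),
            GeneAnnotation("trnF", "tRNA", 15_800, 15_866, "+"),
        ]
        # 134 bp to the origin plus 100 bp beyond it
        assert control_region_length(ann, 16_000) == 234

    def test_missing_flank_rejected(self):
        ann = [GeneAnnotation("cox3", "PCG", 100, 880, "+")]
        with pytest.raises(ValueError, match="trnF"):
            control_region_length(ann, 16_000)


def test_accession_report_length_and_at(rng):
    # synthetic stand-in for a deposited mitogenome FASTA
    seq = CircularSequence("acc", random_seq(rng, 14_124, at=0.665), circular=True)
    report = accession_report(seq)
    assert report["length_bp"] == 14_124
    assert report["at_percent"] == pytest.approx(66.5, abs=1.0)
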