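"""Enhancer deserts, repressive coverage, target genes, adoption candidates."""

import numpy as np
import pytest

from riskloop.core import GenomicInterval, LoopRecord, Peak
from riskloop.loops import RiskLoop
from riskloop.peaks import GeneModel, HCPeakSet
from riskloop.regulatory import (
    adoption_candidates,
    find_deserts,
    predict_targets,
    repressive_coverage,
)


def risk_loop(m1, m2, chrom="chr1"):
    rec = LoopRecord(
        GenomicInterval(chrom, m1 - 5_000, m1 + 5_000),
        GenomicInterval(chrom, m2 - 5_000, m2 + 5_000),
        dataset="hic",
        q_value=0.01,
    )
    return RiskLoop(rec, support=5, supporting_datasets=("hic",), convergence="convergent",
                    span_bp=rec.span_bp)


def k27(intervals):
    return [HCPeakSet("H3K27Ac", "x", peaks=[Peak(interval=iv, mark="H3K27Ac") for iv in intervals])]


class TestFindDeserts:
    def test_empty_300kb_interior_is_desert(self):
        (call,) = find_deserts([risk_loop(100_000, 400_000)], k27([]))
        assert call.is_desert and call.n_k27ac_interior == 0
        assert (call.interior.start, call.interior.end) == (105_000, 395_000)

    def test_single_interior_peak_flips_the_flag(self):
        peaks = k27([GenomicInterval("chr1", 250_000, 251_500)])
        (call,) = find_deserts([risk_loop(100_000, 400_000)], peaks)
        assert not call.is_desert and call.n_k27ac_interior == 1

    def test_peak_in_anchor_does_not_count(self):
        peaks = k27([GenomicInterval("chr1", 100_000, 101_000)])  # inside anchor1
        (call,) = find_deserts([risk_loop(100_000, 400_000)], peaks)
        assert call.is_desert

    def test_short_interior_below_threshold(self):
        (call,) = find_deserts([risk_loop(100_000, 160_000)], k27([]))
        assert call.interior.length == 50_000 and not call.is_desert

    def test_touching_anchors_give_no_interior(self):
        rec = LoopRecord(
            GenomicInterval("chr1", 95_000, 105_000),
            GenomicInterval("chr1", 100_000, 112_000),
            q_value=0.01,
        )
        rl = RiskLoop(rec, 1, ("hic",), "no_motif", rec.span_bp)
        (call,) = find_deserts([rl], k27([]))
        assert call.interior is None and not call.is_desert

    def test_planted_desert_loci(self, small_truth, small_result):
        from riskloop.pipeline import risk_loops_at

        for name, sl in small_truth.special_loci.items():
            rls = risk_loops_at((sl.chrom, sl.risk_pos0), small_result.loops_filtered,
                                small_truth.motifs)
            calls = find_deserts(rls, small_result.k27ac_sets,
                                 k27me3=small_truth.k27me3_peaks["rep1"])
            assert len(calls) == 2
            for c in calls:
                assert c.is_desert, f"locus {name} interior not called a desert"
                assert c.k27me3_covered_fraction > 0.5


def peak_list(intervals):
    return [Peak(interval=iv, mark="H3K27me3") for iv in intervals]


class TestRepressiveCoverage:
    def test_disjoint_halves_cover_fully(self):
        interior = GenomicInterval("chr1", 0, 1_000)
        peaks = peak_list([GenomicInterval("chr1", 0, 500), GenomicInterval("chr1", 500, 1_000)])
        assert repressive_coverage(interior, peaks) == 1.0

    def test_double_covered_half_is_half(self):
        interior = GenomicInterval("chr1", 0, 1_000)
        peaks = peak_list([GenomicInterval("chr1", 0, 500), GenomicInterval("chr1", 100, 500)])
        assert repressive_coverage(interior, peaks) == 0.5

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(3)
        interior = GenomicInterval("chr1", 1_000, 6_000)
        for _ in range(50):
            starts = rng.integers(0, 7_000, size=12)
            lengths = rng.integers(1, 900, size=12)
            peaks = peak_list(
                [GenomicInterval("chr1", int(s), int(s + l)) for s, l in zip(starts, lengths)]
            )
            base = np.zeros(interior.length, dtype=bool)
            for p in peaks:
                lo = max(p.interval.start, interior.start) - interior.start
                hi = min(p.interval.end, interior.end) - interior.start
                if hi > lo:
                    base[lo:hi] = True
            assert repressive_coverage(interior, peaks) == pytest.approx(
                base.sum() / interior.length
            )

    def test_zero_length_warns(self):
        with pytest.warns(UserWarning):
            assert repressive_coverage(None, []) == 0.0


GENES = [
    GeneModel("IN_SMALL", "IN_SMALL", "chr1", "+", 250_000, 258_000),
    GeneModel("IN_LARGE", "IN_LARGE", "chr1", "+", 500_000, 508_000),
    GeneModel("NEAR", "NEAR", "chr1", "+", 900_000, 908_000),
    GeneModel("FAR", "FAR", "chr1", "+", 1_400_000, 1_408_000),
    GeneModel("OTHER", "OTHER", "chr2", "+", 250_000, 258_000),
]


class TestPredictTargets:
    def setup_method(self):
        self.site = ("chr1", 100_000)
        self.loops = [risk_loop(100_000, 400_000), risk_loop(100_000, 700_000)]

    def test_within_loop_beats_window(self):
        preds = {p.gene_id: p for p in predict_targets(self.site, self.loops, GENES)}
        assert preds["IN_SMALL"].basis == "within_loop"
        assert preds["IN_LARGE"].basis == "within_loop"  # outside small, inside large loop
        assert preds["NEAR"].basis == "within_window"

    def test_window_boundary_excludes_distant_gene(self):
        preds = {p.gene_id for p in predict_targets(self.site, self.loops, GENES)}
        assert "FAR" not in preds and "OTHER" not in preds

    def test_zero_window_returns_only_loop_genes(self):
        preds = predict_targets(self.site, self.loops, GENES, window=0)
        assert {p.gene_id for p in preds} == {"IN_SMALL", "IN_LARGE"}
        assert all(p.basis == "within_loop" for p in preds)

    def test_planted_caged_gene_always_within_loop(self, small_truth, small_result):
        from riskloop.pipeline import risk_loops_at

        for sl in small_truth.special_loci.values():
            rls = risk_loops_at((sl.chrom, sl.risk_pos0), small_result.loops_filtered,
                                small_truth.motifs)
            preds = {p.gene_id: p.basis for p in
                     predict_targets((sl.chrom, sl.risk_pos0), rls, small_truth.genes)}
            for gid in sl.caged_genes:
                assert preds[gid] == "within_loop"


class TestAdoptionCandidates:
    def test_planted_enhancer_ranks_first_and_is_risk_flagged(self, small_truth, small_result):
        from riskloop.pipeline import risk_loops_at

        for sl in small_truth.special_loci.values():
            site = (sl.chrom, sl.risk_pos0)
            rls = risk_loops_at(site, small_result.loops_filtered, small_truth.motifs)
            calls = find_deserts(rls, small_result.k27ac_sets)
            widest = max(calls, key=lambda c: c.interior.length)
            cands = adoption_candidates(site, widest, small_result.k27ac_sets,
                                        small_result.annotated)
            top = cands[0]
            assert top.rank == 1 and top.contains_risk_snp
            enh_mid = (sl.enhancer.start + sl.enhancer.end) // 2
            assert top.peak.interval.contains(sl.chrom, enh_mid)
            # the planted geometry: first peak at the desert edge, tens of kb out
            assert 20_000 < top.distance_bp < 100_000

    def test_interior_peaks_excluded(self):
        desert = find_deserts([risk_loop(100_000, 400_000)], k27([]))[0]
        sets = k27([GenomicInterval("chr1", 200_000, 201_500),  # inside the desert
                    GenomicInterval("chr1", 450_000, 451_500)])
        cands = adoption_candidates(("chr1", 100_000), desert, sets)
        assert len(cands) == 1
        assert cands[0].peak.interval.start == 450_000

    def test_no_nearby_peaks_empty(self):
        desert = find_deserts([risk_loop(100_000, 400_000)], k27([]))[0]
        sets = k27([GenomicInterval("chr1", 5_000_000, 5_001_500)])
        assert adoption_candidates(("chr1", 100_000), desert, sets) == []
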