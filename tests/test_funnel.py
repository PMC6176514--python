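"""The nested SNP annotation funnel and its evidence matrix."""

import numpy as np
import pytest

from riskloop.core import GenomicInterval, Peak, SNPRecord
from riskloop.peaks import HCPeakSet
from riskloop.snp_funnel import (
    FunnelCounts,
    annotate_snps,
    attach_loop_hits,
    evidence_matrix,
    funnel_counts,
)


def k27_set(label, intervals):
    return HCPeakSet(
        "H3K27Ac",
        label,
        peaks=[Peak(interval=iv, mark="H3K27Ac", cell_line=label) for iv in intervals],
    )


def ctcf_set(label, summits, width=600):
    peaks = [
        Peak(
            interval=GenomicInterval("chr1", s - width // 2, s + width // 2),
            summit_offset=width // 2,
            mark="CTCF",
            cell_line=label,
        )
        for s in summits
    ]
    return HCPeakSet("CTCF", label, peaks=peaks)


DHS = [GenomicInterval("chr1", 9_900, 10_200)]


class TestAnnotate:
    def test_per_dataset_hit_vector(self):
        sets = [k27_set(f"ds{i}", [GenomicInterval("chr1", 9_000, 11_000)] if i == 3 else [])
                for i in range(9)]
        (a,) = annotate_snps([SNPRecord("rs1", "chr1", 10_000)], DHS, sets, [])
        assert a.in_dhs
        assert a.k27ac_hits == {f"H3K27Ac:ds{i}": i == 3 for i in range(9)}

    @pytest.mark.parametrize("offset, hit", [(999, True), (1_000, True), (1_001, False)])
    def test_ctcf_summit_window_boundary(self, offset, hit):
        """A SNP within +/- 1 kb of a CTCF summit is CTCF-positive."""
        summit = 10_000 + offset
        sets = [ctcf_set("22Rv1", [summit])]
        (a,) = annotate_snps([SNPRecord("rs1", "chr1", 10_000)], DHS, [], sets)
        assert a.any_ctcf is hit

    def test_stage_nesting_requires_open_chromatin(self):
        sets = [k27_set("ds", [GenomicInterval("chr1", 49_000, 51_000)])]
        (a,) = annotate_snps([SNPRecord("rs1", "chr1", 50_000)], DHS, sets, [])
        assert not a.in_dhs and not a.any_k27ac

    def test_duplicate_rsid_rejected(self):
        snps = [SNPRecord("rs1", "chr1", 10), SNPRecord("rs1", "chr1", 20)]
        with pytest.raises(ValueError, match="duplicate rsid"):
            annotate_snps(snps, DHS, [], [])

    def test_order_invariance(self, small_truth, small_result):
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(small_truth.snps))
        shuffled = [small_truth.snps[i] for i in perm]
        k27 = small_result.k27ac_sets
        ctcf = small_result.ctcf_sets
        re_annotated = annotate_snps(shuffled, small_truth.dhs, k27, ctcf)
        by_rsid = {a.snp.rsid: a for a in small_result.annotated}
        for a in re_annotated:
            b = by_rsid[a.snp.rsid]
            assert (a.in_dhs, a.k27ac_hits, a.ctcf_hits) == (b.in_dhs, b.k27ac_hits, b.ctcf_hits)

    def test_infinite_flank_limit(self, small_truth, small_result):
        """With a huge CTCF flank, every open-chromatin SNP sharing a
        chromosome with a CTCF peak becomes CTCF-positive."""
        annotated = annotate_snps(
            small_truth.snps,
            small_truth.dhs,
            [],
            small_result.ctcf_sets,
            ctcf_flank=10**9,
        )
        chroms_with_ctcf = {
            p.interval.chrom for hc in small_result.ctcf_sets for p in hc.peaks
        }
        for a in annotated:
            if a.in_dhs and a.snp.chrom in chroms_with_ctcf:
                assert a.any_ctcf


class TestFunnelCounts:
    def test_planted_strata_recovered_exactly(self, small_truth, small_result):
        cfg = small_truth.config
        c = small_result.counts
        assert c.n_input == cfg.n_snps
        assert c.n_dhs == cfg.n_dhs
        assert c.n_dhs_k27ac == cfg.n_k27ac
        assert c.n_dhs_ctcf == cfg.n_ctcf
        assert c.n_dhs_k27ac_loop == cfg.n_k27ac_loop
        assert c.n_dhs_ctcf_loop == cfg.n_ctcf_loop

    def test_all_outside_dhs_gives_empty_funnel(self):
        snps = [SNPRecord(f"rs{i}", "chr2", 1_000 * i + 10) for i in range(5)]
        annotated = annotate_snps(snps, DHS, [k27_set("ds", [])], [ctcf_set("ds", [])])
        attach_loop_hits(annotated, {"hic": []})
        c = funnel_counts(annotated)
        assert (c.n_dhs, c.n_dhs_k27ac, c.n_dhs_ctcf, c.n_dhs_k27ac_loop, c.n_dhs_ctcf_loop) == (
            0, 0, 0, 0, 0,
        )

    def test_loop_counts_absent_without_loop_data(self):
        annotated = annotate_snps([SNPRecord("rs1", "chr1", 10_000)], DHS, [], [])
        c = funnel_counts(annotated)
        assert c.n_dhs_k27ac_loop is None and c.n_dhs_ctcf_loop is None

    def test_monotonicity_enforced(self):
        with pytest.raises(ValueError, match="nested"):
            FunnelCounts(n_input=10, n_dhs=5, n_dhs_k27ac=7, n_dhs_ctcf=2)

    def test_monotone_on_random_landscapes(self):
        """Funnel nesting holds for arbitrary random inputs, not just planted ones."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            snps = [SNPRecord(f"rs{i}", "chr1", int(p)) for i, p in
                    enumerate(rng.integers(0, 100_000, size=50))]
            dhs = [GenomicInterval("chr1", int(s), int(s) + 400)
                   for s in rng.integers(0, 100_000, size=20)]
            k27 = [k27_set("d1", [GenomicInterval("chr1", int(s), int(s) + 1_000)
                                  for s in rng.integers(0, 100_000, size=15)])]
            ctcf = [ctcf_set("d1", [int(s) for s in rng.integers(500, 100_000, size=15)])]
            annotated = annotate_snps(snps, dhs, k27, ctcf)
            c = funnel_counts(annotated)
            assert c.n_input >= c.n_dhs >= max(c.n_dhs_k27ac, c.n_dhs_ctcf)


class TestEvidenceMatrix:
    def test_shape_and_membership(self, small_truth, small_result):
        mat = evidence_matrix(small_result.annotated, "H3K27Ac")
        assert len(mat) == small_truth.config.n_k27ac
        roster = [hc.label for hc in small_result.k27ac_sets]
        for ds in roster:
            assert ds in mat.columns
        # rows match the planted per-dataset memberships
        for _, row in mat.iterrows():
            mark, datasets = small_truth.snp_mark_datasets[row["rsid"]]
            assert mark == "H3K27Ac"
            got = tuple(ds for ds in small_truth.config.chip_datasets if row[f"H3K27Ac:{ds}"])
            assert got == datasets

    def test_sorted_rows(self, small_result):
        mat = evidence_matrix(small_result.annotated, "CTCF")
        keys = list(zip(mat["chrom"], mat["pos"]))
        assert keys == sorted(keys)

    def test_saturated_row(self):
        sets = [k27_set(f"d{i}", [GenomicInterval("chr1", 9_000, 11_000)]) for i in range(3)]
        annotated = annotate_snps([SNPRecord("rs1", "chr1", 10_000)], DHS, sets, [])
        mat = evidence_matrix(annotated, "H3K27Ac")
        assert mat.shape[0] == 1
        assert all(mat.iloc[0][f"H3K27Ac:d{i}"] for i in range(3))

    def test_empty_input_header_only(self):
        mat = evidence_matrix([], "H3K27Ac")
        assert len(mat) == 0 and list(mat.columns[:3]) == ["rsid", "chrom", "pos"]
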