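"""Deletion fold changes, window reports, and effect recovery."""

import numpy as np
import pandas as pd
import pytest

from riskloop.core import GenomicInterval
from riskloop.deletion import (
    DeletionExperiment,
    compute_fold_changes,
    permutation_pvalue,
    window_report,
)
from riskloop.peaks import GeneModel
from riskloop.simulate import simulate_deletion_expression


def make_exp(data, controls=("c1", "c2"), deleted=("d1", "d2")):
    return DeletionExperiment(
        deletion=GenomicInterval("chr1", 1_000, 2_000),
        control_samples=list(controls),
        deleted_samples=list(deleted),
        expression=pd.DataFrame(data).T,
    )


class TestComputeFoldChanges:
    def test_arithmetic_with_pseudocount(self):
        # pre-normalized values: control mean 2, deleted mean 200
        exp = make_exp({"target": {"c1": 2, "c2": 2, "d1": 200, "d2": 200}})
        (eff,) = compute_fold_changes(exp, normalize=False)
        assert eff.fold_change == pytest.approx(200.5 / 2.5)  # 80.2

    def test_unexpressed_gene_is_exactly_one(self):
        exp = make_exp(
            {
                "silent": {"c1": 0, "c2": 0, "d1": 0, "d2": 0},
                "housek": {"c1": 100, "c2": 100, "d1": 100, "d2": 100},
            }
        )
        eff = {e.gene_id: e for e in compute_fold_changes(exp)}
        assert eff["silent"].fold_change == 1.0 and eff["silent"].log2fc == 0.0

    def test_invariant_to_library_scaling(self):
        rng = np.random.default_rng(1)
        counts = {f"g{i}": {s: int(v) for s, v in
                            zip(("c1", "c2", "d1", "d2"), rng.integers(10, 1_000, 4))}
                  for i in range(20)}
        exp = make_exp(counts)
        base = [e.fold_change for e in compute_fold_changes(exp)]
        scaled_df = exp.expression.copy()
        scaled_df["d1"] = scaled_df["d1"] * 3  # triple one library
        scaled = DeletionExperiment(exp.deletion, exp.control_samples, exp.deleted_samples, scaled_df)
        rescaled = [e.fold_change for e in compute_fold_changes(scaled)]
        assert rescaled == pytest.approx(base, rel=1e-9)

    def test_group_swap_negates_log2fc(self):
        exp = make_exp(
            {
                "a": {"c1": 10, "c2": 12, "d1": 400, "d2": 440},
                "b": {"c1": 500, "c2": 480, "d1": 100, "d2": 90},
            }
        )
        fwd = {e.gene_id: e.log2fc for e in compute_fold_changes(exp)}
        swapped = DeletionExperiment(exp.deletion, exp.deleted_samples, exp.control_samples,
                                     exp.expression)
        rev = {e.gene_id: e.log2fc for e in compute_fold_changes(swapped)}
        for g in fwd:
            assert rev[g] == pytest.approx(-fwd[g], abs=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError, match="non-empty"):
            make_exp({"a": {"c1": 1, "c2": 1, "d1": 1, "d2": 1}}, controls=())
        with pytest.raises(ValueError, match="pseudocount"):
            compute_fold_changes(
                make_exp({"a": {"c1": 1, "c2": 1, "d1": 1, "d2": 1}}), pseudocount=0
            )


GENES = [
    GeneModel("caged", "caged", "chr1", "+", 130_000, 138_000),
    GeneModel("near", "near", "chr1", "+", 300_000, 308_000),
    GeneModel("far", "far", "chr1", "+", 2_000_000, 2_008_000),
]


class TestWindowReport:
    def test_ranking_and_top_responder(self):
        exp = make_exp(
            {
                "caged": {"c1": 10, "c2": 10, "d1": 1_000, "d2": 1_000},
                "near": {"c1": 500, "c2": 500, "d1": 520, "d2": 480},
                "far": {"c1": 50, "c2": 50, "d1": 50, "d2": 50},
            }
        )
        effects = compute_fold_changes(exp, normalize=False)
        rep = window_report(effects, ("chr1", 100_000), GENES)
        assert list(rep.table["gene_id"]) == ["caged", "near"]  # 'far' outside the window
        assert rep.top_responder == "caged" and rep.responder_called

    def test_null_case_flags_no_responder(self):
        exp = make_exp(
            {
                "caged": {"c1": 100, "c2": 100, "d1": 101, "d2": 99},
                "near": {"c1": 500, "c2": 500, "d1": 500, "d2": 500},
            }
        )
        effects = compute_fold_changes(exp, normalize=False)
        rep = window_report(effects, ("chr1", 100_000), GENES[:2])
        assert rep.top_responder is None and not rep.responder_called
        assert abs(rep.table.iloc[0]["log2fc"]) < 0.1

    def test_two_planted_responders_ordered(self):
        exp = make_exp(
            {
                "caged": {"c1": 10, "c2": 10, "d1": 1_000, "d2": 1_000},
                "near": {"c1": 100, "c2": 100, "d1": 300, "d2": 300},
            }
        )
        effects = compute_fold_changes(exp, normalize=False)
        rep = window_report(effects, ("chr1", 100_000), GENES[:2])
        assert list(rep.table["gene_id"]) == ["caged", "near"]
        assert rep.table.iloc[0]["fold_change"] > rep.table.iloc[1]["fold_change"]

    def test_missing_gene_raises_by_name(self):
        exp = make_exp({"caged": {"c1": 1, "c2": 1, "d1": 1, "d2": 1}})
        effects = compute_fold_changes(exp)
        with pytest.raises(KeyError, match="near"):
            window_report(effects, ("chr1", 100_000), GENES[:2])

    def test_empty_window_warns(self):
        exp = make_exp({"caged": {"c1": 1, "c2": 1, "d1": 1, "d2": 1}})
        effects = compute_fold_changes(exp)
        with pytest.warns(UserWarning, match="no genes"):
            rep = window_report(effects, ("chr9", 0), GENES)
        assert rep.table.empty and rep.top_responder is None


class TestPlantedEffectRecovery:
    def test_hundredfold_effect_recovered(self, small_truth):
        sl = small_truth.special_loci["A"]
        exp = simulate_deletion_expression(small_truth, "risk_anchor_deleted", "A", seed=7)
        effects = compute_fold_changes(exp)
        rep = window_report(effects, (sl.chrom, sl.risk_pos0), small_truth.genes)
        assert rep.top_responder == sl.primary_gene
        assert 50 < rep.table.iloc[0]["fold_change"] < 200

    def test_control_scenario_is_flat(self, small_truth):
        sl = small_truth.special_loci["A"]
        exp = simulate_deletion_expression(small_truth, "control", "A", seed=7)
        effects = compute_fold_changes(exp)
        rep = window_report(effects, (sl.chrom, sl.risk_pos0), small_truth.genes)
        assert not rep.responder_called or rep.table.iloc[0]["fold_change"] < 4

    def test_permutation_pvalue_separates_signal_from_null(self, small_truth):
        exp = simulate_deletion_expression(small_truth, "risk_anchor_deleted", "A",
                                           n_reps=3, seed=7)
        sl = small_truth.special_loci["A"]
        p_hit = permutation_pvalue(exp, sl.primary_gene, n_permutations=500, seed=1)
        # n=3 vs 3: the best achievable one-sided label-shuffle p is 2/20
        assert p_hit <= 0.15
        p_null = permutation_pvalue(exp, "TX00001", n_permutations=500, seed=1)
        assert p_null > p_hit
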