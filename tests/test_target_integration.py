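"""Condition means, negated correlation, the support gate and coverage accounting."""

import numpy as np
import pandas as pd
import pytest

from mirlink.differential_expression import de_test, select_candidates
from mirlink.synthetic_data import (
    SimulationConfig,
    evaluate_recovery,
    simulate_expression,
    simulate_predictions,
    simulate_truth,
)
from mirlink.target_integration import (
    ConditionMeans,
    CorrelationMatrix,
    FunctionalTargetSet,
    condition_means,
    correlate,
    infer_functional_targets,
    prediction_support,
    regulation_coverage,
)
from tests.conftest import make_matrix

CMAP = {"p1": "P", "p2": "P", "p3": "P", "r1": "R", "r2": "R", "r3": "R"}


def _means(df_dict):
    return ConditionMeans(values=pd.DataFrame(df_dict).T)


class TestConditionMeans:
    def test_simple_average(self):
        vals = make_matrix([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], samples=list(CMAP))
        cm = condition_means(vals, CMAP)
        assert cm.values.loc["f0", "P"] == pytest.approx(2.0)
        assert cm.values.loc["f0", "R"] == pytest.approx(5.0)

    def test_one_missing_replicate_mean_of_rest(self):
        vals = make_matrix([[1.0, np.nan, 3.0, 4.0, 5.0, 6.0]], samples=list(CMAP))
        cm = condition_means(vals, CMAP)
        assert cm.values.loc["f0", "P"] == pytest.approx(2.0)
        assert cm.incomplete == []

    def test_single_detected_replicate_marks_missing(self):
        vals = make_matrix([[1.0, np.nan, np.nan, 4.0, 5.0, 6.0]], samples=list(CMAP))
        cm = condition_means(vals, CMAP)
        assert np.isnan(cm.values.loc["f0", "P"])
        assert cm.incomplete == ["f0"]
        assert cm.complete.empty

    def test_matches_direct_recompute(self, default_sim):
        _, _, sim, _ = default_sim
        cm = condition_means(sim.cp, sim.condition_map)
        for cond in cm.values.columns:
            samples = [s for s, c in sim.condition_map.items() if c == cond]
            np.testing.assert_allclose(cm.values[cond], sim.cp[samples].mean(axis=1))

    def test_empty_condition_raises(self):
        vals = make_matrix([[1.0, 2.0]], samples=["p1", "p2"])
        with pytest.raises(ValueError, match="no samples"):
            condition_means(vals, {"p1": "P", "p2": "P", "x": "R"})


class TestCorrelate:
    def test_identical_profiles_give_minus_one(self):
        # gene expression numerically equal to the miRNA's Cp profile:
        # Cp up = abundance down = expression up -> strongest inverse evidence
        m = _means({"m1": [20.0, 22.0, 24.0, 21.0]})
        g = _means({"g1": [20.0, 22.0, 24.0, 21.0]})
        corr = correlate(m, g)
        assert corr.values.at["m1", "g1"] == pytest.approx(-1.0)

    def test_negated_profile_gives_plus_one(self):
        m = _means({"m1": [20.0, 22.0, 24.0, 21.0]})
        g = _means({"g1": [-20.0, -22.0, -24.0, -21.0]})
        assert correlate(m, g).values.at["m1", "g1"] == pytest.approx(1.0)

    def test_noiseless_planted_edge(self, noiseless_config):
        truth = simulate_truth(noiseless_config)
        sim = simulate_expression(truth, noiseless_config)
        corr = correlate(
            condition_means(sim.cp, sim.condition_map),
            condition_means(sim.expr, sim.condition_map),
        )
        mirna, gene = next(iter(truth.edge_set))
        assert corr.values.at[mirna, gene] <= -0.99

    def test_negation_matches_abundance_correlation(self, default_sim):
        # Cp is affine in abundance with negative slope, so the negated
        # Cp-expression correlation equals the abundance-expression correlation
        _, truth, sim, _ = default_sim
        corr = correlate(
            condition_means(sim.cp, sim.condition_map),
            condition_means(sim.expr, sim.condition_map),
        )
        gm = condition_means(sim.expr, sim.condition_map).values
        cm = condition_means(sim.cp, sim.condition_map).values
        mirna, gene = sorted(truth.edge_set)[0]
        abundance_profile = (35.0 - cm.loc[mirna]) / 1.0  # invert the affine Cp map
        direct = np.corrcoef(abundance_profile, gm.loc[gene])[0, 1]
        assert corr.values.at[mirna, gene] == pytest.approx(direct, abs=1e-10)

    def test_zero_variance_is_nan(self):
        m = _means({"m1": [20.0, 20.0, 20.0, 20.0]})
        g = _means({"g1": [1.0, 2.0, 3.0, 4.0]})
        assert np.isnan(correlate(m, g).values.at["m1", "g1"])

    def test_too_few_conditions_raises(self):
        m = ConditionMeans(values=pd.DataFrame({"A": [1.0], "B": [2.0]}, index=["m1"]))
        g = ConditionMeans(values=pd.DataFrame({"A": [1.0], "B": [2.0]}, index=["g1"]))
        with pytest.raises(ValueError, match=">= 3 shared"):
            correlate(m, g)


def _corr_from(entries):
    df = pd.DataFrame(entries).T
    df.index.name = "mirna"
    return CorrelationMatrix(values=df, n_conditions=4)


class TestInferFunctionalTargets:
    PRED = pd.DataFrame(
        {
            "mirna": ["m1"] * 6 + ["m2"],
            "gene": ["g1"] * 6 + ["g2"],
            "predictor": list("ABCDEF") + ["A"],
        }
    )

    def test_threshold_boundary_exclusive(self):
        corr = _corr_from({"m1": {"g1": -0.79}})
        fts = infer_functional_targets(corr, self.PRED)
        assert fts.table.empty

    def test_threshold_inclusive_at_cutoff(self):
        corr = _corr_from({"m1": {"g1": -0.8}})
        fts = infer_functional_targets(corr, self.PRED)
        assert fts.pairs == {("m1", "g1")}

    def test_support_gate(self):
        corr = _corr_from({"m2": {"g2": -0.95}})
        fts = infer_functional_targets(corr, self.PRED)
        assert fts.table.empty

    def test_monotone_filters_never_add_pairs(self, default_sim):
        config, truth, sim, pred = default_sim
        corr = correlate(
            condition_means(sim.cp, sim.condition_map),
            condition_means(sim.expr, sim.condition_map),
        )
        base = infer_functional_targets(corr, pred, r_threshold=-0.8, min_support=2).pairs
        stricter_r = infer_functional_targets(corr, pred, r_threshold=-0.9, min_support=2).pairs
        stricter_s = infer_functional_targets(corr, pred, r_threshold=-0.8, min_support=3).pairs
        assert stricter_r <= base
        assert stricter_s <= base

    def test_precision_nondecreasing_in_threshold(self):
        precisions = []
        for r_thr in (-0.8, -0.9, -0.95):
            vals = []
            for seed in (31, 32, 33):
                config = SimulationConfig(seed=seed)
                truth = simulate_truth(config)
                sim = simulate_expression(truth, config)
                pred = simulate_predictions(truth, config)
                corr = correlate(
                    condition_means(sim.cp, sim.condition_map),
                    condition_means(sim.expr, sim.condition_map),
                )
                fts = infer_functional_targets(corr, pred, r_threshold=r_thr)
                vals.append(evaluate_recovery(fts.pairs, truth)["precision"])
            precisions.append(np.mean(vals))
        assert precisions[0] <= precisions[1] + 1e-9 <= precisions[2] + 2e-9

    def test_sorted_by_mirna_then_r(self):
        corr = _corr_from({"m1": {"g1": -0.85, "g2": -0.99}})
        pred = pd.DataFrame(
            {"mirna": ["m1"] * 4, "gene": ["g1", "g1", "g2", "g2"],
             "predictor": ["A", "B", "A", "B"]}
        )
        fts = infer_functional_targets(corr, pred)
        assert fts.table["gene"].tolist() == ["g2", "g1"]


def test_prediction_support_counts_distinct_predictors():
    pred = pd.DataFrame(
        {"mirna": ["m", "m", "m"], "gene": ["g", "g", "h"], "predictor": ["A", "B", "A"]}
    )
    sup = prediction_support(pred)
    assert sup.loc[("m", "g")] == 2 and sup.loc[("m", "h")] == 1


class TestRegulationCoverage:
    def _fts(self, pairs):
        table = pd.DataFrame(
            [(m, g, -0.9, 3) for m, g in pairs], columns=["mirna", "gene", "r", "support"]
        )
        return FunctionalTargetSet(table=table)

    def test_no_targets_zero(self):
        cov = regulation_coverage({"g1", "g2"}, self._fts([]), {"m1"}, ["g1", "g2", "g3"])
        assert cov.fraction == 0.0

    def test_all_de_genes_targeted(self):
        cov = regulation_coverage(
            {"g1", "g2"}, self._fts([("m1", "g1"), ("m1", "g2")]), {"m1"}, ["g1", "g2", "g3"]
        )
        assert cov.fraction == 1.0
        assert cov.table[0].tolist() == [2, 0]

    def test_empty_de_set_undefined(self):
        cov = regulation_coverage(set(), self._fts([("m1", "g1")]), {"m1"}, ["g1"])
        assert cov.fraction is None

    def test_non_de_regulator_does_not_count(self):
        cov = regulation_coverage({"g1"}, self._fts([("m1", "g1")]), {"m2"}, ["g1", "g2"])
        assert cov.fraction == 0.0

    def test_simulated_fraction_matches_planted_truth(self, default_sim):
        config, truth, sim, pred = default_sim
        contrasts = [(c, "parental") for c in config.conditions[1:]]
        cp_de = [de_test(sim.cp, sim.condition_map, c, kind="cp") for c in contrasts]
        expr_de = [de_test(sim.expr, sim.condition_map, c) for c in contrasts]
        de_mirnas = set().union(*[set(r.table.index[r.table["padj"] < 0.05]) for r in cp_de])
        de_genes = set().union(*[set(r.table.index[r.table["padj"] < 0.05]) for r in expr_de])
        candidates = select_candidates(cp_de)
        corr = correlate(
            condition_means(sim.cp, sim.condition_map),
            condition_means(sim.expr, sim.condition_map),
            candidates=candidates,
        )
        fts = infer_functional_targets(corr, pred)
        cov = regulation_coverage(de_genes, fts, de_mirnas, list(sim.expr.index))
        planted_targets = {g for (m, g) in truth.edge_set if m in de_mirnas}
        expected = len(de_genes & planted_targets) / len(de_genes)
        assert cov.fraction == pytest.approx(expected, abs=0.1)
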