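"""The generator must plant exactly the structure downstream stages recover."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirlink.synthetic_data import (
    SimulationConfig,
    simulate_cohorts,
    simulate_expression,
    simulate_melt_curves,
    simulate_predictions,
    simulate_reads,
    simulate_reference,
    simulate_truth,
)
from mirlink.outcome_classification import fit_logistic, roc_auc
from mirlink.qpcr_normalization import count_melt_peaks


class TestSimulateTruth:
    def test_no_regulation_null(self):
        truth = simulate_truth(SimulationConfig(seed=1, n_edges=0))
        assert truth.edge_set == set()

    def test_seed_determinism(self):
        t1 = simulate_truth(SimulationConfig(seed=1))
        t2 = simulate_truth(SimulationConfig(seed=1))
        assert t1.edges == t2.edges and t1.de_mirnas == t2.de_mirnas
        t3 = simulate_truth(SimulationConfig(seed=2))
        assert t3.edges != t1.edges

    def test_edge_count_and_density(self):
        truth = simulate_truth(SimulationConfig(seed=3, n_mirnas=30, n_genes=200, n_edges=150))
        assert len(truth.edge_set) == 150
        assert len(truth.edge_set) / (30 * 200) == pytest.approx(0.025)

    def test_too_many_edges_raises(self):
        with pytest.raises(ValueError, match="cannot place"):
            simulate_truth(SimulationConfig(seed=1, n_mirnas=2, n_genes=3, n_edges=7, shared_targets=True))
        with pytest.raises(ValueError, match="single-regulator"):
            simulate_truth(SimulationConfig(seed=1, n_genes=100, n_edges=101))

    def test_both_shift_signs_represented(self):
        truth = simulate_truth(SimulationConfig(seed=4))
        signs = {np.sign(next(iter(v.values()))) for v in truth.de_mirnas.values()}
        assert signs == {1.0, -1.0}

    def test_strengths_positive(self):
        truth = simulate_truth(SimulationConfig(seed=5))
        assert all(s > 0 for s in truth.edges.values())


class TestSimulateExpression:
    def test_planted_edge_inverse_correlation(self, noiseless_config):
        truth = simulate_truth(noiseless_config)
        sim = simulate_expression(truth, noiseless_config)
        (mirna, gene) = next(iter(truth.edge_set))
        cp_means = sim.cp.loc[mirna].groupby(sim.condition_map).mean()
        ex_means = sim.expr.loc[gene].groupby(sim.condition_map).mean()
        r = -np.corrcoef(cp_means, ex_means.loc[cp_means.index])[0, 1]
        assert r <= -0.99

    def test_null_network_correlations_centered(self):
        config = SimulationConfig(seed=9, n_edges=0)
        truth = simulate_truth(config)
        sim = simulate_expression(truth, config)
        conds = sorted(set(sim.condition_map.values()))
        cpm = np.column_stack(
            [sim.cp[[s for s, c in sim.condition_map.items() if c == cond]].mean(axis=1) for cond in conds]
        )
        exm = np.column_stack(
            [sim.expr[[s for s, c in sim.condition_map.items() if c == cond]].mean(axis=1) for cond in conds]
        )
        rng = np.random.default_rng(0)
        rs = []
        for _ in range(300):
            i, j = rng.integers(0, cpm.shape[0]), rng.integers(0, exm.shape[0])
            rs.append(-np.corrcoef(cpm[i], exm[j])[0, 1])
        assert abs(np.mean(rs)) < 0.1

    def test_zero_bias_means_no_distortion(self):
        config = SimulationConfig(seed=2, cp_bias_amplitude=0.0)
        truth = simulate_truth(config)
        sim = simulate_expression(truth, config)
        pd.testing.assert_frame_equal(sim.cp, sim.cp_nobias)

    def test_bias_amplitude_bounds_distortion(self):
        config = SimulationConfig(seed=2, cp_bias_amplitude=1.5)
        truth = simulate_truth(config)
        sim = simulate_expression(truth, config)
        bias = sim.cp - sim.cp_nobias
        assert np.abs(bias.to_numpy()).max() == pytest.approx(1.5, abs=1e-9)

    def test_cp_antimonotone_with_abundance(self, noiseless_config):
        truth = simulate_truth(noiseless_config)
        sim = simulate_expression(truth, noiseless_config)
        for sample in sim.cp.columns:
            cond = sim.condition_map[sample]
            cp_rank = sim.cp[sample].rank()
            ab_rank = sim.abundance[cond].rank()
            assert stats.spearmanr(cp_rank, ab_rank).statistic == pytest.approx(-1.0)


class TestSimulatePredictions:
    def test_zero_decoys_equal_truth(self):
        config = SimulationConfig(seed=1, decoy_rate=0.0)
        truth = simulate_truth(config)
        pred = simulate_predictions(truth, config)
        assert set(zip(pred["mirna"], pred["gene"])) == truth.edge_set

    def test_support_bounds_and_true_edge_floor(self, default_sim):
        config, truth, _, pred = default_sim
        support = pred.groupby(["mirna", "gene"])["predictor"].nunique()
        assert support.max() <= config.n_predictors
        for edge in truth.edge_set:
            assert support.loc[edge] >= 2

    def test_triples_unique_and_reproducible(self, default_sim):
        config, truth, _, pred = default_sim
        assert not pred.duplicated().any()
        again = simulate_predictions(truth, config)
        pd.testing.assert_frame_equal(pred, again)


class TestSimulateReads:
    def test_reads_match_reference_without_adapter(self):
        config = SimulationConfig(seed=6, n_mirnas=10, n_edges=0, n_reads=500)
        truth = simulate_truth(config)
        reference = simulate_reference(truth, config)
        readsim = simulate_reads(truth, reference, config)
        ref_seqs = set(reference.values())
        for reads in readsim.reads.values():
            assert all(r.sequence in ref_seqs for r in reads)
            assert len(reads) == 500

    def test_counts_are_the_draws(self):
        config = SimulationConfig(seed=6, n_mirnas=10, n_edges=0, n_reads=300)
        truth = simulate_truth(config)
        reference = simulate_reference(truth, config)
        readsim = simulate_reads(truth, reference, config)
        sample = next(iter(readsim.reads))
        from collections import Counter

        seq_counts = Counter(r.sequence for r in readsim.reads[sample])
        for mirna in readsim.counts.index:
            expected = sum(
                readsim.counts.at[other, sample]
                for other in readsim.counts.index
                if reference[other] == reference[mirna]
            )
            assert seq_counts[reference[mirna]] == expected

    def test_multinomial_proportions(self):
        config = SimulationConfig(seed=8, n_mirnas=10, n_edges=0, de_fraction=0.0, n_reads=10_000)
        truth = simulate_truth(config)
        reference = simulate_reference(truth, config)
        readsim = simulate_reads(truth, reference, config)
        # equal abundance for all miRNAs: each p = 1/10
        p = 1.0 / config.n_mirnas
        sigma = np.sqrt(p * (1 - p) * config.n_reads)
        sample = readsim.counts.columns[0]
        dev = (readsim.counts[sample] - config.n_reads * p).abs()
        assert (dev <= 3 * sigma).all()

    def test_empty_reference_raises(self):
        config = SimulationConfig(seed=1)
        truth = simulate_truth(config)
        with pytest.raises(ValueError, match="empty"):
            simulate_reads(truth, {}, config)

    def test_adapter_and_quality_decay(self):
        config = SimulationConfig(seed=6, n_mirnas=5, n_edges=0, n_reads=50,
                                  read_adapter="TGGAATTCTCGG", read_length=30)
        truth = simulate_truth(config)
        reference = simulate_reference(truth, config)
        readsim = simulate_reads(truth, reference, config)
        read = next(iter(readsim.reads.values()))[0]
        assert len(read) == 30
        assert read.quality[-1] < read.quality[0]


class TestSimulateCohorts:
    def test_sizes_and_label_balance(self):
        config = SimulationConfig(seed=10)
        cohorts = simulate_cohorts(config)
        assert [c.n for c in cohorts] == [52, 60, 40]
        for c, prev in zip(cohorts, config.cohort_prevalence):
            k = c.n_recurrent
            lo, hi = stats.binom.ppf([0.025, 0.975], c.n, prev)
            assert lo <= k <= hi
            assert 0 < k < c.n

    def test_null_coefficients_give_chance_auc(self):
        config = SimulationConfig(
            seed=11, cohort_sizes=(400, 400), cohort_prevalence=(0.5, 0.5),
            marker_betas=(0.0, 0.0, 0.0, 0.0),
        )
        cohorts = simulate_cohorts(config)
        auc, _, _ = roc_auc(cohorts[0].expression["miR-190b"], cohorts[0].labels)
        assert abs(auc - 0.5) < 3 * np.sqrt((400 + 1) / (12 * 200 * 200))

    def test_strong_coefficient_training_auc(self):
        config = SimulationConfig(
            seed=12, cohort_sizes=(500, 100), cohort_prevalence=(0.5, 0.5),
            marker_mirnas=("miR-190b",), marker_betas=(3.0,),
        )
        cohorts = simulate_cohorts(config)
        model = fit_logistic(cohorts[0], ["miR-190b"])
        auc, _, _ = roc_auc(model.decision_scores(cohorts[0].expression), cohorts[0].labels)
        assert auc > 0.8


def test_melt_curve_truth_recovered_by_peak_counter():
    curves, truth_counts = simulate_melt_curves(SimulationConfig(seed=13), n_assays=20)
    found = {c.assay_id: count_melt_peaks(c) for c in curves}
    assert found == truth_counts
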