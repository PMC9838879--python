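import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import clamap as cm
from clamap.exceptions import ConfigurationError, DegenerateStatisticError


class TestCircuitStatistic:
    def test_matches_textbook_one_sample_formula(self):
        """{2,4,6,8}: mean 5, sd sqrt(20/3) -> t = 5/(sd/2) = sqrt(15)."""
        values = np.array([2.0, 4.0, 6.0, 8.0])
        sd = np.sqrt(((values - 5.0) ** 2).sum() / 3.0)
        by_hand = 5.0 / (sd / np.sqrt(4))
        assert cm.circuit_statistic(values) == pytest.approx(by_hand)
        assert by_hand == pytest.approx(np.sqrt(15.0))

    def test_zero_mean_noise_gives_small_statistic(self):
        rng = np.random.default_rng(0)
        t = cm.circuit_statistic(rng.normal(0, 1, 500))
        assert abs(t) < 3.0

    def test_near_constant_positive_values_give_large_statistic(self):
        values = 1.0 + 1e-6 * np.arange(4)
        assert cm.circuit_statistic(values) > 1e4

    def test_degenerate_inputs_flagged(self):
        with pytest.raises(DegenerateStatisticError):
            cm.circuit_statistic([1.0, 1.0, 1.0])
        with pytest.raises(DegenerateStatisticError):
            cm.circuit_statistic([1.0])


class TestSubgraphScore:
    def test_single_circuit_hypothesis_equals_thresholded_statistic(self):
        stats_map = {cm.CircuitSpec("ACC", "PtA"): 5.0}
        hyp = cm.SubgraphHypothesis(("ACC",), ("PtA",))
        assert cm.subgraph_score(stats_map, hyp, cluster_threshold=2.0) == 3.0

    def test_additive_over_disjoint_circuit_sets(self):
        stats_map = {
            cm.CircuitSpec("ACC", "PtA"): 5.0,
            cm.CircuitSpec("plPFC", "V1/V2"): 4.0,
        }
        h1 = cm.SubgraphHypothesis(("ACC",), ("PtA",))
        h2 = cm.SubgraphHypothesis(("plPFC",), ("V1/V2",))
        stats_map.update(
            {
                cm.CircuitSpec("ACC", "V1/V2"): 1.0,
                cm.CircuitSpec("plPFC", "PtA"): 2.0,
            }
        )
        h12 = cm.SubgraphHypothesis(("ACC", "plPFC"), ("PtA", "V1/V2"))
        direct = cm.subgraph_score(stats_map, h12)
        parts = sum(
            cm.subgraph_score(stats_map, cm.SubgraphHypothesis((i,), (o,)))
            for i in ("ACC", "plPFC")
            for o in ("PtA", "V1/V2")
        )
        assert direct == pytest.approx(parts)
        assert cm.subgraph_score(stats_map, h1) + cm.subgraph_score(stats_map, h2) == pytest.approx(
            5.0 + 4.0 - 2 * 2.0
        )


class TestCohensD:
    def test_identical_samples_give_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert cm.cohens_d(x, x) == 0.0

    def test_one_pooled_sd_separation_gives_unity(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 2000)
        pooled = np.sqrt((x.var(ddof=1) + x.var(ddof=1)) / 2)
        assert cm.cohens_d(x + pooled, x) == pytest.approx(1.0, rel=1e-9)

    def test_textbook_pooled_formula(self):
        """{0,1,2} vs {2,3,4}: means 1, 3; each variance 1 -> d = -2."""
        assert cm.cohens_d([0, 1, 2], [2, 3, 4]) == pytest.approx(-2.0)

    def test_zero_pooled_sd_flagged(self):
        with pytest.raises(DegenerateStatisticError):
            cm.cohens_d([1.0, 1.0], [1.0, 1.0])


class TestCompareTypes:
    circuit = cm.CircuitSpec("ACC", "ACC")

    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(2)
        x = rng.random(15)
        res = cm.compare_types(x, x, self.circuit)
        assert res.p_value > 0.9
        assert res.direction == "none"

    def test_complete_separation_minimal_p_and_direction(self):
        """All type II respond, no type I does: the most extreme rank
        configuration attainable at n=15 vs 15."""
        ones, zeros = np.ones(15), np.zeros(15)
        res = cm.compare_types(zeros, ones, self.circuit)
        assert res.direction == "II>I"
        assert res.p_value <= 2e-4  # Monte-Carlo floor of the exact test
        # any perturbation away from complete separation weakens the evidence
        weaker = np.concatenate([np.zeros(3), np.ones(12)])
        res2 = cm.compare_types(zeros, weaker, self.circuit)
        assert res2.p_value >= res.p_value

    def test_asymptotic_matches_hand_coded_tie_corrected_z(self):
        """Tie-corrected normal approximation recomputed from the textbook
        formula (midranks, continuity correction)."""
        x = np.array([0.0] * 12 + [1 / 6] * 3)   # type I
        y = np.array([0.0] * 6 + [1 / 6] * 6 + [2 / 6] * 3)  # type II
        res = cm.compare_types(x, y, self.circuit, method="asymptotic")
        n1, n2 = len(y), len(x)
        pooled = np.concatenate([y, x])
        ranks = sps.rankdata(pooled)
        u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        ties = np.unique(pooled, return_counts=True)[1]
        n = n1 + n2
        var = n1 * n2 / 12 * (n + 1 - (ties**3 - ties).sum() / (n * (n - 1)))
        z = (abs(u - n1 * n2 / 2) - 0.5) / np.sqrt(var)
        p_hand = 2 * sps.norm.sf(z)
        assert res.p_value == pytest.approx(p_hand, rel=1e-6)

    def test_all_tied_data_flagged(self):
        res = cm.compare_types(np.zeros(15), np.zeros(15), self.circuit)
        assert res.all_tied and res.p_value == 1.0 and res.direction == "none"

    def test_exact_mc_is_seed_deterministic(self):
        rng = np.random.default_rng(3)
        x, y = rng.random(10), rng.random(10) + 0.3
        a = cm.compare_types(x, y, self.circuit, seed=5)
        b = cm.compare_types(x, y, self.circuit, seed=5)
        assert a.p_value == b.p_value


class TestOmnibus:
    def test_matches_hand_computed_h(self):
        """{1,2},{3,4},{5,6}: H = 12/(6*7) * sum n_i (Rbar_i - 3.5)^2 = 32/7."""
        df = pd.DataFrame(
            {
                "cell_id": [f"c{k}" for k in range(6)],
                "input": ["ACC"] * 2 + ["plPFC"] * 2 + ["ilPFC"] * 2,
                "output": ["PtA"] * 6,
                "subtype": ["I"] * 6,
                "mean_auc": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "mean_aps_per_pulse": 0.0,
                "binary_response": 0.0,
                "qc_status": "pass",
            }
        )
        matrix = cm.assemble_matrix(df)
        h, p = cm.omnibus_across_circuits(matrix, "auc", "I")
        by_hand = 12.0 / (6 * 7) * (2 * (1.5 - 3.5) ** 2 + 0.0 + 2 * (5.5 - 3.5) ** 2)
        assert h == pytest.approx(by_hand) and by_hand == pytest.approx(32.0 / 7.0)
        assert p == pytest.approx(1.0 - sps.chi2.cdf(h, df=2))

    def test_single_group_rejected(self):
        df = pd.DataFrame(
            {
                "cell_id": ["a", "b"],
                "input": ["ACC"] * 2,
                "output": ["PtA"] * 2,
                "subtype": ["I"] * 2,
                "mean_auc": [1.0, 2.0],
                "mean_aps_per_pulse": 0.0,
                "binary_response": 0.0,
                "qc_status": "pass",
            }
        )
        with pytest.raises(ConfigurationError):
            cm.omnibus_across_circuits(cm.assemble_matrix(df), "auc", "I")


def test_comparison_table_has_bh_column(study_matrix):
    table = cm.compare_types_table(study_matrix)
    assert {"p_value", "p_bh", "direction"} <= set(table.columns)
    assert ((table["p_bh"] >= table["p_value"] - 1e-12) & (table["p_bh"] <= 1.0)).all()
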