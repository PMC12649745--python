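import numpy as np
import pandas as pd
import pytest

from helpers import brute_force_bh
from statescape.calibration import (
    _make_dynamics,
    _simulate_condition_dataset,
    transition_test_power,
    transition_test_type1,
)
from statescape.dynstats import (
    bh_fdr,
    fractional_occupancy,
    lifetimes,
    permutation_test_transitions,
    switch_rate,
    temporal_metric_comparison,
    trial_transition_matrix,
)
from statescape.synth import default_scene, simulate_markov_chains


class TestTrialTransitionMatrix:
    def test_arithmetic(self):
        T, flags = trial_transition_matrix(np.array([[8.0, 2.0], [1.0, 9.0]]))
        np.testing.assert_allclose(T, [[0.8, 0.2], [0.1, 0.9]])
        assert not flags.any()

    def test_zero_row_uniform_and_flagged(self):
        T, flags = trial_transition_matrix(np.array([[3.0, 1.0], [0.0, 0.0]]))
        np.testing.assert_allclose(T[1], [0.5, 0.5])
        assert flags.tolist() == [False, True]

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            trial_transition_matrix(np.zeros((2, 2)))

    def test_pooled_mean_recovers_generator(self):
        """Per-trial matrices averaged over 1,000 trials sit within 0.03 of
        the generating chain entrywise."""
        scene = default_scene()
        S = simulate_markov_chains(scene.A_true, scene.pi_true, 400, 1000, seed=0)
        from statescape.calibration import _trial_matrices_from_chains

        mats = _trial_matrices_from_chains(S, 3)
        assert np.abs(mats.mean(axis=0) - scene.A_true).max() < 0.03


class TestTemporalMetrics:
    def test_lifetimes_hand_case(self):
        lt = lifetimes(np.array([0, 0, 1, 1, 1, 0]), fs=1.0)
        np.testing.assert_array_equal(np.sort(lt[0]), [1.0, 2.0])
        np.testing.assert_array_equal(lt[1], [3.0])

    def test_constant_path_single_visit(self):
        lt = lifetimes(np.zeros(50, dtype=int), fs=10.0)
        np.testing.assert_array_equal(lt[0], [5.0])

    def test_lifetimes_partition_the_trial(self):
        rng = np.random.default_rng(0)
        path = rng.integers(0, 3, size=500)
        lt = lifetimes(path, fs=100.0)
        assert sum(v.sum() for v in lt) * 100.0 == pytest.approx(500)

    def test_fo_one_hot_and_uniform(self):
        g = np.zeros((20, 3))
        g[:, 1] = 1.0
        np.testing.assert_allclose(fractional_occupancy(g), [0, 1, 0])
        np.testing.assert_allclose(fractional_occupancy(np.full((10, 4), 0.25)),
                                   [0.25] * 4)

    def test_switch_rate_cases(self):
        assert switch_rate(np.zeros(100, dtype=int), fs=50.0) == 0.0
        path = np.arange(10) % 2
        assert switch_rate(path, fs=10.0) == pytest.approx(9 / 1.0)

    def test_switch_rate_matches_analytic(self):
        """Empirical switching rate approaches sum_k pi_k (1 - A_kk) * fs."""
        A = np.array([[0.95, 0.05], [0.1, 0.9]])
        evals, evecs = np.linalg.eig(A.T)
        stat = np.real(evecs[:, np.argmax(np.real(evals))])
        stat /= stat.sum()
        expect = (stat * (1 - np.diag(A))).sum() * 100.0
        S = simulate_markov_chains(A, stat, 10**5, 10, seed=1)
        rates = [switch_rate(s, fs=100.0) for s in S]
        assert abs(np.mean(rates) - expect) / expect < 0.05


class TestBHFDR:
    def test_hand_checkable_step_up(self):
        mask = bh_fdr(np.array([0.01, 0.02, 0.30]), q=0.05)
        assert mask.tolist() == [True, True, False]

    def test_all_ones_reject_none(self):
        assert not bh_fdr(np.ones(10), 0.05).any()

    def test_empty_input(self):
        assert bh_fdr(np.array([]), 0.05).size == 0

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            m = int(rng.integers(1, 20))
            p = rng.random(m) ** rng.uniform(0.5, 3.0)
            q = rng.uniform(0.01, 0.2)
            np.testing.assert_array_equal(bh_fdr(p, q), brute_force_bh(p, q))


class TestPermutationTest:
    def test_identical_statistics_give_p_one(self):
        mats = np.tile(np.array([[0.9, 0.1], [0.2, 0.8]]), (40, 1, 1))
        parts = np.arange(40) % 4
        conds = np.where(np.arange(40) % 2 == 0, "A", "B")
        dyn = _make_dynamics(mats, parts, conds)
        res = permutation_test_transitions(dyn, n_perm=10, seed=0)
        for lv in res.condition_levels:
            assert (res.pvals[lv] == 1.0).all()

    def test_single_condition_participant_excluded(self):
        rng = np.random.default_rng(3)
        mats = rng.dirichlet(np.ones(2), size=(30, 2))
        parts = np.array([0] * 10 + [1] * 10 + [2] * 10)
        conds = np.array(["A", "B"] * 10 + ["A"] * 10)
        dyn = _make_dynamics(mats, parts, conds)
        with pytest.warns(UserWarning, match="single condition"):
            res = permutation_test_transitions(dyn, n_perm=50, seed=0)
        assert res.excluded_participants == ["2"]

    def test_pvalues_in_valid_range_and_fdr_subset(self):
        scene = default_scene()
        rng = np.random.default_rng(4)
        mats, parts, conds = _simulate_condition_dataset(
            scene.A_true, scene.transition_matrix("B"), scene.pi_true,
            400, 100, 5, rng,
        )
        res = permutation_test_transitions(_make_dynamics(mats, parts, conds),
                                           n_perm=200, seed=1)
        for lv in res.condition_levels:
            p = res.pvals[lv]
            assert (p >= 1 / 201 - 1e-12).all() and (p <= 1.0).all()
            assert (res.rejected[lv] <= (p <= res.q)).all()

    def test_type1_rate_near_nominal(self):
        """Shared chain in both conditions: false-rejection rate at
        q = 0.05 stays below 0.07 over 200 replicate datasets."""
        rate = transition_test_type1(n_replicates=200, n_perm=300, seed=5)
        assert rate <= 0.07

    def test_power_for_planted_difference(self):
        """A +0.15 increment on one directed transition is detected in at
        least 80% of replicates."""
        power = transition_test_power(n_replicates=50, n_perm=500, seed=6)
        assert power >= 0.8


class TestTemporalComparison:
    def _cells(self, rng, n_part=8, K=3, effect=0.0):
        rows = []
        for p in range(n_part):
            base = rng.random(K)
            for cond in ("A", "B"):
                for k in range(K):
                    v = base[k] + 0.1 * rng.standard_normal()
                    if cond == "A":
                        v += effect
                    rows.append({"participant": f"p{p}", "condition": cond,
                                 "state": k, "value": v})
        return pd.DataFrame(rows)

    def test_planted_condition_effect_detected(self):
        rng = np.random.default_rng(7)
        out = temporal_metric_comparison(self._cells(rng, effect=1.0), "fo", seed=0)
        tab = out["anova"]
        p = float(tab.loc[tab["effect"] == "condition", "Pr > F"].iloc[0])
        assert p < 0.001
        assert out["posthoc"]["significant"].all()

    def test_null_pvalues_roughly_uniform(self):
        """With no condition effect the main-effect p-values over
        replicates look uniform (KS test at the 1% level)."""
        from scipy.stats import kstest

        rng = np.random.default_rng(8)
        ps = []
        for _ in range(120):
            out = temporal_metric_comparison(self._cells(rng), "fo", n_perm=200, seed=0)
            tab = out["anova"]
            ps.append(float(tab.loc[tab["effect"] == "condition", "Pr > F"].iloc[0]))
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_switch_rate_is_paired_only(self):
        rng = np.random.default_rng(9)
        df = self._cells(rng, K=1, effect=0.5)
        out = temporal_metric_comparison(df, "switch_rate", seed=0)
        assert "anova" not in out
        assert out["posthoc"]["p"].iloc[0] < 0.05

    def test_too_few_participants_refused(self):
        rng = np.random.default_rng(10)
        with pytest.raises(ValueError, match="3 participants"):
            temporal_metric_comparison(self._cells(rng, n_part=2), "fo")
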