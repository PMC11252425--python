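"""Maximum-likelihood fitting, G² machinery, and effect sizes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coop_punish import (
    CategoryCounts,
    ModelSpec,
    ParameterSet,
    delta_g2_test,
    effect_size_w,
    expected_counts,
    fit,
    g_squared,
    simulate_counts,
)
from conftest import profile_grid_g2


def _pad(pair, slot=0):
    values = np.zeros(8)
    values[2 * slot : 2 * slot + 2] = pair
    return values


class TestGSquared:
    def test_perfect_fit_is_zero(self):
        obs = np.array([3, 1, 3, 1, 2, 2, 3, 1], dtype=float)
        assert g_squared(obs, obs) == 0.0

    def test_two_cell_value(self):
        assert g_squared(_pad([30, 70]), _pad([50, 50])) == pytest.approx(
            16.46, abs=0.005
        )

    def test_zero_observed_cell_contributes_nothing(self):
        stat = g_squared(_pad([0, 100]), _pad([10, 90]))
        assert stat == pytest.approx(2 * 100 * math.log(100 / 90), abs=1e-9)
        assert stat == pytest.approx(21.07, abs=0.005)

    def test_zero_expected_with_positive_observed_is_infinite(self):
        assert math.isinf(g_squared(_pad([5, 95]), _pad([0, 100])))


class TestFit:
    def test_noise_free_recovery(self):
        theta = ParameterSet(0.7, 0.6, 0.3, 0.2, 0.1)
        counts = {"s": CategoryCounts(np.round(expected_counts(theta, 1000, 1000)))}
        result = fit(counts, ModelSpec.saturated(["s"]), seed=4, n_restarts=3)
        assert result.converged
        assert result.g_squared == pytest.approx(0.0, abs=1e-6)
        for name, truth in zip(
            ("C", "P_Moral", "P_Hypocritical", "P_Antisocial", "b"),
            theta.as_array(),
        ):
            assert result.estimates[f"{name}[s]"] == pytest.approx(truth, abs=1e-3)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_profile_grid_oracle_on_small_counts(self, seed):
        """Optimizer G² agrees with an exhaustive profile-grid search."""
        rng = np.random.default_rng(seed)
        counts = CategoryCounts(
            np.concatenate(
                [rng.multinomial(25, np.full(4, 0.25)),
                 rng.multinomial(30, [0.15, 0.45, 0.2, 0.2])]
            )
        )
        result = fit({"s": counts}, ModelSpec.saturated(["s"]), seed=seed,
                     n_restarts=8, compute_se=False)
        assert result.g_squared == pytest.approx(
            profile_grid_g2(counts), abs=1e-3
        )

    def test_small_counts_fixture_against_oracle(self, small_counts):
        result = fit({"s": small_counts}, ModelSpec.saturated(["s"]), seed=0,
                     n_restarts=8, compute_se=False)
        assert result.g_squared == pytest.approx(
            profile_grid_g2(small_counts), abs=1e-3
        )

    def test_deterministic_given_seed_and_stratum_order(self):
        rng = np.random.default_rng(12)
        counts = {
            "a": simulate_counts(ParameterSet(0.5, 0.6, 0.2, 0.1, 0.05), 500, 500, rng),
            "b": simulate_counts(ParameterSet(0.5, 0.4, 0.3, 0.2, 0.10), 500, 500, rng),
        }
        spec = ModelSpec.saturated(["a", "b"]).tie("b")
        first = fit(counts, spec, seed=9, n_restarts=5)
        second = fit(counts, spec, seed=9, n_restarts=5)
        assert first.estimates == second.estimates
        assert first.g_squared == second.g_squared
        # stratum order of the counts mapping is irrelevant
        swapped = fit({"b": counts["b"], "a": counts["a"]}, spec, seed=9,
                      n_restarts=5)
        for key, value in first.estimates.items():
            assert swapped.estimates[key] == pytest.approx(value, abs=1e-6)

    def test_empty_tree_flags_unidentified(self):
        counts = {"s": CategoryCounts(np.array([0, 0, 0, 0, 3, 7, 4, 6]))}
        result = fit(counts, ModelSpec.saturated(["s"]), seed=0, n_restarts=2,
                     compute_se=False)
        assert "P_Moral[s]" in result.unidentified
        assert "P_Hypocritical[s]" in result.unidentified
        assert "C[s]" not in result.unidentified


class TestStandardErrors:
    def test_binomial_closed_form(self):
        """A lone cooperation parameter with no punishment stage reduces to
        the binomial SE sqrt(C(1-C)/N)."""
        spec = ModelSpec.saturated(["s"])
        for name in ("P_Moral", "P_Hypocritical", "P_Antisocial", "b"):
            spec = spec.fix("s", name, 0.0)
        counts = {"s": CategoryCounts(np.array([0, 30, 0, 70, 0, 40, 0, 60]))}
        result = fit(counts, spec, seed=0, n_restarts=2)
        c_hat = result.estimates["C[s]"]
        assert c_hat == pytest.approx(0.35, abs=1e-6)
        assert result.standard_errors["C[s]"] == pytest.approx(
            math.sqrt(c_hat * (1 - c_hat) / 200), rel=1e-4
        )

    def test_information_scaling(self):
        rng = np.random.default_rng(5)
        base = simulate_counts(ParameterSet(0.5, 0.6, 0.3, 0.2, 0.1), 400, 400, rng)
        doubled = CategoryCounts(base.values * 2)
        spec = ModelSpec.saturated(["s"])
        se1 = fit({"s": base}, spec, seed=0, n_restarts=3).standard_errors
        se2 = fit({"s": doubled}, spec, seed=0, n_restarts=3).standard_errors
        for key in se1:
            assert se2[key] == pytest.approx(se1[key] / math.sqrt(2), rel=1e-4)

    def test_monte_carlo_calibration(self):
        """Across replications, the spread of the estimates matches the
        average reported standard error."""
        truth = ParameterSet(0.55, 0.6, 0.3, 0.15, 0.08)
        spec = ModelSpec.saturated(["s"])
        rng = np.random.default_rng(77)
        estimates, ses = [], []
        for _ in range(200):
            counts = {"s": simulate_counts(truth, 1000, 1000, rng)}
            result = fit(counts, spec, seed=1, n_restarts=1)
            estimates.append(result.estimate_array())
            ses.append([result.standard_errors[k] for k in spec.free_parameters])
        sd = np.std(np.asarray(estimates), axis=0, ddof=1)
        mean_se = np.nanmean(np.asarray(ses), axis=0)
        np.testing.assert_allclose(sd, mean_se, rtol=0.15)


class TestDeltaG2:
    def test_null_restriction(self):
        rng = np.random.default_rng(3)
        counts = {
            "a": simulate_counts(ParameterSet(0.5, 0.5, 0.3, 0.2, 0.1), 300, 300, rng)
        }
        base = ModelSpec.saturated(["a"])
        result = delta_g2_test(counts, base, base, n_total=600, n_restarts=3)
        assert result.delta_g_squared == pytest.approx(0.0, abs=1e-6)
        assert result.df == 0
        assert result.p_value == 1.0

    def test_non_nested_specs_rejected_before_fitting(self):
        rng = np.random.default_rng(3)
        counts = {
            s: simulate_counts(ParameterSet(0.5, 0.5, 0.3, 0.2, 0.1), 50, 50, rng)
            for s in ("a", "b")
        }
        base = ModelSpec.saturated(["a", "b"]).tie("C")
        other = ModelSpec.saturated(["a", "b"]).tie("P_Moral")
        with pytest.raises(ValueError, match="not nested"):
            delta_g2_test(counts, base, other, n_total=200)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_nonnegative_and_additive_df(self, seed):
        """ΔG² ≥ 0 on arbitrary data, and chained restrictions add df."""
        rng = np.random.default_rng(seed)
        counts = {
            s: simulate_counts(
                ParameterSet(*rng.uniform(0.05, 0.95, size=5)), 200, 200, rng
            )
            for s in ("a", "b")
        }
        base = ModelSpec.saturated(["a", "b"])
        one = base.tie("P_Moral")
        two = one.tie("b")
        t1 = delta_g2_test(counts, base, one, n_total=800, n_restarts=3)
        t2 = delta_g2_test(counts, base, two, n_total=800, n_restarts=3)
        assert t1.delta_g_squared >= 0
        assert t2.delta_g_squared >= t1.delta_g_squared - 1e-6
        assert t1.df == 1 and t2.df == 2


class TestEffectSizeW:
    # every numerically printed (ΔG², w) pair of the three experiments
    PAIRS = [
        (3.24, 4120, 0.03),
        (13.61, 4120, 0.06),
        (8.37, 4120, 0.05),
        (31.40, 4120, 0.09),
        (16.28, 10160, 0.04),
        (14.64, 10160, 0.04),
        (6.45, 10160, 0.03),
        (0.40, 10160, 0.01),
        (35.17, 10540, 0.06),
        (11.63, 10540, 0.03),
        (0.96, 10540, 0.01),
        (13.38, 10540, 0.04),
        (5.67, 10540, 0.02),
    ]

    @pytest.mark.parametrize("delta, n_total, expected", PAIRS)
    def test_published_pairs(self, delta, n_total, expected):
        assert round(effect_size_w(delta, n_total), 2) == pytest.approx(expected)

    def test_zero_statistic(self):
        assert effect_size_w(0.0, 4120) == 0.0

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            effect_size_w(1.0, 0)
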