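"""Perceptual-model filters: HGF update correctness, associative rules,
learning-rate extraction, and filter invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sensolearn.errors import ModelDivergenceError
from sensolearn.learning import (
    BeliefTrajectory,
    HGFParameters,
    compute_learning_rates,
    hgf_filter,
    k1_filter,
    mean_learning_rate,
    rw_filter,
    trajectory_table,
)


def oracle_hgf_step(u, mu2, sa2, mu3, sa3, omega2, theta, kappa2=1.0,
                    mu4=None, sa4=None, omega3=None, kappa3=1.0):
    """Independent hand transcription of one binary-HGF update.

    Written from the published update equations, deliberately in a
    different style from the package filter (explicit precisions
    throughout); used to freeze expected one-step values.
    """
    muhat1 = 1.0 / (1.0 + math.exp(-mu2))
    pihat1 = 1.0 / (muhat1 * (1.0 - muhat1))
    da1 = u - muhat1

    top3 = mu4 is None
    vol2 = math.exp(kappa2 * mu3 + omega2)
    pihat2 = 1.0 / (sa2 + vol2)
    pi2 = pihat2 + 1.0 / pihat1
    mu2n = mu2 + (1.0 / pi2) * da1
    da2 = ((1.0 / pi2) + (mu2n - mu2) ** 2) * pihat2 - 1.0

    vol3 = theta if top3 else math.exp(kappa3 * mu4 + omega3)
    pihat3 = 1.0 / (sa3 + vol3)
    w2 = vol2 * pihat2
    pi3 = pihat3 + 0.5 * kappa2 ** 2 * w2 * (w2 + (2.0 * w2 - 1.0) * da2)
    mu3n = mu3 + 0.5 * (1.0 / pi3) * kappa2 * w2 * da2

    out = {"muhat1": muhat1, "da1": da1, "mu2": mu2n, "sa2": 1.0 / pi2,
           "da2": da2, "mu3": mu3n, "sa3": 1.0 / pi3}
    if not top3:
        da3 = ((1.0 / pi3) + (mu3n - mu3) ** 2) * pihat3 - 1.0
        pihat4 = 1.0 / (sa4 + theta)
        w3 = vol3 * pihat3
        pi4 = pihat4 + 0.5 * kappa3 ** 2 * w3 * (w3 + (2.0 * w3 - 1.0) * da3)
        mu4n = mu4 + 0.5 * (1.0 / pi4) * kappa3 * w3 * da3
        out.update({"da3": da3, "mu4": mu4n, "sa4": 1.0 / pi4})
    return out


class TestHGF:
    def test_first_prediction_is_half_for_zero_initial_tendency(self):
        traj = hgf_filter([1, 0], HGFParameters(levels=3))
        assert traj.muhat1[0] == 0.5
        assert traj.delta[1][0] == 0.5  # u=1 minus 0.5

    @pytest.mark.parametrize("u0", [0, 1])
    def test_one_step_matches_independent_oracle_hgf3(self, u0):
        p = HGFParameters(levels=3, omega2=-2.5, theta=0.004,
                          mu0=(0.3, 1.2), sigma0=(0.35, 0.8))
        traj = hgf_filter([u0], p)
        exp = oracle_hgf_step(u0, 0.3, 0.35, 1.2, 0.8, -2.5, 0.004)
        assert traj.muhat1[0] == pytest.approx(exp["muhat1"], abs=1e-10)
        assert traj.mu[2][0] == pytest.approx(exp["mu2"], abs=1e-10)
        assert traj.sigma[2][0] == pytest.approx(exp["sa2"], abs=1e-10)
        assert traj.delta[2][0] == pytest.approx(exp["da2"], abs=1e-10)
        assert traj.mu[3][0] == pytest.approx(exp["mu3"], abs=1e-10)
        assert traj.sigma[3][0] == pytest.approx(exp["sa3"], abs=1e-10)

    def test_one_step_matches_independent_oracle_hgf4(self):
        p = HGFParameters(levels=4, omega2=-2.0, omega3=-5.5, theta=0.003,
                          mu0=(0.1, 0.9, 1.1), sigma0=(0.2, 0.7, 1.3))
        traj = hgf_filter([1], p)
        exp = oracle_hgf_step(1, 0.1, 0.2, 0.9, 0.7, -2.0, 0.003,
                              mu4=1.1, sa4=1.3, omega3=-5.5)
        for key, got in [("mu2", traj.mu[2][0]), ("mu3", traj.mu[3][0]),
                         ("mu4", traj.mu[4][0]), ("sa2", traj.sigma[2][0]),
                         ("sa3", traj.sigma[3][0]), ("sa4", traj.sigma[4][0])]:
            assert got == pytest.approx(exp[key], abs=1e-10), key

    def test_iterated_oracle_agreement_and_monotone_rise(self):
        """Constant u=1 input: mu2 strictly increases, matching the
        oracle iterated over 50 trials."""
        p = HGFParameters(levels=3, omega2=-3.0, theta=0.0025)
        traj = hgf_filter([1] * 50, p)
        mu2, sa2, mu3, sa3 = 0.0, 0.1, 1.0, 1.0
        for k in range(50):
            exp = oracle_hgf_step(1, mu2, sa2, mu3, sa3, -3.0, 0.0025)
            assert traj.mu[2][k] == pytest.approx(exp["mu2"], abs=1e-10)
            mu2, sa2 = exp["mu2"], exp["sa2"]
            mu3, sa3 = exp["mu3"], exp["sa3"]
        assert np.all(np.diff(np.concatenate([[0.0], traj.mu[2]])) > 0)

    def test_hgf3_equals_clamped_hgf4(self):
        """HGF4 with kappa3 = 0 and the level-3 walk variance matching
        theta reproduces HGF3's level-2 trajectory to 1e-10."""
        u = np.random.default_rng(3).integers(0, 2, 60)
        theta = 0.004
        t3 = hgf_filter(u, HGFParameters(levels=3, omega2=-2.8, theta=theta))
        t4 = hgf_filter(u, HGFParameters(
            levels=4, omega2=-2.8, omega3=math.log(theta), theta=1e-8,
            kappa3=0.0))
        np.testing.assert_allclose(t4.mu[2], t3.mu[2], atol=1e-10)
        np.testing.assert_allclose(t4.sigma[2], t3.sigma[2], atol=1e-10)
        np.testing.assert_allclose(t4.mu[3], t3.mu[3], atol=1e-10)

    def test_causality_truncation(self):
        u = np.random.default_rng(5).integers(0, 2, 40)
        p = HGFParameters(levels=4)
        full = hgf_filter(u, p)
        half = hgf_filter(u[:20], p)
        np.testing.assert_array_equal(full.mu[2][:20], half.mu[2])
        np.testing.assert_array_equal(full.muhat1[:20], half.muhat1)

    def test_variances_stay_positive_or_divergence_is_signalled(self):
        u = [1, 0] * 30
        try:
            traj = hgf_filter(u, HGFParameters(levels=3, omega2=8.0,
                                               theta=50.0))
        except ModelDivergenceError as err:
            assert err.trial is not None
        else:
            for lev in (2, 3):
                assert np.all(traj.sigma[lev] > 0)

    def test_rejects_invalid_parameters(self):
        with pytest.raises(ValueError):
            HGFParameters(levels=3, theta=-1.0)
        with pytest.raises(ValueError):
            HGFParameters(levels=5)
        with pytest.raises(ValueError):
            HGFParameters(levels=3, sigma0=(0.0, 1.0))


class TestLearningRates:
    def test_frozen_beliefs_give_zero_rate(self):
        traj = BeliefTrajectory(
            u=np.array([1.0, 0.0]),
            muhat1=np.array([0.5, 0.5]),
            mu={2: np.zeros(2), 3: np.ones(2)},
            sigma={2: np.ones(2), 3: np.ones(2)},
            delta={1: np.array([0.5, -0.5]), 2: np.zeros(2)},
            params=HGFParameters(levels=3),
        )
        lr = compute_learning_rates(traj)
        np.testing.assert_allclose(lr[2], 0.0)

    def test_full_update_gives_unit_rate(self):
        """If the level-1 prediction jumps all the way to the observed
        input, the effective level-2 learning rate is 1."""
        from scipy.special import logit
        target = 1.0 - 1e-6
        traj = BeliefTrajectory(
            u=np.array([1.0]),
            muhat1=np.array([0.5]),
            mu={2: np.array([float(logit(target))]), 3: np.ones(1)},
            sigma={2: np.ones(1), 3: np.ones(1)},
            delta={1: np.array([0.5]), 2: np.zeros(1)},
            params=HGFParameters(levels=3),
        )
        lr = compute_learning_rates(traj)
        assert lr[2][0] == pytest.approx((target - 0.5) / 0.5, abs=1e-5)

    def test_rates_bounded_on_typical_trajectories(self):
        u = np.random.default_rng(11).integers(0, 2, 90)
        traj = hgf_filter(u, HGFParameters(levels=3, omega2=-2.0,
                                           theta=0.01))
        lr2 = traj.lr[2][np.isfinite(traj.lr[2])]
        assert np.all(lr2 >= 0) and np.all(lr2 <= 1)

    def test_higher_volatility_blocks_raise_level2_rate(self):
        """Over 100 seeded runs, the mean level-2 learning rate is
        higher in a volatile block (contingency flipping every 10
        trials) than in a stable block (p = 0.9 throughout)."""
        wins = 0
        p = HGFParameters(levels=3, omega2=-2.5, theta=0.1)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            stable = rng.binomial(1, 0.9, 45)
            vol = np.concatenate([
                rng.binomial(1, pr, 9) for pr in (0.9, 0.1, 0.9, 0.1, 0.9)
            ])
            u = np.concatenate([stable, vol])
            traj = hgf_filter(u, p)
            if np.nanmean(traj.lr[2][45:]) > np.nanmean(traj.lr[2][:45]):
                wins += 1
        assert wins >= 80

    def test_mean_learning_rate_respects_mask(self):
        u = np.random.default_rng(2).integers(0, 2, 30)
        traj = hgf_filter(u, HGFParameters(levels=3))
        mask = np.zeros(30, dtype=bool)
        mask[:10] = True
        m = mean_learning_rate(traj, 2, mask)
        assert m == pytest.approx(np.nanmean(traj.lr[2][:10]))


class TestAssociative:
    def test_rw_single_update(self):
        t = rw_filter([1], alpha=0.2, v0=0.5)
        assert t.v[0] == pytest.approx(0.6)

    @pytest.mark.parametrize("alpha,expect", [(0.0, "constant"), (1.0, "track")])
    def test_rw_limits(self, alpha, expect):
        u = np.array([1, 0, 0, 1, 1, 0])
        t = rw_filter(u, alpha=alpha, v0=0.5)
        if expect == "constant":
            np.testing.assert_allclose(t.v, 0.5)
        else:
            np.testing.assert_allclose(t.v, u)

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=60),
           st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_rw_value_is_convex_combination(self, u, alpha, v0):
        t = rw_filter(u, alpha=alpha, v0=v0)
        assert np.all(t.v >= -1e-12) and np.all(t.v <= 1 + 1e-12)

    def test_k1_reduces_to_rw_without_meta_learning(self):
        u = np.random.default_rng(0).integers(0, 2, 50)
        t_rw = rw_filter(u, alpha=0.3, v0=0.4)
        t_k1 = k1_filter(u, alpha0=0.3, mu_meta=0.0, v0=0.4)
        np.testing.assert_array_equal(t_k1.v, t_rw.v)
        np.testing.assert_array_equal(t_k1.alpha, t_rw.alpha)

    def test_k1_rate_grows_under_sustained_errors(self):
        """Persistent same-sign prediction errors (constant u=1 from a
        low start) make the K1 learning rate non-decreasing."""
        t = k1_filter([1] * 20, alpha0=0.05, mu_meta=0.5, v0=0.1)
        assert np.all(np.diff(t.alpha) >= -1e-15)
        assert t.alpha[-1] > t.alpha[0]

    def test_k1_five_trial_hand_computation(self):
        """Spreadsheet-style hand computation of the K1 recurrence."""
        u = [1, 1, 0, 1, 0]
        alpha0, mu_meta, v0 = 0.2, 0.3, 0.5
        beta, h, v = math.log(alpha0), 0.0, v0
        exp_v, exp_a = [], []
        for uk in u:
            d = uk - v
            beta = beta + mu_meta * d * h
            a = min(math.exp(beta), 1.0)
            v = v + a * d
            h = h * max(0.0, 1.0 - a) + a * d
            exp_v.append(v)
            exp_a.append(a)
        t = k1_filter(u, alpha0=alpha0, mu_meta=mu_meta, v0=v0)
        np.testing.assert_allclose(t.v, exp_v, atol=1e-12)
        np.testing.assert_allclose(t.alpha, exp_a, atol=1e-12)

    def test_associative_filters_are_causal(self):
        u = np.random.default_rng(1).integers(0, 2, 30)
        for f in (lambda x: rw_filter(x, 0.25, 0.5),
                  lambda x: k1_filter(x, 0.25, 0.2, 0.5)):
            full, half = f(u), f(u[:15])
            np.testing.assert_array_equal(full.v[:15], half.v)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            rw_filter([1], alpha=1.5)
        with pytest.raises(ValueError):
            k1_filter([1], alpha0=0.0, mu_meta=0.1)
        with pytest.raises(ValueError):
            k1_filter([1], alpha0=0.5, mu_meta=-0.1)


def test_trajectory_table_long_format():
    traj = hgf_filter([1, 0, 1], HGFParameters(levels=3))
    tab = trajectory_table(traj, subject="s1", model="HGF3")
    assert set(tab.columns) == {"subject", "model", "trial", "level",
                                "mu", "sigma", "delta", "alpha"}
    assert len(tab) == 3 * 2  # levels 2 and 3
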