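"""Velocity fluctuations, lateral correlation function, correlation length."""

import numpy as np
import pytest
from scipy import stats

from monolayer_mechanics import collectivity as coll, synthetic as syn
from monolayer_mechanics.fields import (
    CorrelationProfile,
    EstimationError,
    GridSpec,
    VectorField2D,
)


def make_velocity(lateral, spacing=20.7, front_axis="x"):
    lateral = np.asarray(lateral, dtype=float)
    g = GridSpec((0, 0), lateral.shape[1], lateral.shape[0], spacing)
    axial = np.zeros(g.shape)
    if front_axis == "x":
        return VectorField2D(g, axial, lateral, "um/min")
    return VectorField2D(g, lateral, axial, "um/min")


class TestLateralFluctuations:
    def test_uniform_lateral_velocity_gives_zero(self):
        v = make_velocity(np.full((4, 4), 3.3))
        f = coll.lateral_fluctuations(v, "x")
        np.testing.assert_allclose(f.u, 0.0, atol=1e-12)
        assert f.mean_removed == pytest.approx(3.3)

    def test_two_by_two_hand_case(self):
        v = make_velocity([[1.0, 3.0], [5.0, 7.0]])
        f = coll.lateral_fluctuations(v, "x")
        np.testing.assert_allclose(np.sort(f.u.ravel()), [-3, -1, 1, 3])

    def test_purely_axial_flow_gives_zero(self):
        g = GridSpec((0, 0), 4, 4, 20.7)
        v = VectorField2D(g, np.full(g.shape, 2.0), np.zeros(g.shape), "um/min")
        f = coll.lateral_fluctuations(v, "x")
        assert np.all(f.u == 0)

    def test_mean_is_removed_to_machine_precision(self):
        rng = np.random.default_rng(0)
        v = make_velocity(rng.normal(2.0, 1.0, (20, 20)))
        f = coll.lateral_fluctuations(v, "x")
        assert abs(f.u[f.valid].mean()) < 1e-10 * max(1.0, np.abs(f.u).max())


class TestCorrelationFunction:
    def test_sinusoid_matches_cosine(self):
        lam = 20.7 * 16
        y = 20.7 * np.arange(512)
        lateral = np.tile(np.sin(2 * np.pi * y / lam)[:, None], (1, 8))
        f = coll.lateral_fluctuations(make_velocity(lateral), "x")
        prof = coll.correlation_function(f, max_lag=20.7 * 40)
        expected = np.cos(2 * np.pi * prof.r / lam)
        assert np.abs(prof.C - expected).max() < 0.02

    def test_white_noise_is_uncorrelated(self):
        rng = np.random.default_rng(1)
        lateral = rng.normal(0, 1, (200, 50))
        f = coll.lateral_fluctuations(make_velocity(lateral), "x")
        prof = coll.correlation_function(f, max_lag=20.7 * 30)
        bound = 3.0 / np.sqrt(prof.n_pairs[1:])
        assert np.all(np.abs(prof.C[1:]) < bound)

    def test_periodic_pattern_self_similarity(self):
        period = 5
        col = np.arange(period, dtype=float)
        lateral = np.tile(col, 8)[:, None] * np.ones((1, 4))
        f = coll.lateral_fluctuations(make_velocity(lateral), "x")
        prof = coll.correlation_function(f, max_lag=20.7 * 10)
        at_lambda = np.argmin(np.abs(prof.r - period * 20.7))
        assert prof.C[at_lambda] == pytest.approx(1.0, abs=1e-10)

    def test_zero_fluctuations_raise(self):
        f = coll.lateral_fluctuations(make_velocity(np.full((6, 6), 1.0)), "x")
        with pytest.raises(EstimationError):
            coll.correlation_function(f)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        lateral = rng.normal(0, 1, (64, 16))
        f1 = coll.lateral_fluctuations(make_velocity(lateral), "x")
        f2 = coll.lateral_fluctuations(make_velocity(7.5 * lateral), "x")
        p1 = coll.correlation_function(f1)
        p2 = coll.correlation_function(f2)
        np.testing.assert_allclose(p1.C, p2.C, atol=1e-12)
        assert p1.corr_length == p2.corr_length

    def test_isotropic_variant_runs(self):
        rng = np.random.default_rng(3)
        lateral = rng.normal(0, 1, (24, 24))
        f = coll.lateral_fluctuations(make_velocity(lateral), "x")
        prof = coll.correlation_function(f, max_lag=20.7 * 8, pairs="isotropic")
        assert prof.C[0] == 1.0
        assert np.all(prof.n_pairs[1:] > 0)


class TestCorrelationLength:
    def test_exact_grid_crossing(self):
        prof = CorrelationProfile(
            r=np.array([0.0, 20.7, 41.4, 62.1]),
            C=np.array([1.0, 0.5, 0.01, -0.1]),
            n_pairs=np.array([10, 10, 10, 10]),
        )
        assert coll.correlation_length(prof) == pytest.approx(41.4)

    def test_exponential_profile(self):
        ell = 60.0
        r = np.arange(0, 3000, 5.0)
        prof = CorrelationProfile(r=r, C=np.exp(-r / ell), n_pairs=np.ones_like(r, int))
        L = coll.correlation_length(prof)
        assert L == pytest.approx(ell * np.log(100.0), abs=5.0)

    def test_cosine_profile(self):
        lam = 400.0
        r = np.arange(0, 400, 5.0)
        prof = CorrelationProfile(r=r, C=np.cos(2 * np.pi * r / lam),
                                  n_pairs=np.ones_like(r, int))
        L = coll.correlation_length(prof)
        assert L == pytest.approx(lam / (2 * np.pi) * np.arccos(0.01), abs=5.0)

    def test_no_crossing_is_undefined_not_clamped(self):
        r = np.arange(0, 100, 10.0)
        prof = CorrelationProfile(r=r, C=np.full_like(r, 0.5), n_pairs=np.ones_like(r, int))
        assert coll.correlation_length(prof) is None


class TestEstimatorRecovery:
    def test_median_recovery_at_one_scale(self):
        """Estimated threshold length tracks the analytic truth (ℓ = 50 µm)."""
        g = GridSpec((0, 0), 64, 256, 20.7)
        estimates = []
        for seed in range(15):
            f, truth = syn.make_correlated_velocity_field(g, 0.3, 0.2, 50.0, seed=seed)
            fl = coll.lateral_fluctuations(f, "x")
            prof = coll.correlation_function(fl)
            if prof.corr_length is not None:
                estimates.append(prof.corr_length)
        assert np.median(estimates) == pytest.approx(truth, rel=0.10)


class TestWelch:
    def test_identical_samples(self):
        t, df, p = coll.welch_t_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_hand_case(self):
        t, df, p = coll.welch_t_test([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert t == pytest.approx(-1.0)
        assert df == pytest.approx(8.0)

    def test_swap_antisymmetry(self):
        a, b = [1.0, 2.0, 4.0], [2.5, 3.5, 5.0, 6.0]
        t1, _, p1 = coll.welch_t_test(a, b)
        t2, _, p2 = coll.welch_t_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(3, 30))
            b = rng.normal(0.3, 2, rng.integers(3, 30))
            t, df, p = coll.welch_t_test(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert df == pytest.approx(ref.df, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_degenerate_samples_raise(self):
        with pytest.raises(EstimationError):
            coll.welch_t_test([1.0], [2.0, 3.0])
        with pytest.raises(EstimationError):
            coll.welch_t_test([1.0, 1.0], [2.0, 2.0])
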