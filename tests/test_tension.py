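"""Tension profiles: front detection, y-averaging, integration, bulk averages."""

import numpy as np
import pytest

from monolayer_mechanics import synthetic as syn, tension
from monolayer_mechanics.fields import (
    EstimationError,
    GeometryError,
    GridSpec,
    StressField,
    TensionField2D,
    VectorField2D,
)


@pytest.fixture
def grid20():
    return GridSpec((0, 0), 20, 20, 20.72)


class TestDetectFront:
    def test_straight_front(self, grid20):
        mask = np.zeros(grid20.shape, bool)
        mask[:, :10] = True
        assert tension.detect_front(mask, grid20) == pytest.approx(grid20.x[9])

    def test_sawtooth_front_averages(self, grid20):
        mask = np.zeros(grid20.shape, bool)
        mask[0::2, :10] = True
        mask[1::2, :14] = True
        expected = 0.5 * (grid20.x[9] + grid20.x[13])
        assert tension.detect_front(mask, grid20) == pytest.approx(expected)

    def test_translation_equivariance(self, grid20):
        mask = np.zeros(grid20.shape, bool)
        mask[:, :8] = True
        L1 = tension.detect_front(mask, grid20)
        L2 = tension.detect_front(np.roll(mask, 3, axis=1), grid20)
        assert L2 - L1 == pytest.approx(3 * grid20.spacing)

    def test_empty_and_full_masks_raise(self, grid20):
        with pytest.raises(EstimationError):
            tension.detect_front(np.zeros(grid20.shape, bool), grid20)
        with pytest.raises(EstimationError):
            tension.detect_front(np.ones(grid20.shape, bool), grid20)


class TestYAverage:
    def test_constant(self, grid20):
        x, p = tension.y_average(np.full(grid20.shape, 4.2), grid20)
        np.testing.assert_allclose(p, 4.2)

    def test_separable_field(self, grid20):
        X, _ = grid20.meshgrid()
        gx = np.sin(X / 100.0)
        x, p = tension.y_average(gx, grid20)
        np.testing.assert_allclose(p, np.sin(x / 100.0), atol=1e-12)

    def test_full_sine_period_averages_to_zero(self):
        g = GridSpec((0, 0), 4, 64, 10.0)
        _, Y = g.meshgrid()
        Ly = g.n_y * g.spacing
        f = np.sin(2 * np.pi * Y / Ly)
        _, p = tension.y_average(f, g)
        assert np.abs(p).max() < 0.02

    def test_gap_column_flagged(self, grid20):
        valid = np.ones(grid20.shape, bool)
        valid[:, 5] = False
        _, p = tension.y_average(np.ones(grid20.shape), grid20, valid)
        assert np.isnan(p[5]) and p[4] == 1.0


class TestTension1D:
    def test_constant_traction_gives_line_through_L(self, grid20):
        c = 0.4
        t = VectorField2D(grid20, np.full(grid20.shape, c), np.zeros(grid20.shape), "Pa")
        L = grid20.x[15]
        prof = tension.tension_1d(t, L)
        np.testing.assert_allclose(prof.tau, c * (prof.x - L), atol=1e-9)

    def test_two_step_hand_quadrature(self):
        g = GridSpec((0, 0), 6, 4, 10.0)
        tx = np.tile(np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0]), (4, 1))
        t = VectorField2D(g, tx, np.zeros(g.shape), "Pa")
        prof = tension.tension_1d(t, L=0.0)
        # trapezoid accumulation: [0, 10, 20, 35, 55, 75]
        np.testing.assert_allclose(prof.tau, [0.0, 10.0, 20.0, 35.0, 55.0, 75.0])

    def test_tau_at_L_is_zero_for_any_L(self, grid20):
        rng = np.random.default_rng(0)
        t = VectorField2D(grid20, rng.normal(0, 1, grid20.shape),
                          np.zeros(grid20.shape), "Pa")
        for L in (grid20.x[0], 123.4, grid20.x[-1]):
            prof = tension.tension_1d(t, L)
            assert np.interp(L, prof.x, prof.tau) == pytest.approx(0.0, abs=1e-9)

    def test_L_outside_grid_raises(self, grid20):
        t = VectorField2D(grid20, np.ones(grid20.shape), np.zeros(grid20.shape), "Pa")
        with pytest.raises(GeometryError):
            tension.tension_1d(t, L=-50.0)

    def test_fundamental_theorem(self, grid46):
        """Finite-difference d/dx of τ¹ᴰ recovers ⟨t_x⟩_y on smooth fields."""
        _, trac = syn.make_stress_field(
            grid46, "front_profile",
            {"amplitude": 50.0, "x_back": 150.0, "front": 700.0, "width": 100.0},
        )
        prof = tension.tension_1d(trac, L=700.0)
        d = np.gradient(prof.tau, prof.x)
        _, tx = tension.y_average(trac.u, grid46)
        keep = (np.abs(prof.x - 150.0) > 2 * grid46.spacing) \
            & (np.abs(prof.x - 700.0) > 2 * grid46.spacing)
        keep[:2] = keep[-2:] = False
        assert np.abs(d - tx)[keep].max() < 0.05 * np.abs(tx).max()


class TestIsotropicTension:
    def test_values(self, grid20):
        z = np.zeros(grid20.shape)
        s = StressField(grid20, np.full(grid20.shape, 2.0), np.full(grid20.shape, 4.0),
                        np.full(grid20.shape, 9.0))
        np.testing.assert_allclose(tension.isotropic_tension(s).tau, 3.0)
        s2 = StressField(grid20, np.full(grid20.shape, 5.0), np.full(grid20.shape, -5.0), z)
        np.testing.assert_allclose(tension.isotropic_tension(s2).tau, 0.0)


class TestBulkAverage:
    def test_uniform_field_margin_independent(self, grid46):
        t = TensionField2D(grid46, np.full(grid46.shape, 7.0))
        assert tension.bulk_average(t, 200.0) == pytest.approx(7.0)
        assert tension.bulk_average(t, 50.0) == pytest.approx(7.0)

    def test_node_selection_matches_enumeration(self):
        g = GridSpec((0, 0), 49, 49, 20.72)  # ~1000 µm square
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, g.shape)
        t = TensionField2D(g, vals)
        got = tension.bulk_average(t, 200.0)
        acc, n = 0.0, 0
        for iy in range(g.n_y):
            for ix in range(g.n_x):
                x, y = g.x[ix], g.y[iy]
                if 200.0 < x < g.x[-1] - 200.0 and 200.0 < y < g.y[-1] - 200.0:
                    acc += vals[iy, ix]
                    n += 1
        assert got == pytest.approx(acc / n)

    def test_edge_values_excluded(self, grid46):
        vals = np.zeros(grid46.shape)
        X, Y = grid46.meshgrid()
        edge = (X < 200) | (X > grid46.x[-1] - 200) | (Y < 200) | (Y > grid46.y[-1] - 200)
        vals[edge] = 1e6
        t = TensionField2D(grid46, vals)
        assert tension.bulk_average(t, 200.0) == 0.0

    def test_margin_consuming_field_raises(self, grid20):
        t = TensionField2D(grid20, np.ones(grid20.shape))
        with pytest.raises(EstimationError):
            tension.bulk_average(t, 500.0)


class TestCompare1D2D:
    def test_exact_synthetic_identity(self, grid46):
        """For σxx(x) with σxx(L) = 0 and t = div σ, τ¹ᴰ = ⟨σxx⟩_y within 2%."""
        stress, trac = syn.make_stress_field(
            grid46, "front_profile",
            {"amplitude": 50.0, "x_back": 150.0, "front": 700.0, "width": 100.0,
             "modulation": 0.2},
        )
        tau1d = tension.tension_1d(trac, L=700.0)
        _, _, rel = tension.compare_1d_2d(tau1d, stress, margin=200.0)
        assert rel < 0.02

    def test_sxx_profile_ignores_other_components(self, grid46):
        stress, trac = syn.make_stress_field(
            grid46, "front_profile",
            {"amplitude": 50.0, "x_back": 150.0, "front": 700.0, "width": 100.0},
        )
        tau1d = tension.tension_1d(trac, L=700.0)
        _, p1, _ = tension.compare_1d_2d(tau1d, stress, margin=200.0)
        perturbed = StressField(grid46, stress.sxx, stress.syy + 5.0, stress.sxy + 2.0)
        _, p2, _ = tension.compare_1d_2d(tau1d, perturbed, margin=200.0)
        np.testing.assert_allclose(p1.tau, p2.tau)

    def test_zero_traction_gives_zero_profiles(self, grid46):
        z = VectorField2D(grid46, np.zeros(grid46.shape), np.zeros(grid46.shape), "Pa")
        zs = StressField(grid46, np.zeros(grid46.shape), np.zeros(grid46.shape),
                         np.zeros(grid46.shape))
        tau1d = tension.tension_1d(z, L=grid46.x[-1])
        p1, p2, _ = tension.compare_1d_2d(tau1d, zs, margin=200.0)
        assert np.all(p1.tau == 0) and np.all(p2.tau == 0)

    def test_positive_into_bulk_on_front_scene(self, scene):
        """Behind a pulling front the integrated tension is non-negative."""
        k = 1
        prof = tension.tension_1d(scene.truth_traction[k], scene.truth_front.L[k])
        # judge where the coherent tension dominates the cell-scale ripple
        inside = (prof.x > scene.params["x_back"] + 2 * scene.params["rise_width"]) \
            & (prof.x < scene.truth_front.L[k])
        assert prof.tau[inside].min() > -1e-6 * max(1.0, prof.tau.max())
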