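"""Ground-truth generators: determinism, analytic self-consistency."""

import numpy as np
import pytest

from monolayer_mechanics import bism, synthetic as syn, tension
from monolayer_mechanics.fields import (
    GeometryError,
    GridSpec,
    ParameterError,
    VectorField2D,
)


class TestBeadImage:
    def test_no_beads_no_noise_is_constant(self):
        img = syn.make_bead_image(64, 64, 0, noise_sd=0.0, seed=0, background=7.0)
        assert np.all(img == 7.0)

    def test_integrated_intensity_matches_gaussian_mass(self):
        sigma, peak, n = 1.5, 200.0, 100
        img = syn.make_bead_image(
            256, 256, n, bead_sigma_px=sigma, peak_intensity=peak, noise_sd=0.0,
            seed=2, background=0.0,
        )
        expected = n * 2.0 * np.pi * sigma**2 * peak
        assert img.sum() == pytest.approx(expected, rel=0.05)

    def test_seed_determinism(self):
        a = syn.make_bead_image(64, 64, 50, noise_sd=2.0, seed=9)
        b = syn.make_bead_image(64, 64, 50, noise_sd=2.0, seed=9)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("kwargs", [dict(width_px=32), dict(bead_sigma_px=0.0),
                                        dict(noise_sd=-1.0)])
    def test_parameter_errors(self, kwargs):
        base = dict(width_px=64, height_px=64, n_beads=5, seed=0)
        base.update(kwargs)
        with pytest.raises(ParameterError):
            syn.make_bead_image(**base)


class TestWarpImage:
    def _uniform(self, dx, dy, n=17, spacing=16.0):
        g = GridSpec((0, 0), n, n, spacing)
        return VectorField2D(g, np.full(g.shape, dx), np.full(g.shape, dy), "px")

    def test_zero_displacement_is_identity(self, bead_image):
        out = syn.warp_image(bead_image, self._uniform(0.0, 0.0))
        np.testing.assert_allclose(out, bead_image, atol=1e-9)

    def test_integer_translation(self, bead_image):
        out = syn.warp_image(bead_image, self._uniform(3.0, 0.0))
        np.testing.assert_allclose(out[:, 3:], bead_image[:, :-3], atol=1e-9)

    def test_subpixel_shift_moves_centroid(self):
        img = syn.render_gaussian_spots((64, 64), np.array([32.0]), np.array([32.0]),
                                        2.0, 100.0)
        g = GridSpec((0, 0), 5, 5, 16.0)
        d = VectorField2D(g, np.full(g.shape, 0.5), np.zeros(g.shape), "px")
        out = syn.warp_image(img, d)
        xs = np.arange(64)
        c_in = (img.sum(axis=0) * xs).sum() / img.sum()
        c_out = (out.sum(axis=0) * xs).sum() / out.sum()
        assert c_out - c_in == pytest.approx(0.5, abs=0.05)

    def test_grid_not_covering_image_raises(self, bead_image):
        g = GridSpec((0, 0), 5, 5, 16.0)  # covers 64 px, image is 256
        d = VectorField2D(g, np.zeros(g.shape), np.zeros(g.shape), "px")
        with pytest.raises(GeometryError):
            syn.warp_image(bead_image, d)


class TestCorrelatedVelocityField:
    def test_zero_fluctuations(self):
        g = GridSpec((0, 0), 32, 32, 20.7)
        f, _ = syn.make_correlated_velocity_field(g, 0.3, 0.0, 50.0, seed=0)
        assert np.all(f.v == 0.0)
        assert np.all(f.u == 0.3)

    def test_analytic_threshold_lengths(self):
        assert syn.gaussian_threshold_length(50.0) == pytest.approx(151.74, abs=0.01)
        assert syn.exponential_threshold_length(50.0) == pytest.approx(230.26, abs=0.01)

    def test_covariance_at_one_corr_length(self):
        """Monte-Carlo normalised correlation at r = ℓ matches exp(-1/2)."""
        g = GridSpec((0, 0), 64, 256, 20.7)
        ell = 2 * 20.7  # two grid steps, so C(2 steps) has the closed form
        num = den = 0.0
        for seed in range(50):
            f, _ = syn.make_correlated_velocity_field(g, 0.0, 0.2, ell, seed=seed)
            v = f.v
            num += (v[:-2] * v[2:]).mean()
            den += (v**2).mean()
        assert num / den == pytest.approx(np.exp(-0.5), abs=0.03)

    def test_corr_length_below_spacing_raises(self):
        g = GridSpec((0, 0), 32, 32, 20.7)
        with pytest.raises(ParameterError):
            syn.make_correlated_velocity_field(g, 0.3, 0.1, 10.0, seed=0)

    def test_determinism(self):
        g = GridSpec((0, 0), 32, 32, 20.7)
        a, _ = syn.make_correlated_velocity_field(g, 0.3, 0.1, 60.0, seed=4)
        b, _ = syn.make_correlated_velocity_field(g, 0.3, 0.1, 60.0, seed=4)
        np.testing.assert_array_equal(a.v, b.v)


def _numerical_divergence(stress, grid):
    h = grid.spacing
    tx = np.gradient(stress.sxx, h, axis=1) + np.gradient(stress.sxy, h, axis=0)
    ty = np.gradient(stress.sxy, h, axis=1) + np.gradient(stress.syy, h, axis=0)
    return tx, ty


class TestStressFields:
    def test_constant_stress_zero_traction(self, grid46):
        _, trac = syn.make_stress_field(grid46, "constant", {"sxx": 5, "syy": 3})
        assert np.all(trac.u == 0) and np.all(trac.v == 0)

    def test_linear_ramp(self, grid46):
        stress, trac = syn.make_stress_field(grid46, "linear_ramp", {"a": 2.0, "L": 500.0})
        assert np.all(trac.u == 2.0) and np.all(trac.v == 0.0)
        np.testing.assert_allclose(stress.sxx[0], 2.0 * (grid46.x - 500.0))

    @pytest.mark.parametrize("kind,params", [
        ("gaussian_bump", {"amplitude": 10.0, "center": (450, 480), "width": 80.0}),
        ("front_profile", {"amplitude": 50.0, "x_back": 120.0, "front": 700.0,
                           "width": 90.0, "modulation": 0.2}),
        ("potential_bumps", {"bumps": [
            {"potential": "x", "amplitude": 4e3, "center": (400, 450), "width": 90},
            {"potential": "y", "amplitude": 3e3, "center": (520, 380), "width": 110},
        ]}),
    ])
    def test_traction_is_divergence_of_stress(self, grid46, kind, params):
        """Analytic traction agrees with numerical differentiation of σ."""
        stress, trac = syn.make_stress_field(grid46, kind, params)
        tx, ty = _numerical_divergence(stress, grid46)
        scale = max(np.abs(trac.u).max(), np.abs(trac.v).max())
        keep = np.ones(grid46.shape, bool)
        keep[:2] = keep[-2:] = keep[:, :2] = keep[:, -2:] = False
        if kind == "front_profile":
            # the plateau profile is C¹ but its curvature jumps at the two
            # margins; finite differences are first-order there
            X, _ = grid46.meshgrid()
            for kink in (params["x_back"], params["front"]):
                keep &= np.abs(X - kink) > 2 * grid46.spacing
        assert np.abs(tx - trac.u)[keep].max() < 0.05 * scale
        assert np.abs(ty - trac.v)[keep].max() < 0.05 * scale

    def test_unknown_kind_raises(self, grid46):
        with pytest.raises(ParameterError):
            syn.make_stress_field(grid46, "weird")

    def test_force_balance_residual_refines_quadratically(self):
        """Halving the spacing quarters the discrete-divergence residual."""
        residuals = []
        for spacing, n in ((20.72, 46), (10.36, 91)):
            g = GridSpec((0, 0), n, n, spacing)
            stress, trac = syn.make_stress_field(
                g, "gaussian_bump",
                {"amplitude": 10.0, "center": (460, 460), "width": 80.0},
            )
            A = bism.assemble_force_balance(g)
            sigma = np.concatenate(
                [stress.sxx.ravel(), stress.syy.ravel(), stress.sxy.ravel()]
            )
            t = np.concatenate([trac.u.ravel(), trac.v.ravel()])
            n_nodes = g.n_x * g.n_y
            # interior residual (one-sided edge stencils are lower order)
            r = (A @ sigma - t)[:n_nodes].reshape(g.shape)[3:-3, 3:-3]
            residuals.append(np.sqrt((r**2).mean()))
        ratio = residuals[0] / residuals[1]
        assert ratio == pytest.approx(4.0, rel=0.2)


class TestJunctionImage:
    def test_zero_peaks_is_pure_noise(self):
        img = syn.make_junction_image((64, 64), ((10, 10), (50, 50)),
                                      channel_peaks=(0.0, 0.0), noise_sd=1.0, seed=0,
                                      background=0.0)
        assert abs(img.mean()) < 0.5
        assert img.std() == pytest.approx(1.0, rel=0.1)

    def test_vertical_interface_row_peaks(self):
        x0 = 30.0
        img = syn.make_junction_image((64, 64), ((x0, 5), (x0, 58)),
                                      ridge_sigma_px=2.0, noise_sd=0.0, seed=0)
        for row in range(10, 54):
            profile = img[0, row]
            assert abs(np.argmax(profile) - x0) <= 0.1 + 1e-12

    def test_determinism_and_degenerate_segment(self):
        a = syn.make_junction_image((64, 64), ((10, 10), (50, 50)), seed=3)
        b = syn.make_junction_image((64, 64), ((10, 10), (50, 50)), seed=3)
        np.testing.assert_array_equal(a, b)
        with pytest.raises(GeometryError):
            syn.make_junction_image((64, 64), ((10, 10), (10, 10)))


class TestExpandingFrontScenario:
    def test_static_front_when_speed_zero(self):
        s = syn.make_expanding_front_scenario(front_speed=0.0, seed=2, image_px=320,
                                              grid_nodes=16, front_start=300.0,
                                              x_back=80.0, n_beads=800)
        assert np.all(s.truth_front.L == s.truth_front.L[0])

    def test_zero_amplitude_zero_truth(self):
        s = syn.make_expanding_front_scenario(
            tension_amplitude=0.0, incoherent_traction=0.0, seed=2, image_px=320,
            grid_nodes=16, front_start=300.0, x_back=80.0, n_beads=800,
        )
        for trac, stress in zip(s.truth_traction, s.truth_stress):
            assert np.all(trac.u == 0) and np.all(trac.v == 0)
            assert np.all(stress.sxx == 0)

    def test_truth_tension_quadrature_matches_closed_form(self):
        """∫⟨t_x⟩_y dx from the front reproduces the closed-form profile."""
        s = syn.make_expanding_front_scenario(seed=4, incoherent_traction=0.0,
                                              n_beads=500)
        k = 1
        L = s.truth_front.L[k]
        tau = tension.tension_1d(s.truth_traction[k], L)
        p = s.params
        f = syn._front_profile_fx(tau.x, p["x_back"], L, p["rise_width"])
        truth = p["tension_amplitude"] * f
        sel = (tau.x > p["x_back"]) & (tau.x < L)
        rms = np.sqrt(np.mean((tau.tau[sel] - truth[sel]) ** 2))
        assert rms < 0.01 * truth.max()

    def test_determinism(self):
        kw = dict(seed=5, image_px=320, grid_nodes=16, front_start=300.0,
                  x_back=80.0, n_beads=500, n_frames=3)
        a = syn.make_expanding_front_scenario(**kw)
        b = syn.make_expanding_front_scenario(**kw)
        np.testing.assert_array_equal(a.bead_movie.frames[1], b.bead_movie.frames[1])
        np.testing.assert_array_equal(a.truth_velocity.v, b.truth_velocity.v)

    def test_front_leaving_fov_raises(self):
        with pytest.raises(GeometryError):
            syn.make_expanding_front_scenario(front_speed=50.0, n_frames=5, seed=0,
                                              image_px=320, grid_nodes=16,
                                              front_start=300.0, x_back=80.0,
                                              n_beads=500)

    def test_too_few_frames_raises(self):
        with pytest.raises(ParameterError):
            syn.make_expanding_front_scenario(n_frames=2, seed=0)
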