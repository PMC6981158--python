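"""Traction force microscopy on a linear elastic half-space.

The substrate is a soft polyacrylamide gel (Young's modulus 200 Pa by
default, Poisson ratio 0.5) treated as a semi-infinite incompressible
solid.  Surface displacement and surface traction are related by
convolution with the Boussinesq Green tensor, which is diagonalised by the
Fourier transform:

    û(k) = Ĝ(k) t̂(k),
    Ĝ(k) = 2(1+ν)/(E k³) [ (1−ν)k² + ν k_y²,   −ν k_x k_y
                            −ν k_x k_y,         (1−ν)k² + ν k_x² ]

Forward evaluation (traction → displacement) is the oracle used in tests;
the inverse (Fourier-transform traction cytometry, FTTC) solves the 2×2
system per wavevector with zeroth-order Tikhonov regularisation.  Both
directions are computed on a zero-padded grid to suppress periodic images,
and the unobservable zero-frequency mode is pinned to zero (zero-mean
displacement / zero net traction), never divided by.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RectBivariateSpline

from .fields import (
    EstimationError,
    GeometryError,
    GridSpec,
    ParameterError,
    VectorField2D,
)
from . import piv as _piv

__all__ = [
    "SubstrateModel",
    "TfmConfig",
    "bead_displacement",
    "forward_displacement",
    "reconstruct_traction",
    "select_regularization",
    "calibrate_regularization",
    "mean_traction_norm",
]


@dataclass(frozen=True)
class SubstrateModel:
    """Elastic substrate: semi-infinite, homogeneous, isotropic."""

    young_modulus: float = 200.0  # Pa
    poisson_ratio: float = 0.5
    geometry: str = "semi_infinite"

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise ParameterError("Young's modulus must be > 0")
        if not (0 <= self.poisson_ratio <= 0.5):
            raise ParameterError("Poisson ratio must be in [0, 0.5]")
        if self.geometry != "semi_infinite":
            raise ParameterError("only the semi-infinite substrate is supported")


@dataclass(frozen=True)
class TfmConfig:
    """Traction reconstruction grid and regularisation settings."""

    grid_nodes: int = 46
    grid_spacing: float = 20.72  # µm
    regularization: float = 0.0  # Tikhonov parameter, units of µm/Pa
    smooth_sigma_nodes: float = 0.0  # Gaussian pre-filter of u, in grid nodes
    drift_correct: bool = False

    def __post_init__(self) -> None:
        if self.grid_nodes < 8:
            raise ParameterError("grid_nodes must be >= 8")
        if self.regularization < 0 or self.smooth_sigma_nodes < 0:
            raise ParameterError("regularization and smoothing must be >= 0")


def bead_displacement(
    stressed: np.ndarray,
    reference: np.ndarray,
    cfg: _piv.PivConfig = _piv.PivConfig(),
    pixel_size: float = 1.294,
    drift_margin_px: int | None = None,
) -> VectorField2D:
    """Substrate displacement (µm) of the stressed state vs the relaxed reference.

    Runs PIV of the stressed bead image against the relaxed reference and
    converts to µm.  If ``drift_margin_px`` is given, the median vector
    within that margin (assumed cell-free) is subtracted as rigid stage
    drift.
    """
    raw = _piv.piv_displacement(reference, stressed, cfg)
    fieldpx = _piv.interpolate_to_grid(raw, cfg.nodal_distance_px, pixel_size)
    if drift_margin_px is not None:
        margin_um = drift_margin_px * pixel_size
        g = fieldpx.grid
        X, Y = g.meshgrid()
        edge = (
            (X < g.x[0] + margin_um)
            | (X > g.x[-1] - margin_um)
            | (Y < g.y[0] + margin_um)
            | (Y > g.y[-1] - margin_um)
        ) & fieldpx.valid
        if edge.any():
            fieldpx.u -= np.median(fieldpx.u[edge])
            fieldpx.v -= np.median(fieldpx.v[edge])
    return fieldpx.scaled(pixel_size, unit="um")


def _green_tensor(kx: np.ndarray, ky: np.ndarray, substrate: SubstrateModel):
    """Fourier-space Boussinesq Green tensor components (µm/Pa units).

    Returns (Gxx, Gxy, Gyy) arrays; the k = 0 entry is set to 0 (the
    uniform traction mode produces no finite displacement on a half-space
    and is excluded from both directions of the transform).
    """
    E = substrate.young_modulus
    nu = substrate.poisson_ratio
    KX, KY = np.meshgrid(kx, ky)
    k2 = KX**2 + KY**2
    k = np.sqrt(k2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = 2.0 * (1.0 + nu) / (E * k2 * k)
        gxx = pref * ((1.0 - nu) * k2 + nu * KY**2)
        gyy = pref * ((1.0 - nu) * k2 + nu * KX**2)
        gxy = pref * (-nu * KX * KY)
    for g in (gxx, gyy, gxy):
        g[k2 == 0] = 0.0
    return gxx, gxy, gyy


def forward_displacement(
    traction: VectorField2D, substrate: SubstrateModel = SubstrateModel()
) -> VectorField2D:
    """Surface displacement (µm) produced by a traction field (Pa).

    Spectral convolution with the Boussinesq tensor on a grid zero-padded
    to twice the field size.  The traction should decay to ~0 at the field
    border; otherwise wraparound contaminates the result.
    """
    if traction.unit != "Pa":
        raise ParameterError(f"traction field must carry unit 'Pa', got {traction.unit!r}")
    g = traction.grid
    n_y, n_x = g.shape
    pad_y, pad_x = 2 * n_y, 2 * n_x
    h = g.spacing
    tx = np.zeros((pad_y, pad_x))
    ty = np.zeros((pad_y, pad_x))
    tx[:n_y, :n_x] = traction.u
    ty[:n_y, :n_x] = traction.v
    kx = 2.0 * np.pi * np.fft.fftfreq(pad_x, d=h)
    ky = 2.0 * np.pi * np.fft.fftfreq(pad_y, d=h)
    gxx, gxy, gyy = _green_tensor(kx, ky, substrate)
    ftx = np.fft.fft2(tx)
    fty = np.fft.fft2(ty)
    ux = np.fft.ifft2(gxx * ftx + gxy * fty).real[:n_y, :n_x]
    uy = np.fft.ifft2(gxy * ftx + gyy * fty).real[:n_y, :n_x]
    return VectorField2D(grid=g, u=ux, v=uy, unit="um", valid=traction.valid.copy())


def _resample_to_grid(displacement: VectorField2D, grid: GridSpec) -> VectorField2D:
    """Cubic-spline resampling of a displacement field onto the TFM grid."""
    g = displacement.grid
    if (
        grid.x[0] < g.x[0] - g.spacing
        or grid.x[-1] > g.x[-1] + g.spacing
        or grid.y[0] < g.y[0] - g.spacing
        or grid.y[-1] > g.y[-1] + g.spacing
    ):
        raise GeometryError("TFM grid extends beyond the measured displacement field")
    ky = kx = min(3, g.n_y - 1, g.n_x - 1)
    spl_u = RectBivariateSpline(g.y, g.x, displacement.u, kx=kx, ky=ky)
    spl_v = RectBivariateSpline(g.y, g.x, displacement.v, kx=kx, ky=ky)
    return VectorField2D(
        grid=grid,
        u=spl_u(grid.y, grid.x),
        v=spl_v(grid.y, grid.x),
        unit="um",
    )


def reconstruct_traction(
    displacement: VectorField2D,
    substrate: SubstrateModel = SubstrateModel(),
    cfg: TfmConfig = TfmConfig(),
    grid: GridSpec | None = None,
) -> VectorField2D:
    """Fourier-transform traction cytometry (FTTC).

    Inverts the Boussinesq convolution with zeroth-order Tikhonov
    regularisation: per wavevector the 2×2 system
    ``(ĜᴴĜ + λ² I) t̂ = Ĝᴴ û`` is solved, on a zero-padded grid, then
    cropped.  The zero-frequency traction is pinned to zero (no net
    force), which also removes the singular k = 0 mode.

    ``grid`` overrides the default reconstruction grid built from
    ``cfg.grid_nodes`` / ``cfg.grid_spacing`` (anchored at the
    displacement field's origin).
    """
    if displacement.unit != "um":
        raise ParameterError("displacement must be in µm")
    if grid is None:
        grid = GridSpec(
            origin=displacement.grid.origin,
            n_x=cfg.grid_nodes,
            n_y=cfg.grid_nodes,
            spacing=cfg.grid_spacing,
        )
    if not displacement.grid.same_geometry(grid):
        displacement = _resample_to_grid(displacement, grid)
    if cfg.smooth_sigma_nodes > 0:
        from scipy import ndimage

        displacement = VectorField2D(
            grid=grid,
            u=ndimage.gaussian_filter(displacement.u, cfg.smooth_sigma_nodes),
            v=ndimage.gaussian_filter(displacement.v, cfg.smooth_sigma_nodes),
            unit="um",
            valid=displacement.valid.copy(),
        )

    n_y, n_x = grid.shape
    pad_y, pad_x = 2 * n_y, 2 * n_x
    h = grid.spacing
    ux = np.zeros((pad_y, pad_x))
    uy = np.zeros((pad_y, pad_x))
    ux[:n_y, :n_x] = displacement.u
    uy[:n_y, :n_x] = displacement.v
    kx = 2.0 * np.pi * np.fft.fftfreq(pad_x, d=h)
    ky = 2.0 * np.pi * np.fft.fftfreq(pad_y, d=h)
    gxx, gxy, gyy = _green_tensor(kx, ky, substrate)
    fux = np.fft.fft2(ux)
    fuy = np.fft.fft2(uy)

    lam2 = cfg.regularization**2
    # Ĝ is real symmetric: normal equations componentwise
    a11 = gxx * gxx + gxy * gxy + lam2
    a12 = gxy * (gxx + gyy)
    a22 = gxy * gxy + gyy * gyy + lam2
    b1 = gxx * fux + gxy * fuy
    b2 = gxy * fux + gyy * fuy
    det = a11 * a22 - a12 * a12
    with np.errstate(divide="ignore", invalid="ignore"):
        ftx = (a22 * b1 - a12 * b2) / det
        fty = (a11 * b2 - a12 * b1) / det
    # pin the k = 0 mode explicitly (zero-mean traction)
    ftx[0, 0] = 0.0
    fty[0, 0] = 0.0
    ftx[~np.isfinite(ftx)] = 0.0
    fty[~np.isfinite(fty)] = 0.0

    tx = np.fft.ifft2(ftx).real[:n_y, :n_x]
    ty = np.fft.ifft2(fty).real[:n_y, :n_x]
    # enforce the zero-mean (no net force) constraint on the cropped field
    tx -= tx.mean()
    ty -= ty.mean()
    return VectorField2D(grid=grid, u=tx, v=ty, unit="Pa")


def select_regularization(
    displacement: VectorField2D,
    substrate: SubstrateModel = SubstrateModel(),
    cfg: TfmConfig = TfmConfig(),
    grid: GridSpec | None = None,
    candidates: np.ndarray | None = None,
) -> float:
    """L-curve corner search for the Tikhonov parameter.

    Scans candidate λ values, records residual norm ‖Ĝ t̂ − û‖ and solution
    norm ‖t̂‖, and returns the λ of maximum curvature of the log–log
    L-curve.  A helper, not an oracle: the chosen λ is surfaced in config
    and can always be overridden.
    """
    if candidates is None:
        # scale candidates to the problem: λ ~ Ĝ magnitude at mid frequencies
        gscale = 2.0 * (1.0 + substrate.poisson_ratio) / substrate.young_modulus
        span = (displacement.grid.n_x * displacement.grid.spacing) / (2 * np.pi)
        candidates = gscale * span * np.logspace(-5, 0, 24)
    res, sol = [], []
    for lam in candidates:
        c = TfmConfig(
            grid_nodes=cfg.grid_nodes,
            grid_spacing=cfg.grid_spacing,
            regularization=float(lam),
            drift_correct=cfg.drift_correct,
        )
        t = reconstruct_traction(displacement, substrate, c, grid=grid)
        u_back = forward_displacement(t, substrate)
        du = np.hypot(u_back.u - _match(displacement, t.grid).u,
                      u_back.v - _match(displacement, t.grid).v)
        res.append(np.sqrt((du**2).mean()))
        sol.append(np.sqrt((t.u**2 + t.v**2).mean()))
    lr = np.log10(np.maximum(res, 1e-300))
    ls = np.log10(np.maximum(sol, 1e-300))
    # discrete curvature of the parametric curve (lr, ls)
    best, best_curv = float(candidates[len(candidates) // 2]), -np.inf
    for i in range(1, len(candidates) - 1):
        v1 = np.array([lr[i] - lr[i - 1], ls[i] - ls[i - 1]])
        v2 = np.array([lr[i + 1] - lr[i], ls[i + 1] - ls[i]])
        cross = v1[0] * v2[1] - v1[1] * v2[0]
        denom = np.linalg.norm(v1) * np.linalg.norm(v2)
        if denom == 0:
            continue
        curv = cross / denom
        if curv > best_curv:
            best_curv, best = curv, float(candidates[i])
    return best


def calibrate_regularization(
    grid: GridSpec,
    substrate: SubstrateModel,
    noise_sd: float,
    feature_scale: float = 100.0,
    amplitude: float = 1.0,
    smooth_sigma_nodes: float = 1.3,
    seed: int = 0,
    candidates: np.ndarray | None = None,
) -> TfmConfig:
    """Simulation-based calibration of the inversion settings.

    Builds a synthetic calibration scene matched to the measurement
    conditions — a smooth force-dipole traction field of the stated
    feature scale on the same grid and substrate, with displacement noise
    of the stated sd — and returns the TfmConfig (pre-smoothing +
    Tikhonov parameter) minimising the true reconstruction error on that
    scene.  The calibration scene is internal and independent of any
    particular measurement, so the chosen parameters transfer to data of
    comparable feature scale and noise.
    """
    rng = np.random.default_rng(seed)
    X, Y = grid.meshgrid()
    cx, cy = grid.x.mean(), grid.y.mean()
    sep = 2.2 * feature_scale
    w = feature_scale
    tx = amplitude * (
        np.exp(-((X - cx - sep / 2) ** 2 + (Y - cy) ** 2) / (2 * w**2))
        - np.exp(-((X - cx + sep / 2) ** 2 + (Y - cy) ** 2) / (2 * w**2))
    )
    ty = 0.6 * amplitude * (
        np.exp(-((X - cx) ** 2 + (Y - cy - sep / 2) ** 2) / (2 * w**2))
        - np.exp(-((X - cx) ** 2 + (Y - cy + sep / 2) ** 2) / (2 * w**2))
    )
    truth = VectorField2D(grid=grid, u=tx, v=ty, unit="Pa")
    u = forward_displacement(truth, substrate)
    noisy = VectorField2D(
        grid=grid,
        u=u.u + rng.normal(0.0, noise_sd, grid.shape),
        v=u.v + rng.normal(0.0, noise_sd, grid.shape),
        unit="um",
    )
    if candidates is None:
        candidates = np.logspace(-3, 0.5, 18)
    den = (tx**2 + ty**2).sum()
    best_cfg, best_err = None, np.inf
    for lam in candidates:
        cfg = TfmConfig(
            grid_nodes=grid.n_x,
            grid_spacing=grid.spacing,
            regularization=float(lam),
            smooth_sigma_nodes=smooth_sigma_nodes,
        )
        rec = reconstruct_traction(noisy, substrate, cfg, grid=grid)
        err = np.sqrt(((rec.u - tx) ** 2 + (rec.v - ty) ** 2).sum() / den)
        if err < best_err:
            best_err, best_cfg = err, cfg
    return best_cfg


def _match(displacement: VectorField2D, grid: GridSpec) -> VectorField2D:
    if displacement.grid.same_geometry(grid):
        return displacement
    return _resample_to_grid(displacement, grid)


def mean_traction_norm(
    traction: VectorField2D, mask: np.ndarray | None = None
) -> float:
    """Mean traction-vector norm sqrt(t_x² + t_y²), Pa.

    ``mask`` restricts the average (e.g. to the cell-covered region);
    default is the whole field of view.
    """
    norm = traction.magnitude()
    include = traction.valid if mask is None else (traction.valid & mask)
    if not include.any():
        raise EstimationError("empty mask: no nodes to average")
    return float(norm[include].mean())
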