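"""Synthetic ground-truth scenes for monolayer mechanics pipelines.

Every generator in this module produces data whose "true" answer is known
in closed form, so each pipeline stage (PIV, correlation length, traction
reconstruction, stress inversion, tension profiling) can be validated
against an analytic oracle rather than against itself:

* bead images under a known warp (PIV / TFM displacement truth),
* stationary Gaussian random velocity fields with a prescribed spatial
  correlation length (collectivity truth),
* 2D stress-tensor fields whose divergence — the traction the monolayer
  exerts on its substrate, ``div σ = t`` — is evaluated analytically
  (stress-inversion truth),
* an expanding-front scenario that couples all of the above,
* two-channel junction images with a Gaussian ridge along an interface.

All randomness is routed through ``numpy.random.default_rng(seed)``;
identical seeds and parameters give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .fields import (
    FrameSequence,
    FrontTrack,
    GeometryError,
    GridSpec,
    ParameterError,
    StressField,
    VectorField2D,
)

__all__ = [
    "DEFAULT_PIXEL_SIZE",
    "default_bead_sigma_px",
    "SyntheticScene",
    "make_bead_image",
    "warp_image",
    "make_correlated_velocity_field",
    "make_stress_field",
    "make_expanding_front_scenario",
    "make_junction_image",
    "gaussian_threshold_length",
    "exponential_threshold_length",
]

# µm per pixel chosen so that a 16 px PIV nodal distance equals a 20.7 µm
# grid spacing (10x objective, 2x2 binning class of imaging).
DEFAULT_PIXEL_SIZE = 1.294

#: physical bead diameter, µm (carboxylated fluorescent polystyrene beads)
BEAD_DIAMETER_UM = 0.5

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548


def default_bead_sigma_px(pixel_size: float = DEFAULT_PIXEL_SIZE) -> float:
    """Gaussian sigma (px) of a rendered bead.

    The bead's full width at half maximum is set to its physical diameter,
    which is what a diffraction-limited image of a sub-micron bead roughly
    looks like at this magnification.
    """
    return BEAD_DIAMETER_UM / pixel_size / _FWHM_TO_SIGMA


def make_bead_image(
    width_px: int,
    height_px: int,
    n_beads: int,
    bead_sigma_px: float | None = None,
    peak_intensity: float = 500.0,
    noise_sd: float = 5.0,
    seed: int = 0,
    background: float = 100.0,
) -> np.ndarray:
    """Render ``n_beads`` Gaussian spots at uniform random positions.

    Returns a float image ``(height_px, width_px)`` of background +
    superposed Gaussians + white Gaussian noise.  Deterministic per seed.
    """
    if width_px < 64 or height_px < 64:
        raise ParameterError("bead images must be at least 64x64 px")
    if bead_sigma_px is None:
        bead_sigma_px = max(default_bead_sigma_px(), 1.0)
    if bead_sigma_px <= 0:
        raise ParameterError("bead_sigma_px must be > 0")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    img = np.full((height_px, width_px), float(background))
    if n_beads > 0:
        xs = rng.uniform(0, width_px - 1, size=n_beads)
        ys = rng.uniform(0, height_px - 1, size=n_beads)
        img += render_gaussian_spots(
            (height_px, width_px), xs, ys, bead_sigma_px, peak_intensity
        )
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    return img


def render_gaussian_spots(
    shape: tuple[int, int],
    xs: np.ndarray,
    ys: np.ndarray,
    sigma_px: float,
    peak: float,
) -> np.ndarray:
    """Sum of unit-height-``peak`` Gaussians centred at (xs, ys), rendered
    within a ±4 sigma stamp around each centre."""
    h, w = shape
    out = np.zeros(shape)
    half = int(math.ceil(4 * sigma_px))
    for x0, y0 in zip(np.atleast_1d(xs), np.atleast_1d(ys)):
        ix, iy = int(round(x0)), int(round(y0))
        x_lo, x_hi = max(ix - half, 0), min(ix + half + 1, w)
        y_lo, y_hi = max(iy - half, 0), min(iy + half + 1, h)
        if x_lo >= x_hi or y_lo >= y_hi:
            continue
        xg = np.arange(x_lo, x_hi) - x0
        yg = np.arange(y_lo, y_hi) - y0
        out[y_lo:y_hi, x_lo:x_hi] += peak * np.exp(
            -(yg[:, None] ** 2 + xg[None, :] ** 2) / (2.0 * sigma_px**2)
        )
    return out


def warp_image(
    image: np.ndarray,
    displacement: VectorField2D,
    pixel_size: float = 1.0,
    background: float | None = None,
) -> np.ndarray:
    """Apply a displacement field to an image by inverse bilinear sampling.

    ``output(x) = input(x - d(x))`` with ``d`` in pixels, so features move
    *by* ``+d``.  The displacement grid (whose coordinates are divided by
    ``pixel_size`` to land in pixel units) must cover the image; border
    samples falling outside the input are filled with ``background``
    (default: the image minimum).

    Raises
    ------
    GeometryError
        If the displacement grid does not cover the image extent (beyond
        half a grid spacing of slack at each edge).
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    g = displacement.grid
    gx = g.x / pixel_size
    gy = g.y / pixel_size
    slack = 0.5 * g.spacing / pixel_size
    if gx[0] > slack or gy[0] > slack or gx[-1] < w - 1 - slack or gy[-1] < h - 1 - slack:
        raise GeometryError(
            "displacement grid does not cover the image "
            f"(grid x [{gx[0]:.1f}, {gx[-1]:.1f}] px, image width {w} px)"
        )
    from scipy.interpolate import RegularGridInterpolator

    pts_y, pts_x = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    interp_u = RegularGridInterpolator(
        (gy, gx), displacement.u, bounds_error=False, fill_value=None
    )
    interp_v = RegularGridInterpolator(
        (gy, gx), displacement.v, bounds_error=False, fill_value=None
    )
    pts = np.stack([pts_y.ravel(), pts_x.ravel()], axis=-1)
    dx = interp_u(pts).reshape(h, w)
    dy = interp_v(pts).reshape(h, w)
    if background is None:
        background = float(image.min())
    coords = np.stack([pts_y - dy, pts_x - dx])
    return ndimage.map_coordinates(
        image, coords, order=1, mode="constant", cval=background
    )


# ---------------------------------------------------------------------------
# correlated velocity fields
# ---------------------------------------------------------------------------

_LN_100 = math.log(100.0)


def gaussian_threshold_length(corr_length: float) -> float:
    """Distance at which exp(-r²/2ℓ²) first reaches 0.01: ℓ·sqrt(2 ln 100)."""
    return corr_length * math.sqrt(2.0 * _LN_100)


def exponential_threshold_length(corr_length: float) -> float:
    """Distance at which exp(-r/ℓ) first reaches 0.01: ℓ·ln 100."""
    return corr_length * _LN_100


def _stationary_gaussian_field(
    n_y: int, n_x: int, spacing: float, corr_length: float, model: str, rng
) -> np.ndarray:
    """Zero-mean, unit-variance stationary Gaussian random field.

    Synthesised spectrally on the periodic grid: white noise is circularly
    convolved with the kernel whose autocorrelation equals the target
    covariance (square root of the covariance eigenvalues in Fourier
    space), which realises the target covariance exactly up to wraparound.
    """
    iy = np.minimum(np.arange(n_y), n_y - np.arange(n_y)) * spacing
    ix = np.minimum(np.arange(n_x), n_x - np.arange(n_x)) * spacing
    r = np.hypot(iy[:, None], ix[None, :])
    if model == "gaussian":
        cov = np.exp(-(r**2) / (2.0 * corr_length**2))
    elif model == "exponential":
        cov = np.exp(-r / corr_length)
    else:
        raise ParameterError(f"unknown correlation model {model!r}")
    lam = np.fft.fft2(cov).real
    lam[lam < 0] = 0.0  # tiny negative eigenvalues from wraparound
    noise = rng.standard_normal((n_y, n_x))
    fld = np.fft.ifft2(np.fft.fft2(noise) * np.sqrt(lam)).real
    # renormalise to exactly unit marginal variance (eigenvalue clipping and
    # wraparound perturb it at the 1e-3 level)
    target_var = cov[0, 0]
    actual_var = lam.sum() / (n_y * n_x)
    if actual_var > 0:
        fld *= math.sqrt(target_var / actual_var)
    return fld


def make_correlated_velocity_field(
    grid: GridSpec,
    mean_front_velocity: float,
    fluctuation_sd: float,
    corr_length: float,
    model: str = "gaussian",
    seed: int = 0,
) -> tuple[VectorField2D, float]:
    """Velocity field with a prescribed lateral correlation length.

    The axial (x, front-perpendicular) component is uniformly
    ``mean_front_velocity``; the lateral (y, front-parallel) component is a
    stationary Gaussian random field with covariance
    ``fluctuation_sd² · exp(-r²/2ℓ²)`` (gaussian) or ``· exp(-r/ℓ)``
    (exponential).

    Returns
    -------
    (field, truth_length)
        ``field`` in µm/min and the analytic distance at which the
        normalised correlation first reaches the 0.01 threshold.
    """
    if corr_length <= grid.spacing:
        raise ParameterError(
            f"corr_length ({corr_length} µm) must exceed the grid spacing "
            f"({grid.spacing} µm); otherwise the field is white noise"
        )
    rng = np.random.default_rng(seed)
    if fluctuation_sd == 0:
        lateral = np.zeros(grid.shape)
    else:
        lateral = fluctuation_sd * _stationary_gaussian_field(
            grid.n_y, grid.n_x, grid.spacing, corr_length, model, rng
        )
    u = np.full(grid.shape, float(mean_front_velocity))
    fieldv = VectorField2D(grid=grid, u=u, v=lateral, unit="um/min")
    if model == "gaussian":
        truth = gaussian_threshold_length(corr_length)
    else:
        truth = exponential_threshold_length(corr_length)
    return fieldv, truth


# ---------------------------------------------------------------------------
# stress fields with analytic divergence
# ---------------------------------------------------------------------------


def _sat(u):
    """C¹ saturation s(u) = u²/(1+u²) for u > 0, 0 otherwise.

    s and s' are both continuous at u = 0 (s'(0) = 0), so profiles built
    from it integrate cleanly with the trapezoidal rule.
    """
    u = np.maximum(u, 0.0)
    return u**2 / (1.0 + u**2)


def _dsat(u):
    up = np.maximum(u, 0.0)
    return np.where(u > 0, 2.0 * up / (1.0 + up**2) ** 2, 0.0)


def _front_profile_fx(x, x_back, front, width):
    """Plateau profile f(x): 0 at both free margins, ~1 in the bulk.

    f(x) = s((x - x_back)/w)·s((front - x)/w) with the C¹ saturation
    ``_sat``.  Models tension that builds over a length ``width`` inward
    from each free edge of a monolayer strip.
    """
    x = np.asarray(x, dtype=float)
    return _sat((x - x_back) / width) * _sat((front - x) / width)


def _front_profile_dfx(x, x_back, front, width):
    """d f / dx of the plateau profile (zero outside the strip)."""
    x = np.asarray(x, dtype=float)
    ua = (x - x_back) / width
    ub = (front - x) / width
    return (_dsat(ua) * _sat(ub) - _sat(ua) * _dsat(ub)) / width


def make_stress_field(
    grid: GridSpec, kind: str, params: dict | None = None
) -> tuple[StressField, VectorField2D]:
    """Analytic stress field and its exactly evaluated divergence.

    Under the convention ``div σ = t`` (t = traction the monolayer exerts
    on the substrate), returns the pair ``(σ, t)`` with ``t`` computed from
    the closed-form derivatives of ``σ`` — never by finite differences — so
    that any discretisation error seen downstream is attributable to the
    inversion, not to the oracle.

    Kinds
    -----
    constant
        ``sxx, syy, sxy`` constants (params: those names); zero traction.
    linear_ramp
        ``σxx = a (x - L)``, others 0 (params: ``a``, ``L``); ``t = (a, 0)``.
    gaussian_bump
        ``σxx = σyy = A exp(-((x-x0)² + (y-y0)²)/2w²)``, ``σxy = 0``
        (params: ``amplitude``, ``center=(x0, y0)``, ``width``).
    bump_mixture
        independent Gaussian bumps in each component (params: ``bumps``, a
        list of dicts with ``component`` in {sxx, syy, sxy}, ``amplitude``,
        ``center``, ``width``).
    front_profile
        uniaxial tension of a monolayer strip: ``σxx = A f(x) g(y)`` with
        the plateau ``f`` above and a mild front-parallel modulation
        ``g(y) = 1 + m cos(2π (y - y0)/L_y)``; ``σyy = σxy = 0`` (params:
        ``amplitude``, ``x_back``, ``front``, ``width``, ``modulation``).
    """
    params = dict(params or {})
    X, Y = grid.meshgrid()
    z = np.zeros(grid.shape)
    if grid.n_x < 16 or grid.n_y < 16:
        raise ParameterError("stress fields need a grid of at least 16x16 nodes")

    if kind == "constant":
        sxx = np.full(grid.shape, float(params.get("sxx", 1.0)))
        syy = np.full(grid.shape, float(params.get("syy", 1.0)))
        sxy = np.full(grid.shape, float(params.get("sxy", 0.0)))
        tx, ty = z.copy(), z.copy()
    elif kind == "linear_ramp":
        a = float(params.get("a", 1.0))
        L = float(params.get("L", grid.x[-1]))
        sxx = a * (X - L)
        syy, sxy = z.copy(), z.copy()
        tx = np.full(grid.shape, a)
        ty = z.copy()
    elif kind == "gaussian_bump":
        A = float(params.get("amplitude", 1.0))
        x0, y0 = params.get("center", (grid.x.mean(), grid.y.mean()))
        w = float(params.get("width", 5 * grid.spacing))
        bump = A * np.exp(-((X - x0) ** 2 + (Y - y0) ** 2) / (2.0 * w**2))
        sxx = bump
        syy = bump.copy()
        sxy = z.copy()
        tx = -(X - x0) / w**2 * bump
        ty = -(Y - y0) / w**2 * bump
    elif kind == "bump_mixture":
        sxx, syy, sxy = z.copy(), z.copy(), z.copy()
        tx, ty = z.copy(), z.copy()
        for spec_ in params.get("bumps", []):
            A = float(spec_["amplitude"])
            x0, y0 = spec_["center"]
            w = float(spec_["width"])
            bump = A * np.exp(-((X - x0) ** 2 + (Y - y0) ** 2) / (2.0 * w**2))
            dbx = -(X - x0) / w**2 * bump  # ∂x bump
            dby = -(Y - y0) / w**2 * bump  # ∂y bump
            comp = spec_["component"]
            if comp == "sxx":
                sxx += bump
                tx += dbx
            elif comp == "syy":
                syy += bump
                ty += dby
            elif comp == "sxy":
                sxy += bump
                tx += dby
                ty += dbx
            else:
                raise ParameterError(f"unknown stress component {comp!r}")
    elif kind == "potential_bumps":
        # stress in the row space of the force-balance operator: from a
        # smooth vector potential ψ, σ = (∂x ψx, ∂y ψy, ∂y ψx + ∂x ψy).
        # Such fields carry no divergence-free (Airy) component, so they
        # are identifiable from their traction alone — the oracle of
        # choice for stress-inversion accuracy.  Amplitudes are potential
        # amplitudes (Pa·µm²); the resulting stress peaks at roughly
        # amplitude/width·exp(-1/2).
        sxx, syy, sxy = z.copy(), z.copy(), z.copy()
        tx, ty = z.copy(), z.copy()
        for spec_ in params.get("bumps", []):
            A = float(spec_["amplitude"])
            x0, y0 = spec_["center"]
            w = float(spec_["width"])
            b = A * np.exp(-((X - x0) ** 2 + (Y - y0) ** 2) / (2.0 * w**2))
            bx = -(X - x0) / w**2 * b
            by = -(Y - y0) / w**2 * b
            bxx = ((X - x0) ** 2 / w**4 - 1.0 / w**2) * b
            byy = ((Y - y0) ** 2 / w**4 - 1.0 / w**2) * b
            bxy = (X - x0) * (Y - y0) / w**4 * b
            if spec_.get("potential", "x") == "x":
                sxx += bx
                sxy += by
                tx += bxx + byy
                ty += bxy
            else:
                syy += by
                sxy += bx
                tx += bxy
                ty += bxx + byy
    elif kind == "front_profile":
        A = float(params.get("amplitude", 50.0))
        x_back = float(params.get("x_back", grid.x[0] + 3 * grid.spacing))
        front = float(params.get("front", grid.x[-1] - 3 * grid.spacing))
        w = float(params.get("width", 100.0))
        m = float(params.get("modulation", 0.2))
        Ly = grid.n_y * grid.spacing
        g = 1.0 + m * np.cos(2.0 * np.pi * (Y - grid.y[0]) / Ly)
        f = _front_profile_fx(X, x_back, front, w)
        df = _front_profile_dfx(X, x_back, front, w)
        sxx = A * f * g
        syy, sxy = z.copy(), z.copy()
        tx = A * df * g
        ty = z.copy()
    else:
        raise ParameterError(f"unknown stress field kind {kind!r}")

    stress = StressField(grid=grid, sxx=sxx, syy=syy, sxy=sxy)
    traction = VectorField2D(grid=grid, u=tx, v=ty, unit="Pa")
    return stress, traction


# ---------------------------------------------------------------------------
# junction images
# ---------------------------------------------------------------------------


def make_junction_image(
    size: tuple[int, int],
    interface_line: tuple[tuple[float, float], tuple[float, float]],
    ridge_sigma_px: float = 2.0,
    channel_peaks: tuple[float, float] = (1000.0, 600.0),
    noise_sd: float = 10.0,
    seed: int = 0,
    background: float = 100.0,
) -> np.ndarray:
    """Two-channel image with a Gaussian ridge along a cell–cell interface.

    Emulates a junction marker pair (e.g. a GFP-tagged membrane protein and
    an mCherry-tagged partner) both enriched along the same interface.
    Returns an array of shape ``(2, height, width)``.
    """
    h, w = size
    (x1, y1), (x2, y2) = interface_line
    if not (0 <= x1 < w and 0 <= x2 < w and 0 <= y1 < h and 0 <= y2 < h):
        raise GeometryError("interface segment must lie inside the image")
    length = math.hypot(x2 - x1, y2 - y1)
    if length == 0:
        raise GeometryError("interface segment has zero length")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    # distance from each pixel to the segment
    dx, dy = (x2 - x1) / length, (y2 - y1) / length
    px, py = xx - x1, yy - y1
    t = np.clip(px * dx + py * dy, 0.0, length)
    dist = np.hypot(px - t * dx, py - t * dy)
    ridge = np.exp(-(dist**2) / (2.0 * ridge_sigma_px**2))
    out = np.empty((2, h, w))
    for c, peak in enumerate(channel_peaks):
        img = background + peak * ridge
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=(h, w))
        out[c] = img
    return out


# ---------------------------------------------------------------------------
# expanding-front scenario
# ---------------------------------------------------------------------------


@dataclass
class SyntheticScene:
    """End-to-end synthetic scene: an expanding monolayer strip.

    Couples a moving occupancy front, a tension profile building from the
    free margins (hence a traction field and substrate bead displacements),
    and a laterally correlated velocity field, with every ground-truth
    quantity attached on the same analysis grid the pipeline will use.
    """

    cell_movie: FrameSequence
    bead_movie: FrameSequence
    bead_reference: np.ndarray
    masks: list[np.ndarray]  # per-frame pixel occupancy (bool)
    grid: GridSpec  # analysis grid (stress/traction/velocity truth)
    truth_displacement: list[VectorField2D]  # px, stressed vs relaxed, per frame
    truth_velocity: VectorField2D  # µm/min
    truth_stress: list[StressField]
    truth_traction: list[VectorField2D]  # Pa
    truth_corr_length: float  # µm (threshold-0.01 definition)
    truth_front: FrontTrack
    truth_bulk_tension: float  # Pa·µm, margin-discarded spatial mean of τ
    pixel_size: float
    frame_interval: float
    seed: int
    params: dict = field(default_factory=dict)


def make_expanding_front_scenario(
    front_speed: float = 0.3,  # µm/min
    corr_length: float = 55.0,  # µm (GRF scale ℓ; threshold-0.01 length ≈ 3.03ℓ)
    tension_amplitude: float = 100.0,  # Pa·µm, uniaxial plateau of σxx
    n_frames: int = 3,
    seed: int = 0,
    image_px: int = 800,
    pixel_size: float = 20.72 / 16.0,  # µm/px; 16 px == one 20.72 µm grid step
    frame_interval: float = 5.0,  # min
    grid_nodes: int = 46,
    grid_spacing: float = 20.72,  # µm
    front_start: float = 700.0,  # µm
    x_back: float = 150.0,  # µm, static rear free margin of the strip
    rise_width: float = 100.0,  # µm, tension build-up length from each margin
    modulation: float = 0.0,
    fluctuation_sd: float = 0.15,  # µm/min, lateral velocity fluctuations
    incoherent_traction: float = 1.5,  # Pa, rms of cell-scale traction noise
    incoherent_scale: float = 25.0,  # µm, size of individual traction dipoles
    n_beads: int = 7000,
    bead_noise_sd: float = 3.0,
    young_modulus: float = 200.0,  # Pa
    poisson_ratio: float = 0.5,
    margin: float = 200.0,  # µm, discarded for the bulk tension truth
) -> SyntheticScene:
    """Generate the full expanding-monolayer fixture.

    The monolayer occupies the strip ``x ∈ [x_back, L(t)]`` with
    ``L(t) = front_start + front_speed·t``.  Its stress is the sum of a
    coherent uniaxial tension ``σxx = A f(x) g(y)`` — vanishing at both
    free margins, plateauing at ``tension_amplitude`` in the bulk — and an
    incoherent cell-scale component built from randomly placed analytic
    traction dipoles (zero net tension, but a realistic traction-norm
    floor: migrating epithelia show local tractions of a couple of Pa
    while their net, front-perpendicular force balance integrates to tens
    of Pa·µm).  The total implied traction deforms a bead-seeded elastic
    substrate (Young's modulus 200 Pa) whose images are rendered stressed
    (per frame) and relaxed (reference); a speckle "cell" movie advected
    by the true velocity field supports the PIV → collectivity branch.

    Raises
    ------
    GeometryError
        If the front leaves the field of view before ``n_frames`` frames.
    ParameterError
        If ``n_frames < 3``.
    """
    from . import tfm  # deferred: tfm imports piv, keep module load light

    if n_frames < 3:
        raise ParameterError("scenario needs n_frames >= 3")
    rng = np.random.default_rng(seed)
    w_px = h_px = image_px
    extent = image_px * pixel_size

    # analysis grid, centred in the field of view on whole-pixel positions
    grid_extent = (grid_nodes - 1) * grid_spacing
    offset_px = int(round((extent - grid_extent) / pixel_size / 2.0))
    origin = (offset_px * pixel_size, offset_px * pixel_size)
    grid = GridSpec(origin=origin, n_x=grid_nodes, n_y=grid_nodes, spacing=grid_spacing)

    times = frame_interval * np.arange(n_frames)
    fronts = front_start + front_speed * times
    if fronts[-1] >= extent - grid_spacing or fronts[-1] >= grid.x[-1]:
        raise GeometryError(
            f"front exits the field of view: L({times[-1]} min) = {fronts[-1]:.1f} µm "
            f"of {extent:.1f} µm"
        )

    # displacement/warp grid covering the whole image
    n_warp = int(math.ceil(extent / grid_spacing)) + 1
    warp_grid = GridSpec(origin=(0.0, 0.0), n_x=n_warp, n_y=n_warp, spacing=grid_spacing)
    substrate = tfm.SubstrateModel(young_modulus=young_modulus, poisson_ratio=poisson_ratio)

    bead_reference = make_bead_image(
        w_px, h_px, n_beads, noise_sd=bead_noise_sd, seed=int(rng.integers(2**31))
    )

    velocity, truth_corr_length = make_correlated_velocity_field(
        grid,
        mean_front_velocity=front_speed,
        fluctuation_sd=fluctuation_sd,
        corr_length=corr_length,
        model="gaussian",
        seed=int(rng.integers(2**31)),
    )

    # dense fine speckle standing in for the phase-contrast monolayer
    # texture (real monolayers are texture-rich at the cell scale, which
    # is what makes windowed PIV on them reliable)
    texture = make_bead_image(
        w_px,
        h_px,
        n_beads=int(0.047 * w_px * h_px),
        bead_sigma_px=1.5,
        peak_intensity=300.0,
        noise_sd=0.0,
        seed=int(rng.integers(2**31)),
    )
    # velocity on the warp grid (extend the analysis-grid field by nearest
    # node so the whole texture advects smoothly)
    vel_warp_u, vel_warp_v = _resample_nearest(velocity, warp_grid)

    stress_params = dict(
        amplitude=tension_amplitude,
        x_back=x_back,
        width=rise_width,
        modulation=modulation,
    )

    # incoherent cell-scale contractility: random ± traction dipoles,
    # static over the short movie, confined to the strip interior
    inc_grid: StressField | None = None
    inc_trac_grid: VectorField2D | None = None
    inc_trac_warp: VectorField2D | None = None
    if incoherent_traction > 0:
        pad = 4.0 * incoherent_scale
        n_bumps = max(
            8,
            int(
                (fronts[0] - x_back - 2 * pad)
                * (extent - 2 * pad)
                / (4.0 * incoherent_scale) ** 2
            ),
        )
        bumps = [
            {
                "potential": "x" if rng.random() < 0.5 else "y",
                "amplitude": rng.normal(0.0, 1.0),
                "center": (
                    rng.uniform(x_back + pad, fronts[0] - pad),
                    rng.uniform(pad, extent - pad),
                ),
                "width": incoherent_scale,
            }
            for _ in range(n_bumps)
        ]
        inc_grid, inc_trac_grid = make_stress_field(
            grid, "potential_bumps", {"bumps": bumps}
        )
        # scale amplitudes so the rms traction of this component hits the
        # requested level (linear, so a single global factor suffices)
        rms = np.sqrt(np.mean(inc_trac_grid.u**2 + inc_trac_grid.v**2))
        factor = incoherent_traction / rms if rms > 0 else 0.0
        for bmp in bumps:
            bmp["amplitude"] *= factor
        inc_grid, inc_trac_grid = make_stress_field(
            grid, "potential_bumps", {"bumps": bumps}
        )
        _, inc_trac_warp = make_stress_field(
            warp_grid, "potential_bumps", {"bumps": bumps}
        )

    cell_frames: list[np.ndarray] = []
    bead_frames: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    truth_displacement: list[VectorField2D] = []
    truth_stress: list[StressField] = []
    truth_traction: list[VectorField2D] = []
    px_x = pixel_size * np.arange(w_px)

    for k, (t_min, front) in enumerate(zip(times, fronts)):
        stress_k, traction_k = make_stress_field(
            grid, "front_profile", {**stress_params, "front": front}
        )
        _, traction_warp = make_stress_field(
            warp_grid, "front_profile", {**stress_params, "front": front}
        )
        if inc_grid is not None:
            stress_k = StressField(
                grid,
                stress_k.sxx + inc_grid.sxx,
                stress_k.syy + inc_grid.syy,
                stress_k.sxy + inc_grid.sxy,
            )
            traction_k = VectorField2D(
                grid, traction_k.u + inc_trac_grid.u,
                traction_k.v + inc_trac_grid.v, "Pa",
            )
            traction_warp = VectorField2D(
                warp_grid, traction_warp.u + inc_trac_warp.u,
                traction_warp.v + inc_trac_warp.v, "Pa",
            )
        disp_um = tfm.forward_displacement(traction_warp, substrate)
        disp_px = disp_um.scaled(1.0 / pixel_size, unit="px")
        bead_frames.append(warp_image(bead_reference, disp_px, pixel_size=pixel_size))

        # truth displacement sampled on the analysis grid
        disp_grid = tfm.forward_displacement(traction_k, substrate)
        truth_displacement.append(disp_grid.scaled(1.0 / pixel_size, unit="px"))

        mask = np.broadcast_to((px_x >= x_back) & (px_x <= front), (h_px, w_px)).copy()
        masks.append(mask)
        truth_stress.append(stress_k)
        truth_traction.append(traction_k)

        # cells advect with the (time-constant) velocity field
        adv_px = t_min / pixel_size
        adv = VectorField2D(
            grid=warp_grid, u=vel_warp_u * adv_px, v=vel_warp_v * adv_px, unit="px"
        )
        frame = warp_image(texture, adv, pixel_size=pixel_size)
        frame = np.where(mask, frame, float(texture.min()))
        frame += rng.normal(0.0, 2.0, size=frame.shape)
        cell_frames.append(frame)

    # analytic bulk tension of the mid-scenario frame: τ = (σxx + σyy)/2
    mid = n_frames // 2
    tau = 0.5 * (truth_stress[mid].sxx + truth_stress[mid].syy)
    X, Y = grid.meshgrid()
    bulk = (
        (X > grid.x[0] + margin)
        & (X < grid.x[-1] - margin)
        & (Y > grid.y[0] + margin)
        & (Y < grid.y[-1] - margin)
    )
    truth_bulk_tension = float(tau[bulk].mean()) if bulk.any() else float("nan")

    # velocity truth is only defined where cells are
    Xg, _ = grid.meshgrid()
    vel_valid = (Xg >= x_back) & (Xg <= fronts.min())
    velocity.valid = vel_valid

    return SyntheticScene(
        cell_movie=FrameSequence(cell_frames, pixel_size, frame_interval),
        bead_movie=FrameSequence(bead_frames, pixel_size, frame_interval),
        bead_reference=bead_reference,
        masks=masks,
        grid=grid,
        truth_displacement=truth_displacement,
        truth_velocity=velocity,
        truth_stress=truth_stress,
        truth_traction=truth_traction,
        truth_corr_length=truth_corr_length,
        truth_front=FrontTrack(times=times, L=fronts),
        truth_bulk_tension=truth_bulk_tension,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        seed=seed,
        params=dict(
            front_speed=front_speed,
            corr_length=corr_length,
            tension_amplitude=tension_amplitude,
            incoherent_traction=incoherent_traction,
            incoherent_scale=incoherent_scale,
            x_back=x_back,
            rise_width=rise_width,
            modulation=modulation,
            margin=margin,
            young_modulus=young_modulus,
            poisson_ratio=poisson_ratio,
        ),
    )


def _resample_nearest(fieldv: VectorField2D, new_grid: GridSpec):
    """Sample a vector field on a new grid, clamping outside the old hull."""
    g = fieldv.grid
    ix = np.clip(np.round((new_grid.x - g.origin[0]) / g.spacing).astype(int), 0, g.n_x - 1)
    iy = np.clip(np.round((new_grid.y - g.origin[1]) / g.spacing).astype(int), 0, g.n_y - 1)
    return fieldv.u[np.ix_(iy, ix)], fieldv.v[np.ix_(iy, ix)]
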