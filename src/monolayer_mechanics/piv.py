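"""Window-based particle image velocimetry.

Frames are subdivided into square interrogation windows (32 px with 50%
overlap by default); the displacement of each window between two frames is
the peak of the zero-normalised FFT cross-correlation, localised to
sub-pixel precision by a 3-point Gaussian fit in each axis.  Raw vectors
are then resampled onto a regular nodal grid (16 px nodal distance, i.e.
20.7 µm at 1.294 µm/px) with cubic splines.

Windows whose correlation peak is ambiguous (peak-to-second-peak ratio
below a threshold) or degenerate (constant intensity) are masked invalid
rather than inpainted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import RectBivariateSpline

from .fields import (
    EstimationError,
    GeometryError,
    GridSpec,
    ParameterError,
    VectorField2D,
)

__all__ = ["PivConfig", "piv_displacement", "interpolate_to_grid", "to_velocity"]


@dataclass(frozen=True)
class PivConfig:
    """PIV interrogation settings.

    ``window_px``: interrogation window side; ``overlap_fraction``: window
    overlap (0.5 → stride of half a window); ``nodal_distance_px``: spacing
    of the output nodal grid; ``min_peak_ratio``: smallest acceptable
    first-to-second correlation peak ratio before a vector is masked.
    """

    window_px: int = 32
    overlap_fraction: float = 0.5
    nodal_distance_px: int = 16
    interpolation: str = "cubic_spline"
    subpixel: str = "gaussian3"
    min_peak_ratio: float = 1.2
    #: windows whose intensity s.d. is below this fraction of the whole
    #: frame's s.d. carry no texture to correlate and are masked invalid
    min_texture_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.window_px <= 0 or self.nodal_distance_px <= 0:
            raise ParameterError("window_px and nodal_distance_px must be > 0")
        if not (0 <= self.overlap_fraction < 1):
            raise ParameterError("overlap_fraction must be in [0, 1)")

    @property
    def stride_px(self) -> int:
        stride = int(round(self.window_px * (1.0 - self.overlap_fraction)))
        return max(stride, 1)


def _subpixel_offset(cm1: float, c0: float, cp1: float) -> float:
    """3-point Gaussian peak interpolation, with a parabolic fallback when
    a neighbour is non-positive (log undefined)."""
    if not np.isfinite(cm1):
        cm1 = 0.0
    if not np.isfinite(cp1):
        cp1 = 0.0
    if cm1 > 0 and c0 > 0 and cp1 > 0:
        lm, l0, lp = np.log(cm1), np.log(c0), np.log(cp1)
        denom = lm + lp - 2.0 * l0
        if denom < 0:
            return float((lm - lp) / (2.0 * denom))
    denom = cm1 + cp1 - 2.0 * c0
    if denom < 0:
        return float((cm1 - cp1) / (2.0 * denom))
    return 0.0


def piv_displacement(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    cfg: PivConfig = PivConfig(),
) -> VectorField2D:
    """Displacement field of ``frame_b`` relative to ``frame_a``, in px.

    Returns one vector per interrogation window, on a grid whose
    coordinates are the window centres *in pixels* (resample to physical
    units with :func:`interpolate_to_grid`).  A positive ``u`` means the
    pattern moved rightward between the two frames.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise GeometryError(f"frame shapes differ: {a.shape} vs {b.shape}")
    win = cfg.window_px
    if a.shape[0] < 2 * win or a.shape[1] < 2 * win:
        raise GeometryError(
            f"frames must be at least {2 * win} px per side for {win} px windows"
        )
    stride = cfg.stride_px
    h, w = a.shape
    n_wy = (h - win) // stride + 1
    n_wx = (w - win) // stride + 1
    idx_y = stride * np.arange(n_wy)
    idx_x = stride * np.arange(n_wx)

    wins_a = _gather_windows(a, idx_y, idx_x, win)

    # pass 1: aligned windows, integer peak
    wins_b = _gather_windows(b, idx_y, idx_x, win)
    int_y = np.zeros((n_wy, n_wx), dtype=int)
    int_x = np.zeros((n_wy, n_wx), dtype=int)
    u = np.zeros((n_wy, n_wx))
    v = np.zeros((n_wy, n_wx))
    valid = np.ones((n_wy, n_wx), dtype=bool)
    _correlate_pass(wins_a, wins_b, cfg, u, v, valid, int_y, int_x)

    # pass 2 (discrete window offset): re-interrogate frame_b at the
    # integer lag so the two windows share (nearly) the same particles —
    # removes the loss-of-pairs asymmetry that otherwise biases the
    # sub-pixel fit.  Windows whose offset window would leave the image
    # keep their pass-1 estimate.
    off_y = np.rint(v).astype(int)
    off_x = np.rint(u).astype(int)
    refine = (
        valid
        & ((off_y != 0) | (off_x != 0))
        & (idx_y[:, None] + off_y >= 0)
        & (idx_y[:, None] + off_y + win <= h)
        & (idx_x[None, :] + off_x >= 0)
        & (idx_x[None, :] + off_x + win <= w)
    )
    if refine.any():
        ii, jj = np.nonzero(refine)
        wb2 = np.empty((len(ii), win, win))
        for n, (i, j) in enumerate(zip(ii, jj)):
            y0 = idx_y[i] + off_y[i, j]
            x0 = idx_x[j] + off_x[i, j]
            wb2[n] = b[y0 : y0 + win, x0 : x0 + win]
        u2 = np.zeros(len(ii))
        v2 = np.zeros(len(ii))
        valid2 = np.ones(len(ii), dtype=bool)
        _correlate_pass(
            wins_a[ii, jj][:, None], wb2[:, None], cfg,
            u2[:, None], v2[:, None], valid2[:, None],
            np.zeros((len(ii), 1), int), np.zeros((len(ii), 1), int),
        )
        ok = valid2 & (np.abs(u2) <= 2) & (np.abs(v2) <= 2)
        u[ii[ok], jj[ok]] = off_x[ii, jj][ok] + u2[ok]
        v[ii[ok], jj[ok]] = off_y[ii, jj][ok] + v2[ok]

    centre = (win - 1) / 2.0
    grid = GridSpec(
        origin=(idx_x[0] + centre, idx_y[0] + centre),
        n_x=n_wx,
        n_y=n_wy,
        spacing=float(stride),
    )
    return VectorField2D(grid=grid, u=u, v=v, unit="px", valid=valid)


def _gather_windows(img: np.ndarray, idx_y, idx_x, win: int) -> np.ndarray:
    out = np.empty((len(idx_y), len(idx_x), win, win))
    for i, y0 in enumerate(idx_y):
        for j, x0 in enumerate(idx_x):
            out[i, j] = img[y0 : y0 + win, x0 : x0 + win]
    return out


def _correlate_pass(wins_a, wins_b, cfg, u, v, valid, int_y, int_x) -> None:
    """Zero-normalised FFT cross-correlation of window stacks.

    Writes the sub-pixel displacement into ``u``/``v``, the integer lag
    into ``int_y``/``int_x``, and clears ``valid`` for degenerate or
    ambiguous windows.  The linear correlation is normalised by the
    per-lag overlap area (the raw taper biases the peak toward zero lag)
    and the search is limited to |lag| <= window/2 where support is ample.
    """
    win = wins_a.shape[-1]
    n_wy, n_wx = wins_a.shape[:2]
    wa = wins_a - wins_a.mean(axis=(2, 3), keepdims=True)
    wb = wins_b - wins_b.mean(axis=(2, 3), keepdims=True)
    sa = wa.std(axis=(2, 3))
    sb = wb.std(axis=(2, 3))
    floor_a = cfg.min_texture_frac * wa.std()
    floor_b = cfg.min_texture_frac * wb.std()

    fsize = 2 * win
    fa = np.fft.rfft2(wa, s=(fsize, fsize))
    fb = np.fft.rfft2(wb, s=(fsize, fsize))
    corr = np.fft.irfft2(np.conj(fa) * fb, s=(fsize, fsize))
    lag = np.fft.fftfreq(fsize, d=1.0 / fsize).astype(int)  # 0..w-1, -w..-1
    overlap_1d = win - np.abs(lag)
    overlap = np.maximum(overlap_1d[:, None] * overlap_1d[None, :], 1)
    searchable = (np.abs(lag)[:, None] <= win // 2) & (np.abs(lag)[None, :] <= win // 2)
    corr = corr / overlap
    corr[..., ~searchable] = -np.inf

    for i in range(n_wy):
        for j in range(n_wx):
            if sa[i, j] <= floor_a or sb[i, j] <= floor_b:
                valid[i, j] = False
                continue
            c = corr[i, j]
            my, mx = np.unravel_index(np.argmax(c), c.shape)
            peak = c[my, mx]
            # second peak outside a window-scaled neighbourhood of the first
            # (a fixed 3x3 zone would land on the shoulder of a broad peak)
            excl = max(2, win // 8)
            cm = c.copy()
            ys = (my + np.arange(-excl, excl + 1)) % fsize
            xs = (mx + np.arange(-excl, excl + 1)) % fsize
            cm[np.ix_(ys, xs)] = -np.inf
            second = cm.max()
            if peak <= 0 or (second > 0 and peak / second < cfg.min_peak_ratio):
                valid[i, j] = False
                continue
            dy = _subpixel_offset(c[(my - 1) % fsize, mx], peak, c[(my + 1) % fsize, mx])
            dx = _subpixel_offset(c[my, (mx - 1) % fsize], peak, c[my, (mx + 1) % fsize])
            lag_y = my if my <= fsize // 2 else my - fsize
            lag_x = mx if mx <= fsize // 2 else mx - fsize
            int_y[i, j] = lag_y
            int_x[i, j] = lag_x
            v[i, j] = lag_y + dy
            u[i, j] = lag_x + dx


def interpolate_to_grid(
    raw_field: VectorField2D,
    nodal_distance_px: int = 16,
    pixel_size: float = 1.294,
) -> VectorField2D:
    """Resample a raw (pixel-coordinate) PIV field onto the physical nodal grid.

    Each component is interpolated with cubic splines onto a regular grid
    of spacing ``nodal_distance_px * pixel_size`` µm whose origin coincides
    with the first raw node; no extrapolation is performed beyond the raw
    field's hull.  Invalid raw nodes are filled by nearest-neighbour before
    spline fitting, and output nodes whose nearest raw node is invalid stay
    masked.
    """
    g = raw_field.grid
    if g.n_x < 4 or g.n_y < 4 or raw_field.valid.sum() < 16:
        raise EstimationError("need at least a 4x4 grid of valid vectors to interpolate")

    u, v = raw_field.u, raw_field.v
    valid = raw_field.valid
    if not valid.all():
        # nearest-valid fill so the spline has full support
        _, (iy, ix) = ndimage.distance_transform_edt(
            ~valid, return_indices=True
        )
        u = u[iy, ix]
        v = v[iy, ix]

    x_raw, y_raw = g.x, g.y  # pixel coordinates
    spl_u = RectBivariateSpline(y_raw, x_raw, u, kx=3, ky=3)
    spl_v = RectBivariateSpline(y_raw, x_raw, v, kx=3, ky=3)

    step = float(nodal_distance_px)
    n_x = int(np.floor((x_raw[-1] - x_raw[0]) / step)) + 1
    n_y = int(np.floor((y_raw[-1] - y_raw[0]) / step)) + 1
    x_new = x_raw[0] + step * np.arange(n_x)
    y_new = y_raw[0] + step * np.arange(n_y)

    grid = GridSpec(
        origin=(x_new[0] * pixel_size, y_new[0] * pixel_size),
        n_x=n_x,
        n_y=n_y,
        spacing=step * pixel_size,
    )
    u_new = spl_u(y_new, x_new)
    v_new = spl_v(y_new, x_new)

    # validity: nearest raw node must be valid
    jx = np.clip(np.round((x_new - x_raw[0]) / g.spacing).astype(int), 0, g.n_x - 1)
    jy = np.clip(np.round((y_new - y_raw[0]) / g.spacing).astype(int), 0, g.n_y - 1)
    valid_new = raw_field.valid[np.ix_(jy, jx)]

    return VectorField2D(grid=grid, u=u_new, v=v_new, unit="px", valid=valid_new)


def to_velocity(
    displacement: VectorField2D, pixel_size: float, dt: float
) -> VectorField2D:
    """Convert a pixel displacement field to a velocity field in µm/min."""
    if dt <= 0:
        raise ParameterError("frame interval dt must be > 0")
    if displacement.unit != "px":
        raise ParameterError(f"expected a px displacement field, got {displacement.unit!r}")
    return displacement.scaled(pixel_size / dt, unit="um/min")
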