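"""Monolayer tension summaries for an expanding front.

Coordinates: x perpendicular to the moving front, y parallel to it.  The
free margin sits at ``L(t)``, the y-averaged position of the outermost
cell-covered nodes.  Two independent tension estimates are provided:

* the 1D tension by direct integration of the y-averaged traction from
  the free margin, ``τ¹ᴰ(x) = ∫_L^x ⟨t_x⟩_y dx'`` (zero at the margin by
  construction), which needs no stress inversion at all, and
* the isotropic tension of the inferred stress tensor,
  ``τ = (σxx + σyy)/2``, whose y-averaged ``⟨σxx⟩_y`` profile should agree
  with τ¹ᴰ — the standard cross-validation of the inversion.

Bulk summary statistics discard a 200 µm margin along every field
boundary, where the inversion is least reliable.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .fields import (
    EstimationError,
    GeometryError,
    GridSpec,
    StressField,
    TensionField2D,
    TensionProfile1D,
    VectorField2D,
)

__all__ = [
    "occupancy_from_image",
    "detect_front",
    "y_average",
    "tension_1d",
    "isotropic_tension",
    "bulk_average",
    "compare_1d_2d",
]


def occupancy_from_image(
    image: np.ndarray, closing_px: int = 5, threshold: float | None = None
) -> np.ndarray:
    """Boolean cell-occupancy mask from a texture image.

    Thresholds the local intensity variability (cells are textured, the
    free substrate is flat) with Otsu's method unless an explicit
    threshold is given, then closes small gaps morphologically.
    """
    from skimage.filters import threshold_otsu

    img = np.asarray(image, dtype=float)
    rough = ndimage.uniform_filter(img**2, size=15) - ndimage.uniform_filter(img, size=15) ** 2
    rough = np.sqrt(np.maximum(rough, 0.0))
    thr = threshold_otsu(rough) if threshold is None else threshold
    mask = rough > thr
    if closing_px > 0:
        mask = ndimage.binary_closing(mask, structure=np.ones((closing_px, closing_px)))
        mask = ndimage.binary_opening(mask, structure=np.ones((closing_px, closing_px)))
    return mask


def detect_front(
    occupancy_mask: np.ndarray, grid: GridSpec, side: str = "right"
) -> float:
    """Average free-margin position L (µm) from a per-node occupancy mask.

    Per grid row, the outermost occupied x position on the designated
    side; L is the mean over rows.  Rows without occupied nodes are
    skipped.
    """
    mask = np.asarray(occupancy_mask, dtype=bool)
    if mask.shape != grid.shape:
        raise GeometryError(f"mask shape {mask.shape} != grid shape {grid.shape}")
    if not mask.any():
        raise EstimationError("occupancy mask is empty: no front to detect")
    if mask.all():
        raise EstimationError("occupancy mask is full: no free margin in the field")
    x = grid.x
    fronts = []
    for row in mask:
        cols = np.nonzero(row)[0]
        if cols.size == 0:
            continue
        fronts.append(x[cols.max()] if side == "right" else x[cols.min()])
    if not fronts:
        raise EstimationError("no occupied rows")
    return float(np.mean(fronts))


def y_average(
    values: np.ndarray, grid: GridSpec, valid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """y-average of a per-node field: ``⟨f⟩_y(x) = (1/L_y) ∫ f dy``.

    Realised as the mean over valid nodes of each x column.  Returns
    ``(x, profile)``; columns with no valid node carry NaN (a flagged gap,
    not a silent zero).
    """
    vals = np.asarray(values, dtype=float)
    if vals.shape != grid.shape:
        raise GeometryError("field shape does not match grid")
    if valid is None:
        valid = np.ones(grid.shape, dtype=bool)
    prof = np.full(grid.n_x, np.nan)
    for j in range(grid.n_x):
        col = vals[:, j][valid[:, j]]
        if col.size:
            prof[j] = col.mean()
    return grid.x, prof


def tension_1d(
    traction: VectorField2D, L: float, time: float = 0.0
) -> TensionProfile1D:
    """1D tension by integration of the y-averaged x-traction from the margin.

    ``τ¹ᴰ(x) = ∫_L^x ⟨t_x⟩_y dx'`` by the trapezoidal rule on the traction
    grid; the integral is signed, so x on either side of L is handled, and
    ``τ(L) = 0`` holds by construction.
    """
    grid = traction.grid
    x, tx_prof = y_average(traction.u, grid, traction.valid)
    if not (grid.x[0] <= L <= grid.x[-1]):
        raise GeometryError(
            f"front position L = {L:.1f} µm lies outside the grid "
            f"[{grid.x[0]:.1f}, {grid.x[-1]:.1f}] µm"
        )
    if np.isnan(tx_prof).any():
        # integrate through flagged gaps by linear interpolation
        good = ~np.isnan(tx_prof)
        tx_prof = np.interp(x, x[good], tx_prof[good])
    # cumulative integral F(x) = ∫_{x0}^x, then τ(x) = F(x) − F(L)
    F = np.concatenate([[0.0], np.cumsum(0.5 * (tx_prof[1:] + tx_prof[:-1]) * np.diff(x))])
    F_L = float(np.interp(L, x, F))
    return TensionProfile1D(x=x, tau=F - F_L, time=time, source="integration")


def isotropic_tension(stress: StressField) -> TensionField2D:
    """Isotropic 2D tension ``τ = (σxx + σyy)/2`` per node (σxy unused)."""
    return TensionField2D(
        grid=stress.grid,
        tau=0.5 * (stress.sxx + stress.syy),
        valid=stress.valid.copy(),
    )


def bulk_average(tension: TensionField2D, margin: float = 200.0) -> float:
    """Mean tension over nodes strictly farther than ``margin`` (µm) from
    every grid boundary."""
    g = tension.grid
    X, Y = g.meshgrid()
    bulk = (
        (X > g.x[0] + margin)
        & (X < g.x[-1] - margin)
        & (Y > g.y[0] + margin)
        & (Y < g.y[-1] - margin)
        & tension.valid
    )
    if not bulk.any():
        raise EstimationError(
            f"a {margin} µm margin leaves no interior nodes on this "
            f"{g.n_x}x{g.n_y} grid"
        )
    return float(tension.tau[bulk].mean())


def compare_1d_2d(
    tau_eq_integration: TensionProfile1D,
    stress: StressField,
    margin: float = 200.0,
) -> tuple[TensionProfile1D, TensionProfile1D, float]:
    """Cross-validate τ¹ᴰ against the y-averaged σxx of the stress tensor.

    Returns ``(tau_1d, sxx_profile, relative_rms_difference)``; the RMS
    difference is evaluated over the bulk x-range (margins discarded) and
    normalised by the RMS of τ¹ᴰ there.
    """
    x2, sxx_prof = y_average(stress.sxx, stress.grid, stress.valid)
    x1 = tau_eq_integration.x
    lo = max(x1[0], x2[0])
    hi = min(x1[-1], x2[-1])
    if lo >= hi:
        raise GeometryError("tension profile and stress field have disjoint x ranges")
    good = ~np.isnan(sxx_prof)
    sxx_on_x1 = np.interp(x1, x2[good], sxx_prof[good])
    prof2 = TensionProfile1D(x=x1, tau=sxx_on_x1, time=tau_eq_integration.time,
                             source="stress_sxx_yavg")
    in_bulk = (x1 > lo + margin) & (x1 < hi - margin)
    if not in_bulk.any():
        in_bulk = (x1 >= lo) & (x1 <= hi)
    diff = tau_eq_integration.tau[in_bulk] - sxx_on_x1[in_bulk]
    scale = np.sqrt(np.mean(tau_eq_integration.tau[in_bulk] ** 2))
    rel = float(np.sqrt(np.mean(diff**2)) / scale) if scale > 0 else float(
        np.sqrt(np.mean(diff**2))
    )
    return tau_eq_integration, prof2, rel
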