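"""Collectivity of monolayer migration: velocity correlation length.

Migration is assumed to have a dominant axial direction (perpendicular to
the moving front).  Only the *lateral* velocity component — parallel to
the front — enters the analysis.  Per frame:

1. fluctuations ``u_ij = U_ij − U_mean`` with ``U_mean`` the whole-field
   mean of the lateral component;
2. the lateral correlation function
   ``C(r) = ⟨u(r′) u(r′+r)⟩ / sqrt(⟨u(r′)²⟩ ⟨u(r′+r)²⟩)`` over node pairs
   separated by ``r`` along the front-parallel axis (the denominator is
   lag-dependent: it is taken over the same contributing pairs);
3. the correlation length: the first distance at which ``C`` reaches the
   lower threshold 0.01, located by linear interpolation between lags.

Group comparisons (e.g. junction-coupled vs uncoupled monolayers) use the
unpaired Welch t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .fields import (
    CorrelationProfile,
    EstimationError,
    GridSpec,
    ParameterError,
    VectorField2D,
)

__all__ = [
    "FluctuationField",
    "lateral_fluctuations",
    "correlation_function",
    "correlation_length",
    "welch_t_test",
]


@dataclass
class FluctuationField:
    """Lateral velocity fluctuations per node (µm/min), whole-field mean removed."""

    grid: GridSpec
    u: np.ndarray  # fluctuation of the lateral component
    valid: np.ndarray
    mean_removed: float  # the subtracted lateral mean, µm/min
    front_axis: str = "x"
    frame_index: int = 0


def lateral_fluctuations(
    velocity: VectorField2D, front_axis: str = "x", frame_index: int = 0
) -> FluctuationField:
    """Subtract the whole-field mean from the lateral velocity component.

    ``front_axis`` names the axis of dominant (front-perpendicular)
    migration; the lateral component is the other one: the y component
    ``v`` when the front advances along x.
    """
    if front_axis not in ("x", "y"):
        raise ParameterError("front_axis must be 'x' or 'y'")
    lateral = velocity.v if front_axis == "x" else velocity.u
    valid = velocity.valid
    if valid.sum() < 2:
        raise EstimationError("need at least 2 valid nodes for fluctuations")
    mean = float(lateral[valid].mean())
    u = np.where(valid, lateral - mean, 0.0)
    return FluctuationField(
        grid=velocity.grid,
        u=u,
        valid=valid.copy(),
        mean_removed=mean,
        front_axis=front_axis,
        frame_index=frame_index,
    )


def correlation_function(
    fluct: FluctuationField,
    max_lag: float | None = None,
    pairs: str = "lateral",
    threshold: float = 0.01,
) -> CorrelationProfile:
    """Normalised spatial autocorrelation of the lateral fluctuations.

    Parameters
    ----------
    fluct
        Output of :func:`lateral_fluctuations`.
    max_lag
        Largest separation (µm) to evaluate; defaults to the full
        front-parallel extent of the grid.
    pairs
        ``"lateral"`` (default): pairs separated along the front-parallel
        axis only, i.e. within the same front-perpendicular column —
        the lateral correlation function *along the migration front*.
        ``"isotropic"``: all node pairs, binned by distance rounded to the
        nearest multiple of the grid spacing.
    threshold
        Stored on the profile; used by :func:`correlation_length`.

    Raises
    ------
    EstimationError
        If the fluctuations are identically zero (the 0/0 correlation is
        reported explicitly, never silently coerced to 0 or 1).
    """
    grid = fluct.grid
    u = fluct.u
    valid = fluct.valid
    if valid.sum() < 4:
        raise EstimationError("need at least 4 valid nodes")
    if not np.any(u[valid] != 0):
        raise EstimationError(
            "fluctuation field is identically zero: correlation is undefined (0/0)"
        )
    spacing = grid.spacing
    # lateral axis: rows (y) when the front moves along x, else columns
    if fluct.front_axis == "x":
        series = u  # columns indexed by x, series run along axis 0 (y)
        vmask = valid
    else:
        series = u.T
        vmask = valid.T
    n_lat = series.shape[0]
    if max_lag is None:
        max_lag = (n_lat - 1) * spacing
    k_max = min(int(np.floor(max_lag / spacing)), n_lat - 1)

    if pairs == "lateral":
        r, C, n_pairs = _lateral_correlation(series, vmask, spacing, k_max)
    elif pairs == "isotropic":
        r, C, n_pairs = _isotropic_correlation(u, valid, spacing, k_max)
    else:
        raise ParameterError("pairs must be 'lateral' or 'isotropic'")

    profile = CorrelationProfile(r=r, C=C, n_pairs=n_pairs, threshold=threshold)
    profile.corr_length = correlation_length(profile, threshold)
    return profile


def _lateral_correlation(series, vmask, spacing, k_max):
    rs, Cs, ns = [0.0], [1.0], [int(vmask.sum())]
    for k in range(1, k_max + 1):
        a = series[:-k]
        b = series[k:]
        m = vmask[:-k] & vmask[k:]
        n = int(m.sum())
        if n == 0:
            continue
        num = float((a * b)[m].mean())
        den = np.sqrt(float((a**2)[m].mean()) * float((b**2)[m].mean()))
        if den == 0:
            continue
        rs.append(k * spacing)
        Cs.append(num / den)
        ns.append(n)
    return np.array(rs), np.array(Cs), np.array(ns)


def _isotropic_correlation(u, valid, spacing, k_max):
    ys, xs = np.nonzero(valid)
    vals = u[valid]
    # accumulate pair products into distance bins (nearest grid-spacing
    # multiple); O(n²) in valid nodes, intended for modest grids
    num = np.zeros(k_max + 1)
    den_a = np.zeros(k_max + 1)
    den_b = np.zeros(k_max + 1)
    cnt = np.zeros(k_max + 1, dtype=int)
    n = len(vals)
    for i in range(n):
        dy = ys[i + 1 :] - ys[i]
        dx = xs[i + 1 :] - xs[i]
        k = np.rint(np.hypot(dy, dx)).astype(int)
        sel = k <= k_max
        k = k[sel]
        prod = vals[i] * vals[i + 1 :][sel]
        np.add.at(num, k, prod)
        np.add.at(den_a, k, vals[i] ** 2)
        np.add.at(den_b, k, vals[i + 1 :][sel] ** 2)
        np.add.at(cnt, k, 1)
    rs, Cs, ns = [0.0], [1.0], [n]
    for k in range(1, k_max + 1):
        if cnt[k] == 0:
            continue
        den = np.sqrt(den_a[k] / cnt[k] * den_b[k] / cnt[k])
        if den == 0:
            continue
        rs.append(k * spacing)
        Cs.append(num[k] / cnt[k] / den)
        ns.append(int(cnt[k]))
    return np.array(rs), np.array(Cs), np.array(ns)


def correlation_length(
    profile: CorrelationProfile, threshold: float = 0.01
) -> float | None:
    """First distance where C crosses from above to at-or-below ``threshold``.

    Located by linear interpolation between the bracketing lags.  Returns
    None (an explicitly undefined length, never a clamped value) when C
    stays above the threshold over the whole profile.
    """
    r, C = profile.r, profile.C
    if len(r) < 2:
        raise EstimationError("profile needs at least 2 lags")
    for i in range(1, len(r)):
        if C[i - 1] > threshold >= C[i]:
            if C[i] == threshold or C[i - 1] == C[i]:
                return float(r[i])
            frac = (C[i - 1] - threshold) / (C[i - 1] - C[i])
            return float(r[i - 1] + frac * (r[i] - r[i - 1]))
    return None


def welch_t_test(sample_a, sample_b) -> tuple[float, float, float]:
    """Unpaired two-sample t-test with Welch's correction.

    Returns ``(t, df, p)`` with
    ``t = (m_a − m_b)/sqrt(s_a²/n_a + s_b²/n_b)``, the Welch–Satterthwaite
    degrees of freedom, and the two-sided p-value from the t distribution.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise EstimationError("each sample needs at least 2 values")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0 and vb == 0:
        raise EstimationError("both samples have zero variance")
    sea = va / a.size
    seb = vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(sea + seb)
    df = (sea + seb) ** 2 / (sea**2 / (a.size - 1) + seb**2 / (b.size - 1))
    p = float(2.0 * special.stdtr(df, -abs(t)))
    return float(t), float(df), p
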