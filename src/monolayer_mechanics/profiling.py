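"""Line-based image quantification of junction dynamics.

Two tools used when scoring cell–cell interfaces in fluorescence movies:

* kymographs — intensity along a user line, per frame, stacked into a
  position × time image;
* normalised cross-section profiles — intensity of both channels along
  short lines crossing an interface, recentred on the membrane-channel
  peak and min–max normalised per profile, aggregated as mean ± s.d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fields import EstimationError, FrameSequence, GeometryError, ParameterError

__all__ = ["LineSegment", "ProfileSet", "kymograph", "cross_section_profiles"]


@dataclass(frozen=True)
class LineSegment:
    """Sampling line with an averaging band ``width_px`` perpendicular to it."""

    x1: float
    y1: float
    x2: float
    y2: float
    width_px: int = 1

    def __post_init__(self) -> None:
        if self.width_px < 1:
            raise ParameterError("width_px must be >= 1")
        if self.length == 0:
            raise GeometryError("line segment has zero length")

    @property
    def length(self) -> float:
        return float(np.hypot(self.x2 - self.x1, self.y2 - self.y1))


@dataclass
class ProfileSet:
    """Aggregated normalised cross-section profiles.

    ``positions`` are µm (or px when no pixel size is supplied) along the
    line, 0 at the interface; ``profiles`` has shape
    ``(n_profiles, n_channels, n_positions)`` with each profile min–max
    normalised to [0, 1]; ``mean``/``sd`` aggregate over profiles.
    ``n_degenerate`` counts flat profiles excluded from normalisation.
    """

    positions: np.ndarray
    profiles: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: int
    n_degenerate: int = 0


def _sample_line(image: np.ndarray, line: LineSegment) -> np.ndarray:
    """Intensities at unit-spaced points along the line, averaged across
    the perpendicular band, by bilinear interpolation."""
    h, w = image.shape
    for x, y in ((line.x1, line.y1), (line.x2, line.y2)):
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            raise GeometryError(f"line endpoint ({x}, {y}) outside image {w}x{h}")
    n = int(np.floor(line.length)) + 1
    t = np.linspace(0.0, line.length, n)
    dx = (line.x2 - line.x1) / line.length
    dy = (line.y2 - line.y1) / line.length
    xs = line.x1 + t * dx
    ys = line.y1 + t * dy
    # perpendicular unit vector for the averaging band
    px, py = -dy, dx
    offsets = np.arange(line.width_px) - (line.width_px - 1) / 2.0
    acc = np.zeros(n)
    for o in offsets:
        acc += ndimage.map_coordinates(
            np.asarray(image, dtype=float),
            np.stack([ys + o * py, xs + o * px]),
            order=1,
            mode="nearest",
        )
    return acc / len(offsets)


def kymograph(stack: FrameSequence, line: LineSegment) -> np.ndarray:
    """Position × time intensity array along a line.

    Rows are unit-spaced positions along the line, columns the frames of
    the stack.
    """
    cols = [_sample_line(frame, line) for frame in stack.frames]
    return np.stack(cols, axis=1)


def _quadratic_peak(profile: np.ndarray) -> float:
    """Sub-sample position of the profile maximum (3-point parabola)."""
    i = int(np.argmax(profile))
    if 0 < i < len(profile) - 1:
        cm1, c0, cp1 = profile[i - 1], profile[i], profile[i + 1]
        denom = cm1 + cp1 - 2.0 * c0
        if denom < 0:
            return i + float((cm1 - cp1) / (2.0 * denom))
    return float(i)


def cross_section_profiles(
    image: np.ndarray,
    lines: list[LineSegment],
    center_channel: int = 0,
    pixel_size: float = 1.0,
) -> ProfileSet:
    """Normalised two-channel intensity profiles across an interface.

    Each line is sampled as in :func:`kymograph` (single frame); the
    profile is recentred so position 0 is the sub-pixel intensity peak of
    ``center_channel``, and each channel is min–max normalised to [0, 1]
    per profile.  Flat (max == min) profiles are flagged degenerate,
    excluded, and counted.  Mean and s.d. are per position per channel
    over the surviving profiles.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3:
        raise ParameterError("expected a (channels, height, width) image")
    if not lines:
        raise ParameterError("need at least one cross-section line")
    n_ch = img.shape[0]
    if not (0 <= center_channel < n_ch):
        raise ParameterError("center_channel out of range")

    half = min(int(np.floor(line.length)) for line in lines) // 2
    rel = np.arange(-half, half + 1, dtype=float)

    kept: list[np.ndarray] = []
    n_degenerate = 0
    for line in lines:
        raw = np.stack([_sample_line(img[c], line) for c in range(n_ch)])
        peak = _quadratic_peak(raw[center_channel])
        # resample every channel on a common grid centred at the peak
        prof = np.empty((n_ch, rel.size))
        pos = np.arange(raw.shape[1], dtype=float)
        ok = True
        for c in range(n_ch):
            prof[c] = np.interp(peak + rel, pos, raw[c])
            lo, hi = prof[c].min(), prof[c].max()
            if hi == lo:
                ok = False
                break
            prof[c] = (prof[c] - lo) / (hi - lo)
        if ok:
            kept.append(prof)
        else:
            n_degenerate += 1
    if not kept:
        raise EstimationError("all cross-section profiles were degenerate (flat)")
    profiles = np.stack(kept)
    return ProfileSet(
        positions=rel * pixel_size,
        profiles=profiles,
        mean=profiles.mean(axis=0),
        sd=profiles.std(axis=0, ddof=0),
        n=len(kept),
        n_degenerate=n_degenerate,
    )
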