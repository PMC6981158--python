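"""Core containers: grids, image sequences, vector and tensor fields.

All physical coordinates are in micrometres, measured from the top-left
pixel centre, with x increasing rightward (array columns) and y increasing
downward (array rows).  Field arrays are indexed ``[row, col] == [iy, ix]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GridSpec",
    "FrameSequence",
    "VectorField2D",
    "StressField",
    "CorrelationProfile",
    "TensionProfile1D",
    "TensionField2D",
    "FrontTrack",
    "GeometryError",
    "ParameterError",
    "EstimationError",
    "FormatError",
]


class ParameterError(ValueError):
    """An argument is outside its physically meaningful range."""


class GeometryError(ValueError):
    """Grids, images or lines do not cover or match each other."""


class EstimationError(RuntimeError):
    """A quantity cannot be estimated from the given data (degenerate input)."""


class FormatError(ValueError):
    """An input file is not in a supported format."""


@dataclass(frozen=True)
class GridSpec:
    """Regular, isotropic 2D grid of nodes.

    Parameters
    ----------
    origin
        ``(x0, y0)`` position of the first node in µm.
    n_x, n_y
        Node counts along x (columns) and y (rows).
    spacing
        Node spacing in µm, identical along both axes.
    """

    origin: tuple[float, float]
    n_x: int
    n_y: int
    spacing: float

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ParameterError(f"grid spacing must be > 0, got {self.spacing}")
        if self.n_x < 2 or self.n_y < 2:
            raise ParameterError("grids need at least 2 nodes per axis")

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape ``(n_y, n_x)`` of per-node fields on this grid."""
        return (self.n_y, self.n_x)

    @property
    def x(self) -> np.ndarray:
        """x coordinates of the node columns, µm."""
        return self.origin[0] + self.spacing * np.arange(self.n_x)

    @property
    def y(self) -> np.ndarray:
        """y coordinates of the node rows, µm."""
        return self.origin[1] + self.spacing * np.arange(self.n_y)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """``(X, Y)`` coordinate arrays of shape ``(n_y, n_x)``."""
        return np.meshgrid(self.x, self.y)

    def same_geometry(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.n_x == other.n_x
            and self.n_y == other.n_y
            and abs(self.spacing - other.spacing) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )


@dataclass
class FrameSequence:
    """Time-ordered stack of equally shaped 2D intensity images."""

    frames: list[np.ndarray]
    pixel_size: float  # µm / px
    frame_interval: float  # minutes

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ParameterError("pixel_size and frame_interval must be > 0")
        if not self.frames:
            raise ParameterError("a FrameSequence needs at least one frame")
        shape = np.asarray(self.frames[0]).shape
        for i, f in enumerate(self.frames):
            if np.asarray(f).shape != shape:
                raise GeometryError(f"frame {i} shape {np.asarray(f).shape} != {shape}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, ...]:
        return np.asarray(self.frames[0]).shape


_VECTOR_UNITS = {"px", "um", "um/min", "Pa"}


@dataclass
class VectorField2D:
    """2D vector field (displacement, velocity or traction) on a regular grid.

    ``u`` is the x component and ``v`` the y component, both with array
    shape ``grid.shape``.  ``valid`` flags nodes carrying a trustworthy
    measurement; invalid nodes hold NaN-safe placeholder values that must
    never enter statistics.
    """

    grid: GridSpec
    u: np.ndarray
    v: np.ndarray
    unit: str
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.grid.shape or self.v.shape != self.grid.shape:
            raise GeometryError(
                f"component shape {self.u.shape}/{self.v.shape} does not match "
                f"grid shape {self.grid.shape}"
            )
        if self.unit not in _VECTOR_UNITS:
            raise ParameterError(f"unit must be one of {_VECTOR_UNITS}, got {self.unit!r}")
        if self.valid is None:
            self.valid = np.ones(self.grid.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.grid.shape:
                raise GeometryError("valid mask shape does not match grid")

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    def scaled(self, factor: float, unit: str | None = None) -> "VectorField2D":
        return VectorField2D(
            grid=self.grid,
            u=self.u * factor,
            v=self.v * factor,
            unit=self.unit if unit is None else unit,
            valid=self.valid.copy(),
        )


@dataclass
class StressField:
    """Symmetric 2D stress tensor (sxx, syy, sxy) per node, units Pa·µm.

    A 2D monolayer stress is the 3D stress integrated across the tissue
    height, hence Pa·µm.  Symmetry is structural: only one shear component
    is stored.
    """

    grid: GridSpec
    sxx: np.ndarray
    syy: np.ndarray
    sxy: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("sxx", "syy", "sxy"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.grid.shape:
                raise GeometryError(f"{name} shape {arr.shape} != grid {self.grid.shape}")
            setattr(self, name, arr)
        if self.valid is None:
            self.valid = np.ones(self.grid.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)


@dataclass
class CorrelationProfile:
    """Spatial correlation ``C(r)`` of velocity fluctuations at discrete lags.

    ``corr_length`` is the threshold-crossing distance (µm) or None when the
    profile never reaches the threshold within the available lags.
    """

    r: np.ndarray
    C: np.ndarray
    n_pairs: np.ndarray
    threshold: float = 0.01
    corr_length: float | None = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if not (len(self.r) == len(self.C) == len(self.n_pairs)):
            raise ParameterError("r, C and n_pairs must have equal length")
        if len(self.r) and self.r[0] != 0:
            raise ParameterError("lag axis must start at r = 0")

    @property
    def defined(self) -> bool:
        return self.corr_length is not None


@dataclass
class TensionProfile1D:
    """Monolayer tension τ(x) along the front-perpendicular coordinate, Pa·µm."""

    x: np.ndarray
    tau: np.ndarray
    time: float = 0.0
    source: str = "integration"  # {"integration", "stress_sxx_yavg"}

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.x.shape != self.tau.shape:
            raise ParameterError("x and tau must have equal shape")


@dataclass
class TensionField2D:
    """Isotropic 2D tension τ = (σxx + σyy)/2 per node, Pa·µm."""

    grid: GridSpec
    tau: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        if self.tau.shape != self.grid.shape:
            raise GeometryError("tau shape does not match grid")
        if self.valid is None:
            self.valid = np.ones(self.grid.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)


@dataclass
class FrontTrack:
    """Average free-margin position L(t) of an expanding monolayer.

    x is the coordinate perpendicular to the front, y parallel to it.
    """

    times: np.ndarray  # minutes
    L: np.ndarray  # µm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        if self.times.shape != self.L.shape:
            raise ParameterError("times and L must have equal shape")
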