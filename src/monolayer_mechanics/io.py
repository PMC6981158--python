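"""File formats: multi-page TIFF stacks, TSV field tables, YAML manifests.

Every numeric file written here carries its units and grid geometry in a
YAML front-matter block of ``#``-prefixed header lines, so no unitless
numbers ever land on disk.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .fields import (
    FormatError,
    FrameSequence,
    GridSpec,
    StressField,
    VectorField2D,
)

__all__ = [
    "read_stack",
    "write_stack",
    "write_vector_field",
    "read_vector_field",
    "write_stress_field",
    "read_stress_field",
    "write_manifest",
]


def read_stack(
    path: str | Path, pixel_size: float, frame_interval: float
) -> FrameSequence:
    """Read a multi-page grayscale TIFF as a FrameSequence.

    ``pixel_size`` (µm/px) and ``frame_interval`` (min) come from the run
    configuration; if the file carries resolution metadata that disagrees,
    the configured values win and a warning is emitted.

    Raises
    ------
    FormatError
        For RGB/multisample pages (never silently collapsed) or pages of
        mixed shapes.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = tif.pages
        frames = []
        for i, page in enumerate(pages):
            arr = page.asarray()
            if arr.ndim == 3:
                raise FormatError(
                    f"page {i} of {path.name} has {arr.shape[-1]} samples per "
                    "pixel; RGB input is not supported — provide grayscale stacks"
                )
            frames.append(np.asarray(arr, dtype=float))
        try:
            res = pages[0].tags.get("XResolution")
            if res is not None:
                num, den = res.value
                if num and den:
                    file_px = den / num  # units per pixel
                    if abs(file_px - pixel_size) / pixel_size > 0.05:
                        import warnings

                        warnings.warn(
                            f"{path.name}: file resolution suggests "
                            f"{file_px:.4g} per px, config says {pixel_size}; "
                            "using the configured value",
                            stacklevel=2,
                        )
        except (KeyError, TypeError, ValueError):
            pass
    return FrameSequence(frames=frames, pixel_size=pixel_size, frame_interval=frame_interval)


def write_stack(path: str | Path, frames, pixel_size: float | None = None) -> None:
    """Write frames as a multi-page float32 TIFF."""
    arr = np.stack([np.asarray(f, dtype=np.float32) for f in frames])
    kwargs = {}
    if pixel_size:
        kwargs["resolution"] = (1.0 / pixel_size, 1.0 / pixel_size)
    tifffile.imwrite(Path(path), arr, **kwargs)


def _write_table(path: Path, header: dict, frame: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        for line in yaml.safe_dump(header, sort_keys=False).splitlines():
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _read_table(path: Path) -> tuple[dict, pd.DataFrame]:
    header_lines = []
    body_start = 0
    with open(path) as fh:
        while True:
            line = fh.readline()
            if line.startswith("#"):
                # strip exactly the "# " prefix; deeper indentation is
                # significant YAML structure
                header_lines.append(line[2:] if line.startswith("# ") else line[1:])
                body_start = fh.tell()
            else:
                break
        fh.seek(body_start)
        frame = pd.read_csv(fh, sep="\t")
    header = yaml.safe_load("".join(header_lines)) or {}
    return header, frame


def _grid_header(grid: GridSpec) -> dict:
    return {
        "origin_um": [float(grid.origin[0]), float(grid.origin[1])],
        "n_x": grid.n_x,
        "n_y": grid.n_y,
        "spacing_um": float(grid.spacing),
        "coordinates": "x rightward, y downward, µm from the top-left pixel centre",
    }


def write_vector_field(path: str | Path, field: VectorField2D, extra: dict | None = None) -> None:
    """TSV with columns x_um, y_um, u, v, valid and a YAML header."""
    X, Y = field.grid.meshgrid()
    frame = pd.DataFrame(
        {
            "x_um": X.ravel(),
            "y_um": Y.ravel(),
            "u": field.u.ravel(),
            "v": field.v.ravel(),
            "valid": field.valid.ravel().astype(int),
        }
    )
    header = {"kind": "vector_field", "unit": field.unit, "grid": _grid_header(field.grid)}
    if extra:
        header.update(extra)
    _write_table(Path(path), header, frame)


def read_vector_field(path: str | Path) -> VectorField2D:
    header, frame = _read_table(Path(path))
    g = header["grid"]
    grid = GridSpec(
        origin=tuple(g["origin_um"]), n_x=g["n_x"], n_y=g["n_y"], spacing=g["spacing_um"]
    )
    shape = grid.shape
    return VectorField2D(
        grid=grid,
        u=frame["u"].to_numpy().reshape(shape),
        v=frame["v"].to_numpy().reshape(shape),
        unit=header["unit"],
        valid=frame["valid"].to_numpy().astype(bool).reshape(shape),
    )


def write_stress_field(path: str | Path, stress: StressField, extra: dict | None = None) -> None:
    """TSV with columns x_um, y_um, sxx, syy, sxy (Pa·µm) and a YAML header."""
    X, Y = stress.grid.meshgrid()
    frame = pd.DataFrame(
        {
            "x_um": X.ravel(),
            "y_um": Y.ravel(),
            "sxx": stress.sxx.ravel(),
            "syy": stress.syy.ravel(),
            "sxy": stress.sxy.ravel(),
            "valid": stress.valid.ravel().astype(int),
        }
    )
    header = {"kind": "stress_field", "unit": "Pa.um", "grid": _grid_header(stress.grid)}
    if extra:
        header.update(extra)
    _write_table(Path(path), header, frame)


def read_stress_field(path: str | Path) -> StressField:
    header, frame = _read_table(Path(path))
    g = header["grid"]
    grid = GridSpec(
        origin=tuple(g["origin_um"]), n_x=g["n_x"], n_y=g["n_y"], spacing=g["spacing_um"]
    )
    shape = grid.shape
    return StressField(
        grid=grid,
        sxx=frame["sxx"].to_numpy().reshape(shape),
        syy=frame["syy"].to_numpy().reshape(shape),
        sxy=frame["sxy"].to_numpy().reshape(shape),
        valid=frame["valid"].to_numpy().astype(bool).reshape(shape),
    )


def write_manifest(path: str | Path, manifest: dict) -> None:
    with open(Path(path), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
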