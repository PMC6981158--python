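"""End-to-end workflows binding the stages together.

Two workflows, mirroring how a switchable-junction monolayer experiment
is analysed:

* ``collectivity`` — phase-contrast movie → PIV velocity fields →
  lateral fluctuations → correlation length per frame pair;
* ``mechanics`` — stressed bead images + relaxed reference → substrate
  displacement → FTTC traction → stress inversion → isotropic tension →
  1D tension profile and bulk summary per frame.

``run_pipeline`` executes either or both on in-memory frame sequences and
optionally writes every per-stage output (TSV fields with YAML headers,
PNG heat maps, a YAML summary) under an output directory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bism as _bism
from . import collectivity as _coll
from . import io as _io
from . import piv as _piv
from . import tension as _tension
from . import tfm as _tfm
from .fields import FrameSequence, GridSpec

__all__ = ["RunConfig", "run_pipeline", "compare_groups"]


@dataclass
class RunConfig:
    """Everything a run needs besides the images themselves."""

    pixel_size: float = 1.294  # µm/px
    frame_interval: float = 5.0  # min
    piv: _piv.PivConfig = dc_field(default_factory=_piv.PivConfig)
    tfm: _tfm.TfmConfig = dc_field(default_factory=_tfm.TfmConfig)
    substrate: _tfm.SubstrateModel = dc_field(default_factory=_tfm.SubstrateModel)
    bism: _bism.BismConfig = dc_field(default_factory=_bism.BismConfig)
    front_axis: str = "x"
    front_side: str = "right"
    margin: float = 200.0  # µm discarded for bulk statistics
    crop_border_nodes: int = 2  # traction nodes dropped at the field border
    max_lag: float | None = None
    corr_threshold: float = 0.01
    grid: GridSpec | None = None  # analysis grid override for mechanics
    seed: int = 0
    output_dir: str | None = None
    save_heatmaps: bool = False

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["piv"] = dataclasses.asdict(self.piv)
        d["tfm"] = dataclasses.asdict(self.tfm)
        d["substrate"] = dataclasses.asdict(self.substrate)
        d["bism"] = dataclasses.asdict(self.bism)
        if self.grid is not None:
            d["grid"] = dataclasses.asdict(self.grid)
        return d


def _velocity_fields(movie: FrameSequence, config: RunConfig):
    """PIV between consecutive frames, resampled and scaled to µm/min."""
    out = []
    for k in range(len(movie) - 1):
        raw = _piv.piv_displacement(movie.frames[k], movie.frames[k + 1], config.piv)
        disp = _piv.interpolate_to_grid(
            raw, config.piv.nodal_distance_px, movie.pixel_size
        )
        out.append(_piv.to_velocity(disp, movie.pixel_size, movie.frame_interval))
    return out


def run_collectivity(movie: FrameSequence, config: RunConfig) -> pd.DataFrame:
    """Correlation length per consecutive frame pair.

    Returns a table with columns frame, corr_length_um, defined,
    n_pairs_min, mean_front_velocity_um_min.  Undefined lengths (profiles
    never reaching the threshold) carry NaN and defined = 0; downstream
    statistics must exclude them (they are counted, never clamped).
    """
    rows = []
    for k, vel in enumerate(_velocity_fields(movie, config)):
        fluct = _coll.lateral_fluctuations(vel, config.front_axis, frame_index=k)
        profile = _coll.correlation_function(
            fluct, max_lag=config.max_lag, threshold=config.corr_threshold
        )
        axial = vel.u if config.front_axis == "x" else vel.v
        rows.append(
            {
                "frame": k,
                "corr_length_um": profile.corr_length
                if profile.corr_length is not None
                else np.nan,
                "defined": int(profile.corr_length is not None),
                "n_pairs_min": int(profile.n_pairs[1:].min())
                if len(profile.n_pairs) > 1
                else 0,
                "mean_front_velocity_um_min": float(axial[vel.valid].mean()),
            }
        )
    return pd.DataFrame(rows)


def run_mechanics(
    bead_movie: FrameSequence,
    bead_reference: np.ndarray,
    config: RunConfig,
    masks: list[np.ndarray] | None = None,
) -> dict:
    """Traction → stress → tension for every stressed frame.

    ``masks`` are optional per-frame pixel occupancy masks (cells); they
    restrict the cell-region traction statistic and provide the front
    position. Without masks the front defaults to the free-edge side of
    the analysis grid and traction statistics cover the whole field.
    """
    per_frame = []
    fields = {"displacement": [], "traction": [], "stress": [], "tension": [],
              "profiles": []}
    for k, frame in enumerate(bead_movie.frames):
        disp = _tfm.bead_displacement(
            frame, bead_reference, config.piv, bead_movie.pixel_size
        )
        traction = _tfm.reconstruct_traction(
            disp, config.substrate, config.tfm, grid=config.grid
        )
        if config.crop_border_nodes > 0:
            # spectral inversion rings at the field border (the zero padding
            # abuts non-decaying displacement there); drop those nodes
            traction = _crop_field(traction, config.crop_border_nodes)
        stress = _bism.infer_stress(traction, config.bism)
        residual, _ = _bism.residual_report(traction, stress)
        tau2d = _tension.isotropic_tension(stress)
        bulk = _tension.bulk_average(tau2d, config.margin)

        grid = traction.grid
        if masks is not None:
            node_mask = _mask_on_grid(masks[k], grid, bead_movie.pixel_size)
            L = _tension.detect_front(node_mask, grid, config.front_side)
            mean_traction_cells = _tfm.mean_traction_norm(traction, node_mask)
        else:
            node_mask = None
            L = grid.x[-1] if config.front_side == "right" else grid.x[0]
            mean_traction_cells = np.nan
        tau1d = _tension.tension_1d(traction, L, time=k * bead_movie.frame_interval)
        _, sxx_prof, rel_rms = _tension.compare_1d_2d(tau1d, stress, config.margin)

        per_frame.append(
            {
                "frame": k,
                "mean_traction_norm_Pa": _tfm.mean_traction_norm(traction),
                "mean_traction_norm_cells_Pa": mean_traction_cells,
                "bulk_tension_Pa_um": bulk,
                "front_L_um": L,
                "tau1d_vs_sxx_rel_rms": rel_rms,
                "bism_residual": residual,
            }
        )
        fields["displacement"].append(disp)
        fields["traction"].append(traction)
        fields["stress"].append(stress)
        fields["tension"].append(tau2d)
        fields["profiles"].append((tau1d, sxx_prof))

    table = pd.DataFrame(per_frame)
    return {
        "table": table,
        "fields": fields,
        "time_averaged_bulk_tension_Pa_um": float(table["bulk_tension_Pa_um"].mean()),
        "time_averaged_traction_norm_Pa": float(table["mean_traction_norm_Pa"].mean()),
    }


def _crop_field(field, k: int):
    g = field.grid
    sub = GridSpec(
        origin=(g.x[k], g.y[k]), n_x=g.n_x - 2 * k, n_y=g.n_y - 2 * k, spacing=g.spacing
    )
    from .fields import VectorField2D

    return VectorField2D(
        grid=sub,
        u=field.u[k:-k, k:-k],
        v=field.v[k:-k, k:-k],
        unit=field.unit,
        valid=field.valid[k:-k, k:-k],
    )


def _mask_on_grid(pixel_mask: np.ndarray, grid: GridSpec, pixel_size: float):
    ix = np.clip(np.round(grid.x / pixel_size).astype(int), 0, pixel_mask.shape[1] - 1)
    iy = np.clip(np.round(grid.y / pixel_size).astype(int), 0, pixel_mask.shape[0] - 1)
    return pixel_mask[np.ix_(iy, ix)]


def run_pipeline(
    config: RunConfig,
    workflow: str = "both",
    cell_movie: FrameSequence | None = None,
    bead_movie: FrameSequence | None = None,
    bead_reference: np.ndarray | None = None,
    masks: list[np.ndarray] | None = None,
) -> dict:
    """Execute the requested workflow(s) and optionally write all outputs.

    Returns a summary dict with the per-frame tables and scalar summaries;
    re-running with identical inputs and config reproduces every number
    bit-identically (the pipeline itself draws no random numbers).
    """
    if workflow not in ("collectivity", "mechanics", "both"):
        raise ValueError(f"unknown workflow {workflow!r}")
    summary: dict = {"config": config.as_dict(), "workflow": workflow}

    if workflow in ("collectivity", "both"):
        if cell_movie is None:
            raise ValueError("collectivity workflow needs a cell movie")
        coll = run_collectivity(cell_movie, config)
        defined = coll[coll["defined"] == 1]["corr_length_um"]
        summary["collectivity"] = {
            "table": coll,
            "mean_corr_length_um": float(defined.mean()) if len(defined) else np.nan,
            "n_undefined": int((coll["defined"] == 0).sum()),
        }

    if workflow in ("mechanics", "both"):
        if bead_movie is None or bead_reference is None:
            raise ValueError("mechanics workflow needs bead images and a reference")
        summary["mechanics"] = run_mechanics(bead_movie, bead_reference, config, masks)

    if config.output_dir:
        _write_outputs(Path(config.output_dir), summary, config)
    return summary


def compare_groups(lengths_a, lengths_b) -> dict:
    """Welch t-test between two groups of correlation lengths (or any
    per-frame scalar), as used to compare treated vs control monolayers."""
    t, df, p = _coll.welch_t_test(lengths_a, lengths_b)
    return {
        "t": t,
        "df": df,
        "p": p,
        "mean_a": float(np.mean(lengths_a)),
        "mean_b": float(np.mean(lengths_b)),
    }


def _write_outputs(out: Path, summary: dict, config: RunConfig) -> None:
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"workflow": summary["workflow"], "config": summary["config"]}
    if "collectivity" in summary:
        summary["collectivity"]["table"].to_csv(
            out / "collectivity.tsv", sep="\t", index=False
        )
    if "mechanics" in summary:
        mech = summary["mechanics"]
        mech["table"].to_csv(out / "mechanics_summary.tsv", sep="\t", index=False)
        for k, (disp, trac, strs, tau) in enumerate(
            zip(
                mech["fields"]["displacement"],
                mech["fields"]["traction"],
                mech["fields"]["stress"],
                mech["fields"]["tension"],
            )
        ):
            _io.write_vector_field(out / f"displacement_{k:03d}.tsv", disp)
            _io.write_vector_field(out / f"traction_{k:03d}.tsv", trac)
            _io.write_stress_field(out / f"stress_{k:03d}.tsv", strs)
            tau1d, sxx_prof = mech["fields"]["profiles"][k]
            pd.DataFrame(
                {
                    "x_um": tau1d.x,
                    "tau1d_Pa_um": tau1d.tau,
                    "sxx_yavg_Pa_um": sxx_prof.tau,
                }
            ).to_csv(out / f"tension_profile_{k:03d}.tsv", sep="\t", index=False)
            if config.save_heatmaps:
                _heatmap(out / f"traction_norm_{k:03d}.png", trac.magnitude(),
                         trac.grid, "traction norm (Pa)")
                _heatmap(out / f"tension_{k:03d}.png", tau.tau, tau.grid,
                         "tension (Pa·µm)")
    _io.write_manifest(out / "manifest.yaml", manifest)


def _heatmap(path: Path, values: np.ndarray, grid: GridSpec, label: str) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(
        values,
        origin="upper",
        extent=(grid.x[0], grid.x[-1], grid.y[-1], grid.y[0]),
        cmap="inferno",
    )
    fig.colorbar(im, ax=ax, label=label)
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
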