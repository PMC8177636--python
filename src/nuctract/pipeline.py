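"""End-to-end orchestration: segment → average → align → anneal → forces.

Driven by a resolved configuration dict (see :mod:`nuctract.defaults`).
All outputs are plain text (CSV/YAML) plus optional figures; a failed run
removes the partial outputs it created.  Given the same configuration and
seed, every output is reproduced byte-for-byte.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import shapely.geometry
import yaml

from .annealing import AnnealConfig, anneal
from .contour import Contour
from .contour_io import read_contour_csv, write_contour_csv
from .elasticity import ElasticParams
from .ensemble import align_pair, average_contours
from .errors import NuctractError
from .geometry import frames
from .shell import ShellModel
from .solid import SolidModel
from .synth import ChannelGeometry

logger = logging.getLogger(__name__)

__all__ = ["run_stage_pair", "volume_report", "build_model", "elastic_params",
           "channel_geometry", "anneal_config", "load_stage_contour"]


def elastic_params(cfg: dict) -> ElasticParams:
    e = cfg["elastic"]
    return ElasticParams(
        E=float(e["youngs_modulus"]),
        nu=float(e["poisson_ratio"]),
        h=float(e["shell_thickness"]),
        strain_convention=e["strain_convention"],
    )


def channel_geometry(cfg: dict) -> ChannelGeometry:
    return ChannelGeometry(**{k: float(v) for k, v in cfg["channel"].items()})


def anneal_config(cfg: dict) -> AnnealConfig:
    a = dict(cfg["anneal"])
    return AnnealConfig(
        seed=int(cfg["seed"]),
        initial_acceptance=float(a["initial_acceptance"]),
        cooling_factor=float(a["cooling_factor"]),
        sweeps_max=int(a["sweeps_max"]),
        stall_sweeps=int(a["stall_sweeps"]),
        move_fraction=float(a["move_fraction"]),
        temperature=None if a.get("temperature") is None else float(a["temperature"]),
        n_points=None if a.get("n_points") is None else int(a["n_points"]),
        reproject=bool(a.get("reproject", False)),
    )


def build_model(cfg: dict):
    params = elastic_params(cfg)
    name = cfg["model"]
    if name == "solid":
        geom = channel_geometry(cfg)
        return SolidModel(params, height=geom.height_at)
    if name == "shell":
        return ShellModel(params)
    raise NuctractError(f"unknown model {name!r}; choose 'solid' or 'shell'")


def load_stage_contour(spec, n_average: int | None = None) -> Contour:
    """A stage input: one contour CSV path, or a list of paths to average."""
    if isinstance(spec, (str, Path)):
        return read_contour_csv(spec)
    contours = [read_contour_csv(p) for p in spec]
    if len(contours) == 1:
        return contours[0]
    return average_contours(contours, n_average)


def run_stage_pair(cfg: dict, output_dir) -> dict[str, Path]:
    """Full pipeline on one initial/target stage pair.

    ``cfg`` must be a resolved config with ``inputs: {initial: ..., target:
    ...}`` (paths or path lists).  Writes aligned target, best mapping,
    energy trace, traction profile CSV, surface frame CSV and the effective
    config into ``output_dir``; returns the paths keyed by artifact name.
    Partial outputs are removed if any stage fails.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _path(name: str) -> Path:
        p = out / name
        written.append(p)
        return p

    try:
        inputs = cfg.get("inputs") or {}
        if "initial" not in inputs or "target" not in inputs:
            raise NuctractError("config must name inputs.initial and inputs.target")
        initial = load_stage_contour(inputs["initial"])
        target = load_stage_contour(inputs["target"])
        logger.info("loaded contours: %d / %d points", len(initial), len(target))

        pair = align_pair(initial, target)
        logger.info("alignment shift from centroid-aligned position: %.6g um",
                    pair.shift)
        write_contour_csv(pair.initial, _path("initial_centred.csv"))
        write_contour_csv(pair.target, _path("target_aligned.csv"))

        model = build_model(cfg)
        result = anneal(pair.initial, pair.target, model, anneal_config(cfg))
        logger.info("annealed: %d sweeps, T0=%.4g, best energy %.6g",
                    len(result.trace), result.temperature0, result.energy)
        result.trace.to_csv(_path("energy_trace.csv"), index=False)

        mapping = result.mapping
        pd.DataFrame(
            {
                "x0_um": mapping.initial.points[:, 0],
                "y0_um": mapping.initial.points[:, 1],
                "x1_um": mapping.target.points[:, 0],
                "y1_um": mapping.target.points[:, 1],
            }
        ).to_csv(_path("mapping.csv"), index=False)

        fr = frames(mapping.initial)
        fr.to_dataframe().to_csv(_path("frames.csv"), index=False)
        profile = model.traction_profile(mapping, fr)
        profile.to_csv(_path("traction.csv"))

        effective = dict(cfg)
        with open(_path("effective_config.yaml"), "w") as fh:
            yaml.safe_dump(effective, fh, sort_keys=True)

        artifacts = {
            "initial": out / "initial_centred.csv",
            "target": out / "target_aligned.csv",
            "trace": out / "energy_trace.csv",
            "mapping": out / "mapping.csv",
            "frames": out / "frames.csv",
            "traction": out / "traction.csv",
            "config": out / "effective_config.yaml",
        }
        if cfg["plots"]["enabled"]:
            artifacts.update(_write_plots(cfg, mapping, profile, result, out, written))
        return artifacts
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _write_plots(cfg, mapping, profile, result, out: Path, written: list[Path]):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fmt = cfg["plots"]["format"]
    scale = float(cfg["plots"]["arrow_pa_per_um"])
    made = {}

    fig, ax = plt.subplots(figsize=(6, 6))
    ip = mapping.initial.points
    tp = mapping.target.points
    ax.plot(np.append(ip[:, 0], ip[0, 0]), np.append(ip[:, 1], ip[0, 1]),
            "k-", lw=1, label="initial")
    ax.plot(np.append(tp[:, 0], tp[0, 0]), np.append(tp[:, 1], tp[0, 1]),
            "g-", lw=1, label="target")
    u = mapping.u
    ax.quiver(ip[:, 0], ip[:, 1], u[:, 0], u[:, 1], angles="xy",
              scale_units="xy", scale=1.0, color="b", width=0.003,
              label="deformation")
    t = profile.traction_vec / scale  # one unit of length = `scale` Pa
    ax.quiver(ip[:, 0], ip[:, 1], t[:, 0], t[:, 1], angles="xy",
              scale_units="xy", scale=1.0, color="r", width=0.003,
              label=f"traction (1 um = {scale:g} Pa)")
    ax.set_aspect("equal")
    ax.legend(loc="upper right", fontsize=8)
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    p = out / f"field.{fmt}"
    written.append(p)
    fig.savefig(p, dpi=150)
    plt.close(fig)
    made["field_plot"] = p

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2), sharex=True)
    order = np.argsort(profile.s1)
    s1 = profile.s1[order]
    for ax_i, vals, color, label in (
        (axes[0], profile.magnitude[order], "r", "|t| (Pa)"),
        (axes[1], profile.traction_vec[order, 0], "b", "t_x (Pa)"),
        (axes[2], profile.traction_vec[order, 1], "m", "t_y (Pa)"),
    ):
        ax_i.plot(s1, vals, color=color, lw=1.2)
        ax_i.set_xlabel("s1 (um)")
        ax_i.set_ylabel(label)
    fig.tight_layout()
    p = out / f"profiles.{fmt}"
    written.append(p)
    fig.savefig(p, dpi=150)
    plt.close(fig)
    made["profile_plot"] = p
    return made


def volume_report(manifest: dict, geometry: ChannelGeometry) -> pd.DataFrame:
    """Per-contour and per-stage nucleus volumes from area × local height.

    ``manifest`` maps stage name → list of contour CSV paths (or Contours).
    Each polygon is split at the constriction boundaries and every region's
    area is multiplied by that region's channel height.  Returns one row per
    contour plus ``<stage>/mean`` and ``<stage>/sd`` summary rows.
    """
    x0 = geometry.constriction_start
    x1 = x0 + geometry.constriction_length
    big = 1e6
    regions = [
        (shapely.geometry.box(-big, -big, x0, big), geometry.channel_height),
        (shapely.geometry.box(x0, -big, x1, big), geometry.constriction_height),
        (shapely.geometry.box(x1, -big, big, big), geometry.channel_height),
    ]

    rows = []
    for stage, entries in manifest.items():
        if entries is None:
            raise NuctractError(f"stage {stage!r} has no contours (untagged entry)")
        volumes = []
        for i, entry in enumerate(entries):
            contour = entry if isinstance(entry, Contour) else read_contour_csv(entry)
            poly = shapely.geometry.Polygon(contour.points)
            vol = sum(poly.intersection(box).area * h for box, h in regions)
            volumes.append(vol)
            name = str(entry) if not isinstance(entry, Contour) else f"contour_{i}"
            rows.append({"stage": stage, "contour": name, "volume_um3": vol})
        volumes = np.asarray(volumes)
        rows.append({"stage": stage, "contour": "mean",
                     "volume_um3": float(volumes.mean())})
        rows.append({"stage": stage, "contour": "sd",
                     "volume_um3": float(volumes.std(ddof=0))})
    return pd.DataFrame(rows)
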