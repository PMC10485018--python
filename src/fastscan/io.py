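"""Configuration files, run outputs, and round-trip readers.

Configs are flat YAML with one section per component (``simulator``,
``features``, ``scan``, ``stopping``, ``noise``, ``roi``) whose keys
mirror the dataclass field names.  Unknown keys are rejected by name;
missing keys fall back to the documented defaults.  Run outputs are
plain CSV/TIFF/JSON so a scan is fully reconstructable from disk.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .acquisition import ScanConfig, ScanTrajectory, StoppingRule
from .com import CoMMaps, ROI
from .erd import FeatureConfig
from .reconstruction import MeasurementSet
from .sample import NoiseModel, SimulatorConfig

__all__ = [
    "RunConfig",
    "RunManifest",
    "load_config",
    "write_config",
    "write_outputs",
    "read_scan_log",
]


@dataclass(frozen=True)
class RunConfig:
    simulator: SimulatorConfig = SimulatorConfig()
    features: FeatureConfig = FeatureConfig()
    scan: ScanConfig = ScanConfig()
    noise: NoiseModel = NoiseModel()
    roi: ROI | None = None  # None = full detector


_SECTIONS = {
    "simulator": SimulatorConfig,
    "features": FeatureConfig,
    "scan": ScanConfig,
    "stopping": StoppingRule,
    "noise": NoiseModel,
    "roi": ROI,
}

_TUPLE_FIELDS = {
    "thickness_levels",
    "bubble_radius_range",
    "flake_radius_range",
}


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    for key in data:
        if key not in valid:
            raise ValueError(f"unknown key {section}.{key!r} in config")
    kwargs = {
        k: tuple(v) if k in _TUPLE_FIELDS and v is not None else v
        for k, v in data.items()
    }
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config section {section!r}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Parse and validate a run configuration file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    for key in data:
        if key not in _SECTIONS:
            raise ValueError(f"unknown config section {key!r}")

    stopping = _build_section(StoppingRule, data.get("stopping", {}), "stopping")
    scan_data = dict(data.get("scan", {}))
    if "stopping" in scan_data:
        raise ValueError("unknown key scan.stopping in config (use a top-level 'stopping' section)")
    scan = _build_section(ScanConfig, scan_data, "scan")
    scan = dataclasses.replace(scan, stopping=stopping)

    roi = None
    if data.get("roi"):
        roi = _build_section(ROI, data["roi"], "roi")
    return RunConfig(
        simulator=_build_section(SimulatorConfig, data.get("simulator", {}), "simulator"),
        features=_build_section(FeatureConfig, data.get("features", {}), "features"),
        scan=scan,
        noise=_build_section(NoiseModel, data.get("noise", {}), "noise"),
        roi=roi,
    )


def write_config(cfg: RunConfig, path) -> None:
    data = {
        "simulator": dataclasses.asdict(cfg.simulator),
        "features": dataclasses.asdict(cfg.features),
        "scan": {
            k: v
            for k, v in dataclasses.asdict(cfg.scan).items()
            if k != "stopping"
        },
        "stopping": dataclasses.asdict(cfg.scan.stopping),
        "noise": dataclasses.asdict(cfg.noise),
    }
    if cfg.roi is not None:
        data["roi"] = dataclasses.asdict(cfg.roi)
    data["simulator"]["thickness_levels"] = list(cfg.simulator.thickness_levels)
    data["simulator"]["bubble_radius_range"] = list(cfg.simulator.bubble_radius_range)
    if cfg.simulator.flake_radius_range is not None:
        data["simulator"]["flake_radius_range"] = list(cfg.simulator.flake_radius_range)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass
class RunManifest:
    """Provenance record emitted next to every run's outputs."""

    config_snapshot: str = ""
    seeds: dict = field(default_factory=dict)
    version: str = ""
    outputs: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""
    complete: bool = False

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _scan_log_frame(traj: ScanTrajectory) -> pd.DataFrame:
    m = traj.measurements
    rows_, cols_ = traj.grid_shape
    n_pix = rows_ * cols_
    records = []
    offset = 0
    for rec in traj.iterations:
        for j, (r, c) in enumerate(rec.points):
            records.append(
                {
                    "iteration": rec.iteration,
                    "point_index_in_batch": j,
                    "row": r,
                    "col": c,
                    "measured_value": m.values[offset + j],
                    "cumulative_coverage": (offset + j + 1) / n_pix,
                }
            )
        offset += len(rec.points)
    return pd.DataFrame.from_records(records)


def _metrics_frame(traj: ScanTrajectory) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {
                "iteration": r.iteration,
                "n_measured": r.n_measured,
                "coverage_fraction": r.coverage,
                "nrmse": r.nrmse,
                "ssim": r.ssim,
                "total_erd": r.total_erd,
                "route_length": r.route_length,
            }
            for r in traj.iterations
        ]
    )


def read_scan_log(path, grid_shape: tuple[int, int]) -> MeasurementSet:
    """Rebuild the MeasurementSet (locations, values, order) from a scan log."""
    df = pd.read_csv(path, float_precision="round_trip")
    loc = df[["row", "col"]].to_numpy(dtype=np.intp)
    return MeasurementSet(loc, df["measured_value"].to_numpy(), grid_shape)


def write_outputs(
    traj: ScanTrajectory,
    maps: CoMMaps | None,
    manifest: RunManifest,
    outdir,
) -> RunManifest:
    """Emit scan log, metrics, masks, reconstructions, CoM maps, manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest.started = manifest.started or _now()
    manifest.complete = False

    def _emit(name: str, fname: str, writer) -> None:
        path = outdir / fname
        writer(path)
        manifest.outputs[name] = str(path)

    try:
        # %.17g keeps float64 round-trips exact
        _emit(
            "scan_log",
            "scan_log.csv",
            lambda p: _scan_log_frame(traj).to_csv(p, index=False, float_format="%.17g"),
        )
        _emit(
            "metrics",
            "metrics.csv",
            lambda p: _metrics_frame(traj).to_csv(p, index=False, float_format="%.17g"),
        )
        _emit(
            "mask",
            "measured_mask.tif",
            lambda p: tifffile.imwrite(
                str(p), traj.measurements.mask.astype(np.uint8) * 255
            ),
        )
        if traj.final_idw is not None:
            _emit(
                "reconstruction_idw",
                "reconstruction_idw.tif",
                lambda p: tifffile.imwrite(
                    str(p), traj.final_idw.values.astype(np.float32)
                ),
            )
        if traj.final_biharmonic is not None:
            _emit(
                "reconstruction_biharmonic",
                "reconstruction_biharmonic.tif",
                lambda p: tifffile.imwrite(
                    str(p), traj.final_biharmonic.values.astype(np.float32)
                ),
            )
        if maps is not None:
            _emit(
                "com_maps",
                "com_maps.tif",
                lambda p: tifffile.imwrite(
                    str(p),
                    np.stack([maps.comx, maps.comy]).astype(np.float32),
                ),
            )
            _emit(
                "com_csv",
                "com_maps.csv",
                lambda p: _com_frame(maps).to_csv(p, index=False),
            )
        manifest.finished = _now()
        manifest.complete = True
    finally:
        manifest.to_json(outdir / "manifest.json")
        manifest.outputs["manifest"] = str(outdir / "manifest.json")
        manifest.to_json(outdir / "manifest.json")
    return manifest


def _com_frame(maps: CoMMaps) -> pd.DataFrame:
    rows, cols = maps.comx.shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return pd.DataFrame(
        {
            "row": rr.ravel(),
            "col": cc.ravel(),
            "comx": maps.comx.ravel(),
            "comy": maps.comy.ravel(),
            "valid": maps.valid.ravel().astype(int),
        }
    )


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()
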