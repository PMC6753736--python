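"""Structured configuration files, run manifests and table output.

Configuration is YAML with explicit units in the key names (cm, mm, deg).
A minimal file only needs a plan and a noise level; machine constants and
phantom modules default to the baseline setup (SAD 100 cm, SDD 180 cm,
20x20 cm field, 6-ball/8-cm table module, 4-ball/6-cm head module, 3 mm
ball radius).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError
from .experiments import ExperimentConfig, SummaryTable
from .phantom import (
    DEFAULT_BALL_RADIUS,
    Mounting,
    PhantomModule,
    baseline_collimator_module,
    baseline_table_module,
    planar_layout,
    spiral_layout,
)
from .plan import MachineConstants, TestPlan

_PLAN_KEYS = {"n_gantry", "n_collimator", "pairs", "sigma_mm"}
_MACHINE_KEYS = {"sad_cm", "sdd_cm", "field_size_cm"}
_MODULE_KEYS = {
    "layout", "n_balls", "cube_edge_cm", "max_per_plane", "radius_cm",
    "beam_offset_cm", "cuboid_cm", "turns", "markers", "mounting",
    "pose_rotation", "pose_translation_cm",
}
_TOP_KEYS = {"plan", "machine", "phantom", "replicates", "seed", "include_sources"}


def _check_keys(section: dict, allowed: set, where: str, bad: list) -> None:
    for k in section:
        if k not in allowed:
            bad.append(f"{where}.{k}")


def _machine_from(cfg: dict, bad: list) -> MachineConstants:
    _check_keys(cfg, _MACHINE_KEYS, "machine", bad)
    fs = cfg.get("field_size_cm", (20.0, 20.0))
    if np.isscalar(fs):
        fs = (float(fs), float(fs))
    try:
        return MachineConstants(
            sad=float(cfg.get("sad_cm", 100.0)),
            sdd=float(cfg.get("sdd_cm", 180.0)),
            field_size=(float(fs[0]), float(fs[1])),
        )
    except (ConfigurationError, TypeError, ValueError) as exc:
        bad.append(f"machine: {exc}")
        return MachineConstants()


def _module_from(cfg: dict, mounting: Mounting, bad: list, where: str) -> PhantomModule:
    _check_keys(cfg, _MODULE_KEYS, where, bad)
    try:
        if "markers" in cfg:
            d = dict(cfg)
            d.setdefault("mounting", mounting.value)
            return PhantomModule.from_dict(d)
        layout = cfg.get("layout", "planar")
        radius = float(cfg.get("radius_cm", DEFAULT_BALL_RADIUS))
        if layout == "planar":
            if mounting is Mounting.TABLE:
                mod = planar_layout(
                    int(cfg.get("n_balls", 6)),
                    max_per_plane=int(cfg.get("max_per_plane", 4)),
                    bounding_cube_edge=float(cfg.get("cube_edge_cm", 8.0)),
                    mounting=mounting,
                    ball_radius=radius,
                )
            else:
                mod = planar_layout(
                    int(cfg.get("n_balls", 4)),
                    max_per_plane=int(cfg.get("max_per_plane", 3)),
                    bounding_cube_edge=float(cfg.get("cube_edge_cm", 6.0)),
                    mounting=mounting,
                    ball_radius=radius,
                )
                mod = mod.with_pose(
                    translation=np.array([0.0, 0.0, float(cfg.get("beam_offset_cm", 35.0))])
                )
            return mod
        if layout == "spiral":
            if mounting is not Mounting.TABLE:
                raise ConfigurationError("spiral layout is table-mounted only")
            cuboid = cfg.get("cuboid_cm", (26.0, 18.0, 26.0))
            return spiral_layout(
                int(cfg.get("n_balls", 18)),
                cuboid=tuple(float(c) for c in cuboid),
                turns=float(cfg.get("turns", 2.0)),
                ball_radius=radius,
            )
        raise ConfigurationError(f"unknown layout {layout!r}")
    except (ConfigurationError, TypeError, ValueError, KeyError) as exc:
        bad.append(f"{where}: {exc}")
        return baseline_table_module() if mounting is Mounting.TABLE else baseline_collimator_module()


def config_from_dict(raw: dict) -> ExperimentConfig:
    """Build a fully resolved experiment configuration, validating units/ranges."""
    bad: list[str] = []
    if not isinstance(raw, dict) or "plan" not in raw:
        raise ConfigurationError("config must be a mapping with a 'plan' section")
    _check_keys(raw, _TOP_KEYS, "", bad)
    machine = _machine_from(raw.get("machine", {}) or {}, bad)
    pcfg = raw["plan"] or {}
    _check_keys(pcfg, _PLAN_KEYS, "plan", bad)
    sigma = float(pcfg.get("sigma_mm", 0.0))
    try:
        if "pairs" in pcfg:
            plan = TestPlan(
                pairs=tuple((float(t), float(p)) for t, p in pcfg["pairs"]),
                sigma_mm=sigma, machine=machine,
            )
        else:
            plan = TestPlan.grid(
                int(pcfg.get("n_gantry", 5)), int(pcfg.get("n_collimator", 5)),
                sigma_mm=sigma, machine=machine,
            )
    except (ConfigurationError, TypeError, ValueError) as exc:
        bad.append(f"plan: {exc}")
        plan = TestPlan.grid(5, 5, 0.0)
    ph = raw.get("phantom", {}) or {}
    _check_keys(ph, {"table", "collimator"}, "phantom", bad)
    table = _module_from(ph.get("table", {}) or {}, Mounting.TABLE, bad, "phantom.table")
    coll = _module_from(ph.get("collimator", {}) or {}, Mounting.COLLIMATOR, bad, "phantom.collimator")
    try:
        cfg = ExperimentConfig(
            plan=plan,
            table=table,
            collimator=coll,
            n_replicates=int(raw.get("replicates", 1000)),
            seed=int(raw.get("seed", 0)),
            include_sources=bool(raw.get("include_sources", True)),
        )
    except (ConfigurationError, TypeError, ValueError) as exc:
        bad.append(str(exc))
        cfg = None
    if bad:
        raise ConfigurationError("invalid configuration keys/values: " + "; ".join(bad))
    return cfg


def config_to_dict(cfg: ExperimentConfig) -> dict:
    m = cfg.plan.machine
    return {
        "plan": {
            "pairs": [[t, p] for t, p in cfg.plan.pairs],
            "sigma_mm": cfg.plan.sigma_mm,
        },
        "machine": {
            "sad_cm": m.sad, "sdd_cm": m.sdd, "field_size_cm": list(m.field_size),
        },
        "phantom": {
            "table": cfg.table.to_dict(),
            "collimator": cfg.collimator.to_dict(),
        },
        "replicates": cfg.n_replicates,
        "seed": cfg.seed,
        "include_sources": cfg.include_sources,
    }


def load_config(path: str | Path) -> ExperimentConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# manifests and table output
# ---------------------------------------------------------------------------


def config_hash(cfg: ExperimentConfig) -> str:
    canonical = json.dumps(config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance of one CLI run: a run is reproducible from hash + seed."""

    config_hash: str
    seed: int
    code_version: str
    timings_s: dict = field(default_factory=dict)
    n_failures: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    @classmethod
    def start(cls, cfg: ExperimentConfig) -> "RunManifest":
        from . import __version__

        return cls(config_hash=config_hash(cfg), seed=cfg.seed, code_version=__version__)

    def time_stage(self, name: str, t0: float) -> None:
        self.timings_s[name] = round(time.perf_counter() - t0, 3)


def write_summary(summary: SummaryTable, path: str | Path, manifest: RunManifest | None = None) -> None:
    """Stable-column CSV of a summary table (units in the header row)."""
    if summary.rows.empty:
        raise ConfigurationError("refusing to write an empty summary table")
    df = summary.rows.copy()
    df.insert(0, "sigma_mm", summary.sigma_mm)
    df["n_replicates"] = summary.n_replicates
    df["n_failures"] = summary.n_failures
    if manifest is not None:
        df["config_hash"] = manifest.config_hash
    cols = ["sigma_mm", "metric", "unit", "sd", "ci95_low", "ci95_high",
            "n_samples", "n_replicates", "n_failures"]
    if manifest is not None:
        cols.append("config_hash")
    df[cols].to_csv(path, index=False)
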