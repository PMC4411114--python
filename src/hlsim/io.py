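"""Run configuration files and trajectory serialization.

Config files are YAML with three optional sections::

    scenario: fig4_default      # a registered preset ...
    overrides:                  # ... and/or parameter overrides
      Initial Regulatory Cells: 2000
    settings:
      final_time: 2000
      dt: 0.0078125
      saveper: 1

A config may name a scenario or supply parameters directly, not both
ways of fixing the full parameter set at once.  Trajectories are
written as CSV (one row per saved day, full double precision) with a
JSON sidecar holding the exact parameter and settings snapshot, which
is sufficient to replay the run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .integrator import Trajectory
from .model import STOCK_NAMES
from .params import ModelParameters, ParameterError, SimulationSettings
from .scenarios import get_scenario

__all__ = ["RunConfig", "load_config", "write_trajectory", "read_trajectory",
           "meta_path"]

_SETTINGS_KEYS = {"initial_time", "final_time", "dt", "saveper", "label",
                  "horizon"}


@dataclass(frozen=True)
class RunConfig:
    """Validated contents of a run configuration."""

    scenario: str | None = None
    overrides: dict = field(default_factory=dict)
    parameters: dict | None = None          # full inline parameter set
    settings: dict = field(default_factory=dict)
    output: str | None = None
    log_level: str = "INFO"
    plot: bool = False

    def resolve(self) -> tuple[ModelParameters, SimulationSettings]:
        """Materialize parameters and settings."""
        if self.scenario:
            params, settings = get_scenario(self.scenario, self.overrides)
        else:
            base = (ModelParameters.from_dict(self.parameters)
                    if self.parameters is not None else ModelParameters())
            params = base.with_overrides(self.overrides)
            settings = SimulationSettings()
        kw = {k: v for k, v in self.settings.items()}
        if "horizon" in kw:
            kw["final_time"] = kw.pop("horizon")
        if kw:
            base_kw = dict(initial_time=settings.initial_time,
                           final_time=settings.final_time, dt=settings.dt,
                           saveper=settings.saveper, label=settings.label)
            base_kw.update(kw)
            settings = SimulationSettings(**base_kw)
        return params, settings


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    raw = yaml.safe_load(p.read_text()) or {}
    if not isinstance(raw, dict):
        raise ParameterError(f"config {p} must be a mapping, got {type(raw).__name__}")
    known = {"scenario", "overrides", "parameters", "settings", "output",
             "log_level", "plot"}
    unknown = set(raw) - known
    if unknown:
        raise ParameterError(
            f"unknown config keys {sorted(unknown)}; valid keys: {sorted(known)}")
    cfg = RunConfig(
        scenario=raw.get("scenario"),
        overrides=dict(raw.get("overrides") or {}),
        parameters=raw.get("parameters"),
        settings=dict(raw.get("settings") or {}),
        output=raw.get("output"),
        log_level=str(raw.get("log_level", "INFO")),
        plot=bool(raw.get("plot", False)),
    )
    if cfg.scenario and cfg.parameters is not None:
        raise ParameterError(
            "config may name a scenario or supply a full inline parameter "
            "set, not both")
    bad = set(cfg.settings) - _SETTINGS_KEYS
    if bad:
        raise ParameterError(
            f"unknown settings keys {sorted(bad)}; valid: {sorted(_SETTINGS_KEYS)}")
    cfg.resolve()  # fail fast on unknown parameter keys / scenario names
    return cfg


def meta_path(path) -> Path:
    return Path(str(path) + ".meta.json")


def write_trajectory(traj: Trajectory, path) -> Path:
    """Write a trajectory as CSV plus a JSON metadata sidecar.

    The CSV has header ``time,csc,ctac,mtc,helper,killer,regulator`` and
    one row per saved time at full double precision (round-trip exact).
    """
    if len(traj) == 0:
        raise ValueError("refusing to write an empty trajectory")
    p = Path(path)
    df = traj.to_frame()
    df.to_csv(p, index=False, float_format="%.17g")
    meta = {
        "parameters": traj.params_used.to_dict() if traj.params_used else None,
        "settings": {
            "initial_time": traj.settings.initial_time,
            "final_time": traj.settings.final_time,
            "dt": traj.settings.dt,
            "saveper": traj.settings.saveper,
            "label": traj.settings.label,
        },
    }
    meta_path(p).write_text(json.dumps(meta, indent=1))
    return p


def read_trajectory(path) -> Trajectory:
    """Read a trajectory CSV (and its sidecar, if present) back."""
    p = Path(path)
    df = pd.read_csv(p, float_precision="round_trip")
    expected = ["time", *STOCK_NAMES]
    if list(df.columns) != expected:
        raise ValueError(f"{p} does not look like a trajectory file "
                         f"(columns {list(df.columns)}, expected {expected})")
    params = None
    settings = None
    mp = meta_path(p)
    if mp.exists():
        meta = json.loads(mp.read_text())
        if meta.get("parameters"):
            params = ModelParameters.from_dict(meta["parameters"])
        s = meta.get("settings") or {}
        if s:
            settings = SimulationSettings(**s)
    if settings is None:
        times = df["time"].to_numpy()
        saveper = float(times[1] - times[0]) if len(times) > 1 else 1.0
        settings = SimulationSettings(initial_time=float(times[0]),
                                      final_time=float(times[-1]),
                                      saveper=saveper)
    return Trajectory(times=df["time"].to_numpy(dtype=float),
                      states=df[list(STOCK_NAMES)].to_numpy(dtype=float),
                      params_used=params, settings=settings)
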