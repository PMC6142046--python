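"""Shared I/O: histograms, trajectories, configurations and run manifests.

Histograms travel as JSON (edges + frequencies, lossless float repr),
trajectories and calibration histories as CSV, configurations as YAML.
All round trips are exact.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationHistory, Histogram, MetricPair, Parametrization
from .chemistry import LeapPolicy, ReactionNetwork
from .protrusions import ElasticityParams, StrainParams, ThresholdSet
from .simulator import CellTrajectory, RunConfig
from .surface import ChemoattractantField, SurfaceGrid
from .translocation import MotionParams

__all__ = [
    "ConfigError",
    "configure_logging",
    "write_histogram",
    "read_histogram",
    "write_trajectory",
    "read_trajectory",
    "write_chem_trajectory",
    "config_to_dict",
    "config_from_dict",
    "write_config",
    "read_config",
    "write_manifest",
    "write_history",
    "read_history",
]


class ConfigError(ValueError):
    """Malformed or incomplete configuration input."""


def configure_logging(level: int | str = "INFO", **module_levels: int | str) -> None:
    """Structured logging to stderr; per-module levels via keyword arguments.

    ``configure_logging("INFO", simulator="DEBUG")`` raises the simulator
    module to debug verbosity while the rest of the package stays at INFO.
    """
    import logging
    import sys

    root = logging.getLogger("mesomig")
    root.setLevel(level)
    if not root.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        root.addHandler(handler)
    for module, lvl in module_levels.items():
        logging.getLogger(f"mesomig.{module}").setLevel(lvl)


# ---------------------------------------------------------------------------
# histograms


def write_histogram(hist: Histogram, path: str | Path) -> None:
    payload = {
        "feature": hist.feature,
        "edges": [float(e) for e in hist.edges],
        "frequencies": [float(f) for f in hist.frequencies],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_histogram(path: str | Path) -> Histogram:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"malformed histogram JSON at line {exc.lineno}: {exc.msg}") from exc
    for key in ("feature", "edges", "frequencies"):
        if key not in payload:
            raise ConfigError(f"histogram file missing required field '{key}'")
    return Histogram(
        np.asarray(payload["edges"], dtype=float),
        np.asarray(payload["frequencies"], dtype=float),
        payload["feature"],
    )


# ---------------------------------------------------------------------------
# trajectories


def write_trajectory(traj: CellTrajectory, path: str | Path) -> None:
    traj.to_dataframe().to_csv(path, index=False)


def read_trajectory(path: str | Path) -> CellTrajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"t_min", "x_mm", "y_mm", "z_mm", "vx", "vy", "vz", "n_protrusions", "llp_um"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"trajectory file missing required field '{sorted(missing)[0]}'")
    return CellTrajectory(
        t_min=df["t_min"].to_numpy(float),
        position_mm=df[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
        velocity_um_min=df[["vx", "vy", "vz"]].to_numpy(float),
        n_protrusions=df["n_protrusions"].to_numpy(np.int64),
        llp_um=df["llp_um"].to_numpy(float),
    )


def write_chem_trajectory(t_s: np.ndarray, counts: np.ndarray, path: str | Path) -> None:
    """Chemistry trajectory CSV: t_s, RTK, RTKF, PI3K, PI3KA (counts shape (4, n))."""
    pd.DataFrame(
        {
            "t_s": t_s,
            "RTK": counts[0],
            "RTKF": counts[1],
            "PI3K": counts[2],
            "PI3KA": counts[3],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration


def config_to_dict(config: RunConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)
    d["field"]["gradient_uM_per_mm"] = [float(v) for v in config.field.gradient_uM_per_mm]
    d["field"]["origin_mm"] = [float(v) for v in config.field.origin_mm]
    d["initial_counts"] = [int(v) for v in config.initial_counts]
    return d


_SECTIONS = {
    "field": ChemoattractantField,
    "network": ReactionNetwork,
    "leap": LeapPolicy,
    "thresholds": ThresholdSet,
    "strain": StrainParams,
    "elasticity": ElasticityParams,
    "motion": MotionParams,
    "grid": SurfaceGrid,
}


def config_from_dict(d: dict[str, Any]) -> RunConfig:
    if not isinstance(d, dict):
        raise ConfigError("configuration root must be a mapping")
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        if name not in d:
            raise ConfigError(f"configuration missing required field '{name}'")
        section = d[name]
        field_names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(section) - field_names
        if unknown:
            raise ConfigError(f"unknown key '{sorted(unknown)[0]}' in section '{name}'")
        try:
            kwargs[name] = cls(**section)
        except TypeError as exc:
            raise ConfigError(f"invalid section '{name}': {exc}") from exc
    for name in ("initial_counts", "kernel_sigma_sites", "horizon_min", "dt_min"):
        if name not in d:
            raise ConfigError(f"configuration missing required field '{name}'")
    kwargs["initial_counts"] = tuple(int(v) for v in d["initial_counts"])
    kwargs["kernel_sigma_sites"] = float(d["kernel_sigma_sites"])
    kwargs["horizon_min"] = float(d["horizon_min"])
    kwargs["dt_min"] = float(d["dt_min"])
    return RunConfig(**kwargs)


def write_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def read_config(path: str | Path) -> RunConfig:
    try:
        d = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML: {exc}") from exc
    return config_from_dict(d)


def write_manifest(
    path: str | Path, config: RunConfig, seeds: list[int], extra: dict | None = None
) -> None:
    """Run manifest: full resolved configuration plus the seeds used."""
    payload = {"config": config_to_dict(config), "seeds": [int(s) for s in seeds]}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1, default=float))


# ---------------------------------------------------------------------------
# calibration history


def write_history(history: CalibrationHistory, path: str | Path) -> None:
    history.to_dataframe().to_csv(path, index=False)


def read_history(path: str | Path) -> CalibrationHistory:
    df = pd.read_csv(path, float_precision="round_trip")
    hist = CalibrationHistory()
    param_fields = [f.name for f in dataclasses.fields(Parametrization)]
    for _, row in df.iterrows():
        kwargs = {name: row[name] for name in param_fields}
        for name in ("s_birth", "s_exp", "s_ret"):
            kwargs[name] = int(kwargs[name])
        hist.append(
            Parametrization(**kwargs), MetricPair(float(row["bc_llp"]), float(row["bc_np"]))
        )
    return hist
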