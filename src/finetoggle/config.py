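"""Run configuration, output writing and reproducibility metadata.

A run is fully described by a flat key=value (or JSON) configuration:
model keys (the nine rates, atp, atp_mode, oligomer_order), solver keys
(dt, t_max, window, tol, method), and experiment keys (grid, factors,
ATP list, seed, burn-in, hysteresis).  Unknown keys are rejected rather
than ignored, and every output directory receives a provenance record
(the fully resolved configuration plus seed and package version) from
which the run can be re-executed byte-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from .analysis import GridSpec
from .deterministic import SolverSettings
from .model import ATP_MODES, RATE_NAMES, RateSet

__all__ = ["RunConfig", "ConfigError", "parse_config", "write_outputs", "write_provenance"]

log = logging.getLogger("finetoggle")

#: CSV convention used everywhere: comma separator, header row, '.'
#: decimal, no index column, floats at 10 significant digits.
CSV_KWARGS = dict(index=False, float_format="%.10g")


class ConfigError(ValueError):
    """Invalid, unknown or conflicting configuration input."""


_FLOAT_KEYS = {
    "lambda2", "lambda3", "ca1", "cd1", "ca2", "cd2",
    "gamma2", "gamma3", "gamma4", "atp",
    "dt", "t_max", "window", "tol",
    "ip_min", "ip_max", "rna1", "rna2",
    "burn_in", "hysteresis", "sample_dt", "cluster_tol",
}
_INT_KEYS = {"oligomer_order", "grid_n", "seed", "n_seeds"}
_STR_KEYS = {"atp_mode", "method"}
_LIST_KEYS = {"factors", "atp_values"}
_ALL_KEYS = _FLOAT_KEYS | _INT_KEYS | _STR_KEYS | _LIST_KEYS


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration for any subcommand."""

    rates: RateSet = field(default_factory=RateSet)
    oligomer_order: int = 2
    solver: SolverSettings = field(default_factory=SolverSettings)
    grid: GridSpec = field(default_factory=GridSpec)
    cluster_tol: float = 1.0
    seed: int = 1
    n_seeds: int = 1
    t_max: float = 1e6
    burn_in: float = 1e5
    hysteresis: float = 10.0
    sample_dt: float = 100.0
    factors: tuple = (1e-2, 1e-1, 1.0, 1e1, 1e2)
    atp_values: tuple = ()

    def as_dict(self) -> Dict[str, object]:
        return {
            **self.rates.as_dict(),
            "oligomer_order": self.oligomer_order,
            "dt": self.solver.dt,
            "t_max": self.t_max,
            "window": self.solver.window,
            "tol": self.solver.tol,
            "method": self.solver.method,
            "grid_n": self.grid.n,
            "ip_min": self.grid.ip_min,
            "ip_max": self.grid.ip_max,
            "rna1": self.grid.rna1,
            "rna2": self.grid.rna2,
            "cluster_tol": self.cluster_tol,
            "seed": self.seed,
            "n_seeds": self.n_seeds,
            "burn_in": self.burn_in,
            "hysteresis": self.hysteresis,
            "sample_dt": self.sample_dt,
            "factors": list(self.factors),
            "atp_values": list(self.atp_values),
        }


def _coerce(key: str, value: object) -> object:
    try:
        if key in _FLOAT_KEYS:
            return float(value)
        if key in _INT_KEYS:
            if isinstance(value, str):
                value = float(value)
            if value != int(value):
                raise ValueError
            return int(value)
        if key in _STR_KEYS:
            return str(value)
        if key in _LIST_KEYS:
            if isinstance(value, str):
                parts = [p for p in value.replace(";", ",").split(",") if p.strip()]
                return tuple(float(p) for p in parts)
            return tuple(float(v) for v in value)
    except (TypeError, ValueError):
        raise ConfigError(f"cannot parse value {value!r} for key {key!r}") from None
    raise ConfigError(f"unknown configuration key {key!r}")


def _read_config_file(path: Union[str, Path]) -> Dict[str, object]:
    text = Path(path).read_text()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        raw = json.loads(text)
        if not isinstance(raw, dict):
            raise ConfigError("JSON config must be an object of key: value pairs")
        return dict(raw)
    entries: Dict[str, object] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected key=value, got {line!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key in entries:
            raise ConfigError(f"duplicate key {key!r} in config file")
        entries[key] = value
    return entries


def parse_config(
    path: Optional[Union[str, Path]] = None,
    overrides: Sequence[str] = (),
) -> RunConfig:
    """Build a RunConfig from an optional file plus ``key=value`` overrides.

    Absent keys take the documented defaults (the default rate table,
    atp=1, dimer regulation, the standard solver and grid).  Overrides
    win over file values.  Unknown keys and unparsable values raise
    :class:`ConfigError`.
    """
    entries: Dict[str, object] = {}
    if path is not None:
        entries.update(_read_config_file(path))
    for item in overrides:
        if "=" not in item:
            raise ConfigError(f"override {item!r} is not of the form key=value")
        key, value = (part.strip() for part in item.split("=", 1))
        entries[key] = value

    for key in entries:
        if key not in _ALL_KEYS:
            raise ConfigError(f"unknown configuration key {key!r}")
    values = {key: _coerce(key, val) for key, val in entries.items()}

    if "atp_mode" in values and values["atp_mode"] not in ATP_MODES:
        raise ConfigError(f"unknown atp_mode {values['atp_mode']!r}")

    try:
        rates = RateSet(**{k: values[k] for k in RATE_NAMES + ("atp", "atp_mode") if k in values})
        solver_kwargs = {k: values[k] for k in ("dt", "window", "tol", "method") if k in values}
        if "t_max" in values:
            solver_kwargs["t_max"] = values["t_max"]
        solver = SolverSettings(**solver_kwargs)
        grid_kwargs = {k: values[k] for k in ("ip_min", "ip_max", "rna1", "rna2") if k in values}
        if "grid_n" in values:
            grid_kwargs["n"] = values["grid_n"]
        grid = GridSpec(**grid_kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from None

    config = RunConfig(
        rates=rates,
        oligomer_order=values.get("oligomer_order", 2),
        solver=solver,
        grid=grid,
        cluster_tol=values.get("cluster_tol", 1.0),
        seed=values.get("seed", 1),
        n_seeds=values.get("n_seeds", 1),
        t_max=values.get("t_max", 1e6),
        burn_in=values.get("burn_in", 1e5),
        hysteresis=values.get("hysteresis", 10.0),
        sample_dt=values.get("sample_dt", 100.0),
        factors=values.get("factors", (1e-2, 1e-1, 1.0, 1e1, 1e2)),
        atp_values=values.get("atp_values", ()),
    )
    if config.oligomer_order not in (1, 2, 3, 4):
        raise ConfigError("oligomer_order must be in 1..4")
    log.info("resolved config: %s", json.dumps(config.as_dict()))
    return config


def write_outputs(frames: Dict[str, pd.DataFrame], out_dir: Union[str, Path]) -> List[Path]:
    """Write named DataFrames as CSV files under ``out_dir``.

    Deterministic row order is the caller's responsibility (time order,
    grid row-major, or scan order); this function fixes the dialect.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in frames.items():
        path = out_dir / (name if name.endswith(".csv") else f"{name}.csv")
        frame.to_csv(path, **CSV_KWARGS)
        written.append(path)
    return written


def write_provenance(config: RunConfig, out_dir: Union[str, Path], extra: Optional[Dict] = None) -> Path:
    """Record the resolved config (plus seed and version) next to outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"version": __version__, "config": config.as_dict()}
    if extra:
        payload.update(extra)
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path
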