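"""CSV time-series I/O and run configuration.

The on-disk dialect is a two-column CSV with header ``time,value`` and an
optional leading comment line declaring units, e.g.::

    # units: time=h length=mm
    time,value
    0,5.0
    1,5.8

All series are converted to the internal unit system (seconds, mm) on
load.  Errors from malformed files carry the offending line number.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import yaml

from .timeseries import TimeSeries

__all__ = ["read_timeseries", "write_timeseries", "RunConfig", "load_config"]

_TIME_FACTORS = {"s": 1.0, "min": 60.0, "h": 3600.0}
_LENGTH_FACTORS = {"mm": 1.0, "cm": 10.0}


def _parse_units_comment(line: str, lineno: int) -> tuple[float, float]:
    body = line.lstrip("#").strip()
    if body.lower().startswith("units:"):
        body = body[len("units:"):]
    t_factor, x_factor = 1.0, 1.0
    for token in body.replace(",", " ").split():
        if "=" not in token:
            raise ValueError(f"line {lineno}: malformed units token {token!r}")
        key, _, unit = token.partition("=")
        key, unit = key.strip().lower(), unit.strip().lower()
        if key == "time":
            if unit not in _TIME_FACTORS:
                raise ValueError(f"line {lineno}: unknown time unit {unit!r} (use s, min or h)")
            t_factor = _TIME_FACTORS[unit]
        elif key == "length":
            if unit not in _LENGTH_FACTORS:
                raise ValueError(f"line {lineno}: unknown length unit {unit!r} (use mm or cm)")
            x_factor = _LENGTH_FACTORS[unit]
        else:
            raise ValueError(f"line {lineno}: unknown units key {key!r}")
    return t_factor, x_factor


def read_timeseries(path, kind: str) -> TimeSeries:
    """Read a validated, unit-converted series from CSV.

    ``kind`` must be ``"radius"`` or ``"release"``.  Non-monotone times,
    out-of-range values and malformed rows raise ``ValueError`` naming the
    offending line.
    """
    path = Path(path)
    t_factor, x_factor = 1.0, 1.0
    times, values = [], []
    with path.open(newline="") as fh:
        header_seen = False
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not cell.strip() for cell in row):
                continue
            if row[0].lstrip().startswith("#"):
                t_factor, x_factor = _parse_units_comment(",".join(row), lineno)
                continue
            if not header_seen:
                got = [cell.strip().lower() for cell in row]
                if got != ["time", "value"]:
                    raise ValueError(f"{path}: line {lineno}: expected header 'time,value', got {row!r}")
                header_seen = True
                continue
            if len(row) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns, got {len(row)}")
            try:
                t, v = float(row[0]), float(row[1])
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-numeric entry in {row!r}") from None
            times.append(t * t_factor)
            values.append(v * x_factor if kind == "radius" else v)
            if len(times) >= 2 and times[-1] <= times[-2]:
                raise ValueError(f"{path}: line {lineno}: times must be strictly increasing")
            if kind == "release" and not 0.0 <= v <= 1.0:
                raise ValueError(f"{path}: line {lineno}: release value {v} outside [0, 1]")
            if kind == "radius" and v <= 0:
                raise ValueError(f"{path}: line {lineno}: radius value {v} must be > 0")
    if not header_seen:
        raise ValueError(f"{path}: missing 'time,value' header")
    return TimeSeries(times=times, values=values, kind=kind)


def write_timeseries(ts: TimeSeries, path) -> None:
    """Write a series in the internal units (s, mm) with a units comment."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write("# units: time=s length=mm\n")
        writer = csv.writer(fh)
        writer.writerow(["time", "value"])
        for t, v in zip(ts.times, ts.values):
            writer.writerow([repr(float(t)), repr(float(v))])


@dataclass
class RunConfig:
    """Validated run configuration (YAML-backed).

    Unknown keys are rejected so that typos fail loudly rather than
    silently falling back to defaults.
    """

    time_unit: str = "s"
    length_unit: str = "mm"
    max_terms: int = 200
    tail_tol: float = 1e-12
    radius_sd: float = 0.0
    release_sd: float = 0.0
    seed: int = 0
    joint_growth_fit: bool = False
    d_lower: float = 1e-12
    d_upper: float = 1.0
    out_dir: str = "."
    log_level: str = "INFO"


_SCHEMA = {
    "units": {"time", "length"},
    "series": {"max_terms", "tail_tol"},
    "noise": {"radius_sd", "release_sd", "seed"},
    "fit": {"joint_growth_fit", "d_lower", "d_upper"},
    "output": {"dir"},
    "log_level": None,
}


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    cfg = RunConfig()
    for key, value in raw.items():
        if key not in _SCHEMA:
            raise ValueError(f"{path}: unknown config key {key!r}")
        if key == "log_level":
            cfg.log_level = str(value)
            continue
        if not isinstance(value, dict):
            raise ValueError(f"{path}: section {key!r} must be a mapping")
        for sub, subval in value.items():
            if sub not in _SCHEMA[key]:
                raise ValueError(f"{path}: unknown config key {key}.{sub}")
            if key == "units":
                unit = str(subval).lower()
                table = _TIME_FACTORS if sub == "time" else _LENGTH_FACTORS
                if unit not in table:
                    raise ValueError(f"{path}: unknown {sub} unit {subval!r}")
                setattr(cfg, f"{sub}_unit", unit)
            elif key == "output":
                cfg.out_dir = str(subval)
            else:
                attr = {"max_terms": "max_terms", "tail_tol": "tail_tol",
                        "radius_sd": "radius_sd", "release_sd": "release_sd",
                        "seed": "seed", "joint_growth_fit": "joint_growth_fit",
                        "d_lower": "d_lower", "d_upper": "d_upper"}[sub]
                setattr(cfg, attr, type(getattr(cfg, attr))(subval))
    return cfg
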