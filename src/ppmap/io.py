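"""Serialization and run configuration.

CSV floats are written with 17 significant digits so that every file
round-trips bit-exactly through the package's own readers.  Run
configuration is one flat YAML document per run; command-line flags
override file values, and the fully resolved configuration is echoed next
to the results so a run can be reproduced from it alone.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Any, Iterable

import yaml

from .model import ModelParams, Orbit, State
from .orbits import ScanRow

__all__ = [
    "write_orbit_csv",
    "read_orbit_csv",
    "write_scan_csv",
    "read_scan_csv",
    "write_json",
    "read_json",
    "load_config",
    "resolve_config",
    "write_resolved_config",
]

_FMT = "%.17g"


def _f(x: float | None) -> str:
    return "" if x is None else _FMT % x


def write_orbit_csv(path: str | Path, orbit: Orbit) -> None:
    """Columns: n (iteration index within the run), x, y."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["n", "x", "y"])
        for i, s in enumerate(orbit.states):
            w.writerow([orbit.transient_discarded + i, _f(s.x), _f(s.y)])


def read_orbit_csv(path: str | Path) -> list[tuple[int, float, float]]:
    with open(path, newline="") as fh:
        r = csv.reader(fh)
        header = next(r)
        if header != ["n", "x", "y"]:
            raise ValueError(f"unexpected orbit CSV header: {header}")
        return [(int(n), float(x), float(y)) for n, x, y in r]


def write_scan_csv(path: str | Path, rows: Iterable[ScanRow]) -> None:
    """Columns: alpha, verdict, r_min, r_max, r_mean (empty when absent)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["alpha", "verdict", "r_min", "r_max", "r_mean"])
        for row in rows:
            w.writerow([_f(row.alpha), row.verdict, _f(row.r_min),
                        _f(row.r_max), _f(row.r_mean)])


def read_scan_csv(path: str | Path) -> list[ScanRow]:
    def opt(s: str) -> float | None:
        return None if s == "" else float(s)

    with open(path, newline="") as fh:
        r = csv.reader(fh)
        header = next(r)
        if header != ["alpha", "verdict", "r_min", "r_max", "r_mean"]:
            raise ValueError(f"unexpected scan CSV header: {header}")
        return [
            ScanRow(float(a), v, opt(r1), opt(r2), opt(r3))
            for a, v, r1, r2, r3 in r
        ]


def write_json(path: str | Path, obj: Any) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> Any:
    with open(path) as fh:
        return json.load(fh)


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Load a flat YAML config file; absent path means empty config."""
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a flat YAML mapping")
    return cfg


def resolve_config(
    defaults: dict[str, Any],
    file_cfg: dict[str, Any],
    cli_overrides: dict[str, Any],
) -> dict[str, Any]:
    """defaults < config file < explicit CLI flags (None = not given)."""
    out = dict(defaults)
    out.update({k: v for k, v in file_cfg.items() if v is not None})
    out.update({k: v for k, v in cli_overrides.items() if v is not None})
    return out


def write_resolved_config(out_dir: str | Path, cfg: dict[str, Any]) -> Path:
    path = Path(out_dir) / "resolved_config.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return path
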