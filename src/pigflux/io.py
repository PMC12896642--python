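"""Configuration files, result writers, and run manifests.

Configurations are flat YAML (or JSON, which YAML subsumes) key-value
files mirroring :class:`~pigflux.config.SimulationConfig` field names.
Unknown keys are rejected; missing keys take the documented defaults.
Floats are serialised via ``repr`` round-trip so that re-running from a
manifest reproduces outputs byte-identically.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .config import SimulationConfig
from .population import PopulationSummary, SensitivityTable

__all__ = [
    "load_config",
    "save_config",
    "write_population_summary",
    "write_sensitivity_table",
    "write_manifest",
]


def load_config(path: str | Path) -> SimulationConfig:
    """Read a YAML/JSON config file; empty file means all defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return SimulationConfig.from_dict(data)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    """Write the fully resolved configuration (round-trips exactly)."""
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True)
    )


def write_population_summary(
    summary: PopulationSummary, out_dir: str | Path,
    write_ranges: bool = True,
) -> list[Path]:
    """Write summary JSON (and per-pig range CSV); returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    summary_path = out_dir / "population_summary.json"
    summary_path.write_text(json.dumps(summary.to_dict(), indent=2) + "\n")
    paths.append(summary_path)
    if write_ranges:
        ranges_path = out_dir / "pig_ranges.csv"
        summary.ranges_frame().to_csv(ranges_path, index=False)
        paths.append(ranges_path)
    return paths


def write_sensitivity_table(
    table: SensitivityTable, out_dir: str | Path
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "sensitivity.csv"
    table.to_frame().rename(columns={
        "mean_range_kg": "mean_range_kg",
    }).to_csv(path, index=False)
    return path


def write_manifest(
    config: SimulationConfig, out_dir: str | Path,
    outputs: list[Path], command: str,
) -> Path:
    """Record everything needed to re-execute a run bit-identically."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "tool": "pigflux",
        "version": __version__,
        "command": command,
        "timestamp_utc": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "root_seed": config.seed,
        "config": config.to_dict(),
        "outputs": [str(Path(p).name) for p in outputs],
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
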