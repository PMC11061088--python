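"""Run configuration and snapshot serialization.

Configuration is YAML with a closed schema: unknown keys are rejected
with the offending key path, missing keys take defaults, and the fully
resolved configuration is echoed into every result file so a run can be
reproduced from its output alone.  Field snapshots are stored as a
compressed array archive with an embedded JSON manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, fields as dc_fields
from pathlib import Path

import numpy as np
import yaml

from fieldground.control import GroundConfig

__all__ = ["RunConfig", "load_config", "export_snapshots", "import_snapshots"]

SNAPSHOT_FORMAT_VERSION = 1


@dataclass
class RunConfig:
    """Validated run parameters (see docs for units and effects)."""

    n_spatial: int = 64  # samples per spatial dimension
    n_angle: int = 16  # samples on circular feature axes (hue, direction)
    n_size: int = 13  # samples on the size axis
    seed: int = 0
    noise: bool = False  # enable stochastic field dynamics
    noise_q: float = 0.1  # noise strength when enabled
    tau: float = 10.0  # membrane time constant, ms
    h: float = -5.0  # field resting level
    beta: float = 4.0  # sigmoid steepness
    snapshot_cadence_ms: float = 50.0
    process_timeout_ms: float = 2000.0
    global_timeout_ms: float = 60000.0

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    def to_ground_config(self) -> GroundConfig:
        return GroundConfig(
            n_spatial=self.n_spatial,
            noise=self.noise_q if self.noise else 0.0,
            seed=self.seed,
            process_timeout_ms=self.process_timeout_ms,
            global_timeout_ms=self.global_timeout_ms,
        )


_VALIDATORS = {
    "n_spatial": lambda v: isinstance(v, int) and v >= 8,
    "n_angle": lambda v: isinstance(v, int) and v >= 8,
    "n_size": lambda v: isinstance(v, int) and v >= 8,
    "seed": lambda v: isinstance(v, int) and v >= 0,
    "noise": lambda v: isinstance(v, bool),
    "noise_q": lambda v: isinstance(v, (int, float)) and v >= 0,
    "tau": lambda v: isinstance(v, (int, float)) and v > 0,
    "h": lambda v: isinstance(v, (int, float)) and v < 0,
    "beta": lambda v: isinstance(v, (int, float)) and v > 0,
    "snapshot_cadence_ms": lambda v: isinstance(v, (int, float)) and v > 0,
    "process_timeout_ms": lambda v: isinstance(v, (int, float)) and v > 0,
    "global_timeout_ms": lambda v: isinstance(v, (int, float)) and v > 0,
}


def load_config(path_or_text: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration, filling defaults and rejecting
    unknown or invalid keys by name."""
    if path_or_text is None:
        return RunConfig()
    s = str(path_or_text)
    if "\n" not in s and len(s) < 1024 and Path(s).exists():
        s = Path(s).read_text()
    data = yaml.safe_load(s) or {}
    if not isinstance(data, dict):
        raise ValueError("configuration must be a YAML mapping")
    cfg = RunConfig()
    for key, value in data.items():
        if key not in _VALIDATORS:
            raise ValueError(f"unknown configuration key: {key!r}")
        if isinstance(value, int) and isinstance(getattr(cfg, key), float):
            value = float(value)
        if not _VALIDATORS[key](value):
            raise ValueError(f"invalid value for configuration key {key!r}: {value!r}")
        setattr(cfg, key, value)
    return cfg


def export_snapshots(trajectory, path: str | Path, events=None) -> None:
    """Write field snapshots to a compressed archive with a JSON manifest.

    ``trajectory`` is a sequence of ``(t_ms, field_name, array)`` records;
    the manifest preserves order, timestamps and the event log.
    """
    arrays = {}
    manifest = {"version": SNAPSHOT_FORMAT_VERSION, "snapshots": [], "events": events or []}
    for i, (t_ms, name, arr) in enumerate(trajectory):
        key = f"snap_{i:05d}"
        arrays[key] = np.asarray(arr)
        manifest["snapshots"].append({"key": key, "t_ms": float(t_ms), "field": name})
    arrays["manifest"] = np.frombuffer(
        json.dumps(manifest).encode("utf-8"), dtype=np.uint8
    )
    np.savez_compressed(path, **arrays)


def import_snapshots(path: str | Path):
    """Lossless inverse of :func:`export_snapshots`.

    Returns ``(trajectory, events)``; raises on format-version mismatch.
    """
    with np.load(path) as data:
        manifest = json.loads(bytes(data["manifest"]).decode("utf-8"))
        if manifest.get("version") != SNAPSHOT_FORMAT_VERSION:
            raise ValueError(
                f"snapshot format version {manifest.get('version')} "
                f"not supported (expected {SNAPSHOT_FORMAT_VERSION})"
            )
        trajectory = [
            (m["t_ms"], m["field"], data[m["key"]].copy())
            for m in manifest["snapshots"]
        ]
    return trajectory, manifest["events"]
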