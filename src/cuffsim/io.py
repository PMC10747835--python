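"""Trace CSV round-tripping and run configuration files.

Trace files carry one row per sample at the sampling rate, with the
header ``time_s,proximal,distal,pressure``; times are serialized with
4 decimal places (0.1 ms resolution at 200 Hz ticks) and values with
6 significant digits, so a write/read/write cycle is byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .experiment import PatternSpec
from .hr_pipeline import WatchModel, load_watch_models
from .plant import PlantParams
from .signal_model import PPGTrace, SubjectProfile

__all__ = [
    "TraceFormatError",
    "TraceSet",
    "write_trace",
    "read_trace",
    "RunConfig",
    "load_run_config",
]

TRACE_COLUMNS = ("time_s", "proximal", "distal", "pressure")


class TraceFormatError(ValueError):
    """Malformed trace CSV (missing column, bad cell, bad time axis)."""


@dataclass
class TraceSet:
    """The three simultaneously logged channels of one recording."""

    proximal: PPGTrace
    distal: PPGTrace
    pressure: PPGTrace

    @property
    def fs_hz(self) -> float:
        return self.proximal.fs_hz


def write_trace(path: str | Path, traces: TraceSet) -> None:
    n = len(traces.proximal)
    if len(traces.distal) != n or len(traces.pressure) != n:
        raise ValueError("all channels must have the same length")
    df = pd.DataFrame(
        {
            "time_s": [f"{t:.4f}" for t in traces.proximal.times],
            "proximal": [f"{v:.6g}" for v in traces.proximal.values],
            "distal": [f"{v:.6g}" for v in traces.distal.values],
            "pressure": [f"{v:.6g}" for v in traces.pressure.values],
        }
    )
    df.to_csv(path, index=False)


def read_trace(path: str | Path) -> TraceSet:
    """Parse a trace CSV; malformed rows are rejected with their line
    number (header is line 1)."""
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - delegated parse failure
        raise TraceFormatError(f"{path}: unreadable CSV ({exc})") from exc
    for col in TRACE_COLUMNS:
        if col not in df.columns:
            raise TraceFormatError(f"{path}: missing required column '{col}'")
    numeric = {}
    for col in TRACE_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy() | df[col].isna().to_numpy())
        if bad.size:
            raise TraceFormatError(
                f"{path}: non-numeric value in column '{col}' at line {bad[0] + 2}"
            )
        numeric[col] = vals.to_numpy(dtype=float)
    t = numeric["time_s"]
    if len(t) < 2:
        raise TraceFormatError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        line = int(np.flatnonzero(dt <= 0)[0]) + 3
        raise TraceFormatError(f"{path}: non-monotone time at line {line}")
    fs = 1.0 / float(np.median(dt))
    t0 = float(t[0])
    return TraceSet(
        proximal=PPGTrace(numeric["proximal"], fs_hz=fs, t0_s=t0, label="proximal"),
        distal=PPGTrace(numeric["distal"], fs_hz=fs, t0_s=t0, label="distal"),
        pressure=PPGTrace(numeric["pressure"], fs_hz=fs, t0_s=t0, label="pressure"),
    )


@dataclass
class RunConfig:
    """Everything one simulated attack session needs."""

    subject: SubjectProfile = field(default_factory=SubjectProfile)
    plant: PlantParams = field(default_factory=PlantParams)
    pattern: PatternSpec = field(default_factory=PatternSpec.A)
    watch: WatchModel | None = None
    duration_s: float = 120.0
    seed: int = 0
    x_air_max: float | None = None
    distance_samples: int | None = None
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ValueError("seed must be a non-negative integer")


_PATTERN_BUILDERS = {"A": PatternSpec.A, "B": PatternSpec.B, "C": PatternSpec.C}


def pattern_from_name(
    name: str, n_stop: int | None = None, n_appear: int | None = None
) -> PatternSpec:
    """Pattern by label with optional explicit cycle counts."""
    name = name.upper()
    if name not in _PATTERN_BUILDERS:
        raise ValueError("pattern must be A, B or C")
    if n_stop is None and n_appear is None:
        return _PATTERN_BUILDERS[name]()
    default = _PATTERN_BUILDERS[name]()
    return PatternSpec(
        name,
        default.n_stop if n_stop is None else n_stop,
        default.n_appear if n_appear is None else n_appear,
    )


def watch_from_name(name: str | None) -> WatchModel | None:
    if name is None or name.lower() in ("none", ""):
        return None
    models = load_watch_models()
    key = name.lower()
    if key not in models:
        raise ValueError(f"unknown watch '{name}' (choose from {sorted(models)} or 'none')")
    return models[key]


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration.

    Recognized sections: ``subject``, ``plant``, ``pattern`` (name plus
    optional n_stop/n_appear), and scalars ``watch``, ``duration_s``,
    ``seed``, ``x_air_max``, ``distance_samples``, ``out_dir``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kw: dict = {}
    if "subject" in raw:
        kw["subject"] = SubjectProfile(**raw["subject"])
    if "plant" in raw:
        kw["plant"] = PlantParams(**raw["plant"])
    if "pattern" in raw:
        p = raw["pattern"]
        if isinstance(p, str):
            kw["pattern"] = pattern_from_name(p)
        else:
            kw["pattern"] = pattern_from_name(p["name"], p.get("n_stop"), p.get("n_appear"))
    if "watch" in raw:
        kw["watch"] = watch_from_name(raw["watch"])
    for key in ("duration_s", "seed", "x_air_max", "distance_samples"):
        if key in raw:
            kw[key] = raw[key]
    if "out_dir" in raw:
        kw["out_dir"] = Path(raw["out_dir"])
    return RunConfig(**kw)
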