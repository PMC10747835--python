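"""Offline heart-rate estimation and the smartwatch display model.

The pipeline mirrors how a wearable turns a raw PPG trace into the
number on its screen:

1. a 41-sample moving average (~200 ms at 200 Hz) suppresses contact
   noise;
2. peaks are picked with a *height* threshold (the mean of the smoothed
   trace over the recording) and a *distance* constraint (100 samples
   at rest, 50 after exercise, i.e. 0.5 s / 0.25 s);
3. the heart rate at time t is 60 divided by the mean of the most
   recent (up to 10) inter-peak intervals, evaluated on a 1 s grid;
4. the display clamps the estimate to the watch's displayable range.

Commercial watches differ only in step 4 here; their proprietary
smoothing/confidence logic is deliberately not modelled.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import scipy.signal
import yaml

from .signal_model import PPGTrace

__all__ = [
    "PeakSeries",
    "BPMSeries",
    "WatchModel",
    "load_watch_models",
    "smooth",
    "find_peaks_offline",
    "bpm_series",
    "watch_display",
]

REST_DISTANCE_SAMPLES = 100
EXERCISE_DISTANCE_SAMPLES = 50
BPM_INTERVAL_WINDOW = 10


@dataclass(frozen=True)
class PeakSeries:
    """Detected pulse peaks: strictly increasing times in seconds."""

    peak_times_s: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.peak_times_s, dtype=float)
        if t.ndim != 1:
            raise ValueError("peak times must be 1-D")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("peak times must be strictly increasing")
        object.__setattr__(self, "peak_times_s", t)

    @property
    def intervals_s(self) -> np.ndarray:
        """Inter-peak intervals d_k = t_k - t_(k-1)."""
        return np.diff(self.peak_times_s)

    def __len__(self) -> int:
        return len(self.peak_times_s)


@dataclass(frozen=True)
class BPMSeries:
    """Heart-rate estimate on a 1 s grid; NaN where undefined."""

    times_s: np.ndarray
    bpm: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        b = np.asarray(self.bpm, dtype=float)
        if t.shape != b.shape:
            raise ValueError("times and bpm must have the same shape")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "bpm", b)

    def tail_mean(self, window_s: float = 10.0) -> float:
        """Mean over the final ``window_s`` seconds (NaN-aware)."""
        mask = self.times_s > self.times_s[-1] - window_s
        vals = self.bpm[mask]
        return float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else float("nan")


@dataclass(frozen=True)
class WatchModel:
    """Display limits of a wearable heart-rate app."""

    name: str
    min_display: float
    max_display: float
    update_period_s: float = 1.0
    dropout: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.min_display < self.max_display:
            raise ValueError("need 0 < min_display < max_display")


def load_watch_models() -> dict[str, WatchModel]:
    """The four watch models with published display limits."""
    text = importlib.resources.files("cuffsim").joinpath("data/watches.yaml").read_text()
    raw = yaml.safe_load(text)
    return {
        name: WatchModel(name=name, **params) for name, params in raw["watches"].items()
    }


def smooth(trace: PPGTrace, window: int = 41) -> PPGTrace:
    """Centred moving average with truncated windows at the edges.

    Output length equals input length; a constant trace is unchanged
    and an impulse spreads to 1/window over the window.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and positive")
    if window > len(trace):
        raise ValueError("window longer than trace")
    v = trace.values
    kernel = np.ones(window)
    sums = np.convolve(v, kernel, mode="same")
    counts = np.convolve(np.ones_like(v), kernel, mode="same")
    return PPGTrace(sums / counts, fs_hz=trace.fs_hz, t0_s=trace.t0_s, label=trace.label)


def find_peaks_offline(
    trace: PPGTrace,
    height: float | None = None,
    distance_samples: int = REST_DISTANCE_SAMPLES,
) -> PeakSeries:
    """Strict local maxima above ``height``, at least ``distance_samples``
    apart.

    ``height`` defaults to the mean of the supplied (smoothed) trace.
    When two candidates violate the distance constraint the larger one
    wins; equal heights go to the earlier peak.
    """
    if distance_samples < 1:
        raise ValueError("distance_samples must be >= 1")
    v = trace.values
    if len(v) == 0:
        return PeakSeries(np.array([]))
    if height is None:
        height = float(np.mean(v))
    candidates, _ = scipy.signal.find_peaks(v)
    candidates = candidates[v[candidates] > height]
    # greedy selection: tallest first, ties to the earlier sample
    order = sorted(range(len(candidates)), key=lambda k: (-v[candidates[k]], candidates[k]))
    kept: list[int] = []
    for k in order:
        idx = candidates[k]
        if all(abs(idx - j) >= distance_samples for j in kept):
            kept.append(idx)
    kept.sort()
    times = trace.t0_s + np.asarray(kept, dtype=float) / trace.fs_hz
    return PeakSeries(times)


def bpm_series(
    peaks: PeakSeries,
    duration_s: float,
    window: int = BPM_INTERVAL_WINDOW,
) -> BPMSeries:
    """Heart rate b(t) on a 1 s grid from inter-peak intervals.

    b(t) = 60 / mean of the most recent min(m, window) intervals whose
    closing peak lies at or before t (m = intervals accumulated so
    far); NaN until the first interval exists.
    """
    grid = np.arange(0.0, np.floor(duration_s) + 0.5, 1.0)
    out = np.full(grid.shape, np.nan)
    t = peaks.peak_times_s
    d = peaks.intervals_s
    if len(d) == 0:
        return BPMSeries(grid, out)
    closing = t[1:]  # interval k closes at peak time t_k
    for gi, g in enumerate(grid):
        m = int(np.searchsorted(closing, g, side="right"))
        if m == 0:
            continue
        recent = d[max(0, m - window) : m]
        out[gi] = 60.0 / float(np.mean(recent))
    return BPMSeries(grid, out)


def watch_display(bpm: BPMSeries, watch: WatchModel | None) -> BPMSeries:
    """What the watch face shows: the estimate clamped to the model's
    displayable range (or blanked outside it for dropout models).
    ``watch=None`` is a transparent display."""
    if watch is None:
        return BPMSeries(bpm.times_s.copy(), bpm.bpm.copy())
    vals = bpm.bpm.copy()
    finite = np.isfinite(vals)
    if watch.dropout:
        vals[finite & ((vals < watch.min_display) | (vals > watch.max_display))] = np.nan
    else:
        vals[finite] = np.clip(vals[finite], watch.min_display, watch.max_display)
    return BPMSeries(bpm.times_s.copy(), vals)
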