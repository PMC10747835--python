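"""Attack patterns, full-session simulation and verdict classification.

A pressure pattern is the pair (N_stop, N_appear): how many heartbeats
the cuff suppresses per cycle and how many it lets through.  The
long-run displayed-to-true heart-rate ratio an ideal device achieves is
N_appear / (N_stop + N_appear):

* Pattern A (equal counts)        -> 1/2 of the true rate,
* Pattern B (more appearing)      -> e.g. (2,4) -> 2/3,
* Pattern C (more suppressed)     -> e.g. (4,2) -> 1/3.

A session runs the closed-loop controller for two minutes, pushes the
distal trace through the heart-rate pipeline and a watch display model,
uses the proximal trace through the same pipeline as ground truth, and
classifies the end-of-session outcome with the +/-15 BPM rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .controller import (
    CalibrationConfig,
    ControlConfig,
    SessionLog,
    run_calibration,
    run_control,
)
from .hr_pipeline import (
    BPMSeries,
    EXERCISE_DISTANCE_SAMPLES,
    REST_DISTANCE_SAMPLES,
    WatchModel,
    bpm_series,
    find_peaks_offline,
    smooth,
    watch_display,
)
from .plant import PlantParams
from .signal_model import BeatTemplate, SubjectProfile

__all__ = [
    "PatternSpec",
    "SessionResult",
    "theoretical_ratio",
    "classify",
    "run_session",
    "summarize_sessions",
]

VERDICT_BAND_BPM = 15.0


@dataclass(frozen=True)
class PatternSpec:
    """Attack cycle class: A (n_stop = n_appear), B (n_appear > n_stop),
    C (n_appear < n_stop)."""

    name: str
    n_stop: int
    n_appear: int

    def __post_init__(self) -> None:
        if self.n_appear < 1:
            raise ValueError("n_appear must be >= 1")
        if self.n_stop < 0:
            raise ValueError("n_stop must be >= 0")
        rules = {
            "A": self.n_stop == self.n_appear,
            "B": self.n_appear > self.n_stop,
            "C": self.n_appear < self.n_stop,
        }
        if self.name not in rules:
            raise ValueError("pattern name must be A, B or C")
        if not rules[self.name]:
            raise ValueError(
                f"pattern {self.name} requires "
                f"{'n_stop == n_appear' if self.name == 'A' else ('n_appear > n_stop' if self.name == 'B' else 'n_appear < n_stop')}"
            )

    @classmethod
    def A(cls, n: int = 3) -> "PatternSpec":
        return cls("A", n, n)

    @classmethod
    def B(cls, n_stop: int = 2, n_appear: int = 4) -> "PatternSpec":
        return cls("B", n_stop, n_appear)

    @classmethod
    def C(cls, n_stop: int = 4, n_appear: int = 2) -> "PatternSpec":
        return cls("C", n_stop, n_appear)


def theoretical_ratio(pattern: PatternSpec) -> float:
    """Ideal displayed/true heart-rate fraction for a pattern."""
    return pattern.n_appear / (pattern.n_stop + pattern.n_appear)


def classify(true_bpm: float, displayed_bpm: float) -> str:
    """+/-15 BPM session verdict: 'decreased' iff displayed < true - 15,
    'increased' iff displayed > true + 15, else 'unchanged'."""
    if not (np.isfinite(true_bpm) and np.isfinite(displayed_bpm)):
        raise ValueError("both rates must be finite")
    if displayed_bpm < true_bpm - VERDICT_BAND_BPM:
        return "decreased"
    if displayed_bpm > true_bpm + VERDICT_BAND_BPM:
        return "increased"
    return "unchanged"


@dataclass
class SessionResult:
    """Outcome of one attack session."""

    log: SessionLog
    true_bpm_series: BPMSeries
    estimated_bpm_series: BPMSeries  # distal pipeline, before the display
    displayed_bpm_series: BPMSeries
    end_of_session_true: float
    end_of_session_displayed: float
    verdict: str
    x_air_max: float
    pattern: PatternSpec
    watch: WatchModel | None

    def transcript(self) -> pd.DataFrame:
        """1 s cadence transcript: time, true, estimated and displayed BPM."""
        return pd.DataFrame(
            {
                "time_s": self.true_bpm_series.times_s,
                "true_bpm": self.true_bpm_series.bpm,
                "estimated_bpm": self.estimated_bpm_series.bpm,
                "displayed_bpm": self.displayed_bpm_series.bpm,
            }
        )


def _distance_for(subject: SubjectProfile) -> int:
    """Peak-spacing parameter: 100 samples at resting rates, 50 at
    after-exercise rates (> 100 bpm)."""
    return REST_DISTANCE_SAMPLES if subject.true_hr_bpm <= 100 else EXERCISE_DISTANCE_SAMPLES


def estimate_bpm(trace, distance_samples: int, duration_s: float) -> BPMSeries:
    """Full offline pipeline on one trace: smooth, peak-pick with the
    2-min-mean height threshold, Eq.-style interval averaging."""
    sm = smooth(trace)
    peaks = find_peaks_offline(sm, height=None, distance_samples=distance_samples)
    return bpm_series(peaks, duration_s)


def run_session(
    subject: SubjectProfile,
    pattern: PatternSpec,
    watch: WatchModel | None = None,
    plant: PlantParams | None = None,
    duration_s: float = 120.0,
    seed: int = 0,
    x_air_max: float | None = None,
    template: BeatTemplate | None = None,
    distance_samples: int | None = None,
    tail_window_s: float = 10.0,
) -> SessionResult:
    """Simulate one attack session end to end.

    If ``x_air_max`` is not supplied, the calibration procedure is run
    first (with a seed derived from ``seed``).  The end-of-session
    value is the mean displayed reading over the final ``tail_window_s``
    seconds.
    """
    if plant is None:
        plant = PlantParams()
    if x_air_max is None:
        cal = run_calibration(plant, subject, CalibrationConfig(), seed=seed + 1, template=template)
        x_air_max = cal.x_air_max
    if distance_samples is None:
        distance_samples = _distance_for(subject)

    config = ControlConfig(x_air_max=x_air_max, n_stop=pattern.n_stop, n_appear=pattern.n_appear)
    log = run_control(plant, subject, config, duration_s, seed=seed, template=template)

    true_series = estimate_bpm(log.proximal_trace, distance_samples, duration_s)
    est_series = estimate_bpm(log.distal_trace, distance_samples, duration_s)
    disp_series = watch_display(est_series, watch)

    end_true = true_series.tail_mean(tail_window_s)
    end_disp = disp_series.tail_mean(tail_window_s)
    if np.isfinite(end_true) and np.isfinite(end_disp):
        verdict = classify(end_true, end_disp)
    else:
        verdict = "unchanged"
    return SessionResult(
        log=log,
        true_bpm_series=true_series,
        estimated_bpm_series=est_series,
        displayed_bpm_series=disp_series,
        end_of_session_true=end_true,
        end_of_session_displayed=end_disp,
        verdict=verdict,
        x_air_max=x_air_max,
        pattern=pattern,
        watch=watch,
    )


def summarize_sessions(results: list[tuple[str, str, int, SessionResult]]) -> pd.DataFrame:
    """Summary table (pattern x subject x session -> verdict), one row
    per session, mirroring a study report layout.

    ``results`` holds (pattern_name, subject_label, session_index, result).
    """
    rows = []
    for pattern_name, subject_label, session_idx, res in results:
        rows.append(
            {
                "pattern": pattern_name,
                "subject": subject_label,
                "session": session_idx,
                "watch": res.watch.name if res.watch else "none",
                "true_bpm": res.end_of_session_true,
                "displayed_bpm": res.end_of_session_displayed,
                "verdict": res.verdict,
            }
        )
    return pd.DataFrame(rows)
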