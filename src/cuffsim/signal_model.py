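"""Synthetic photoplethysmogram (PPG) generation.

A PPG sensor reports reflected-light intensity in raw A/D counts; each
cardiac cycle produces one pulse on top of a DC baseline.  This module
builds quasi-periodic beat trains, renders them into sampled traces, and
models the effect of an inflated upper-arm cuff: the pulse amplitude at
any sensor distal to the cuff shrinks as cuff pressure rises and the
peaks vanish entirely above a subject-specific occlusion threshold.

Two sensor sites matter throughout the package:

* *proximal* — heart side of the cuff, never affected by cuff pressure;
* *distal*   — wrist/finger side, attenuated by the cuff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "BeatTemplate",
    "SubjectProfile",
    "PPGTrace",
    "generate_beat_times",
    "occlusion_attenuation",
    "render_pulse_component",
    "render_ppg",
]

DEFAULT_FS_HZ = 200.0


@dataclass(frozen=True)
class BeatTemplate:
    """Unit-amplitude waveform of a single pulse.

    ``samples`` holds the shape on a uniform phase grid covering the
    active part of one beat; ``duration_fraction`` is the portion of the
    inter-beat interval the shape occupies (the remainder is baseline).
    ``peak_fraction`` is the phase of the systolic peak measured as a
    fraction of the whole inter-beat interval.
    """

    samples: np.ndarray
    duration_fraction: float = 0.5

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 1 or s.size < 3:
            raise ValueError("template needs at least 3 samples")
        if not np.isfinite(s).all():
            raise ValueError("template samples must be finite")
        if abs(s.max() - 1.0) > 1e-9 or s.min() < 0.0:
            raise ValueError("template must peak at 1 and be non-negative")
        if s[0] >= 0.05 or s[-1] >= 0.05:
            raise ValueError("template must start and end near baseline")
        if not 0.0 < self.duration_fraction <= 1.0:
            raise ValueError("duration_fraction must be in (0, 1]")
        object.__setattr__(self, "samples", s)

    @property
    def peak_fraction(self) -> float:
        """Phase of the peak as a fraction of the inter-beat interval."""
        return float(np.argmax(self.samples) / (len(self.samples) - 1)) * self.duration_fraction

    @classmethod
    def raised_cosine(cls, n: int = 101, duration_fraction: float = 0.5) -> "BeatTemplate":
        """Single raised-cosine bump; peak lands at 25% of the beat
        interval for the default ``duration_fraction`` of 0.5."""
        x = np.linspace(0.0, 1.0, n)
        return cls(samples=0.5 * (1.0 - np.cos(2.0 * np.pi * x)), duration_fraction=duration_fraction)


@dataclass(frozen=True)
class SubjectProfile:
    """Physiological parameters of a simulated wearer.

    ``occlusion_threshold_counts`` is the cuff pressure (A/D counts)
    around which distal pulse peaks disappear; ``occlusion_softness``
    sets the width of the transition between full and zero amplitude.
    """

    true_hr_bpm: float = 80.0
    hr_jitter_sd: float = 0.0
    amplitude_counts: float = 300.0
    baseline_counts: float = 400.0
    noise_sd_counts: float = 0.0
    occlusion_threshold_counts: float = 300.0
    occlusion_softness: float = 20.0

    def __post_init__(self) -> None:
        if self.true_hr_bpm <= 0:
            raise ValueError("true_hr_bpm must be positive")
        if self.amplitude_counts <= 0:
            raise ValueError("amplitude_counts must be positive")
        if self.occlusion_threshold_counts <= 0:
            raise ValueError("occlusion threshold must be positive")
        if self.occlusion_softness <= 0:
            raise ValueError("occlusion_softness must be positive")
        if self.noise_sd_counts < 0 or self.hr_jitter_sd < 0:
            raise ValueError("noise/jitter SDs must be non-negative")

    @classmethod
    def rest(cls, hr_bpm: float = 80.0, **kw) -> "SubjectProfile":
        """Resting regime (normal adult heart rate, 60-100 bpm)."""
        return cls(true_hr_bpm=hr_bpm, **kw)

    @classmethod
    def after_exercise(cls, hr_bpm: float = 140.0, **kw) -> "SubjectProfile":
        """After-exercise regime (120-150 bpm)."""
        return cls(true_hr_bpm=hr_bpm, **kw)

    @classmethod
    def sharp(cls, occlusion_threshold_counts: float, **kw) -> "SubjectProfile":
        """Subject with a near-step attenuation curve: peaks vanish as
        soon as cuff pressure exceeds the threshold."""
        kw.setdefault("occlusion_softness", 0.5)
        return cls(occlusion_threshold_counts=occlusion_threshold_counts, **kw)


@dataclass
class PPGTrace:
    """Uniformly sampled sensor signal in A/D counts."""

    values: np.ndarray
    fs_hz: float = DEFAULT_FS_HZ
    t0_s: float = 0.0
    label: str = "proximal"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if v.ndim != 1 or v.size < 1:
            raise ValueError("trace must be a non-empty 1-D array")
        if not np.isfinite(v).all():
            raise ValueError("trace values must be finite")
        self.values = v

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.values)) / self.fs_hz

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.fs_hz


def generate_beat_times(
    duration_s: float,
    hr_bpm: float,
    jitter_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Beat onset times for a quasi-periodic heart.

    Inter-beat intervals are 60/hr_bpm seconds plus independent Gaussian
    perturbations truncated at +/-3 SD (keeps intervals positive for any
    sane jitter).  Onsets start at t=0 and are strictly increasing;
    the last onset is strictly less than ``duration_s``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if hr_bpm <= 0:
        raise ValueError("hr_bpm must be positive")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ibi = 60.0 / hr_bpm
    n_max = int(np.ceil(duration_s / ibi)) + int(4 * np.ceil(duration_s * jitter_sd / ibi)) + 8
    if jitter_sd > 0:
        perturb = np.clip(rng.normal(0.0, jitter_sd, n_max), -3 * jitter_sd, 3 * jitter_sd)
    else:
        perturb = np.zeros(n_max)
    intervals = np.maximum(ibi + perturb, 0.05)
    onsets = np.concatenate([[0.0], np.cumsum(intervals)])
    return onsets[onsets < duration_s]


def occlusion_attenuation(
    pressure_counts: float | np.ndarray,
    threshold_counts: float,
    softness_counts: float,
) -> float | np.ndarray:
    """Multiplicative pulse-amplitude factor under cuff pressure.

    A logistic roll-off: ~1 with the cuff vented, 1/2 at the occlusion
    threshold, and < 0.01 once pressure exceeds threshold + 3*softness.
    Negative pressures are clamped to zero (vented cuff).
    """
    if threshold_counts <= 0:
        raise ValueError("threshold must be positive")
    if softness_counts <= 0:
        raise ValueError("softness must be positive")
    p = np.maximum(np.asarray(pressure_counts, dtype=float), 0.0)
    out = expit((threshold_counts - p) / (softness_counts / 2.0))
    return float(out) if np.isscalar(pressure_counts) else out


def render_pulse_component(
    beat_times: np.ndarray,
    template: BeatTemplate,
    amplitude_counts: float,
    fs_hz: float,
    duration_s: float,
    hr_bpm_hint: float | None = None,
) -> np.ndarray:
    """Noiseless, baseline-free pulse waveform (A/D counts).

    Each beat occupies ``template.duration_fraction`` of the gap to the
    next onset, so bumps never overlap.  The final beat reuses the mean
    interval (or 60/hr_bpm_hint) for its width.
    """
    n = int(round(duration_s * fs_hz))
    pulse = np.zeros(n)
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size == 0:
        return pulse
    if np.any(beat_times < 0) or np.any(beat_times > duration_s):
        raise ValueError("beat times must lie within [0, duration_s]")
    if beat_times.size > 1:
        fallback = float(np.mean(np.diff(beat_times)))
    else:
        fallback = 60.0 / hr_bpm_hint if hr_bpm_hint else 1.0
    intervals = np.append(np.diff(beat_times), fallback)
    tmpl_x = np.linspace(0.0, 1.0, len(template.samples))
    for onset, ibi in zip(beat_times, intervals):
        width = template.duration_fraction * ibi
        i0 = int(np.ceil(onset * fs_hz))
        i1 = min(int(np.floor((onset + width) * fs_hz)), n - 1)
        if i1 < i0:
            continue
        t = np.arange(i0, i1 + 1) / fs_hz
        phase = (t - onset) / width
        pulse[i0 : i1 + 1] += amplitude_counts * np.interp(phase, tmpl_x, template.samples)
    return pulse


def render_ppg(
    beat_times: np.ndarray,
    template: BeatTemplate,
    profile: SubjectProfile,
    fs_hz: float = DEFAULT_FS_HZ,
    duration_s: float = 60.0,
    attenuation: float | np.ndarray = 1.0,
    seed: int | np.random.Generator = 0,
    label: str = "proximal",
) -> PPGTrace:
    """Render a sampled PPG trace.

    ``attenuation`` is either a scalar or a per-sample factor in [0, 1]
    applied to the pulse component (1 = unoccluded, 0 = flat baseline).
    Additive white Gaussian sensor noise with the profile's SD is drawn
    from ``seed``; the result is reproducible for a fixed seed.
    """
    n = int(round(duration_s * fs_hz))
    att = np.asarray(attenuation, dtype=float)
    if att.ndim == 0:
        att = np.full(n, float(att))
    if att.shape != (n,):
        raise ValueError("attenuation series length must match duration * fs")
    pulse = render_pulse_component(
        beat_times, template, profile.amplitude_counts, fs_hz, duration_s, profile.true_hr_bpm
    )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = profile.baseline_counts + att * pulse
    if profile.noise_sd_counts > 0:
        values = values + rng.normal(0.0, profile.noise_sd_counts, n)
    return PPGTrace(values=values, fs_hz=fs_hz, label=label)
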