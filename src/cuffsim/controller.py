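"""Calibration and pulse-wave-control state machines.

Both procedures close the loop between the streaming peak detector, the
cuff plant and the synthetic signal model at a fixed tick of T ms
(default 5 ms, i.e. the 200 Hz logging rate).

Calibration (distal sensor) searches downward on a 400/20 pressure grid
for the largest grid value at which the distal pulse still disappears:
pressurize to the current target, hold, read the 2-s disappearance
verdict, vent for 1 s, and either lower the target by one step or stop
and return target + step.

Control (proximal sensor) repeats the attack cycle: pressurize to the
calibrated x_air_max, keep pressure until N_stop peaks are counted,
vent down to release_fraction * x_air_max, and idle until N_appear
peaks are counted.  Peak counting for each phase starts once the
corresponding pressure condition is met (the keep-pressure counter runs
only after reaching x_air_max, the standby counter only after reaching
the release level), so beats falling inside plant transitions belong to
neither quota.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .detector import DetectorState, detector_step, is_disappeared
from .plant import PlantParams, PlantState, plant_step
from .signal_model import (
    BeatTemplate,
    SubjectProfile,
    PPGTrace,
    generate_beat_times,
    occlusion_attenuation,
    render_pulse_component,
)

__all__ = [
    "CalibrationConfig",
    "ControlConfig",
    "CalibrationResult",
    "SessionLog",
    "CalibrationError",
    "SignalLossError",
    "run_calibration",
    "run_control",
]


class CalibrationError(RuntimeError):
    """Calibration descended to a non-positive target without finding a
    pressure at which the pulse persists."""


class SignalLossError(RuntimeError):
    """The control loop saw no proximal peaks for over 10 s."""


@dataclass(frozen=True)
class CalibrationConfig:
    initial_target_counts: float = 400.0
    step_counts: float = 20.0
    vent_time_s: float = 1.0
    hold_time_s: float = 6.0
    sample_period_ms: float = 5.0
    pressurize_timeout_s: float = 30.0

    def __post_init__(self) -> None:
        if self.step_counts <= 0 or self.vent_time_s <= 0 or self.hold_time_s <= 0:
            raise ValueError("step, vent time and hold time must be positive")
        if self.sample_period_ms <= 0:
            raise ValueError("sample period must be positive")


@dataclass(frozen=True)
class ControlConfig:
    x_air_max: float
    n_stop: int = 3
    n_appear: int = 3
    release_fraction: float = 0.5
    sample_period_ms: float = 5.0

    def __post_init__(self) -> None:
        if self.x_air_max <= 0:
            raise ValueError("x_air_max must be positive")
        if self.n_stop < 0:
            raise ValueError("n_stop must be >= 0")
        if self.n_appear < 1:
            raise ValueError("n_appear must be >= 1")
        if not 0.0 < self.release_fraction < 1.0:
            raise ValueError("release_fraction must be in (0, 1)")
        if self.sample_period_ms <= 0:
            raise ValueError("sample period must be positive")


@dataclass
class CalibrationResult:
    x_air_max: float
    trials: list[tuple[float, bool]]  # (tested target, disappeared verdict)


@dataclass
class SessionLog:
    """Tick-level transcript of one control session."""

    df: pd.DataFrame
    beat_times: np.ndarray
    fs_hz: float
    subject: SubjectProfile
    config: ControlConfig
    template: BeatTemplate

    @property
    def proximal_trace(self) -> PPGTrace:
        return PPGTrace(self.df["proximal"].to_numpy(), fs_hz=self.fs_hz, label="proximal")

    @property
    def distal_trace(self) -> PPGTrace:
        return PPGTrace(self.df["distal"].to_numpy(), fs_hz=self.fs_hz, label="distal")

    @property
    def pressure_trace(self) -> PPGTrace:
        return PPGTrace(self.df["pressure"].to_numpy(), fs_hz=self.fs_hz, label="pressure")

    def beat_peak_times(self) -> np.ndarray:
        """True waveform peak times of every rendered beat."""
        onsets = self.beat_times
        if onsets.size == 0:
            return onsets
        if onsets.size > 1:
            fallback = float(np.mean(np.diff(onsets)))
        else:
            fallback = 60.0 / self.subject.true_hr_bpm
        intervals = np.append(np.diff(onsets), fallback)
        return onsets + self.template.peak_fraction * intervals

    def beat_phases(self) -> np.ndarray:
        """Controller phase at the moment of each beat's waveform peak."""
        phases = self.df["phase"].to_numpy()
        idx = np.clip((self.beat_peak_times() * self.fs_hz).astype(int), 0, len(phases) - 1)
        return phases[idx]

    def surviving_fraction(self) -> float:
        """Fraction of true beats whose peak falls in the released
        (standby) window — the session-log bookkeeping measure that the
        theoretical ratio N_appear/(N_stop+N_appear) predicts."""
        ph = self.beat_phases()
        if ph.size == 0:
            return float("nan")
        return float(np.mean(ph == "wait"))

    def occluded_beats_per_cycle(self) -> float:
        """Mean number of beats outside the released window per
        completed attack cycle."""
        ph = self.beat_phases()
        n_cycles = self.completed_cycles()
        if n_cycles == 0:
            return float("nan")
        return float(np.sum(ph != "wait") / n_cycles)

    def completed_cycles(self) -> int:
        phases = self.df["phase"].to_numpy()
        # a cycle completes at each wait -> pressurize transition
        return int(np.sum((phases[:-1] == "wait") & (phases[1:] == "pressurize")))


def _session_arrays(
    subject: SubjectProfile,
    template: BeatTemplate,
    duration_s: float,
    fs_hz: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Beat times, noiseless pulse component and the two sensor-noise
    streams for one simulated session."""
    ss = np.random.SeedSequence(seed)
    beat_rng, prox_rng, dist_rng = (np.random.default_rng(s) for s in ss.spawn(3))
    beats = generate_beat_times(duration_s, subject.true_hr_bpm, subject.hr_jitter_sd, beat_rng)
    pulse = render_pulse_component(
        beats, template, subject.amplitude_counts, fs_hz, duration_s, subject.true_hr_bpm
    )
    n = len(pulse)
    if subject.noise_sd_counts > 0:
        noise_p = prox_rng.normal(0.0, subject.noise_sd_counts, n)
        noise_d = dist_rng.normal(0.0, subject.noise_sd_counts, n)
    else:
        noise_p = np.zeros(n)
        noise_d = np.zeros(n)
    return beats, pulse, noise_p, noise_d


def run_calibration(
    plant: PlantParams,
    subject: SubjectProfile,
    config: CalibrationConfig = CalibrationConfig(),
    seed: int = 0,
    template: BeatTemplate | None = None,
) -> CalibrationResult:
    """Search for the user-specific target pressure x_air_max.

    The distal-sensor detector supplies the disappearance verdict at
    the end of each trial's hold window.  Returns the smallest grid
    value at which the pulse still disappears... formally: on the first
    target whose verdict is "still visible", returns target + step.
    """
    if template is None:
        template = BeatTemplate.raised_cosine()
    dt = config.sample_period_ms / 1000.0
    fs = 1.0 / dt
    n_trials_max = int(np.ceil(config.initial_target_counts / config.step_counts)) + 1
    per_trial = (
        config.initial_target_counts / plant.pump_rate_counts_per_s
        + config.hold_time_s
        + config.vent_time_s
        + 1.0
    )
    duration = n_trials_max * per_trial + 5.0
    beats, pulse, _, noise_d = _session_arrays(subject, template, duration, fs, seed)
    n = len(pulse)

    det = DetectorState()
    ps = PlantState()
    theta = subject.occlusion_threshold_counts
    soft = subject.occlusion_softness
    target = config.initial_target_counts
    trials: list[tuple[float, bool]] = []
    i = 0

    def tick(pump: bool, valve: bool) -> float:
        """Advance one sample; returns current time. Feeds the distal
        sample to the detector."""
        nonlocal ps, det, i
        if i >= n:
            raise CalibrationError("calibration exceeded its simulation budget")
        ps = plant_step(ps, pump, valve, dt, plant)
        if pump and ps.pressure_counts > target:
            # the pump shuts off within the tick once the target is met
            ps = replace(ps, pressure_counts=float(target))
        t = i * dt
        att = occlusion_attenuation(ps.pressure_counts, theta, soft)
        sample = subject.baseline_counts + att * pulse[i] + noise_d[i]
        det, _ = detector_step(det, sample, t)
        i += 1
        return t

    while True:
        # pressurize to the current target
        t_start = i * dt
        while ps.pressure_counts < target:
            t = tick(pump=True, valve=False)
            if t - t_start > config.pressurize_timeout_s:
                raise CalibrationError(f"could not reach target {target:.0f}")
        # keep pressure for the hold window, then read the verdict
        hold_ticks = int(round(config.hold_time_s / dt))
        for _ in range(hold_ticks):
            t = tick(pump=False, valve=False)
        disappeared = is_disappeared(det, t)
        trials.append((target, disappeared))
        # open the solenoid valve for the vent interval
        for _ in range(int(round(config.vent_time_s / dt))):
            tick(pump=False, valve=True)
        if not disappeared:
            return CalibrationResult(x_air_max=target + config.step_counts, trials=trials)
        target -= config.step_counts
        if target <= 0:
            raise CalibrationError("pulse disappeared at every positive grid pressure")


def run_control(
    plant: PlantParams,
    subject: SubjectProfile,
    config: ControlConfig,
    duration_s: float,
    seed: int = 0,
    template: BeatTemplate | None = None,
) -> SessionLog:
    """Run the pulse-wave-control attack for ``duration_s`` seconds.

    The proximal-sensor detector paces the cycle; the distal trace in
    the returned log shows the suppressed peaks an attacked wearable
    would see.
    """
    if template is None:
        template = BeatTemplate.raised_cosine()
    dt = config.sample_period_ms / 1000.0
    fs = 1.0 / dt
    n = int(round(duration_s * fs))
    cols = ["time_s", "phase", "pump_on", "valve_open", "pressure", "proximal", "distal", "peak_event"]
    if n == 0:
        df = pd.DataFrame({c: [] for c in cols})
        return SessionLog(df, np.array([]), fs, subject, config, template)

    beats, pulse, noise_p, noise_d = _session_arrays(subject, template, duration_s, fs, seed)
    det = DetectorState()
    ps = PlantState()
    theta = subject.occlusion_threshold_counts
    soft = subject.occlusion_softness
    release_level = config.release_fraction * config.x_air_max

    # with nothing to suppress the cuff never needs pressurizing
    phase = "pressurize" if config.n_stop > 0 else "release"
    count = 0  # peaks counted toward the active quota
    counting = False  # quota counting armed (pressure condition met)
    last_event_t = 0.0

    phases = np.empty(n, dtype=object)
    pump_col = np.zeros(n, dtype=bool)
    valve_col = np.zeros(n, dtype=bool)
    pressure_col = np.zeros(n)
    proximal = np.zeros(n)
    distal = np.zeros(n)
    peak_col = np.zeros(n, dtype=bool)

    for i in range(n):
        t = i * dt
        pump = phase == "pressurize"
        valve = phase == "release"
        ps = plant_step(ps, pump, valve, dt, plant)
        # actuators cut off within the tick at their setpoints
        if pump and ps.pressure_counts > config.x_air_max:
            ps = replace(ps, pressure_counts=float(config.x_air_max))
        elif valve and ps.pressure_counts < release_level:
            ps = replace(ps, pressure_counts=float(release_level))

        # pressure-condition transitions; arm the quota counter
        if phase == "pressurize" and ps.pressure_counts >= config.x_air_max:
            phase, count, counting = "hold", 0, True
        elif phase == "release" and ps.pressure_counts <= release_level:
            phase, count, counting = "wait", 0, True

        att = occlusion_attenuation(ps.pressure_counts, theta, soft)
        proximal[i] = subject.baseline_counts + pulse[i] + noise_p[i]
        distal[i] = subject.baseline_counts + att * pulse[i] + noise_d[i]

        det, event = detector_step(det, proximal[i], t)
        if event is not None:
            peak_col[i] = True
            last_event_t = t
            if counting:
                count += 1
                if phase == "hold" and count >= config.n_stop:
                    phase, counting = "release", False
                elif phase == "wait" and count >= config.n_appear:
                    phase = "pressurize" if config.n_stop > 0 else "release"
                    counting = False
        if t - last_event_t > 10.0:
            raise SignalLossError("no proximal peaks for over 10 s")

        phases[i] = phase
        pump_col[i] = pump
        valve_col[i] = valve
        pressure_col[i] = ps.pressure_counts

    df = pd.DataFrame(
        {
            "time_s": np.arange(n) * dt,
            "phase": phases,
            "pump_on": pump_col,
            "valve_open": valve_col,
            "pressure": pressure_col,
            "proximal": proximal,
            "distal": distal,
            "peak_event": peak_col,
        }
    )
    return SessionLog(df, beats, fs, subject, config, template)
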