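"""Streaming adaptive-threshold pulse-peak detection.

This is the controller-side detector: it consumes one sample per tick,
keeps a running signal envelope, and places its threshold halfway
between the envelope minimum and maximum.  A peak is confirmed when the
signal, having risen through the threshold, falls back below it; the
reported peak time is the time of the largest sample in that excursion,
so it lands within a sample of the true waveform peak while the
*confirmation* (the event the controller acts on) happens on the
falling edge.

Two rules follow the attack procedure:

* if no peak has been detected for 2 s the threshold and envelope are
  reset, so detection recovers quickly once a suppressed pulse returns
  (at resting rates the inter-beat interval is at most ~1 s, so 2 s of
  silence reliably means the pulse is gone, not merely slow);
* ``is_disappeared`` reports that 2-s silence as the pulse-wave
  "disappearing state" used by calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import inf, isnan, nan

__all__ = ["DetectorState", "PeakEvent", "detector_step", "is_disappeared"]


class OutOfOrderError(ValueError):
    """Samples must arrive in non-decreasing time order."""


@dataclass
class PeakEvent:
    """A confirmed pulse peak: confirmed at ``t_confirm_s``, located at
    ``t_peak_s`` (the excursion maximum)."""

    t_peak_s: float
    t_confirm_s: float
    height_counts: float


@dataclass
class DetectorState:
    """Mutable state of the streaming detector.

    ``min_span_counts`` is the smallest envelope span treated as signal
    rather than noise floor; ``refractory_s`` bounds the event rate at
    240/min, above the adult physiological maximum.
    """

    refractory_s: float = 0.25
    disappear_after_s: float = 2.0
    min_span_counts: float = 25.0
    threshold_counts: float = nan
    running_min: float = inf
    running_max: float = -inf
    last_peak_time_s: float | None = None
    above_threshold: bool = False
    start_time_s: float | None = None
    last_time_s: float | None = None
    last_reset_time_s: float | None = None
    _excursion_max: float = -inf
    _excursion_max_t: float = nan

    def __post_init__(self) -> None:
        if self.refractory_s <= 0:
            raise ValueError("refractory_s must be positive")
        if self.disappear_after_s <= 0:
            raise ValueError("disappear_after_s must be positive")


def detector_step(
    state: DetectorState, sample: float, t_s: float
) -> tuple[DetectorState, PeakEvent | None]:
    """Feed one sample; return the updated state and any peak event.

    At most one event is emitted per upward excursion through the
    threshold, and never two events whose peak times are closer than
    the refractory period.
    """
    if state.last_time_s is not None and t_s < state.last_time_s:
        raise OutOfOrderError(f"sample at t={t_s} precedes t={state.last_time_s}")
    if state.start_time_s is None:
        state.start_time_s = t_s
        state.last_reset_time_s = t_s
    state.last_time_s = t_s

    # threshold/envelope reset after 2 s without a peak
    anchor = max(
        state.last_peak_time_s if state.last_peak_time_s is not None else -inf,
        state.last_reset_time_s if state.last_reset_time_s is not None else -inf,
    )
    if t_s - anchor >= state.disappear_after_s:
        state.running_min = sample
        state.running_max = sample
        state.above_threshold = False
        state._excursion_max = -inf
        state.last_reset_time_s = t_s

    state.running_min = min(state.running_min, sample)
    state.running_max = max(state.running_max, sample)
    span = state.running_max - state.running_min
    state.threshold_counts = 0.5 * (state.running_min + state.running_max)

    event: PeakEvent | None = None
    if span >= state.min_span_counts and sample > state.threshold_counts:
        if not state.above_threshold:
            state.above_threshold = True
            state._excursion_max = sample
            state._excursion_max_t = t_s
        elif sample > state._excursion_max:
            state._excursion_max = sample
            state._excursion_max_t = t_s
    elif state.above_threshold and sample <= state.threshold_counts:
        # falling edge: confirm the excursion's maximum as a peak
        state.above_threshold = False
        t_peak = state._excursion_max_t
        ok = (
            state.last_peak_time_s is None
            or t_peak - state.last_peak_time_s >= state.refractory_s
        )
        if ok and not isnan(t_peak):
            event = PeakEvent(
                t_peak_s=t_peak, t_confirm_s=t_s, height_counts=state._excursion_max
            )
            state.last_peak_time_s = t_peak
        state._excursion_max = -inf
        state._excursion_max_t = nan
    return state, event


def is_disappeared(state: DetectorState, t_s: float) -> bool:
    """True iff no peak has been detected for 2 s.

    Requires 2 s of observed signal before it can fire, so a freshly
    started detector does not report a spurious disappearance.
    Monotone: once true it stays true until a new peak event.
    """
    if state.start_time_s is None or t_s - state.start_time_s < state.disappear_after_s:
        return False
    if state.last_peak_time_s is None:
        return True
    return t_s - state.last_peak_time_s >= state.disappear_after_s
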