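"""Cuff pressure dynamics under pump/valve commands.

The cuff, micro air pump and solenoid valve are modelled as a linear
plant on the pressure sensor's A/D-count scale: the pump adds pressure
at a constant rate, the open valve vents at a constant rate, and a
closed system may leak slowly.  The default pump rate pressurizes
0 -> 400 counts in about half a second, the timing the physical device
achieved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

__all__ = ["PlantState", "PlantParams", "plant_step"]


@dataclass(frozen=True)
class PlantState:
    """Cuff pressure plus actuator flags at simulation time ``t_s``."""

    pressure_counts: float = 0.0
    pump_on: bool = False
    valve_open: bool = False
    t_s: float = 0.0

    def __post_init__(self) -> None:
        if self.pressure_counts < 0:
            raise ValueError("pressure must be non-negative")


@dataclass(frozen=True)
class PlantParams:
    """Pressurization / venting rates in A/D counts per second."""

    pump_rate_counts_per_s: float = 800.0
    vent_rate_counts_per_s: float = 800.0
    leak_rate_counts_per_s: float = 0.0

    def __post_init__(self) -> None:
        if self.pump_rate_counts_per_s <= 0 or self.vent_rate_counts_per_s <= 0:
            raise ValueError("pump and vent rates must be positive")
        if self.leak_rate_counts_per_s < 0:
            raise ValueError("leak rate must be non-negative")

    @classmethod
    def ideal(cls) -> "PlantParams":
        """Effectively instantaneous transitions (one controller tick)."""
        return cls(pump_rate_counts_per_s=1e7, vent_rate_counts_per_s=1e7)

    @classmethod
    def slow_pump(cls) -> "PlantParams":
        """Underpowered pump: pressurization takes longer than a beat
        interval at after-exercise heart rates."""
        return cls(pump_rate_counts_per_s=300.0, vent_rate_counts_per_s=800.0)


def plant_step(
    state: PlantState,
    pump_on: bool,
    valve_open: bool,
    dt: float,
    params: PlantParams,
) -> PlantState:
    """Advance the plant by ``dt`` seconds under the given commands.

    Pump with valve closed raises pressure at the pump rate; an open
    valve vents at the vent rate (floored at 0); with everything shut
    the pressure holds minus any leak.  Running the pump against an
    open valve is legal (net rate) but almost certainly a controller
    bug, so it raises a warning.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if pump_on and valve_open:
        warnings.warn("pump running with valve open; net rate applied", stacklevel=2)
    rate = 0.0
    if pump_on:
        rate += params.pump_rate_counts_per_s
    if valve_open:
        rate -= params.vent_rate_counts_per_s
    else:
        rate -= params.leak_rate_counts_per_s
    pressure = max(0.0, state.pressure_counts + rate * dt)
    return replace(
        state,
        pressure_counts=pressure,
        pump_on=pump_on,
        valve_open=valve_open,
        t_s=state.t_s + dt,
    )
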