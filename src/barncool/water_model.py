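"""Sprinkler duty-cycle water accounting and occupancy-driven savings.

The barn's evaporative-cooling sprinklers run on a temperature-triggered
duty cycle: above a low threshold (22.2 degC) each sprinkler runs 1 min in
every 15; above a high threshold (32.2 degC) it runs 1 min in every 5 —
three times as often. Each sprinkler draws 2.83 L/min while on, and three
sprinklers serve each of six headgate sections.

If a section's headgates are empty, the water dispensed there is wasted.
The savings model converts the average empty duration per section (from
the occupancy pipeline) into annual seconds of avoidable sprinkler
activity, by scaling the observed footage back to full sprinkler-on days:

    savings_s = mean_empty_s x sprinklers x scale x freq x days

where ``scale`` is daily sprinkler-on minutes over observed footage
minutes (at printed precision, e.g. 5.71 = 600/105) and ``freq`` is 1 for
the low band or 3 for the high band. Annual scenarios then follow a fixed
rounding convention: per-section minutes are truncated, barn-wide minutes
are minutes x sections, and liters are rounded to the nearest liter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import floor
from typing import Literal

__all__ = [
    "SprinklerSchedule",
    "ClimateSummary",
    "SavingsInputs",
    "BandSavings",
    "SavingsReport",
    "scheduled_on_minutes",
    "consumption_liters",
    "savings_seconds",
    "scenario_report",
]


@dataclass(frozen=True)
class ClimateSummary:
    """Days and mean daily hours above each sprinkler-trigger threshold.

    The two bands are tallied independently by the weather service (a day
    above the high threshold also counts its low-band hours), so no
    ordering between the counts is enforced.
    """

    days_above_low: float = 123
    hours_per_day_low: float = 10.0
    days_above_high: float = 7
    hours_per_day_high: float = 7.0

    def __post_init__(self) -> None:
        for name in ("days_above_low", "hours_per_day_low",
                     "days_above_high", "hours_per_day_high"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SprinklerSchedule:
    """Temperature-triggered duty cycle and flow of the barn sprinklers."""

    low_threshold_c: float = 22.2
    high_threshold_c: float = 32.2
    low_period_min: float = 15.0
    high_period_min: float = 5.0
    on_duration_min: float = 1.0
    flow_l_per_min: float = 2.83
    sprinklers_per_section: int = 3
    n_sections: int = 6

    def __post_init__(self) -> None:
        if self.on_duration_min > min(self.low_period_min, self.high_period_min):
            raise ValueError("on duration cannot exceed the cycle period")
        if self.flow_l_per_min <= 0:
            raise ValueError("flow must be positive")
        if self.sprinklers_per_section < 1 or self.n_sections < 1:
            raise ValueError("sprinkler and section counts must be >= 1")

    def period_min(self, band: Literal["low", "high"]) -> float:
        return self.low_period_min if band == "low" else self.high_period_min


@dataclass(frozen=True)
class SavingsInputs:
    """Inputs to the per-band savings product.

    ``mean_empty_s`` is the occupancy pipeline's average empty-interval
    duration per section; ``scale`` the printed footage-to-day factor;
    ``freq_multiplier`` 1 in the low band, 3 in the high band (the 5-min
    cycle fires three times as often as the 15-min cycle).
    """

    mean_empty_s: float
    scale: float
    days: float
    freq_multiplier: int = 1

    def __post_init__(self) -> None:
        if self.mean_empty_s < 0 or self.scale <= 0 or self.days < 0:
            raise ValueError("savings inputs must be non-negative (scale positive)")
        if self.freq_multiplier not in (1, 3):
            raise ValueError("freq_multiplier must be 1 (low band) or 3 (high band)")


@dataclass(frozen=True)
class BandSavings:
    band: Literal["low", "high"]
    seconds_per_section: float


@dataclass(frozen=True)
class SavingsReport:
    """Annual savings for one scenario, with the fixed rounding convention.

    ``minutes_per_section = floor(seconds_per_section / 60)`` (truncated),
    ``total_minutes = minutes_per_section x n_sections``, and
    ``liters = round(total_minutes x flow)``.
    """

    bands: tuple[BandSavings, ...]
    seconds_per_section: float
    minutes_per_section: int
    total_minutes: int
    liters: int
    n_sections: int
    flow_l_per_min: float

    def to_dict(self) -> dict:
        return {
            "bands": {b.band: b.seconds_per_section for b in self.bands},
            "seconds_per_section": self.seconds_per_section,
            "minutes_per_section": self.minutes_per_section,
            "total_minutes": self.total_minutes,
            "liters": self.liters,
            "n_sections": self.n_sections,
            "flow_l_per_min": self.flow_l_per_min,
        }


def scheduled_on_minutes(schedule: SprinklerSchedule, climate: ClimateSummary,
                         band: Literal["low", "high"]) -> float:
    """Annual on-minutes per sprinkler for one temperature band.

    days x hours/day x cycles/hour x on-minutes/cycle; e.g. 123 d x 10 h x
    4/h x 1 min = 4920 min in the low band.
    """
    if band == "low":
        days, hours = climate.days_above_low, climate.hours_per_day_low
    elif band == "high":
        days, hours = climate.days_above_high, climate.hours_per_day_high
    else:
        raise ValueError(f"band must be 'low' or 'high', got {band!r}")
    cycles_per_hour = 60.0 / schedule.period_min(band)
    return days * hours * cycles_per_hour * schedule.on_duration_min


def consumption_liters(on_minutes: float, schedule: SprinklerSchedule,
                       per: Literal["sprinkler", "section", "barn"] = "sprinkler"
                       ) -> float:
    """Water drawn for a given number of on-minutes, at sprinkler/section/barn scope."""
    if on_minutes < 0:
        raise ValueError("on_minutes must be non-negative")
    mult = {
        "sprinkler": 1,
        "section": schedule.sprinklers_per_section,
        "barn": schedule.sprinklers_per_section * schedule.n_sections,
    }[per]
    return on_minutes * schedule.flow_l_per_min * mult


def savings_seconds(inputs: SavingsInputs, schedule: SprinklerSchedule) -> float:
    """Annual avoidable sprinkler seconds per section for one band."""
    return (inputs.mean_empty_s
            * schedule.sprinklers_per_section
            * inputs.scale
            * inputs.freq_multiplier
            * inputs.days)


def scenario_report(low_inputs: SavingsInputs, high_inputs: SavingsInputs,
                    schedule: SprinklerSchedule | None = None) -> SavingsReport:
    """Combine low- and high-band savings into an annual scenario report."""
    if schedule is None:
        schedule = SprinklerSchedule()
    low_s = savings_seconds(low_inputs, schedule)
    high_s = savings_seconds(high_inputs, schedule)
    total_s = low_s + high_s
    minutes = floor(total_s / 60.0)
    total_minutes = minutes * schedule.n_sections
    liters = round(total_minutes * schedule.flow_l_per_min)
    return SavingsReport(
        bands=(BandSavings("low", low_s), BandSavings("high", high_s)),
        seconds_per_section=total_s,
        minutes_per_section=minutes,
        total_minutes=total_minutes,
        liters=int(liters),
        n_sections=schedule.n_sections,
        flow_l_per_min=schedule.flow_l_per_min,
    )
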