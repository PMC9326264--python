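"""Per-chamber lighting schedules and the time-lapse sampling plan.

A chamber schedule is a minute-resolution table driving three channels:

* daylight — on exactly between local sunrise and sunset;
* moonlight — a PWM duty cycle (0-100%) proportional to the normalized
  lunar brightness index, dark by day;
* ALAN — the treatment's constant illuminance, dusk-to-dawn (the photocell
  switches it on whenever the daylight channel is off).

The sampling plan reproduces the observation arithmetic of the study design:
one frame every `interval_min` minutes across an inclusive `span_h`-hour
window (so 5 min / 24 h gives 289 frames), on every second night of the
period, for each animal in each chamber.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from moonsim.ephemeris import GeoLocation, sun_rise_set

__all__ = ["Treatment", "STUDY_TREATMENTS", "SamplingPlan", "build_schedule", "sampling_plan"]

_ALLOWED_ALAN_LUX = (0.0, 0.1, 0.5, 1.0, 10.0, 50.0)


@dataclass(frozen=True)
class Treatment:
    """One ALAN treatment chamber.

    ``mitigation`` marks the long-pass (>= 510 nm) filtered variant, used in
    the study at 10 lx only; it is meaningless without ALAN.
    """

    alan_lux: float
    mitigation: bool = False
    chamber_id: str = ""

    def __post_init__(self) -> None:
        if self.alan_lux not in _ALLOWED_ALAN_LUX:
            raise ValueError(f"alan_lux must be one of {_ALLOWED_ALAN_LUX}")
        if self.mitigation and self.alan_lux == 0:
            raise ValueError("mitigation filter requires alan_lux > 0")

    @property
    def label(self) -> str:
        if self.alan_lux == 0:
            return "control"
        base = f"{self.alan_lux:g}lx"
        return base + "-mit" if self.mitigation else base


#: The study's seven chambers: control, 0.1, 0.5, 1, 10, 10-mitigation, 50 lx.
STUDY_TREATMENTS: tuple[Treatment, ...] = (
    Treatment(0.0, chamber_id="C1"),
    Treatment(0.1, chamber_id="C2"),
    Treatment(0.5, chamber_id="C3"),
    Treatment(1.0, chamber_id="C4"),
    Treatment(10.0, chamber_id="C5"),
    Treatment(10.0, mitigation=True, chamber_id="C6"),
    Treatment(50.0, chamber_id="C7"),
)


def build_schedule(
    loc: GeoLocation,
    start: date,
    end: date,
    treatment: Treatment,
    brightness: pd.DataFrame,
) -> pd.DataFrame:
    """Minute-resolution lighting plan for one chamber over [start, end].

    `brightness` must be a normalized brightness series (with an ``index``
    column) covering the date range at 1-minute resolution.  Returns columns
    timestamp_utc, daylight_on, moon_duty_pct, moon_lux, alan_on, alan_lux.
    """
    ts = pd.DatetimeIndex(brightness["timestamp_utc"])
    if "index" not in brightness.columns:
        raise ValueError("brightness series is not normalized (no 'index' column)")
    t0 = pd.Timestamp(start, tz="UTC")
    t1 = pd.Timestamp(end, tz="UTC") + pd.Timedelta(days=1)
    sel = (ts >= t0) & (ts < t1)
    sub = brightness.loc[sel].reset_index(drop=True)
    expected = int((t1 - t0) / pd.Timedelta(minutes=1))
    if len(sub) != expected:
        raise ValueError(
            f"brightness series covers {len(sub)} of the {expected} minutes "
            f"in {start}..{end}"
        )
    sub_ts = pd.DatetimeIndex(sub["timestamp_utc"])

    daylight = np.zeros(len(sub), dtype=bool)
    day = start
    while day <= end:
        rise, sset = sun_rise_set(loc, day)
        daylight |= (sub_ts >= rise) & (sub_ts < sset)
        day += timedelta(days=1)

    index = sub["index"].to_numpy()
    moon_duty = np.where(daylight, 0.0, 100.0 * index)
    moon_lux = np.where(daylight, 0.0, sub["lux"].to_numpy())
    alan_on = ~daylight if treatment.alan_lux > 0 else np.zeros(len(sub), dtype=bool)
    return pd.DataFrame(
        {
            "timestamp_utc": sub_ts,
            "daylight_on": daylight,
            "moon_duty_pct": moon_duty,
            "moon_lux": moon_lux,
            "alan_on": alan_on,
            "alan_lux": np.where(alan_on, treatment.alan_lux, 0.0),
        }
    )


@dataclass(frozen=True)
class SamplingPlan:
    """Time-lapse observation arithmetic."""

    interval_min: int
    span_h: int
    nights: tuple[int, ...]  # observation night indices within the period
    chambers: int
    animals_per_chamber: int

    @property
    def frames_per_24h(self) -> int:
        return self.span_h * 60 // self.interval_min + 1

    @property
    def total_frames(self) -> int:
        return (
            self.frames_per_24h
            * self.chambers
            * self.animals_per_chamber
            * len(self.nights)
        )


def sampling_plan(
    interval_min: int = 5,
    span_h: int = 24,
    period_days: int = 28,
    cadence_nights: int = 2,
    dropped_nights: tuple[int, ...] = (21,),
    chambers: int = 7,
    animals_per_chamber: int = 12,
) -> SamplingPlan:
    """Every `cadence_nights`-th night of the period, minus dropped nights.

    Defaults give the study plan: a photo every 5 min for 24 h (289 frames,
    endpoints inclusive), every second night over 28 days, night 21 lost,
    hence 13 observation nights and 289 x 7 x 12 x 13 = 315,588 frames.
    """
    for name, v in [("interval_min", interval_min), ("span_h", span_h),
                    ("period_days", period_days), ("cadence_nights", cadence_nights)]:
        if not (isinstance(v, (int, np.integer)) and v > 0):
            raise ValueError(f"{name} must be a positive integer")
    if (span_h * 60) % interval_min != 0:
        raise ValueError("interval must divide the span evenly")
    scheduled = list(range(1, period_days + 1, cadence_nights))
    bad = set(dropped_nights) - set(scheduled)
    if bad:
        raise ValueError(f"dropped nights {sorted(bad)} are not scheduled nights")
    nights = tuple(n for n in scheduled if n not in set(dropped_nights))
    return SamplingPlan(
        interval_min=int(interval_min),
        span_h=int(span_h),
        nights=nights,
        chambers=int(chambers),
        animals_per_chamber=int(animals_per_chamber),
    )
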