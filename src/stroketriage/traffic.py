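"""Hourly directional travel-time profiles and baseline-relative deltas.

A :class:`TrafficProfile` holds 24 hourly drive times for one day type
(weekday or weekend) and one direction (urban→suburban or suburban→urban).
The signed difference between an hour's drive time and the 3 a.m. free-flow
baseline is the *traffic delta*: the delay (positive) or acceleration
(negative) a transport departing at that hour experiences.  Deltas measured
on one reference route are applied as absolute minutes to every transport
in the same direction, regardless of route length; a proportional mode
(delta scaled by route time relative to the reference route) exists behind
a flag and is off by default.

Each paradigm cares about a different direction: drip-and-ship transfers
and mothership rides move the patient toward the urban comprehensive
center (suburban→urban), while the drip-and-drive interventionalist drives
outward (urban→suburban).

The module bundles reference profiles whose summary statistics match the
study setting: on weekdays the urban→suburban direction averages 66 min
with a 93 min peak at 16:00 and the suburban→urban direction averages
65 min with peaks of 90 min at 07:00 and 78 min at 16:00; at weekends both
directions average 57 min with maxima of 65 and 60 min.  The hourly values
themselves are smooth curves constructed to those constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np
import pandas as pd

from .outcome import ConfigurationError

__all__ = [
    "DayType",
    "Direction",
    "TrafficProfile",
    "delta",
    "paradigm_deltas",
    "summarize_profile",
    "reference_profiles",
    "read_profiles_csv",
    "write_profiles_csv",
]

DAY_TYPES = ("weekday", "weekend")
DIRECTIONS = ("urban_to_suburban", "suburban_to_urban")

DayType = str
Direction = str

# Reference hourly drive times (minutes) for the 68 km urban<->suburban
# corridor, hours 0-23.  Constructed to reproduce the printed means, maxima
# and peak hours quoted in the module docstring.
_REFERENCE_TIMES: Dict[Tuple[str, str], Tuple[int, ...]] = {
    ("weekday", "urban_to_suburban"): (
        55, 53, 52, 52, 53, 55, 59, 63, 65, 66, 65, 66,
        71, 76, 81, 88, 93, 88, 83, 66, 62, 59, 57, 56,
    ),
    ("weekday", "suburban_to_urban"): (
        55, 53, 52, 52, 53, 56, 76, 90, 84, 72, 68, 66,
        66, 67, 70, 75, 78, 69, 65, 62, 60, 58, 57, 56,
    ),
    ("weekend", "urban_to_suburban"): (
        53, 53, 52, 52, 52, 53, 54, 54, 55, 56, 58, 59,
        65, 65, 65, 65, 60, 59, 58, 58, 57, 56, 55, 54,
    ),
    ("weekend", "suburban_to_urban"): (
        57, 56, 55, 55, 55, 55, 55, 56, 57, 57, 57, 58,
        59, 60, 60, 60, 60, 59, 58, 57, 56, 55, 55, 56,
    ),
}


@dataclass(frozen=True)
class TrafficProfile:
    """24 hourly drive times for one day type and direction."""

    day_type: DayType
    direction: Direction
    times: tuple = field(default_factory=tuple)
    baseline_hour: int = 3

    def __post_init__(self) -> None:
        if self.day_type not in DAY_TYPES:
            raise ConfigurationError(f"unknown day_type {self.day_type!r}")
        if self.direction not in DIRECTIONS:
            raise ConfigurationError(f"unknown direction {self.direction!r}")
        times = tuple(float(t) for t in self.times)
        if len(times) != 24:
            raise ConfigurationError("a profile needs exactly 24 hourly values")
        if any(t <= 0 for t in times):
            raise ConfigurationError("travel times must be positive")
        if not 0 <= self.baseline_hour <= 23:
            raise ConfigurationError("baseline_hour must be in 0..23")
        object.__setattr__(self, "times", times)

    @property
    def baseline_time(self) -> float:
        return self.times[self.baseline_hour]


def delta(profile: TrafficProfile, hour: int) -> float:
    """Signed drive-time delta (minutes) relative to the free-flow baseline."""
    if not (isinstance(hour, (int, np.integer)) and 0 <= hour <= 23):
        raise ValueError(f"hour must be an integer in 0..23, got {hour!r}")
    return profile.times[hour] - profile.baseline_time


ProfileSet = Mapping[Tuple[DayType, Direction], TrafficProfile]


def paradigm_deltas(profiles: ProfileSet, day_type: DayType, hour: int) -> Dict[str, float]:
    """Per-paradigm traffic delta (minutes) for one dispatch hour.

    Drip-and-drive follows the urban→suburban direction (the
    interventionalist drives out); drip-and-ship and mothership both move
    the patient toward the urban center and follow suburban→urban.
    """
    try:
        us = profiles[(day_type, "urban_to_suburban")]
        su = profiles[(day_type, "suburban_to_urban")]
    except KeyError as exc:
        raise ConfigurationError(
            f"missing traffic profile {exc.args[0]!r}; both directions are "
            f"required for day_type={day_type!r}"
        ) from None
    d_su = delta(su, hour)
    return {
        "mothership": d_su,
        "drip_and_ship": d_su,
        "drip_and_drive": delta(us, hour),
    }


def summarize_profile(profile: TrafficProfile) -> Dict[str, object]:
    """Mean, maximum, peak hour and below-mean hours of a profile."""
    t = np.asarray(profile.times)
    mean = float(t.mean())
    argmax = int(t.argmax())
    return {
        "mean": mean,
        "max": float(t.max()),
        "argmax_hour": argmax,
        "hours_at_or_below_mean": [int(h) for h in np.flatnonzero(t <= mean)],
    }


def reference_profiles() -> Dict[Tuple[DayType, Direction], TrafficProfile]:
    """The bundled weekday/weekend directional profiles (see module docs)."""
    return {
        key: TrafficProfile(day_type=key[0], direction=key[1], times=times)
        for key, times in _REFERENCE_TIMES.items()
    }


def read_profiles_csv(path) -> Dict[Tuple[DayType, Direction], TrafficProfile]:
    """Load profiles from a CSV with columns day_type, direction, hour, minutes.

    Every (day_type, direction) group present must contain exactly the 24
    hours 0-23; incomplete groups are a configuration error.
    """
    df = pd.read_csv(path)
    required = {"day_type", "direction", "hour", "minutes"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"traffic CSV lacks columns: {sorted(missing)}")
    out: Dict[Tuple[str, str], TrafficProfile] = {}
    for (day_type, direction), grp in df.groupby(["day_type", "direction"], sort=True):
        grp = grp.sort_values("hour")
        hours = grp["hour"].to_numpy()
        if len(hours) != 24 or not np.array_equal(hours, np.arange(24)):
            raise ConfigurationError(
                f"profile ({day_type}, {direction}) must list hours 0..23 exactly once"
            )
        out[(day_type, direction)] = TrafficProfile(
            day_type=day_type,
            direction=direction,
            times=tuple(grp["minutes"].astype(float)),
        )
    return out


def write_profiles_csv(profiles: ProfileSet, path) -> None:
    rows: Iterable = (
        (p.day_type, p.direction, hour, minutes)
        for p in profiles.values()
        for hour, minutes in enumerate(p.times)
    )
    df = pd.DataFrame(rows, columns=["day_type", "direction", "hour", "minutes"])
    df.sort_values(["day_type", "direction", "hour"]).to_csv(path, index=False)
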