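"""Onset-to-needle and onset-to-groin timelines for the three paradigms.

Each transport paradigm turns travel times plus fixed workflow intervals
into two clinically decisive numbers: the onset-to-needle time (start of
intravenous thrombolysis) and the onset-to-groin time (endovascular groin
puncture).

* mothership — drive straight to a comprehensive stroke center (CSC/CSC+),
  bypassing closer primary stroke centers (PSC); a traffic delta shifts
  both door-to-needle and door-to-groin.
* drip-and-ship — thrombolyse at the nearest PSC, then transfer the
  patient; if the patient reaches the CSC within 90 min of first imaging
  at the PSC no reimaging is needed and door-to-groin drops from 60 to
  30 min; the delta shifts door-to-groin.
* drip-and-drive — thrombolyse at the PSC while the neurointerventionalist
  drives out from the CSC+; the delta shifts the arrival-to-groin interval.

The scalar functions additionally return an audit trace of named event
timestamps; the ``*_times`` helpers are vectorised over numpy arrays and
carry the identical arithmetic for whole grids of travel times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Paradigm",
    "WorkflowTimes",
    "ParadigmTimeline",
    "mothership_timeline",
    "drip_and_ship_timeline",
    "drip_and_drive_timeline",
    "mothership_times",
    "drip_and_ship_times",
    "drip_and_drive_times",
]


class Paradigm(str, Enum):
    MOTHERSHIP = "mothership"
    DRIP_AND_SHIP = "drip_and_ship"
    DRIP_AND_DRIVE = "drip_and_drive"


@dataclass(frozen=True)
class WorkflowTimes:
    """Fixed prehospital and in-hospital intervals, all in minutes.

    Defaults follow commonly proposed quality targets: 30 min from onset to
    first medical response, 30 min ambulance on-scene time, PSC
    door-to-needle 30 / needle-to-door 20, CSC door-to-needle 30 and
    door-to-groin 60 (30 when the reimaging window of 90 min is met).  In
    drip-and-drive the interventionalist leaves 10 min after needle and
    needs 20 min from PSC arrival to groin puncture.
    """

    onset_to_fmr: float = 30.0
    on_scene: float = 30.0
    dtn_psc: float = 30.0
    ntd_psc: float = 20.0
    dtn_csc: float = 30.0
    dtg_csc: float = 60.0
    dtg_csc_fast: float = 30.0
    reimage_window: float = 90.0
    ntl_dd: float = 10.0
    arr_to_groin_dd: float = 20.0
    imaging_offset_psc: float = 0.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.dtg_csc_fast > self.dtg_csc:
            raise ValueError("dtg_csc_fast may not exceed dtg_csc")

    @property
    def prehospital(self) -> float:
        """Onset to scene departure: first medical response + on-scene time."""
        return self.onset_to_fmr + self.on_scene


@dataclass(frozen=True)
class ParadigmTimeline:
    paradigm: Paradigm
    t_needle: float
    t_groin: float
    trace: tuple = field(default_factory=tuple)  # ordered (event, minutes from onset)

    def __post_init__(self) -> None:
        stamps = [t for _, t in self.trace]
        if any(b < a for a, b in zip(stamps, stamps[1:])):
            raise ValueError("trace timestamps must be non-decreasing")


def _clamped(interval, delta):
    """Interval shifted by a signed traffic delta, floored at zero."""
    shifted = interval + delta
    lo = np.minimum(shifted, 0)
    if np.any(lo < 0):
        warnings.warn(
            "traffic acceleration would make an in-hospital interval negative; "
            "clamping at 0",
            stacklevel=3,
        )
    return np.maximum(shifted, 0.0)


def _check_nonneg(**kwargs) -> None:
    for name, v in kwargs.items():
        if np.any(np.asarray(v) < 0):
            raise ValueError(f"{name} must be non-negative")


def mothership_times(t_travel_to_csc, delta, w: WorkflowTimes):
    """Vectorised (t_needle, t_groin) for direct-to-CSC transport."""
    _check_nonneg(t_travel_to_csc=t_travel_to_csc)
    door = w.prehospital + np.asarray(t_travel_to_csc, dtype=float)
    t_needle = door + _clamped(w.dtn_csc, delta)
    t_groin = door + _clamped(w.dtg_csc, delta)
    return t_needle, t_groin


def drip_and_ship_times(t_travel_to_psc, t_transfer_psc_to_csc, delta, w: WorkflowTimes):
    """Vectorised (t_needle, t_groin, csc_door) for PSC-then-transfer transport."""
    _check_nonneg(
        t_travel_to_psc=t_travel_to_psc,
        t_transfer_psc_to_csc=t_transfer_psc_to_csc,
    )
    psc_door = w.prehospital + np.asarray(t_travel_to_psc, dtype=float)
    t_needle = psc_door + w.dtn_psc
    depart = t_needle + w.ntd_psc
    csc_door = depart + np.asarray(t_transfer_psc_to_csc, dtype=float)
    imaging = psc_door + w.imaging_offset_psc
    fast = (csc_door - imaging) <= w.reimage_window
    dtg = np.where(fast, w.dtg_csc_fast, w.dtg_csc)
    t_groin = csc_door + _clamped(dtg, delta)
    return t_needle, t_groin, csc_door


def drip_and_drive_times(t_travel_to_psc, t_interventionalist_travel, delta, w: WorkflowTimes):
    """Vectorised (t_needle, t_groin) for the travelling-interventionalist paradigm."""
    _check_nonneg(
        t_travel_to_psc=t_travel_to_psc,
        t_interventionalist_travel=t_interventionalist_travel,
    )
    psc_door = w.prehospital + np.asarray(t_travel_to_psc, dtype=float)
    t_needle = psc_door + w.dtn_psc
    arrive = t_needle + w.ntl_dd + np.asarray(t_interventionalist_travel, dtype=float)
    t_groin = arrive + _clamped(w.arr_to_groin_dd, delta)
    # Guard for user-supplied constants where the patient chain could lag
    # behind the interventionalist chain; a no-op with the defaults.
    t_groin = np.maximum(t_groin, t_needle)
    return t_needle, t_groin


def mothership_timeline(
    t_travel_to_csc: float, delta: float, w: WorkflowTimes
) -> ParadigmTimeline:
    """Timeline for direct transport to the nearest CSC/CSC+.

    The traffic delta (signed minutes, positive = delay) is added to both
    the door-to-needle and the door-to-groin interval at the CSC.
    """
    t_needle, t_groin = mothership_times(t_travel_to_csc, delta, w)
    door = w.prehospital + t_travel_to_csc
    trace = (
        ("onset", 0.0),
        ("first_medical_response", w.onset_to_fmr),
        ("scene_departure", w.prehospital),
        ("csc_door", door),
        ("needle", float(t_needle)),
        ("groin_puncture", float(t_groin)),
    )
    return ParadigmTimeline(Paradigm.MOTHERSHIP, float(t_needle), float(t_groin), trace)


def drip_and_ship_timeline(
    t_travel_to_psc: float,
    t_transfer_psc_to_csc: float,
    delta: float,
    w: WorkflowTimes,
) -> ParadigmTimeline:
    """Timeline for thrombolysis at the PSC followed by patient transfer.

    If the patient reaches the CSC door within ``w.reimage_window`` minutes
    of first imaging at the PSC (inclusive), reimaging is skipped and the
    fast door-to-groin time applies.  The traffic delta shifts the
    door-to-groin interval at the receiving CSC.
    """
    t_needle, t_groin, csc_door = drip_and_ship_times(
        t_travel_to_psc, t_transfer_psc_to_csc, delta, w
    )
    psc_door = w.prehospital + t_travel_to_psc
    trace = (
        ("onset", 0.0),
        ("first_medical_response", w.onset_to_fmr),
        ("scene_departure", w.prehospital),
        ("psc_door", psc_door),
        ("needle", float(t_needle)),
        ("psc_departure", float(t_needle) + w.ntd_psc),
        ("csc_door", float(csc_door)),
        ("groin_puncture", float(t_groin)),
    )
    return ParadigmTimeline(
        Paradigm.DRIP_AND_SHIP, float(t_needle), float(t_groin), trace
    )


def drip_and_drive_timeline(
    t_travel_to_psc: float,
    t_interventionalist_travel: float,
    delta: float,
    w: WorkflowTimes,
) -> ParadigmTimeline:
    """Timeline for thrombolysis at the PSC with an out-driving interventionalist.

    The interventionalist leaves the CSC+ ``w.ntl_dd`` minutes after needle
    and punctures ``w.arr_to_groin_dd`` minutes after reaching the PSC; the
    traffic delta shifts that arrival-to-groin interval.
    """
    t_needle, t_groin = drip_and_drive_times(
        t_travel_to_psc, t_interventionalist_travel, delta, w
    )
    psc_door = w.prehospital + t_travel_to_psc
    leave = float(t_needle) + w.ntl_dd
    trace = (
        ("onset", 0.0),
        ("first_medical_response", w.onset_to_fmr),
        ("scene_departure", w.prehospital),
        ("psc_door", psc_door),
        ("needle", float(t_needle)),
        ("interventionalist_leave", leave),
        ("interventionalist_arrival", leave + t_interventionalist_travel),
        ("groin_puncture", float(t_groin)),
    )
    return ParadigmTimeline(
        Paradigm.DRIP_AND_DRIVE, float(t_needle), float(t_groin), trace
    )
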