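"""Expected probability of good outcome for a screen-positive stroke patient.

The clinical endpoint is a modified Rankin Scale score of 0-1 at 90 days.
A patient who screens positive for a probable large-vessel occlusion (LVO)
on a prehospital severity scale is in truth a mixture of three groups: true
LVO, non-LVO ischaemic stroke, and mimics/other.  Each treated group has a
time-decay curve giving the probability of good outcome as a non-increasing
function of onset-to-treatment time; untreated and mimic outcomes are
time-constant.  :func:`expected_good_outcome` composes these pieces into a
single expectation given the onset-to-needle (IVT) and onset-to-groin (EVT)
times a transport paradigm achieves.

The composition used here is a documented reconstruction: it honours the
stated treatment rates (90 % of LVO patients receive EVT; 80 % of LVO and
non-LVO patients with onset-to-needle under 4.5 h receive IVT) and
attributes an EVT-treated patient's outcome to the EVT curve alone.  The
shipped decay-curve parameters are synthetic placeholders; supply published
coefficients for any real-world use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.special import expit

__all__ = [
    "DecayCurve",
    "CohortMix",
    "TreatmentRates",
    "ConfigurationError",
    "curve_value",
    "expected_good_outcome",
]

_CURVE_KINDS = ("logistic", "linear", "constant")


class ConfigurationError(ValueError):
    """A required model component is missing or inconsistent."""


@dataclass(frozen=True)
class DecayCurve:
    """Probability of good outcome as a function of onset-to-treatment time.

    Parameters
    ----------
    kind:
        ``"logistic"``, ``"linear"`` or ``"constant"``.
    p0:
        Probability at t = 0 (treatment at onset).
    p_floor:
        Probability at and beyond the end of the treatment window.
    t_max:
        Treatment-window length in minutes; the curve is ``p_floor`` for
        every t >= t_max.
    shape:
        Steepness scale in minutes for the logistic kind (midpoint at
        t_max / 2); ignored by the linear and constant kinds.
    """

    kind: str
    p0: float
    p_floor: float
    t_max: float = 480.0
    shape: float = 90.0

    def __post_init__(self) -> None:
        if self.kind not in _CURVE_KINDS:
            raise ConfigurationError(f"unknown curve kind {self.kind!r}")
        if not (0.0 <= self.p_floor <= self.p0 <= 1.0):
            raise ConfigurationError(
                f"need 0 <= p_floor <= p0 <= 1, got p0={self.p0}, p_floor={self.p_floor}"
            )
        if self.t_max <= 0:
            raise ConfigurationError("t_max must be positive")
        if self.kind == "logistic" and self.shape <= 0:
            raise ConfigurationError("logistic shape must be positive")

    def __call__(self, t):
        return curve_value(self, t)


def curve_value(curve: DecayCurve, t):
    """Evaluate a decay curve at onset-to-treatment time ``t`` (minutes).

    Accepts scalars or numpy arrays.  Values are clamped to
    [p_floor, p0], and every t >= t_max maps to p_floor.  Negative times
    are a domain error.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("onset-to-treatment time must be non-negative")
    if curve.kind == "constant":
        inside = np.full_like(t, curve.p0)
    elif curve.kind == "linear":
        inside = curve.p0 + (curve.p_floor - curve.p0) * t / curve.t_max
    else:  # logistic, rescaled so value(0) = p0 and value(t_max) = p_floor
        mid = curve.t_max / 2.0
        g = expit((mid - t) / curve.shape)
        g0 = expit(mid / curve.shape)
        g1 = expit((mid - curve.t_max) / curve.shape)
        span = g0 - g1
        frac = (g - g1) / span if span > 0 else np.zeros_like(g)
        inside = curve.p_floor + (curve.p0 - curve.p_floor) * frac
    out = np.where(t >= curve.t_max, curve.p_floor, inside)
    out = np.clip(out, curve.p_floor, curve.p0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CohortMix:
    """Composition of the screen-positive cohort and its untreated outcomes.

    ``p_lvo`` + ``p_nlvo`` + ``p_other`` must equal 1.  ``p_good_other`` is
    the time-constant good-outcome probability for mimics/other;
    ``p_good_lvo_untreated`` and ``p_good_nlvo_untreated`` apply when the
    respective group receives no reperfusion therapy.
    """

    p_lvo: float = 0.6
    p_nlvo: float = 0.3
    p_other: float = 0.1
    p_good_other: float = 0.90
    p_good_lvo_untreated: float = 0.10
    p_good_nlvo_untreated: float = 0.35

    def __post_init__(self) -> None:
        for name in (
            "p_lvo", "p_nlvo", "p_other",
            "p_good_other", "p_good_lvo_untreated", "p_good_nlvo_untreated",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if abs(self.p_lvo + self.p_nlvo + self.p_other - 1.0) > 1e-9:
            raise ConfigurationError("cohort fractions must sum to 1")


@dataclass(frozen=True)
class TreatmentRates:
    """Treatment uptake and the IVT eligibility window.

    ``evt_rate`` is the probability an LVO patient receives endovascular
    therapy; ``ivt_rate`` the probability an eligible patient receives
    intravenous thrombolysis; ``ivt_window`` the onset-to-needle limit in
    minutes (strict: eligibility requires t_needle < ivt_window).
    """

    evt_rate: float = 0.90
    ivt_rate: float = 0.80
    ivt_window: float = 270.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.evt_rate <= 1.0 and 0.0 <= self.ivt_rate <= 1.0):
            raise ConfigurationError("treatment rates must lie in [0, 1]")
        if self.ivt_window <= 0:
            raise ConfigurationError("ivt_window must be positive")


def expected_good_outcome(
    t_needle,
    t_groin,
    mix: CohortMix,
    rates: TreatmentRates,
    curves: Mapping[str, DecayCurve],
):
    """Expected good-outcome probability for the screen-positive cohort.

    Parameters
    ----------
    t_needle:
        Onset-to-needle time in minutes, or ``None`` if no IVT pathway.
        Scalars and numpy arrays are both accepted.
    t_groin:
        Onset-to-groin time in minutes, or ``None`` if no EVT pathway.
    curves:
        Mapping with keys ``"evt"``, ``"ivt_lvo"`` and ``"ivt_nlvo"``; a
        curve may be omitted only if its pathway is absent.

    Notes
    -----
    With t_needle present and below the IVT window, an eligible patient
    receives IVT with probability ``ivt_rate``; an LVO patient receives EVT
    with probability ``evt_rate`` (outcome then read from the EVT curve
    alone).  Patients of each group not reaching therapy fall back to their
    untreated probability; mimics contribute ``p_good_other`` throughout.
    """
    evt_open = t_groin is not None
    ivt_open = t_needle is not None

    if ivt_open:
        t_needle = np.asarray(t_needle, dtype=float)
        if np.any(t_needle < 0):
            raise ValueError("t_needle must be non-negative")
        ivt_elig = (t_needle < rates.ivt_window).astype(float)
    else:
        ivt_elig = 0.0
    p_ivt = ivt_elig * rates.ivt_rate

    if evt_open:
        t_groin = np.asarray(t_groin, dtype=float)
        if np.any(t_groin < 0):
            raise ValueError("t_groin must be non-negative")
        if "evt" not in curves:
            raise ConfigurationError("EVT pathway requested but no 'evt' curve given")
        p_evt_treated = curve_value(curves["evt"], t_groin)
        evt_rate = rates.evt_rate
    else:
        p_evt_treated = 0.0
        evt_rate = 0.0

    if ivt_open:
        for key in ("ivt_lvo", "ivt_nlvo"):
            if key not in curves:
                raise ConfigurationError(f"IVT pathway requested but no {key!r} curve given")
        p_ivt_lvo = curve_value(curves["ivt_lvo"], t_needle)
        p_ivt_nlvo = curve_value(curves["ivt_nlvo"], t_needle)
    else:
        p_ivt_lvo = p_ivt_nlvo = 0.0

    lvo_no_evt = p_ivt * p_ivt_lvo + (1.0 - p_ivt) * mix.p_good_lvo_untreated
    lvo_term = evt_rate * p_evt_treated + (1.0 - evt_rate) * lvo_no_evt
    nlvo_term = p_ivt * p_ivt_nlvo + (1.0 - p_ivt) * mix.p_good_nlvo_untreated

    result = (
        mix.p_lvo * lvo_term
        + mix.p_nlvo * nlvo_term
        + mix.p_other * mix.p_good_other
    )
    result = np.asarray(result, dtype=float)
    return float(result) if result.ndim == 0 else result
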