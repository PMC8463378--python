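"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written from first principles in plain
Python — literal term-by-term expectation expansion, step-by-step event
chains, exhaustive nearest-hospital scans — and shares no arithmetic with
the library code it validates.
"""

import math


def linear_curve(p0, p_floor, t_max, t):
    """Linear decay evaluated directly."""
    if t >= t_max:
        return p_floor
    v = p0 + (p_floor - p0) * t / t_max
    return min(p0, max(p_floor, v))


def expected_outcome_expansion(
    t_needle,
    t_groin,
    p_lvo,
    p_nlvo,
    p_other,
    evt_rate,
    ivt_rate,
    ivt_window,
    p_evt,
    p_ivt_lvo,
    p_ivt_nlvo,
    p_good_lvo_untreated,
    p_good_nlvo_untreated,
    p_good_other,
):
    """Literal expansion of the cohort expectation, term by term.

    ``p_evt``, ``p_ivt_lvo`` and ``p_ivt_nlvo`` are callables t -> prob.
    """
    ivt_elig = 1.0 if (t_needle is not None and t_needle < ivt_window) else 0.0
    q = ivt_elig * ivt_rate
    lvo_no_evt = q * (p_ivt_lvo(t_needle) if q else 0.0) + (1 - q) * p_good_lvo_untreated
    term_lvo = p_lvo * (
        evt_rate * (p_evt(t_groin) if t_groin is not None else 0.0)
        + (1 - evt_rate) * lvo_no_evt
    )
    term_nlvo = p_nlvo * (
        q * (p_ivt_nlvo(t_needle) if q else 0.0) + (1 - q) * p_good_nlvo_untreated
    )
    term_other = p_other * p_good_other
    return term_lvo + term_nlvo + term_other


# --- event-chain timelines -------------------------------------------------

def chain_mothership(t_travel, delta, c):
    """Accumulate the mothership event chain step by step. ``c`` is a dict
    of workflow constants."""
    t = 0.0
    t += c["onset_to_fmr"]
    t += c["on_scene"]
    t += t_travel
    needle = t + max(0.0, c["dtn_csc"] + delta)
    groin = t + max(0.0, c["dtg_csc"] + delta)
    return needle, groin


def chain_drip_and_ship(t_psc, t_transfer, delta, c):
    t = 0.0
    t += c["onset_to_fmr"]
    t += c["on_scene"]
    t += t_psc
    psc_door = t
    needle = psc_door + c["dtn_psc"]
    depart = needle + c["ntd_psc"]
    csc_door = depart + t_transfer
    imaging = psc_door + c["imaging_offset_psc"]
    if csc_door - imaging <= c["reimage_window"]:
        dtg = c["dtg_csc_fast"]
    else:
        dtg = c["dtg_csc"]
    groin = csc_door + max(0.0, dtg + delta)
    return needle, groin


def chain_drip_and_drive(t_psc, t_iv, delta, c):
    t = 0.0
    t += c["onset_to_fmr"]
    t += c["on_scene"]
    t += t_psc
    needle = t + c["dtn_psc"]
    arrive = needle + c["ntl_dd"] + t_iv
    groin = arrive + max(0.0, c["arr_to_groin_dd"] + delta)
    return needle, max(groin, needle)


WORKFLOW_CONSTANTS = {
    "onset_to_fmr": 30.0,
    "on_scene": 30.0,
    "dtn_psc": 30.0,
    "ntd_psc": 20.0,
    "dtn_csc": 30.0,
    "dtg_csc": 60.0,
    "dtg_csc_fast": 30.0,
    "reimage_window": 90.0,
    "ntl_dd": 10.0,
    "arr_to_groin_dd": 20.0,
    "imaging_offset_psc": 0.0,
}


# --- brute-force per-cell catchment classifier -----------------------------

def brute_classify_cell(point, hospitals, speed, detour, deltas, curve_params):
    """Classify one cell by exhaustive scan + literal expectation expansion.

    ``hospitals`` is a list of (id, level, x, y) tuples with level in
    {"PSC", "CSC", "CSC_PLUS"}; ``deltas`` maps paradigm -> minutes;
    ``curve_params`` maps pathway -> (p0, p_floor, t_max) linear curves.
    Returns the winning label under priority mothership > drip_and_ship >
    drip_and_drive.
    """

    def minutes(a, b):
        return detour * math.hypot(a[0] - b[0], a[1] - b[1]) / speed

    def nearest(frm, levels):
        cands = sorted(h for h in hospitals if h[1] in levels)
        best = min(cands, key=lambda h: (minutes(frm, (h[2], h[3])), h[0]))
        return best, minutes(frm, (best[2], best[3]))

    def outcome(t_needle, t_groin):
        curves = {
            k: (lambda t, p=curve_params[k]: linear_curve(p[0], p[1], p[2], t))
            for k in curve_params
        }
        return expected_outcome_expansion(
            t_needle, t_groin,
            p_lvo=0.6, p_nlvo=0.3, p_other=0.1,
            evt_rate=0.9, ivt_rate=0.8, ivt_window=270.0,
            p_evt=curves["evt"],
            p_ivt_lvo=curves["ivt_lvo"],
            p_ivt_nlvo=curves["ivt_nlvo"],
            p_good_lvo_untreated=0.10,
            p_good_nlvo_untreated=0.35,
            p_good_other=0.90,
        )

    c = WORKFLOW_CONSTANTS
    probs = {}
    _, t_ms = nearest(point, {"CSC", "CSC_PLUS"})
    probs["mothership"] = outcome(*chain_mothership(t_ms, deltas["mothership"], c))

    if any(h[1] == "PSC" for h in hospitals):
        psc, t_psc = nearest(point, {"PSC"})
        psc_xy = (psc[2], psc[3])
        _, t_transfer = nearest(psc_xy, {"CSC", "CSC_PLUS"})
        probs["drip_and_ship"] = outcome(
            *chain_drip_and_ship(t_psc, t_transfer, deltas["drip_and_ship"], c)
        )
        if any(h[1] == "CSC_PLUS" for h in hospitals):
            _, t_iv = nearest(psc_xy, {"CSC_PLUS"})
            probs["drip_and_drive"] = outcome(
                *chain_drip_and_drive(t_psc, t_iv, deltas["drip_and_drive"], c)
            )

    priority = ["mothership", "drip_and_ship", "drip_and_drive"]
    rounded = {k: round(v, 12) for k, v in probs.items()}
    return max(
        (lab for lab in priority if lab in rounded),
        key=lambda lab: (rounded[lab], -priority.index(lab)),
    )
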