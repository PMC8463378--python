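# Methods

## Decision model

The unit of analysis is a patient location (a grid cell) at a dispatch hour.
For each transport paradigm the model builds an event chain from fixed
workflow intervals plus travel times, producing an onset-to-needle time
t_n (start of intravenous thrombolysis, IVT) and an onset-to-groin time
t_g (endovascular therapy, EVT), and evaluates the expected probability of
good outcome (mRS 0–1 at 90 days) over the screen-positive cohort. The cell
is labelled with the argmax paradigm; areas are accumulated per label.

Assumptions baked into the composition:

* The cohort is exactly three groups — true LVO, non-LVO ischaemic stroke,
  mimics/other — with fixed mixing fractions; screening performance is an
  input, not modelled.
* An LVO patient receives EVT with probability `evt_rate` regardless of
  location; an EVT-treated patient's outcome is read from the EVT decay
  curve alone (no additive IVT benefit). IVT reaches `ivt_rate` of LVO and
  non-LVO patients whose t_n is strictly below the 270 min window.
* Untreated and mimic outcomes are time-constant.
* Workflow intervals are deterministic; there is no stochastic variation,
  no hemorrhage-risk term, and no capacity constraint at any hospital.

One structural caveat: the expectation is non-increasing in t_n only when
each IVT curve's floor is at least the corresponding untreated probability.
If a curve dips below its untreated fallback, crossing the eligibility
boundary raises the expectation — treating would then be predicted to harm,
which is a mis-specified curve, not a model feature. The shipped defaults
satisfy the constraint; configurations that violate it are not rejected,
since the curves are user-supplied science.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| onset_to_fmr / on_scene | 30 / 30 | min | standard quality-measure targets for response and scene time |
| dtn_psc / ntd_psc | 30 / 20 | min | PSC door-to-needle and needle-to-door targets |
| dtn_csc / dtg_csc | 30 / 60 | min | CSC door-to-needle / door-to-groin |
| dtg_csc_fast / reimage_window | 30 / 90 | min | transferred patients arriving within 90 min of first PSC imaging skip reimaging |
| ntl_dd / arr_to_groin_dd | 10 / 20 | min | interventionalist leaves 10 min after needle; punctures 20 min after PSC arrival |
| imaging_offset_psc | 0 | min | first imaging assumed at PSC door; exposed as configuration because the instant of "first imaging" is a modelling choice |
| evt_rate / ivt_rate / ivt_window | 0.90 / 0.80 / 270 | –, –, min | treatment uptake for the modelled cohort; window strict (`t_n < 270`) |
| p_lvo / p_nlvo / p_other | 0.60 / 0.30 / 0.10 | – | plausible mix for a RACE ≥ 5 cohort; placeholder — calibrate to local screening data |
| decay curves | logistic, e.g. EVT p0 0.65 → floor 0.10 over 480 min | – | synthetic placeholders with realistic shape and ordering; replace with published coefficients for real use |
| travel model | speed 68/52 km/min, detour 1.0 | – | calibrated so the 68 km reference corridor takes the 52 min free-flow baseline of the bundled profiles |

The logistic curve is rescaled so that value(0) = p0 and value(t_max) =
p_floor exactly (midpoint t_max/2, steepness `shape` in minutes); linear and
constant kinds are available for analytically checkable configurations.

## Traffic deltas

A profile is 24 hourly drive times for one day type and direction. The
delta at hour h is `times[h] − times[3]`: the 3 a.m. value is taken as
free-flow with ambulance right of way. Deltas are applied as **absolute
minutes** to every route in the same direction irrespective of route length
(the measured corridor generalises additively); a proportional mode —
delta scaled by the route's share of the reference free-flow time — exists
behind `delta_mode: proportional` and is off by default. Paradigm routing:
mothership and DS move the patient toward the urban center
(suburban→urban); the DD interventionalist drives outward
(urban→suburban). The mothership delta shifts both door-to-needle and
door-to-groin; the DS delta the receiving center's door-to-groin; the DD
delta the arrival-to-groin interval. Hours are integral; a timeline is
evaluated at its dispatch hour without interpolation. Negative deltas may
never push an in-hospital interval below zero (clamped, with a warning).

The bundled profiles are hand-constructed integer curves that reproduce,
exactly, the reference corridor's summary statistics: weekday
urban→suburban mean 66 min with a unique 93 min maximum at 16:00 and
at-or-below-mean hours spanning 19:00–11:00; weekday suburban→urban mean
65 min with peaks of 90 min at 07:00 and 78 min at 16:00; weekend means
57 min in both directions with maxima 65 and 60 min. The unprinted 3 a.m.
baselines are set to 52/52 (weekday) and 53/55 (weekend) minutes —
roughly 78–88 km/h over the 68 km corridor; any choice consistent with the
published summaries would do, and deltas are invariant to a constant shift.

## Synthetic geography

Coordinates are planar kilometres; only relative travel times matter, so no
geodesy is used. Travel time is `detour_factor × Euclidean distance /
speed`, which is symmetric and satisfies the triangle inequality — unlike
real road networks it cannot represent asymmetric congestion or barriers.

* `toy3`: one PSC, one CSC, one CSC+ on a 100×100 km grid, with the
  PSC–CSC+ separation fixed at 68 km to mirror the reference corridor.
* `nwde-like`: 286×224 km (64,064 km² at the default 2 km cell), 21 PSC,
  23 CSC, 5 CSC+. The five CSC+ sit at jittered urban anchors; CSCs
  cluster around them (σ 22 km) the way hospitals follow population; PSCs
  are rejection-sampled into the rural gaps (32–62 km from any
  thrombectomy-capable center, ≥ 55 km from a CSC+), and a whole layout is
  accepted once the mean nearest PSC→CSC/CSC+ distance lies in 44 ± 6 km
  and the mean nearest PSC→CSC+ distance in 67 ± 10 km. All tested seeds
  converge within one or two layout attempts.

Generation is fully determined by the seed, down to byte-identical GeoJSON
(sorted keys, fixed coordinate rounding). What the generator does **not**
emulate: real road topology, population-weighted incidence (areas are
unweighted km²), coastline/estuary barriers, and hospital-level differences
in door times. Passing tests therefore demonstrate the correctness of the
decision machinery under controlled geometry, not the reproduction of any
real region's catchment sizes.

## Catchment classification

The vectorised classifier precomputes, per cell: travel to the nearest
EVT-capable center (mothership), the nearest PSC, and — per PSC — the
transfer leg to its nearest EVT-capable center and the interventionalist
leg from its nearest CSC+. "Nearest" ties break on the lexicographically
lowest hospital id. Probabilities are rounded to 12 decimals before the
argmax so tie-breaking is platform-independent; exact ties resolve by the
fixed priority mothership > drip-and-ship > drip-and-drive (fewest
handoffs). Cells without road access are labelled unroutable and excluded
from classification but included in the area denominator; percentages are
rounded half away from zero to integers. A scalar per-cell path
(`classify_cell`) mirrors the vectorised arithmetic through the scalar
timeline functions and serves as an audit trail; tests additionally compare
the vectorised path against an independently coded brute-force classifier.

A note on the co-located corner case: with all travel times zero the DS
patient reaches the comprehensive center 110 min after onset, 50 min after
first PSC imaging, so the no-reimaging branch applies and the groin time is
140 min (not 60 + 30 + 20 + 60 = 170 — chaining the constants without the
reimaging rule is a tempting but inconsistent shortcut). Mothership (120)
still dominates.

## Operation-log module

Weekday is Monday–Friday. Per-hour medians use the standard mid-rule;
window counts use half-open clock windows `[start, end)` that may wrap
midnight. One printed-rounding wrinkle: 69/128 = 53.9 % rounds to 54 %
under the package's half-away rule, while accounts of such logs sometimes
quote 53 %; the package reports 54. The `lueneburg-like` preset fixes
per-hour counts and transfer times deterministically (the seed only places
calendar dates), so its marginals are exact by construction: 106/22
weekday/weekend split, zero weekday operations at 02–03 h, 15 operations at
10 h, 69 in 08:00–17:00, mean and median transfer 82 min in both strata,
longest weekday median (102 min) at 15 h and longest weekend median
(95 min) on Saturdays at 23 h. The sampling mode draws hours from a
categorical distribution and transfer times from a lognormal
(median 82 min, σ 0.25 by default).

## Problem sizes and tolerances

Validation runs use the 50×50-cell `toy3` grid across all 48 hour/day-type
combinations (exact label agreement with the brute-force oracle), 1,000
random parameter draws for the outcome expectation (equality with the
literal expansion at 1e-12), and the 16,016-cell `nwde-like` region for the
full hourly series — the latter completes in well under a second per
day-type, so the default cell size leaves ample headroom for finer grids.

## Limitations

Beyond the generator's simplifications above: decay-curve coefficients are
placeholders; traffic deltas derive from a single corridor and are applied
region-wide (the package's absolute mode inherits that approximation — it
is least realistic for short mothership rides near the urban center);
helicopter transport, mobile stroke units, seasonality and incident
congestion are out of scope; and the binary good/poor outcome discards the
rest of the mRS distribution.
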