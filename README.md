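# stroketriage

Transport-decision modelling for acute ischaemic stroke with suspected
large-vessel occlusion (LVO): given a patient location, a hospital network
and the hour of the day, which prehospital transport paradigm maximises the
expected probability of a good outcome?

The package is aimed at stroke-systems-of-care researchers and health-services
modellers. It compares the three standard paradigms:

* **mothership** — drive directly to a comprehensive stroke center (CSC or
  CSC+), bypassing closer primary stroke centers (PSC);
* **drip-and-ship (DS)** — thrombolyse at the nearest PSC, then transfer the
  patient to the CSC/CSC+ nearest to that PSC;
* **drip-and-drive (DD)** — thrombolyse at the PSC while a
  neurointerventionalist drives out from the nearest high-volume university
  center (CSC+) to perform the thrombectomy on site.

Its distinctive feature is **diurnal traffic modulation**: hourly directional
drive-time profiles (weekday/weekend, urban→suburban and suburban→urban) are
reduced to signed deltas against the 3 a.m. free-flow baseline, and each
paradigm is slowed or accelerated by the delta of the direction its critical
leg travels. During the morning rush the inbound (suburban→urban) direction
is congested, which penalises mothership and DS but barely affects the
outbound-driving interventionalist — so the DD catchment area surges; in the
afternoon the asymmetry reverses in favour of DS.

## Model

For a screen-positive patient (RACE ≥ 5) the cohort is a mixture of true LVO
(fraction *p*<sub>LVO</sub>), non-LVO ischaemic stroke (*p*<sub>nLVO</sub>)
and mimics (*p*<sub>other</sub>). With onset-to-needle time *t*<sub>n</sub>
and onset-to-groin time *t*<sub>g</sub> delivered by a paradigm, the expected
probability of good outcome (mRS 0–1 at 90 days) is

P(good) = *p*<sub>LVO</sub> [ *r*<sub>EVT</sub> P<sub>EVT</sub>(*t*<sub>g</sub>) + (1−*r*<sub>EVT</sub>)( *q* P<sub>IVT,LVO</sub>(*t*<sub>n</sub>) + (1−*q*) *u*<sub>LVO</sub> ) ]
 + *p*<sub>nLVO</sub> [ *q* P<sub>IVT,nLVO</sub>(*t*<sub>n</sub>) + (1−*q*) *u*<sub>nLVO</sub> ]
 + *p*<sub>other</sub> *u*<sub>other</sub>,

where *q* = *r*<sub>IVT</sub> · 1{*t*<sub>n</sub> < 270 min} (80 % IVT uptake
within the 4.5 h window), *r*<sub>EVT</sub> = 0.90, the P(·) are monotone
non-increasing treatment decay curves clamped to a window, and the *u* are
time-constant untreated/mimic outcome probabilities. The timelines feed this
expectation with fixed workflow intervals (onset-to-response 30, on-scene 30,
door-to-needle 30, PSC needle-to-door 20, CSC door-to-groin 60 min — or 30 min
when a transferred patient arrives within 90 min of first imaging and needs
no reimaging; in DD the interventionalist leaves 10 min after needle and
punctures 20 min after arrival). Every grid cell is labelled with the
argmax paradigm; per-paradigm areas and integer percentages of the total
region summarise each hour.

The shipped decay-curve coefficients are synthetic placeholders — replace
them with published estimates (via the YAML/JSON model configuration) for
any substantive use.

## Worked example

Score the three paradigms for a location 80 km from the CSC+, 12 km from its
PSC (the PSC 68 km from the CSC+), dispatched at the 7 a.m. weekday peak:

```python
from stroketriage import (WorkflowTimes, default_config, expected_good_outcome,
                          mothership_timeline, drip_and_ship_timeline,
                          drip_and_drive_timeline, paradigm_deltas,
                          reference_profiles)

cfg, w = default_config(), WorkflowTimes()
mix, rates, curves = (cfg.cohort_mix.build(), cfg.treatment_rates.build(),
                      cfg.build_curves())
d = paradigm_deltas(reference_profiles(), "weekday", 7)
speed = 68 / 52                      # km/min: the 68 km corridor in 52 min
tl = {
    "mothership":     mothership_timeline(80 / speed, d["mothership"], w),
    "drip_and_ship":  drip_and_ship_timeline(12 / speed, 68 / speed,
                                             d["drip_and_ship"], w),
    "drip_and_drive": drip_and_drive_timeline(12 / speed, 68 / speed,
                                              d["drip_and_drive"], w),
}
for name, t in tl.items():
    p = expected_good_outcome(t.t_needle, t.t_groin, mix, rates, curves)
    print(f"{name}: needle={t.t_needle:.1f} groin={t.t_groin:.1f} P(good)={p:.4f}")
```

```
mothership: needle=189.2 groin=219.2 P(good)=0.4398
drip_and_ship: needle=99.2 groin=269.2 P(good)=0.4233
drip_and_drive: needle=99.2 groin=192.2 P(good)=0.4951
```

At the morning peak the inbound delta (+38 min) hits both patient-moving
paradigms, while the outbound interventionalist only loses 11 min:
drip-and-drive wins this cell. The same comparison swept over a whole grid
gives the catchment maps:

```bash
stroketriage map --preset toy3 --day-type weekday --hour 7 \
    --out map7.geojson --png map7.png
```

```
      paradigm    km2  percent
    mothership 6956.0       70
 drip_and_ship    0.0        0
drip_and_drive 3044.0       30
    unroutable    0.0        0
```

At 16:00 the same region is 94 % mothership / 6 % drip-and-ship and
drip-and-drive vanishes. `stroketriage series` writes the full 24-hour area
table; `stroketriage oplog generate | summarize` handles emergency-operation
logs (counts, percentages and transfer-time statistics by hour and day type).

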