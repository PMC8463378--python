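"""Catchment-area classification: which paradigm wins where, hour by hour.

For every routable grid cell the three transport paradigms are scored by
the expected probability of good outcome they deliver from that cell, and
the cell is labelled with the argmax.  The geometry behind each score:

* mothership — drive from the cell to the nearest thrombectomy-capable
  center (CSC or CSC+);
* drip-and-ship — drive to the nearest PSC, thrombolyse, then transfer to
  the CSC/CSC+ nearest to *that PSC*;
* drip-and-drive — drive to the nearest PSC while the interventionalist
  from the CSC+ nearest to that PSC drives out to it.

Hour-of-day traffic deltas are routed per paradigm (patient transports
follow the suburban→urban profile, the interventionalist the
urban→suburban one).  Ties are broken by a fixed priority mothership >
drip-and-ship > drip-and-drive (fewest handoffs); probabilities are
rounded to 12 decimals before comparison so tie-breaking is reproducible
across platforms.  Per-paradigm areas are reported in km² and as integer
percentages of the *total* region area, unroutable cells included,
rounded half away from zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .config import ModelConfig
from .geography import (
    EVT_CAPABLE,
    HospitalNetwork,
    Level,
    RegionGrid,
    TravelModel,
    nearest_hospital,
    travel_time,
)
from .outcome import ConfigurationError, expected_good_outcome
from .timelines import (
    drip_and_drive_times,
    drip_and_ship_times,
    mothership_times,
)
from .traffic import ProfileSet, paradigm_deltas

__all__ = [
    "LABELS",
    "UNROUTABLE",
    "CatchmentMap",
    "classify_cell",
    "classify_map",
    "area_summary",
    "hourly_series",
    "round_half_away",
    "map_to_geojson",
    "render_map",
]

#: Paradigm labels in tie-breaking priority order.
LABELS: Tuple[str, ...] = ("mothership", "drip_and_ship", "drip_and_drive")
UNROUTABLE = "unroutable"

#: Map colours: green mothership, red drip-and-ship, purple drip-and-drive,
#: gray unroutable.
MAP_COLORS = {
    "mothership": "#2ca02c",
    "drip_and_ship": "#d62728",
    "drip_and_drive": "#9467bd",
    UNROUTABLE: "#999999",
}

_ROUND_DECIMALS = 12


def round_half_away(x):
    """Round to the nearest integer, halves away from zero (2.5 -> 3, -2.5 -> -3)."""
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return int(out) if out.ndim == 0 else out.astype(int)


@dataclass(frozen=True)
class CatchmentMap:
    """Per-cell winning paradigm for one hour of one day type."""

    day_type: str
    hour: int
    labels: np.ndarray  # str per cell; UNROUTABLE where no road access
    cell_area: float
    total_area: float

    @property
    def areas_km2(self) -> Dict[str, float]:
        return {
            lab: float(np.count_nonzero(self.labels == lab) * self.cell_area)
            for lab in LABELS + (UNROUTABLE,)
        }

    @property
    def percents(self) -> Dict[str, int]:
        return {
            lab: round_half_away(100.0 * a / self.total_area)
            for lab, a in self.areas_km2.items()
        }


class _Geometry:
    """Per-cell travel geometry shared by all 48 hour/day-type evaluations."""

    def __init__(self, grid: RegionGrid, network: HospitalNetwork, model: TravelModel):
        cells = grid.centroids
        evt_xy = network.coords(EVT_CAPABLE)
        if evt_xy.size == 0:
            raise ConfigurationError("region has no thrombectomy-capable hospital")
        psc_xy = network.coords({Level.PSC})
        plus_xy = network.coords({Level.CSC_PLUS})

        def _dist(points, targets):
            return np.hypot(
                points[:, 0][:, None] - targets[:, 0][None, :],
                points[:, 1][:, None] - targets[:, 1][None, :],
            )

        # mothership: cell -> nearest EVT-capable center
        self.t_mothership = model.minutes(_dist(cells, evt_xy).min(axis=1))

        self.has_psc = psc_xy.size > 0
        self.has_plus = plus_xy.size > 0
        if self.has_psc:
            d_psc = _dist(cells, psc_xy)
            nearest_psc = d_psc.argmin(axis=1)  # first min = lowest id
            self.t_to_psc = model.minutes(d_psc[np.arange(len(cells)), nearest_psc])
            # per-PSC onward legs, indexed by the cell's nearest PSC
            t_transfer_by_psc = model.minutes(_dist(psc_xy, evt_xy).min(axis=1))
            self.t_transfer = t_transfer_by_psc[nearest_psc]
            if self.has_plus:
                t_iv_by_psc = model.minutes(_dist(psc_xy, plus_xy).min(axis=1))
                self.t_interventionalist = t_iv_by_psc[nearest_psc]


def _applied_deltas(
    profiles: ProfileSet,
    config: ModelConfig,
    day_type: str,
    hour: int,
    geometry: _Geometry,
    zero_delta: bool,
    delta_override: Optional[Mapping[str, float]],
):
    """Per-paradigm delta, as scalars (absolute mode) or per-cell arrays."""
    if zero_delta:
        base = {lab: 0.0 for lab in LABELS}
    else:
        base = paradigm_deltas(profiles, day_type, hour)
    if delta_override:
        base = {**base, **delta_override}
    if config.delta_mode == "absolute" or zero_delta:
        return base
    # proportional: scale the reference-route delta by each route's share of
    # the reference free-flow drive time
    su = profiles[(day_type, "suburban_to_urban")].baseline_time
    us = profiles[(day_type, "urban_to_suburban")].baseline_time
    return {
        "mothership": base["mothership"] * geometry.t_mothership / su,
        "drip_and_ship": base["drip_and_ship"] * geometry.t_transfer / su,
        "drip_and_drive": base["drip_and_drive"] * geometry.t_interventionalist / us,
    }


def _paradigm_probabilities(
    geometry: _Geometry,
    deltas: Mapping[str, float],
    config: ModelConfig,
) -> Dict[str, np.ndarray]:
    """Expected good-outcome probability per cell for each feasible paradigm."""
    w = config.workflow.build()
    mix = config.cohort_mix.build()
    rates = config.treatment_rates.build()
    curves = config.build_curves()

    probs: Dict[str, np.ndarray] = {}
    tn, tg = mothership_times(geometry.t_mothership, deltas["mothership"], w)
    probs["mothership"] = expected_good_outcome(tn, tg, mix, rates, curves)
    if geometry.has_psc:
        tn, tg, _ = drip_and_ship_times(
            geometry.t_to_psc, geometry.t_transfer, deltas["drip_and_ship"], w
        )
        probs["drip_and_ship"] = expected_good_outcome(tn, tg, mix, rates, curves)
        if geometry.has_plus:
            tn, tg = drip_and_drive_times(
                geometry.t_to_psc,
                geometry.t_interventionalist,
                deltas["drip_and_drive"],
                w,
            )
            probs["drip_and_drive"] = expected_good_outcome(tn, tg, mix, rates, curves)
    return probs


def classify_map(
    grid: RegionGrid,
    network: HospitalNetwork,
    model: TravelModel,
    profiles: ProfileSet,
    config: ModelConfig,
    day_type: str,
    hour: int,
    zero_delta: bool = False,
    delta_override: Optional[Mapping[str, float]] = None,
    _geometry: Optional[_Geometry] = None,
) -> CatchmentMap:
    """Label every cell with the paradigm of highest predicted good outcome.

    ``zero_delta=True`` evaluates every paradigm at the free-flow baseline
    (all deltas zero), reproducing the 3 a.m. reference scenario for any
    hour.  ``delta_override`` replaces individual paradigm deltas, which is
    how sensitivity sweeps are driven.
    """
    geometry = _geometry or _Geometry(grid, network, model)
    deltas = _applied_deltas(
        profiles, config, day_type, hour, geometry, zero_delta, delta_override
    )
    probs = _paradigm_probabilities(geometry, deltas, config)

    order = [lab for lab in LABELS if lab in probs]
    stacked = np.round(
        np.vstack([np.broadcast_to(probs[lab], grid.n_cells) for lab in order]),
        _ROUND_DECIMALS,
    )
    winner = stacked.argmax(axis=0)  # first max wins -> priority order
    labels = np.array(order, dtype=object)[winner]
    labels[~grid.routable] = UNROUTABLE
    return CatchmentMap(
        day_type=day_type,
        hour=hour,
        labels=labels,
        cell_area=grid.cell_area,
        total_area=grid.total_area,
    )


def classify_cell(
    point,
    network: HospitalNetwork,
    model: TravelModel,
    profiles: ProfileSet,
    config: ModelConfig,
    day_type: str,
    hour: int,
    routable: bool = True,
    zero_delta: bool = False,
) -> Tuple[str, Dict[str, float]]:
    """Scalar classification of a single location (audit/debug path).

    Returns the winning label and the per-paradigm probabilities.  Uses the
    scalar nearest-neighbour and timeline functions rather than the
    vectorised grid path.  ``delta_mode="proportional"`` is only supported
    by :func:`classify_map`.
    """
    if not routable:
        return UNROUTABLE, {}
    if config.delta_mode != "absolute":
        raise ConfigurationError("classify_cell supports absolute delta mode only")
    from .outcome import expected_good_outcome as ego
    from .timelines import (
        drip_and_drive_timeline,
        drip_and_ship_timeline,
        mothership_timeline,
    )

    w = config.workflow.build()
    mix = config.cohort_mix.build()
    rates = config.treatment_rates.build()
    curves = config.build_curves()
    deltas = (
        {lab: 0.0 for lab in LABELS}
        if zero_delta
        else paradigm_deltas(profiles, day_type, hour)
    )

    probs: Dict[str, float] = {}
    _, t_ms = nearest_hospital(point, network, EVT_CAPABLE, model)
    tl = mothership_timeline(t_ms, deltas["mothership"], w)
    probs["mothership"] = ego(tl.t_needle, tl.t_groin, mix, rates, curves)

    pscs = network.with_roles({Level.PSC})
    if pscs:
        psc, t_psc = nearest_hospital(point, network, {Level.PSC}, model)
        _, t_transfer = nearest_hospital(psc.location, network, EVT_CAPABLE, model)
        tl = drip_and_ship_timeline(t_psc, t_transfer, deltas["drip_and_ship"], w)
        probs["drip_and_ship"] = ego(tl.t_needle, tl.t_groin, mix, rates, curves)
        if network.with_roles({Level.CSC_PLUS}):
            _, t_iv = nearest_hospital(psc.location, network, {Level.CSC_PLUS}, model)
            tl = drip_and_drive_timeline(t_psc, t_iv, deltas["drip_and_drive"], w)
            probs["drip_and_drive"] = ego(tl.t_needle, tl.t_groin, mix, rates, curves)

    rounded = {lab: round(p, _ROUND_DECIMALS) for lab, p in probs.items()}
    label = max(LABELS, key=lambda lab: (rounded.get(lab, -1.0), -LABELS.index(lab)))
    return label, probs


def area_summary(cmap: CatchmentMap) -> pd.DataFrame:
    """Table of (paradigm, km², percent of total region area)."""
    areas = cmap.areas_km2
    pct = cmap.percents
    return pd.DataFrame(
        {
            "paradigm": list(areas),
            "km2": [areas[k] for k in areas],
            "percent": [pct[k] for k in areas],
        }
    )


def hourly_series(
    grid: RegionGrid,
    network: HospitalNetwork,
    model: TravelModel,
    profiles: ProfileSet,
    config: ModelConfig,
    day_type: str,
    zero_delta: bool = False,
) -> Tuple[List[CatchmentMap], pd.DataFrame]:
    """One catchment map per hour 0-23 plus a long-format area table."""
    geometry = _Geometry(grid, network, model)
    maps = [
        classify_map(
            grid, network, model, profiles, config, day_type, hour,
            zero_delta=zero_delta, _geometry=geometry,
        )
        for hour in range(24)
    ]
    rows = [
        (day_type, m.hour, lab, m.areas_km2[lab], m.percents[lab])
        for m in maps
        for lab in LABELS + (UNROUTABLE,)
    ]
    table = pd.DataFrame(rows, columns=["day_type", "hour", "paradigm", "km2", "percent"])
    return maps, table


def map_to_geojson(cmap: CatchmentMap, grid: RegionGrid) -> str:
    """Serialise per-cell labels as square-cell GeoJSON polygons."""
    half = grid.cell_size / 2.0
    features = []
    for (x, y), lab in zip(grid.centroids, cmap.labels):
        x0, x1 = round(x - half, 3), round(x + half, 3)
        y0, y1 = round(y - half, 3), round(y + half, 3)
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]],
                },
                "properties": {"label": lab},
            }
        )
    return json.dumps(
        {
            "type": "FeatureCollection",
            "features": features,
            "properties": {"day_type": cmap.day_type, "hour": cmap.hour},
        },
        sort_keys=True,
        separators=(",", ":"),
    )


def render_map(cmap: CatchmentMap, grid: RegionGrid, network: HospitalNetwork, path) -> None:
    """Render the map as PNG (green mothership, red DS, purple DD, gray no-road)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    order = LABELS + (UNROUTABLE,)
    codes = np.array([order.index(lab) for lab in cmap.labels])
    img = codes.reshape(grid.ny, grid.nx)
    fig, ax = plt.subplots(figsize=(7, 7 * grid.ny / grid.nx))
    ax.imshow(
        img,
        origin="lower",
        cmap=ListedColormap([MAP_COLORS[lab] for lab in order]),
        vmin=-0.5,
        vmax=len(order) - 0.5,
        extent=(
            grid.xmin,
            grid.xmin + grid.nx * grid.cell_size,
            grid.ymin,
            grid.ymin + grid.ny * grid.cell_size,
        ),
    )
    markers = {Level.PSC: ("o", "gold"), Level.CSC: ("^", "deepskyblue"), Level.CSC_PLUS: ("*", "navy")}
    for h in network.hospitals:
        m, c = markers[h.level]
        ax.plot(h.x, h.y, m, color=c, markersize=9, markeredgecolor="black")
    ax.set_title(f"{cmap.day_type} {cmap.hour:02d}:00")
    ax.set_xlabel("km")
    ax.set_ylabel("km")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
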