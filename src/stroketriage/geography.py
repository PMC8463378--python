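"""Synthetic regions, hospital networks and a planar travel-time model.

Real catchment analyses sit on road networks and commercial travel-time
APIs; nothing there is reproducible on a desk.  This module generates toy
study regions that carry the same structure: a planar grid of cells
(kilometre coordinates, no geodesy — only relative travel times matter), a
hospital network with three capability levels (PSC: thrombolysis only;
CSC: thrombolysis + thrombectomy; CSC+: high-volume university center that
can also dispatch an interventionalist), and a travel model mapping
distance to minutes through a constant speed and detour factor.

Two presets are bundled:

* ``"toy3"`` — one hospital of each level on a 100x100 km grid, with the
  PSC placed exactly 68 km from the CSC+ to mirror the reference
  urban<->suburban corridor the traffic profiles were measured on.
* ``"nwde-like"`` — a northwest-Germany-sized region (~64,000 km²) with
  21 PSCs, 23 CSCs and 5 CSC+, placed by seeded rejection sampling until
  the mean nearest PSC→CSC/CSC+ distance is ≈44 km and the mean nearest
  PSC→CSC+ distance is ≈67 km.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence, Tuple

import numpy as np

from .outcome import ConfigurationError

__all__ = [
    "Level",
    "Hospital",
    "HospitalNetwork",
    "RegionGrid",
    "TravelModel",
    "travel_time",
    "nearest_hospital",
    "generate_region",
    "region_to_geojson",
    "grid_to_csv",
    "PRESETS",
]


class Level(str, Enum):
    PSC = "PSC"
    CSC = "CSC"
    CSC_PLUS = "CSC_PLUS"


#: Roles that can receive a mothership or drip-and-ship patient.
EVT_CAPABLE = frozenset({Level.CSC, Level.CSC_PLUS})


@dataclass(frozen=True)
class Hospital:
    id: str
    level: Level
    x: float
    y: float

    @property
    def location(self) -> Tuple[float, float]:
        return (self.x, self.y)


class HospitalNetwork:
    """Immutable collection of hospitals with per-level coordinate views."""

    def __init__(self, hospitals: Iterable[Hospital]):
        hospitals = sorted(hospitals, key=lambda h: h.id)
        ids = [h.id for h in hospitals]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("hospital ids must be unique")
        self.hospitals: Tuple[Hospital, ...] = tuple(hospitals)

    def with_roles(self, roles: Iterable[Level]) -> Tuple[Hospital, ...]:
        roles = frozenset(Level(r) for r in roles)
        if not roles:
            raise ConfigurationError("empty role set")
        return tuple(h for h in self.hospitals if h.level in roles)

    def coords(self, roles: Iterable[Level]) -> np.ndarray:
        hs = self.with_roles(roles)
        return np.array([[h.x, h.y] for h in hs], dtype=float).reshape(len(hs), 2)

    def __len__(self) -> int:
        return len(self.hospitals)


@dataclass(frozen=True)
class TravelModel:
    """Distance-to-minutes conversion: detour_factor x Euclidean / speed."""

    speed: float = 68.0 / 52.0  # km/min; the 68 km reference route in 52 min
    detour_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ConfigurationError("speed must be positive")
        if self.detour_factor < 1.0:
            raise ConfigurationError("detour factor must be >= 1")

    def minutes(self, distance_km):
        return self.detour_factor * np.asarray(distance_km, dtype=float) / self.speed


def travel_time(model: TravelModel, a: Sequence[float], b: Sequence[float]) -> float:
    """Travel time in minutes between two planar points (km coordinates)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("coordinates must be finite")
    return float(model.minutes(np.hypot(*(a - b))))


def nearest_hospital(
    point: Sequence[float],
    network: HospitalNetwork,
    roles: Iterable[Level],
    model: TravelModel,
) -> Tuple[Hospital, float]:
    """Closest hospital with one of the given roles; ties go to the lowest id.

    Hospitals are scanned in id order, and ``argmin`` keeps the first
    minimum, which realises the tie rule.
    """
    hs = network.with_roles(roles)
    if not hs:
        raise ConfigurationError(f"no hospital with a role in {set(roles)!r}")
    times = [travel_time(model, point, h.location) for h in hs]
    i = int(np.argmin(times))
    return hs[i], times[i]


@dataclass(frozen=True)
class RegionGrid:
    """Discretised rectangular study region.

    ``centroids`` is an (n, 2) array of cell centres in km; ``routable``
    flags cells reachable by road.  Total area always counts every cell,
    routable or not.
    """

    xmin: float
    ymin: float
    nx: int
    ny: int
    cell_size: float
    routable: np.ndarray

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ConfigurationError("cell size must be positive")
        if self.routable.shape != (self.nx * self.ny,):
            raise ConfigurationError("routable flags must cover every cell")

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    @property
    def total_area(self) -> float:
        return self.n_cells * self.cell_area

    @property
    def centroids(self) -> np.ndarray:
        xs = self.xmin + (np.arange(self.nx) + 0.5) * self.cell_size
        ys = self.ymin + (np.arange(self.ny) + 0.5) * self.cell_size
        gx, gy = np.meshgrid(xs, ys, indexing="xy")
        return np.column_stack([gx.ravel(), gy.ravel()])


def _full_grid(width: float, height: float, cell_size: float) -> RegionGrid:
    nx = int(round(width / cell_size))
    ny = int(round(height / cell_size))
    return RegionGrid(
        xmin=0.0,
        ymin=0.0,
        nx=nx,
        ny=ny,
        cell_size=cell_size,
        routable=np.ones(nx * ny, dtype=bool),
    )


def _toy3(rng: np.random.Generator, cell_size: float):
    grid = _full_grid(100.0, 100.0, cell_size)
    network = HospitalNetwork(
        [
            Hospital("csc_plus_01", Level.CSC_PLUS, 16.0, 50.0),  # urban center
            Hospital("csc_01", Level.CSC, 50.0, 84.0),
            Hospital("psc_01", Level.PSC, 84.0, 50.0),  # 68 km from the CSC+
        ]
    )
    return grid, network, TravelModel()


def _nwde_like(rng: np.random.Generator, cell_size: float):
    """Rejection-sample a region matching the study territory's summary shape.

    286 x 224 km (64,064 km² at 2 km cells), 5 CSC+ spread across the
    region, 23 CSCs scattered, and 21 PSCs seeded at ~44 km from a
    thrombectomy-capable anchor.  A layout is accepted once the mean
    nearest PSC→CSC/CSC+ distance falls in 44 ± 6 km and the mean nearest
    PSC→CSC+ distance in 67 ± 10 km.
    """
    width, height = 286.0, 224.0
    anchors = np.array(
        [[60.0, 150.0], [210.0, 170.0], [150.0, 60.0], [70.0, 50.0], [230.0, 60.0]]
    )
    for _ in range(500):
        # five urban CSC+ anchors, jittered; CSCs cluster around them the
        # way hospitals follow population
        csc_plus = np.clip(
            anchors + rng.normal(0.0, 10.0, anchors.shape),
            12.0,
            [width - 12.0, height - 12.0],
        )
        cluster = rng.integers(0, len(csc_plus), 23)
        cscs = np.clip(
            csc_plus[cluster] + rng.normal(0.0, 22.0, (23, 2)),
            6.0,
            [width - 6.0, height - 6.0],
        )
        pool = np.vstack([csc_plus, cscs])
        # PSCs fill the rural gaps: 32-62 km from any thrombectomy-capable
        # center and at least 55 km from a CSC+
        pscs = []
        for _ in range(6000):
            p = np.array(
                [rng.uniform(4.0, width - 4.0), rng.uniform(4.0, height - 4.0)]
            )
            d = np.hypot(*(pool - p).T).min()
            dp = np.hypot(*(csc_plus - p).T).min()
            if 32.0 <= d <= 62.0 and dp >= 55.0:
                pscs.append(p)
                if len(pscs) == 21:
                    break
        if len(pscs) < 21:
            continue
        pscs = np.array(pscs)
        d_csc = np.hypot(
            *(pscs[:, None, :] - pool[None, :, :]).transpose(2, 0, 1)
        ).min(axis=1)
        d_plus = np.hypot(
            *(pscs[:, None, :] - csc_plus[None, :, :]).transpose(2, 0, 1)
        ).min(axis=1)
        if abs(d_csc.mean() - 44.0) <= 6.0 and abs(d_plus.mean() - 67.0) <= 10.0:
            break
    else:  # pragma: no cover - acceptance bands make this effectively unreachable
        raise RuntimeError("could not place a layout satisfying the distance targets")

    hospitals = (
        [
            Hospital(f"csc_plus_{i + 1:02d}", Level.CSC_PLUS, float(x), float(y))
            for i, (x, y) in enumerate(np.round(csc_plus, 3))
        ]
        + [
            Hospital(f"csc_{i + 1:02d}", Level.CSC, float(x), float(y))
            for i, (x, y) in enumerate(np.round(cscs, 3))
        ]
        + [
            Hospital(f"psc_{i + 1:02d}", Level.PSC, float(x), float(y))
            for i, (x, y) in enumerate(np.round(pscs, 3))
        ]
    )
    grid = _full_grid(width, height, cell_size)
    return grid, HospitalNetwork(hospitals), TravelModel()


PRESETS = {"toy3": _toy3, "nwde-like": _nwde_like}


def generate_region(
    seed: int,
    preset: str = "toy3",
    cell_size: float = 2.0,
    unroutable_border_fraction: float = 0.0,
):
    """Generate a reproducible (grid, network, travel model) triple.

    The same seed always yields the same region, down to byte-identical
    GeoJSON serialisation.  ``unroutable_border_fraction`` marks that share
    of border cells as road-free (rendered gray on maps).
    """
    if preset not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
        )
    rng = np.random.default_rng(seed)
    grid, network, model = PRESETS[preset](rng, cell_size)
    if unroutable_border_fraction > 0:
        ix = np.arange(grid.n_cells)
        col = ix % grid.nx
        row = ix // grid.nx
        border = ix[(col == 0) | (col == grid.nx - 1) | (row == 0) | (row == grid.ny - 1)]
        k = int(round(unroutable_border_fraction * len(border)))
        routable = grid.routable.copy()
        routable[rng.choice(border, size=k, replace=False)] = False
        grid = RegionGrid(grid.xmin, grid.ymin, grid.nx, grid.ny, grid.cell_size, routable)
    return grid, network, model


def region_to_geojson(grid: RegionGrid, network: HospitalNetwork) -> str:
    """Serialise region outline + hospitals as a deterministic GeoJSON string."""
    xmax = grid.xmin + grid.nx * grid.cell_size
    ymax = grid.ymin + grid.ny * grid.cell_size
    features = [
        {
            "type": "Feature",
            "geometry": {
                "type": "Polygon",
                "coordinates": [
                    [
                        [grid.xmin, grid.ymin],
                        [xmax, grid.ymin],
                        [xmax, ymax],
                        [grid.xmin, ymax],
                        [grid.xmin, grid.ymin],
                    ]
                ],
            },
            "properties": {"kind": "region", "cell_size_km": grid.cell_size},
        }
    ]
    for h in network.hospitals:
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [round(h.x, 3), round(h.y, 3)]},
                "properties": {"id": h.id, "kind": "hospital", "level": h.level.value},
            }
        )
    return json.dumps(
        {"type": "FeatureCollection", "features": features},
        sort_keys=True,
        separators=(",", ":"),
    )


def grid_to_csv(grid: RegionGrid, path) -> None:
    """Write the cell table (id, x, y, routable) as CSV."""
    import pandas as pd

    c = grid.centroids
    pd.DataFrame(
        {
            "cell_id": np.arange(grid.n_cells),
            "x": c[:, 0],
            "y": c[:, 1],
            "routable": grid.routable.astype(int),
        }
    ).to_csv(path, index=False)
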