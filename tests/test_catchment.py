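"""Catchment classification, area accounting and map export."""

import numpy as np
import pytest

from stroketriage import (
    Hospital,
    HospitalNetwork,
    Level,
    TravelModel,
    generate_region,
    round_half_away,
)
from stroketriage.catchment import (
    LABELS,
    UNROUTABLE,
    CatchmentMap,
    area_summary,
    classify_cell,
    classify_map,
    hourly_series,
    map_to_geojson,
)

from .oracles import brute_classify_cell

ORACLE_CURVES = {
    "evt": (0.70, 0.10, 400.0),
    "ivt_lvo": (0.50, 0.10, 300.0),
    "ivt_nlvo": (0.65, 0.35, 300.0),
}


def oracle_hospitals(network):
    return [(h.id, h.level.value, h.x, h.y) for h in network.hospitals]


class TestClassifyCell:
    def test_csc_only_region_is_all_mothership(self, profiles, linear_config):
        net = HospitalNetwork([Hospital("only_csc", Level.CSC, 50.0, 50.0)])
        grid, _, model = generate_region(1, "toy3")
        cmap = classify_map(grid, net, model, profiles, linear_config, "weekday", 7)
        assert set(np.unique(cmap.labels)) == {"mothership"}

    def test_colocated_all_levels_ties_to_mothership(self, profiles, linear_config):
        """PSC on top of the only CSC+, zero deltas: mothership and
        drip-and-drive tie at groin 120 and the fixed priority keeps
        mothership."""
        net = HospitalNetwork(
            [
                Hospital("plus", Level.CSC_PLUS, 50.0, 50.0),
                Hospital("psc", Level.PSC, 50.0, 50.0),
            ]
        )
        model = TravelModel()
        label, probs = classify_cell(
            (50.0, 50.0), net, model, profiles, linear_config, "weekday", 3
        )
        assert label == "mothership"
        assert probs["mothership"] == probs["drip_and_drive"]
        assert probs["drip_and_ship"] < probs["mothership"]

    def test_unroutable_cell(self, profiles, linear_config, toy3):
        _, net, model = toy3
        label, probs = classify_cell(
            (1.0, 1.0), net, model, profiles, linear_config, "weekday", 7,
            routable=False,
        )
        assert label == UNROUTABLE and probs == {}

    def test_no_csc_plus_excludes_drip_and_drive(self, profiles, linear_config):
        net = HospitalNetwork(
            [
                Hospital("csc", Level.CSC, 10.0, 50.0),
                Hospital("psc", Level.PSC, 90.0, 50.0),
            ]
        )
        _, probs = classify_cell(
            (80.0, 50.0), net, TravelModel(), profiles, linear_config, "weekday", 7
        )
        assert "drip_and_drive" not in probs and "drip_and_ship" in probs


class TestOracleEquivalence:
    def test_vectorised_equals_brute_force_toy3(self, toy3, profiles, linear_config):
        grid, net, model = toy3
        hs = oracle_hospitals(net)
        from stroketriage.traffic import paradigm_deltas

        for day_type, hour in [("weekday", 7), ("weekday", 16), ("weekend", 13)]:
            cmap = classify_map(
                grid, net, model, profiles, linear_config, day_type, hour
            )
            deltas = paradigm_deltas(profiles, day_type, hour)
            for i in np.linspace(0, grid.n_cells - 1, 100, dtype=int):
                want = brute_classify_cell(
                    tuple(grid.centroids[i]), hs, model.speed, model.detour_factor,
                    deltas, ORACLE_CURVES,
                )
                assert cmap.labels[i] == want, (day_type, hour, i)

    def test_vectorised_equals_brute_force_random_network(self, profiles, linear_config):
        """Multi-hospital region where nearest-facility choice is non-trivial."""
        rng = np.random.default_rng(5)
        hospitals = (
            [Hospital(f"psc_{i}", Level.PSC, *rng.uniform(0, 100, 2)) for i in range(3)]
            + [Hospital(f"csc_{i}", Level.CSC, *rng.uniform(0, 100, 2)) for i in range(2)]
            + [Hospital("plus_0", Level.CSC_PLUS, *rng.uniform(0, 100, 2))]
        )
        net = HospitalNetwork(hospitals)
        grid, _, model = generate_region(1, "toy3", cell_size=5.0)  # 20x20
        hs = oracle_hospitals(net)
        from stroketriage.traffic import paradigm_deltas

        for hour in (3, 7, 16):
            cmap = classify_map(grid, net, model, profiles, linear_config, "weekday", hour)
            deltas = paradigm_deltas(profiles, "weekday", hour)
            got = [
                brute_classify_cell(tuple(c), hs, model.speed, model.detour_factor,
                                    deltas, ORACLE_CURVES)
                for c in grid.centroids
            ]
            assert list(cmap.labels) == got


class TestAreas:
    def test_single_label_is_100_percent(self):
        labels = np.array(["mothership"] * 100, dtype=object)
        cmap = CatchmentMap("weekday", 3, labels, cell_area=4.0, total_area=400.0)
        assert cmap.percents["mothership"] == 100
        assert cmap.areas_km2["mothership"] == 400.0

    def test_partition_sums_to_total(self, toy3, profiles, linear_config):
        grid, net, model = toy3
        for hour in range(0, 24, 6):
            cmap = classify_map(grid, net, model, profiles, linear_config, "weekday", hour)
            assert sum(cmap.areas_km2.values()) == grid.total_area

    def test_area_summary_table(self, toy3, profiles, linear_config):
        grid, net, model = toy3
        cmap = classify_map(grid, net, model, profiles, linear_config, "weekday", 7)
        table = area_summary(cmap)
        assert set(table["paradigm"]) == set(LABELS) | {UNROUTABLE}
        assert table["km2"].sum() == grid.total_area

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(39.5) == 40
        assert round_half_away(6.25) == 6
        assert round_half_away(-2.5) == -3
        assert round_half_away(12.5) == 13


class TestHourlySeries:
    def test_flat_traffic_gives_identical_maps(self, toy3, linear_config):
        from stroketriage import TrafficProfile

        grid, net, model = toy3
        flat = {
            (d, dr): TrafficProfile(d, dr, (60.0,) * 24)
            for d in ("weekday",)
            for dr in ("urban_to_suburban", "suburban_to_urban")
        }
        maps, _ = hourly_series(grid, net, model, flat, linear_config, "weekday")
        for m in maps[1:]:
            assert np.array_equal(m.labels, maps[0].labels)

    def test_dd_area_larger_at_morning_than_afternoon_peak(
        self, toy3, profiles, linear_config
    ):
        grid, net, model = toy3
        _, table = hourly_series(grid, net, model, profiles, linear_config, "weekday")
        dd = table[table.paradigm == "drip_and_drive"].set_index("hour")["km2"]
        assert dd[7] >= dd[16]
        assert dd[7] > 0  # counter-commute advantage materialises

    def test_zero_delta_override_reproduces_baseline_map(
        self, toy3, profiles, linear_config
    ):
        grid, net, model = toy3
        baseline = classify_map(grid, net, model, profiles, linear_config, "weekday", 3)
        maps, _ = hourly_series(
            grid, net, model, profiles, linear_config, "weekday", zero_delta=True
        )
        for m in maps:
            assert np.array_equal(m.labels, baseline.labels)


class TestSensitivityAndExport:
    def test_increasing_dd_delta_never_grows_dd_area(self, toy3, profiles, linear_config):
        grid, net, model = toy3
        from stroketriage.traffic import paradigm_deltas

        for hour in (3, 7, 10, 16):
            deltas = paradigm_deltas(profiles, "weekday", hour)
            prev = None
            for extra in (0.0, 5.0, 15.0, 40.0):
                cmap = classify_map(
                    grid, net, model, profiles, linear_config, "weekday", hour,
                    delta_override={"drip_and_drive": deltas["drip_and_drive"] + extra},
                )
                area = cmap.areas_km2["drip_and_drive"]
                if prev is not None:
                    assert area <= prev
                prev = area

    def test_geojson_export_deterministic_and_labelled(self, toy3, profiles, linear_config):
        grid, net, model = toy3
        cmap = classify_map(grid, net, model, profiles, linear_config, "weekday", 7)
        a = map_to_geojson(cmap, grid)
        b = map_to_geojson(cmap, grid)
        assert a == b
        assert '"label":"drip_and_drive"' in a

    def test_proportional_delta_mode_runs(self, toy3, profiles, linear_config):
        grid, net, model = toy3
        cfg = linear_config.model_copy(update={"delta_mode": "proportional"})
        cmap = classify_map(grid, net, model, profiles, cfg, "weekday", 7)
        assert sum(cmap.areas_km2.values()) == grid.total_area
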