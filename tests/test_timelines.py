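"""Paradigm event chains: needle and groin times from travel + workflow."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stroketriage import (
    WorkflowTimes,
    drip_and_drive_timeline,
    drip_and_ship_timeline,
    mothership_timeline,
)
from stroketriage.timelines import drip_and_ship_times

from . import oracles


class TestMothership:
    @pytest.mark.parametrize(
        "travel, delta, needle, groin",
        [
            (50.0, 0.0, 140.0, 170.0),
            (0.0, 0.0, 90.0, 120.0),
            (50.0, 27.0, 167.0, 197.0),  # delta delays both door times
        ],
    )
    def test_event_chain(self, workflow, travel, delta, needle, groin):
        tl = mothership_timeline(travel, delta, workflow)
        assert (tl.t_needle, tl.t_groin) == (needle, groin)

    def test_negative_travel_rejected(self, workflow):
        with pytest.raises(ValueError):
            mothership_timeline(-1.0, 0.0, workflow)

    def test_acceleration_clamped_at_zero_interval(self, workflow):
        with pytest.warns(UserWarning):
            tl = mothership_timeline(10.0, -45.0, workflow)
        # door-to-needle would be 30-45 < 0 -> clamped to 0
        assert tl.t_needle == 70.0
        assert tl.t_groin == 70.0 + 15.0


class TestDripAndShip:
    @pytest.mark.parametrize(
        "t_psc, t_transfer, delta, needle, groin",
        [
            (20.0, 30.0, 0.0, 110.0, 190.0),  # arrives 80 min after imaging: fast
            (20.0, 60.0, 0.0, 110.0, 250.0),  # 110 min gap: reimaging needed
            # co-located PSC/CSC: arrival 50 min after imaging, no reimaging
            (0.0, 0.0, 0.0, 90.0, 140.0),
        ],
    )
    def test_event_chain(self, workflow, t_psc, t_transfer, delta, needle, groin):
        tl = drip_and_ship_timeline(t_psc, t_transfer, delta, workflow)
        assert (tl.t_needle, tl.t_groin) == (needle, groin)

    def test_reimaging_threshold_inclusive(self, workflow):
        # with t_psc=20 the no-reimaging branch holds exactly up to transfer=40
        at = drip_and_ship_timeline(20.0, 40.0, 0.0, workflow)
        past = drip_and_ship_timeline(20.0, 40.5, 0.0, workflow)
        assert at.t_groin == 200.0  # csc_door 170 + fast 30
        assert past.t_groin == 230.5  # csc_door 170.5 + full 60

    def test_single_jump_of_exactly_30(self, workflow):
        """t_groin minus its affine trend has one upward step of 30 min."""
        transfers = np.arange(0.0, 120.5, 0.5)
        groin = np.array(
            [drip_and_ship_timeline(20.0, t, 0.0, workflow).t_groin for t in transfers]
        )
        steps = np.diff(groin - transfers)  # remove the affine part
        jumps = steps[steps != 0]
        assert len(jumps) == 1 and jumps[0] == 30.0
        assert (
            workflow.dtg_csc - workflow.dtg_csc_fast == 30.0
        )


class TestDripAndDrive:
    @pytest.mark.parametrize(
        "t_psc, t_iv, delta, needle, groin",
        [
            (20.0, 60.0, 0.0, 110.0, 200.0),
            (0.0, 0.0, 0.0, 90.0, 120.0),
            (20.0, 60.0, -5.0, 110.0, 195.0),  # acceleration shortens arrival-to-groin
        ],
    )
    def test_event_chain(self, workflow, t_psc, t_iv, delta, needle, groin):
        tl = drip_and_drive_timeline(t_psc, t_iv, delta, workflow)
        assert (tl.t_needle, tl.t_groin) == (needle, groin)


class TestSharedProperties:
    def test_needle_time_equal_across_paradigms_at_zero_travel(self, workflow):
        ms = mothership_timeline(0.0, 0.0, workflow)
        ds = drip_and_ship_timeline(0.0, 0.0, 0.0, workflow)
        dd = drip_and_drive_timeline(0.0, 0.0, 0.0, workflow)
        assert ms.t_needle == ds.t_needle == dd.t_needle == 90.0
        assert ms.t_groin == 120.0 and dd.t_groin == 120.0
        assert ms.t_groin < ds.t_groin  # mothership beats DS when co-located

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        a=st.floats(0, 200), b=st.floats(0, 200),
        inc=st.floats(0, 60), delta=st.floats(-20, 40),
    )
    def test_monotone_in_travel_times(self, a, b, inc, delta, workflow):
        ms0 = mothership_timeline(a, delta, workflow)
        ms1 = mothership_timeline(a + inc, delta, workflow)
        assert ms1.t_needle >= ms0.t_needle and ms1.t_groin >= ms0.t_groin
        ds0 = drip_and_ship_timeline(a, b, delta, workflow)
        ds1 = drip_and_ship_timeline(a + inc, b, delta, workflow)
        ds2 = drip_and_ship_timeline(a, b + inc, delta, workflow)
        assert ds1.t_needle >= ds0.t_needle and ds1.t_groin >= ds0.t_groin
        assert ds2.t_groin >= ds0.t_groin
        dd0 = drip_and_drive_timeline(a, b, delta, workflow)
        dd1 = drip_and_drive_timeline(a + inc, b, delta, workflow)
        dd2 = drip_and_drive_timeline(a, b + inc, delta, workflow)
        assert dd1.t_needle >= dd0.t_needle and dd1.t_groin >= dd0.t_groin
        assert dd2.t_groin >= dd0.t_groin

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(a=st.floats(0, 150), b=st.floats(0, 150), delta=st.floats(0, 40))
    def test_matches_event_chain_oracle(self, a, b, delta, workflow):
        c = oracles.WORKFLOW_CONSTANTS
        assert mothership_timeline(a, delta, workflow).t_groin == pytest.approx(
            oracles.chain_mothership(a, delta, c)[1], abs=1e-9
        )
        ds = drip_and_ship_timeline(a, b, delta, workflow)
        assert (ds.t_needle, ds.t_groin) == pytest.approx(
            oracles.chain_drip_and_ship(a, b, delta, c), abs=1e-9
        )
        dd = drip_and_drive_timeline(a, b, delta, workflow)
        assert (dd.t_needle, dd.t_groin) == pytest.approx(
            oracles.chain_drip_and_drive(a, b, delta, c), abs=1e-9
        )

    def test_traces_are_consistent(self, workflow):
        """Each trace timestamp equals the previous plus a declared interval."""
        for tl in (
            mothership_timeline(37.0, 5.0, workflow),
            drip_and_ship_timeline(12.0, 55.0, 5.0, workflow),
            drip_and_drive_timeline(12.0, 48.0, 5.0, workflow),
        ):
            stamps = [t for _, t in tl.trace]
            assert stamps[0] == 0.0
            assert all(b >= a for a, b in zip(stamps, stamps[1:]))
            assert stamps[-1] == tl.t_groin
            events = dict(tl.trace)
            assert events["needle"] == tl.t_needle

    def test_vectorised_matches_scalar(self, workflow):
        rng = np.random.default_rng(7)
        a = rng.uniform(0, 120, 50)
        b = rng.uniform(0, 120, 50)
        tn, tg, _ = drip_and_ship_times(a, b, 12.0, workflow)
        for i in range(50):
            tl = drip_and_ship_timeline(float(a[i]), float(b[i]), 12.0, workflow)
            assert (tl.t_needle, tl.t_groin) == (tn[i], tg[i])

    def test_workflow_validation(self):
        with pytest.raises(ValueError):
            WorkflowTimes(dtn_psc=-1.0)
        with pytest.raises(ValueError):
            WorkflowTimes(dtg_csc_fast=70.0, dtg_csc=60.0)
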