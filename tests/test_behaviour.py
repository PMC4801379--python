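"""Sensing, detection-probability, and single-step movement rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import canopyfly as cf
from canopyfly.behaviour import Fly, FlyStatus, _cone_direction
from canopyfly.geometry import Canopy


def curve_value(x):
    # independent direct evaluation of the fitted curve
    return 163.659 - 64.852 * math.log(x + 1.636)


class TestDetectionCurve:
    def test_worked_example_at_10cm(self):
        # 10 cm = 2.5 grid units; the curve gives ~71.6%, printed as 71%
        y = cf.fruit_detection_probability(2.5)
        assert y == pytest.approx(curve_value(2.5), abs=1e-9)
        assert math.floor(y) == 71

    def test_clamping(self):
        assert cf.fruit_detection_probability(0.0) == 100.0  # unclamped 131.7
        assert curve_value(0.0) > 100.0
        # at the 40 cm detection radius: 163.659 - 64.852 ln(11.636) = 4.51
        assert cf.fruit_detection_probability(10.0) == pytest.approx(4.5055, abs=0.001)
        # unclamped curve crosses zero at x = exp(a/b) - c = 10.84
        zero_x = math.exp(163.659 / 64.852) - 1.636
        assert zero_x == pytest.approx(10.84, abs=0.01)
        assert cf.fruit_detection_probability(zero_x + 0.01) == 0.0
        assert cf.fruit_detection_probability(50.0) == 0.0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            cf.fruit_detection_probability(-0.1)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=60.0), st.floats(min_value=0.0, max_value=60.0))
    def test_monotone_and_bounded(self, x1, x2):
        lo, hi = sorted((x1, x2))
        p_lo = cf.fruit_detection_probability(lo)
        p_hi = cf.fruit_detection_probability(hi)
        assert 0.0 <= p_hi <= p_lo <= 100.0


def _lone_fly(position, heading=(0, 0, 1)):
    return Fly(id=0, position=np.array(position, float), heading=np.array(heading, float))


def _custom_canopy(veg, fruit, center=(8.0, 8.0)):
    return Canopy(
        shape="closed", seed=None,
        veg=np.array(veg, int).reshape(-1, 3),
        fruit=np.array(fruit, int).reshape(-1, 3),
        center=center, radius=10.0, base_z=5, top_z=29,
        has_radial_partition=False,
    )


class TestSenseFruit:
    def test_no_fruit_in_range_consumes_no_randomness(self, spec, rng):
        canopy = _custom_canopy([(8, 8, 20)], [(8, 8, 25)])
        fly = _lone_fly((40, 40, 10))
        state_before = rng.bit_generator.state
        assert cf.sense_fruit(fly, canopy, spec, rng) is None
        assert rng.bit_generator.state == state_before

    def test_very_close_fruit_always_detected(self, spec, rng):
        # at 0.5 units the curve exceeds 100 and clamps: certain detection
        canopy = _custom_canopy([(8, 8, 20)], [(8, 8, 12)])
        fly = _lone_fly((8.0, 8.0, 11.5))
        for _ in range(200):
            assert cf.sense_fruit(fly, canopy, spec, rng) == 0

    def test_detection_frequency_matches_curve(self, spec):
        # Monte Carlo at 2.5 units against the analytic Bernoulli probability
        canopy = _custom_canopy([(8, 8, 20)], [(8, 8, 12)])
        fly = _lone_fly((8.0, 8.0, 9.5))
        p_expected = cf.fruit_detection_probability(2.5) / 100.0
        rng = np.random.default_rng(777)
        hits = sum(
            cf.sense_fruit(fly, canopy, spec, rng) is not None for _ in range(10_000)
        )
        assert hits / 10_000 == pytest.approx(p_expected, abs=0.01)

    def test_resting_fruit_is_not_a_candidate(self, spec, rng):
        canopy = _custom_canopy([(8, 8, 20)], [(8, 8, 12)])
        fly = _lone_fly((8.0, 8.0, 12.0))  # sitting on the fruit
        assert cf.sense_fruit(fly, canopy, spec, rng) is None


class TestSelectFoliageTarget:
    def test_single_cube_always_chosen(self, spec, rng):
        canopy = _custom_canopy([(8, 8, 14)], [])
        fly = _lone_fly((8.0, 8.0, 10.0))
        for _ in range(50):
            assert cf.select_foliage_target(fly, canopy, spec, rng) == 0

    def test_empty_volume_returns_none(self, spec, rng):
        canopy = _custom_canopy([(8, 8, 28)], [])
        fly = _lone_fly((8.0, 8.0, 10.0))  # cube is 18 units away
        assert cf.select_foliage_target(fly, canopy, spec, rng) is None

    def test_symmetric_cubes_chosen_equally(self, spec):
        # two equidistant cubes mirrored about the vertical through the fly
        canopy = _custom_canopy([(6, 8, 12), (10, 8, 12)], [])
        fly = _lone_fly((8.0, 8.0, 10.0))
        rng = np.random.default_rng(99)
        picks = [cf.select_foliage_target(fly, canopy, spec, rng) for _ in range(10_000)]
        frac = np.mean(np.array(picks) == 0)
        assert frac == pytest.approx(0.5, abs=0.02)


class TestTopAndEdge:
    def test_above_all_vegetation_is_top(self, tiny_canopy, spec):
        fly = _lone_fly((8.0, 8.0, 40.0))
        assert cf.at_canopy_top(fly, tiny_canopy, spec)

    def test_interior_of_closed_canopy(self, closed_canopy, spec):
        fly = _lone_fly((32.0, 32.0, 17.0), heading=(1, 0, 0))
        assert not cf.at_canopy_top(fly, closed_canopy, spec)
        assert not cf.at_canopy_edge(fly, closed_canopy, spec)

    def test_matches_cone_count_oracle(self, closed_canopy, spec, rng):
        for _ in range(100):
            pos = rng.uniform([14, 14, 6], [50, 50, 32])
            heading = rng.normal(size=3)
            heading[2] = abs(heading[2])
            fly = _lone_fly(pos, heading=heading)
            veg = closed_canopy.veg.astype(float)
            rel = veg - pos
            d = np.linalg.norm(rel, axis=1)
            keep = d > 1e-9
            top_expected = not np.any(
                keep & (d <= spec.detection_radius) & (rel[:, 2] >= 0)
            )
            assert cf.at_canopy_top(fly, closed_canopy, spec) == top_expected
            h = np.array([heading[0], heading[1], 0.0])
            h /= np.linalg.norm(h)
            edge_expected = not np.any(
                keep & (rel @ h >= d * math.cos(math.radians(30)))
            )
            assert cf.at_canopy_edge(fly, closed_canopy, spec) == edge_expected


class TestStepFly:
    def test_departs_top_without_logging(self, spec, rng):
        canopy = _custom_canopy([(8, 8, 10)], [])
        fly = _lone_fly((8.0, 8.0, 25.0))  # vegetation far below only
        cf.step_fly(fly, canopy, spec, rng)
        assert fly.status is FlyStatus.DEPARTED_TOP
        assert fly.minutes_elapsed == 0 and fly.visit_log == []

    def test_adjacent_fruit_landing(self, spec, rng):
        # fly on the axis, vegetation above (defeats the top check), fruit
        # one unit away with a clear line: detection certain, lands on fruit
        canopy = _custom_canopy([(8, 8, 15), (8, 8, 18)], [(9, 8, 10)])
        fly = _lone_fly((8.0, 8.0, 10.0))
        cf.step_fly(fly, canopy, spec, rng)
        assert fly.minutes_elapsed == 1
        assert fly.visit_log == [(1, (9, 8, 10), "fruit")]
        assert canopy.fruit_visits[0] == 1

    def test_edge_departure_fraction(self, spec):
        # fly at the canopy edge facing outward, with vegetation above it so
        # only the edge gate can fire; departure rate must match the 20% rule
        canopy = _custom_canopy([(20, 8, 22)], [], center=(8.0, 8.0))
        rng = np.random.default_rng(31)
        departed = 0
        n = 10_000
        for _ in range(n):
            fly = _lone_fly((22.0, 8.0, 15.0), heading=(1, 0, 0))
            assert cf.at_canopy_edge(fly, canopy, spec)
            assert not cf.at_canopy_top(fly, canopy, spec)
            cf.step_fly(fly, canopy, spec, rng)
            departed += fly.status is FlyStatus.DEPARTED_EDGE
        assert departed / n == pytest.approx(0.2, abs=0.01)

    def test_zero_leave_probability_never_departs_edge(self):
        spec = cf.SensingSpec(leave_probability_edge=0.0)
        canopy = _custom_canopy([(20, 8, 22)], [], center=(8.0, 8.0))
        rng = np.random.default_rng(5)
        for _ in range(300):
            fly = _lone_fly((22.0, 8.0, 15.0), heading=(1, 0, 0))
            cf.step_fly(fly, canopy, spec, rng)
            assert fly.status is not FlyStatus.DEPARTED_EDGE

    def test_minutes_advance_by_one_unless_departed(self, closed_canopy, spec, rng):
        for _ in range(50):
            start = rng.uniform([20, 20, 8], [44, 44, 28])
            fly = _lone_fly(start, heading=rng.normal(size=3))
            before = fly.minutes_elapsed
            cf.step_fly(fly, closed_canopy, spec, rng)
            if fly.status is FlyStatus.FORAGING:
                assert fly.minutes_elapsed == before + 1
            else:
                assert fly.minutes_elapsed == before

    def test_stepping_departed_fly_rejected(self, tiny_canopy, spec, rng):
        fly = _lone_fly((8, 8, 40))
        cf.step_fly(fly, tiny_canopy, spec, rng)
        assert fly.status is FlyStatus.DEPARTED_TOP
        with pytest.raises(ValueError):
            cf.step_fly(fly, tiny_canopy, spec, rng)


def test_cone_direction_within_half_angle(rng):
    for half in (math.radians(15), math.radians(110), math.pi / 2):
        for _ in range(200):
            v = _cone_direction(rng, half)
            assert np.linalg.norm(v) == pytest.approx(1.0)
            assert math.acos(np.clip(v[2], -1, 1)) <= half + 1e-9


def test_sensing_spec_validation():
    with pytest.raises(ValueError):
        cf.SensingSpec(detection_radius=0)
    with pytest.raises(ValueError):
        cf.SensingSpec(leave_probability_edge=1.5)
    with pytest.raises(ValueError):
        cf.SensingSpec(fov_foliage=400)
    assert cf.SensingSpec().hop_range == (1.0, 10.0)
    assert cf.SensingSpec(detection_radius=0.5).hop_range == (0.5, 0.5)
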