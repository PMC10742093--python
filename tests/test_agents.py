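import math

import numpy as np
import pytest

from predprey.agents import (
    Cluster,
    MotionState,
    PredatorMode,
    PredatorState,
    cluster_preys,
    move,
    predator_energy_update,
    predator_step,
    prey_energy_update,
    prey_escape_heading,
    prey_gather_heading,
    prey_select_state,
    prey_wander_heading,
)
from predprey.config import SimConfig
from predprey.rng import make_rng
from predprey.vision import VisualPercept


def percept(matched=0.0, apparent=0.0, bearing=None):
    return VisualPercept(matched, apparent, bearing, 30.0 if bearing is not None else None)


class TestPreySelectState:
    THS = 0.05

    def test_escape_dominates_any_percept(self):
        p = percept(matched=0.9, apparent=0.9, bearing=0.0)
        assert prey_select_state(3.0, p, 2.0, 0.0, self.THS) == MotionState.ESCAPE

    def test_escape_dominance_exhaustive_grid(self):
        """odor_sum > fe forces ESCAPE for every combination of rule inputs."""
        for odor in (0.01, 1.0, 5.0, 19.0):
            for fe in (0.0, 0.005, 0.9, 4.9):
                if odor <= fe:
                    continue
                for matched, apparent, bearing in [
                    (0.0, 0.0, None), (0.2, 0.01, 0.3), (0.2, 0.5, 0.3), (1.0, 1.0, 2.0),
                ]:
                    got = prey_select_state(
                        odor, percept(matched, apparent, bearing), fe, 0.0, self.THS
                    )
                    assert got == MotionState.ESCAPE

    def test_gather_without_odor(self):
        p = percept(matched=0.05, apparent=0.01, bearing=1.0)
        assert prey_select_state(0.0, p, 2.0, 0.04, self.THS) == MotionState.GATHER

    def test_wander_when_nothing_visible(self):
        assert prey_select_state(0.0, percept(), 2.0, 0.04, self.THS) == MotionState.WANDER

    def test_halt_when_mate_large(self):
        p = percept(matched=0.06, apparent=0.08, bearing=1.0)
        assert prey_select_state(0.0, p, 2.0, 0.05, self.THS) == MotionState.HALT

    def test_detected_odor_suppresses_gathering(self):
        """Sub-threshold but detected odor forbids settling (cluster dispersal)."""
        p = percept(matched=0.5, apparent=0.5, bearing=1.0)
        got = prey_select_state(1.0, p, 5.0, 0.0, self.THS, odor_detection_min=0.05)
        assert got == MotionState.WANDER


class TestHeadingRules:
    def test_escape_keeps_course_when_odor_falls(self):
        rng = make_rng(0, "escape")
        assert prey_escape_heading(1.0, 4.0, 5.0, rng) == 1.0

    def test_escape_redraws_when_odor_rises(self):
        rng = make_rng(0, "escape")
        h = prey_escape_heading(1.0, 5.0, 4.0, rng)
        assert h != 1.0 and 0 <= h < 2 * math.pi

    def test_escape_zero_change_keeps_course(self):
        rng = make_rng(0, "escape")
        assert prey_escape_heading(1.0, 4.0, 4.0, rng) == 1.0

    @pytest.mark.parametrize(
        "mate,expected",
        [((10.0, 0.0), 0.0), ((0.0, 10.0), math.pi / 2), ((-5.0, 0.0), math.pi)],
    )
    def test_gather_heads_to_nearest_mate(self, mate, expected):
        p = percept(matched=0.1, apparent=0.02, bearing=math.atan2(mate[1], mate[0]))
        assert prey_gather_heading((0.0, 0.0), p) == pytest.approx(expected)

    def test_gather_requires_visible_mate(self):
        with pytest.raises(ValueError):
            prey_gather_heading((0.0, 0.0), percept())

    def test_wander_turn_bounded(self):
        rng = make_rng(3, "wander")
        h = 1.0
        for _ in range(500):
            h2 = prey_wander_heading(h, rng, math.pi / 6)
            diff = (h2 - h + math.pi) % (2 * math.pi) - math.pi
            assert abs(diff) <= math.pi / 6 + 1e-12
            h = h2

    def test_wander_turn_unbiased(self):
        """Sample-mean oracle: mean turn ~ 0 within 3 sigma / sqrt(n)."""
        rng = make_rng(5, "wander")
        max_turn = math.pi / 6
        turns = []
        h = 0.0
        for _ in range(10_000):
            h2 = prey_wander_heading(h, rng, max_turn)
            turns.append((h2 - h + math.pi) % (2 * math.pi) - math.pi)
            h = h2
        sigma = max_turn / math.sqrt(3)
        assert abs(np.mean(turns)) < 3 * sigma / math.sqrt(len(turns))


class TestEnergyRules:
    def test_prey_rates(self, default_cfg):
        assert prey_energy_update(10.0, MotionState.HALT, 0.0, default_cfg) == pytest.approx(11.2)
        assert prey_energy_update(10.0, MotionState.WANDER, 1.0, default_cfg) == pytest.approx(9.8)
        assert prey_energy_update(10.0, MotionState.GATHER, 1.0, default_cfg) == pytest.approx(9.8)
        assert prey_energy_update(10.0, MotionState.ESCAPE, 2.0, default_cfg) == pytest.approx(9.4)

    def test_predator_rates(self, default_cfg):
        assert predator_energy_update(50.0, PredatorMode.HUNT, 0, default_cfg) == pytest.approx(46.7)
        assert predator_energy_update(50.0, PredatorMode.HUNT, 2, default_cfg) == pytest.approx(50.7)
        assert predator_energy_update(120.0, PredatorMode.REST, 0, default_cfg) == pytest.approx(119.5)

    def test_predator_energy_floors_at_zero(self, default_cfg):
        assert predator_energy_update(1.0, PredatorMode.HUNT, 0, default_cfg) == 0.0


class TestClusterPreys:
    def test_three_point_cluster_and_outlier(self):
        pts = [(0, 0), (1, 0), (0, 1), (100, 100)]
        clusters = cluster_preys(pts, link_distance=2.0)
        assert len(clusters) == 2
        big = max(clusters, key=lambda c: len(c.members))
        assert big.members == (0, 1, 2)
        assert np.allclose(big.centroid, (1 / 3, 1 / 3))

    def test_all_far_apart_gives_singletons(self):
        pts = [(0, 0), (50, 0), (0, 50)]
        clusters = cluster_preys(pts, link_distance=5.0)
        assert [c.members for c in clusters] == [(0,), (1,), (2,)]

    def test_empty_input(self):
        assert cluster_preys([], 5.0) == []

    def test_matches_transitive_closure_oracle(self, np_rng):
        """Oracle: O(n^3) boolean transitive closure of the link relation."""
        pts = np_rng.uniform(0, 40, size=(30, 2))
        link = 5.0
        n = len(pts)
        reach = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(n):
                reach[i, j] = i == j or np.hypot(*(pts[i] - pts[j])) <= link
        for k in range(n):
            for i in range(n):
                for j in range(n):
                    reach[i, j] = reach[i, j] or (reach[i, k] and reach[k, j])
        oracle = {tuple(sorted(np.flatnonzero(reach[i]))) for i in range(n)}
        got = {c.members for c in cluster_preys(pts, link)}
        assert got == oracle

    def test_partition_property(self, np_rng):
        pts = np_rng.uniform(0, 60, size=(25, 2))
        clusters = cluster_preys(pts, 8.0)
        seen = sorted(i for c in clusters for i in c.members)
        assert seen == list(range(25))


class TestPredatorStep:
    def test_heads_to_largest_cluster_centroid(self, default_cfg):
        state = PredatorState(pos=np.zeros(2), heading=2.0, energy=50.0)
        clusters = [
            Cluster((0, 1), np.array([10.0, 0.0])),
            Cluster((2,), np.array([-10.0, 0.0])),
        ]
        out = predator_step(state, clusters, default_cfg)
        assert out.heading == pytest.approx(0.0)
        assert out.pos[0] == pytest.approx(default_cfg.speed_predator)

    def test_rests_at_threshold_with_zero_displacement(self, default_cfg):
        state = PredatorState(pos=np.array([1.0, 2.0]), heading=0.5, energy=default_cfg.thse)
        out = predator_step(state, [Cluster((0,), np.array([50.0, 0.0]))], default_cfg)
        assert out.mode == PredatorMode.REST
        assert np.allclose(out.pos, (1.0, 2.0))

    def test_resumes_hunting_after_hysteresis_drain(self, default_cfg):
        resting = PredatorState(
            pos=np.zeros(2), heading=0.0,
            energy=default_cfg.thse - default_cfg.predator_rest_hysteresis - 1,
            mode=PredatorMode.REST,
        )
        out = predator_step(resting, [Cluster((0,), np.array([50.0, 0.0]))], default_cfg)
        assert out.mode == PredatorMode.HUNT

    def test_equal_clusters_deterministic_tiebreak(self, default_cfg):
        state = PredatorState(pos=np.zeros(2), heading=0.0, energy=10.0)
        clusters = [
            Cluster((0,), np.array([0.0, 30.0])),
            Cluster((1,), np.array([30.0, 0.0])),
        ]
        out = predator_step(state, clusters, default_cfg)
        assert out.heading == pytest.approx(math.pi / 2)  # lowest member index wins

    def test_no_prey_stays_put(self, default_cfg):
        state = PredatorState(pos=np.array([3.0, 4.0]), heading=1.0, energy=10.0)
        out = predator_step(state, [], default_cfg)
        assert np.allclose(out.pos, (3.0, 4.0))


class TestMove:
    def test_straight_step(self):
        pos, heading = move((0.0, 0.0), 0.0, 1.0, 200.0)
        assert np.allclose(pos, (1.0, 0.0)) and heading == 0.0

    def test_wall_reflection_and_clamp(self):
        pos, heading = move((99.5, 0.0), 0.0, 1.0, 200.0)
        assert pos[0] == pytest.approx(100.0)
        assert heading == pytest.approx(math.pi)

    def test_corner_reflects_both_axes(self):
        pos, heading = move((99.9, 99.9), math.pi / 4, 1.0, 200.0)
        assert pos[0] == pytest.approx(100.0) and pos[1] == pytest.approx(100.0)
        assert heading == pytest.approx(math.pi + math.pi / 4)

    def test_overlapping_agents_move_independently(self):
        a = move((5.0, 5.0), 1.0, 1.0, 200.0)
        b = move((5.0, 5.0), 1.0, 1.0, 200.0)
        assert np.allclose(a[0], b[0]) and a[1] == b[1]


class TestRandomWalkPolicy:
    def test_random_walk_predator_moves_without_clusters(self, default_cfg):
        import dataclasses as dc

        from predprey.rng import make_rng

        cfg = dc.replace(default_cfg, predator_policy="random_walk")
        state = PredatorState(pos=np.zeros(2), heading=0.0, energy=10.0)
        out = predator_step(state, [], cfg, make_rng(0, "wander"))
        assert np.hypot(*out.pos) == pytest.approx(cfg.speed_predator)
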