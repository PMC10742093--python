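"""Agent state machines, energy bookkeeping, clustering, and motion.

Prey cycle through four motion states re-evaluated every step from fresh
percepts: ESCAPE (odor above the heritable threshold ``fe``; strictly highest
priority), GATHER / HALT (mates' matched-pixel fraction above the heritable
threshold ``fg``, halting once the nearest mate looks large enough), and
WANDER otherwise.  Energy couples to the state: halting replenishes, moving
costs a constant amount, escaping costs proportionally to the escape speed —
the trade-off that generates selective pressure on ``fe`` and ``fg``.

The predator pursues the centroid of the largest prey cluster while emitting
odor (constant energy cost), digests prey standing inside its odor field, and
rests once its energy passes ``thse`` (with hysteresis, so it resumes hunting
after a small drain).
"""

from __future__ import annotations

import dataclasses
import enum
import math
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .config import SimConfig
from .rng import RNGStream
from .vision import VisualPercept

__all__ = [
    "MotionState", "PredatorMode", "PreyState", "PredatorState", "Cluster",
    "prey_select_state", "prey_escape_heading", "prey_gather_heading",
    "prey_wander_heading", "prey_energy_update", "cluster_preys",
    "predator_step", "predator_energy_update", "move",
]


class MotionState(enum.IntEnum):
    WANDER = 0
    GATHER = 1
    HALT = 2      # zero-speed sub-state of gathering
    ESCAPE = 3


class PredatorMode(enum.IntEnum):
    HUNT = 0
    REST = 1


@dataclasses.dataclass
class PreyState:
    id: int
    pos: np.ndarray
    heading: float
    energy: float
    fe: float                     # escaping preference factor
    fg: float                     # gathering preference factor
    motion_state: MotionState = MotionState.WANDER
    speed: float = 0.0
    prev_odor_sum: float = 0.0
    alive: bool = True
    deaths: int = 0


@dataclasses.dataclass
class PredatorState:
    pos: np.ndarray
    heading: float
    energy: float
    mode: PredatorMode = PredatorMode.HUNT


@dataclasses.dataclass
class Cluster:
    members: Tuple[int, ...]      # prey indices, ascending
    centroid: np.ndarray


# -- prey rules ---------------------------------------------------------------

def prey_select_state(
    odor_sum: float,
    percept: VisualPercept,
    fe: float,
    fg: float,
    ths_gather_stop: float,
    odor_detection_min: float = 0.0,
) -> MotionState:
    """Behaviour priority: escape > gather/halt > wander.

    Visual gathering only happens in the absence of detected odor: a summed
    sensor reading at or above ``odor_detection_min`` suppresses gathering
    even when it does not exceed the escape threshold ``fe`` (so a bold prey
    inside the predator's field keeps moving rather than settling to rest —
    the predator disperses clusters).  Gathering additionally requires a
    visible mate (a percept with zero matched pixels cannot steer an
    approach even when ``fg`` is 0).
    """
    if odor_sum > fe:
        return MotionState.ESCAPE
    no_odor = odor_sum < odor_detection_min or odor_sum == 0.0
    if no_odor and percept.nearest_bearing is not None and percept.matched_fraction >= fg:
        if percept.largest_apparent >= ths_gather_stop:
            return MotionState.HALT
        return MotionState.GATHER
    return MotionState.WANDER


def prey_escape_heading(
    heading: float, odor_sum: float, prev_odor_sum: float, rng: RNGStream
) -> float:
    """Abrupt uniform heading redraw when the summed odor reading is rising."""
    if odor_sum - prev_odor_sum > 0.0:
        return float(rng.uniform(0.0, 2.0 * math.pi))
    return heading


def prey_gather_heading(viewer_pos, percept: VisualPercept) -> float:
    """Turn toward the nearest visible mate."""
    if percept.nearest_bearing is None:
        raise ValueError("gather heading requires a visible mate")
    return float(percept.nearest_bearing)


def prey_wander_heading(heading: float, rng: RNGStream, max_turn: float) -> float:
    """Bounded random turn, wrapped to [0, 2*pi)."""
    if max_turn <= 0:
        raise ValueError("max_turn must be positive")
    turn = float(rng.uniform(-max_turn, max_turn))
    return (heading + turn) % (2.0 * math.pi)


def prey_energy_update(
    e: float, motion_state: MotionState, speed: float, cfg: SimConfig
) -> float:
    """One-step prey energy change given its motion state."""
    tau = cfg.time_unit
    if motion_state == MotionState.HALT:
        return e + cfg.rest_gain_rate * tau
    if motion_state == MotionState.ESCAPE:
        return e - cfg.escape_cost_coeff * speed * tau
    return e - cfg.move_cost_rate * tau        # WANDER or GATHER


# -- clustering & predator ----------------------------------------------------

def cluster_preys(positions: Sequence, link_distance: float) -> List[Cluster]:
    """Single-linkage connected components at the given link distance.

    Two prey share a cluster iff a chain of pairwise distances at most
    ``link_distance`` connects them.  Clusters are ordered by their smallest
    member index, so downstream tie-breaks are deterministic.
    """
    if link_distance <= 0:
        raise ValueError("link_distance must be positive")
    pts = np.asarray(positions, dtype=float)
    n = len(pts)
    if n == 0:
        return []
    if n == 1:
        return [Cluster((0,), pts[0].copy())]
    adj = squareform(pdist(pts)) <= link_distance
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    clusters = []
    for c in range(n_comp):
        members = tuple(int(i) for i in np.flatnonzero(labels == c))
        clusters.append(Cluster(members, pts[list(members)].mean(axis=0)))
    clusters.sort(key=lambda cl: cl.members[0])
    return clusters


def largest_cluster(clusters: Sequence[Cluster]) -> Optional[Cluster]:
    """Largest cluster; ties broken by the lowest member index (list order)."""
    if not clusters:
        return None
    best = clusters[0]
    for cl in clusters[1:]:
        if len(cl.members) > len(best.members):
            best = cl
    return best


def predator_step(
    state: PredatorState,
    clusters: Sequence[Cluster],
    cfg: SimConfig,
    rng: Optional[RNGStream] = None,
) -> PredatorState:
    """Mode update, steering, and motion for the predator.

    Switches to REST the step its energy reaches ``thse`` (zero displacement
    that step) and back to HUNT once drained below ``thse - hysteresis``.
    With no alive prey (degenerate world) it stays in place.
    """
    mode = state.mode
    if mode == PredatorMode.HUNT and state.energy >= cfg.thse:
        mode = PredatorMode.REST
    elif mode == PredatorMode.REST and state.energy < cfg.thse - cfg.predator_rest_hysteresis:
        mode = PredatorMode.HUNT
    pos = state.pos.copy()
    heading = state.heading
    if mode == PredatorMode.HUNT:
        if cfg.predator_policy == "random_walk":
            if rng is None:
                raise ValueError("random_walk policy needs an RNG stream")
            heading = prey_wander_heading(heading, rng, cfg.wander_max_turn)
            pos, heading = move(pos, heading, cfg.speed_predator, cfg.arena_length)
        else:
            target = largest_cluster(clusters)
            if target is not None:
                delta = target.centroid - pos
                if np.hypot(delta[0], delta[1]) > 1e-12:
                    heading = float(math.atan2(delta[1], delta[0]))
                pos, heading = move(pos, heading, cfg.speed_predator, cfg.arena_length)
    return PredatorState(pos=pos, heading=heading, energy=state.energy, mode=mode)


def predator_energy_update(e: float, mode: PredatorMode, n_digesting: int, cfg: SimConfig) -> float:
    """Hunting costs odor emission and gains from digestion; resting drains slowly.

    Energy is a non-negative stock: the predator cannot die, so instead of
    going negative while starving its energy saturates at zero.
    """
    if n_digesting < 0:
        raise ValueError("n_digesting must be non-negative")
    tau = cfg.time_unit
    if mode == PredatorMode.HUNT:
        e = e - cfg.emit_cost_rate * tau + cfg.digest_gain_rate * n_digesting * tau
    else:
        e = e - cfg.rest_metabolic_rate * tau
    return max(e, 0.0)


# -- motion -------------------------------------------------------------------

def move(
    pos, heading: float, speed: float, arena_length: float, rng: Optional[RNGStream] = None
) -> Tuple[np.ndarray, float]:
    """Advance one step with specular wall reflection; no agent collisions.

    A candidate step leaving ``[-L/2, L/2]^2`` reflects the heading about the
    violated wall's normal and clamps the position onto the boundary.
    """
    half = arena_length / 2.0
    x = pos[0] + speed * math.cos(heading)
    y = pos[1] + speed * math.sin(heading)
    if x > half or x < -half:
        heading = math.pi - heading
        x = min(max(x, -half), half)
    if y > half or y < -half:
        heading = -heading
        y = min(max(y, -half), half)
    return np.array([x, y]), heading % (2.0 * math.pi)
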