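"""Synchronous world update and run logging.

Each step applies a fixed phase order, so results are independent of agent
iteration order:

1. odor field evolves (diffusion + evaporation), then the predator injects at
   its current position if it entered the step hunting;
2. every prey's percept and odor-sensor readings are computed from the
   pre-step positions (synchronous update);
3. prey select a motion state and apply the matching heading/speed rule;
4. the predator clusters the prey, updates its hunt/rest mode, and steers;
5. all prey move (specular wall reflection);
6. energies update — prey from their motion state, the predator from odor
   emission and digestion counted at post-move prey positions;
7. prey whose energy fell below zero die and are reborn;
8. each prey's previous-odor memory is refreshed.

``run`` produces a :class:`SimLog` holding the complete per-step history;
``(config, seed)`` fully determines it.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import agents, evolution
from .agents import MotionState, PredatorMode, PredatorState, PreyState
from .config import SimConfig
from .odor import OdorField, sensor_positions
from .rng import RNGStream, make_rng
from .vision import CameraModel, compose_percept

__all__ = ["World", "SimLog", "SimLogFormatError", "step", "run", "write_log", "read_log"]

_STREAMS = ("init", "wander", "escape", "rebirth")


class SimLogFormatError(ValueError):
    """A log directory is missing, truncated, or internally inconsistent."""


@dataclasses.dataclass
class World:
    preys: List[PreyState]
    predator: Optional[PredatorState]
    field: OdorField
    t: int = 0


@dataclasses.dataclass
class SimLog:
    """Complete per-step record of one run (t = 0 snapshot included).

    All per-step arrays have leading dimension ``n_steps + 1``.  ``prey_state``
    holds :class:`MotionState` codes; ``pred_n_digest[t]`` is the number of
    prey digested during step ``t`` (0 at t = 0 and while resting).
    """

    config: SimConfig
    seed: int
    prey_energy: np.ndarray      # (T+1, n)
    prey_state: np.ndarray       # (T+1, n) int8
    prey_x: np.ndarray
    prey_y: np.ndarray
    prey_heading: np.ndarray
    prey_fe: np.ndarray
    prey_fg: np.ndarray
    pred_energy: np.ndarray      # (T+1,)
    pred_x: np.ndarray
    pred_y: np.ndarray
    pred_heading: np.ndarray
    pred_mode: np.ndarray        # (T+1,) int8
    pred_n_digest: np.ndarray    # (T+1,) int32
    prey_digested: np.ndarray    # (T+1, n) bool: lost energy to digestion that step
    deaths: List[evolution.DeathEvent]

    @property
    def n_steps(self) -> int:
        return self.prey_energy.shape[0] - 1

    def mean_prey_energy(self) -> np.ndarray:
        return self.prey_energy.mean(axis=1)

    def arrays_equal(self, other: "SimLog") -> bool:
        for f in dataclasses.fields(self):
            if f.name in ("config", "seed", "deaths"):
                continue
            if not np.array_equal(getattr(self, f.name), getattr(other, f.name)):
                return False
        return self.deaths == other.deaths and self.seed == other.seed


def _camera(cfg: SimConfig) -> CameraModel:
    return CameraModel(
        hfov=np.deg2rad(cfg.camera_hfov_deg),
        vfov=np.deg2rad(cfg.camera_vfov_deg),
        width=cfg.image_width,
        height=cfg.image_height,
        eye_height=cfg.prey_height,
    )


def init_world(cfg: SimConfig, rngs: Dict[str, RNGStream]) -> World:
    preys = evolution.init_population(cfg, rngs["init"])
    predator = None
    if cfg.n_predator >= 1:
        half = cfg.arena_length / 2.0
        r = rngs["init"]
        predator = PredatorState(
            pos=np.array([r.uniform(-half, half), r.uniform(-half, half)]),
            heading=float(r.uniform(0.0, 2.0 * np.pi)),
            energy=cfg.initial_energy_predator,
            mode=PredatorMode.HUNT,
        )
    field = OdorField(cfg.arena_length, cfg.field_cell_size)
    return World(preys=preys, predator=predator, field=field, t=0)


def step(
    world: World,
    cfg: SimConfig,
    rngs: Dict[str, RNGStream],
    camera: Optional[CameraModel] = None,
    _vision_buffer: Optional[np.ndarray] = None,
) -> tuple[World, int, List[evolution.DeathEvent]]:
    """Advance one step.

    Returns ``(world, n_digesting, digested_flags, states_used, death_events)``
    for this step; ``digested_flags[i]`` says whether prey slot ``i`` lost
    energy to the predator's digestion, and ``states_used[i]`` is the motion
    state that drove slot ``i`` this step (for a slot reborn this step, the
    dying prey's last state — the reborn child has not acted yet).
    """
    if camera is None:
        camera = _camera(cfg)
    preys = world.preys
    pred = world.predator

    # (1) field dynamics, then injection along the predator trajectory
    world.field.evolve(cfg.field_evaporation, cfg.field_diffusion)
    if pred is not None and pred.mode == PredatorMode.HUNT:
        world.field.inject(pred.pos, cfg.odor_injection_width, cfg.injection_amplitude)

    # (2) synchronous sensing from pre-step positions
    positions = [p.pos for p in preys]
    odor_sums = []
    percepts = []
    for i, p in enumerate(preys):
        left, right = sensor_positions(p.pos, p.heading, cfg.odor_sensor_offset)
        odor_sums.append(world.field.sample(left) + world.field.sample(right))
        mates = positions[:i] + positions[i + 1 :]
        percepts.append(
            compose_percept(
                p.pos, p.heading, mates, cfg.prey_radius, cfg.prey_height,
                camera, _buffer=_vision_buffer,
            )
        )

    # (3) decisions and heading/speed rules
    for p, odor, percept in zip(preys, odor_sums, percepts):
        state = agents.prey_select_state(
            odor, percept, p.fe, p.fg, cfg.ths_gather_stop, cfg.odor_detection_min
        )
        p.motion_state = state
        if state == MotionState.ESCAPE:
            p.heading = agents.prey_escape_heading(
                p.heading, odor, p.prev_odor_sum, rngs["escape"]
            )
            p.speed = cfg.speed_escape
        elif state == MotionState.GATHER:
            p.heading = agents.prey_gather_heading(p.pos, percept)
            p.speed = cfg.speed_gather
        elif state == MotionState.HALT:
            p.speed = 0.0
        else:
            p.heading = agents.prey_wander_heading(p.heading, rngs["wander"], cfg.wander_max_turn)
            p.speed = cfg.speed_wander

    # (4) predator control (clusters from pre-move prey positions)
    if pred is not None:
        clusters = agents.cluster_preys(positions, cfg.cluster_link_distance)
        pred = agents.predator_step(pred, clusters, cfg, rngs.get("wander"))
        world.predator = pred

    # (5) prey motion
    for p in preys:
        if p.speed > 0.0:
            p.pos, p.heading = agents.move(p.pos, p.heading, p.speed, cfg.arena_length)

    # (6) energy updates; digestion at post-move prey positions.  Digestion is
    # an energy transfer: each prey inside the hunting predator's odor field
    # loses digest_gain_rate * tau and the predator gains the same amount.
    for p in preys:
        p.energy = agents.prey_energy_update(p.energy, p.motion_state, p.speed, cfg)
    n_digesting = 0
    digested = [False] * len(preys)
    if pred is not None:
        if pred.mode == PredatorMode.HUNT:
            for i, p in enumerate(preys):
                if world.field.sample(p.pos) >= cfg.digest_concentration_min:
                    digested[i] = True
                    p.energy -= cfg.digest_gain_rate * cfg.time_unit
                    n_digesting += 1
        pred.energy = agents.predator_energy_update(pred.energy, pred.mode, n_digesting, cfg)

    # motion states that actually drove this step's dynamics (a slot reborn
    # in phase 7 gets a fresh WANDER child; the log keeps the dying prey's
    # last state so the energy ledger stays replayable)
    states_used = [p.motion_state for p in preys]

    # (7) death -> rebirth (population size constant)
    events: List[evolution.DeathEvent] = []
    dead_idx = [i for i, p in enumerate(preys) if evolution.check_death(p)]
    survivors = [p for p in preys if not evolution.check_death(p)]
    for i in dead_idx:
        child = evolution.rebirth(preys[i], survivors, cfg, rngs["rebirth"])
        preys[i] = child
        events.append(
            evolution.DeathEvent(world.t + 1, child.id, child.fe, child.fg)
        )

    # (8) odor memory for the next step's escape-turn rule
    reborn = set(dead_idx)
    for i, (p, odor) in enumerate(zip(preys, odor_sums)):
        if i in reborn:
            continue  # freshly reborn this step: keep the reset memory
        p.prev_odor_sum = odor

    world.t += 1
    return world, n_digesting, digested, states_used, events


def run(cfg: SimConfig, seed: Optional[int] = None) -> SimLog:
    """Run ``cfg.n_steps`` steps from a fresh world; bit-reproducible per seed."""
    if seed is None:
        seed = cfg.seed
    rngs = {name: make_rng(seed, name) for name in _STREAMS}
    world = init_world(cfg, rngs)
    camera = _camera(cfg)
    buffer = np.zeros((camera.height, camera.width), dtype=bool)

    T, n = cfg.n_steps, cfg.n_prey
    log = SimLog(
        config=cfg,
        seed=seed,
        prey_energy=np.zeros((T + 1, n)),
        prey_state=np.zeros((T + 1, n), dtype=np.int8),
        prey_x=np.zeros((T + 1, n)),
        prey_y=np.zeros((T + 1, n)),
        prey_heading=np.zeros((T + 1, n)),
        prey_fe=np.zeros((T + 1, n)),
        prey_fg=np.zeros((T + 1, n)),
        pred_energy=np.zeros(T + 1),
        pred_x=np.zeros(T + 1),
        pred_y=np.zeros(T + 1),
        pred_heading=np.zeros(T + 1),
        pred_mode=np.zeros(T + 1, dtype=np.int8),
        pred_n_digest=np.zeros(T + 1, dtype=np.int32),
        prey_digested=np.zeros((T + 1, n), dtype=bool),
        deaths=[],
    )
    _snapshot(log, world, 0, 0, [False] * n, [p.motion_state for p in world.preys])
    for t in range(T):
        world, n_digesting, digested, states_used, events = step(world, cfg, rngs, camera, buffer)
        _snapshot(log, world, t + 1, n_digesting, digested, states_used)
        log.deaths.extend(events)
    return log


def _snapshot(log: SimLog, world: World, t: int, n_digesting: int, digested, states_used) -> None:
    for i, p in enumerate(world.preys):
        log.prey_digested[t, i] = digested[i]
        log.prey_state[t, i] = int(states_used[i])
        log.prey_energy[t, i] = p.energy
        log.prey_x[t, i] = p.pos[0]
        log.prey_y[t, i] = p.pos[1]
        log.prey_heading[t, i] = p.heading
        log.prey_fe[t, i] = p.fe
        log.prey_fg[t, i] = p.fg
    pred = world.predator
    if pred is not None:
        log.pred_energy[t] = pred.energy
        log.pred_x[t] = pred.pos[0]
        log.pred_y[t] = pred.pos[1]
        log.pred_heading[t] = pred.heading
        log.pred_mode[t] = int(pred.mode)
    log.pred_n_digest[t] = n_digesting


# -- persistence ---------------------------------------------------------------

def write_log(log: SimLog, path: str | Path) -> None:
    """Write a log directory: prey.csv, predator.csv, deaths.csv, config.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    T1, n = log.prey_energy.shape
    t_col = np.repeat(np.arange(T1), n)
    id_col = np.tile(np.arange(n), T1)
    prey = pd.DataFrame(
        {
            "t": t_col,
            "id": id_col,
            "energy": log.prey_energy.ravel(),
            "state": log.prey_state.ravel(),
            "x": log.prey_x.ravel(),
            "y": log.prey_y.ravel(),
            "heading": log.prey_heading.ravel(),
            "fe": log.prey_fe.ravel(),
            "fg": log.prey_fg.ravel(),
            "digested": log.prey_digested.ravel().astype(int),
        }
    )
    prey.to_csv(path / "prey.csv", index=False, float_format="%.17g")
    pred = pd.DataFrame(
        {
            "t": np.arange(T1),
            "energy": log.pred_energy,
            "x": log.pred_x,
            "y": log.pred_y,
            "heading": log.pred_heading,
            "mode": log.pred_mode,
            "n_digest": log.pred_n_digest,
        }
    )
    pred.to_csv(path / "predator.csv", index=False, float_format="%.17g")
    deaths = pd.DataFrame(
        [(d.time_step, d.prey_id, d.inherited_fe, d.inherited_fg) for d in log.deaths],
        columns=["time_step", "prey_id", "inherited_fe", "inherited_fg"],
    )
    deaths.to_csv(path / "deaths.csv", index=False, float_format="%.17g")
    meta = {"seed": log.seed, "config": log.config.to_dict()}
    (path / "config.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_log(path: str | Path) -> SimLog:
    """Load a log directory written by :func:`write_log`; lossless round trip."""
    path = Path(path)
    for name in ("prey.csv", "predator.csv", "deaths.csv", "config.json"):
        if not (path / name).exists():
            raise SimLogFormatError(f"missing {name} in {path}")
    try:
        meta = json.loads((path / "config.json").read_text())
        cfg = SimConfig.from_dict(meta["config"])
        seed = int(meta["seed"])
        prey = pd.read_csv(path / "prey.csv", float_precision="round_trip")
        pred = pd.read_csv(path / "predator.csv", float_precision="round_trip")
        deaths = pd.read_csv(path / "deaths.csv", float_precision="round_trip")
    except (json.JSONDecodeError, KeyError, pd.errors.ParserError) as exc:
        raise SimLogFormatError(f"malformed log in {path}: {exc}") from exc
    T1 = cfg.n_steps + 1
    n = cfg.n_prey
    if len(prey) != T1 * n or len(pred) != T1:
        raise SimLogFormatError(
            f"log in {path} is truncated: expected {T1 * n} prey rows and "
            f"{T1} predator rows, found {len(prey)} and {len(pred)}"
        )

    def pivot(col: str, dtype=float) -> np.ndarray:
        return prey[col].to_numpy().reshape(T1, n).astype(dtype)

    return SimLog(
        config=cfg,
        seed=seed,
        prey_energy=pivot("energy"),
        prey_state=pivot("state", np.int8),
        prey_x=pivot("x"),
        prey_y=pivot("y"),
        prey_heading=pivot("heading"),
        prey_fe=pivot("fe"),
        prey_fg=pivot("fg"),
        prey_digested=pivot("digested", bool),
        pred_energy=pred["energy"].to_numpy(),
        pred_x=pred["x"].to_numpy(),
        pred_y=pred["y"].to_numpy(),
        pred_heading=pred["heading"].to_numpy(),
        pred_mode=pred["mode"].to_numpy().astype(np.int8),
        pred_n_digest=pred["n_digest"].to_numpy().astype(np.int32),
        deaths=[
            evolution.DeathEvent(int(r.time_step), int(r.prey_id), float(r.inherited_fe), float(r.inherited_fg))
            for r in deaths.itertuples()
        ],
    )
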