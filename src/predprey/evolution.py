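"""Steady-state evolution: death below zero energy, inheritance, rebirth.

A prey whose energy falls below zero dies and is immediately replaced, keeping
the population size constant.  The replacement inherits the two preference
factors from a parent sampled among the currently alive prey with probability
proportional to energy (fitter lineages propagate), perturbed by Gaussian
mutation and clipped to the configured factor ranges.  This event-driven
death-rebirth scheme — no crossover, no synchronous generations — is what
drives the factor distributions to converge under predation pressure.
"""

from __future__ import annotations

import dataclasses
from math import pi
from typing import List, Sequence

import numpy as np

from .agents import MotionState, PreyState
from .config import SimConfig
from .rng import RNGStream

__all__ = ["DeathEvent", "init_population", "check_death", "rebirth"]

_WEIGHT_FLOOR = 1e-6   # keeps the selection distribution well-defined


@dataclasses.dataclass(frozen=True)
class DeathEvent:
    time_step: int
    prey_id: int
    inherited_fe: float
    inherited_fg: float


def init_population(cfg: SimConfig, rng: RNGStream) -> List[PreyState]:
    """Fresh population: uniform factors, uniform poses, full initial energy."""
    half = cfg.arena_length / 2.0
    preys = []
    for i in range(cfg.n_prey):
        preys.append(
            PreyState(
                id=i,
                pos=np.array(
                    [rng.uniform(-half, half), rng.uniform(-half, half)]
                ),
                heading=float(rng.uniform(0.0, 2.0 * pi)),
                energy=cfg.initial_energy_prey,
                fe=float(rng.uniform(*cfg.fe_range)),
                fg=float(rng.uniform(*cfg.fg_range)),
                motion_state=MotionState.WANDER,
            )
        )
    return preys


def check_death(prey: PreyState) -> bool:
    """Death criterion: energy strictly below zero."""
    return prey.energy < 0.0


def _mutate(value: float, rng: RNGStream, sigma_frac: float, bounds) -> float:
    lo, hi = bounds
    sigma = sigma_frac * (hi - lo)
    if sigma > 0.0:
        value = value + float(rng.normal(0.0, sigma))
    return float(np.clip(value, lo, hi))


def rebirth(
    dead: PreyState, alive: Sequence[PreyState], cfg: SimConfig, rng: RNGStream
) -> PreyState:
    """Replace a dead prey in place (same id), inheriting mutated factors.

    Parent selection is energy-proportional over the alive prey (with a small
    positive floor on weights); with no survivors the factors are redrawn
    uniformly — a population restart.
    """
    if alive:
        weights = np.array([max(p.energy, _WEIGHT_FLOOR) for p in alive])
        idx = int(rng.choice(len(alive), p=weights / weights.sum()))
        parent = alive[idx]
        fe = _mutate(parent.fe, rng, cfg.mutation_sigma_frac, cfg.fe_range)
        fg = _mutate(parent.fg, rng, cfg.mutation_sigma_frac, cfg.fg_range)
    else:
        fe = float(rng.uniform(*cfg.fe_range))
        fg = float(rng.uniform(*cfg.fg_range))
    half = cfg.arena_length / 2.0
    return PreyState(
        id=dead.id,
        pos=np.array([rng.uniform(-half, half), rng.uniform(-half, half)]),
        heading=float(rng.uniform(0.0, 2.0 * pi)),
        energy=cfg.initial_energy_prey,
        fe=fe,
        fg=fg,
        motion_state=MotionState.WANDER,
        speed=0.0,
        prev_odor_sum=0.0,
        alive=True,
        deaths=dead.deaths + 1,
    )
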