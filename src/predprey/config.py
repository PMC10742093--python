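"""Simulation configuration: defaults, validation, and YAML/JSON round-trip.

All world, agent, energy, field, and analysis parameters for one run live in a
single flat :class:`SimConfig`.  Defaults encode the reference study conditions:
a square arena of side ``L = 200`` world units, odor injection width
``phi_w = 20``, 20 prey, 1 predator, 6000 steps, heritable preference factors
``fe in [0, 10]`` (escape threshold on summed odor) and ``fg in [0, 0.3]``
(gather threshold on the matched-pixel fraction).
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Any, Tuple

import yaml

__all__ = ["SimConfig", "ConfigError", "ValidationError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Malformed configuration document (unparseable or unknown keys)."""


class ValidationError(ConfigError):
    """A configuration field violates its invariant; ``field`` names it."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


@dataclasses.dataclass
class SimConfig:
    # world
    arena_length: float = 200.0          # square arena side L, world units
    odor_injection_width: float = 20.0   # phi_w, spatial scale of the odor bump
    n_prey: int = 20
    n_predator: int = 1
    n_steps: int = 6000                  # run horizon T
    time_unit: float = 1.0               # tau; multiplies all per-step energy rates

    # agent geometry / camera
    prey_radius: float = 10.0
    prey_height: float = 5.0
    camera_hfov_deg: float = 120.0
    camera_vfov_deg: float = 90.0
    image_width: int = 200
    image_height: int = 150

    # heritable factor ranges
    fe_range: Tuple[float, float] = (0.0, 10.0)
    fg_range: Tuple[float, float] = (0.0, 0.3)

    # thresholds
    eth: float = 20.0                    # prey-mean energy threshold (Tsy)
    thse: float = 100.0                  # predator rest threshold (Tsd)
    ths_gather_stop: float = 0.2         # apparent-size fraction that halts gathering

    # energy rates (per step, times tau)
    move_cost_rate: float = 0.2
    rest_gain_rate: float = 1.2
    emit_cost_rate: float = 3.3
    escape_cost_coeff: float = 0.3       # escape cost = coeff * speed * tau
    digest_gain_rate: float = 2.0        # predator gain per digesting prey
    rest_metabolic_rate: float = 0.5     # predator drain while resting

    # speeds, world units per step
    speed_wander: float = 1.0
    speed_gather: float = 1.0
    speed_escape: float = 2.0
    speed_predator: float = 1.5

    initial_energy_prey: float = 10.0
    initial_energy_predator: float = 10.0

    # clustering / evolution
    cluster_link_distance: float = 30.0  # 3 * prey_radius
    mutation_sigma_frac: float = 0.05    # sigma = frac * |factor range|

    # odor field
    field_cell_size: float = 1.0
    field_evaporation: float = 0.1       # multiplicative decay in (0, 1)
    field_diffusion: float = 0.05        # explicit 4-neighbour coefficient <= 0.25
    injection_amplitude: float = 1.0
    digest_concentration_min: float = 0.5  # "within the odor field" concentration cut
    odor_detection_min: float = 0.05       # summed reading below this counts as "no odor"

    # analysis
    n_hist_bins: int = 20
    kde_bandwidth_factor: float = 6.0

    # behaviour details
    wander_max_turn: float = math.pi / 6
    odor_sensor_offset: float = 10.0     # sensors at the base, +/- offset off-axis
    predator_rest_hysteresis: float = 10.0
    predator_policy: str = "cluster_seeking"  # or "random_walk" (robot parity)

    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.fe_range, list):
            self.fe_range = tuple(self.fe_range)
        if isinstance(self.fg_range, list):
            self.fg_range = tuple(self.fg_range)
        self.validate()

    # -- validation -----------------------------------------------------------

    def validate(self) -> None:
        pos = [
            "arena_length", "odor_injection_width", "n_prey",
            "time_unit", "prey_radius", "prey_height", "image_width",
            "image_height", "cluster_link_distance", "field_cell_size",
            "injection_amplitude", "n_hist_bins", "kde_bandwidth_factor",
            "wander_max_turn", "odor_sensor_offset",
        ]
        for name in pos:
            if not getattr(self, name) > 0:
                raise ValidationError(name, "must be strictly positive")
        if self.n_steps < 0:
            raise ValidationError("n_steps", "must be non-negative")
        if self.n_predator not in (0, 1):
            raise ValidationError("n_predator", "engine supports 0 or 1 predators")
        nonneg = [
            "move_cost_rate", "rest_gain_rate", "emit_cost_rate",
            "escape_cost_coeff", "digest_gain_rate", "rest_metabolic_rate",
            "speed_wander", "speed_gather", "speed_escape", "speed_predator",
            "field_diffusion", "digest_concentration_min", "odor_detection_min",
            "predator_rest_hysteresis", "seed",
        ]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValidationError(name, "must be non-negative")
        for name in ("fe_range", "fg_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(name, "must be a non-degenerate interval (lower < upper)")
        if not 0.0 < self.field_evaporation < 1.0:
            raise ValidationError("field_evaporation", "must lie strictly in (0, 1)")
        if self.field_diffusion > 0.25:
            raise ValidationError("field_diffusion", "explicit scheme unstable above 0.25")
        if not 0.0 < self.camera_hfov_deg <= 360.0:
            raise ValidationError("camera_hfov_deg", "must lie in (0, 360]")
        if not self.camera_vfov_deg > 0:
            raise ValidationError("camera_vfov_deg", "must be strictly positive")
        if not 0.0 < self.ths_gather_stop <= 1.0:
            raise ValidationError("ths_gather_stop", "must lie in (0, 1]")
        if not 0.0 <= self.mutation_sigma_frac < 1.0:
            raise ValidationError("mutation_sigma_frac", "must lie in [0, 1)")
        if self.predator_policy not in ("cluster_seeking", "random_walk"):
            raise ValidationError("predator_policy", "must be 'cluster_seeking' or 'random_walk'")

    # -- (de)serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fe_range"] = list(self.fe_range)
        d["fg_range"] = list(self.fg_range)
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def load_config(path: str | Path) -> SimConfig:
    """Load a YAML (or JSON: valid YAML) config file, apply defaults, validate.

    An empty document yields the full default configuration.
    """
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - message content only
        raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must be a mapping of keys to values")
    return SimConfig.from_dict(data)


def save_config(cfg: SimConfig, path: str | Path) -> None:
    cfg.save(path)
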