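"""Replicated parameter sweeps over arena length and odor injection width.

Each (L, phi_w) condition is run for a fixed number of independent trials;
the trial seed is a pure function of the base seed and the stable
(condition, trial) index, so cells can be executed in any order — or in
parallel — with identical results.  Aggregates report per-condition means and
standard deviations with missing metrics (thresholds never reached) excluded.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .config import SimConfig
from .engine import run
from .metrics import RunMetrics, summarize_run

__all__ = ["SweepResult", "trial_seed", "run_sweep"]

_METRIC_COLUMNS = [
    "tsy", "tsd", "ets", "d_ed", "dm_fe", "dm_fg",
    "kde_mode_fe", "kde_mode_fg", "mean_fe", "mean_fg",
    "n_deaths", "min_mean_prey_energy",
]


@dataclasses.dataclass
class SweepResult:
    """Raw per-trial metric grid plus recomputable aggregates."""

    records: pd.DataFrame      # long format: L, phi_w, trial, seed, error, metrics
    n_trials: int

    def aggregate(self) -> pd.DataFrame:
        """Per-condition mean, standard deviation, and valid-trial count."""
        ok = self.records[self.records["error"].isna()]
        return ok.groupby(["L", "phi_w"])[_METRIC_COLUMNS].agg(["mean", "std", "count"])

    def condition(self, L: float, phi_w: float) -> pd.DataFrame:
        r = self.records
        return r[(r["L"] == L) & (r["phi_w"] == phi_w)]


def trial_seed(base_seed: int, condition_index: int, n_trials: int, trial: int) -> int:
    """Stable, order-independent seed schedule for sweep cells."""
    return int(base_seed + condition_index * n_trials + trial)


def run_sweep(
    L_values: Sequence[float],
    phiw_values: Sequence[float],
    n_trials: int,
    base_cfg: Optional[SimConfig] = None,
    base_seed: int = 0,
    keep_logs: bool = False,
) -> SweepResult:
    """Run ``len(L) * len(phi_w) * n_trials`` independent simulations.

    A failing run is recorded in its row's ``error`` column and the sweep
    continues.  With ``keep_logs`` the full :class:`SimLog` objects are
    attached to the result as ``result.logs`` (memory permitting).
    """
    if not L_values or not phiw_values:
        raise ValueError("L_values and phiw_values must be non-empty")
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    if base_cfg is None:
        base_cfg = SimConfig()
    rows: List[dict] = []
    logs = []
    cond = 0
    for L in L_values:
        for phi_w in phiw_values:
            for k in range(n_trials):
                seed = trial_seed(base_seed, cond, n_trials, k)
                row = {"L": L, "phi_w": phi_w, "trial": k, "seed": seed, "error": None}
                try:
                    cfg = dataclasses.replace(
                        base_cfg, arena_length=L, odor_injection_width=phi_w, seed=seed
                    )
                    log = run(cfg)
                    row.update(summarize_run(log).to_dict())
                    if keep_logs:
                        logs.append(log)
                except Exception as exc:  # noqa: BLE001 - per-cell fault isolation
                    row["error"] = f"{type(exc).__name__}: {exc}"
                    row.update({c: np.nan for c in _METRIC_COLUMNS})
                rows.append(row)
            cond += 1
    records = pd.DataFrame(rows)
    # missing metrics (threshold never reached) become NaN, excluded by mean/std
    records[_METRIC_COLUMNS] = records[_METRIC_COLUMNS].astype(float)
    result = SweepResult(records=records, n_trials=n_trials)
    if keep_logs:
        result.logs = logs  # type: ignore[attr-defined]
    return result
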