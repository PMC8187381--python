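"""Config-driven parameter sweeps with tidy tabular output.

Each sweep is a pure function of (base parameters, grids, seed list): one
row per condition and seed carrying the full parameter provenance, the
final cumulative average cooperation and average fusion, and a short
config hash so any figure can be regenerated from its table alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from . import __version__
from .params import ModelParams, PRESETS, S_FUSION
from .simulation import run_simulation

logger = logging.getLogger(__name__)

__all__ = ["sweep_s_policy", "sweep_threshold", "sweep_errors", "sweep_cost",
           "run_conditions", "load_config", "write_run_manifest"]

_PROVENANCE_COLS = [
    "n_agents", "games_per_gen", "generations", "benefit", "cost",
    "extra_cost", "threshold", "delta", "mutation_rate", "ostracism_type",
    "s_policy", "err_perception", "err_execution", "fusion_levels",
]


def run_conditions(conditions: Iterable[ModelParams],
                   seeds: Sequence[int],
                   record_every: int = 0) -> pd.DataFrame:
    """Run every (condition, seed) pair and tabulate the final metrics."""
    rows = []
    for params in conditions:
        for seed in seeds:
            res = run_simulation(
                params, seed=seed,
                record_every=record_every or params.generations)
            row = {c: getattr(params, c) for c in _PROVENANCE_COLS}
            row.update(seed=seed, config_hash=params.config_hash(),
                       avg_cooperation=res.avg_cooperation,
                       avg_fusion=res.avg_fusion)
            rows.append(row)
            logger.info("type=%s S=%s T=%.2f seed=%d coop=%.3f fusion=%.3f",
                        params.ostracism_type, params.s_policy,
                        params.threshold, seed,
                        res.avg_cooperation, res.avg_fusion)
    return pd.DataFrame(rows)


def sweep_s_policy(base: ModelParams,
                   ostracism_types: Sequence[int] = (0, 1, 2, 3),
                   s_values: Sequence = (0.0, 0.1, 0.5, 0.9, S_FUSION),
                   seeds: Sequence[int] = (0, 1, 2)) -> pd.DataFrame:
    """In-group mixing sweep: cartesian (ostracism type, S policy, seed)."""
    conditions = [base.replace(ostracism_type=t, s_policy=s)
                  for t in ostracism_types for s in s_values]
    return run_conditions(conditions, seeds)


def sweep_threshold(base: ModelParams,
                    t_values: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8),
                    ostracism_types: Sequence[int] = (1, 2, 3),
                    s_policy=S_FUSION,
                    seeds: Sequence[int] = (0, 1, 2)) -> pd.DataFrame:
    """Fusion-threshold sweep: only agents with f_i >= T may ostracise."""
    conditions = [base.replace(ostracism_type=t, threshold=T,
                               s_policy=s_policy)
                  for t in ostracism_types for T in t_values]
    return run_conditions(conditions, seeds)


def sweep_errors(base: ModelParams,
                 e_x_values: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4),
                 e_p_values: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4),
                 ostracism_types: Sequence[int] = (1, 2, 3),
                 s_policy=S_FUSION,
                 seeds: Sequence[int] = (0, 1, 2)) -> pd.DataFrame:
    """Execution- and perception-error sweeps (each error varied alone)."""
    conditions = [base.replace(ostracism_type=t, err_execution=ex,
                               err_perception=0.0, s_policy=s_policy)
                  for t in ostracism_types for ex in e_x_values]
    conditions += [base.replace(ostracism_type=t, err_perception=ep,
                                err_execution=0.0, s_policy=s_policy)
                   for t in ostracism_types for ep in e_p_values
                   if ep != 0.0]
    return run_conditions(conditions, seeds)


def sweep_cost(base: ModelParams,
               ct_fractions: Sequence[float] = (0.0, 0.05, 0.10, 0.15,
                                                0.20, 0.30),
               t_values: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8),
               ostracism_type: int = 3,
               s_policy=S_FUSION,
               seeds: Sequence[int] = (0, 1, 2)) -> pd.DataFrame:
    """Differential-cost sweep: agents with f_i >= T pay c + c_T per
    donation, with c_T given as a fraction of c."""
    conditions = [base.replace(ostracism_type=ostracism_type, threshold=T,
                               extra_cost=frac * base.cost,
                               s_policy=s_policy)
                  for frac in ct_fractions for T in t_values]
    df = run_conditions(conditions, seeds)
    df["ct_fraction"] = df["extra_cost"] / df["cost"]
    return df


#: Numbered preconfigured sweep families (cooperation/fusion panels of the
#: mixing sweep share a table).
FIGURE_SWEEPS = {
    1: ("s_policy", sweep_s_policy),
    2: ("s_policy", sweep_s_policy),   # fusion panel of the same sweep
    3: ("s_policy", sweep_s_policy),
    4: ("threshold", sweep_threshold),
    5: ("errors", sweep_errors),
    6: ("cost", sweep_cost),
}


def load_config(path: str | Path) -> ModelParams:
    """Read a YAML mapping of ModelParams field names."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return ModelParams(**data)


def write_run_manifest(out_dir: str | Path, params: ModelParams,
                       seeds: Sequence[int], extra: dict | None = None) -> Path:
    """Drop a JSON manifest (params, seeds, version) next to the outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"params": params.to_dict(), "seeds": list(seeds),
                "config_hash": params.config_hash(),
                "fusionsim_version": __version__}
    manifest.update(extra or {})
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def preset_params(base: ModelParams, scale: str) -> tuple[ModelParams, list[int]]:
    """Apply a named scale preset; returns (params, default seed list)."""
    preset = PRESETS[scale]
    params = base.replace(generations=preset["generations"],
                          games_per_gen=preset["games_per_gen"])
    seeds = [base.seed + k for k in range(preset["n_seeds"])]
    return params, seeds
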