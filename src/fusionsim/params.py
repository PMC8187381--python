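"""Exogenous model parameters and experiment presets.

``ModelParams`` collects every constant of the simulation: population size,
game counts, donation economics, the similarity band, mutation, the ostracism
configuration (type, fusion threshold ``T``, differential cost ``c_T``),
the in-group mixing policy ``S_i`` and the two hypocrisy-error rates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from typing import Literal, Union

__all__ = ["ModelParams", "S_FUSION", "PRESETS", "s_policy_code"]

#: Sentinel for the ``S_i = f_i`` mixing policy (partner drawn from the
#: in-group with probability equal to the agent's own fusion level).
S_FUSION: Literal["fusion"] = "fusion"

SPolicy = Union[float, Literal["fusion"]]


@dataclass(frozen=True)
class ModelParams:
    """Every exogenous constant of one simulation condition.

    Parameters
    ----------
    n_agents
        Population size ``N``.
    games_per_gen
        Donation games ``m`` played per generation.
    generations
        Generations ``M`` per run.
    benefit, cost
        Donation economics ``b`` and ``c`` with ``b > c > 0``.
    extra_cost
        Differential cost ``c_T`` added to the donation cost of every agent
        whose fusion is at least ``threshold``.
    threshold
        Minimum fusion ``T`` an agent must hold before it may ostracise
        (and before it is charged ``extra_cost``).
    delta
        Half-width of the similarity band used in reputation self-comparison.
    mutation_rate
        Per-element mutation probability applied to the three action-rule
        bits and (when ``mutate_fusion``) the fusion level of each offspring.
    ostracism_type
        0 = none, 1 = interaction stage, 2 = reproduction stage, 3 = both.
    s_policy
        In-group mixing: a fixed probability in [0, 1] (0 means fully global
        mixing) or the sentinel ``"fusion"`` meaning ``S_i = f_i``.
    err_perception, err_execution
        Probability ``e_p`` that a perceived contribution ratio is replaced
        by a Uniform[0, 1] draw, and probability ``e_x`` that an ostracism
        that should happen is not executed.
    fusion_levels
        Number of intervals of the discrete fusion scale: fusion takes the
        values ``k / fusion_levels`` for ``k = 0..fusion_levels``.  The
        default 4 is the five-option pictorial (Venn-overlap) scale used to
        assess identity fusion in humans.  0 selects a continuous fusion
        level in [0, 1]; see docs/methods.md for why the discrete scale is
        the model's reference condition.
    seed
        Base RNG seed for the run.
    mutate_fusion
        When False the fusion level is never mutated; used for runs that pin
        the population to the unfused base model.
    init_fusion
        ``"uniform"`` draws initial fusion levels from Uniform[0, 1];
        ``"zero"`` starts every agent unfused (no RNG draw is consumed).
    """

    n_agents: int = 100
    games_per_gen: int = 5000
    generations: int = 50_000
    benefit: float = 1.0
    cost: float = 0.7
    extra_cost: float = 0.0
    threshold: float = 0.0
    delta: int = 0
    mutation_rate: float = 0.01
    ostracism_type: int = 0
    s_policy: SPolicy = 0.0
    err_perception: float = 0.0
    err_execution: float = 0.0
    fusion_levels: int = 4
    seed: int = 0
    mutate_fusion: bool = True
    init_fusion: Literal["uniform", "zero"] = "uniform"

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be positive")
        if not self.benefit > self.cost > 0:
            raise ValueError("requires benefit > cost > 0")
        if self.extra_cost < 0:
            raise ValueError("extra_cost must be non-negative")
        if not 0.0 <= self.threshold < 1.0:
            raise ValueError("threshold must lie in [0, 1)")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.ostracism_type not in (0, 1, 2, 3):
            raise ValueError("ostracism_type must be one of 0, 1, 2, 3")
        if self.fusion_levels < 0:
            raise ValueError("fusion_levels must be >= 0 (0 = continuous)")
        if self.s_policy != S_FUSION:
            s = float(self.s_policy)
            if not 0.0 <= s <= 1.0:
                raise ValueError("fixed s_policy must lie in [0, 1]")
        for name in ("mutation_rate", "err_perception", "err_execution"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with ``changes`` applied (validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Short stable hash of all parameters, for output provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def s_policy_code(policy: SPolicy) -> tuple[int, float]:
    """Encode the mixing policy for the numeric kernels.

    Returns ``(mode, value)`` where mode 0 means a fixed probability
    ``value`` and mode 1 means ``S_i = f_i`` (value ignored).
    """
    if policy == S_FUSION:
        return 1, 0.0
    return 0, float(policy)


#: Experiment scales. ``full`` is the long-run reference scale; ``desk`` is
#: the scaled-down configuration used for routine verification (docs/methods).
PRESETS: dict[str, dict] = {
    "full": {"generations": 50_000, "games_per_gen": 5000, "n_seeds": 5},
    "desk": {"generations": 2000, "games_per_gen": 5000, "n_seeds": 3},
}
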