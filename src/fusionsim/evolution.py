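"""End-of-generation selection, reproduction, mutation and state reset.

Selection is roulette-wheel on payoff (clonal reproduction): each slot of
the next generation independently copies the action rules and fusion level
of a parent drawn with probability proportional to shifted payoff.  Under
type-2/3 ostracism an agent first excludes every candidate it resolves as a
hypocrite; exclusions that empty the pool fall back to the full population.
"""

from __future__ import annotations

import numpy as np

from . import _kernels as K
from .model_core import AgentState
from .params import ModelParams

__all__ = ["fitness_weights", "mutate", "reproduce"]


def fitness_weights(payoffs) -> np.ndarray:
    """Normalised selection weights proportional to shifted payoffs.

    Payoffs may be negative (costs without receipts); they are shifted by
    the most negative value so weights are non-negative.  An all-zero
    shifted vector yields the uniform distribution.
    """
    payoffs = np.asarray(payoffs, dtype=float)
    if payoffs.size == 0:
        raise ValueError("need at least one agent")
    return K.fitness_weights_arr(payoffs)


def mutate(agent: AgentState, mu: float, rng: np.random.Generator,
           mutate_fusion: bool = True, fusion_levels: int = 4) -> AgentState:
    """Return a mutated copy: each rule bit flips independently with
    probability mu; fusion is resampled uniformly from the fusion scale
    (``fusion_levels`` intervals; 0 = continuous) with probability mu."""
    bits = list(agent.rules)
    for k in range(3):
        if rng.random() < mu:
            bits[k] = 1 - bits[k]
    fusion = agent.fusion
    if mutate_fusion and rng.random() < mu:
        fusion = float(K.draw_fusion(fusion_levels, rng))
    return AgentState(fusion=fusion, rule_s=bits[0], rule_u=bits[1],
                      rule_d=bits[2])


def reproduce(population: list[AgentState], params: ModelParams,
              rng: np.random.Generator) -> list[AgentState]:
    """One full selection/reproduction step on a list of agents.

    Returns the offspring population (heritable traits copied from the
    selected parents, then mutated; all within-generation state zeroed).
    The parent population is left untouched; callers also reset the group
    reputation.
    """
    fusion = np.array([a.fusion for a in population])
    payoff = np.array([a.payoff for a in population])
    npos = np.array([a.n_pos for a in population], dtype=np.int64)
    nneu = np.array([a.n_neu for a in population], dtype=np.int64)
    nneg = np.array([a.n_neg for a in population], dtype=np.int64)
    parents = K.reproduce_select(fusion, payoff, npos, nneu, nneg,
                                 params.ostracism_type, params.threshold,
                                 params.err_perception, params.err_execution,
                                 rng)
    offspring = []
    for p in parents:
        src = population[int(p)]
        offspring.append(AgentState(fusion=src.fusion, rule_s=src.rule_s,
                                    rule_u=src.rule_u, rule_d=src.rule_d))
    for k, child in enumerate(offspring):
        offspring[k] = mutate(child, params.mutation_rate, rng,
                              mutate_fusion=params.mutate_fusion,
                              fusion_levels=params.fusion_levels)
    return offspring
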