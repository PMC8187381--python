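"""Brute-force oracles and deterministic micro-scenarios.

These pin down the model mechanics independently of the main engine:

- :func:`exhaustive_decision_table` enumerates all 24 (rule vector,
  comparison class) donation outcomes;
- :func:`scripted_trace` replays hand-written encounter sequences with all
  stochastic gates forced, producing full state trajectories for golden
  comparison;
- :func:`base_model_reference` is a separately coded simulator of the
  unfused base model (isolated personal reputations, no group, no
  ostracism) that follows the same documented draw order, so an all-unfused
  run of the main engine must match it bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = ["exhaustive_decision_table", "scripted_trace", "TraceStep",
           "TraceState", "base_model_reference", "rule_index"]


# ---------------------------------------------------------------------------
# donation-decision table
# ---------------------------------------------------------------------------

def exhaustive_decision_table() -> list[dict]:
    """All 8 rule vectors x 3 comparison classes with the expected action.

    The expected outcome is spelled out per class rather than via any
    shared lookup, so the table is an independent enumeration.
    """
    rows = []
    for s in (0, 1):
        for u in (0, 1):
            for d in (0, 1):
                for cls in ("similar", "upward", "downward"):
                    if cls == "similar":
                        donate = s == 1
                    elif cls == "upward":
                        donate = u == 1
                    else:
                        donate = d == 1
                    rows.append({"rules": (s, u, d), "comparison": cls,
                                 "donate": donate})
    return rows


def rule_index(s: int, u: int, d: int) -> int:
    """Pack a rule vector into 0..7 as s*4 + u*2 + d ((1,1,0) -> 6)."""
    return s * 4 + u * 2 + d


# ---------------------------------------------------------------------------
# scripted traces
# ---------------------------------------------------------------------------

@dataclass
class TraceStep:
    """One forced encounter: who meets whom and whether the stochastic
    ostracism gates resolve to exclusion.  Decisions and assessments are
    then deterministic."""

    donor: int
    recipient: int
    ostracised: bool = False


@dataclass
class TraceState:
    """Full model state between trace steps."""

    fusion: list[float]
    rules: list[tuple[int, int, int]]
    rep: list[int] = field(default_factory=list)
    payoff: list[float] = field(default_factory=list)
    n_pos: list[int] = field(default_factory=list)
    n_neu: list[int] = field(default_factory=list)
    n_neg: list[int] = field(default_factory=list)
    group_rep: int = 0

    def __post_init__(self) -> None:
        n = len(self.fusion)
        for name in ("rep", "payoff", "n_pos", "n_neu", "n_neg"):
            if not getattr(self, name):
                setattr(self, name, [0] * n)

    def ctr(self, i: int):
        denom = self.n_pos[i] + self.n_neu[i] + self.n_neg[i]
        if denom == 0:
            return None
        return (self.n_pos[i] + self.n_neu[i]) / denom

    def snapshot(self) -> dict:
        return {
            "rep": list(self.rep), "group_rep": self.group_rep,
            "payoff": list(self.payoff),
            "n_pos": list(self.n_pos), "n_neu": list(self.n_neu),
            "n_neg": list(self.n_neg),
            "ctr": [self.ctr(i) for i in range(len(self.fusion))],
        }


def scripted_trace(state: TraceState, scenario: list[TraceStep],
                   benefit: float = 1.0, cost: float = 0.7,
                   extra_cost: float = 0.0, threshold: float = 0.0,
                   delta: int = 0) -> list[dict]:
    """Replay forced encounters by direct application of the rules.

    Every rule is applied longhand here — reputation views, the standing
    assessment, the type-1 exception, counters, payoffs — with no calls
    into the engine.  Returns the state snapshot after every step (an empty
    scenario returns just the initial snapshot).
    """
    traj = [state.snapshot()]
    for step in scenario:
        i, j = step.donor, step.recipient
        f_i, f_j = state.fusion[i], state.fusion[j]
        # reputation views (self-view uses the donor's own fused blend)
        if f_i == 0.0:
            view_self = float(state.rep[i])
            view_other = float(state.rep[j])
        else:
            view_self = (1 - f_i) * state.rep[i] + f_i * state.group_rep
            view_other = (1 - f_j) * state.rep[j] + f_j * state.group_rep

        if step.ostracised:
            donated = False
        else:
            if view_other > view_self + delta:
                bit = state.rules[i][1]          # upward
            elif view_other < view_self - delta:
                bit = state.rules[i][2]          # downward
            else:
                bit = state.rules[i][0]          # similar
            donated = bit == 1

        if donated:
            pay = cost + (extra_cost if f_i >= threshold else 0.0)
            state.payoff[i] -= pay
            state.payoff[j] += benefit
            state.rep[i] = min(5, state.rep[i] + 1)
            if f_i > 0:
                state.group_rep = min(5, state.group_rep + 1)
                state.n_pos[i] += 1
        elif step.ostracised:
            # personal penalty only; the group holds the defection legitimate
            if view_other >= view_self:
                state.rep[i] = max(-5, state.rep[i] - 1)
            if f_i > 0:
                state.n_neu[i] += 1
        elif view_other >= view_self:
            state.rep[i] = max(-5, state.rep[i] - 1)
            if f_i > 0:
                state.group_rep = max(-5, state.group_rep - 1)
                state.n_neg[i] += 1
        else:
            if f_i > 0:
                state.n_neu[i] += 1
        traj.append(state.snapshot())
    return traj


# ---------------------------------------------------------------------------
# unfused base-model reference
# ---------------------------------------------------------------------------

@njit(cache=True)
def _base_model_kernel(n, m, m_gen, benefit, cost, s_value, mu,
                       hist_gens, rng):
    """Indirect-reciprocity base model: isolated personal reputations only.

    Follows the documented draw order of the engine (init bits; per game:
    donor, mixing gate, partner; per slot: selection; per offspring: three
    mutation bits) so that an all-unfused engine run with fusion mutation
    disabled is bit-identical.
    """
    rules = np.zeros((n, 3), dtype=np.uint8)
    for i in range(n):
        for bit in range(3):
            rules[i, bit] = 1 if rng.random() < 0.5 else 0
    rep = np.zeros(n, dtype=np.int64)
    payoff = np.zeros(n)
    donations_per_gen = np.zeros(m_gen, dtype=np.int64)
    rule_hist = np.zeros(8, dtype=np.int64)

    new_rules = np.zeros((n, 3), dtype=np.uint8)
    for gen in range(m_gen):
        dons = 0
        for _ in range(m):
            i = int(rng.random() * n)
            rng.random()  # in-group mixing gate; moot when nobody is fused
            u = rng.random()
            j = int(u * (n - 1))
            if j >= i:
                j += 1
            if rep[j] > rep[i]:
                bit = rules[i, 1]
            elif rep[j] < rep[i]:
                bit = rules[i, 2]
            else:
                bit = rules[i, 0]
            if bit == 1:
                dons += 1
                payoff[i] -= cost
                payoff[j] += benefit
                if rep[i] < 5:
                    rep[i] += 1
            elif rep[j] >= rep[i]:
                if rep[i] > -5:
                    rep[i] -= 1
        donations_per_gen[gen] = dons
        if gen >= m_gen - hist_gens:
            for i in range(n):
                rule_hist[rules[i, 0] * 4 + rules[i, 1] * 2 + rules[i, 2]] += 1

        # roulette selection on shifted payoff
        lo = payoff[0]
        for k in range(1, n):
            if payoff[k] < lo:
                lo = payoff[k]
        shift = -lo if lo < 0.0 else 0.0
        total = 0.0
        for k in range(n):
            total += payoff[k] + shift
        for i in range(n):
            u = rng.random()
            if total <= 0.0:
                parent = int(u * n)
            else:
                acc = 0.0
                parent = n - 1
                for k in range(n):
                    acc += (payoff[k] + shift) / total
                    if u < acc:
                        parent = k
                        break
            for bit in range(3):
                new_rules[i, bit] = rules[parent, bit]
        for i in range(n):
            for bit in range(3):
                rules[i, bit] = new_rules[i, bit]
                if rng.random() < mu:
                    rules[i, bit] = 1 - rules[i, bit]
        rep[:] = 0
        payoff[:] = 0.0
    return donations_per_gen, rules, rule_hist


def base_model_reference(n_agents: int = 100, games_per_gen: int = 5000,
                         generations: int = 500, benefit: float = 1.0,
                         cost: float = 0.7, s_value: float = 0.0,
                         mutation_rate: float = 0.01,
                         hist_gens: int = 100, seed: int = 0) -> dict:
    """Run the unfused base model and summarise its trajectory.

    Returns per-generation donation counts, the cumulative cooperation
    level, the final rule matrix and a rule-vector histogram (packed via
    :func:`rule_index`) accumulated over the last ``hist_gens`` parent
    generations.
    """
    rng = np.random.default_rng(seed)
    donations, rules, hist = _base_model_kernel(
        n_agents, games_per_gen, generations, benefit, cost, s_value,
        mutation_rate, hist_gens, rng)
    return {
        "donations_per_gen": donations,
        "avg_cooperation": float(donations.sum()) / (games_per_gen * generations),
        "final_rules": rules,
        "rule_histogram": hist,
        "modal_rule": tuple(int(b) for b in np.unravel_index(
            np.argmax(hist), (2, 2, 2))),
    }
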