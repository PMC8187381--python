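"""Plain-Python reference implementation of one full generation.

Re-implements the engine's documented mechanics and draw order step by
step, without touching the package's kernels, so that engine runs can be
checked draw-for-draw at small scale.  Deliberately naive and explicit.
"""

from __future__ import annotations

import numpy as np

from fusionsim.params import ModelParams, s_policy_code


def _ctr(npos, nneu, nneg):
    d = npos + nneu + nneg
    return None if d == 0 else (npos + nneu) / d


def _check_ostracise(f_i, f_j, ctr_i, ctr_j, p, rng):
    """Mirror of the documented gate order for one observer/target pair."""
    if f_i < p.threshold or f_i <= 0.0 or f_j <= 0.0:
        return False
    if rng.random() >= f_i:
        return False
    if rng.random() < p.err_perception:
        ctr_j = rng.random()
    if ctr_i is None or ctr_j is None:
        return False
    if not (f_j >= f_i and ctr_j < ctr_i):
        return False
    return rng.random() >= p.err_execution


class RefState:
    def __init__(self, fusion, rules):
        n = len(fusion)
        self.fusion = [float(f) for f in fusion]
        self.rules = [list(map(int, r)) for r in rules]
        self.rep = [0] * n
        self.payoff = [0.0] * n
        self.npos = [0] * n
        self.nneu = [0] * n
        self.nneg = [0] * n
        self.group = 0


def ref_generation(state: RefState, p: ModelParams,
                   rng: np.random.Generator) -> int:
    """Play m games, then select/reproduce/mutate and reset. Returns the
    donation count."""
    n = len(state.fusion)
    s_mode, s_value = s_policy_code(p.s_policy)
    donations = 0
    for _ in range(p.games_per_gen):
        i = int(rng.random() * n)
        f_i = state.fusion[i]
        s_i = f_i if s_mode == 1 else s_value
        in_group = rng.random() < s_i
        u = rng.random()
        j = None
        if in_group:
            eligible = [k for k in range(n)
                        if k != i and state.fusion[k] >= f_i]
            if eligible:
                j = eligible[int(u * len(eligible))]
        if j is None:
            j = int(u * (n - 1))
            if j >= i:
                j += 1
        f_j = state.fusion[j]
        if f_i == 0.0:
            vs, vo = float(state.rep[i]), float(state.rep[j])
        else:
            vs = (1 - f_i) * state.rep[i] + f_i * state.group
            vo = (1 - f_j) * state.rep[j] + f_j * state.group

        ostracised = False
        if p.ostracism_type in (1, 3):
            ostracised = _check_ostracise(
                f_i, f_j, _ctr(state.npos[i], state.nneu[i], state.nneg[i]),
                _ctr(state.npos[j], state.nneu[j], state.nneg[j]), p, rng)

        if ostracised:
            if vo >= vs and state.rep[i] > -5:
                state.rep[i] -= 1
            if f_i > 0:
                state.nneu[i] += 1
            continue
        if vo > vs + p.delta:
            bit = state.rules[i][1]
        elif vo < vs - p.delta:
            bit = state.rules[i][2]
        else:
            bit = state.rules[i][0]
        if bit == 1:
            donations += 1
            cost = p.cost + (p.extra_cost if f_i >= p.threshold else 0.0)
            state.payoff[i] -= cost
            state.payoff[j] += p.benefit
            if state.rep[i] < 5:
                state.rep[i] += 1
            if f_i > 0:
                if state.group < 5:
                    state.group += 1
                state.npos[i] += 1
        elif vo >= vs:
            if state.rep[i] > -5:
                state.rep[i] -= 1
            if f_i > 0:
                if state.group > -5:
                    state.group -= 1
                state.nneg[i] += 1
        else:
            if f_i > 0:
                state.nneu[i] += 1

    # selection weights: shift by the most negative payoff, normalise,
    # degenerate to uniform when everything is zero
    lo = min(state.payoff)
    shift = -lo if lo < 0 else 0.0
    weights = [pay + shift for pay in state.payoff]
    total = 0.0
    for w in weights:
        total += w
    if total <= 0.0:
        weights = [1.0 / n] * n
    else:
        weights = [w / total for w in weights]

    parents = []
    for i in range(n):
        excluded = [False] * n
        if (p.ostracism_type in (2, 3) and state.fusion[i] >= p.threshold
                and state.fusion[i] > 0):
            ctr_i = _ctr(state.npos[i], state.nneu[i], state.nneg[i])
            for j in range(n):
                if state.fusion[j] > 0:
                    if _check_ostracise(
                            state.fusion[i], state.fusion[j], ctr_i,
                            _ctr(state.npos[j], state.nneu[j],
                                 state.nneg[j]), p, rng):
                        excluded[j] = True
        total2 = 0.0
        n_avail = 0
        for k in range(n):
            if not excluded[k]:
                total2 += weights[k]
                n_avail += 1
        u = rng.random()
        parent = None
        if n_avail == 0:
            tot = 0.0
            for w in weights:
                tot += w
            acc = 0.0
            for k in range(n):
                acc += weights[k] / tot
                if u < acc:
                    parent = k
                    break
            if parent is None:
                parent = n - 1
        elif total2 <= 0.0:
            target = int(u * n_avail)
            idx = 0
            for k in range(n):
                if not excluded[k]:
                    if idx == target:
                        parent = k
                        break
                    idx += 1
        else:
            acc = 0.0
            for k in range(n):
                if not excluded[k]:
                    acc += weights[k] / total2
                    if u < acc:
                        parent = k
                        break
            if parent is None:
                for k in range(n - 1, -1, -1):
                    if not excluded[k]:
                        parent = k
                        break
        parents.append(parent)

    new_fusion = [state.fusion[k] for k in parents]
    new_rules = [list(state.rules[k]) for k in parents]
    for i in range(n):
        for b in range(3):
            if rng.random() < p.mutation_rate:
                new_rules[i][b] = 1 - new_rules[i][b]
        if p.mutate_fusion and rng.random() < p.mutation_rate:
            if p.fusion_levels > 0:
                new_fusion[i] = (int(rng.random() * (p.fusion_levels + 1))
                                 / p.fusion_levels)
            else:
                new_fusion[i] = rng.random()
    state.fusion = new_fusion
    state.rules = new_rules
    state.rep = [0] * n
    state.payoff = [0.0] * n
    state.npos = [0] * n
    state.nneu = [0] * n
    state.nneg = [0] * n
    state.group = 0
    return donations
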