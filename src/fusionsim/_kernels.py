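"""Numba kernels implementing the model mechanics over flat numpy arrays.

All stochastic gates consume plain ``rng.random()`` doubles in a fixed,
documented order (see docs/methods.md, "Random draw order"), so a run is a
pure function of (parameters, seed).  The scalar helpers are shared with the
object-level API in :mod:`fusionsim.model_core`.

State layout (population of N agents):

- ``fusion``   float64[N]   — identity fusion f_i in [0, 1], heritable
- ``rules``    uint8[N, 3]  — action-rule bits in column order (s, u, d)
- ``rep``      int64[N]     — personal reputation r_i in [-5, 5]
- ``payoff``   float64[N]   — accumulated benefits minus costs
- ``npos/nneu/nneg`` int64[N] — group-contribution counters
- ``group_rep`` int64[1]    — shared group reputation r_G in [-5, 5]

Comparison classes are encoded as the column index of ``rules``:
0 = similar, 1 = upward, 2 = downward.
"""

from __future__ import annotations

import numpy as np
from numba import njit

REP_MIN = -5
REP_MAX = 5

#: Sentinel for an undefined contribution ratio (no group-relevant actions).
CTR_UNDEFINED = -1.0

CLS_SIMILAR = 0
CLS_UPWARD = 1
CLS_DOWNWARD = 2


# ---------------------------------------------------------------------------
# scalar helpers
# ---------------------------------------------------------------------------

@njit(cache=True)
def perceived_rep(f_observer, f_target, r_target, r_group):
    """Observer's view of the target's reputation.

    An unfused observer (f_i = 0) sees only the isolated personal
    reputation; a fused observer sees the convex blend
    (1 - f_j) * r_j + f_j * r_G.
    """
    if f_observer == 0.0:
        return float(r_target)
    return (1.0 - f_target) * r_target + f_target * r_group


@njit(cache=True)
def classify(view_self, view_other, delta):
    """Self-comparison class of the other's reputation view vs one's own."""
    if view_other > view_self + delta:
        return CLS_UPWARD
    if view_other < view_self - delta:
        return CLS_DOWNWARD
    return CLS_SIMILAR


@njit(cache=True)
def ctr_value(n_pos, n_neu, n_neg):
    """Group contribution ratio; CTR_UNDEFINED when no actions yet."""
    denom = n_pos + n_neu + n_neg
    if denom == 0:
        return CTR_UNDEFINED
    return (n_pos + n_neu) / denom


@njit(cache=True)
def is_hypocrite(f_observer, f_target, ctr_observer, ctr_target):
    """Vicarious-hypocrisy predicate: f_j >= f_i and ctr_j < ctr_i.

    Either ratio being undefined (sentinel < 0) means no evidence and
    therefore no hypocrisy.
    """
    if ctr_observer < 0.0 or ctr_target < 0.0:
        return False
    return f_target >= f_observer and ctr_target < ctr_observer


@njit(cache=True)
def _perceive_ctr(true_ctr, e_p, rng):
    """Perception-noise gate: one gate draw, one value draw when it fires."""
    if rng.random() < e_p:
        return rng.random()
    return true_ctr


@njit(cache=True)
def _check_and_ostracise(f_i, f_j, ctr_i, ctr_j, threshold, e_p, e_x, rng):
    """Full ostracism gate sequence for one observer/target pair.

    Order: T gate, mutual-fusion gate, Bernoulli(f_i) check gate,
    perception noise on the target's ratio, hypocrisy predicate,
    execution-failure gate.  Draws are consumed only for gates reached.
    """
    if f_i < threshold or f_i <= 0.0 or f_j <= 0.0:
        return False
    if rng.random() >= f_i:
        return False
    perceived = _perceive_ctr(ctr_j, e_p, rng)
    if not is_hypocrite(f_i, f_j, ctr_i, perceived):
        return False
    return rng.random() >= e_x


@njit(cache=True)
def _draw_partner(donor, fusion, in_group, rng):
    """One uniform draw selects the recipient.

    In-group branch: uniform over {j != donor : f_j >= f_donor}; an empty
    eligible set falls back to the global uniform draw.  Both branches map
    the single draw through the same "skip the donor" indexing, so with a
    homogeneous population they coincide draw-for-draw.
    """
    n = fusion.shape[0]
    u = rng.random()
    if in_group:
        n_elig = 0
        for k in range(n):
            if k != donor and fusion[k] >= fusion[donor]:
                n_elig += 1
        if n_elig > 0:
            target = int(u * n_elig)
            idx = 0
            for k in range(n):
                if k != donor and fusion[k] >= fusion[donor]:
                    if idx == target:
                        return k
                    idx += 1
    j = int(u * (n - 1))
    if j >= donor:
        j += 1
    return j


# ---------------------------------------------------------------------------
# one generation of games
# ---------------------------------------------------------------------------

@njit(cache=True)
def play_games(fusion, rules, rep, payoff, npos, nneu, nneg, group_rep,
               m, s_mode, s_value, ostracism_type, threshold, delta,
               e_p, e_x, benefit, cost, extra_cost, rng):
    """Play ``m`` donation games in place; returns (donations, gated_donations).

    ``gated_donations`` counts donations by agents with fusion >= T, which
    are the ones charged ``cost + extra_cost``.
    """
    n = fusion.shape[0]
    donations = 0
    gated = 0
    for _ in range(m):
        i = int(rng.random() * n)
        f_i = fusion[i]
        s_i = f_i if s_mode == 1 else s_value
        in_group = rng.random() < s_i
        j = _draw_partner(i, fusion, in_group, rng)
        f_j = fusion[j]

        view_self = perceived_rep(f_i, f_i, rep[i], group_rep[0])
        view_other = perceived_rep(f_i, f_j, rep[j], group_rep[0])

        ostracised = False
        if ostracism_type == 1 or ostracism_type == 3:
            ctr_i = ctr_value(npos[i], nneu[i], nneg[i])
            ctr_j = ctr_value(npos[j], nneu[j], nneg[j])
            ostracised = _check_and_ostracise(
                f_i, f_j, ctr_i, ctr_j, threshold, e_p, e_x, rng)

        if ostracised:
            # forced defection: personal penalty only when the recipient
            # stood at least as high; the group holds it legitimate.
            if view_other >= view_self:
                if rep[i] > REP_MIN:
                    rep[i] -= 1
            if f_i > 0.0:
                nneu[i] += 1
        else:
            cls = classify(view_self, view_other, delta)
            if rules[i, cls] == 1:
                donations += 1
                pay_cost = cost
                if f_i >= threshold:
                    pay_cost = cost + extra_cost
                    gated += 1
                payoff[i] -= pay_cost
                payoff[j] += benefit
                if rep[i] < REP_MAX:
                    rep[i] += 1
                if f_i > 0.0:
                    if group_rep[0] < REP_MAX:
                        group_rep[0] += 1
                    npos[i] += 1
            elif view_other >= view_self:
                if rep[i] > REP_MIN:
                    rep[i] -= 1
                if f_i > 0.0:
                    if group_rep[0] > REP_MIN:
                        group_rep[0] -= 1
                    nneg[i] += 1
            else:
                # legitimate defection under standing: no reputation change
                if f_i > 0.0:
                    nneu[i] += 1
    return donations, gated


# ---------------------------------------------------------------------------
# selection, reproduction, mutation
# ---------------------------------------------------------------------------

@njit(cache=True)
def fitness_weights_arr(payoff):
    """Roulette weights: payoffs shifted to be non-negative, normalised.

    All-zero shifted payoffs degenerate to the uniform distribution.
    """
    n = payoff.shape[0]
    lo = payoff[0]
    for k in range(1, n):
        if payoff[k] < lo:
            lo = payoff[k]
    shift = -lo if lo < 0.0 else 0.0
    w = np.empty(n)
    total = 0.0
    for k in range(n):
        w[k] = payoff[k] + shift
        total += w[k]
    if total <= 0.0:
        for k in range(n):
            w[k] = 1.0 / n
    else:
        for k in range(n):
            w[k] /= total
    return w


@njit(cache=True)
def _roulette_restricted(weights, excluded, rng):
    """One draw from ``weights`` over non-excluded slots.

    A fully excluded or zero-weight candidate set degenerates to the full
    population / uniform draw respectively.
    """
    n = weights.shape[0]
    total = 0.0
    n_avail = 0
    for k in range(n):
        if not excluded[k]:
            total += weights[k]
            n_avail += 1
    u = rng.random()
    if n_avail == 0:
        # exclusions emptied the pool: reproduce from everyone
        total = 0.0
        for k in range(n):
            total += weights[k]
        acc = 0.0
        for k in range(n):
            acc += weights[k] / total
            if u < acc:
                return k
        return n - 1
    if total <= 0.0:
        # all survivors carry zero weight: uniform among them
        target = int(u * n_avail)
        idx = 0
        for k in range(n):
            if not excluded[k]:
                if idx == target:
                    return k
                idx += 1
        return n - 1
    acc = 0.0
    for k in range(n):
        if not excluded[k]:
            acc += weights[k] / total
            if u < acc:
                return k
    for k in range(n - 1, -1, -1):
        if not excluded[k]:
            return k
    return n - 1


@njit(cache=True)
def reproduce_select(fusion, payoff, npos, nneu, nneg,
                     ostracism_type, threshold, e_p, e_x, rng):
    """Roulette-wheel parent choice for every slot; returns parent indices.

    Under type-2/3 ostracism each slot's agent i first walks the candidate
    list in index order and excludes every j it resolves as a hypocrite
    (independent check/perception/execution draws per candidate).
    """
    n = fusion.shape[0]
    weights = fitness_weights_arr(payoff)
    parents = np.empty(n, dtype=np.int64)
    excluded = np.zeros(n, dtype=np.bool_)
    check = ostracism_type == 2 or ostracism_type == 3
    for i in range(n):
        for k in range(n):
            excluded[k] = False
        if check and fusion[i] >= threshold and fusion[i] > 0.0:
            ctr_i = ctr_value(npos[i], nneu[i], nneg[i])
            for j in range(n):
                if fusion[j] > 0.0:
                    ctr_j = ctr_value(npos[j], nneu[j], nneg[j])
                    if _check_and_ostracise(fusion[i], fusion[j], ctr_i,
                                            ctr_j, threshold, e_p, e_x, rng):
                        excluded[j] = True
        parents[i] = _roulette_restricted(weights, excluded, rng)
    return parents


@njit(cache=True)
def draw_fusion(levels, rng):
    """One fusion level: uniform over the discrete scale {k/levels}, or
    Uniform[0, 1] when levels == 0 (continuous variant)."""
    if levels > 0:
        return int(rng.random() * (levels + 1)) / levels
    return rng.random()


@njit(cache=True)
def mutate_population(fusion, rules, mu, mutate_fusion, levels, rng):
    """Per-offspring mutation in place: bit flips and fusion resampling.

    Each rule bit flips independently with probability mu; fusion is
    resampled uniformly from the fusion scale with probability mu when
    enabled.
    """
    n = fusion.shape[0]
    for i in range(n):
        for bit in range(3):
            if rng.random() < mu:
                rules[i, bit] = 1 - rules[i, bit]
        if mutate_fusion:
            if rng.random() < mu:
                fusion[i] = draw_fusion(levels, rng)
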