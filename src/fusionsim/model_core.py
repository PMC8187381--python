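"""Domain types and single-encounter mechanics of the donation game.

This module exposes the model's mechanics one encounter at a time, on small
dataclasses — convenient for inspection, oracles and tests.  The scalar
logic is shared with the vectorised engine in :mod:`fusionsim._kernels`.

Model summary.  Agents hold a heritable identity-fusion level ``f_i`` toward
a single group and three heritable action-rule bits ``(s, u, d)`` that decide
whether to donate to a recipient perceived as similar, above, or below
themselves.  Reputations follow the *standing* norm: donations raise the
donor's personal reputation (and, for fused donors, the shared group
reputation); defection against an equal-or-better-standing recipient lowers
them; defection against a lower-standing recipient is legitimate and free.
Fused agents additionally track a group contribution ratio and may ostracise
perceived hypocrites — equally-or-more-fused agents contributing less.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from . import _kernels as K
from .params import ModelParams, s_policy_code

__all__ = [
    "REP_MIN", "REP_MAX",
    "AgentState", "GroupState", "InteractionOutcome",
    "perceived_reputation", "classify_comparison", "donation_decision",
    "contribution_ratio", "is_hypocrite", "apply_perception_error",
    "should_check_and_ostracise", "select_partner", "assess_and_update",
]

REP_MIN = K.REP_MIN
REP_MAX = K.REP_MAX

ComparisonClass = Literal["similar", "upward", "downward"]

_CLS_NAMES: tuple[ComparisonClass, ...] = ("similar", "upward", "downward")


@dataclass
class AgentState:
    """One agent: heritable strategy plus within-generation state.

    ``fusion`` and the three rule bits are heritable; reputation, payoff and
    the contribution counters reset at the start of every generation.
    """

    fusion: float = 0.0
    rule_s: int = 0
    rule_u: int = 0
    rule_d: int = 0
    personal_rep: int = 0
    payoff: float = 0.0
    n_pos: int = 0
    n_neu: int = 0
    n_neg: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fusion <= 1.0:
            raise ValueError("fusion must lie in [0, 1]")
        for bit in (self.rule_s, self.rule_u, self.rule_d):
            if bit not in (0, 1):
                raise ValueError("rule bits must be 0 or 1")
        if not REP_MIN <= self.personal_rep <= REP_MAX:
            raise ValueError("personal_rep out of range")

    @property
    def rules(self) -> tuple[int, int, int]:
        return (self.rule_s, self.rule_u, self.rule_d)


@dataclass
class GroupState:
    """The single shared group reputation r_G."""

    group_rep: int = 0

    def __post_init__(self) -> None:
        if not REP_MIN <= self.group_rep <= REP_MAX:
            raise ValueError("group_rep out of range")


@dataclass
class InteractionOutcome:
    """Record of one donation game."""

    donor_index: int
    recipient_index: int
    donated: bool
    ostracised: bool
    delta_personal: int
    delta_group: int
    comparison_class: Optional[ComparisonClass] = None


def perceived_reputation(observer: AgentState, target: AgentState,
                         group: GroupState) -> float:
    """Observer's view of the target's reputation.

    An unfused observer sees the raw personal reputation; a fused observer
    sees the blend ``(1 - f_j) r_j + f_j r_G``.
    """
    return float(K.perceived_rep(observer.fusion, target.fusion,
                                 target.personal_rep, group.group_rep))


def classify_comparison(donor_view_self: float, donor_view_other: float,
                        delta: int = 0) -> ComparisonClass:
    """Similar / upward / downward self-comparison with band half-width delta."""
    return _CLS_NAMES[K.classify(float(donor_view_self),
                                 float(donor_view_other), delta)]


def donation_decision(donor: AgentState,
                      comparison: ComparisonClass) -> bool:
    """Donor's rule bit for the observed comparison class."""
    return bool(donor.rules[_CLS_NAMES.index(comparison)])


def contribution_ratio(agent: AgentState) -> Optional[float]:
    """Group contribution ratio (n_pos + n_neu) / total, None when undefined."""
    v = K.ctr_value(agent.n_pos, agent.n_neu, agent.n_neg)
    return None if v < 0.0 else float(v)


def is_hypocrite(observer: AgentState, target: AgentState,
                 perceived_ctr_target: Optional[float]) -> bool:
    """True iff the target is at least as fused yet perceived to contribute
    strictly less than the observer; any undefined ratio defeats the charge."""
    ctr_obs = contribution_ratio(observer)
    if ctr_obs is None or perceived_ctr_target is None:
        return False
    return bool(K.is_hypocrite(observer.fusion, target.fusion,
                               ctr_obs, perceived_ctr_target))


def apply_perception_error(true_ctr: Optional[float], e_p: float,
                           rng: np.random.Generator) -> Optional[float]:
    """With probability e_p replace the perceived ratio by Uniform[0, 1].

    The replacement applies even to an undefined ratio: misperception
    fabricates a value where none exists.  Consumes one gate draw and, on
    replacement, one value draw.
    """
    if rng.random() < e_p:
        return float(rng.random())
    return true_ctr


def should_check_and_ostracise(observer: AgentState, target: AgentState,
                               params: ModelParams,
                               rng: np.random.Generator) -> bool:
    """Full ostracism gate sequence for one observer/target pair.

    In order: fusion-threshold gate (f_i >= T), mutual-fusion gate,
    Bernoulli(f_i) check gate, perception noise on the target's ratio,
    hypocrisy predicate, and the execution-failure gate (probability e_x
    of not ostracising when it should).
    """
    if observer.fusion < params.threshold:
        return False
    if observer.fusion <= 0.0 or target.fusion <= 0.0:
        return False
    if rng.random() >= observer.fusion:
        return False
    perceived = apply_perception_error(contribution_ratio(target),
                                       params.err_perception, rng)
    if not is_hypocrite(observer, target, perceived):
        return False
    return rng.random() >= params.err_execution


def select_partner(donor_index: int, population: list[AgentState],
                   params: ModelParams, rng: np.random.Generator) -> int:
    """Draw the recipient for one game.

    With probability S_i (fixed, or f_i under the ``"fusion"`` policy) the
    draw is uniform over the donor's in-group {j != i : f_j >= f_i};
    otherwise — and whenever the in-group is empty — uniform over everyone
    else.  Consumes exactly two draws (mixing gate, partner).
    """
    n = len(population)
    if n < 2:
        raise ValueError("partner selection needs a population of at least 2")
    fusion = np.array([a.fusion for a in population])
    mode, value = s_policy_code(params.s_policy)
    s_i = fusion[donor_index] if mode == 1 else value
    in_group = rng.random() < s_i
    return int(K._draw_partner(donor_index, fusion, bool(in_group), rng))


def assess_and_update(donor: AgentState, recipient: AgentState,
                      group: GroupState, donated: bool,
                      ostracised_type1: bool,
                      views: tuple[float, float],
                      params: ModelParams,
                      donor_index: int = 0,
                      recipient_index: int = 1) -> InteractionOutcome:
    """Apply payoff transfer, standing assessment and contribution counting.

    ``views`` are the donor's pre-update reputation views (self, other).
    A type-1-ostracism defection decrements the donor's personal reputation
    iff the recipient stood at least as high, but never touches the group
    reputation: from the group's perspective the defection is legitimate,
    so it counts toward ``n_neu``.  Unfused donors update only their
    personal reputation and accumulate no counters.
    """
    if donated and ostracised_type1:
        raise ValueError("an ostracised encounter cannot be a donation")
    view_self, view_other = views
    fused = donor.fusion > 0.0
    d_personal = 0
    d_group = 0
    cls: Optional[ComparisonClass] = None
    if not ostracised_type1:
        cls = classify_comparison(view_self, view_other, params.delta)

    if donated:
        pay_cost = params.cost
        if donor.fusion >= params.threshold:
            pay_cost += params.extra_cost
        donor.payoff -= pay_cost
        recipient.payoff += params.benefit
        if donor.personal_rep < REP_MAX:
            d_personal = 1
        if fused:
            if group.group_rep < REP_MAX:
                d_group = 1
            donor.n_pos += 1
    elif ostracised_type1:
        if view_other >= view_self and donor.personal_rep > REP_MIN:
            d_personal = -1
        if fused:
            donor.n_neu += 1
    elif view_other >= view_self:
        if donor.personal_rep > REP_MIN:
            d_personal = -1
        if fused:
            if group.group_rep > REP_MIN:
                d_group = -1
            donor.n_neg += 1
    else:
        if fused:
            donor.n_neu += 1

    donor.personal_rep += d_personal
    group.group_rep += d_group
    return InteractionOutcome(
        donor_index=donor_index, recipient_index=recipient_index,
        donated=donated, ostracised=ostracised_type1,
        delta_personal=d_personal, delta_group=d_group,
        comparison_class=cls)
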