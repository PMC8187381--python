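"""Unit and property tests for the single-encounter mechanics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fusionsim import (AgentState, GroupState, ModelParams,
                       apply_perception_error, assess_and_update,
                       classify_comparison, contribution_ratio,
                       donation_decision, is_hypocrite,
                       perceived_reputation, select_partner,
                       should_check_and_ostracise)
from fusionsim.oracles import exhaustive_decision_table

fusion_st = st.floats(0.0, 1.0, allow_nan=False)
rep_st = st.integers(-5, 5)


def agent(f=0.0, rules=(1, 1, 0), rep=0, **kw):
    return AgentState(fusion=f, rule_s=rules[0], rule_u=rules[1],
                      rule_d=rules[2], personal_rep=rep, **kw)


class TestPerceivedReputation:
    @pytest.mark.parametrize("f_obs,f_tgt,r_tgt,r_g,expected", [
        (0.3, 0.5, 4, -2, 1.0),    # fused observer blends target and group
        (0.0, 0.9, 3, -5, 3.0),    # unfused observer sees raw personal rep
        (0.1, 0.0, -5, 5, -5.0),   # unfused target collapses to raw rep
    ])
    def test_examples(self, f_obs, f_tgt, r_tgt, r_g, expected):
        v = perceived_reputation(agent(f_obs), agent(f_tgt, rep=r_tgt),
                                 GroupState(group_rep=r_g))
        assert v == pytest.approx(expected)

    @settings(deadline=None, derandomize=True)
    @given(f_obs=fusion_st, f_tgt=fusion_st, r_tgt=rep_st, r_g=rep_st)
    def test_convex_combination(self, f_obs, f_tgt, r_tgt, r_g):
        """A fused view always lies between the personal and group reps."""
        v = perceived_reputation(agent(f_obs), agent(f_tgt, rep=r_tgt),
                                 GroupState(group_rep=r_g))
        lo, hi = min(r_tgt, r_g), max(r_tgt, r_g)
        if f_obs == 0.0:
            assert v == r_tgt
        else:
            assert lo - 1e-12 <= v <= hi + 1e-12
        assert -5.0 <= v <= 5.0


class TestClassifyComparison:
    @pytest.mark.parametrize("vs,vo,delta,expected", [
        (2, 2, 0, "similar"),
        (2, 3, 0, "upward"),
        (2.0, 1.5, 0, "downward"),
        (2, 3, 1, "similar"),
    ])
    def test_examples(self, vs, vo, delta, expected):
        assert classify_comparison(vs, vo, delta) == expected

    @settings(deadline=None, derandomize=True)
    @given(vs=st.floats(-5, 5), vo=st.floats(-5, 5),
           delta=st.integers(0, 3))
    def test_exactly_one_class(self, vs, vo, delta):
        cls = classify_comparison(vs, vo, delta)
        assert cls in ("similar", "upward", "downward")
        if cls == "similar":
            assert abs(vo - vs) <= delta
        elif cls == "upward":
            assert vo > vs + delta
        else:
            assert vo < vs - delta


def test_donation_decision_matches_exhaustive_table():
    """The rule-bit lookup agrees with the brute-force 24-row enumeration."""
    table = exhaustive_decision_table()
    assert len(table) == 24
    for row in table:
        donor = agent(rules=row["rules"])
        assert donation_decision(donor, row["comparison"]) == row["donate"]


class TestContributionRatio:
    @pytest.mark.parametrize("pos,neu,neg,expected", [
        (3, 1, 1, 0.8),
        (0, 0, 0, None),   # no group-relevant actions yet: undefined
        (0, 0, 4, 0.0),
        (2, 0, 0, 1.0),
    ])
    def test_examples(self, pos, neu, neg, expected):
        a = agent(f=0.5, n_pos=pos, n_neu=neu, n_neg=neg)
        assert contribution_ratio(a) == (pytest.approx(expected)
                                         if expected is not None else None)

    @settings(deadline=None, derandomize=True)
    @given(pos=st.integers(0, 100), neu=st.integers(0, 100),
           neg=st.integers(0, 100))
    def test_range(self, pos, neu, neg):
        v = contribution_ratio(agent(n_pos=pos, n_neu=neu, n_neg=neg))
        if pos + neu + neg == 0:
            assert v is None
        else:
            assert 0.0 <= v <= 1.0


class TestIsHypocrite:
    def test_both_clauses_hold(self):
        obs = agent(f=0.4, n_pos=9, n_neg=1)       # ctr 0.9
        tgt = agent(f=0.6)
        assert is_hypocrite(obs, tgt, 0.5)

    def test_fusion_clause_fails(self):
        obs = agent(f=0.6, n_pos=9, n_neg=1)
        tgt = agent(f=0.4)
        assert not is_hypocrite(obs, tgt, 0.1)

    def test_undefined_observer_ratio(self):
        """No evidence about oneself means no basis for dissonance."""
        obs = agent(f=0.4)
        tgt = agent(f=0.6)
        assert not is_hypocrite(obs, tgt, 0.5)
        assert not is_hypocrite(agent(f=0.4, n_pos=1), tgt, None)

    @settings(deadline=None, derandomize=True)
    @given(f_i=fusion_st, f_j=fusion_st,
           ctr_i=st.floats(0, 1), lo=st.floats(0, 1), hi=st.floats(0, 1))
    def test_monotone_in_target_ctr(self, f_i, f_j, ctr_i, lo, hi):
        """Raising the target's perceived ratio can only clear the charge."""
        lo, hi = min(lo, hi), max(lo, hi)
        pos = int(round(ctr_i * 100))
        obs = AgentState(fusion=f_i, n_pos=pos, n_neg=100 - pos)
        tgt = agent(f=f_j, n_pos=1)
        if is_hypocrite(obs, tgt, hi):
            assert is_hypocrite(obs, tgt, lo)


class TestPerceptionError:
    def test_no_error_passes_through(self, rng):
        assert apply_perception_error(0.7, 0.0, rng) == 0.7
        assert apply_perception_error(None, 0.0, rng) is None

    def test_full_error_is_uniform(self, rng):
        draws = [apply_perception_error(0.7, 1.0, rng) for _ in range(10000)]
        assert abs(np.mean(draws) - 0.5) < 0.02

    def test_error_replaces_undefined(self, rng):
        v = apply_perception_error(None, 1.0, rng)
        assert v is not None and 0.0 <= v <= 1.0


class TestOstracismGates:
    def _pair(self):
        obs = agent(f=1.0, n_pos=1)            # ctr 1
        tgt = agent(f=1.0, n_neg=1)            # ctr 0
        return obs, tgt

    def test_all_gates_pass(self, scripted_rng):
        obs, tgt = self._pair()
        p = ModelParams()
        stub = scripted_rng([0.5, 0.9, 0.9])   # check gate, e_p gate, e_x gate
        assert should_check_and_ostracise(obs, tgt, p, stub)

    def test_threshold_gate_blocks_without_draws(self, scripted_rng):
        obs, tgt = self._pair()
        obs.fusion = 0.5
        stub = scripted_rng([])
        p = ModelParams(threshold=0.6, ostracism_type=1)
        assert not should_check_and_ostracise(obs, tgt, p, stub)
        assert stub.consumed == 0

    def test_unfused_target_blocks(self, scripted_rng):
        obs, _ = self._pair()
        tgt = agent(f=0.0, n_neg=1)
        assert not should_check_and_ostracise(obs, tgt, ModelParams(),
                                              scripted_rng([]))

    def test_execution_error_blocks(self, scripted_rng):
        obs, tgt = self._pair()
        p = ModelParams(err_execution=1.0)
        stub = scripted_rng([0.5, 0.9, 0.99])
        assert not should_check_and_ostracise(obs, tgt, p, stub)

    def test_undefined_observer_ctr_blocks(self, scripted_rng):
        obs = agent(f=1.0)
        tgt = agent(f=1.0, n_neg=1)
        stub = scripted_rng([0.5, 0.9])
        assert not should_check_and_ostracise(obs, tgt, ModelParams(), stub)

    def test_matches_kernel_gate_sequence(self):
        """Python gate sequence and the engine kernel consume the same
        stream and agree, across random configurations."""
        from fusionsim import _kernels as K
        rng_cfg = np.random.default_rng(7)
        for _ in range(200):
            f_i, f_j = rng_cfg.random(), rng_cfg.random()
            pos_i, neg_i = rng_cfg.integers(0, 3), rng_cfg.integers(0, 3)
            pos_j, neg_j = rng_cfg.integers(0, 3), rng_cfg.integers(0, 3)
            p = ModelParams(threshold=float(rng_cfg.random() * 0.9),
                            err_perception=float(rng_cfg.random()),
                            err_execution=float(rng_cfg.random()))
            seed = int(rng_cfg.integers(0, 2**31))
            obs = agent(f=f_i, n_pos=int(pos_i), n_neg=int(neg_i))
            tgt = agent(f=f_j, n_pos=int(pos_j), n_neg=int(neg_j))
            got_py = should_check_and_ostracise(
                obs, tgt, p, np.random.default_rng(seed))
            got_k = K._check_and_ostracise(
                f_i, f_j, K.ctr_value(pos_i, 0, neg_i),
                K.ctr_value(pos_j, 0, neg_j), p.threshold,
                p.err_perception, p.err_execution,
                np.random.default_rng(seed))
            assert got_py == bool(got_k)


class TestSelectPartner:
    def test_global_mixing_uniform_support(self, rng):
        pop = [agent(f=0.1 * k) for k in range(5)]
        p = ModelParams(s_policy=0.0)
        picks = {select_partner(2, pop, p, rng) for _ in range(300)}
        assert picks == {0, 1, 3, 4}

    def test_single_eligible_partner(self, rng):
        pop = [agent(f=0.9), agent(f=0.95), agent(f=0.1)]
        p = ModelParams(s_policy=1.0)
        for _ in range(20):
            assert select_partner(0, pop, p, rng) == 1

    def test_empty_in_group_falls_back_to_global(self, rng):
        pop = [agent(f=1.0), agent(f=0.5), agent(f=0.2)]
        p = ModelParams(s_policy=1.0)
        picks = {select_partner(0, pop, p, rng) for _ in range(200)}
        assert picks == {1, 2}

    def test_requires_two_agents(self, rng):
        with pytest.raises(ValueError):
            select_partner(0, [agent()], ModelParams(), rng)


class TestAssessAndUpdate:
    def test_donation_clamps_at_cap(self):
        donor = agent(f=1.0, rep=5)
        rec = agent(f=1.0)
        grp = GroupState(group_rep=5)
        out = assess_and_update(donor, rec, grp, donated=True,
                                ostracised_type1=False, views=(5.0, 5.0),
                                params=ModelParams())
        assert donor.personal_rep == 5 and grp.group_rep == 5
        assert out.delta_personal == 0 and out.delta_group == 0
        assert donor.n_pos == 1            # the action still counts

    def test_illegitimate_defection_decrements_both(self):
        donor = agent(f=0.5, rules=(0, 0, 0))
        rec = agent(f=0.5)
        grp = GroupState()
        out = assess_and_update(donor, rec, grp, donated=False,
                                ostracised_type1=False, views=(0.0, 0.0),
                                params=ModelParams())
        assert donor.personal_rep == -1 and grp.group_rep == -1
        assert donor.n_neg == 1
        assert out.comparison_class == "similar"

    def test_type1_exception_spares_group(self):
        """An ostracism defection on a better-standing target costs the
        donor personally but is legitimate from the group's viewpoint."""
        donor = agent(f=1.0)
        rec = agent(f=1.0, rep=3)
        grp = GroupState(group_rep=2)
        assess_and_update(donor, rec, grp, donated=False,
                          ostracised_type1=True, views=(2.0, 2.1),
                          params=ModelParams())
        assert donor.personal_rep == -1
        assert grp.group_rep == 2
        assert donor.n_neu == 1 and donor.n_neg == 0

    def test_legitimate_defection_free(self):
        donor = agent(f=0.4, rep=2)
        grp = GroupState()
        assess_and_update(donor, agent(), grp, donated=False,
                          ostracised_type1=False, views=(1.2, 0.8),
                          params=ModelParams())
        assert donor.personal_rep == 2 and grp.group_rep == 0
        assert donor.n_neu == 1

    def test_unfused_donor_leaves_group_untouched(self):
        donor = agent(f=0.0)
        grp = GroupState()
        assess_and_update(donor, agent(), grp, donated=True,
                          ostracised_type1=False, views=(0.0, 0.0),
                          params=ModelParams())
        assert donor.personal_rep == 1 and grp.group_rep == 0
        assert donor.n_pos == 0            # counters only for fused donors

    def test_donation_payoff_transfer(self):
        p = ModelParams(extra_cost=0.1, threshold=0.5)
        donor = agent(f=0.75)
        rec = agent()
        assess_and_update(donor, rec, GroupState(), donated=True,
                          ostracised_type1=False, views=(0.0, 0.0), params=p)
        assert donor.payoff == pytest.approx(-0.8)   # c + c_T, gated by T
        assert rec.payoff == pytest.approx(1.0)

    def test_donated_and_ostracised_is_contradiction(self):
        with pytest.raises(ValueError):
            assess_and_update(agent(), agent(), GroupState(), donated=True,
                              ostracised_type1=True, views=(0, 0),
                              params=ModelParams())

    @settings(deadline=None, derandomize=True)
    @given(f=fusion_st, vs=st.floats(-5, 5), vo=st.floats(-5, 5),
           donated=st.booleans(), ost=st.booleans())
    def test_population_payoff_conservation(self, f, vs, vo, donated, ost):
        """Each donation moves total payoff by exactly b - c(-c_T); every
        defection moves it by zero."""
        if donated and ost:
            donated = False
        p = ModelParams(extra_cost=0.05, threshold=0.5)
        donor, rec = agent(f=f), agent()
        assess_and_update(donor, rec, GroupState(), donated=donated,
                          ostracised_type1=ost, views=(vs, vo), params=p)
        total = donor.payoff + rec.payoff
        if donated:
            expected = p.benefit - p.cost - (p.extra_cost if f >= 0.5 else 0)
            assert total == pytest.approx(expected)
        else:
            assert total == 0.0
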