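"""Deliberation: value monitoring, goal formation, plan ranking."""

import itertools
import random

import pytest

from moralagent import (AffectConfig, Agent, Goal, GoalStatus, Plan,
                        Proposition, Value, WorldState)
from moralagent.deliberation import (NoPlanError, PlanEvaluation,
                                     anticipatory_appraisal, form_goals,
                                     monitor_values, select_plan)
from moralagent.logic import is_variable


# ---------------------------------------------------------------------------
# value monitoring
# ---------------------------------------------------------------------------

def test_stolen_chocolate_puts_honesty_at_stake():
    world = WorldState({Proposition.parse("stole(chocolate)")})
    honesty = Value(id="honesty", priority=0.9,
                    violation_conditions=[(Proposition.parse("stole(X)"),)])
    assert monitor_values(world, [honesty]) == ["honesty"]
    assert honesty.at_stake
    assert monitor_values(WorldState(), [honesty]) == []
    assert not honesty.at_stake


def brute_force_at_stake(world, value):
    """Oracle: try every substitution of variables by world constants."""
    constants = sorted({a for f in world.facts for a in f.args})
    for cond in value.violation_conditions:
        variables = sorted({a for p in cond for a in p.args
                            if is_variable(a)})
        if variables and not constants:
            continue   # nothing a variable could bind to
        for combo in itertools.product(constants, repeat=len(variables)):
            binding = dict(zip(variables, combo))
            if all(p.substitute(binding) in world.facts for p in cond):
                return True
    return False


def test_monitor_values_agrees_with_brute_force_oracle():
    rng = random.Random(7)
    preds = ["p", "q", "r"]
    consts = ["a", "b", "c"]
    for _ in range(200):
        facts = {Proposition(rng.choice(preds),
                             tuple(rng.choices(consts, k=rng.randint(0, 2))))
                 for _ in range(rng.randint(0, 5))}
        world = WorldState(facts)
        values = []
        for i in range(rng.randint(1, 3)):
            conds = []
            for _ in range(rng.randint(1, 2)):
                conj = tuple(
                    Proposition(rng.choice(preds),
                                tuple(rng.choice(consts + ["X", "Y"])
                                      for _ in range(rng.randint(0, 2))))
                    for _ in range(rng.randint(1, 2)))
                conds.append(conj)
            values.append(Value(id=f"v{i}", priority=0.5,
                                violation_conditions=conds))
        got = set(monitor_values(world, values))
        want = {v.id for v in values if brute_force_at_stake(world, v)}
        assert got == want


# ---------------------------------------------------------------------------
# goal formation
# ---------------------------------------------------------------------------

def test_adoption_condition_activates_goal(chocolate):
    agent, world, _ = chocolate()
    agent.beliefs = world
    monitor_values(world, agent.values)
    activated = form_goals(agent)
    assert [g.id for g in activated] == ["eat_chocolate"]
    assert agent.goal("eat_chocolate").status is GoalStatus.ACTIVE


def test_no_conditions_no_goals():
    agent = Agent(id="a", goals=[Goal(
        id="g", importance_of_success=0.5, importance_of_failure=0.5,
        adoption_conditions=[(Proposition.parse("never(x)"),)])])
    assert form_goals(agent) == []


def test_restoration_goal_inherits_value_priority():
    honesty = Value(id="honesty", priority=0.9,
                    violation_conditions=[(Proposition.parse("stole(X)"),)])
    agent = Agent(id="a", values=[honesty])
    agent.beliefs = WorldState({Proposition.parse("stole(candy)")})
    monitor_values(agent.beliefs, agent.values)
    (goal,) = form_goals(agent)
    assert goal.origin == "honesty"
    assert goal.importance_of_success == 0.9
    assert goal.importance_of_failure == 0.9
    assert goal.status is GoalStatus.ACTIVE
    # idempotent: a second formation pass does not duplicate it
    assert form_goals(agent) == []


# ---------------------------------------------------------------------------
# plan selection
# ---------------------------------------------------------------------------

def _ev(pid, utility):
    return PlanEvaluation(plan_id=pid, anticipated_emotions=[], eer=0.0,
                          utility=utility)


def test_select_plan_argmax_and_tie_break():
    assert select_plan([_ev("p1", 0.4), _ev("p2", 0.1)]) == "p1"
    assert select_plan([_ev("b", 0.3), _ev("a", 0.3)]) == "a"
    with pytest.raises(NoPlanError):
        select_plan([])


def test_select_plan_agrees_with_exhaustive_max():
    rng = random.Random(11)
    for _ in range(100):
        evs = [_ev(f"p{i}", round(rng.uniform(-1, 1), 3))
               for i in range(rng.randint(1, 8))]
        best = max(evs, key=lambda e: e.utility).utility
        candidates = sorted(e.plan_id for e in evs if e.utility == best)
        assert select_plan(evs) == candidates[0]


# ---------------------------------------------------------------------------
# anticipatory appraisal: the moral-deterrence dilemma
# ---------------------------------------------------------------------------

def _utilities(make, honesty_priority):
    agent, world, config = make(honesty_priority=honesty_priority)
    agent.beliefs = world
    monitor_values(world, agent.values)
    form_goals(agent)
    return {p.id: anticipatory_appraisal(p, agent, world, config)
            for p in agent.plan_library}


def test_high_honesty_prefers_asking(chocolate):
    evs = _utilities(chocolate, honesty_priority=0.9)
    assert evs["ask"].utility > evs["steal"].utility
    # the deterrent is the anticipated shame of stealing
    assert "shame" in {e.type.value for e in evs["steal"].anticipated_emotions}
    assert all(e.anticipatory for e in evs["steal"].anticipated_emotions)


def test_low_honesty_prefers_stealing(chocolate):
    evs = _utilities(chocolate, honesty_priority=0.2)
    assert evs["steal"].utility > evs["ask"].utility


def test_utility_without_side_effects_is_goal_term_only(chocolate):
    """A plan touching nothing beyond its goal has utility p*IoS-(1-p)*IoF."""
    agent, world, config = chocolate()
    agent.beliefs = world
    monitor_values(world, agent.values)
    form_goals(agent)
    ask = next(p for p in agent.plan_library if p.id == "ask")
    ev = anticipatory_appraisal(ask, agent, world, config)
    p, g = ask.probability_of_success, agent.goal("eat_chocolate")
    # ask achieves the goal without moral side effects: EER = joy only
    joy = g.importance_of_success * p * 1.0
    assert ev.eer == pytest.approx(joy)
    assert ev.utility == pytest.approx(
        p * g.importance_of_success - (1 - p) * g.importance_of_failure + joy)


def test_inapplicable_plan_probability_zero(chocolate):
    agent, world, config = chocolate()
    agent.beliefs = world
    monitor_values(world, agent.values)
    form_goals(agent)
    from moralagent import Action, Plan
    blocked = Plan(id="blocked", goal_id="eat_chocolate",
                   probability_of_success=0.9,
                   steps=[Action(id="x", actor="anna",
                                 preconditions=((Proposition.parse("open(door)"),),))])
    agent.plan_library.append(blocked)
    ev = anticipatory_appraisal(blocked, agent, world, config)
    assert ev.warnings
    assert ev.utility == pytest.approx(
        -agent.goal("eat_chocolate").importance_of_failure
        + ev.eer)


def test_raising_violated_value_priority_never_raises_utility(chocolate):
    """Monotone moral deterrence for the plan that puts honesty at stake."""
    priorities = [0.05 * k for k in range(1, 21)]
    utilities = [_utilities(chocolate, pr)["steal"].utility
                 for pr in priorities]
    assert all(u1 >= u2 for u1, u2 in zip(utilities, utilities[1:]))
    # and the ask plan, which does not violate honesty, is unaffected
    ask = [_utilities(chocolate, pr)["ask"].utility for pr in priorities]
    assert max(ask) == pytest.approx(min(ask))
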