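"""Shared fixtures: a minimal moral-dilemma agent built in code.

The "chocolate" dilemma: an agent craves a chocolate candy that another
agent owns, and can either ask for it (lower probability of success) or
steal it (higher probability, but a violation of her honesty value).
Whether she steals depends on the priority of honesty relative to the
goal's importance — the canonical test of moral deterrence through
anticipated shame.
"""

import pytest

from moralagent import (Action, AffectConfig, Agent, Goal, Plan, Proposition,
                        Value, WorldState)


def make_chocolate_agent(honesty_priority: float = 0.9,
                         p_steal: float = 0.65,
                         p_ask: float = 0.5) -> tuple[Agent, WorldState, AffectConfig]:
    """Build a fresh chocolate-dilemma agent, world and affect config."""
    world = WorldState({Proposition.parse("has(ben, candy)")})
    steal = Plan(
        id="steal", goal_id="eat_chocolate",
        probability_of_success=p_steal,
        steps=[Action(
            id="take_candy", actor="anna",
            add_effects=(Proposition.parse("has(anna, candy)"),
                         Proposition.parse("stole(anna)")),
            delete_effects=(Proposition.parse("has(ben, candy)"),),
        )])
    ask = Plan(
        id="ask", goal_id="eat_chocolate",
        probability_of_success=p_ask,
        steps=[Action(
            id="ask_candy", actor="anna",
            add_effects=(Proposition.parse("has(anna, candy)"),),
        )],
        failure_add_effects=(Proposition.parse("refused(ben)"),),
    )
    agent = Agent(
        id="anna",
        goals=[Goal(
            id="eat_chocolate",
            importance_of_success=0.8, importance_of_failure=0.4,
            adoption_conditions=[(Proposition.parse("has(ben, candy)"),)],
            success_conditions=[(Proposition.parse("has(anna, candy)"),)],
            failure_conditions=[(Proposition.parse("refused(ben)"),)],
        )],
        values=[Value(
            id="honesty", priority=honesty_priority,
            violation_conditions=[(Proposition.parse("stole(X)"),)],
        )],
        plan_library=[steal, ask],
    )
    # single-step plans at full emotional weight, and no hope/fear band
    # crossings for the chosen success probabilities
    config = AffectConfig(effort_reference_length=1)
    return agent, world, config


@pytest.fixture
def chocolate():
    return make_chocolate_agent
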