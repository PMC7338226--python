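"""Deliberation: value monitoring, goal formation, and plan ranking.

The agent ranks the plans of its active goals by a utility combining goal
achievement with anticipated emotional well-being:

    utility = p * IoS - (1 - p) * IoF + w * EER

where p is the plan's probability of success, IoS/IoF the goal's
importance of success/failure, and EER the expected emotional reward of
the emotions anticipated by mentally simulating the plan.  The agent
commits to the plan with the best trade-off between positive and negative
anticipated emotions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .agent import Agent, Goal, GoalStatus, Plan, Value
from .appraisal import (AffectConfig, AppraisalVariable, CauseRef, Change,
                        EmotionInstance, Responsibility, VariableKind,
                        appraise_outcome, derive_affect, effort_factor,
                        expected_emotional_reward)
from .logic import WorldState


class NoPlanError(ValueError):
    """Raised when plan selection is attempted with no evaluations."""


def monitor_values(world: WorldState, values: list[Value]) -> list[str]:
    """Flag values whose violation conditions hold; return their ids.

    Also clears the ``at_stake`` flag of values no longer violated, so the
    flag always reflects the last monitoring.
    """
    at_stake: list[str] = []
    for v in values:
        v.at_stake = v.violated_in(world)
        if v.at_stake:
            at_stake.append(v.id)
    return at_stake


def form_goals(agent: Agent) -> list[Goal]:
    """Adopt goals whose adoption conditions hold; spawn restoration goals.

    Every value currently at stake originates a goal to bring it back to
    balance, inheriting the value's priority as both importance of success
    and importance of failure.  Goals already achieved or failed are never
    re-activated.
    """
    activated: list[Goal] = []
    for g in agent.goals:
        if g.status is GoalStatus.INACTIVE and any(
                agent.beliefs.holds(c) for c in g.adoption_conditions):
            g.transition(GoalStatus.ACTIVE)
            activated.append(g)
    for v in agent.values:
        if not v.at_stake:
            continue
        if any(g.origin == v.id and g.status in (GoalStatus.ACTIVE,
                                                 GoalStatus.ACHIEVED,
                                                 GoalStatus.FAILED)
               for g in agent.goals):
            continue
        restoration = Goal(
            id=f"restore_{v.id}",
            importance_of_success=v.priority,
            importance_of_failure=v.priority,
            status=GoalStatus.ACTIVE,
            origin=v.id,
        )
        agent.goals.append(restoration)
        activated.append(restoration)
    return activated


@dataclass
class PlanEvaluation:
    plan_id: str
    anticipated_emotions: list[EmotionInstance]
    eer: float
    utility: float
    warnings: list[str] = field(default_factory=list)


def _detect_changes(agent: Agent, world: WorldState,
                    goal_status: dict[str, GoalStatus],
                    value_at_stake: dict[str, bool],
                    cause: CauseRef, probability: float,
                    effort: float) -> list[Change]:
    """Compare goal/value conditions against the world; record new changes.

    ``goal_status`` and ``value_at_stake`` are the bookkeeping maps of the
    caller (real or simulated) and are updated in place.
    """
    changes: list[Change] = []
    for v in agent.values:
        violated = v.violated_in(world)
        if violated and not value_at_stake[v.id]:
            value_at_stake[v.id] = True
            changes.append(Change("value_at_stake", v.id, cause,
                                  probability, effort))
        elif not violated and value_at_stake[v.id]:
            value_at_stake[v.id] = False
            changes.append(Change("value_restored", v.id, cause,
                                  probability, effort))
    for g in agent.goals:
        if goal_status[g.id] is not GoalStatus.ACTIVE:
            continue
        if g.is_restoration:
            # a restoration goal succeeds when its value is back in balance
            if not agent.value(g.origin).violated_in(world):
                goal_status[g.id] = GoalStatus.ACHIEVED
                changes.append(Change("goal_achieved", g.id, cause,
                                      probability, effort))
            continue
        if any(world.holds(c) for c in g.success_conditions):
            goal_status[g.id] = GoalStatus.ACHIEVED
            changes.append(Change("goal_achieved", g.id, cause,
                                  probability, effort))
        elif any(world.holds(c) for c in g.failure_conditions):
            goal_status[g.id] = GoalStatus.FAILED
            changes.append(Change("goal_failed", g.id, cause,
                                  probability, effort))
    return changes


def anticipatory_appraisal(plan: Plan, agent: Agent, world: WorldState,
                           config: AffectConfig = AffectConfig()) -> PlanEvaluation:
    """Evaluate a plan by mentally simulating its execution.

    The plan's steps are applied to a copy of the world under ideal
    conditions; the resulting goal/value changes are appraised and turned
    into anticipatory emotions, including hope or fear from the plan's
    probability of success.  If a step is inapplicable the probability is
    treated as zero and a warning is recorded.
    """
    goal = agent.goal(plan.goal_id)
    if goal.status is not GoalStatus.ACTIVE:
        raise ValueError(f"plan {plan.id}: goal {goal.id} is not active")

    sim_world = world.copy()
    sim_goal_status = {g.id: g.status for g in agent.goals}
    sim_value_at_stake = {v.id: v.at_stake for v in agent.values}
    warnings: list[str] = []
    p = plan.probability_of_success
    eff = effort_factor(plan.length, config.effort_reference_length)

    delta: list[Change] = []
    for step in plan.steps:
        if not step.applicable(sim_world):
            warnings.append(f"step {step.id} inapplicable; "
                            "probability treated as 0")
            p = 0.0
            break
        step.apply(sim_world)
        delta.extend(_detect_changes(
            agent, sim_world, sim_goal_status, sim_value_at_stake,
            CauseRef(step.id, step.actor), plan.probability_of_success, eff))

    variables = appraise_outcome(delta, agent)
    variables.append(AppraisalVariable(
        kind=VariableKind.LIKELIHOOD, intensity=p,
        responsibility=Responsibility.NONE,
        source=goal.id, cause=CauseRef(plan.id)))
    emotions = derive_affect(variables, config, anticipatory=True)
    eer = expected_emotional_reward(emotions)
    utility = (p * goal.importance_of_success
               - (1.0 - p) * goal.importance_of_failure
               + config.eer_weight * eer)
    return PlanEvaluation(plan.id, emotions, eer, utility, warnings)


def select_plan(evaluations: list[PlanEvaluation]) -> str:
    """Commit to the highest-utility plan; ties broken by lexicographic id."""
    if not evaluations:
        raise NoPlanError("no plan evaluations to select from")
    best = min(evaluations, key=lambda ev: (-ev.utility, ev.plan_id))
    return best.plan_id
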