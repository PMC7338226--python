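"""The six-phase reasoning cycle and its trace.

Each cycle runs, in order: Value Monitoring, Goal Formation, Emotional
Anticipatory Appraisal, Execution, Monitoring, Emotional Appraisal.  Plan
outcomes are scripted by default for reproducibility; a Bernoulli sampling
mode behind an explicit seed is available.  Exogenous events (actions of
other characters, or non-intentional happenings) are injected by the
script during Monitoring and appraised like any other change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

from .agent import Agent, Event, GoalStatus, Plan
from .appraisal import (AffectConfig, CauseRef, Change, EmotionInstance,
                        appraise_outcome, derive_affect, effort_factor)
from .deliberation import (PlanEvaluation, anticipatory_appraisal, form_goals,
                           monitor_values, select_plan, _detect_changes)
from .logic import WorldState

PHASES = ("value_monitoring", "goal_formation", "anticipatory_appraisal",
          "execution", "monitoring", "emotional_appraisal")


@dataclass
class CycleScript:
    """Scripted outcomes and events for one cycle.

    ``outcomes`` maps plan id -> True (success) / False (failure); a plan
    missing from the map in "sample" mode is resolved by a Bernoulli draw
    on its probability of success.
    """

    outcomes: dict[str, bool] = field(default_factory=dict)
    events: list[Event] = field(default_factory=list)


@dataclass
class OutcomeScript:
    cycles: list[CycleScript] = field(default_factory=list)
    mode: str = "scripted"          # "scripted" | "sample"
    seed: Optional[int] = None

    def for_cycle(self, i: int) -> CycleScript:
        return self.cycles[i] if i < len(self.cycles) else CycleScript()


@dataclass
class PhaseRecord:
    cycle: int
    phase: str
    payload: dict[str, Any]


@dataclass
class CycleTrace:
    agent_id: str
    records: list[PhaseRecord] = field(default_factory=list)
    completed_cycles: int = 0
    truncated: bool = False          # cut by max_cycles with goals pending
    warnings: list[str] = field(default_factory=list)

    def add(self, cycle: int, phase: str, **payload: Any) -> None:
        self.records.append(PhaseRecord(cycle, phase, payload))

    def selected_plan(self, cycle: int = 0) -> Optional[str]:
        for r in self.records:
            if r.cycle == cycle and r.phase == "anticipatory_appraisal":
                return r.payload.get("chosen")
        return None

    def final_emotions(self) -> list[EmotionInstance]:
        """Emotions of the last non-empty Emotional Appraisal phase."""
        out: list[EmotionInstance] = []
        for r in self.records:
            if r.phase == "emotional_appraisal" and r.payload["emotions"]:
                out = r.payload["emotions"]
        return out

    def final_emotion_types(self) -> set[str]:
        return {e.type.value for e in self.final_emotions()
                if e.intensity > 0.0}

    def to_jsonl(self) -> str:
        """Line-delimited structured records, one per phase."""
        lines = []
        for r in self.records:
            lines.append(json.dumps(
                {"agent": self.agent_id, "cycle": r.cycle, "phase": r.phase,
                 "payload": _jsonable(r.payload)},
                sort_keys=True))
        return "\n".join(lines) + "\n"

    def to_log(self) -> str:
        """Human-readable trace."""
        lines = [f"=== trace for agent {self.agent_id} ==="]
        for r in self.records:
            lines.append(f"[cycle {r.cycle}] {r.phase}: "
                         f"{json.dumps(_jsonable(r.payload), sort_keys=True)}")
        lines.append(f"completed cycles: {self.completed_cycles}"
                     + (" (truncated)" if self.truncated else ""))
        return "\n".join(lines) + "\n"


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, EmotionInstance):
        return {"type": obj.type.value, "intensity": round(obj.intensity, 6),
                "anticipatory": obj.anticipatory}
    if isinstance(obj, PlanEvaluation):
        return {"plan": obj.plan_id, "eer": round(obj.eer, 6),
                "utility": round(obj.utility, 6),
                "emotions": _jsonable(obj.anticipated_emotions),
                "warnings": obj.warnings}
    if isinstance(obj, Change):
        return {"kind": obj.kind, "subject": obj.subject,
                "cause": obj.cause.id}
    if hasattr(obj, "value") and isinstance(obj.value, str):  # enums
        return obj.value
    return obj


def execute_and_monitor(agent: Agent, world: WorldState, chosen: Plan,
                        outcome_success: bool,
                        config: AffectConfig = AffectConfig(),
                        trace: Optional[CycleTrace] = None) -> tuple[WorldState, list[Change]]:
    """Execute a plan under a scripted outcome and monitor its effects.

    On success every step's effects are applied in sequence; on failure
    the plan's failure-branch effects are applied instead.  Goal and value
    status updates are recorded in the returned delta, with the causing
    action attached for responsibility attribution.
    """
    goal_status = {g.id: g.status for g in agent.goals}
    value_at_stake = {v.id: v.at_stake for v in agent.values}
    eff = effort_factor(chosen.length, config.effort_reference_length)
    p = chosen.probability_of_success
    delta: list[Change] = []

    if outcome_success:
        for step in chosen.steps:
            if not step.applicable(world):
                msg = (f"plan {chosen.id}: step {step.id} inapplicable "
                       "at execution; skipped")
                if trace is not None:
                    trace.warnings.append(msg)
                continue
            step.apply(world)
            delta.extend(_detect_changes(agent, world, goal_status,
                                         value_at_stake,
                                         CauseRef(step.id, step.actor),
                                         p, eff))
    else:
        cause = CauseRef(f"{chosen.id}_failure", chosen.actor)
        for prop in chosen.failure_delete_effects:
            world.remove(prop)
        for prop in chosen.failure_add_effects:
            world.add(prop)
        delta.extend(_detect_changes(agent, world, goal_status,
                                     value_at_stake, cause, p, eff))

    # commit bookkeeping back onto the agent
    for g in agent.goals:
        if goal_status[g.id] is not g.status:
            g.transition(goal_status[g.id])
    for v in agent.values:
        v.at_stake = value_at_stake[v.id]
    return world, delta


def _apply_events(agent: Agent, world: WorldState,
                  events: list[Event]) -> list[Change]:
    goal_status = {g.id: g.status for g in agent.goals}
    value_at_stake = {v.id: v.at_stake for v in agent.values}
    delta: list[Change] = []
    for ev in events:
        ev.apply(world)
        delta.extend(_detect_changes(agent, world, goal_status,
                                     value_at_stake,
                                     CauseRef(ev.id, ev.actor), 1.0, 1.0))
    for g in agent.goals:
        if goal_status[g.id] is not g.status:
            g.transition(goal_status[g.id])
    for v in agent.values:
        v.at_stake = value_at_stake[v.id]
    return delta


def run_cycle(agent: Agent, world: WorldState,
              script: Optional[OutcomeScript] = None,
              max_cycles: int = 1,
              config: AffectConfig = AffectConfig()) -> CycleTrace:
    """Run the agent's six-phase reasoning cycle.

    Terminates when no active goals remain and no further scripted events
    are pending, or after ``max_cycles`` cycles (flagged as truncated).
    Fully deterministic given the scenario, script and seed.
    """
    if max_cycles < 1:
        raise ValueError("max_cycles must be >= 1")
    script = script or OutcomeScript()
    rng = (np.random.default_rng(script.seed)
           if script.mode == "sample" else None)
    agent.beliefs = world
    trace = CycleTrace(agent_id=agent.id)

    for cycle in range(max_cycles):
        cs = script.for_cycle(cycle)

        # 1. Value Monitoring
        at_stake = monitor_values(world, agent.values)
        trace.add(cycle, "value_monitoring", values_at_stake=at_stake)

        # 2. Goal Formation
        activated = form_goals(agent)
        trace.add(cycle, "goal_formation",
                  goals_adopted=[g.id for g in activated],
                  active_goals=[g.id for g in agent.active_goals()])

        # 3. Emotional Anticipatory Appraisal
        evaluations = [anticipatory_appraisal(plan, agent, world, config)
                       for g in agent.active_goals()
                       for plan in agent.plans_for(g.id)]
        chosen_id: Optional[str] = None
        if evaluations:
            chosen_id = select_plan(evaluations)
        trace.add(cycle, "anticipatory_appraisal",
                  evaluations=evaluations, chosen=chosen_id)
        for ev in evaluations:
            if ev.plan_id == chosen_id:
                agent.emotional_state.extend(ev.anticipated_emotions)
            trace.warnings.extend(ev.warnings)

        # 4. Execution
        delta: list[Change] = []
        if chosen_id is not None:
            chosen = next(p for p in agent.plan_library if p.id == chosen_id)
            if chosen_id in cs.outcomes:
                success = cs.outcomes[chosen_id]
            elif rng is not None:
                success = bool(rng.random() < chosen.probability_of_success)
            else:
                success = True
            world, exec_delta = execute_and_monitor(
                agent, world, chosen, success, config, trace)
            delta.extend(exec_delta)
            trace.add(cycle, "execution", plan=chosen_id, success=success)
        else:
            trace.add(cycle, "execution", plan=None, success=None)

        # 5. Monitoring (exogenous events + world delta)
        delta.extend(_apply_events(agent, world, cs.events))
        trace.add(cycle, "monitoring", delta=delta,
                  facts=sorted(str(f) for f in world.facts))

        # 6. Emotional Appraisal
        variables = appraise_outcome(delta, agent)
        emotions = derive_affect(variables, config, anticipatory=False)
        agent.emotional_state.extend(emotions)
        trace.add(cycle, "emotional_appraisal", emotions=emotions)

        trace.completed_cycles = cycle + 1
        more_events = any(script.for_cycle(i).events
                          for i in range(cycle + 1, max_cycles))
        if not agent.active_goals() and not more_events:
            break
    else:
        pass
    if agent.active_goals():
        trace.truncated = True
    return trace
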