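"""Domain types for the belief–desire–intention agent with moral values.

Goals carry an importance of success and of failure and three condition
sets (adoption, success, failure).  Values carry a priority and violation
conditions; a value whose violation condition holds is *at stake* and
originates a restoration goal.  Plans are authored in the scenario file
(planning is not part of the model) with a scalar probability of success.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from .logic import Condition, Proposition, WorldState


class GoalStatus(enum.Enum):
    INACTIVE = "inactive"
    ACTIVE = "active"
    ACHIEVED = "achieved"
    FAILED = "failed"
    DROPPED = "dropped"


# legal transitions: inactive -> active -> {achieved, failed, dropped}
_TRANSITIONS = {
    GoalStatus.INACTIVE: {GoalStatus.ACTIVE},
    GoalStatus.ACTIVE: {GoalStatus.ACHIEVED, GoalStatus.FAILED,
                        GoalStatus.DROPPED},
    GoalStatus.ACHIEVED: set(),
    GoalStatus.FAILED: set(),
    GoalStatus.DROPPED: set(),
}


def _check_unit(x: float, what: str) -> float:
    if not 0.0 < x <= 1.0:
        raise ValueError(f"{what} must lie in (0, 1], got {x}")
    return float(x)


@dataclass
class Goal:
    id: str
    importance_of_success: float
    importance_of_failure: float
    adoption_conditions: list[Condition] = field(default_factory=list)
    success_conditions: list[Condition] = field(default_factory=list)
    failure_conditions: list[Condition] = field(default_factory=list)
    status: GoalStatus = GoalStatus.INACTIVE
    # either "intrinsic" or the id of the value this goal restores
    origin: str = "intrinsic"

    def __post_init__(self) -> None:
        _check_unit(self.importance_of_success, f"goal {self.id} IoS")
        _check_unit(self.importance_of_failure, f"goal {self.id} IoF")

    @property
    def is_restoration(self) -> bool:
        return self.origin != "intrinsic"

    def transition(self, new: GoalStatus) -> None:
        if new not in _TRANSITIONS[self.status]:
            raise ValueError(
                f"goal {self.id}: illegal transition "
                f"{self.status.value} -> {new.value}"
            )
        self.status = new


@dataclass
class Value:
    """A moral value: a priority and the conditions under which it is violated."""

    id: str
    priority: float
    violation_conditions: list[Condition] = field(default_factory=list)
    at_stake: bool = False

    def __post_init__(self) -> None:
        _check_unit(self.priority, f"value {self.id} priority")

    def violated_in(self, world: WorldState) -> bool:
        return any(world.holds(c) for c in self.violation_conditions)


@dataclass(frozen=True)
class Action:
    """STRIPS-style action: preconditions plus add/delete effects."""

    id: str
    actor: str
    preconditions: tuple[Condition, ...] = ()
    add_effects: tuple[Proposition, ...] = ()
    delete_effects: tuple[Proposition, ...] = ()

    def applicable(self, world: WorldState) -> bool:
        return all(world.holds(c) for c in self.preconditions)

    def apply(self, world: WorldState) -> None:
        """Effects are applied atomically; deleting an absent fact is a no-op."""
        for p in self.delete_effects:
            world.remove(p)
        for p in self.add_effects:
            world.add(p)


@dataclass
class Plan:
    id: str
    goal_id: str
    steps: list[Action]
    probability_of_success: float
    # effects of the failure branch, applied when execution is scripted
    # (or sampled) to fail
    failure_add_effects: tuple[Proposition, ...] = ()
    failure_delete_effects: tuple[Proposition, ...] = ()

    def __post_init__(self) -> None:
        _check_unit(self.probability_of_success,
                    f"plan {self.id} probability_of_success")

    @property
    def length(self) -> int:
        return len(self.steps)

    @property
    def actor(self) -> Optional[str]:
        return self.steps[0].actor if self.steps else None


@dataclass
class Agent:
    """A character: beliefs, goals, moral values, plan library, emotions."""

    id: str
    beliefs: WorldState = field(default_factory=WorldState)
    goals: list[Goal] = field(default_factory=list)
    values: list[Value] = field(default_factory=list)
    plan_library: list[Plan] = field(default_factory=list)
    emotional_state: list = field(default_factory=list)  # list[EmotionInstance]

    def __post_init__(self) -> None:
        gids = [g.id for g in self.goals]
        vids = [v.id for v in self.values]
        if len(set(gids)) != len(gids):
            raise ValueError(f"agent {self.id}: duplicate goal ids")
        if len(set(vids)) != len(vids):
            raise ValueError(f"agent {self.id}: duplicate value ids")

    def goal(self, goal_id: str) -> Goal:
        for g in self.goals:
            if g.id == goal_id:
                return g
        raise KeyError(f"agent {self.id}: unknown goal {goal_id!r}")

    def value(self, value_id: str) -> Value:
        for v in self.values:
            if v.id == value_id:
                return v
        raise KeyError(f"agent {self.id}: unknown value {value_id!r}")

    def active_goals(self) -> list[Goal]:
        return [g for g in self.goals if g.status is GoalStatus.ACTIVE]

    def plans_for(self, goal_id: str) -> list[Plan]:
        return [p for p in self.plan_library if p.goal_id == goal_id]


@dataclass(frozen=True)
class Event:
    """An exogenous occurrence scripted by the scenario.

    Events carry an acting character (so moral responsibility can be
    attributed) or ``actor=None`` for non-intentional happenings.
    """

    id: str
    actor: Optional[str]
    add_effects: tuple[Proposition, ...] = ()
    delete_effects: tuple[Proposition, ...] = ()

    def apply(self, world: WorldState) -> None:
        for p in self.delete_effects:
            world.remove(p)
        for p in self.add_effects:
            world.add(p)
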