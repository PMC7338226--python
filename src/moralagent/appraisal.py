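"""Emotional appraisal: appraisal variables and affect derivation.

Emotion generation is a two-step process.  First, changes in the status of
goals and values are appraised into *appraisal variables* (desirability,
undesirability, praiseworthiness, blameworthiness, likelihood), each with
an intensity and, for the moral variables, a responsibility attribution
(self- vs other-caused).  Second, *affect derivation* maps variables to
emotion types:

    desirability              -> joy
    undesirability            -> distress
    praiseworthiness, self    -> pride
    praiseworthiness, other   -> admiration
    blameworthiness, self     -> shame
    blameworthiness, other    -> reproach
    likelihood high / low     -> hope / fear

When the same situation is appraised both against a goal and against a
value (the two variables share a cause), compound emotions arise:

    joy + pride        -> gratification
    joy + admiration   -> gratitude
    distress + shame   -> remorse      (distress + self-reproach)
    distress + reproach-> anger

Intensity is the product of the importance of the goal or value, the
probability of success of the plan, and an effort factor derived from the
plan's length.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .agent import Agent, Goal, GoalStatus, Value


class VariableKind(enum.Enum):
    DESIRABILITY = "desirability"
    UNDESIRABILITY = "undesirability"
    PRAISEWORTHINESS = "praiseworthiness"
    BLAMEWORTHINESS = "blameworthiness"
    LIKELIHOOD = "likelihood"


class Responsibility(enum.Enum):
    SELF = "self"
    OTHER = "other"
    NONE = "none"


MORAL_KINDS = {VariableKind.PRAISEWORTHINESS, VariableKind.BLAMEWORTHINESS}


class EmotionType(enum.Enum):
    JOY = "joy"
    DISTRESS = "distress"
    HOPE = "hope"
    FEAR = "fear"
    PRIDE = "pride"
    SHAME = "shame"
    ADMIRATION = "admiration"
    REPROACH = "reproach"
    GRATIFICATION = "gratification"
    GRATITUDE = "gratitude"
    REMORSE = "remorse"
    ANGER = "anger"


#: Positive- and negative-valence emotion types, used by the expected
#: emotional reward (EER): the sum of anticipated positive intensities
#: minus the sum of anticipated negative intensities.
POSITIVE_EMOTIONS = frozenset({
    EmotionType.JOY, EmotionType.HOPE, EmotionType.PRIDE,
    EmotionType.ADMIRATION, EmotionType.GRATIFICATION, EmotionType.GRATITUDE,
})
NEGATIVE_EMOTIONS = frozenset(EmotionType) - POSITIVE_EMOTIONS

COMPOUND_EMOTIONS = frozenset({
    EmotionType.GRATIFICATION, EmotionType.GRATITUDE,
    EmotionType.REMORSE, EmotionType.ANGER,
})


@dataclass(frozen=True)
class CauseRef:
    """What produced a change: an action or event id and its acting character."""

    id: str
    actor: Optional[str] = None


@dataclass(frozen=True)
class AppraisalVariable:
    kind: VariableKind
    intensity: float
    responsibility: Responsibility
    source: str            # goal id or value id
    cause: CauseRef

    def __post_init__(self) -> None:
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError(f"intensity outside [0, 1]: {self.intensity}")
        if self.kind in MORAL_KINDS:
            if self.responsibility is Responsibility.NONE:
                raise ValueError(
                    f"{self.kind.value} must be self- or other-caused")
        elif self.responsibility is not Responsibility.NONE:
            raise ValueError(
                f"{self.kind.value} carries no responsibility attribution")


@dataclass(frozen=True)
class EmotionInstance:
    type: EmotionType
    intensity: float
    cause: tuple[AppraisalVariable, ...]
    anticipatory: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError(f"intensity outside [0, 1]: {self.intensity}")
        n = len(self.cause)
        if self.type in COMPOUND_EMOTIONS and n != 2:
            raise ValueError(
                f"compound {self.type.value} must cite exactly two "
                f"component variables, got {n}")


@dataclass(frozen=True)
class AffectConfig:
    """Tunables of affect derivation.

    co_emit_components
        Whether the component emotions of a compound are emitted alongside
        it (default) or suppressed.
    theta_hope / theta_fear
        Likelihood thresholds: hope fires at likelihood >= theta_hope,
        fear at likelihood <= theta_fear.
    effort_reference_length
        Plan length at which the effort factor saturates at 1.
    eer_weight
        Weight of the EER term in plan utility.
    """

    co_emit_components: bool = True
    theta_hope: float = 0.7
    theta_fear: float = 0.3
    effort_reference_length: int = 5
    eer_weight: float = 1.0


def emotion_intensity(importance: float, probability: float,
                      effort_factor: float) -> float:
    """Multiplicative intensity model: importance x probability x effort."""
    for name, x in (("importance", importance), ("probability", probability),
                    ("effort_factor", effort_factor)):
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"{name} outside [0, 1]: {x}")
    return importance * probability * effort_factor


def effort_factor(plan_length: int, reference_length: int = 5) -> float:
    """Effort grows with plan length and saturates at the reference length."""
    if plan_length < 0:
        raise ValueError("plan length must be non-negative")
    if reference_length < 1:
        raise ValueError("reference length must be positive")
    return min(1.0, plan_length / reference_length)


# --------------------------------------------------------------------------
# Outcome appraisal: status changes -> appraisal variables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Change:
    """One status change observed during Monitoring.

    kind is one of goal_achieved, goal_failed, value_at_stake,
    value_restored.  probability and effort carry the factors of the plan
    (or event) that produced the change; exogenous events use 1.0 for both.
    """

    kind: str
    subject: str
    cause: CauseRef
    probability: float = 1.0
    effort: float = 1.0


Delta = tuple[Change, ...]

_CHANGE_KINDS = {"goal_achieved", "goal_failed", "value_at_stake",
                 "value_restored"}


def appraise_outcome(delta: Sequence[Change], agent: Agent) -> list[AppraisalVariable]:
    """Turn goal/value status changes into appraisal variables.

    Responsibility for the moral variables is *self* when the causing
    action's actor is the appraising agent, *other* otherwise.
    """
    out: list[AppraisalVariable] = []
    for ch in delta:
        if ch.kind not in _CHANGE_KINDS:
            raise ValueError(f"unknown change kind {ch.kind!r}")
        if ch.kind in ("goal_achieved", "goal_failed"):
            goal = agent.goal(ch.subject)
            importance = (goal.importance_of_success
                          if ch.kind == "goal_achieved"
                          else goal.importance_of_failure)
            kind = (VariableKind.DESIRABILITY if ch.kind == "goal_achieved"
                    else VariableKind.UNDESIRABILITY)
            out.append(AppraisalVariable(
                kind=kind,
                intensity=emotion_intensity(importance, ch.probability,
                                            ch.effort),
                responsibility=Responsibility.NONE,
                source=goal.id, cause=ch.cause))
        else:
            value = agent.value(ch.subject)
            kind = (VariableKind.BLAMEWORTHINESS if ch.kind == "value_at_stake"
                    else VariableKind.PRAISEWORTHINESS)
            resp = (Responsibility.SELF if ch.cause.actor == agent.id
                    else Responsibility.OTHER)
            out.append(AppraisalVariable(
                kind=kind,
                intensity=emotion_intensity(value.priority, ch.probability,
                                            ch.effort),
                responsibility=resp,
                source=value.id, cause=ch.cause))
    return out


# --------------------------------------------------------------------------
# Affect derivation: appraisal variables -> emotions
# --------------------------------------------------------------------------

_SIMPLE_RULES = {
    (VariableKind.DESIRABILITY, Responsibility.NONE): EmotionType.JOY,
    (VariableKind.UNDESIRABILITY, Responsibility.NONE): EmotionType.DISTRESS,
    (VariableKind.PRAISEWORTHINESS, Responsibility.SELF): EmotionType.PRIDE,
    (VariableKind.PRAISEWORTHINESS, Responsibility.OTHER): EmotionType.ADMIRATION,
    (VariableKind.BLAMEWORTHINESS, Responsibility.SELF): EmotionType.SHAME,
    (VariableKind.BLAMEWORTHINESS, Responsibility.OTHER): EmotionType.REPROACH,
}

# compound = (event-based kind, standard-based kind + responsibility)
_COMPOUND_RULES = {
    (VariableKind.DESIRABILITY, Responsibility.SELF): EmotionType.GRATIFICATION,
    (VariableKind.DESIRABILITY, Responsibility.OTHER): EmotionType.GRATITUDE,
    (VariableKind.UNDESIRABILITY, Responsibility.SELF): EmotionType.REMORSE,
    (VariableKind.UNDESIRABILITY, Responsibility.OTHER): EmotionType.ANGER,
}


def derive_affect(variables: Iterable[AppraisalVariable],
                  config: AffectConfig = AffectConfig(),
                  anticipatory: bool = False) -> list[EmotionInstance]:
    """Apply the affect-derivation rule table.

    A compound emotion fires when an event-based variable (desirability or
    undesirability) and a standard-based one (praise/blameworthiness) are
    tagged with the same cause; compound intensity is the mean of its two
    components.  Under ``co_emit_components=False`` the components that
    took part in a compound are suppressed.
    """
    variables = list(variables)
    emotions: list[EmotionInstance] = []
    in_compound: set[int] = set()   # indices of vars consumed by a compound

    # compounds first: group by cause
    by_cause: dict[CauseRef, list[int]] = {}
    for i, v in enumerate(variables):
        by_cause.setdefault(v.cause, []).append(i)
    for idxs in by_cause.values():
        events = [i for i in idxs
                  if variables[i].kind in (VariableKind.DESIRABILITY,
                                           VariableKind.UNDESIRABILITY)]
        standards = [i for i in idxs
                     if variables[i].kind in MORAL_KINDS]
        for ie in events:
            for istd in standards:
                ev, sv = variables[ie], variables[istd]
                # valence must agree: joy pairs with praise, distress with blame
                wants_praise = ev.kind is VariableKind.DESIRABILITY
                if wants_praise != (sv.kind is VariableKind.PRAISEWORTHINESS):
                    continue
                etype = _COMPOUND_RULES[(ev.kind, sv.responsibility)]
                emotions.append(EmotionInstance(
                    type=etype,
                    intensity=(ev.intensity + sv.intensity) / 2.0,
                    cause=(ev, sv), anticipatory=anticipatory))
                in_compound.update((ie, istd))

    for i, v in enumerate(variables):
        if v.kind is VariableKind.LIKELIHOOD:
            if v.intensity >= config.theta_hope:
                emotions.append(EmotionInstance(
                    EmotionType.HOPE, v.intensity, (v,), anticipatory))
            elif v.intensity <= config.theta_fear:
                emotions.append(EmotionInstance(
                    EmotionType.FEAR, v.intensity, (v,), anticipatory))
            continue
        if not config.co_emit_components and i in in_compound:
            continue
        etype = _SIMPLE_RULES[(v.kind, v.responsibility)]
        emotions.append(EmotionInstance(etype, v.intensity, (v,), anticipatory))
    return emotions


def expected_emotional_reward(emotions: Iterable[EmotionInstance]) -> float:
    """EER: summed positive-valence minus summed negative-valence intensity."""
    eer = 0.0
    for e in emotions:
        eer += e.intensity if e.type in POSITIVE_EMOTIONS else -e.intensity
    return eer
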