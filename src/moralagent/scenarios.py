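"""Scenario bank: machine-readable narrative scenarios and their loader.

Seven scenarios are packaged: three "actor" scenarios, where the
protagonist must choose between two authored plans and the model predicts
both the choice and the resulting emotions, and four "audience" scenarios
from classic literary works (Hamlet, The Count of Montecristo, Therese
Raquin, The Vicomte of Bragelonne), where the characters' behavior is
scripted as events and the model predicts each character's emotional
state.

Scenario files are YAML (JSON is valid YAML and therefore accepted).  The
goal/value numerics in the fixtures are authored to satisfy the ordinal
constraints implied by the narrative summaries; the packaged ground-truth
prediction marks are the published reference the engine must reproduce.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .agent import Action, Agent, Event, Goal, Plan, Value
from .appraisal import AffectConfig, EmotionType
from .cycle import CycleScript, CycleTrace, OutcomeScript, run_cycle
from .logic import Proposition, WorldState, parse_condition

EMOTION_NAMES = frozenset(e.value for e in EmotionType)


class ScenarioValidationError(ValueError):
    """Schema violation; the message lists the offending fields."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid scenario:\n  - " + "\n  - ".join(errors))


# ---------------------------------------------------------------------------
# Packaged ground truth: the prediction marks of the published score tables.
# Actor scenarios: predicted course of action and protagonist emotion set.
# Audience scenarios: main-character emotion sets; other-character sets are
# provisional (the source table's column alignment is partly corrupted).
# ---------------------------------------------------------------------------
ACTOR_PREDICTED_PLANS: dict[str, str] = {
    "wallace": "giving_key",
    "at_school": "revenging",
    "difficult_choice": "staying",
}

ACTOR_PREDICTED_EMOTIONS: dict[str, frozenset[str]] = {
    "wallace": frozenset({"shame"}),
    "at_school": frozenset({"joy", "pride", "shame", "gratification"}),
    "difficult_choice": frozenset({"distress", "joy", "shame", "remorse"}),
}

AUDIENCE_MAIN_EMOTIONS: dict[str, frozenset[str]] = {
    "hamlet": frozenset({"reproach", "anger", "distress"}),
    "montecristo": frozenset({"joy", "gratification", "pride"}),
    "therese_raquin": frozenset({"remorse", "distress", "shame"}),
    "bragelonne": frozenset({"gratification"}),
}

#: Provisional: transcribed from a typographically garbled source table.
AUDIENCE_OTHER_EMOTIONS_PROVISIONAL: dict[str, frozenset[str]] = {
    "hamlet": frozenset({"shame"}),
    "montecristo": frozenset({"distress"}),
    "therese_raquin": frozenset({"remorse", "distress", "shame"}),
    "bragelonne": frozenset({"gratitude"}),
}

ACTOR_SCENARIOS = ("wallace", "at_school", "difficult_choice")
AUDIENCE_SCENARIOS = ("hamlet", "montecristo", "therese_raquin", "bragelonne")


@dataclass
class CharacterSpec:
    id: str
    protagonist: bool
    raw: dict[str, Any]

    def build(self) -> Agent:
        """Construct a fresh (mutable) agent from the immutable spec."""
        goals = [
            Goal(
                id=g["id"],
                importance_of_success=float(g["importance_of_success"]),
                importance_of_failure=float(g["importance_of_failure"]),
                adoption_conditions=[parse_condition(c)
                                     for c in g.get("adoption", [])],
                success_conditions=[parse_condition(c)
                                    for c in g.get("success", [])],
                failure_conditions=[parse_condition(c)
                                    for c in g.get("failure", [])],
            )
            for g in self.raw.get("goals", [])
        ]
        values = [
            Value(
                id=v["id"],
                priority=float(v["priority"]),
                violation_conditions=[parse_condition(c)
                                      for c in v.get("violation", [])],
            )
            for v in self.raw.get("values", [])
        ]
        plans = [
            Plan(
                id=p["id"],
                goal_id=p["goal"],
                probability_of_success=float(p["probability_of_success"]),
                steps=[
                    Action(
                        id=s["id"],
                        actor=s["actor"],
                        preconditions=tuple(parse_condition(c)
                                            for c in s.get("preconditions", [])),
                        add_effects=tuple(Proposition.parse(t)
                                          for t in s.get("add", [])),
                        delete_effects=tuple(Proposition.parse(t)
                                             for t in s.get("delete", [])),
                    )
                    for s in p.get("steps", [])
                ],
                failure_add_effects=tuple(
                    Proposition.parse(t) for t in p.get("failure_add", [])),
                failure_delete_effects=tuple(
                    Proposition.parse(t) for t in p.get("failure_delete", [])),
            )
            for p in self.raw.get("plans", [])
        ]
        return Agent(id=self.id, goals=goals, values=values,
                     plan_library=plans)


@dataclass
class Scenario:
    id: str
    study: str                      # "actor" | "audience"
    title: str
    narrative: str
    world_facts: list[str]
    characters: list[CharacterSpec]
    script_raw: dict[str, Any]
    max_cycles: int
    predicted_plan: Optional[str]
    predicted_emotions: dict[str, frozenset[str]]
    provisional_emotions: dict[str, frozenset[str]] = field(default_factory=dict)
    affect_overrides: dict[str, Any] = field(default_factory=dict)

    # -- construction helpers -------------------------------------------
    def build_world(self) -> WorldState:
        return WorldState({Proposition.parse(f) for f in self.world_facts})

    def build_script(self) -> OutcomeScript:
        cycles = []
        for c in self.script_raw.get("cycles", []):
            events = [
                Event(
                    id=e["id"],
                    actor=e.get("actor"),
                    add_effects=tuple(Proposition.parse(t)
                                      for t in e.get("add", [])),
                    delete_effects=tuple(Proposition.parse(t)
                                         for t in e.get("delete", [])),
                )
                for e in c.get("events", [])
            ]
            cycles.append(CycleScript(
                outcomes={k: bool(v) for k, v in
                          c.get("outcomes", {}).items()},
                events=events))
        return OutcomeScript(cycles=cycles,
                             mode=self.script_raw.get("mode", "scripted"),
                             seed=self.script_raw.get("seed"))

    def affect_config(self) -> AffectConfig:
        return AffectConfig(**self.affect_overrides)

    def character(self, character_id: str) -> CharacterSpec:
        for c in self.characters:
            if c.id == character_id:
                return c
        raise KeyError(f"scenario {self.id}: unknown character "
                       f"{character_id!r}")

    @property
    def protagonist(self) -> CharacterSpec:
        for c in self.characters:
            if c.protagonist:
                return c
        raise ValueError(f"scenario {self.id}: no protagonist declared")

    def to_dict(self) -> dict[str, Any]:
        """Canonical serialization; load -> serialize -> load is identity."""
        out: dict[str, Any] = {
            "id": self.id, "study": self.study, "title": self.title,
            "narrative": self.narrative, "world": list(self.world_facts),
            "max_cycles": self.max_cycles,
            "characters": [
                {"id": c.id, "protagonist": c.protagonist, **c.raw}
                for c in self.characters],
            "script": self.script_raw,
            "predictions": {
                "emotions": {k: sorted(v)
                             for k, v in self.predicted_emotions.items()},
            },
        }
        if self.predicted_plan is not None:
            out["predictions"]["plan"] = self.predicted_plan
        if self.provisional_emotions:
            out["predictions"]["provisional_emotions"] = {
                k: sorted(v) for k, v in self.provisional_emotions.items()}
        if self.affect_overrides:
            out["affect"] = dict(self.affect_overrides)
        return out


def _validate(doc: Any, origin: str) -> list[str]:
    errs: list[str] = []
    if not isinstance(doc, dict):
        return [f"{origin}: document is not a mapping"]
    for key in ("id", "study", "world", "characters", "script",
                "predictions"):
        if key not in doc:
            errs.append(f"missing field: {key}")
    if errs:
        return errs
    if doc["study"] not in ("actor", "audience"):
        errs.append(f"study must be actor|audience, got {doc['study']!r}")

    char_ids = {c.get("id") for c in doc.get("characters", [])} - {None}
    protagonists = 0
    goal_ids: dict[str, set[str]] = {}
    for c in doc.get("characters", []):
        cid = c.get("id")
        if not cid:
            errs.append("character with no id")
            continue
        protagonists += bool(c.get("protagonist"))
        goal_ids[cid] = {g["id"] for g in c.get("goals", [])}
        for p in c.get("plans", []):
            if p.get("goal") not in goal_ids[cid]:
                errs.append(f"plan {p.get('id')!r} of {cid} references "
                            f"unknown goal {p.get('goal')!r}")
            for s in p.get("steps", []):
                if s.get("actor") not in char_ids:
                    errs.append(f"step {s.get('id')!r}: actor "
                                f"{s.get('actor')!r} is not a declared "
                                "character")

    preds = doc.get("predictions", {})
    for cid, emos in {**preds.get("emotions", {}),
                      **preds.get("provisional_emotions", {})}.items():
        if cid not in char_ids:
            errs.append(f"predictions reference unknown character {cid!r}")
        bad = set(emos) - EMOTION_NAMES
        if bad:
            errs.append(f"unknown emotion types for {cid}: {sorted(bad)}")

    if doc["study"] == "actor":
        if "plan" not in preds:
            errs.append("actor scenario missing predicted plan")
        prot = [c for c in doc["characters"] if c.get("protagonist")]
        if protagonists != 1:
            errs.append(f"actor scenario needs exactly 1 protagonist, "
                        f"got {protagonists}")
        elif len(prot[0].get("plans", [])) != 2:
            errs.append("actor protagonist must have exactly 2 plans")
        elif preds.get("plan") not in {p["id"] for p in prot[0]["plans"]}:
            errs.append(f"predicted plan {preds.get('plan')!r} not in the "
                        "protagonist's plan pair")
    return errs


def scenario_from_dict(doc: dict[str, Any],
                       origin: str = "<dict>") -> Scenario:
    errors = _validate(doc, origin)
    if errors:
        raise ScenarioValidationError(errors)
    characters = []
    for c in doc["characters"]:
        raw = {k: v for k, v in c.items() if k not in ("id", "protagonist")}
        characters.append(CharacterSpec(id=c["id"],
                                        protagonist=bool(c.get("protagonist")),
                                        raw=raw))
    preds = doc["predictions"]
    scenario = Scenario(
        id=doc["id"], study=doc["study"],
        title=doc.get("title", doc["id"]),
        narrative=doc.get("narrative", ""),
        world_facts=list(doc["world"]),
        characters=characters,
        script_raw=doc["script"],
        max_cycles=int(doc.get("max_cycles", 1)),
        predicted_plan=preds.get("plan"),
        predicted_emotions={k: frozenset(v)
                            for k, v in preds.get("emotions", {}).items()},
        provisional_emotions={k: frozenset(v) for k, v in
                              preds.get("provisional_emotions", {}).items()},
        affect_overrides=dict(doc.get("affect", {})),
    )
    # building every agent exercises the numeric range checks
    for c in scenario.characters:
        c.build()
    scenario.build_world()
    scenario.build_script()
    scenario.affect_config()
    return scenario


def load_scenario(path: str | Path) -> Scenario:
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        raise ScenarioValidationError([f"{path.name}: empty file"])
    return scenario_from_dict(doc, origin=path.name)


def packaged_scenario_dir() -> Path:
    return Path(importlib.resources.files("moralagent")) / "data" / "scenarios"


def load_packaged(scenario_id: str) -> Scenario:
    return load_scenario(packaged_scenario_dir() / f"{scenario_id}.yaml")


def all_scenario_ids() -> tuple[str, ...]:
    return ACTOR_SCENARIOS + AUDIENCE_SCENARIOS


# ---------------------------------------------------------------------------
# Prediction surface
# ---------------------------------------------------------------------------

def predicted_behavior(scenario: Scenario) -> str:
    """The course of action the model predicts for an actor scenario."""
    if scenario.study != "actor":
        raise ValueError(
            f"scenario {scenario.id} is an audience scenario; it has no "
            "behavioral choice")
    assert scenario.predicted_plan is not None
    return scenario.predicted_plan


def predicted_emotions(scenario: Scenario, character: str) -> frozenset[str]:
    """The emotion types the model predicts for a character."""
    spec = scenario.character(character)  # raises KeyError if unknown
    if spec.id in scenario.predicted_emotions:
        return scenario.predicted_emotions[spec.id]
    if spec.id in scenario.provisional_emotions:
        return scenario.provisional_emotions[spec.id]
    raise KeyError(f"scenario {scenario.id}: no prediction for "
                   f"character {character!r}")


def run_scenario(scenario: Scenario,
                 config: Optional[AffectConfig] = None) -> dict[str, CycleTrace]:
    """Run every character's reasoning cycle; return traces by character."""
    cfg = config or scenario.affect_config()
    traces: dict[str, CycleTrace] = {}
    for spec in scenario.characters:
        agent = spec.build()
        world = scenario.build_world()
        traces[spec.id] = run_cycle(agent, world, scenario.build_script(),
                                    max_cycles=scenario.max_cycles,
                                    config=cfg)
    return traces
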