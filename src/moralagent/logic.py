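"""Propositional world model and condition matching.

The agent's beliefs are a set of ground propositions such as
``stole(chocolate)``.  Goal and value conditions are conjunctions of
proposition patterns; a pattern argument starting with an uppercase letter
(Prolog convention) is a variable that unifies with any constant, with
bindings shared across the conjunction.  There is no negation-as-failure:
the smallest language sufficient for the packaged scenarios.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

_IDENT = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def is_variable(token: str) -> bool:
    """A term is a variable iff its first character is an uppercase letter."""
    return bool(token) and token[0].isupper()


@dataclass(frozen=True)
class Proposition:
    """A predicate applied to a tuple of terms, e.g. ``has(anna, candy)``."""

    name: str
    args: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not _IDENT.match(self.name):
            raise ValueError(f"invalid predicate name: {self.name!r}")
        for a in self.args:
            if not _IDENT.match(a):
                raise ValueError(f"invalid argument {a!r} in {self.name}")

    @property
    def is_ground(self) -> bool:
        return not any(is_variable(a) for a in self.args)

    def substitute(self, binding: dict[str, str]) -> "Proposition":
        return Proposition(
            self.name, tuple(binding.get(a, a) for a in self.args)
        )

    def __str__(self) -> str:  # e.g. stole(chocolate)
        return f"{self.name}({', '.join(self.args)})" if self.args else self.name

    @classmethod
    def parse(cls, text: str) -> "Proposition":
        """Parse ``name(arg1, arg2)`` or bare ``name``."""
        text = text.strip()
        if "(" not in text:
            return cls(text)
        m = re.match(r"^([A-Za-z_][A-Za-z0-9_]*)\((.*)\)$", text)
        if not m:
            raise ValueError(f"cannot parse proposition: {text!r}")
        name, inner = m.group(1), m.group(2).strip()
        args = tuple(a.strip() for a in inner.split(",")) if inner else ()
        return cls(name, args)


# A condition is a conjunction of proposition patterns.
Condition = tuple[Proposition, ...]


def parse_condition(items: Iterable[str]) -> Condition:
    return tuple(Proposition.parse(s) for s in items)


def _match_one(pattern: Proposition, fact: Proposition,
               binding: dict[str, str]) -> Optional[dict[str, str]]:
    if pattern.name != fact.name or len(pattern.args) != len(fact.args):
        return None
    out = dict(binding)
    for p, f in zip(pattern.args, fact.args):
        if is_variable(p):
            if p in out and out[p] != f:
                return None
            out[p] = f
        elif p != f:
            return None
    return out


def _solve(patterns: list[Proposition], facts: frozenset[Proposition],
           binding: dict[str, str]) -> Iterator[dict[str, str]]:
    if not patterns:
        yield binding
        return
    head, rest = patterns[0], patterns[1:]
    for fact in facts:
        b = _match_one(head, fact, binding)
        if b is not None:
            yield from _solve(rest, facts, b)


@dataclass
class WorldState:
    """A set of ground facts, updated through perception and action effects."""

    facts: set[Proposition] = field(default_factory=set)

    def __post_init__(self) -> None:
        for f in self.facts:
            if not f.is_ground:
                raise ValueError(f"world facts must be ground: {f}")

    def holds(self, condition: Condition) -> bool:
        """True iff the conjunction is satisfiable against the fact base."""
        return next(
            _solve(list(condition), frozenset(self.facts), {}), None
        ) is not None

    def add(self, fact: Proposition) -> None:
        if not fact.is_ground:
            raise ValueError(f"cannot assert non-ground fact: {fact}")
        self.facts.add(fact)

    def remove(self, fact: Proposition) -> bool:
        """Delete a fact; deleting an absent fact is a no-op returning False."""
        if fact in self.facts:
            self.facts.remove(fact)
            return True
        return False

    def copy(self) -> "WorldState":
        return WorldState(set(self.facts))

    def __contains__(self, fact: Proposition) -> bool:
        return fact in self.facts
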