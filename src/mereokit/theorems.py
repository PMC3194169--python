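"""Executable verification of the has_grain relation properties.

The grain relation is *defined* (a grain is a proper part of an entity that
instantiates a matching collective type), so irreflexivity, asymmetry and
the two propagation laws are theorems, not assumptions: any violation found
on any constructible model is a bug in the definitions.  This module checks
them by exhaustive evaluation over finite models, and searches for the
non-transitivity witness (a galaxy collects stars and a star collects
molecules, yet the galaxy does not collect molecules).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .model import FiniteModel, TypeRegistry, has_grain, proper_parts
from .fixtures import galaxy_fixture, random_model, standard_random_vocab

__all__ = [
    "PropertyReport",
    "check_relation_properties",
    "run_theorem_suite",
    "DEFAULT_SUITE_SIZE",
    "DEFAULT_MAX_ENTITIES",
]

DEFAULT_SUITE_SIZE = 500
DEFAULT_MAX_ENTITIES = 8

UNIVERSAL_PROPERTIES = ("irreflexivity", "asymmetry", "propagation_I", "propagation_II")


@dataclass
class PropertyReport:
    """Outcome of checking one relation property over a model suite.

    For the universal properties, an empty violation list means the
    property held everywhere.  The non-transitivity report is existential:
    it passes when a witness triple was found.
    """

    name: str
    kind: str  # "universal" | "existential"
    models_checked: int = 0
    violations: list[tuple[str, tuple]] = field(default_factory=list)
    witness: Optional[tuple] = None

    @property
    def passed(self) -> bool:
        if self.kind == "universal":
            return not self.violations
        return self.witness is not None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "models_checked": self.models_checked,
            "passed": self.passed,
            "violations": [
                {"model": digest, "witness": list(w)} for digest, w in self.violations
            ],
            "witness": list(self.witness) if self.witness else None,
        }


def _digest(model: FiniteModel) -> str:
    payload = repr(
        (
            sorted(model.entities),
            sorted((e, sorted(t.name for t in ts)) for e, ts in model.instance_of.items()),
            sorted(model.direct_part),
        )
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:10]


def check_relation_properties(
    models: Iterable[FiniteModel], registry: TypeRegistry
) -> dict[str, PropertyReport]:
    """Check irreflexivity, asymmetry and propagation I/II of has_grain over
    every entity triple of every model, and search the suite for a
    non-transitivity witness."""
    reports = {p: PropertyReport(p, "universal") for p in UNIVERSAL_PROPERTIES}
    reports["non_transitivity"] = PropertyReport("non_transitivity", "existential")

    for model in models:
        digest = _digest(model)
        ents = sorted(model.entities)
        pp = {e: proper_parts(model, e) for e in ents}
        hg = {
            (x, y)
            for x in ents
            for y in ents
            if x != y and has_grain(model, registry, x, y)
        }

        def has_part(x: str, y: str) -> bool:  # reflexive parthood
            return x == y or y in pp[x]

        for x in ents:
            if has_grain(model, registry, x, x):
                reports["irreflexivity"].violations.append((digest, (x,)))
        for x, y in hg:
            if (y, x) in hg:
                reports["asymmetry"].violations.append((digest, (x, y)))
        for x in ents:
            for y, z in hg:
                if has_part(x, y) and not has_part(x, z):
                    reports["propagation_I"].violations.append((digest, (x, y, z)))
        for x, y in hg:
            for z in ents:
                if has_part(y, z) and not has_part(x, z):
                    reports["propagation_II"].violations.append((digest, (x, y, z)))
        if reports["non_transitivity"].witness is None:
            for x, y in hg:
                for z in ents:
                    if (y, z) in hg and (x, z) not in hg:
                        reports["non_transitivity"].witness = (x, y, z)
                        break
                if reports["non_transitivity"].witness is not None:
                    break
        for r in reports.values():
            r.models_checked += 1
    return reports


def _merge_registries(*regs: TypeRegistry) -> TypeRegistry:
    out = TypeRegistry()
    for r in regs:
        out.types |= r.types
        out.is_a |= r.is_a
        out.disjoint_pairs |= r.disjoint_pairs
    return out


def run_theorem_suite(
    seed: int = 0,
    n_models: int = DEFAULT_SUITE_SIZE,
    max_entities: int = DEFAULT_MAX_ENTITIES,
) -> dict[str, PropertyReport]:
    """The shipped verification suite: seeded random models plus the galaxy
    fixture (which supplies the non-transitivity witness)."""
    reg, vocab = standard_random_vocab()
    gal = galaxy_fixture()
    registry = _merge_registries(reg, gal.registry)
    rng_sizes = [(seed * 1000 + i) % (2**31) for i in range(n_models)]
    models = [
        random_model((i % max_entities) + 1, vocab, s)
        for i, s in enumerate(rng_sizes)
    ]
    models.append(gal.model)
    return check_relation_properties(models, registry)


def reports_to_json(reports: dict[str, PropertyReport]) -> str:
    return json.dumps({k: r.to_dict() for k, r in reports.items()}, indent=2)
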