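"""Finite instance models of mereological reality.

A :class:`FiniteModel` is a finite universe of entities carrying type labels
and an acyclic *direct parthood* graph.  ``has_proper_part`` is the transitive
closure of that graph; ``has_grain`` and ``has_component`` are derived
subrelations.  All semantics in this package (collective/compound
classification, DL class-expression extensions, the theorem suite) is
evaluated against these models.

The central notions:

* a **collective** is an entity whose *grains* — its multiply occurring,
  uniform parts, e.g. the water molecules of a portion of water — all
  instantiate one type (mono-sortality), and at least one grain exists;
* a **compound** is an entity divided by a *partition* into pairwise disjoint,
  jointly exhaustive *components*, which may be of several types
  (multi-sortality);
* each axis (mono-/multi-sortal, number-flexible/number-strict) varies
  independently, yielding a four-way classification realized by
  :func:`classify_complex`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

__all__ = [
    "TypeName",
    "TypeRegistry",
    "FiniteModel",
    "Partition",
    "Cardinality",
    "TypeSpec",
    "exactly",
    "at_least",
    "ANY",
    "ModelError",
    "CycleError",
    "UnknownEntityError",
    "UnknownTypeError",
    "InvalidPartitionError",
    "NoPartsAtLevelError",
    "build_model",
    "proper_parts",
    "grains_of",
    "satisfies_coll",
    "has_grain",
    "is_n_coll",
    "is_valid_partition",
    "leaf_content",
    "has_component",
    "components_at_level",
    "is_strict_compound",
    "classify_complex",
]


class ModelError(ValueError):
    """Base class for model construction and query errors."""


class CycleError(ModelError):
    """Raised when the direct-parthood graph contains a cycle."""


class UnknownEntityError(ModelError):
    """Raised when an operation references an entity not in the model."""


class UnknownTypeError(ModelError):
    """Raised when an operation references an undeclared type."""


class InvalidPartitionError(ModelError):
    """Raised when a partition fails disjointness/exhaustiveness checks."""


class NoPartsAtLevelError(ModelError):
    """Raised by classify_complex when an entity has no part at the level."""


# ---------------------------------------------------------------------------
# types and the type registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TypeName:
    """A named type.

    ``kind`` is ``"plain"`` for ordinary types, ``"coll"`` for a collective
    type over a base type (the COLL-index applied to the base, e.g.
    ``Propanol_COLL`` over ``Propanol_Molecule``), or ``"n_coll"`` for a
    strict collective of fixed cardinality (e.g. an ``H_PAIR``).
    The COLL-index is a naming convention plus generated axioms, never a
    higher-order constructor.
    """

    name: str
    kind: str = "plain"
    base: Optional["TypeName"] = None
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("plain", "coll", "n_coll"):
            raise ValueError(f"bad TypeName kind: {self.kind!r}")
        if self.kind in ("coll", "n_coll") and self.base is None:
            raise ValueError(f"{self.kind} type {self.name!r} needs a base type")
        if self.kind == "n_coll" and (self.n is None or self.n < 1):
            raise ValueError(f"n_coll type {self.name!r} needs n >= 1")
        if self.kind == "plain" and (self.base is not None or self.n is not None):
            raise ValueError("plain types carry no base/n")

    @staticmethod
    def coll(base: "TypeName", name: Optional[str] = None) -> "TypeName":
        return TypeName(name or f"{base.name}_COLL", kind="coll", base=base)

    @staticmethod
    def n_coll(base: "TypeName", n: int, name: Optional[str] = None) -> "TypeName":
        if name is None:
            name = f"{base.name}_PAIR" if n == 2 else f"{base.name}_{n}_COLL"
        return TypeName(name, kind="n_coll", base=base, n=n)

    def __repr__(self) -> str:  # compact, used in error messages
        return self.name


@dataclass
class TypeRegistry:
    """A named-type is_a hierarchy with disjointness axioms.

    Subsumption queries use the reflexive-transitive closure of the asserted
    ``is_a`` edges.  Whether a collective type such as ``Entity_COLL`` is
    itself a subtype of anything is deliberately left to the modeller: no
    implicit edges are added for coll/n_coll types.
    """

    types: set[TypeName] = field(default_factory=set)
    is_a: set[tuple[TypeName, TypeName]] = field(default_factory=set)
    disjoint_pairs: set[frozenset[TypeName]] = field(default_factory=set)

    def add(self, *ts: TypeName) -> "TypeRegistry":
        self.types.update(ts)
        return self

    def add_is_a(self, child: TypeName, parent: TypeName) -> "TypeRegistry":
        self.types.update((child, parent))
        if child != parent and child in self.supertypes_of(parent):
            raise ModelError(f"is_a cycle: {child} <-> {parent}")
        self.is_a.add((child, parent))
        self._check_disjoint_consistency()
        return self

    def add_disjoint(self, a: TypeName, b: TypeName) -> "TypeRegistry":
        self.types.update((a, b))
        self.disjoint_pairs.add(frozenset((a, b)))
        self._check_disjoint_consistency()
        return self

    def _check_disjoint_consistency(self) -> None:
        for pair in self.disjoint_pairs:
            a, b = tuple(pair)
            if self.is_subtype(a, b) or self.is_subtype(b, a):
                raise ModelError(f"types {a} and {b} both disjoint and in an is_a chain")

    def supertypes_of(self, t: TypeName) -> set[TypeName]:
        """Reflexive-transitive closure of is_a above ``t``."""
        seen = {t}
        frontier = [t]
        while frontier:
            cur = frontier.pop()
            for child, parent in self.is_a:
                if child == cur and parent not in seen:
                    seen.add(parent)
                    frontier.append(parent)
        return seen

    def is_subtype(self, a: TypeName, b: TypeName) -> bool:
        return b in self.supertypes_of(a)

    def by_name(self, name: str) -> TypeName:
        for t in self.types:
            if t.name == name:
                return t
        raise UnknownTypeError(f"type {name!r} not declared")

    def coll_types_instantiated_by(self, types: Iterable[TypeName]) -> set[TypeName]:
        """All coll/n_coll registry types subsuming any of ``types``."""
        out: set[TypeName] = set()
        for t in types:
            for sup in self.supertypes_of(t):
                if sup.kind in ("coll", "n_coll"):
                    out.add(sup)
        return out


# ---------------------------------------------------------------------------
# finite models
# ---------------------------------------------------------------------------

Entity = str


@dataclass
class FiniteModel:
    """Entities with type labels and an acyclic direct-parthood graph.

    ``grain_designation`` optionally marks, per entity, which of its direct
    parts count as candidate grains; without a designation every direct part
    is a candidate grain (a portion of water has its molecules, not their
    atoms, as grains).
    """

    entities: set[Entity] = field(default_factory=set)
    instance_of: dict[Entity, frozenset[TypeName]] = field(default_factory=dict)
    direct_part: set[tuple[Entity, Entity]] = field(default_factory=set)
    grain_designation: dict[Entity, frozenset[Entity]] = field(default_factory=dict)

    def types_of(self, x: Entity) -> frozenset[TypeName]:
        self._require(x)
        return self.instance_of.get(x, frozenset())

    def direct_parts_of(self, x: Entity) -> set[Entity]:
        self._require(x)
        return {p for w, p in self.direct_part if w == x}

    def instantiates(self, x: Entity, t: TypeName, registry: TypeRegistry) -> bool:
        """True iff ``x`` is an instance of ``t`` under is_a closure."""
        return any(registry.is_subtype(tt, t) for tt in self.types_of(x))

    def _require(self, *xs: Entity) -> None:
        for x in xs:
            if x not in self.entities:
                raise UnknownEntityError(f"entity {x!r} not in model")


def build_model(
    type_assignments: Mapping[Entity, Iterable[TypeName]],
    part_edges: Iterable[tuple[Entity, Entity]] = (),
    grain_designation: Optional[Mapping[Entity, Iterable[Entity]]] = None,
) -> FiniteModel:
    """Validate and build a :class:`FiniteModel`.

    Rejects parthood cycles (naming an offending entity) and references to
    undeclared entities; a grain designation must pick from direct parts.
    """
    entities = set(type_assignments)
    edges = {(w, p) for w, p in part_edges}
    for w, p in edges:
        for e in (w, p):
            if e not in entities:
                raise UnknownEntityError(f"edge {(w, p)} references unknown entity {e!r}")
    # cycle check: DFS over the direct-part graph
    succ: dict[Entity, list[Entity]] = {}
    for w, p in edges:
        succ.setdefault(w, []).append(p)
    state: dict[Entity, int] = {}  # 1 = on stack, 2 = done

    def visit(e: Entity, stack: list[Entity]) -> None:
        state[e] = 1
        for nxt in succ.get(e, ()):
            if state.get(nxt) == 1:
                raise CycleError(f"parthood cycle through entity {nxt!r}")
            if state.get(nxt) != 2:
                visit(nxt, stack + [nxt])
        state[e] = 2

    for e in entities:
        if state.get(e) != 2:
            visit(e, [e])

    designation: dict[Entity, frozenset[Entity]] = {}
    if grain_designation:
        for x, gs in grain_designation.items():
            gset = frozenset(gs)
            if x not in entities:
                raise UnknownEntityError(f"grain designation for unknown entity {x!r}")
            direct = {p for w, p in edges if w == x}
            if not gset <= direct:
                raise ModelError(
                    f"designated grains of {x!r} must be direct parts; got {sorted(gset - direct)}"
                )
            designation[x] = gset

    return FiniteModel(
        entities=entities,
        instance_of={e: frozenset(ts) for e, ts in type_assignments.items()},
        direct_part=edges,
        grain_designation=designation,
    )


def proper_parts(model: FiniteModel, x: Entity) -> set[Entity]:
    """Transitive closure of direct parthood below ``x`` (never contains x)."""
    model._require(x)
    out: set[Entity] = set()
    frontier = [x]
    while frontier:
        cur = frontier.pop()
        for w, p in model.direct_part:
            if w == cur and p not in out:
                out.add(p)
                frontier.append(p)
    return out


def grains_of(model: FiniteModel, x: Entity) -> set[Entity]:
    """Candidate grains of ``x``: the designated set if present, else the
    direct parts."""
    model._require(x)
    if x in model.grain_designation:
        return set(model.grain_designation[x])
    return model.direct_parts_of(x)


def satisfies_coll(
    model: FiniteModel, registry: TypeRegistry, x: Entity, base: TypeName
) -> bool:
    """Does ``x`` satisfy the collective axioms for grain type ``base``?

    Grain-Existence: at least one grain; Mono-Sortality: every grain
    instantiates ``base``.  Empty collectives are rejected — an entity with
    no grains is a collective of nothing, hence of anything, which is why
    the theory forbids them.
    """
    if base not in registry.types:
        raise UnknownTypeError(f"type {base} not declared")
    grains = grains_of(model, x)
    return bool(grains) and all(model.instantiates(g, base, registry) for g in grains)


def has_grain(model: FiniteModel, registry: TypeRegistry, x: Entity, y: Entity) -> bool:
    """``x has_grain y``: y is a proper part of x, and x instantiates a
    collective type whose base type y instantiates.

    Derived, not primitive: irreflexivity, asymmetry and the propagation
    theorems follow from the proper-parthood conjunct.
    """
    model._require(x, y)
    if y not in proper_parts(model, x):
        return False
    for coll in registry.coll_types_instantiated_by(model.types_of(x)):
        assert coll.base is not None
        if model.instantiates(y, coll.base, registry):
            return True
    return False


def is_n_coll(
    model: FiniteModel, registry: TypeRegistry, x: Entity, base: TypeName, n: int
) -> bool:
    """Strict collective test: ``x`` is a collective of ``base`` with exactly
    ``n`` grains (n=2 is the pair pattern)."""
    if n < 1:
        raise ValueError("n-collectives require n >= 1")
    return satisfies_coll(model, registry, x, base) and len(grains_of(model, x)) == n


# ---------------------------------------------------------------------------
# partitions, components, compounds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Partition:
    """A whole together with an enumeration of its segments.

    Segments are compared as sets; the listed order carries no meaning.
    """

    whole: Entity
    segments: tuple[Entity, ...]

    def __init__(self, whole: Entity, segments: Sequence[Entity]):
        object.__setattr__(self, "whole", whole)
        object.__setattr__(self, "segments", tuple(segments))
        if len(self.segments) < 1:
            raise ValueError("a partition needs at least one segment")


def leaf_content(model: FiniteModel, x: Entity) -> set[Entity]:
    """The mereological atoms of ``x``: its partless proper parts, or ``x``
    itself when it has none."""
    pp = proper_parts(model, x)
    if not pp:
        return {x}
    return {y for y in pp if not model.direct_parts_of(y)}


def is_valid_partition(model: FiniteModel, p: Partition) -> bool:
    """Segments must be proper parts of the whole, pairwise mereologically
    disjoint, and jointly exhaustive.

    The models are discrete and atomistic, so mereological overlap and
    "the sum of the segments overlaps the compound completely" are judged
    on leaf content: two segments are disjoint when they share no
    mereological atom, and the partition is exhaustive when the union of
    the segments' atoms equals the whole's atoms.  Judging the sum on leaf
    content (rather than on raw entity sets) is what lets a partition
    crisscross granularity levels — half a protein in monomers, half in
    atoms — without the intermediate entities getting in the way.
    """
    model._require(p.whole)
    whole_parts = proper_parts(model, p.whole)
    if len(set(p.segments)) != len(p.segments):
        return False  # duplicated segment overlaps itself
    contents = []
    for s in p.segments:
        if s not in whole_parts:
            return False
        contents.append(leaf_content(model, s))
    for a, b in itertools.combinations(contents, 2):
        if a & b:
            return False
    covered: set[Entity] = set()
    for c in contents:
        covered |= c
    return covered == leaf_content(model, p.whole)


def has_component(
    model: FiniteModel,
    x: Entity,
    y: Entity,
    p: Optional[Partition] = None,
) -> bool:
    """Componenthood, relativized to a partition when one is given.

    With ``p``: y is a component of x iff y is one of p's segments (a part
    of a segment is not itself a component with respect to p).  Without a
    partition the relation reduces to proper parthood: in a discrete finite
    model every proper part extends to some partition, by taking the
    remaining atoms as singleton segments.
    """
    model._require(x, y)
    if p is not None:
        if p.whole != x or not is_valid_partition(model, p):
            raise InvalidPartitionError(f"not a valid partition of {x!r}: {p.segments}")
        return y in p.segments
    return y in proper_parts(model, x)


LevelSpec = Union[TypeName, Sequence[TypeName]]


def _level_types(level: LevelSpec) -> tuple[TypeName, ...]:
    if isinstance(level, TypeName):
        return (level,)
    return tuple(level)


def components_at_level(
    model: FiniteModel, registry: TypeRegistry, x: Entity, level: LevelSpec
) -> set[Entity]:
    """Proper parts of ``x`` at a granularity level, the level given as a
    type (e.g. Molecule, Atom) or a disjunction of types (e.g.
    Proton/Neutron/Electron for the subatomic level)."""
    lts = _level_types(level)
    for lt in lts:
        if lt not in registry.types:
            raise UnknownTypeError(f"level type {lt} not declared")
    return {
        y
        for y in proper_parts(model, x)
        if any(model.instantiates(y, lt, registry) for lt in lts)
    }


# ---------------------------------------------------------------------------
# composition specifications and the four-way classifier
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Cardinality:
    """exactly(n) / at_least(n) / ANY slot cardinality."""

    kind: str  # "exactly" | "at_least" | "any"
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("exactly", "at_least", "any"):
            raise ValueError(f"bad cardinality kind {self.kind!r}")
        if self.kind in ("exactly", "at_least") and (self.n is None or self.n < 1):
            raise ValueError(f"{self.kind} requires n >= 1")

    def admits(self, count: int) -> bool:
        if self.kind == "exactly":
            return count == self.n
        if self.kind == "at_least":
            assert self.n is not None
            return count >= self.n
        return True


def exactly(n: int) -> Cardinality:
    return Cardinality("exactly", n)


def at_least(n: int) -> Cardinality:
    return Cardinality("at_least", n)


ANY = Cardinality("any")


@dataclass(frozen=True)
class TypeSpec:
    """A composition specification: per-component-type cardinality slots.

    ``closed`` forbids parts of types outside the listed slots.  Whether the
    number of components is essential for the type is read off the slots:
    any ``exactly`` slot makes the specification strict.
    """

    name: TypeName
    slots: tuple[tuple[TypeName, Cardinality], ...]
    closed: bool = True

    def __init__(
        self,
        name: TypeName,
        slots: Sequence[tuple[TypeName, Cardinality]],
        closed: bool = True,
    ):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "slots", tuple(slots))
        object.__setattr__(self, "closed", closed)

    @property
    def strict(self) -> bool:
        return any(card.kind == "exactly" for _, card in self.slots)

    def satisfied_by(
        self, registry: TypeRegistry, item_types: Sequence[frozenset[TypeName]]
    ) -> bool:
        """Check a multiset of items (given by their type sets) against the
        slots."""

        def inst(ts: frozenset[TypeName], slot_t: TypeName) -> bool:
            return any(registry.is_subtype(t, slot_t) for t in ts)

        for slot_t, card in self.slots:
            count = sum(1 for ts in item_types if inst(ts, slot_t))
            if not card.admits(count):
                return False
        if self.closed:
            for ts in item_types:
                if not any(inst(ts, slot_t) for slot_t, _ in self.slots):
                    return False
        return True


def is_strict_compound(
    model: FiniteModel,
    registry: TypeRegistry,
    x: Entity,
    p: Partition,
    spec: TypeSpec,
) -> bool:
    """Is ``x``, under partition ``p``, a strict compound per ``spec``?

    The modal reading — "it is not possible to add further segments or to
    subtract any segment such that the result is still an X" — is made
    decidable by testing spec violation under every single-segment removal
    and under addition of one hypothetical segment of each slot type.
    """
    if not is_valid_partition(model, p):
        raise InvalidPartitionError(f"not a valid partition: {p.segments}")
    item_types = [model.types_of(s) for s in p.segments]
    if not spec.satisfied_by(registry, item_types):
        return False
    for i in range(len(item_types)):
        if spec.satisfied_by(registry, item_types[:i] + item_types[i + 1 :]):
            return False  # a segment can be subtracted: number not essential
    for slot_t, _ in spec.slots:
        if spec.satisfied_by(registry, item_types + [frozenset((slot_t,))]):
            return False  # a segment can be added
    return True


#: the four categories of complex entities
CATEGORIES = (
    "flexible_collective",
    "strict_collective",
    "flexible_compound",
    "strict_compound",
)


def classify_complex(
    model: FiniteModel,
    registry: TypeRegistry,
    x: Entity,
    spec: TypeSpec,
    level: LevelSpec,
) -> str:
    """Four-way classification of a complex entity at a granularity level.

    Mono-sortality is judged on the most specific declared types of the
    parts at the level, so it is both granularity dependent (a water portion
    is mono-sortal at the Molecule level, multi-sortal at the Atom level)
    and specificity dependent (a fruit basket is a collective of fruits and
    a mixture of apples and pears).  Number-strictness is read off ``spec``.
    """
    parts = components_at_level(model, registry, x, level)
    if not parts:
        raise NoPartsAtLevelError(f"{x!r} has no part at level {level!r}")
    lts = _level_types(level)
    sorts: set[TypeName] = set()
    for y in parts:
        for t in model.types_of(y):
            if any(registry.is_subtype(t, lt) for lt in lts):
                sorts.add(t)
    # drop redundant supertypes: declaring {H-Atom, Atom} is the same sort
    # as declaring {H-Atom}
    minimal = {
        t
        for t in sorts
        if not any(s != t and registry.is_subtype(s, t) for s in sorts)
    }
    mono = len(minimal) == 1
    if mono:
        return "strict_collective" if spec.strict else "flexible_collective"
    return "strict_compound" if spec.strict else "flexible_compound"
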