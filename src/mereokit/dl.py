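"""Description-logic class expressions with finite-model semantics.

Three pieces live here:

* a small class-expression AST (atomic classes, boolean connectives,
  existential/universal restrictions and qualified cardinality restrictions)
  with a Manchester-style surface syntax;
* a DL-safety checker: OWL 2 forbids cardinality restrictions on *non-simple*
  roles (a role that is transitive or has a transitive subrole), which is
  exactly why ``has_proper_part exactly 3 Atom`` is not admissible while
  ``has_component exactly 3 Atom`` is;
* a bounded-model subsumption oracle: it decides ``C ⊑ D`` by exhaustively
  checking every acyclic finite model up to a size bound, returning either
  "holds up to size k" or a concrete countermodel.  Roles declared as
  primitive subroles of ``has_proper_part`` (``has_grain``,
  ``has_component``) are interpreted as *arbitrary* subrelations of proper
  parthood, which is how an OWL reasoner sees them.

The oracle works under classical closed-world finite semantics; the OWL
output of :mod:`mereokit.patterns` targets open-world reasoners.  A
subsumption *failure* found here is definitive (the countermodel is a real
countermodel); a subsumption *success* is evidence bounded by the model size
checked.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from .model import (
    FiniteModel,
    TypeName,
    TypeRegistry,
    UnknownTypeError,
    build_model,
    grains_of,
    proper_parts,
)

__all__ = [
    "RoleSpec",
    "default_roles",
    "ClassExpr",
    "Atomic",
    "Not",
    "And",
    "Or",
    "Some",
    "Only",
    "Exactly",
    "Min",
    "Max",
    "Axiom",
    "SubClassOf",
    "EquivalentTo",
    "DisjointWith",
    "TBox",
    "Verdict",
    "Violation",
    "ExprSyntaxError",
    "UndeclaredSymbolError",
    "ResourceCapError",
    "ExternalReasonerUnavailable",
    "extension",
    "is_dl_safe",
    "non_simple_roles",
    "parse_expr",
    "render_expr",
    "expand_definitions",
    "bounded_subsumption",
    "check_with_external_reasoner",
    "HAS_PROPER_PART",
    "PROPER_PART_OF",
    "HAS_GRAIN",
    "HAS_COMPONENT",
]

HAS_PROPER_PART = "has_proper_part"
PROPER_PART_OF = "proper_part_of"
HAS_GRAIN = "has_grain"
HAS_COMPONENT = "has_component"


class UndeclaredSymbolError(ValueError):
    """An expression references an undeclared class or role."""


class ExprSyntaxError(ValueError):
    """Surface-syntax parse error; carries the offending position."""

    def __init__(self, message: str, pos: int):
        super().__init__(f"{message} (at position {pos})")
        self.pos = pos


class ExternalReasonerUnavailable(RuntimeError):
    """The optional external DL reasoner cannot be used in this environment."""


class ResourceCapError(RuntimeError):
    """Bounded search exceeded its model cap; carries the partial verdict."""

    def __init__(self, partial: "Verdict"):
        super().__init__(
            f"model cap reached after {partial.models_checked} models "
            f"(no countermodel so far, result incomplete)"
        )
        self.partial_verdict = partial


# ---------------------------------------------------------------------------
# roles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RoleSpec:
    name: str
    transitive: bool = False
    subrole_of: Optional[str] = None
    inverse_of: Optional[str] = None


def default_roles() -> dict[str, RoleSpec]:
    """The mereological role box: transitive proper parthood with its two
    non-transitive primitive subroles."""
    specs = [
        RoleSpec(HAS_PROPER_PART, transitive=True),
        RoleSpec(PROPER_PART_OF, transitive=True, inverse_of=HAS_PROPER_PART),
        RoleSpec(HAS_GRAIN, subrole_of=HAS_PROPER_PART),
        RoleSpec(HAS_COMPONENT, subrole_of=HAS_PROPER_PART),
    ]
    return {s.name: s for s in specs}


# ---------------------------------------------------------------------------
# class-expression AST
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Atomic:
    name: str


@dataclass(frozen=True)
class Not:
    arg: "ClassExpr"


@dataclass(frozen=True)
class And:
    args: tuple["ClassExpr", ...]

    def __init__(self, *args: "ClassExpr"):
        if len(args) == 1 and isinstance(args[0], tuple):
            args = args[0]
        if len(args) < 2:
            raise ValueError("And needs at least two operands")
        object.__setattr__(self, "args", tuple(args))


@dataclass(frozen=True)
class Or:
    args: tuple["ClassExpr", ...]

    def __init__(self, *args: "ClassExpr"):
        if len(args) == 1 and isinstance(args[0], tuple):
            args = args[0]
        if len(args) < 2:
            raise ValueError("Or needs at least two operands")
        object.__setattr__(self, "args", tuple(args))


@dataclass(frozen=True)
class Some:
    role: str
    filler: "ClassExpr"


@dataclass(frozen=True)
class Only:
    role: str
    filler: "ClassExpr"


@dataclass(frozen=True)
class Exactly:
    role: str
    n: int
    filler: "ClassExpr"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("exactly requires n >= 1")


@dataclass(frozen=True)
class Min:
    role: str
    n: int
    filler: "ClassExpr"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("min requires n >= 1")


@dataclass(frozen=True)
class Max:
    role: str
    n: int
    filler: "ClassExpr"

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("max requires n >= 0")


ClassExpr = Union[Atomic, Not, And, Or, Some, Only, Exactly, Min, Max]

_CARD_NODES = (Exactly, Min, Max)
_RESTRICTIONS = (Some, Only, Exactly, Min, Max)


def atom(t: Union[TypeName, str]) -> Atomic:
    return Atomic(t.name if isinstance(t, TypeName) else t)


def walk(expr: ClassExpr) -> Iterable[ClassExpr]:
    yield expr
    if isinstance(expr, Not):
        yield from walk(expr.arg)
    elif isinstance(expr, (And, Or)):
        for a in expr.args:
            yield from walk(a)
    elif isinstance(expr, _RESTRICTIONS):
        yield from walk(expr.filler)


def roles_in(expr: ClassExpr) -> set[str]:
    return {e.role for e in walk(expr) if isinstance(e, _RESTRICTIONS)}


def atoms_in(expr: ClassExpr) -> set[str]:
    return {e.name for e in walk(expr) if isinstance(e, Atomic)}


# ---------------------------------------------------------------------------
# axioms and TBoxes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Axiom:
    kind: str  # "subclass" | "equivalent" | "disjoint"
    lhs: ClassExpr
    rhs: ClassExpr
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("subclass", "equivalent", "disjoint"):
            raise ValueError(f"bad axiom kind {self.kind!r}")


def SubClassOf(lhs: ClassExpr, rhs: ClassExpr, provenance: str = "") -> Axiom:
    return Axiom("subclass", lhs, rhs, provenance)


def EquivalentTo(lhs: ClassExpr, rhs: ClassExpr, provenance: str = "") -> Axiom:
    return Axiom("equivalent", lhs, rhs, provenance)


def DisjointWith(lhs: ClassExpr, rhs: ClassExpr, provenance: str = "") -> Axiom:
    return Axiom("disjoint", lhs, rhs, provenance)


@dataclass
class TBox:
    roles: dict[str, RoleSpec] = field(default_factory=default_roles)
    axioms: list[Axiom] = field(default_factory=list)

    def add(self, *axioms: Axiom) -> "TBox":
        for ax in axioms:
            for e in (ax.lhs, ax.rhs):
                for r in roles_in(e):
                    if r not in self.roles:
                        raise UndeclaredSymbolError(f"role {r!r} not declared")
            if ax not in self.axioms:
                self.axioms.append(ax)
        return self

    def definitions(self) -> dict[str, ClassExpr]:
        """First equivalence axiom per defined atomic name.

        Additional equivalences for the same name are kept as model
        constraints by the oracle rather than macro-expanded.
        """
        defs: dict[str, ClassExpr] = {}
        for ax in self.axioms:
            if ax.kind == "equivalent" and isinstance(ax.lhs, Atomic):
                defs.setdefault(ax.lhs.name, ax.rhs)
        return defs


def expand_definitions(expr: ClassExpr, defs: Mapping[str, ClassExpr]) -> ClassExpr:
    """Substitute defined atomic names by their definitions, recursively."""

    def go(e: ClassExpr, seen: frozenset[str]) -> ClassExpr:
        if isinstance(e, Atomic):
            if e.name in defs:
                if e.name in seen:
                    raise ValueError(f"cyclic definition of {e.name!r}")
                return go(defs[e.name], seen | {e.name})
            return e
        if isinstance(e, Not):
            return Not(go(e.arg, seen))
        if isinstance(e, And):
            return And(*(go(a, seen) for a in e.args))
        if isinstance(e, Or):
            return Or(*(go(a, seen) for a in e.args))
        if isinstance(e, Some):
            return Some(e.role, go(e.filler, seen))
        if isinstance(e, Only):
            return Only(e.role, go(e.filler, seen))
        if isinstance(e, Exactly):
            return Exactly(e.role, e.n, go(e.filler, seen))
        if isinstance(e, Min):
            return Min(e.role, e.n, go(e.filler, seen))
        if isinstance(e, Max):
            return Max(e.role, e.n, go(e.filler, seen))
        raise TypeError(f"not a class expression: {e!r}")

    return go(expr, frozenset())


# ---------------------------------------------------------------------------
# interval evaluator (bitmask semantics)
# ---------------------------------------------------------------------------
#
# Extensions are computed as entity bitmasks.  To prune the oracle's search
# while role interpretations are only partially fixed, every node is
# evaluated to a (lo, hi) pair: lo = entities certainly in the extension
# under every completion, hi = entities possibly in it.  With all roles
# fixed, lo == hi and the evaluation is exact.


class _Ctx:
    __slots__ = ("n", "U", "atom_masks", "role_bounds")

    def __init__(
        self,
        n: int,
        atom_masks: Mapping[str, int],
        role_bounds: Mapping[str, tuple[Sequence[int], Sequence[int]]],
    ):
        self.n = n
        self.U = (1 << n) - 1
        self.atom_masks = atom_masks
        self.role_bounds = role_bounds


def _ieval(expr: ClassExpr, ctx: _Ctx) -> tuple[int, int]:
    U = ctx.U
    if isinstance(expr, Atomic):
        try:
            m = ctx.atom_masks[expr.name]
        except KeyError:
            raise UndeclaredSymbolError(f"class {expr.name!r} not declared") from None
        return m, m
    if isinstance(expr, Not):
        lo, hi = _ieval(expr.arg, ctx)
        return ~hi & U, ~lo & U
    if isinstance(expr, And):
        lo, hi = U, U
        for a in expr.args:
            alo, ahi = _ieval(a, ctx)
            lo &= alo
            hi &= ahi
        return lo, hi
    if isinstance(expr, Or):
        lo, hi = 0, 0
        for a in expr.args:
            alo, ahi = _ieval(a, ctx)
            lo |= alo
            hi |= ahi
        return lo, hi
    if isinstance(expr, _RESTRICTIONS):
        try:
            succ_lo, succ_hi = ctx.role_bounds[expr.role]
        except KeyError:
            raise UndeclaredSymbolError(f"role {expr.role!r} not declared") from None
        flo, fhi = _ieval(expr.filler, ctx)
        lo = hi = 0
        for i in range(ctx.n):
            bit = 1 << i
            if isinstance(expr, Some):
                if succ_lo[i] & flo:
                    lo |= bit
                if succ_hi[i] & fhi:
                    hi |= bit
            elif isinstance(expr, Only):
                if not (succ_hi[i] & ~flo & U):
                    lo |= bit
                if not (succ_lo[i] & ~fhi & U):
                    hi |= bit
            else:
                cmin = (succ_lo[i] & flo).bit_count()
                cmax = (succ_hi[i] & fhi).bit_count()
                if isinstance(expr, Exactly):
                    if cmin == expr.n == cmax:
                        lo |= bit
                    if cmin <= expr.n <= cmax:
                        hi |= bit
                elif isinstance(expr, Min):
                    if cmin >= expr.n:
                        lo |= bit
                    if cmax >= expr.n:
                        hi |= bit
                else:  # Max
                    if cmax <= expr.n:
                        lo |= bit
                    if cmin <= expr.n:
                        hi |= bit
        return lo, hi
    raise TypeError(f"not a class expression: {expr!r}")


def _eeval(expr: ClassExpr, ctx: _Ctx) -> int:
    lo, hi = _ieval(expr, ctx)
    assert lo == hi, "exact evaluation requires fully fixed roles"
    return lo


# ---------------------------------------------------------------------------
# extension over a FiniteModel
# ---------------------------------------------------------------------------


def _model_ctx(
    model: FiniteModel,
    registry: Optional[TypeRegistry],
    tbox: Optional[TBox],
) -> tuple[_Ctx, list[str]]:
    order = sorted(model.entities)
    idx = {e: i for i, e in enumerate(order)}
    n = len(order)

    hpp = [0] * n
    grain = [0] * n
    for e in order:
        i = idx[e]
        for p in proper_parts(model, e):
            hpp[i] |= 1 << idx[p]
        for g in grains_of(model, e):
            grain[i] |= 1 << idx[g]

    def invert(succ: list[int]) -> list[int]:
        pred = [0] * n
        for i in range(n):
            m = succ[i]
            while m:
                j = (m & -m).bit_length() - 1
                pred[j] |= 1 << i
                m &= m - 1
        return pred

    role_bounds: dict[str, tuple[list[int], list[int]]] = {}
    for name, succ in [
        (HAS_PROPER_PART, hpp),
        (PROPER_PART_OF, invert(hpp)),
        (HAS_GRAIN, grain),
        ("grain_of", invert(grain)),
        (HAS_COMPONENT, hpp),  # unrelativized componenthood = proper parthood
        ("component_of", invert(hpp)),
    ]:
        role_bounds[name] = (succ, succ)

    atom_masks: dict[str, int] = {}
    names = {t.name for ts in model.instance_of.values() for t in ts}
    if registry is not None:
        names |= {t.name for t in registry.types}
    for name in names:
        m = 0
        if registry is not None:
            try:
                t = registry.by_name(name)
            except UnknownTypeError:
                t = None
            for e in order:
                if t is not None and model.instantiates(e, t, registry):
                    m |= 1 << idx[e]
        else:
            for e in order:
                if any(t.name == name for t in model.types_of(e)):
                    m |= 1 << idx[e]
        atom_masks[name] = m

    class _Masks(dict):
        """Unknown atomics are an error only when a registry is supplied."""

        def __missing__(self, key: str) -> int:
            if registry is not None:
                raise KeyError(key)
            return 0

    return _Ctx(n, _Masks(atom_masks), role_bounds), order


def extension(
    expr: ClassExpr,
    model: FiniteModel,
    tbox: Optional[TBox] = None,
    registry: Optional[TypeRegistry] = None,
) -> set[str]:
    """The set of entities of ``model`` satisfying ``expr``.

    ``has_proper_part`` is the transitive closure of direct parthood,
    ``has_grain`` relates an entity to its candidate grains, and
    unrelativized ``has_component`` coincides with proper parthood.  ``only``
    over an entity with no role successors is vacuously satisfied.  When a
    ``tbox`` carries a definition (an equivalence with an atomic left-hand
    side) for a name appearing in ``expr``, the definition is expanded
    before evaluation; a ``registry`` makes atomic classes respect the is_a
    hierarchy and makes undeclared names an error.
    """
    if tbox is not None:
        expr = expand_definitions(expr, tbox.definitions())
    ctx, order = _model_ctx(model, registry, tbox)
    try:
        mask = _eeval(expr, ctx)
    except KeyError as exc:
        raise UndeclaredSymbolError(f"class {exc.args[0]!r} not declared") from None
    return {order[i] for i in range(len(order)) if mask >> i & 1}


# ---------------------------------------------------------------------------
# DL safety
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    role: str
    node: ClassExpr
    reason: str


def non_simple_roles(roles: Mapping[str, RoleSpec]) -> set[str]:
    """Roles that are transitive or have a transitive subrole (directly or
    through inverses), mirroring the OWL 2 global restrictions."""
    bad = {name for name, r in roles.items() if r.transitive}
    changed = True
    while changed:
        changed = False
        for name, r in roles.items():
            # non-simplicity propagates upward along the subrole hierarchy
            if name in bad and r.subrole_of is not None and r.subrole_of not in bad:
                bad.add(r.subrole_of)
                changed = True
            # and across inverses, in both directions
            if r.inverse_of is not None:
                if name in bad and r.inverse_of not in bad:
                    bad.add(r.inverse_of)
                    changed = True
                if r.inverse_of in bad and name not in bad:
                    bad.add(name)
                    changed = True
    return bad


def is_dl_safe(expr: ClassExpr, tbox: TBox) -> list[Violation]:
    """Flag every qualified cardinality restriction over a non-simple role.

    An empty list means the expression is admissible in OWL DL; reasoners
    reject number restrictions on transitive (or transitively-closed)
    roles to preserve decidability.
    """
    bad = non_simple_roles(tbox.roles)
    out = []
    for node in walk(expr):
        if isinstance(node, _CARD_NODES) and node.role in bad:
            out.append(
                Violation(
                    node.role,
                    node,
                    f"cardinality restriction on non-simple role {node.role!r}",
                )
            )
    return out


# ---------------------------------------------------------------------------
# surface syntax
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\s*(?:(\()|(\))|(\d+)|([A-Za-z_][A-Za-z0-9_'\-]*))")
_KEYWORDS = {"and", "or", "not", "some", "only", "exactly", "min", "max"}


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    toks = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip():
                raise ExprSyntaxError(f"unexpected character {text[pos]!r}", pos)
            break
        pos = m.end()
        if m.group(1):
            toks.append(("(", "(", m.start(1)))
        elif m.group(2):
            toks.append((")", ")", m.start(2)))
        elif m.group(3):
            toks.append(("num", m.group(3), m.start(3)))
        else:
            word = m.group(4)
            toks.append(("kw" if word in _KEYWORDS else "name", word, m.start(4)))
    return toks


def parse_expr(text: str) -> ClassExpr:
    """Parse a Manchester-style class expression.

    ``and`` binds tighter than ``or``; ``not`` and restrictions
    (``role some C``, ``role only C``, ``role exactly n C``, ``min``,
    ``max``) bind tightest.  Example::

        has_grain some H-Atom and has_grain only H-Atom
    """
    toks = _tokenize(text)
    pos = 0

    def peek() -> Optional[tuple[str, str, int]]:
        return toks[pos] if pos < len(toks) else None

    def take() -> tuple[str, str, int]:
        nonlocal pos
        if pos >= len(toks):
            raise ExprSyntaxError("unexpected end of expression", len(text))
        t = toks[pos]
        pos += 1
        return t

    def parse_or() -> ClassExpr:
        args = [parse_and()]
        while peek() and peek()[:2] == ("kw", "or"):
            take()
            args.append(parse_and())
        return args[0] if len(args) == 1 else Or(*args)

    def parse_and() -> ClassExpr:
        args = [parse_unary()]
        while peek() and peek()[:2] == ("kw", "and"):
            take()
            args.append(parse_unary())
        return args[0] if len(args) == 1 else And(*args)

    def parse_unary() -> ClassExpr:
        nxt = peek()
        if nxt is None:
            raise ExprSyntaxError("unexpected end of expression", len(text))
        if nxt[:2] == ("kw", "not"):
            take()
            return Not(parse_unary())
        if nxt[0] == "(":
            take()
            inner = parse_or()
            closing = take()
            if closing[0] != ")":
                raise ExprSyntaxError("expected ')'", closing[2])
            return inner
        if nxt[0] == "name":
            kind, word, at = take()
            follow = peek()
            if follow and follow[0] == "kw" and follow[1] in (
                "some",
                "only",
                "exactly",
                "min",
                "max",
            ):
                _, op, op_at = take()
                if op in ("some", "only"):
                    filler = parse_unary()
                    return (Some if op == "some" else Only)(word, filler)
                num = take()
                if num[0] != "num":
                    raise ExprSyntaxError(f"{op} expects a number", num[2])
                n = int(num[1])
                filler = parse_unary()
                try:
                    return {"exactly": Exactly, "min": Min, "max": Max}[op](word, n, filler)
                except ValueError as exc:
                    raise ExprSyntaxError(str(exc), op_at) from None
            return Atomic(word)
        raise ExprSyntaxError(f"unexpected token {nxt[1]!r}", nxt[2])

    out = parse_or()
    if pos != len(toks):
        raise ExprSyntaxError(f"trailing input {toks[pos][1]!r}", toks[pos][2])
    return out


def _render_filler(e: ClassExpr) -> str:
    if isinstance(e, Atomic):
        return e.name
    return f"({render_expr(e)})"


def render_expr(expr: ClassExpr) -> str:
    """Render to the surface syntax; ``parse_expr(render_expr(e)) == e``."""
    if isinstance(expr, Atomic):
        return expr.name
    if isinstance(expr, Not):
        return f"not {_render_filler(expr.arg)}"
    if isinstance(expr, And):
        return " and ".join(
            f"({render_expr(a)})" if isinstance(a, (And, Or)) else render_expr(a)
            for a in expr.args
        )
    if isinstance(expr, Or):
        return " or ".join(
            f"({render_expr(a)})" if isinstance(a, (And, Or)) else render_expr(a)
            for a in expr.args
        )
    if isinstance(expr, Some):
        return f"{expr.role} some {_render_filler(expr.filler)}"
    if isinstance(expr, Only):
        return f"{expr.role} only {_render_filler(expr.filler)}"
    if isinstance(expr, Exactly):
        return f"{expr.role} exactly {expr.n} {_render_filler(expr.filler)}"
    if isinstance(expr, Min):
        return f"{expr.role} min {expr.n} {_render_filler(expr.filler)}"
    if isinstance(expr, Max):
        return f"{expr.role} max {expr.n} {_render_filler(expr.filler)}"
    raise TypeError(f"not a class expression: {expr!r}")


# ---------------------------------------------------------------------------
# bounded subsumption oracle
# ---------------------------------------------------------------------------


@dataclass
class Verdict:
    """Result of a bounded subsumption check.

    ``holds`` is definitive when False (``countermodel`` witnesses
    ext(C) ⊄ ext(D)); when True it means no countermodel exists with at most
    ``max_size_checked`` entities.  ``role_edges`` records the primitive
    subrole interpretation of the countermodel, ``witness`` the entity in
    ext(C) \\ ext(D).
    """

    holds: bool
    countermodel: Optional[FiniteModel] = None
    max_size_checked: int = 0
    models_checked: int = 0
    witness: Optional[str] = None
    role_edges: Optional[dict[str, set[tuple[str, str]]]] = None
    complete: bool = True

    def to_dict(self) -> dict:
        out = {
            "holds": self.holds,
            "max_size_checked": self.max_size_checked,
            "models_checked": self.models_checked,
            "complete": self.complete,
        }
        if self.countermodel is not None:
            cm = self.countermodel
            out["countermodel"] = {
                "entities": {
                    e: sorted(t.name for t in cm.instance_of.get(e, ()))
                    for e in sorted(cm.entities)
                },
                "parts": sorted(cm.direct_part),
                "witness": self.witness,
                "role_edges": {
                    r: sorted(pairs) for r, pairs in (self.role_edges or {}).items()
                },
            }
        return out


def _closed_label_sets(
    vocab: Sequence[str],
    implications: Sequence[tuple[str, str]],
    exclusions: Sequence[frozenset[str]],
) -> list[frozenset[str]]:
    out = []
    for r in range(len(vocab) + 1):
        for combo in itertools.combinations(vocab, r):
            s = frozenset(combo)
            # keep only label sets closed under atomic subclass implications
            # and free of disjoint pairs; every admissible labelling of an
            # entity is exactly one of these
            if any(a in s and b not in s for a, b in implications):
                continue
            if any(pair <= s for pair in exclusions):
                continue
            out.append(s)
    # order: small label sets first — minimal countermodels tend to be sparse
    out.sort(key=lambda s: (len(s), sorted(s)))
    return out


def _graphs(n: int) -> list[tuple[int, list[int], list[int]]]:
    """All direct-parthood DAGs on n topologically ordered entities.

    Edges only go from lower to higher index; every acyclic model is
    isomorphic to one of these (the oracle's isomorphism-lite pruning).
    Returns (edge_bitmap, hpp successor masks, ppo predecessor masks),
    sorted by edge count so sparse models are visited first.
    """
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    out = []
    for bits in range(1 << len(pairs)):
        direct = [0] * n
        for k, (i, j) in enumerate(pairs):
            if bits >> k & 1:
                direct[i] |= 1 << j
        hpp = [0] * n
        for i in range(n - 1, -1, -1):
            m = direct[i]
            acc = m
            while m:
                j = (m & -m).bit_length() - 1
                acc |= hpp[j]
                m &= m - 1
            hpp[i] = acc
        pred = [0] * n
        for i in range(n):
            m = hpp[i]
            while m:
                j = (m & -m).bit_length() - 1
                pred[j] |= 1 << i
                m &= m - 1
        out.append((bits, hpp, pred, direct))
    out.sort(key=lambda t: bin(t[0]).count("1"))
    return [(b, h, p) for b, h, p, _ in out], pairs


def _axioms_feasible(model_axioms, ctx: _Ctx) -> bool:
    for kind, l, r in model_axioms:
        llo, lhi = _ieval(l, ctx)
        rlo, rhi = _ieval(r, ctx)
        if kind == "subclass" and llo & ~rhi & ctx.U:
            return False
        if kind == "equivalent" and ((llo & ~rhi & ctx.U) or (rlo & ~lhi & ctx.U)):
            return False
        if kind == "disjoint" and llo & rlo:
            return False
    return True


def _axioms_hold(model_axioms, ctx: _Ctx) -> bool:
    for kind, l, r in model_axioms:
        le = _eeval(l, ctx)
        re_ = _eeval(r, ctx)
        if kind == "subclass" and le & ~re_ & ctx.U:
            return False
        if kind == "equivalent" and le != re_:
            return False
        if kind == "disjoint" and le & re_:
            return False
    return True


def bounded_subsumption(
    tbox: TBox,
    c: ClassExpr,
    d: ClassExpr,
    max_size: int = 5,
    vocab: Optional[Iterable[Union[str, TypeName]]] = None,
    max_models: int = 50_000_000,
) -> Verdict:
    """Decide ``c ⊑ d`` over all acyclic finite models with at most
    ``max_size`` entities labelled from ``vocab``.

    Models must satisfy the tbox: atomic subclass axioms constrain the
    admissible label sets, atomic disjointness excludes co-labelling, and
    any remaining axiom is checked model by model.  Defined names
    (equivalences with an atomic left side) are macro-expanded.  Roles other
    than proper parthood and its inverse are interpreted as arbitrary
    subrelations of proper parthood — the primitive-subrole regime of an
    OWL reasoner — and searched by per-entity backtracking with interval
    pruning.

    Returns the first countermodel found, else ``holds=True``.  Raises
    :class:`ResourceCapError` (carrying the partial verdict) if more than
    ``max_models`` candidate models are examined.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    if c == d:
        return Verdict(holds=True, max_size_checked=max_size, models_checked=0)

    defs = tbox.definitions()
    c_x = expand_definitions(c, defs)
    d_x = expand_definitions(d, defs)

    # sort axioms into label-level constraints and per-model checks
    implications: list[tuple[str, str]] = []
    exclusions: list[frozenset[str]] = []
    model_axioms: list[tuple[str, ClassExpr, ClassExpr]] = []
    seen_def: set[str] = set()
    for ax in tbox.axioms:
        if ax.kind == "equivalent" and isinstance(ax.lhs, Atomic):
            if ax.lhs.name not in seen_def:
                seen_def.add(ax.lhs.name)  # the macro definition itself
                continue
        l = expand_definitions(ax.lhs, defs)
        r = expand_definitions(ax.rhs, defs)
        if ax.kind == "subclass" and isinstance(l, Atomic) and isinstance(r, Atomic):
            implications.append((l.name, r.name))
        elif ax.kind == "disjoint" and isinstance(l, Atomic) and isinstance(r, Atomic):
            exclusions.append(frozenset((l.name, r.name)))
        else:
            model_axioms.append((ax.kind, l, r))

    all_exprs = [c_x, d_x] + [e for _, l, r in model_axioms for e in (l, r)]
    if vocab is None:
        names = set().union(*(atoms_in(e) for e in all_exprs)) if all_exprs else set()
        names |= {a for a, b in implications} | {b for a, b in implications}
        names |= {n for pair in exclusions for n in pair}
        vocab_names = sorted(names - set(defs))
    else:
        vocab_names = sorted(v.name if isinstance(v, TypeName) else v for v in vocab)
    for e in all_exprs:
        undeclared = atoms_in(e) - set(vocab_names)
        if undeclared:
            raise UndeclaredSymbolError(
                f"classes {sorted(undeclared)} neither in vocab nor defined"
            )

    fixed_roles = {HAS_PROPER_PART, PROPER_PART_OF}
    free_roles = sorted(set().union(*(roles_in(e) for e in all_exprs)) - fixed_roles)
    for r in free_roles:
        spec = tbox.roles.get(r)
        if spec is None:
            raise UndeclaredSymbolError(f"role {r!r} not declared")
        if spec.subrole_of != HAS_PROPER_PART:
            raise UndeclaredSymbolError(
                f"role {r!r} must be a declared subrole of has_proper_part"
            )

    label_sets = _closed_label_sets(vocab_names, implications, exclusions)
    models_checked = 0

    for n in range(1, max_size + 1):
        U = (1 << n) - 1
        allpairs = [U & ~(1 << i) for i in range(n)]
        zeros = [0] * n
        graphs, pairs = _graphs(n)

        for labeling in itertools.product(label_sets, repeat=n):
            atom_masks = {name: 0 for name in vocab_names}
            for i, labels in enumerate(labeling):
                for name in labels:
                    atom_masks[name] |= 1 << i
            # labeling-level filter: could any parthood/role structure make
            # some entity a countermodel witness?
            loose = {HAS_PROPER_PART: (zeros, allpairs), PROPER_PART_OF: (zeros, allpairs)}
            for r in free_roles:
                loose[r] = (zeros, allpairs)
            ctx0 = _Ctx(n, atom_masks, loose)
            clo, chi = _ieval(c_x, ctx0)
            dlo, dhi = _ieval(d_x, ctx0)
            if not (chi & ~dlo & U):
                continue

            for bits, hpp, pred in graphs:
                bounds: dict[str, tuple[Sequence[int], Sequence[int]]] = {
                    HAS_PROPER_PART: (hpp, hpp),
                    PROPER_PART_OF: (pred, pred),
                }
                for r in free_roles:
                    bounds[r] = (zeros, hpp)
                ctx = _Ctx(n, atom_masks, bounds)
                clo, chi = _ieval(c_x, ctx)
                dlo, dhi = _ieval(d_x, ctx)
                if not (chi & ~dlo & U):
                    if not free_roles:
                        models_checked += 1
                    continue
                if not _axioms_feasible(model_axioms, ctx):
                    continue

                if not free_roles:
                    models_checked += 1
                    if models_checked > max_models:
                        raise ResourceCapError(
                            Verdict(True, None, n, models_checked, complete=False)
                        )
                    if not _axioms_hold(model_axioms, ctx):
                        continue
                    bad = _eeval(c_x, ctx) & ~_eeval(d_x, ctx) & U
                    if bad:
                        return _countermodel_verdict(
                            n, labeling, hpp, pairs, bits, {}, bad, max_size, models_checked
                        )
                    continue

                # backtracking search over per-entity successor sets of the
                # free primitive subroles, with interval pruning
                variables = [(r, i) for r in free_roles for i in range(n) if hpp[i]]
                assignment: dict[str, list[int]] = {r: [0] * n for r in free_roles}

                found = _search_roles(
                    variables,
                    0,
                    assignment,
                    free_roles,
                    hpp,
                    pred,
                    n,
                    atom_masks,
                    c_x,
                    d_x,
                    model_axioms,
                )
                models_checked += found[1]
                if models_checked > max_models:
                    raise ResourceCapError(
                        Verdict(True, None, n, models_checked, complete=False)
                    )
                if found[0] is not None:
                    bad, role_succ = found[0]
                    return _countermodel_verdict(
                        n, labeling, hpp, pairs, bits, role_succ, bad, max_size, models_checked
                    )

    return Verdict(holds=True, max_size_checked=max_size, models_checked=models_checked)


def _search_roles(
    variables,
    k,
    assignment,
    free_roles,
    hpp,
    pred,
    n,
    atom_masks,
    c_x,
    d_x,
    model_axioms,
):
    """Backtrack over successor sets; returns ((bad_mask, role_succ) | None,
    leaves_examined)."""
    U = (1 << n) - 1
    leaves = 0

    def bounds_for(upto: int):
        b = {HAS_PROPER_PART: (hpp, hpp), PROPER_PART_OF: (pred, pred)}
        for r in free_roles:
            lo = list(assignment[r])
            hi = list(assignment[r])
            for r2, i2 in variables[upto:]:
                if r2 == r:
                    hi[i2] = hpp[i2]
            b[r] = (lo, hi)
        return b

    def rec(k: int):
        nonlocal leaves
        ctx = _Ctx(n, atom_masks, bounds_for(k))
        clo, chi = _ieval(c_x, ctx)
        dlo, dhi = _ieval(d_x, ctx)
        if not (chi & ~dlo & U):
            return None
        if not _axioms_feasible(model_axioms, ctx):
            return None
        if k == len(variables):
            leaves += 1
            if not _axioms_hold(model_axioms, ctx):
                return None
            bad = _eeval(c_x, ctx) & ~_eeval(d_x, ctx) & U
            if bad:
                return bad, {r: list(assignment[r]) for r in free_roles}
            return None
        role, i = variables[k]
        succ = hpp[i]
        # enumerate subsets of succ, empty set first
        sub = 0
        while True:
            assignment[role][i] = sub
            hit = rec(k + 1)
            if hit is not None:
                return hit
            if sub == succ:
                break
            sub = (sub - succ) & succ  # next subset of succ
        assignment[role][i] = 0
        return None

    return rec(0), max(leaves, 1)


def _countermodel_verdict(
    n, labeling, hpp, pairs, bits, role_succ, bad, max_size, models_checked
) -> Verdict:
    names = [f"e{i}" for i in range(n)]
    types = {names[i]: [TypeName(t) for t in sorted(labeling[i])] for i in range(n)}
    direct = []
    for k, (i, j) in enumerate(pairs):
        if bits >> k & 1:
            direct.append((names[i], names[j]))
    designation = None
    if HAS_GRAIN in role_succ:
        direct_map: dict[str, set[str]] = {}
        for w, p in direct:
            direct_map.setdefault(w, set()).add(p)
        designation = {}
        for i in range(n):
            chosen = {names[j] for j in range(n) if role_succ[HAS_GRAIN][i] >> j & 1}
            designation[names[i]] = chosen & direct_map.get(names[i], set())
    cm = build_model(types, direct, designation)
    witness_i = (bad & -bad).bit_length() - 1
    role_edges = {
        r: {
            (names[i], names[j])
            for i in range(n)
            for j in range(n)
            if succ[i] >> j & 1
        }
        for r, succ in role_succ.items()
    }
    return Verdict(
        holds=False,
        countermodel=cm,
        max_size_checked=max_size,
        models_checked=models_checked,
        witness=names[witness_i],
        role_edges=role_edges or None,
    )


# ---------------------------------------------------------------------------
# optional external reasoner cross-check
# ---------------------------------------------------------------------------


def check_with_external_reasoner(ontology) -> set[tuple[str, str]]:
    """Run an external OWL reasoner (owlready2 + HermiT) over an
    :class:`mereokit.patterns.Ontology` and return the inferred subclass
    pairs (subclass_name, superclass_name).

    Raises :class:`ExternalReasonerUnavailable` when owlready2 (or its Java
    runtime) is not installed; callers and tests treat that as a skip, never
    a failure.  Refuses ontologies that are not DL-safe.
    """
    try:
        import owlready2  # type: ignore
    except Exception as exc:  # pragma: no cover - optional dependency
        raise ExternalReasonerUnavailable("owlready2 is not installed") from exc

    from .patterns import ontology_violations

    viol = ontology_violations(ontology)
    if viol:
        raise ValueError(f"ontology is outside OWL DL: {viol[0].reason}")

    # pragma: no cover - exercised only when the optional stack is present
    world = owlready2.World()
    onto = world.get_ontology(f"http://mereokit.example/{ontology.name}#")

    def conv(expr, classes, props):
        if isinstance(expr, Atomic):
            return classes[expr.name]
        if isinstance(expr, Not):
            return owlready2.Not(conv(expr.arg, classes, props))
        if isinstance(expr, And):
            return owlready2.And([conv(a, classes, props) for a in expr.args])
        if isinstance(expr, Or):
            return owlready2.Or([conv(a, classes, props) for a in expr.args])
        if isinstance(expr, Some):
            return props[expr.role].some(conv(expr.filler, classes, props))
        if isinstance(expr, Only):
            return props[expr.role].only(conv(expr.filler, classes, props))
        if isinstance(expr, Exactly):
            return props[expr.role].exactly(expr.n, conv(expr.filler, classes, props))
        if isinstance(expr, Min):
            return props[expr.role].min(expr.n, conv(expr.filler, classes, props))
        if isinstance(expr, Max):
            return props[expr.role].max(expr.n, conv(expr.filler, classes, props))
        raise TypeError(repr(expr))

    with onto:
        props = {}
        for name, spec in ontology.tbox.roles.items():
            prop = type(name, (owlready2.ObjectProperty,), {})
            props[name] = prop
        for name, spec in ontology.tbox.roles.items():
            if spec.transitive:
                props[name].is_a.append(owlready2.TransitiveProperty)
            if spec.subrole_of:
                props[name].is_a.append(props[spec.subrole_of])
            if spec.inverse_of:
                props[name].inverse_property = props[spec.inverse_of]
        classes = {
            t.name if isinstance(t, TypeName) else t: None for t in ontology.classes
        }
        for cname in classes:
            classes[cname] = type(cname, (owlready2.Thing,), {})
        for ax in ontology.tbox.axioms:
            if ax.kind == "subclass" and isinstance(ax.lhs, Atomic):
                classes[ax.lhs.name].is_a.append(conv(ax.rhs, classes, props))
            elif ax.kind == "equivalent" and isinstance(ax.lhs, Atomic):
                classes[ax.lhs.name].equivalent_to.append(conv(ax.rhs, classes, props))
            elif ax.kind == "disjoint":
                owlready2.AllDisjoint(
                    [conv(ax.lhs, classes, props), conv(ax.rhs, classes, props)]
                )
    try:
        with world:
            owlready2.sync_reasoner(world, infer_property_values=False)
    except Exception as exc:
        raise ExternalReasonerUnavailable(f"reasoner failed to run: {exc}") from exc

    inferred = set()
    for cname, cls in classes.items():
        for anc in cls.ancestors():
            if anc is not cls and anc.name in classes:
                inferred.add((cname, anc.name))
    return inferred
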