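"""Ontology design patterns for collectives, compounds and mixtures.

Each pattern compiles a small parameter specification into named-class
axioms: the collective pattern (``X_COLL`` as the things with some and only
``X`` grains), the strict-collective pattern (``X_PAIR`` and general
n-collectives via qualified cardinality), molecule composition patterns in
three styles (nested collective components, flat typed components, plain
proper parthood — the last deliberately outside OWL DL), flexible compounds,
and three mixture representations plus a reasoner-friendly rewrite that
avoids the primitive subroles altogether so that a standard reasoner can
classify mixtures as collectives.

Every generated axiom carries a provenance annotation naming the pattern
that produced it.  :func:`build_propanol_ontology` regenerates the
propanol-mixture example ontology (two disjoint isomers, three mixture
representation variants, and the rewrite under which all three are entailed
subclasses of ``Propanol_COLL``).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from .model import TypeName
from .dl import (
    And,
    Atomic,
    Axiom,
    ClassExpr,
    DisjointWith,
    EquivalentTo,
    Exactly,
    HAS_COMPONENT,
    HAS_GRAIN,
    HAS_PROPER_PART,
    Min,
    Max,
    Not,
    Only,
    Or,
    PROPER_PART_OF,
    RoleSpec,
    Some,
    SubClassOf,
    TBox,
    Violation,
    atoms_in,
    default_roles,
    is_dl_safe,
    render_expr,
    roles_in,
)

__all__ = [
    "Ontology",
    "FractionSpec",
    "DLSafetyError",
    "PatternError",
    "coll_pattern",
    "n_coll_pattern",
    "molecule_pattern",
    "flexible_compound_pattern",
    "mixture_pattern",
    "build_propanol_ontology",
    "build_pattern_catalog",
    "ontology_violations",
    "emit_owl",
    "parse_owl_functional",
]


class PatternError(ValueError):
    """Pattern parameters are unusable (e.g. a mixture of one fraction)."""


class DLSafetyError(ValueError):
    """Refusing to serialize an ontology that is outside OWL DL."""


def _name(t: Union[TypeName, str]) -> str:
    return t.name if isinstance(t, TypeName) else t


@dataclass
class Ontology:
    """Named classes plus a TBox, serializable to OWL 2.

    Axiom provenance (which pattern generated each axiom) travels on the
    axioms themselves and is emitted as an annotation.
    """

    name: str
    classes: set[str] = field(default_factory=set)
    tbox: TBox = field(default_factory=TBox)

    def add_axioms(self, axioms: Iterable[Axiom]) -> "Ontology":
        for ax in axioms:
            self.tbox.add(ax)
            self.classes |= atoms_in(ax.lhs) | atoms_in(ax.rhs)
        return self

    @property
    def axioms(self) -> list[Axiom]:
        return self.tbox.axioms

    def fragment(self, roles: set[str]) -> TBox:
        """The sub-TBox using only the given role symbols.

        Dropping axioms is monotone for entailment checking: a subsumption
        that holds over the fragment's models holds a fortiori over the
        models of the full ontology.
        """
        keep = [
            ax
            for ax in self.tbox.axioms
            if (roles_in(ax.lhs) | roles_in(ax.rhs)) <= roles
        ]
        return TBox(roles=dict(self.tbox.roles), axioms=keep)


# ---------------------------------------------------------------------------
# patterns
# ---------------------------------------------------------------------------


def coll_pattern(
    base: Union[TypeName, str],
    coll_name: Optional[str] = None,
    provenance: str = "pattern:coll formula:12",
) -> list[Axiom]:
    """The collective class over a base type.

    ``Base_COLL equivalentTo (has_grain some Base) and (has_grain only
    Base)``: at least one grain, and nothing but ``Base`` grains.  The
    ``_COLL`` suffix is a naming convention; the axioms, not the name, carry
    the semantics.  Applying the pattern twice yields the same axiom (the
    TBox deduplicates).
    """
    b = _name(base)
    cname = coll_name or f"{b}_COLL"
    rhs = And(Some(HAS_GRAIN, Atomic(b)), Only(HAS_GRAIN, Atomic(b)))
    return [EquivalentTo(Atomic(cname), rhs, provenance)]


def n_coll_pattern(
    base: Union[TypeName, str],
    n: int,
    name: Optional[str] = None,
    coll_name: Optional[str] = None,
    provenance: str = "pattern:n_coll formula:7",
) -> list[Axiom]:
    """Strict collectives of fixed cardinality (pairs, trios, ...).

    ``X_PAIR equivalentTo X_COLL and (has_grain exactly n X) and
    (has_grain only X)``; n=1 is the singleton collective, which the theory
    admits.  Includes the base collective definition.
    """
    if n < 1:
        raise PatternError("n-collectives require n >= 1")
    b = _name(base)
    cname = coll_name or f"{b}_COLL"
    if name is None:
        name = f"{b}_PAIR" if n == 2 else f"{b}_{n}_COLL"
    axioms = coll_pattern(b, cname)
    rhs = And(
        Atomic(cname),
        Exactly(HAS_GRAIN, n, Atomic(b)),
        Only(HAS_GRAIN, Atomic(b)),
    )
    axioms.append(EquivalentTo(Atomic(name), rhs, provenance))
    return axioms


def molecule_pattern(
    name: Union[TypeName, str],
    composition: Mapping[Union[TypeName, str], int],
    variant: str,
    guard: Union[TypeName, str] = "Atom",
) -> list[Axiom]:
    """Molecule composition axioms in one of three styles.

    ``nested``: each multi-atom slot is one component that is a strict
    collective of its atoms (an H2O molecule has one O-Atom component and
    one component that is an H-Atom pair).  ``flat``: typed component
    counts directly (``has_component exactly 2 H-Atom``).  ``proper_part``:
    counts over bare proper parthood — *not* OWL DL admissible, since
    proper parthood is transitive and transitive roles cannot appear in
    number restrictions; emitted for demonstration, and
    :func:`emit_owl` refuses it without an override.

    Each variant closes the composition with an ``only`` conjunct over the
    listed atom types (``or not Atom`` in the proper-part variant, which
    must tolerate non-atomic parts reached transitively).
    """
    if variant not in ("nested", "flat", "proper_part"):
        raise PatternError(f"unknown molecule variant {variant!r}")
    comp = sorted(((_name(t), c) for t, c in composition.items()))
    if not comp or any(c < 1 for _, c in comp):
        raise PatternError("composition counts must be >= 1")
    mname = _name(name)
    axioms: list[Axiom] = []
    if variant == "flat":
        conjuncts: list[ClassExpr] = [
            Exactly(HAS_COMPONENT, c, Atomic(t)) for t, c in comp
        ]
        closure = [Atomic(t) for t, _ in comp]
        conjuncts.append(
            Only(HAS_COMPONENT, closure[0] if len(closure) == 1 else Or(*closure))
        )
        axioms.append(
            SubClassOf(Atomic(mname), And(*conjuncts), "pattern:molecule/flat formula:13")
        )
    elif variant == "nested":
        conjuncts = []
        closure = []
        for t, c in comp:
            if c == 1:
                conjuncts.append(Exactly(HAS_COMPONENT, 1, Atomic(t)))
                closure.append(Atomic(t))
            else:
                cname = f"{t}_COLL"
                axioms += coll_pattern(t, cname)
                conjuncts.append(
                    Exactly(
                        HAS_COMPONENT,
                        1,
                        And(Atomic(cname), Exactly(HAS_GRAIN, c, Atomic(t))),
                    )
                )
                # the closure admits both the collective component and the
                # atoms inside it, which componenthood reaches transitively
                closure.append(Atomic(cname))
                closure.append(Atomic(t))
        conjuncts.append(
            Only(HAS_COMPONENT, closure[0] if len(closure) == 1 else Or(*closure))
        )
        axioms.append(
            SubClassOf(
                Atomic(mname), And(*conjuncts), "pattern:molecule/nested formula:11"
            )
        )
    else:  # proper_part
        conjuncts = [Exactly(HAS_PROPER_PART, c, Atomic(t)) for t, c in comp]
        closure = [Atomic(t) for t, _ in comp] + [Not(Atomic(_name(guard)))]
        conjuncts.append(Only(HAS_PROPER_PART, Or(*closure)))
        axioms.append(
            SubClassOf(
                Atomic(mname),
                And(*conjuncts),
                "pattern:molecule/proper_part formula:16",
            )
        )
    return axioms


def flexible_compound_pattern(
    name: Union[TypeName, str],
    component_coll: Union[TypeName, str],
    provenance: str = "pattern:flexible_compound formula:9,10",
) -> list[Axiom]:
    """Flexible compounds are compounds of flexible collectives:
    ``Name subClassOf has_component some Component_COLL`` (a hand has some
    collective of fingers; an alcohol molecule has some collective of
    carbon atoms, of inessential size at this level of specificity)."""
    coll = _name(component_coll)
    is_coll = (
        isinstance(component_coll, TypeName) and component_coll.kind in ("coll", "n_coll")
    ) or coll.endswith(("_COLL", "_PAIR"))
    if not is_coll:
        warnings.warn(
            f"flexible_compound_pattern expects a collective class; got {coll!r}",
            stacklevel=2,
        )
    return [SubClassOf(Atomic(_name(name)), Some(HAS_COMPONENT, Atomic(coll)), provenance)]


@dataclass(frozen=True)
class FractionSpec:
    """Parameters for a mixture: the per-fraction grain types and collective
    class names, their most specific common supertype, and the granularity
    guard (the level, e.g. Molecule, at which the closure condition speaks).
    """

    fractions: tuple[tuple[str, str], ...]  # (grain type, collective class name)
    closure_type: str
    granularity_guard: str
    closure_coll_name: Optional[str] = None

    def __init__(
        self,
        fractions: Sequence[tuple[Union[TypeName, str], Union[TypeName, str]]],
        closure_type: Union[TypeName, str],
        granularity_guard: Union[TypeName, str],
        closure_coll_name: Optional[Union[TypeName, str]] = None,
    ):
        fr = tuple((_name(g), _name(c)) for g, c in fractions)
        if len(fr) < 2:
            raise PatternError("a mixture needs at least two fractions")
        grains = [g for g, _ in fr]
        if len(set(grains)) != len(grains):
            raise PatternError("fraction grain types must be pairwise distinct")
        object.__setattr__(self, "fractions", fr)
        object.__setattr__(self, "closure_type", _name(closure_type))
        object.__setattr__(self, "granularity_guard", _name(granularity_guard))
        object.__setattr__(
            self,
            "closure_coll_name",
            _name(closure_coll_name) if closure_coll_name else f"{_name(closure_type)}_COLL",
        )


MIXTURE_VARIANTS = (
    "grain_disjunction",
    "supertype",
    "fraction_compound",
    "reasoner_friendly",
)


def mixture_pattern(
    name: Union[TypeName, str],
    spec: FractionSpec,
    variant: str,
) -> list[Axiom]:
    """Axioms for one of the mixture representations.

    ``grain_disjunction`` drops grain uniformity (``has_grain some (A or
    B)``); ``supertype`` subsumes the grains under their common supertype
    (``has_grain some Super``); ``fraction_compound`` represents the mixture
    as a compound of fraction collectives, with the closure conjunct
    ``has_component only (Super_COLL or not Guard)``; ``reasoner_friendly``
    rewrites the fraction-compound view using proper parthood only — no
    ``has_grain``/``has_component`` symbol appears — plus the matching
    collective definition, so a DL classifier can compute that mixtures are
    collectives.
    """
    mname = _name(name)
    if variant not in MIXTURE_VARIANTS:
        raise PatternError(f"unknown mixture variant {variant!r}")
    grains = [g for g, _ in spec.fractions]
    if variant == "grain_disjunction":
        rhs: ClassExpr = Some(HAS_GRAIN, Or(*(Atomic(g) for g in grains)))
        return [SubClassOf(Atomic(mname), rhs, "pattern:mixture/grain_disjunction formula:17")]
    if variant == "supertype":
        rhs = Some(HAS_GRAIN, Atomic(spec.closure_type))
        return [SubClassOf(Atomic(mname), rhs, "pattern:mixture/supertype formula:18")]
    if variant == "fraction_compound":
        axioms = []
        for g, cname in spec.fractions:
            axioms += coll_pattern(g, cname, "pattern:coll formula:21,22")
        axioms += coll_pattern(
            spec.closure_type, spec.closure_coll_name, "pattern:coll formula:20"
        )
        conjuncts: list[ClassExpr] = [
            Some(HAS_COMPONENT, Atomic(cname)) for _, cname in spec.fractions
        ]
        conjuncts.append(
            Only(
                HAS_COMPONENT,
                Or(Atomic(spec.closure_coll_name), Not(Atomic(spec.granularity_guard))),
            )
        )
        axioms.append(
            EquivalentTo(
                Atomic(mname), And(*conjuncts), "pattern:mixture/fraction_compound formula:19,23"
            )
        )
        return axioms
    # reasoner_friendly: proper parthood only
    coll = spec.closure_coll_name
    coll_def = EquivalentTo(
        Atomic(coll),
        And(
            Some(HAS_PROPER_PART, Atomic(spec.closure_type)),
            Only(
                HAS_PROPER_PART,
                Or(Atomic(spec.closure_type), Not(Atomic(spec.granularity_guard))),
            ),
        ),
        "pattern:mixture/reasoner_friendly formula:25",
    )
    conjuncts = [Some(HAS_PROPER_PART, Atomic(g)) for g in grains]
    conjuncts.append(
        Only(
            HAS_PROPER_PART,
            Or(Atomic(coll), Some(PROPER_PART_OF, Atomic(coll))),
        )
    )
    mix_def = EquivalentTo(
        Atomic(mname), And(*conjuncts), "pattern:mixture/reasoner_friendly formula:24"
    )
    return [coll_def, mix_def]


# ---------------------------------------------------------------------------
# the propanol example ontology and the full pattern catalog
# ---------------------------------------------------------------------------

PROPANOL_CLASSES = {
    "molecule": "Molecule",
    "propanol": "Propanol_Molecule",
    "n_propanol": "N-Propanol_Molecule",
    "i_propanol": "I-Propanol_Molecule",
    "coll": "Propanol_COLL",
    "mixtures": ("Propanol_Mixture_1", "Propanol_Mixture_2", "Propanol_Mixture_3"),
}


def build_propanol_ontology(collective_molecule_disjoint: bool = True) -> Ontology:
    """Regenerate the propanol mixture ontology.

    Content: the molecule taxonomy (``Propanol_Molecule`` below ``Molecule``
    with the two disjoint isomers ``N-Propanol_Molecule`` and
    ``I-Propanol_Molecule``), the grain-based collective classes for
    propanol and each isomer, three mixture representation variants in the
    reasoner-friendly (proper-parthood-only) regime, and the
    reasoner-friendly collective definition.

    ``collective_molecule_disjoint`` adds a disjointness axiom between
    ``Propanol_COLL`` and ``Molecule``.  With it, the bounded oracle
    confirms that every mixture variant is subsumed by ``Propanol_COLL``;
    without it, the fraction-compound rewrite admits a countermodel in
    which a molecule that is not a propanol molecule satisfies the
    collective definition.  The disjointness is therefore shipped on by
    default.
    """
    C = PROPANOL_CLASSES
    onto = Ontology(name="propanol")
    onto.add_axioms(
        [
            SubClassOf(Atomic(C["propanol"]), Atomic(C["molecule"]), "pattern:taxonomy"),
            SubClassOf(Atomic(C["n_propanol"]), Atomic(C["propanol"]), "pattern:taxonomy"),
            SubClassOf(Atomic(C["i_propanol"]), Atomic(C["propanol"]), "pattern:taxonomy"),
            DisjointWith(Atomic(C["n_propanol"]), Atomic(C["i_propanol"]), "figure:1"),
        ]
    )
    # grain-based collective classes
    onto.add_axioms(coll_pattern(C["propanol"], C["coll"], "pattern:coll formula:20"))
    onto.add_axioms(
        coll_pattern(C["n_propanol"], "N-Propanol_COLL", "pattern:coll formula:21")
    )
    onto.add_axioms(
        coll_pattern(C["i_propanol"], "I-Propanol_COLL", "pattern:coll formula:22")
    )

    iso_or = Or(Atomic(C["n_propanol"]), Atomic(C["i_propanol"]))
    mol = Atomic(C["molecule"])
    prop = Atomic(C["propanol"])
    v1, v2, v3 = C["mixtures"]
    # three mixture variants, all in the proper-parthood-only regime
    onto.add_axioms(
        [
            EquivalentTo(
                Atomic(v1),
                And(
                    Some(HAS_PROPER_PART, iso_or),
                    Only(HAS_PROPER_PART, Or(iso_or, Not(mol))),
                ),
                "pattern:mixture/grain_disjunction(rf)",
            ),
            EquivalentTo(
                Atomic(v2),
                And(
                    Some(HAS_PROPER_PART, prop),
                    Only(HAS_PROPER_PART, Or(prop, Not(mol))),
                ),
                "pattern:mixture/supertype(rf)",
            ),
        ]
    )
    spec = FractionSpec(
        fractions=[
            (C["n_propanol"], "N-Propanol_COLL"),
            (C["i_propanol"], "I-Propanol_COLL"),
        ],
        closure_type=C["propanol"],
        granularity_guard=C["molecule"],
        closure_coll_name=C["coll"],
    )
    onto.add_axioms(mixture_pattern(v3, spec, "reasoner_friendly"))
    if collective_molecule_disjoint:
        onto.add_axioms(
            [
                DisjointWith(
                    Atomic(C["coll"]), mol, "aux:collective-molecule-disjointness"
                )
            ]
        )
    return onto


def build_pattern_catalog() -> Ontology:
    """One ontology exercising every shipped pattern: the worked molecule
    examples (water in all three styles, the H-atom pair), the flexible
    compounds (hand, alcohol), the blood-plasma mixture in all three
    grain/component representations, and the full propanol build.

    Contains the deliberately non-DL-safe proper-parthood water axioms, so
    serialization requires the unsafe override.
    """
    onto = Ontology(name="pattern_catalog")
    onto.add_axioms(n_coll_pattern("H-Atom", 2, name="H_PAIR"))
    water = {"O-Atom": 1, "H-Atom": 2}
    onto.add_axioms(molecule_pattern("Water_Molecule", water, "nested"))
    onto.add_axioms(molecule_pattern("Water_Molecule", water, "flat"))
    onto.add_axioms(molecule_pattern("Water_Molecule", water, "proper_part"))
    onto.add_axioms(
        molecule_pattern("Hydrogen_Peroxide_Molecule", {"O-Atom": 2, "H-Atom": 2}, "flat")
    )
    onto.add_axioms(coll_pattern("Finger"))
    onto.add_axioms(
        flexible_compound_pattern("Hand", "Finger_COLL", "pattern:flexible_compound formula:9")
    )
    onto.add_axioms(coll_pattern("C-Atom", "C_COLL"))
    onto.add_axioms(
        flexible_compound_pattern(
            "Alcohol_Molecule", "C_COLL", "pattern:flexible_compound formula:10"
        )
    )
    plasma = FractionSpec(
        fractions=[
            ("AlbuminMolecule", "Albumin_COLL"),
            ("GlobulinMolecule", "Globulin_COLL"),
        ],
        closure_type="PlasmaProteinMolecule",
        granularity_guard="Molecule",
    )
    for variant in ("grain_disjunction", "supertype", "fraction_compound"):
        onto.add_axioms(mixture_pattern("BloodPlasmaSample", plasma, variant))
    propanol_spec = FractionSpec(
        fractions=[
            ("N-Propanol_Molecule", "N-Propanol_COLL"),
            ("I-Propanol_Molecule", "I-Propanol_COLL"),
        ],
        closure_type="Propanol_Molecule",
        granularity_guard="Molecule",
        closure_coll_name="Propanol_COLL",
    )
    onto.add_axioms(mixture_pattern("Propanol_Mixture", propanol_spec, "fraction_compound"))
    for ax in build_propanol_ontology().axioms:
        onto.add_axioms([ax])
    return onto


# ---------------------------------------------------------------------------
# OWL serialization
# ---------------------------------------------------------------------------


def ontology_violations(ontology: Ontology) -> list[Violation]:
    """DL-safety violations anywhere in the ontology's axioms."""
    out: list[Violation] = []
    for ax in ontology.axioms:
        for side in (ax.lhs, ax.rhs):
            out.extend(is_dl_safe(side, ontology.tbox))
    return out


def _sorted_axioms(ontology: Ontology) -> list[Axiom]:
    return sorted(
        ontology.axioms,
        key=lambda ax: (ax.provenance, ax.kind, render_expr(ax.lhs), render_expr(ax.rhs)),
    )


def _func_expr(e: ClassExpr) -> str:
    if isinstance(e, Atomic):
        return f":{e.name}"
    if isinstance(e, Not):
        return f"ObjectComplementOf({_func_expr(e.arg)})"
    if isinstance(e, And):
        return f"ObjectIntersectionOf({' '.join(_func_expr(a) for a in e.args)})"
    if isinstance(e, Or):
        return f"ObjectUnionOf({' '.join(_func_expr(a) for a in e.args)})"
    if isinstance(e, Some):
        return f"ObjectSomeValuesFrom(:{e.role} {_func_expr(e.filler)})"
    if isinstance(e, Only):
        return f"ObjectAllValuesFrom(:{e.role} {_func_expr(e.filler)})"
    if isinstance(e, Exactly):
        return f"ObjectExactCardinality({e.n} :{e.role} {_func_expr(e.filler)})"
    if isinstance(e, Min):
        return f"ObjectMinCardinality({e.n} :{e.role} {_func_expr(e.filler)})"
    if isinstance(e, Max):
        return f"ObjectMaxCardinality({e.n} :{e.role} {_func_expr(e.filler)})"
    raise TypeError(repr(e))


_AXIOM_HEADS = {
    "subclass": "SubClassOf",
    "equivalent": "EquivalentClasses",
    "disjoint": "DisjointClasses",
}


def emit_owl(
    ontology: Ontology, dialect: str = "functional", allow_unsafe: bool = False
) -> str:
    """Serialize to OWL 2 text.

    ``functional`` is the canonical machine dialect (and the one
    :func:`parse_owl_functional` round-trips); ``manchester`` is the
    human-facing one.  Output ordering is deterministic: classes
    alphabetically, axioms by provenance tag.  Refuses an ontology with
    DL-safety violations unless ``allow_unsafe`` is set.
    """
    viol = ontology_violations(ontology)
    if viol and not allow_unsafe:
        raise DLSafetyError(
            f"{len(viol)} cardinality restriction(s) on non-simple roles "
            f"(first: {viol[0].reason}); pass allow_unsafe=True to emit anyway"
        )
    classes = sorted(ontology.classes)
    roles = sorted(ontology.tbox.roles.values(), key=lambda r: r.name)
    axioms = _sorted_axioms(ontology)
    if dialect == "functional":
        iri = f"http://mereokit.example/{ontology.name}"
        lines = [
            f"Prefix(:=<{iri}#>)",
            "Prefix(owl:=<http://www.w3.org/2002/07/owl#>)",
            "Prefix(rdfs:=<http://www.w3.org/2000/01/rdf-schema#>)",
            f"Ontology(<{iri}>",
        ]
        for r in roles:
            lines.append(f"Declaration(ObjectProperty(:{r.name}))")
        for r in roles:
            if r.transitive:
                lines.append(f"TransitiveObjectProperty(:{r.name})")
            if r.subrole_of:
                lines.append(f"SubObjectPropertyOf(:{r.name} :{r.subrole_of})")
            if r.inverse_of:
                lines.append(f"InverseObjectProperties(:{r.name} :{r.inverse_of})")
        for c in classes:
            lines.append(f"Declaration(Class(:{c}))")
        for ax in axioms:
            head = _AXIOM_HEADS[ax.kind]
            ann = (
                f'Annotation(rdfs:comment "{ax.provenance}") ' if ax.provenance else ""
            )
            lines.append(
                f"{head}({ann}{_func_expr(ax.lhs)} {_func_expr(ax.rhs)})"
            )
        lines.append(")")
        return "\n".join(lines) + "\n"
    if dialect == "manchester":
        iri = f"http://mereokit.example/{ontology.name}"
        lines = [f"Prefix: : <{iri}#>", f"Ontology: <{iri}>", ""]
        for r in roles:
            lines.append(f"ObjectProperty: {r.name}")
            if r.transitive:
                lines.append("    Characteristics: Transitive")
            if r.subrole_of:
                lines.append(f"    SubPropertyOf: {r.subrole_of}")
            if r.inverse_of:
                lines.append(f"    InverseOf: {r.inverse_of}")
            lines.append("")
        by_class: dict[str, list[Axiom]] = {c: [] for c in classes}
        loose: list[Axiom] = []
        for ax in axioms:
            if isinstance(ax.lhs, Atomic):
                by_class[ax.lhs.name].append(ax)
            else:
                loose.append(ax)
        heads = {"subclass": "SubClassOf", "equivalent": "EquivalentTo", "disjoint": "DisjointWith"}
        for c in classes:
            lines.append(f"Class: {c}")
            for ax in by_class[c]:
                if ax.provenance:
                    lines.append(f'    Annotations: rdfs:comment "{ax.provenance}"')
                lines.append(f"    {heads[ax.kind]}: {render_expr(ax.rhs)}")
            lines.append("")
        for ax in loose:
            lines.append(
                f"DisjointClasses: {render_expr(ax.lhs)}, {render_expr(ax.rhs)}"
            )
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown dialect {dialect!r}")


# -- functional-syntax parsing (for the round-trip guarantee) ---------------

_SEXP_TOKEN = re.compile(r'\s*(\(|\)|"[^"]*"|[^\s()"]+)')


def _sexp_tokens(text: str) -> list[str]:
    toks = []
    pos = 0
    while pos < len(text):
        m = _SEXP_TOKEN.match(text, pos)
        if not m:
            break
        toks.append(m.group(1))
        pos = m.end()
    return toks


def _parse_sexp(toks: list[str], pos: int):
    head = toks[pos]
    if pos + 1 < len(toks) and toks[pos + 1] == "(":
        pos += 2
        children = []
        while toks[pos] != ")":
            child, pos = _parse_sexp(toks, pos)
            children.append(child)
        return (head, children), pos + 1
    return head, pos + 1


def _expr_from_sexp(node) -> ClassExpr:
    if isinstance(node, str):
        if not node.startswith(":"):
            raise ValueError(f"expected a class name, got {node!r}")
        return Atomic(node[1:])
    head, kids = node
    if head == "ObjectComplementOf":
        return Not(_expr_from_sexp(kids[0]))
    if head == "ObjectIntersectionOf":
        return And(*(_expr_from_sexp(k) for k in kids))
    if head == "ObjectUnionOf":
        return Or(*(_expr_from_sexp(k) for k in kids))
    if head == "ObjectSomeValuesFrom":
        return Some(kids[0][1:], _expr_from_sexp(kids[1]))
    if head == "ObjectAllValuesFrom":
        return Only(kids[0][1:], _expr_from_sexp(kids[1]))
    if head in ("ObjectExactCardinality", "ObjectMinCardinality", "ObjectMaxCardinality"):
        n = int(kids[0])
        role = kids[1][1:]
        filler = _expr_from_sexp(kids[2])
        return {"ObjectExactCardinality": Exactly, "ObjectMinCardinality": Min,
                "ObjectMaxCardinality": Max}[head](role, n, filler)
    raise ValueError(f"unsupported class expression head {head!r}")


def parse_owl_functional(text: str) -> Ontology:
    """Parse the functional-syntax dialect produced by :func:`emit_owl`."""
    body_lines = [
        ln for ln in text.splitlines() if ln.strip() and not ln.startswith("Prefix(")
    ]
    toks = _sexp_tokens("\n".join(body_lines))
    if not toks or toks[0] != "Ontology":
        raise ValueError("not a functional-syntax ontology document")
    # Ontology( <iri> form* )
    assert toks[1] == "("
    iri = toks[2]
    name = iri.strip("<>").rsplit("/", 1)[-1]
    pos = 3
    forms = []
    while toks[pos] != ")":
        form, pos = _parse_sexp(toks, pos)
        forms.append(form)

    roles: dict[str, RoleSpec] = {}
    classes: set[str] = set()
    axioms: list[Axiom] = []

    def role(name_: str) -> RoleSpec:
        return roles.setdefault(name_, RoleSpec(name_))

    for form in forms:
        head, kids = form
        if head == "Declaration":
            dhead, dkids = kids[0]
            if dhead == "Class":
                classes.add(dkids[0][1:])
            elif dhead == "ObjectProperty":
                role(dkids[0][1:])
        elif head == "TransitiveObjectProperty":
            r = role(kids[0][1:])
            roles[r.name] = RoleSpec(r.name, True, r.subrole_of, r.inverse_of)
        elif head == "SubObjectPropertyOf":
            r = role(kids[0][1:])
            roles[r.name] = RoleSpec(r.name, r.transitive, kids[1][1:], r.inverse_of)
        elif head == "InverseObjectProperties":
            r = role(kids[0][1:])
            role(kids[1][1:])
            roles[r.name] = RoleSpec(r.name, r.transitive, r.subrole_of, kids[1][1:])
        elif head in ("SubClassOf", "EquivalentClasses", "DisjointClasses"):
            prov = ""
            if kids and isinstance(kids[0], tuple) and kids[0][0] == "Annotation":
                prov = kids[0][1][1].strip('"')
                kids = kids[1:]
            kind = {"SubClassOf": "subclass", "EquivalentClasses": "equivalent",
                    "DisjointClasses": "disjoint"}[head]
            axioms.append(
                Axiom(kind, _expr_from_sexp(kids[0]), _expr_from_sexp(kids[1]), prov)
            )
        else:
            raise ValueError(f"unsupported axiom head {head!r}")

    onto = Ontology(name=name, classes=classes, tbox=TBox(roles=roles, axioms=[]))
    onto.add_axioms(axioms)
    return onto
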