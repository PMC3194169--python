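"""DL layer: expression semantics, safety checking, the surface syntax,
and the bounded subsumption oracle."""

import pytest
from hypothesis import given, settings, strategies as st

from mereokit.dl import (
    And,
    Atomic,
    DisjointWith,
    Exactly,
    ExprSyntaxError,
    HAS_COMPONENT,
    HAS_GRAIN,
    HAS_PROPER_PART,
    Max,
    Min,
    Not,
    Only,
    Or,
    PROPER_PART_OF,
    Some,
    SubClassOf,
    TBox,
    UndeclaredSymbolError,
    bounded_subsumption,
    extension,
    is_dl_safe,
    non_simple_roles,
    parse_expr,
    render_expr,
)
from mereokit.fixtures import (
    chemistry_registry,
    make_molecule,
    random_model,
    standard_random_vocab,
)


class TestExtension:
    def test_flat_water_component_counts(self, water_flat):
        expr = And(
            Exactly(HAS_COMPONENT, 1, Atomic("O-Atom")),
            Exactly(HAS_COMPONENT, 2, Atomic("H-Atom")),
        )
        got = extension(expr, water_flat.model, registry=water_flat.registry)
        assert got == {"h2o_1"}

    def test_only_is_vacuous_without_successors(self, water_flat):
        expr = Only(HAS_GRAIN, Atomic("H-Atom"))
        got = extension(expr, water_flat.model, registry=water_flat.registry)
        # atoms have no grains, so the universal restriction holds for them
        assert {"h2o_1_h1", "h2o_1_h2", "h2o_1_o1"} <= got

    def test_atomic_respects_is_a(self):
        fx = make_molecule("N_propanol")
        got = extension(Atomic("Propanol_Molecule"), fx.model, registry=fx.registry)
        assert fx.root in got
        got = extension(Atomic("Alcohol_Molecule"), fx.model, registry=fx.registry)
        assert fx.root in got

    def test_undeclared_atomic_is_an_error_with_registry(self, water_flat):
        with pytest.raises(UndeclaredSymbolError):
            extension(Atomic("Nonsense"), water_flat.model, registry=water_flat.registry)

    @pytest.mark.parametrize("seed", range(8))
    def test_boolean_semantics_on_random_models(self, seed):
        _, vocab = standard_random_vocab()
        model = random_model(7, vocab, seed)
        a, b = Atomic("A"), Atomic("B")
        ea = extension(a, model)
        eb = extension(b, model)
        assert extension(And(a, b), model) == ea & eb
        assert extension(Or(a, b), model) == ea | eb
        assert extension(Not(a), model) == model.entities - ea

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("n", [1, 2])
    def test_exactly_is_min_and_max(self, seed, n):
        _, vocab = standard_random_vocab()
        model = random_model(7, vocab, seed + 100)
        ex = extension(Exactly(HAS_PROPER_PART, n, Atomic("A")), model)
        mi = extension(Min(HAS_PROPER_PART, n, Atomic("A")), model)
        ma = extension(Max(HAS_PROPER_PART, n, Atomic("A")), model)
        assert ex == mi & ma


class TestDlSafety:
    def test_proper_part_cardinality_flagged(self):
        # a count of atoms over transitive parthood is outside OWL DL
        assert len(is_dl_safe(parse_expr("has_proper_part exactly 3 Atom"), TBox())) == 1

    def test_component_cardinality_admissible(self):
        assert is_dl_safe(parse_expr("has_component exactly 3 Atom"), TBox()) == []

    def test_proper_part_water_definition_flagged_twice(self):
        expr = parse_expr(
            "has_proper_part exactly 1 O-Atom and has_proper_part exactly 2 H-Atom"
            " and has_proper_part only (H-Atom or O-Atom or not Atom)"
        )
        assert len(is_dl_safe(expr, TBox())) == 2

    def test_non_simple_set(self):
        bad = non_simple_roles(TBox().roles)
        assert bad == {HAS_PROPER_PART, PROPER_PART_OF}


def _expr_strategy():
    names = st.sampled_from(["A", "B", "H-Atom", "O-Atom", "X_COLL"])
    roles = st.sampled_from([HAS_GRAIN, HAS_COMPONENT, HAS_PROPER_PART])
    return st.recursive(
        names.map(Atomic),
        lambda inner: st.one_of(
            inner.map(Not),
            st.tuples(inner, inner).map(lambda t: And(*t)),
            st.tuples(inner, inner).map(lambda t: Or(*t)),
            st.tuples(roles, inner).map(lambda t: Some(*t)),
            st.tuples(roles, inner).map(lambda t: Only(*t)),
            st.tuples(roles, st.integers(1, 4), inner).map(lambda t: Exactly(*t)),
            st.tuples(roles, st.integers(1, 4), inner).map(lambda t: Min(*t)),
            st.tuples(roles, st.integers(0, 4), inner).map(lambda t: Max(*t)),
        ),
        max_leaves=12,
    )


class TestSurfaceSyntax:
    def test_grain_conjunction(self):
        got = parse_expr("has_grain some H-Atom and has_grain only H-Atom")
        assert got == And(Some(HAS_GRAIN, Atomic("H-Atom")), Only(HAS_GRAIN, Atomic("H-Atom")))

    def test_precedence_and_binds_tighter_than_or(self):
        got = parse_expr("A and B or C")
        assert got == Or(And(Atomic("A"), Atomic("B")), Atomic("C"))

    def test_exactly_zero_rejected(self):
        with pytest.raises(ExprSyntaxError):
            parse_expr("has_grain exactly 0 X")

    def test_max_zero_allowed(self):
        assert parse_expr("has_grain max 0 X") == Max(HAS_GRAIN, 0, Atomic("X"))

    def test_syntax_error_carries_position(self):
        with pytest.raises(ExprSyntaxError) as exc:
            parse_expr("A and ()")
        assert exc.value.pos >= 6

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(_expr_strategy())
    def test_render_parse_roundtrip(self, expr):
        assert parse_expr(render_expr(expr)) == expr


def _taxonomy_tbox() -> TBox:
    tbox = TBox()
    tbox.add(
        SubClassOf(Atomic("Propanol_Molecule"), Atomic("Molecule")),
        SubClassOf(Atomic("N-Propanol_Molecule"), Atomic("Propanol_Molecule")),
        SubClassOf(Atomic("I-Propanol_Molecule"), Atomic("Propanol_Molecule")),
        DisjointWith(Atomic("N-Propanol_Molecule"), Atomic("I-Propanol_Molecule")),
    )
    return tbox


class TestBoundedSubsumption:
    def test_reflexivity_short_circuits(self):
        e = parse_expr("has_grain some A")
        v = bounded_subsumption(TBox(), e, e, max_size=3, vocab=["A"])
        assert v.holds and v.models_checked == 0

    def test_atomic_non_subsumption_has_tiny_countermodel(self):
        v = bounded_subsumption(TBox(), Atomic("A"), Atomic("B"), max_size=2)
        assert not v.holds
        assert len(v.countermodel.entities) == 1

    def test_subclass_axiom_enforced(self):
        tbox = TBox()
        tbox.add(SubClassOf(Atomic("B"), Atomic("A")))
        v = bounded_subsumption(tbox, Atomic("B"), Atomic("A"), max_size=3)
        assert v.holds

    def test_disjointness_enforced(self):
        tbox = TBox()
        tbox.add(DisjointWith(Atomic("A"), Atomic("B")))
        v = bounded_subsumption(tbox, Atomic("A"), Not(Atomic("B")), max_size=3)
        assert v.holds

    def test_some_propagates_up_the_hierarchy(self):
        tbox = _taxonomy_tbox()
        v = bounded_subsumption(
            tbox,
            parse_expr("has_proper_part some N-Propanol_Molecule"),
            parse_expr("has_proper_part some Propanol_Molecule"),
            max_size=3,
        )
        assert v.holds

    def test_countermodel_respects_axioms(self):
        tbox = _taxonomy_tbox()
        v = bounded_subsumption(
            tbox,
            parse_expr("has_proper_part some Propanol_Molecule"),
            parse_expr("has_proper_part some N-Propanol_Molecule"),
            max_size=3,
        )
        assert not v.holds
        cm = v.countermodel
        # some entity is a propanol molecule that is not the N-isomer
        names = {e: {t.name for t in cm.instance_of[e]} for e in cm.entities}
        assert any(
            "Propanol_Molecule" in ts and "N-Propanol_Molecule" not in ts
            for ts in names.values()
        )

    def test_primitive_subrole_is_not_its_superrole(self):
        # x with a proper part need not have a grain: has_grain is primitive
        v = bounded_subsumption(
            TBox(),
            parse_expr("has_proper_part some A"),
            parse_expr("has_grain some A"),
            max_size=3,
        )
        assert not v.holds
        assert v.role_edges is not None and v.role_edges[HAS_GRAIN] == set()

    def test_grain_subrole_implies_proper_part(self):
        v = bounded_subsumption(
            TBox(),
            parse_expr("has_grain some A"),
            parse_expr("has_proper_part some A"),
            max_size=3,
        )
        assert v.holds


class TestExternalReasoner:
    def test_cross_check_when_reasoner_available(self):
        pytest.importorskip("owlready2")
        from mereokit.dl import check_with_external_reasoner
        from mereokit.patterns import PROPANOL_CLASSES, build_propanol_ontology

        inferred = check_with_external_reasoner(build_propanol_ontology())
        for mix in PROPANOL_CLASSES["mixtures"]:
            assert (mix, PROPANOL_CLASSES["coll"]) in inferred
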