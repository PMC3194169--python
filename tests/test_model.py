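"""Model layer: parthood closure, grains, collectives, partitions,
components and the four-way classifier."""

import pytest

from mereokit.model import (
    ANY,
    CycleError,
    InvalidPartitionError,
    NoPartsAtLevelError,
    Partition,
    TypeName,
    TypeRegistry,
    TypeSpec,
    UnknownEntityError,
    at_least,
    build_model,
    classify_complex,
    components_at_level,
    exactly,
    grains_of,
    has_component,
    has_grain,
    is_n_coll,
    is_strict_compound,
    is_valid_partition,
    proper_parts,
    satisfies_coll,
)
from mereokit.fixtures import (
    ATOM,
    H,
    MOLECULE,
    WATER,
    galaxy_fixture,
    make_molecule,
    portion_of_water,
)


class TestBuildModel:
    def test_water_model_is_valid(self, water_flat):
        assert len(water_flat.model.entities) == 4

    def test_empty_model(self):
        m = build_model({}, [])
        assert m.entities == set()

    def test_cycle_rejected_naming_entity(self):
        with pytest.raises(CycleError) as exc:
            build_model({"a": set(), "b": set()}, [("a", "b"), ("b", "a")])
        assert "'a'" in str(exc.value) or "'b'" in str(exc.value)

    def test_self_loop_rejected(self):
        with pytest.raises(CycleError):
            build_model({"a": set()}, [("a", "a")])

    def test_unknown_entity_in_edge(self):
        with pytest.raises(UnknownEntityError):
            build_model({"a": set()}, [("a", "ghost")])

    def test_designation_must_pick_direct_parts(self):
        with pytest.raises(Exception):
            build_model(
                {"a": set(), "b": set(), "c": set()},
                [("a", "b"), ("b", "c")],
                {"a": {"c"}},  # c is a part of a, but not a direct part
            )


class TestProperParts:
    def test_propanol_has_twelve_atoms(self):
        fx = make_molecule("N_propanol")
        assert len(proper_parts(fx.model, fx.root)) == 12  # C3H8O

    def test_leaf_has_no_parts(self, water_flat):
        assert proper_parts(water_flat.model, "h2o_1_h1") == set()

    def test_three_level_chain_closure(self):
        m = build_model({"a": set(), "b": set(), "c": set()}, [("a", "b"), ("b", "c")])
        assert proper_parts(m, "a") == {"b", "c"}
        assert proper_parts(m, "b") == {"c"}

    def test_never_contains_self(self, exemplars):
        for fx in exemplars.values():
            for e in fx.model.entities:
                assert e not in proper_parts(fx.model, e)

    def test_unknown_entity(self, water_flat):
        with pytest.raises(UnknownEntityError):
            proper_parts(water_flat.model, "nope")


class TestGrains:
    def test_portion_grains_are_the_molecules(self):
        fx = portion_of_water(n_molecules=5)
        assert grains_of(fx.model, "portion") == {f"w{i}" for i in range(1, 6)}

    def test_no_parts_no_grains(self, water_flat):
        assert grains_of(water_flat.model, "h2o_1_o1") == set()

    def test_designation_overrides_direct_parts(self):
        ents = {f"e{i}": set() for i in range(6)}
        edges = [("e0", f"e{i}") for i in range(1, 6)]
        m = build_model(ents, edges, {"e0": {"e1", "e2", "e3"}})
        assert grains_of(m, "e0") == {"e1", "e2", "e3"}


class TestCollectives:
    def test_portion_is_water_collective(self):
        fx = portion_of_water()
        assert satisfies_coll(fx.model, fx.registry, "portion", WATER)

    def test_singleton_collective_allowed(self):
        fx = portion_of_water(n_molecules=1)
        assert satisfies_coll(fx.model, fx.registry, "portion", WATER)
        assert is_n_coll(fx.model, fx.registry, "portion", WATER, 1)

    def test_zero_grains_never_a_collective(self, water_flat):
        # grain existence: empty collectives are rejected
        assert not satisfies_coll(
            water_flat.model, water_flat.registry, "h2o_1_h1", H
        )

    def test_fruit_basket_specificity(self, exemplars):
        fx = exemplars["fruit_basket"]
        apple = fx.registry.by_name("Apple")
        fruit = fx.registry.by_name("Fruit")
        assert not satisfies_coll(fx.model, fx.registry, "basket", apple)
        assert satisfies_coll(fx.model, fx.registry, "basket", fruit)

    def test_herd_has_grain_cow(self, exemplars):
        fx = exemplars["herd"]
        assert has_grain(fx.model, fx.registry, "herd", "cow1")

    def test_has_grain_irreflexive(self, exemplars):
        for fx in exemplars.values():
            for e in fx.model.entities:
                assert not has_grain(fx.model, fx.registry, e, e)

    def test_galaxy_non_transitivity(self):
        fx = galaxy_fixture()
        assert has_grain(fx.model, fx.registry, "galaxy", "star1")
        assert has_grain(fx.model, fx.registry, "star1", "mol1")
        assert not has_grain(fx.model, fx.registry, "galaxy", "mol1")

    def test_kidney_pair_cardinality(self, exemplars):
        fx = exemplars["pair_of_kidneys"]
        kidney = fx.registry.by_name("Kidney")
        assert is_n_coll(fx.model, fx.registry, "pair", kidney, 2)
        assert not is_n_coll(fx.model, fx.registry, "pair", kidney, 3)

    def test_h_pair_inside_nested_water(self, water_nested):
        assert is_n_coll(
            water_nested.model, water_nested.registry, "h2o_1_hpair", H, 2
        )


class TestPartitions:
    def test_water_into_oxygen_and_h_pair(self, water_nested):
        p = Partition("h2o_1", ["h2o_1_o1", "h2o_1_hpair"])
        assert is_valid_partition(water_nested.model, p)

    def test_non_exhaustive_rejected(self, water_flat):
        p = Partition("h2o_1", ["h2o_1_o1", "h2o_1_h1"])  # h2 left out
        assert not is_valid_partition(water_flat.model, p)

    def test_overlapping_segments_rejected(self, water_flat):
        p = Partition("h2o_1", ["h2o_1_o1", "h2o_1_o1"])
        assert not is_valid_partition(water_flat.model, p)

    def test_partition_may_crisscross_granularity(self):
        # half of a two-monomer chain split as a monomer, half as atoms
        ents = {e: set() for e in ["prot", "m1", "m2", "a1", "a2", "a3", "a4"]}
        edges = [
            ("prot", "m1"), ("prot", "m2"),
            ("m1", "a1"), ("m1", "a2"), ("m2", "a3"), ("m2", "a4"),
        ]
        m = build_model(ents, edges)
        assert is_valid_partition(m, Partition("prot", ["m1", "a3", "a4"]))
        assert not is_valid_partition(m, Partition("prot", ["m1", "m2", "a3"]))

    def test_atomic_partition_of_flat_water(self, water_flat):
        p = Partition("h2o_1", ["h2o_1_o1", "h2o_1_h1", "h2o_1_h2"])
        assert is_valid_partition(water_flat.model, p)


class TestComponents:
    def test_segment_is_component_wrt_partition(self, water_nested):
        p = Partition("h2o_1", ["h2o_1_o1", "h2o_1_hpair"])
        assert has_component(water_nested.model, "h2o_1", "h2o_1_o1", p)

    def test_part_of_segment_is_not_a_component_wrt_partition(self, water_nested):
        p = Partition("h2o_1", ["h2o_1_o1", "h2o_1_hpair"])
        assert not has_component(water_nested.model, "h2o_1", "h2o_1_h1", p)

    def test_unrelativized_reduces_to_proper_parthood(self, water_nested):
        assert has_component(water_nested.model, "h2o_1", "h2o_1_h1")

    def test_invalid_partition_raises(self, water_flat):
        p = Partition("h2o_1", ["h2o_1_o1"])
        with pytest.raises(InvalidPartitionError):
            has_component(water_flat.model, "h2o_1", "h2o_1_o1", p)

    def test_components_at_atom_level(self, water_flat):
        got = components_at_level(water_flat.model, water_flat.registry, "h2o_1", ATOM)
        assert len(got) == 3

    def test_no_molecular_components_of_a_molecule(self, water_flat):
        reg = water_flat.registry
        assert components_at_level(water_flat.model, reg, "h2o_1", MOLECULE) == set()

    def test_subatomic_level_as_disjunction(self):
        reg = TypeRegistry()
        proton, neutron, electron = (
            TypeName("Proton"), TypeName("Neutron"), TypeName("Electron"),
        )
        reg.add(proton, neutron, electron, TypeName("Atom"))
        m = build_model(
            {"atom": {TypeName("Atom")}, "p1": {proton}, "n1": {neutron}, "e1": {electron}},
            [("atom", "p1"), ("atom", "n1"), ("atom", "e1")],
        )
        got = components_at_level(m, reg, "atom", [proton, neutron, electron])
        assert got == {"p1", "n1", "e1"}


class TestStrictCompounds:
    def _water_partition(self, fx):
        return Partition("h2o_1", sorted(fx.model.direct_parts_of("h2o_1")))

    def test_water_is_a_strict_compound(self, water_flat):
        spec = water_flat.specs["Water_Molecule"]
        p = self._water_partition(water_flat)
        assert is_strict_compound(water_flat.model, water_flat.registry, "h2o_1", p, spec)

    def test_peroxide_fails_the_water_spec(self, water_flat, peroxide):
        spec = water_flat.specs["Water_Molecule"]
        p = Partition("h2o2_1", sorted(peroxide.model.direct_parts_of("h2o2_1")))
        assert not is_strict_compound(peroxide.model, peroxide.registry, "h2o2_1", p, spec)

    def test_portion_of_water_is_not_strict(self):
        # removing one molecule leaves a portion of water: number inessential
        fx = portion_of_water(n_molecules=3, with_atoms=False)
        spec = fx.specs["Portion_of_Water"]
        p = Partition("portion", sorted(fx.model.direct_parts_of("portion")))
        assert not is_strict_compound(fx.model, fx.registry, "portion", p, spec)


class TestClassifier:
    def test_four_exemplars_four_categories(self, exemplars):
        got = {}
        for name in ("portion_of_water", "pair_of_kidneys", "hand", "propanol_molecule"):
            fx = exemplars[name]
            spec = next(iter(fx.specs.values()))
            level = fx.levels.get("part") or fx.levels.get("molecule")
            got[name] = classify_complex(fx.model, fx.registry, fx.root, spec, level)
        assert got == {
            "portion_of_water": "flexible_collective",
            "pair_of_kidneys": "strict_collective",
            "hand": "flexible_compound",
            "propanol_molecule": "strict_compound",
        }

    def test_water_portion_granularity_flip(self, exemplars):
        fx = exemplars["portion_of_water"]
        spec = next(iter(fx.specs.values()))
        atom_spec = TypeSpec(TypeName("X"), [(ATOM, at_least(1))])
        assert (
            classify_complex(fx.model, fx.registry, fx.root, spec, fx.levels["molecule"])
            == "flexible_collective"
        )
        assert (
            classify_complex(fx.model, fx.registry, fx.root, atom_spec, fx.levels["atom"])
            == "flexible_compound"
        )

    def test_o2_o3_granularity_flip(self, exemplars):
        fx = exemplars["o2_o3_mixture"]
        spec = next(iter(fx.specs.values()))
        atom_spec = TypeSpec(TypeName("X"), [(ATOM, at_least(1))])
        assert (
            classify_complex(fx.model, fx.registry, fx.root, spec, fx.levels["molecule"])
            == "flexible_compound"
        )
        assert (
            classify_complex(fx.model, fx.registry, fx.root, atom_spec, fx.levels["atom"])
            == "flexible_collective"
        )

    def test_fruit_basket_specificity_flip(self, exemplars):
        # described specifically (apples vs pears) the basket is a mixture;
        # described merely as fruits it is a mono-sortal collective
        fx = exemplars["fruit_basket"]
        spec = next(iter(fx.specs.values()))
        fruit = fx.registry.by_name("Fruit")
        assert classify_complex(fx.model, fx.registry, fx.root, spec, fruit) == (
            "flexible_compound"
        )
        coarse = build_model(
            {e: {fruit} if e != "basket" else fx.model.instance_of[e]
             for e in fx.model.entities},
            fx.model.direct_part,
        )
        assert classify_complex(coarse, fx.registry, fx.root, spec, fruit) == (
            "flexible_collective"
        )

    def test_no_parts_at_level_raises(self, water_flat):
        spec = water_flat.specs["Water_Molecule"]
        with pytest.raises(NoPartsAtLevelError):
            classify_complex(
                water_flat.model, water_flat.registry, "h2o_1_o1", spec, ATOM
            )
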