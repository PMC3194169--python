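"""Deterministic worked-example models and seeded random model generation.

Everything here is built programmatically: molecule fixtures (water,
hydrogen peroxide, the two propanol isomers, methanol, ethanol), the
exemplar catalog for the four-way classification (a portion of water, a
pair of kidneys, hands with four/five/six fingers, a propanol molecule),
the galaxy/star/molecule non-transitivity witness, the fruit basket, the
oxygen/ozone mixture, blood plasma, and a herd.

Molecule fixtures are composition-only: isomers share their atom multiset
(C3H8O for both propanols) and differ solely by type label.  Telling them
apart by bond topology is structure, not number, and is out of scope here.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .model import (
    ANY,
    FiniteModel,
    TypeName,
    TypeRegistry,
    TypeSpec,
    at_least,
    build_model,
    exactly,
)

__all__ = [
    "Fixture",
    "MOLECULE_KINDS",
    "chemistry_registry",
    "make_molecule",
    "portion_of_water",
    "make_exemplars",
    "galaxy_fixture",
    "random_model",
    "standard_random_vocab",
]


@dataclass
class Fixture:
    """A worked example: a model, the registry interpreting its type labels,
    the entity of interest, and any composition specs / levels that go with
    it."""

    model: FiniteModel
    registry: TypeRegistry
    root: str
    specs: dict[str, TypeSpec] = field(default_factory=dict)
    levels: dict[str, TypeName] = field(default_factory=dict)


# -- shared chemical vocabulary ---------------------------------------------

ATOM = TypeName("Atom")
H = TypeName("H-Atom")
O = TypeName("O-Atom")
C = TypeName("C-Atom")
MOLECULE = TypeName("Molecule")
WATER = TypeName("Water_Molecule")
PEROXIDE = TypeName("Hydrogen_Peroxide_Molecule")
ALCOHOL = TypeName("Alcohol_Molecule")
PROPANOL = TypeName("Propanol_Molecule")
N_PROPANOL = TypeName("N-Propanol_Molecule")
I_PROPANOL = TypeName("I-Propanol_Molecule")
METHANOL = TypeName("Methanol_Molecule")
ETHANOL = TypeName("Ethanol_Molecule")

#: molecule kind -> (molecule type, composition by atom type)
MOLECULE_KINDS: dict[str, tuple[TypeName, dict[TypeName, int]]] = {
    "H2O": (WATER, {O: 1, H: 2}),
    "H2O2": (PEROXIDE, {O: 2, H: 2}),
    "N_propanol": (N_PROPANOL, {C: 3, H: 8, O: 1}),
    "I_propanol": (I_PROPANOL, {C: 3, H: 8, O: 1}),
    "methanol": (METHANOL, {C: 1, H: 4, O: 1}),
    "ethanol": (ETHANOL, {C: 2, H: 6, O: 1}),
}


def chemistry_registry() -> TypeRegistry:
    reg = TypeRegistry()
    for a in (H, O, C):
        reg.add_is_a(a, ATOM)
    for m in (WATER, PEROXIDE, ALCOHOL):
        reg.add_is_a(m, MOLECULE)
    for m in (PROPANOL, METHANOL, ETHANOL):
        reg.add_is_a(m, ALCOHOL)
    reg.add_is_a(N_PROPANOL, PROPANOL)
    reg.add_is_a(I_PROPANOL, PROPANOL)
    reg.add_disjoint(N_PROPANOL, I_PROPANOL)
    return reg


def _atom_prefix(t: TypeName) -> str:
    return t.name.split("-")[0].lower()


def make_molecule(
    kind: str,
    mol_id: Optional[str] = None,
    nested: bool = False,
    registry: Optional[TypeRegistry] = None,
) -> Fixture:
    """A single molecule with its atoms as parts.

    ``nested=True`` (water only) groups the two hydrogen atoms into an
    explicit H-pair entity — the strict-collective component used by the
    nested molecule pattern — so the molecule's direct parts are one O-atom
    and one pair rather than three atoms.
    """
    if kind not in MOLECULE_KINDS:
        raise KeyError(f"unknown molecule kind {kind!r}; know {sorted(MOLECULE_KINDS)}")
    mtype, comp = MOLECULE_KINDS[kind]
    reg = registry or chemistry_registry()
    mol = mol_id or f"{kind.lower()}_1"
    types: dict[str, set[TypeName]] = {mol: {mtype}}
    edges: list[tuple[str, str]] = []
    atoms: dict[TypeName, list[str]] = {}
    for t in sorted(comp, key=lambda t: t.name):
        for i in range(comp[t]):
            a = f"{mol}_{_atom_prefix(t)}{i + 1}"
            types[a] = {t}
            atoms.setdefault(t, []).append(a)
    if nested:
        if kind != "H2O":
            raise ValueError("nested fixtures are provided for water only")
        h_coll = TypeName.coll(H, "H-Atom_COLL")
        h_pair = TypeName.n_coll(H, 2, "H_PAIR")
        reg.add_is_a(h_pair, h_coll)
        pair = f"{mol}_hpair"
        types[pair] = {h_coll, h_pair}
        edges += [(mol, atoms[O][0]), (mol, pair)]
        edges += [(pair, a) for a in atoms[H]]  # H atoms are parts via the pair
    else:
        for alist in atoms.values():
            edges += [(mol, a) for a in alist]
    model = build_model(types, edges)
    spec = TypeSpec(mtype, [(t, exactly(c)) for t, c in sorted(comp.items(), key=lambda i: i[0].name)])
    return Fixture(model, reg, mol, specs={mtype.name: spec}, levels={"atom": ATOM})


def portion_of_water(n_molecules: int = 5, with_atoms: bool = True) -> Fixture:
    """A portion of water: a flexible collective of water molecules.

    Its grains are the molecules (direct parts); the atoms sit one level
    below, which is what makes the portion mono-sortal at the Molecule
    level and multi-sortal at the Atom level.
    """
    if n_molecules < 1:
        raise ValueError("a collective needs at least one grain")
    reg = chemistry_registry()
    portion_t = TypeName("Portion_of_Water")
    water_coll = TypeName.coll(WATER, "Water_Molecule_COLL")
    reg.add(portion_t, water_coll)
    reg.add_is_a(portion_t, water_coll)
    types: dict[str, set[TypeName]] = {"portion": {portion_t}}
    edges = []
    for i in range(n_molecules):
        mol = f"w{i + 1}"
        types[mol] = {WATER}
        edges.append(("portion", mol))
        if with_atoms:
            for j, t in enumerate([O, H, H]):
                a = f"{mol}_{_atom_prefix(t)}{j}"
                types[a] = {t}
                edges.append((mol, a))
    spec = TypeSpec(portion_t, [(WATER, at_least(1))])
    return Fixture(
        build_model(types, edges),
        reg,
        "portion",
        specs={portion_t.name: spec},
        levels={"molecule": MOLECULE, "atom": ATOM},
    )


def galaxy_fixture() -> Fixture:
    """Galaxy -> star -> molecule: the non-transitivity witness.

    The galaxy is a star collection and the star a molecule collection, but
    the galaxy is not a molecule collection — has_grain does not compose.
    """
    reg = TypeRegistry()
    galaxy_t, star_t, mol_t = TypeName("Galaxy"), TypeName("Star"), TypeName("Molecule")
    star_coll = TypeName.coll(star_t, "Star_COLL")
    mol_coll = TypeName.coll(mol_t, "Molecule_COLL")
    reg.add(galaxy_t, star_t, mol_t, star_coll, mol_coll)
    reg.add_is_a(galaxy_t, star_coll)
    reg.add_is_a(star_t, mol_coll)
    model = build_model(
        {
            "galaxy": {galaxy_t},
            "star1": {star_t},
            "star2": {star_t},
            "mol1": {mol_t},
            "mol2": {mol_t},
        },
        [
            ("galaxy", "star1"),
            ("galaxy", "star2"),
            ("star1", "mol1"),
            ("star1", "mol2"),
        ],
    )
    return Fixture(model, reg, "galaxy")


def _hand(n_fingers: int) -> Fixture:
    reg = TypeRegistry()
    hand_t = TypeName("Hand")
    part_t = TypeName("Hand_Part")
    finger_t, palm_t = TypeName("Finger"), TypeName("Palm")
    reg.add(hand_t)
    reg.add_is_a(finger_t, part_t)
    reg.add_is_a(palm_t, part_t)
    types: dict[str, set[TypeName]] = {"hand": {hand_t}, "palm": {palm_t}}
    edges = [("hand", "palm")]
    for i in range(n_fingers):
        f = f"finger{i + 1}"
        types[f] = {finger_t}
        edges.append(("hand", f))
    spec = TypeSpec(hand_t, [(finger_t, at_least(1)), (palm_t, at_least(1))])
    return Fixture(
        build_model(types, edges),
        reg,
        "hand",
        specs={"Hand": spec},
        levels={"part": part_t},
    )


def make_exemplars() -> dict[str, Fixture]:
    """The exemplar catalog: one fixture per cell of the four-way
    classification, plus the granularity/specificity examples."""
    out: dict[str, Fixture] = {}

    out["portion_of_water"] = portion_of_water()
    out["portion_of_water_singleton"] = portion_of_water(n_molecules=1)

    # strict collective: a pair of kidneys
    reg = TypeRegistry()
    kidney_t = TypeName("Kidney")
    pair_t = TypeName("Kidney_Pair")
    kidney_coll = TypeName.coll(kidney_t, "Kidney_COLL")
    kidney_pair = TypeName.n_coll(kidney_t, 2, "Kidney_PAIR")
    reg.add(kidney_t)
    reg.add_is_a(kidney_pair, kidney_coll)
    reg.add_is_a(pair_t, kidney_pair)
    model = build_model(
        {"pair": {pair_t}, "k1": {kidney_t}, "k2": {kidney_t}},
        [("pair", "k1"), ("pair", "k2")],
    )
    out["pair_of_kidneys"] = Fixture(
        model,
        reg,
        "pair",
        specs={"Kidney_Pair": TypeSpec(pair_t, [(kidney_t, exactly(2))])},
        levels={"part": kidney_t},
    )

    out["hand"] = _hand(5)
    out["hand_4_fingers"] = _hand(4)
    out["hand_6_fingers"] = _hand(6)

    prop = make_molecule("N_propanol", mol_id="propanol_1")
    prop.levels["part"] = ATOM
    out["propanol_molecule"] = prop

    out["galaxy"] = galaxy_fixture()

    # specificity: a collective of fruits that is a mixture of apples and pears
    reg = TypeRegistry()
    fruit_t = TypeName("Fruit")
    apple_t, pear_t = TypeName("Apple"), TypeName("Pear")
    basket_t = TypeName("Fruit_Basket")
    fruit_coll = TypeName.coll(fruit_t, "Fruit_COLL")
    reg.add_is_a(apple_t, fruit_t)
    reg.add_is_a(pear_t, fruit_t)
    reg.add(basket_t)
    reg.add_is_a(basket_t, fruit_coll)
    model = build_model(
        {"basket": {basket_t}, "apple1": {apple_t}, "pear1": {pear_t}},
        [("basket", "apple1"), ("basket", "pear1")],
    )
    out["fruit_basket"] = Fixture(
        model,
        reg,
        "basket",
        specs={"Fruit_Basket": TypeSpec(basket_t, [(fruit_t, at_least(1))])},
        levels={"fruit": fruit_t},
    )

    # granularity: an O2/O3 mixture is multi-sortal at the Molecule level but
    # mono-sortal (oxygen atoms only) at the Atom level
    reg = chemistry_registry()
    oxygen_t = TypeName("Oxygen_Molecule")
    ozone_t = TypeName("Ozone_Molecule")
    mix_t = TypeName("Oxygen_Ozone_Mixture")
    reg.add_is_a(oxygen_t, MOLECULE)
    reg.add_is_a(ozone_t, MOLECULE)
    reg.add(mix_t)
    types = {"mix": {mix_t}, "o2_1": {oxygen_t}, "o3_1": {ozone_t}}
    edges = [("mix", "o2_1"), ("mix", "o3_1")]
    for mol, count in (("o2_1", 2), ("o3_1", 3)):
        for i in range(count):
            a = f"{mol}_o{i + 1}"
            types[a] = {O}
            edges.append((mol, a))
    out["o2_o3_mixture"] = Fixture(
        build_model(types, edges),
        reg,
        "mix",
        specs={"Oxygen_Ozone_Mixture": TypeSpec(mix_t, [(MOLECULE, at_least(1))])},
        levels={"molecule": MOLECULE, "atom": ATOM},
    )

    # blood plasma: a mixture of albumin and globulin fractions
    reg = TypeRegistry()
    molecule_t = TypeName("Molecule")
    protein_t = TypeName("PlasmaProteinMolecule")
    albumin_t, globulin_t = TypeName("AlbuminMolecule"), TypeName("GlobulinMolecule")
    plasma_t = TypeName("BloodPlasmaSample")
    reg.add_is_a(protein_t, molecule_t)
    reg.add_is_a(albumin_t, protein_t)
    reg.add_is_a(globulin_t, protein_t)
    reg.add(plasma_t)
    types = {"plasma": {plasma_t}}
    edges = []
    for i in range(3):
        types[f"alb{i + 1}"] = {albumin_t}
        edges.append(("plasma", f"alb{i + 1}"))
    for i in range(2):
        types[f"glob{i + 1}"] = {globulin_t}
        edges.append(("plasma", f"glob{i + 1}"))
    out["blood_plasma"] = Fixture(
        build_model(types, edges),
        reg,
        "plasma",
        specs={"BloodPlasmaSample": TypeSpec(plasma_t, [(protein_t, at_least(1))])},
        levels={"molecule": molecule_t},
    )

    # a herd: flexible collective of cows
    reg = TypeRegistry()
    cow_t, herd_t = TypeName("Cow"), TypeName("Herd")
    cow_coll = TypeName.coll(cow_t, "Cow_COLL")
    reg.add(cow_t)
    reg.add_is_a(herd_t, cow_coll)
    types = {"herd": {herd_t}}
    edges = []
    for i in range(4):
        types[f"cow{i + 1}"] = {cow_t}
        edges.append(("herd", f"cow{i + 1}"))
    out["herd"] = Fixture(
        build_model(types, edges),
        reg,
        "herd",
        specs={"Herd": TypeSpec(herd_t, [(cow_t, at_least(1))])},
        levels={"cow": cow_t},
    )

    return out


# -- random models ----------------------------------------------------------


def standard_random_vocab() -> tuple[TypeRegistry, list[TypeName]]:
    """A small vocabulary for random models: three plain types (one
    subsuming another) and collective types over two of them, so that
    has_grain is frequently non-empty."""
    a, b, c = TypeName("A"), TypeName("B"), TypeName("C")
    a_coll = TypeName.coll(a, "A_COLL")
    b_coll = TypeName.coll(b, "B_COLL")
    reg = TypeRegistry()
    reg.add(c, a_coll, b_coll)
    reg.add_is_a(b, a)
    return reg, [a, b, c, a_coll, b_coll]


def random_model(
    n_entities: int,
    vocab: Sequence[TypeName],
    seed: int,
    edge_prob: float = 0.35,
    designation_prob: float = 0.25,
) -> FiniteModel:
    """A seeded random acyclic model.

    Edges only run from lower to higher entity index, so the part graph is
    acyclic by construction; each entity gets one or two labels from the
    vocabulary, and occasionally an explicit grain designation over a
    subset of its direct parts.
    """
    if n_entities < 0:
        raise ValueError("n_entities must be >= 0")
    rng = random.Random(seed)
    names = [f"e{i}" for i in range(n_entities)]
    types = {
        e: set(rng.sample(list(vocab), k=rng.choice((1, 1, 2)))) if vocab else set()
        for e in names
    }
    edges = [
        (names[i], names[j])
        for i in range(n_entities)
        for j in range(i + 1, n_entities)
        if rng.random() < edge_prob
    ]
    designation = {}
    direct: dict[str, list[str]] = {}
    for w, p in edges:
        direct.setdefault(w, []).append(p)
    for e in names:
        if direct.get(e) and rng.random() < designation_prob:
            k = rng.randint(0, len(direct[e]))
            designation[e] = set(rng.sample(direct[e], k=k))
    return build_model(types, edges, designation or None)
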