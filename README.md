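# mereokit

Grains, components and mixtures for biomedical ontology engineering:
finite-model mereology, OWL design patterns, and a bounded-model
subsumption oracle.

## The problem

Biomedical ontologies lean heavily on parthood. Two of its subrelations do
very different work:

* **has_grain** relates a *collective* to its multiply occurring, uniform
  parts — the H₂O molecules of a portion of water, the cows of a herd;
* **has_component** relates a *compound* to the segments of a partition —
  the one oxygen and two hydrogen atoms of a water molecule, the bones of
  a skull.

Both are subrelations of the transitive **has_proper_part**. Crossing the
two distinguishing axes — mono- vs multi-sortal parts, and whether the
*number* of parts is essential — yields four kinds of complex entity:

|                    | mono-sortal              | multi-sortal           |
|--------------------|--------------------------|------------------------|
| **number flexible**| flexible collective (a portion of water) | flexible compound (a hand) |
| **number strict**  | strict collective (a pair of kidneys)    | strict compound (a propanol molecule) |

The axes are granularity- and specificity-dependent: a portion of water is
mono-sortal at the molecule level but multi-sortal at the atom level, and
an O₂/O₃ mixture is multi-sortal in molecules yet mono-sortal in oxygen
atoms. Mixtures (blood plasma, disinfectant propanol) sit exactly on this
boundary: compounds of *fractions*, each fraction a collective of
same-sort grains.

There is a catch for OWL: counting parts needs qualified cardinality
restrictions (`has_grain exactly 2 H-Atom`), but OWL 2 forbids cardinality
restrictions over *non-simple* roles — roles that are transitive or have a
transitive subrole — so `has_proper_part exactly 3 Atom` is inexpressible,
and the primitive subroles `has_grain`/`has_component` carry no semantics
a reasoner could use to subsume a mixture under a collective class. The
package implements the repair: a *reasoner-friendly* design pattern that
defines mixtures and collectives with proper parthood only,

```
Propanol_COLL     ≡ (has_proper_part some Propanol_Molecule) and
                    (has_proper_part only (Propanol_Molecule or not Molecule))
Propanol_Mixture  ≡ (has_proper_part some N-Propanol_Molecule) and
                    (has_proper_part some I-Propanol_Molecule) and
                    (has_proper_part only (Propanol_COLL or
                                           proper_part_of some Propanol_COLL))
```

under which `Propanol_Mixture ⊑ Propanol_COLL` becomes a genuine
entailment.

## What the package provides

* `mereokit.model` — finite instance models (entities, type labels, an
  acyclic direct-parthood graph) with executable versions of the relations
  and axioms: `proper_parts`, `grains_of`, `satisfies_coll`, `has_grain`,
  `is_n_coll`, `is_valid_partition`, `has_component`,
  `components_at_level`, `is_strict_compound`, and the four-way
  `classify_complex`.
* `mereokit.dl` — a small DL class-expression language with Manchester-
  style parsing/rendering, finite-model `extension`, the OWL 2
  non-simple-role safety check `is_dl_safe`, and `bounded_subsumption`: an
  exhaustive oracle over all acyclic models up to a size bound that either
  certifies `C ⊑ D` up to that bound or returns a concrete countermodel.
* `mereokit.patterns` — compilers from pattern parameters to annotated OWL
  axioms (`coll_pattern`, `n_coll_pattern`, `molecule_pattern`,
  `flexible_compound_pattern`, `mixture_pattern`),
  `build_propanol_ontology`, and OWL 2 serialization (functional and
  Manchester syntax) with a functional-syntax parser for round-trips.
* `mereokit.theorems` — executable verification that irreflexivity,
  asymmetry and the two propagation laws of `has_grain` hold on every
  constructible model, plus the galaxy/star/molecule non-transitivity
  witness.
* `mereokit.fixtures` — deterministic worked-example models and a seeded
  random-model generator.
* `mereokit.cli` — the `mereokit` command
  (`generate-ontology`, `classify`, `subsume`, `dl-safety`,
  `verify-theorems`, `demo-propanol`).

## Worked example

```python
import mereokit as mk
from mereokit.fixtures import make_exemplars

ex = make_exemplars()
for name in ("portion_of_water", "pair_of_kidneys", "hand", "propanol_molecule"):
    fx = ex[name]
    spec = next(iter(fx.specs.values()))
    level = fx.levels.get("part") or fx.levels.get("molecule")
    cat = mk.classify_complex(fx.model, fx.registry, fx.root, spec, level)
    print(f"{name:22s} -> {cat}")
```

prints the four exemplars landing in the four distinct categories:

```
portion_of_water       -> flexible_collective
pair_of_kidneys        -> strict_collective
hand                   -> flexible_compound
propanol_molecule      -> strict_compound
```

The mixture walkthrough regenerates the propanol ontology and proves the
subsumptions with the bounded oracle:

```
$ mereokit demo-propanol --out-dir demo --max-size 4
axiom configuration: collective/molecule disjointness ON
wrote demo/propanol.ofn
wrote demo/propanol.omn
Propanol_Mixture_1 subClassOf Propanol_COLL: holds (checked 35632 models up to size 4)
Propanol_Mixture_2 subClassOf Propanol_COLL: holds (checked 39954 models up to size 4)
Propanol_Mixture_3 subClassOf Propanol_COLL: holds (checked 12448 models up to size 4)
wrote demo/subsumption_report.json
```

"holds (checked N models up to size k)" means every acyclic finite model
with at most k entities over the ontology's vocabulary satisfies the
subsumption; a failure would come back with an explicit countermodel.
Passing `--no-collective-molecule-disjointness` drops the auxiliary
disjointness axiom, and the oracle then exhibits the countermodel that
breaks the fraction-compound variant (exit status 1).

```
$ mereokit dl-safety "has_proper_part exactly 3 Atom"
{
  "expression": "has_proper_part exactly 3 Atom",
  "dl_safe": false,
  "violations": [
    {"role": "has_proper_part",
     "reason": "cardinality restriction on non-simple role 'has_proper_part'"}
  ]
}
```

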