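# Methods

## The model of mereological reality

All semantics is evaluated against finite instance models: a set of
entities, a map from entities to non-empty sets of type labels, and an
acyclic *direct parthood* graph. `has_proper_part` is the transitive
closure of direct parthood; acyclicity is enforced at build time, which
makes irreflexivity and asymmetry of every parthood subrelation structural
rather than checked.

The models are **discrete and atomistic**. No continuous-matter semantics
is attempted: every worked example (molecules, portions, herds, organs)
is naturally discrete, and "the mereological sum of the segments overlaps
the compound completely" is read on *leaf content* — the set of partless
entities below a thing (or the thing itself when it has no parts). Two
segments of a partition overlap iff they share a mereological atom, and a
partition is exhaustive iff its segments' atoms union to the whole's
atoms. Judging the sum on leaf content rather than raw entity sets is what
lets a partition crisscross granularity levels (half a protein split into
monomers, half into atoms) without intermediate entities blocking
exhaustiveness.

**Grains.** The grain relation is treated as derivable, not primitive. The
candidate grains of an entity default to its *direct* proper parts,
overridable by an explicit per-entity designation. This encodes the
reading that a water portion's grains are its molecules, never the atoms
two levels down; the designation hook covers models where direct parthood
and intended granularity disagree. `x has_grain y` then holds iff `y` is a
proper part of `x` and some type of `x` is (a subtype of) a collective
type whose base type `y` instantiates. Collective types over a base
(`X_COLL`, `X_PAIR`) live in the type registry; whether `X_COLL` is itself
a subtype of anything (e.g. of `X`'s ancestors) is left entirely to the
modeller — the registry adds no implicit edges.

**Collective minimum size is 1.** Singleton collectives are admitted;
empty ones are rejected (an entity with no grains would vacuously satisfy
every collective type). Connectedness is ignored throughout — no spatial
relation is modelled, and nothing distinguishes bunches of O, O₂ and O₃
beyond their type labels.

**Componenthood.** Relativized to a partition, a component is exactly a
segment (a part of a segment is not a component with respect to that
partition). Unrelativized componenthood reduces to proper parthood: in a
discrete finite model every proper part extends to a partition by taking
the remaining atoms as singleton segments.

**Strict compounds.** The modal formulation ("no segment can be added or
subtracted such that the result is still an X") is made decidable through
cardinality-based composition specs: per-component-type slots with
`exactly(n)` / `at_least(n)` / `any` cardinalities and an optional closure
flag. A partition is a strict compound for a spec iff the spec is
satisfied and violated under every single-segment removal and every
addition of one hypothetical segment of a slot type.

**The four-way classifier.** At a granularity level (a type or disjunction
of types), an entity's parts at that level are collected; mono-sortality
means their most specific declared types (after discarding redundant
supertypes) form a single sort, and number-strictness is read off the
spec's slots (any `exactly` slot makes it strict). This makes
mono-sortality granularity-dependent by construction — a water portion is
mono-sortal at the Molecule level and multi-sortal at the Atom level.
*Specificity* is expressed through the labels themselves: a basket whose
contents are declared `Apple` and `Pear` classifies as a mixture, while
relabelling them as bare `Fruit` recovers the collective reading (the
collective reading is also available without relabelling through
`satisfies_coll` with base `Fruit`). A separate specificity knob on the
classifier was considered and rejected: it would duplicate what the type
labels already say.

## DL semantics and the safety check

Class expressions (atomic, boolean connectives, `some`, `only`,
`exactly/min/max n`) are evaluated to entity sets under closed-world
finite semantics: `has_proper_part` as the transitive closure,
`proper_part_of` its inverse, `has_grain` as the candidate-grain relation,
and unrelativized `has_component` coinciding with proper parthood.
`only` over an entity with no successors holds vacuously; negation is
classical complement within the model's entity set. These closed-world
finite models deliberately differ in regime from the open-world OWL
output; results from the oracle and from an external reasoner are
therefore reported separately and never conflated.

The safety check mirrors the OWL 2 global restrictions: a role is
non-simple if it is transitive or has a transitive subrole, propagated
across inverses; every qualified cardinality restriction over a non-simple
role is flagged. With the shipped role box this flags exactly the
proper-parthood counting axioms (the "count atoms via has_proper_part"
style) and passes the `has_grain`/`has_component` ones.

## The bounded subsumption oracle

True entailment for these FOL-defined relations is beyond OWL, so
subsumption is decided *up to a model-size bound*: `C ⊑ D` is checked
against every acyclic finite model with at most `max_size` entities
(default 5 — the worked examples need at most five relevant entities per
pattern). A negative answer is definitive and comes with a countermodel; a
positive answer means "no countermodel up to this size".

Mechanics, in order of importance:

* **Isomorphism-lite pruning.** Only parthood DAGs whose direct edges run
  from lower to higher entity index are enumerated; every acyclic model is
  isomorphic to one of these. Labelings over those graphs are enumerated
  freely, so some models are visited more than once but none are missed.
* **Macro expansion.** Defined names (equivalence axioms with an atomic
  left side) are substituted into the checked expressions. A name with
  more than one definition keeps its first as the macro and the rest as
  per-model equality constraints.
* **Label-set closure.** Atomic subclass axioms and atomic disjointness
  are folded into the set of admissible per-entity label sets, so the
  taxonomy costs nothing per model. Remaining axioms are checked model by
  model, and only for models that could still yield a countermodel.
* **Primitive subroles.** Roles other than proper parthood and its
  inverse (`has_grain`, `has_component`) are interpreted as *arbitrary*
  subrelations of proper parthood — exactly the information an OWL
  reasoner has. They are searched by per-entity successor-subset
  backtracking with interval pruning: every node of an expression is
  evaluated to a certain/possible pair of entity bitmasks under the
  partially fixed roles, and branches that cannot produce a witness in
  `ext(C) \ ext(D)` are cut. The search is exhaustive; the ordering
  (sparse labelings and graphs first, empty successor sets first) merely
  finds countermodels early.
* A configurable cap on examined models raises a resource-guard error
  carrying the partial verdict (`complete=False`).

The deliberately slow path — both subroles free — is exercised by the
negative control, where a countermodel is found within a few hundred
models; the positive mixture checks are role-free after expansion and
complete at size 5 in roughly a minute each on one CPU (the shipped demo
uses size 4, a few hundred milliseconds, with size 5 used by the test
suite; both bounds exceed the minimal-countermodel sizes that occur in
these patterns).

## The propanol ontology and the auxiliary disjointness axiom

`build_propanol_ontology` regenerates the mixture example: the taxonomy
(`Propanol_Molecule` under `Molecule`, two disjoint isomers — the isomer
disjointness is asserted explicitly), the grain-based collective classes
for propanol and both isomers, three mixture representation variants in
the proper-parthood-only regime (grain-disjunction analogue, supertype
analogue, and the fraction-compound rewrite), and the reasoner-friendly
collective definition. `Propanol_COLL` carries both its grain-based and
its parthood-based definition; entailment checks over the
parthood-only fragment are monotone evidence for the full ontology, and
the `Ontology.fragment` helper selects that fragment.

One design question the source material leaves open is whether something
can be both a propanol collective and a molecule. Running the oracle both
ways settles it: **without** an auxiliary axiom, the fraction-compound
variant admits a 5-entity countermodel in which a plain `Molecule` with a
propanol-molecule part satisfies the collective definition, slips through
the mixture's closure condition, and breaks the subsumption; **with**
`DisjointWith(Propanol_COLL, Molecule)` all three variants are entailed
subclasses of `Propanol_COLL` at every bound. The disjointness is
therefore shipped on by default, exposed as the
`collective_molecule_disjoint` build flag and the CLI's
`--no-collective-molecule-disjointness`.

The `_COLL`/`_PAIR` suffixes are a naming convention only: the generated
axioms, not the names, carry the semantics, and no higher-order collective
constructor is introduced into OWL. The nested and flat molecule patterns
are alternative modelling styles of the same chemistry, not logically
equivalent classes: each classifies exactly the water molecule of its
matching fixture shape and both exclude hydrogen peroxide; the nested
closure conjunct admits both the collective component and the atoms it
contains, since componenthood reaches the atoms transitively. The hand
pattern is compiled as written, which entails that a hand has at least one
finger; the known caveat (a hand that lost all fingers) is documented here
rather than patched into the axiom.

## Fixtures and the random suite

Molecule fixtures are composition-only: both propanol isomers carry the
C₃H₈O atom multiset and differ solely by label — distinguishing isomers
by bond topology is structure, not number, and is out of scope. Portions,
herds and plasma samples default to small grain counts (3–5) appropriate
for desk-scale checks; hands come in 4-, 5- and 6-finger variants, all
satisfying the flexible hand spec and none strictly.

The theorem suite checks irreflexivity, asymmetry and the two propagation
laws of `has_grain` by exhaustive evaluation over 500 seeded random
models of up to 8 entities (edges from lower to higher index at
probability 0.35, one or two labels per entity from a vocabulary with two
collective types, occasional explicit grain designations), plus the
galaxy fixture for the non-transitivity witness. Since the properties are
theorems of the definitions, any violation is a bug; the suite's role is
regression, and its seed is fixed for reproducibility.

What the synthetic models do not emulate: real ontologies' open-world
character, roles beyond mereology, continuous quantities and spatial
connection. Passing tests show the formal machinery behaves as specified
on discrete finite structures; they say nothing about the empirical
adequacy of any particular biomedical classification.

## Known limitations

* Positive oracle verdicts are bounded evidence, not proofs of
  entailment; the bound is configurable and reported in every verdict.
* The oracle's cost grows steeply with the size bound and vocabulary;
  size 5 with a four-type vocabulary is the practical desk-scale limit.
* Structure blindness: isomers are distinguished by label only.
* The external-reasoner cross-check needs the optional owlready2/HermiT
  stack; in its absence those checks skip rather than fail.
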