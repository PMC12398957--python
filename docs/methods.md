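# Methods

## Scope and data model

`chirdelta` operates on molecules with exactly one tetrahedral stereocenter,
represented as canonical isomeric SMILES.  The two enantiomers of a pair are
linked by their *pair key*, the stereo-depleted canonical SMILES they share.
Three binary labels live on each molecule, complementary within a pair:

| endpoint     | classes        | meaning                                    |
|--------------|----------------|--------------------------------------------|
| `cip`        | R / S          | CIP absolute configuration of the center   |
| `smiles_tag` | AT / ATAT      | `@` vs `@@` parity tag in canonical SMILES |
| `elution`    | First / Last   | order of elution of the pair on one column |

Canonicalization, stereo perception and CIP assignment delegate to RDKit;
CIP labels come from its full CIP-rules implementation (`rdCIPLabeler`),
not from parity heuristics.  Canonical SMILES strings are
toolkit-version-sensitive; pair keys and vector-file keys should therefore
be produced and consumed with the same RDKit version.

## Stereo operators

* `invert_enantiomer` flips every tetrahedral parity and re-canonicalizes;
  it is an involution, flips the CIP label, and commutes with stereo
  depletion (`strip ∘ invert = strip`).
* `strip_stereo` removes all stereo descriptors (tetrahedral and double
  bond) and canonicalizes; idempotent.
* `relabel_cip_aligned` rewrites a SMILES so its tag follows the convention
  `@` = S, `@@` = R **without changing the molecule**.  This exploits the
  fact that the written parity tag depends on the order in which the
  center's neighbors appear in the string: the function searches
  deterministic re-rootings (`rootedAtAtom = 0, 1, …`), then seeded atom
  renumberings, for a rewrite whose tag class matches, and verifies that
  the rewrite re-canonicalizes to the input.  The output is therefore
  generally non-canonical SMILES; it is intended as input to string-based
  encoders, letting one test how the labeling scheme (SMILES parity vs
  CIP) affects downstream models separately from the structure
  representation.

## Curation

Filters are applied in order, each drop logged with a reason code:
`flagged` (generic drop hook for upstream annotations, e.g. unclear
major/minor enantiomer assignments), `parse`, `element` (whitelist H, B, C,
N, O, F, P, S, Cl, Br, I), stereo profile (`no_stereocenter`,
`multi_stereocenter`, `stereo_type`), duplicates, and `orphan` (enantiomer
partner missing).

Stereo profile decisions: a molecule is kept only when it has exactly one
*assigned* tetrahedral center.  Unassigned-but-assignable tetrahedral
centers and assigned double-bond stereo cause rejection (`stereo_type`),
since extra stereo features would make pair membership ambiguous.
Potential but *unassigned* double-bond stereo is tolerated — it is
pervasive in real libraries and does not affect the parity tag.

Duplicates: rows with the same canonical SMILES are contradictory when they
carry different elution labels, or different retention times within the
same experiment; contradictory groups are dropped entirely.  Consistent
duplicates keep their first occurrence.  Retention orderings are never
compared across experiments; a cross-experiment consistency check would
require pairing first and is out of curation's scope.

## Descriptors

A backend is any deterministic map from SMILES to a fixed-length real
vector.  Built-ins:

* **Morgan count fingerprints** — radius 3, 512 positions, CIP-based
  chirality invariants, bond types and ring membership included, no count
  simulation.  Counts are integers, so `ori_opp` antisymmetry is exact.
* **External vectors** — a TSV of precomputed embeddings keyed by canonical
  SMILES, for heteroencoder latent-space vectors featurized outside the
  package.  `required_keys` pre-computes the complete key list (original +
  inverted + stereo-depleted SMILES) so one external pass suffices.
* **Mock embedder** (`synth`) — see below.

Delta descriptors may be negative (differences of counts); downstream
models must not assume non-negativity, and none of the bundled ones do.
Descriptors are used unscaled by default: random forests are insensitive to
monotone per-feature scaling, and keeping raw values preserves the exact
antisymmetry of `ori_opp`.  A stereo-blind backend yields all-zero deltas;
this is reported as a warning, not an error, because a zero delta is itself
an informative measurement of the backend.

## Splitting and leakage

Splits are uniform random selections of whole pairs (default 9:1 with
`round(n/10)` test pairs; an explicit `test_count` overrides the fraction,
e.g. 194 of 1929 pairs).  Keeping pairs intact is essential: with `ori`
descriptors, enantiomer embeddings are nearly identical, so letting one
member into training while testing on the other leaks almost the entire
answer.  `leak_one_enantiomer` constructs exactly that pathological split
on purpose (deterministically, the lexicographically smaller member of
each test pair moves to training; a seed makes the choice random), so the
effect can be measured: test accuracy collapses toward the out-of-bag
accuracy, which was depressed all along by the same mechanism — a
bootstrap that leaves a molecule out usually keeps its partner in.

## Models and metrics

The classifier is scikit-learn's random forest with `n_estimators = 100`,
`bootstrap = True`, `oob_score = True`, `random_state = 0`; all other
options at library defaults.  Tree counts 50/100/200/300 are the supported
sweep.  Class-probability ties at 0.5 resolve to the lexicographically
smaller class label so reported metrics are reproducible.  With fully
grown trees the predicted probability equals the fraction of tree votes.

Pair metrics (test set only): a pair is **correct** when both members get
their true labels, **undecided** when both get the same label, **wrong**
when both are swapped.  For complementary truths these three cases are
exhaustive and mutually exclusive, so correct + undecided + wrong = 100%.
"Test set accuracy" is molecule-level.  The replicate driver repeats the
whole grid over alternative split seeds and reports mean and standard
deviation per cell.

## Outliers and maps

An outlier pair has both members misclassified with winning-class
probability strictly greater than 0.8 ("exceeds" is read as a strict
inequality; a probability of exactly 0.8 does not qualify).  Each outlier
member is matched to its nearest training molecule by exact brute-force
Euclidean scan in the same descriptor space (backend + mode) the model was
trained in; ties resolve to the lowest training-row index.

t-SNE maps use 2 components, learning rate 200, PCA initialization,
perplexity 30, seed 0 (recorded in the output); the library requires at
least `3 × perplexity` rows, surfaced as a precondition.  The canonical
artifact is a CSV of coordinates plus all three labels (read it back with
`read_map` for bit-exact coordinates); a static scatter image is optional.
On small fixtures this learning rate produces tightly stacked clusters —
acceptable, since the maps are qualitative.

## Synthetic libraries

`generate_library` emulates the structure of a curated chiral-HPLC dataset:
`n_pairs` single-stereocenter molecules built from templates
`a[C@H](b)c`, with `{a, b, c}` an unordered combination of three distinct
fragments from a fixed 43-fragment alphabet over the allowed elements.
Scaffolds are deduplicated by pair key, validated against the same stereo
checks as curation, and emitted as both enantiomers with a shared
experiment id — so generated libraries pass `curate` without a single
drop.

Elution order is planted in descriptor space: a molecule is First when the
first nonzero component of its `ori_opp` delta under a fixed reference
mock embedder (32 dimensions, seed 0) is positive — a one-feature linear
threshold that a forest working on the same features can recover exactly.
`signal_strength` is the fraction of pairs following the rule (the rest
are coin flips); `noise_flip_rate` then flips each pair's labels
independently.  Defaults are `signal_strength = 1`, `noise_flip_rate = 0`:
a noiseless, fully learnable benchmark.  Retention times are a per-pair
base drawn uniformly from 2–18 min plus a 0.3–4 min gap for the Last
member, so `label_elution` reconstructs the planted labels.

The mock embedder hashes SMILES token bigrams (SHA-256 of seed + bigram →
seeded Gaussian pattern, position-weighted by `1/√(i+1)`) into a
fixed-dimension vector: deterministic across processes, training-free, and
stereo-sensitive because the `@`/`@@` tokens and their contexts contribute
distinct patterns.  `chiral_scale` shrinks exactly those contributions;
small values (e.g. 0.01) emulate realistic embeddings whose enantiomer
vectors nearly coincide, which is what makes the leakage experiment
reproduce its characteristic OOB/test-gap collapse.

What the generator does **not** emulate: real chromatographic physics, any
dependence of elution on mobile phase or temperature, the geometry of real
heteroencoder latent spaces, or structure–property relationships beyond
the planted rule.  Passing tests therefore demonstrate correctness of the
machinery (operators, pairing, splitting, metrics, leakage mechanics), not
predictive performance on real chiral chromatography data — for that, the
external-vector route and a measured dataset are required.

## Numerical and design choices

* Whitespace inside SMILES is stripped before parsing so typeset strings
  round-trip.
* Retention-time ties drop the pair rather than guessing an order; times
  are never compared across experiments.
* The 9:1 default rounds with `round(n/10)`; exact historical test counts
  are reproduced via explicit `test_count`.
* `ori_opp` antisymmetry is exact (0) for integer-count backends and
  bounded by 1e-9 per component for real-valued backends.
* Descriptor matrices and map CSVs store floats with 17 significant
  digits, which round-trips IEEE doubles exactly (use the provided readers;
  generic CSV float parsers are not exact).
* Problem sizes used by the test suite and the acceptance script — 200-pair
  sweeps for operator algebra, 500-pair benchmarks for learning behavior,
  one 1929-pair library for full-scale split accounting — keep every run
  deterministic and complete in seconds on a single CPU.

## Known limitations

* Molecules with multiple stereocenters, axial chirality or double-bond
  stereo as the property-carrying feature are out of scope by design.
* `relabel_cip_aligned` returns the first qualifying rewrite, which is
  deterministic but not unique; consumers should treat it as *a* valid
  CIP-aligned representation, not a canonical one.
* Pair-level metrics require complementary truths; endpoints without that
  structure would need a different partition of outcomes.
* The heteroencoders themselves are not bundled; their vectors enter only
  through the external-vector file.
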