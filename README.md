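# chirdelta

Delta descriptors of molecular chirality, with a pair-aware machine-learning
protocol for evaluating them.

## The problem

Most molecular descriptors cannot tell two enantiomers apart: mirror-image
molecules have identical graphs, so fingerprints and learned embeddings that
encode constitution alone give both members of a pair the same vector.  Yet
chirality-sensitive properties — most prominently the elution order of
enantiomers on a chiral HPLC column such as Chiralpak AD-H — differ between
the two.  Even embeddings that *do* see the stereo tag (SMILES-trained
heteroencoder latent-space vectors, chirality-aware Morgan fingerprints)
place enantiomers almost on top of each other, because the `@`/`@@` parity
tag is a tiny part of the input.

`chirdelta` amplifies the stereochemical component by latent-space
arithmetic.  For a molecule *m* with embedding *v(m)* it builds

* **ori** — the embedding itself, `v(m)`;
* **ori-opp** — the difference to the opposite enantiomer,
  `v(m) − v(ent(m))`;
* **ori-ns** — the difference to the stereo-depleted molecule,
  `v(m) − v(ns(m))`.

`ori-opp` descriptors are exactly antisymmetric within a pair:
`ori_opp(m) = −ori_opp(ent(m))`.

The evaluation protocol is built around enantiomer pairs.  Molecules are
curated to a single tetrahedral stereocenter and an element whitelist,
grouped into pairs by their stereo-depleted canonical SMILES, split 9:1 at
the pair level (both enantiomers always on the same side), and classified
with a random forest (100 trees, bootstrap, OOB scoring) on three binary
endpoints with complementary truth inside each pair: CIP label (R/S),
SMILES parity tag (@/@@), and elution order (First/Last).  Besides
molecule-level accuracy, each test pair is scored as **correct** (both
members right), **undecided** (both members assigned the same class — no
enantiodiscrimination at all) or **wrong** (both swapped); the three
percentages partition 100%.  High-confidence wrong pairs (both predicted
probabilities > 0.8) are flagged as outliers — typically "chirality
cliffs" — and matched to their nearest training molecule by Euclidean
distance in the same descriptor space; t-SNE maps visualize the descriptor
spaces with any of the three labelings.

Who it is for: cheminformaticians building enantioselective QSPR models
(chiral chromatography, absolute-configuration assignment) who need
chirality-aware descriptors and leakage-proof pair-level evaluation.

## Worked example

Everything is testable without downloads: the `synth` module generates
libraries of single-stereocenter enantiomer pairs with retention times whose
First/Last labels follow a planted rule in the `ori-opp` space of a
deterministic mock embedder.

```python
import chirdelta as cd
from chirdelta.modeling import RFConfig, run_endpoint_study
from chirdelta.synth import SyntheticSpec, generate_library, mock_embedder

frame = generate_library(SyntheticSpec(n_pairs=200, seed=0))
records, rejected = cd.curate(frame)
pairs, _ = cd.build_pairs(records)
pairs, _ = cd.label_all_elution(records, pairs)
split = cd.split_pairs(pairs, test_fraction=0.1, seed=0)
backend = mock_embedder(dimension=32, seed=0)
report = run_endpoint_study(records, pairs, split, backend,
                            mode="ori_opp", endpoint="elution", config=RFConfig())
print(f"molecules: {len(records)}  pairs: {len(pairs)}  "
      f"train/test pairs: {len(split.train_pair_keys)}/{len(split.test_pair_keys)}")
print(f"OOB accuracy:       {report.oob_accuracy:.3f}")
print(f"Test accuracy:      {report.test_accuracy:.3f}")
print(f"% correct pairs:    {report.pct_correct_pairs:.1f}")
print(f"% undecided pairs:  {report.pct_undecided_pairs:.1f}")
```

Output:

```
molecules: 400  pairs: 200  train/test pairs: 180/20
OOB accuracy:       1.000
Test accuracy:      1.000
% correct pairs:    100.0
% undecided pairs:  0.0
```

The library is noiseless and its elution rule lives in the very descriptor
space the model sees, so the forest recovers it exactly: every test pair is
correct, none undecided.  Lower `signal_strength` or raise
`noise_flip_rate` in `SyntheticSpec` to degrade this controllably; with
`signal_strength=0` the test accuracy drops to chance (~0.5).

The same pipeline runs from the shell:

```bash
chirdelta synth --n-pairs 200 --seed 0 --out library.csv
chirdelta curate library.csv --out curated.csv --rejected rejected.csv
chirdelta study curated.csv --backend mock --modes ori,ori-opp,ori-ns \
    --endpoints cip,smiles_tag,elution --test-fraction 0.1 --out report.csv
chirdelta outliers curated.csv --backend mock --test-fraction 0.1 --out outliers.csv
chirdelta map curated.csv --backend mock --mode ori-opp --color cip_label \
    --perplexity 20 --out map.csv --image map.png
```

Real embeddings plug in through two routes: `--backend morgan` uses
chirality-aware Morgan count fingerprints (radius 3, 512 positions)
computed in-process, and `--backend external --vectors FILE` loads
precomputed heteroencoder latent-space vectors keyed by canonical SMILES
(`chirdelta featurize --keys-out` writes the full list of original,
inverted and stereo-depleted SMILES keys such a file must cover).

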