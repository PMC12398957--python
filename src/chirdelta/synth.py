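"""Synthetic enantiomer libraries and a deterministic mock embedder.

Real chiral-HPLC libraries with measured elution orders are external and
large, so every stage of this package is exercised instead on generated
libraries that share their structure: single-stereocenter molecules in
enantiomer pairs, per-experiment retention times, and a class signal of
controllable strength.

Molecules are built from scaffold templates ``a[C@H](b)c`` whose three
substituents are drawn (as an unordered combination) from a fixed fragment
alphabet over the allowed element set, which guarantees chemical validity
and exactly one stereocenter.  Elution order is *planted*: a molecule is
First when the first component of its ``ori_opp`` delta under a fixed
reference mock embedder is positive — a linear threshold rule that a
classifier working in the same descriptor space can recover exactly.
``signal_strength`` scales how many pairs follow the rule,
``noise_flip_rate`` adds label noise on top; retention times are then
synthesized to agree with the labels.

The mock embedder hashes the token-bigram sequence of the SMILES string
into a fixed-dimension vector, so it is deterministic, training-free, and
stereo-sensitive: the ``@``/``@@`` tokens (and their contexts) contribute
distinct patterns, and a stereo-depleted string maps to a third vector.
The relative size of those chiral contributions is tunable via
``chiral_scale``, which makes it possible to emulate embeddings whose
enantiomer vectors are nearly — but not exactly — identical.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from rdkit import Chem

from . import chem
from .descriptors import EmbedderBackend

#: Substituent fragments (attached via their first atom when written as a
#: branch, via their last chain atom when written as the SMILES prefix).
#: All fragments use allowed elements only and introduce no extra
#: stereocenters or stereogenic double bonds.
FRAGMENT_ALPHABET = (
    "C", "CC", "CCC", "CC(C)C", "CCCC",
    "N", "NC", "NCC", "O", "OC", "OCC",
    "F", "Cl", "Br", "I",
    "C#N", "C(F)(F)F", "CO", "CN", "COC", "CCO", "CF", "CCl", "CBr",
    "C(=O)O", "C(=O)N", "C(=O)OC", "CC#N",
    "S", "SC", "CS",
    "c1ccccc1", "c1ccc(F)cc1", "c1ccc(Cl)cc1", "c1ccc(Br)cc1",
    "c1ccc(C)cc1", "c1ccc(OC)cc1", "c1ccc(C(F)(F)F)cc1",
    "c1ccncc1", "c1ccco1", "c1cccs1", "Cc1ccccc1", "OCc1ccccc1",
)

_TOKEN = re.compile(r"\[[^\]]*\]|Cl|Br|@@|@|\d|%\d\d|[A-Za-z=#\-\+\(\)/\\\.]")


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into atom/bond/ring tokens."""
    return _TOKEN.findall(smiles)


def _is_chiral_token(token: str) -> bool:
    return "@" in token


class MockEmbedder(EmbedderBackend):
    """Deterministic, training-free SMILES embedder for fixtures.

    The vector is the position-weighted sum of per-bigram unit-variance
    Gaussian patterns, each derived from a cryptographic hash of
    ``(seed, previous token, token)`` so results are stable across
    processes.  Bigrams touching a chirality token are scaled by
    *chiral_scale*: 1.0 gives a strongly stereo-sensitive embedding, small
    values emulate embeddings where the enantiomer difference is a tiny
    perturbation of the molecular embedding (as for real latent-space
    vectors).
    """

    def __init__(self, dimension: int = 32, seed: int = 0, chiral_scale: float = 1.0):
        if dimension < 2:
            raise ValueError("dimension must be >= 2")
        self.backend_id = f"mock_d{dimension}_s{seed}" + (
            "" if chiral_scale == 1.0 else f"_c{chiral_scale:g}"
        )
        self.dimension = dimension
        self.seed = seed
        self.chiral_scale = float(chiral_scale)
        self._patterns: dict[tuple[str, str], np.ndarray] = {}

    def _pattern(self, prev: str, token: str) -> np.ndarray:
        key = (prev, token)
        pat = self._patterns.get(key)
        if pat is None:
            digest = hashlib.sha256(
                f"{self.seed}|{prev}|{token}".encode()
            ).digest()
            sub_seed = int.from_bytes(digest[:4], "big")
            pat = np.random.default_rng(sub_seed).standard_normal(self.dimension)
            self._patterns[key] = pat
        return pat

    def embed(self, smiles: str) -> np.ndarray:
        tokens = tokenize(smiles)
        vec = np.zeros(self.dimension, dtype=np.float64)
        prev = "^"
        for i, token in enumerate(tokens):
            weight = 1.0 / np.sqrt(i + 1.0)
            if _is_chiral_token(token) or _is_chiral_token(prev):
                weight *= self.chiral_scale
            vec += weight * self._pattern(prev, token)
            prev = token
        return vec


def mock_embedder(dimension: int = 32, seed: int = 0, chiral_scale: float = 1.0) -> MockEmbedder:
    """Build a :class:`MockEmbedder` (see class docstring)."""
    return MockEmbedder(dimension=dimension, seed=seed, chiral_scale=chiral_scale)


#: Reference embedder defining the planted elution rule; fixed so libraries
#: generated with different seeds share one learnable rule.
RULE_DIMENSION = 32
RULE_SEED = 0


def planted_rule_backend() -> MockEmbedder:
    """The fixed reference embedder whose ori_opp space defines elution."""
    return mock_embedder(dimension=RULE_DIMENSION, seed=RULE_SEED)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic library.

    ``signal_strength`` is the fraction of pairs whose First/Last labels
    follow the planted descriptor rule (the rest are coin flips);
    ``noise_flip_rate`` independently flips each pair's final labels.  The
    defaults produce a fully rule-determined, noise-free library.
    """

    n_pairs: int
    seed: int = 0
    signal_strength: float = 1.0
    noise_flip_rate: float = 0.0

    def __post_init__(self):
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must lie in [0, 1]")
        if not 0.0 <= self.noise_flip_rate <= 1.0:
            raise ValueError("noise_flip_rate must lie in [0, 1]")


def _candidate_scaffolds(rng: np.random.Generator) -> list[tuple[str, str, str]]:
    combos = list(combinations(FRAGMENT_ALPHABET, 3))
    rng.shuffle(combos)
    return combos


def _build_molecule(a: str, b: str, c: str) -> str | None:
    """Assemble one enantiomer from three substituents; None when invalid."""
    smiles = f"{a}[C@H]({b}){c}"
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    can = Chem.MolToSmiles(mol)
    if "@" not in can:
        return None  # center collapsed to non-stereogenic
    if chem._stereo_reason(Chem.MolFromSmiles(can)) is not None:
        return None
    return can


def generate_library(spec: SyntheticSpec) -> pd.DataFrame:
    """Generate a raw library table that passes curation without any drop.

    Returns a frame with columns ``smiles, retention_time, experiment_id``,
    two rows (the two enantiomers, one shared experiment) per pair.  Pair
    member labeled First receives the smaller retention time.  Output is
    deterministic for a given *spec*.
    """
    rng = np.random.default_rng(spec.seed)
    rule = planted_rule_backend()
    rows = []
    seen_pair_keys: set[str] = set()
    n_done = 0
    for a, b, c in _candidate_scaffolds(rng):
        if n_done >= spec.n_pairs:
            break
        s1 = _build_molecule(a, b, c)
        if s1 is None:
            continue
        pair_key = chem.strip_stereo(s1)
        if pair_key in seen_pair_keys:
            continue  # same molecule reachable from another combination
        s2 = chem.invert_enantiomer(s1)
        if s1 == s2:
            continue
        seen_pair_keys.add(pair_key)

        delta = rule.embed(s1) - rule.embed(s2)
        nonzero = np.flatnonzero(delta)
        rule_first_is_s1 = bool(delta[nonzero[0]] > 0) if nonzero.size else True
        if rng.random() >= spec.signal_strength:
            rule_first_is_s1 = bool(rng.random() < 0.5)
        if rng.random() < spec.noise_flip_rate:
            rule_first_is_s1 = not rule_first_is_s1

        base = float(rng.uniform(2.0, 18.0))
        gap = float(rng.uniform(0.3, 4.0))
        t1 = base if rule_first_is_s1 else base + gap
        t2 = base + gap if rule_first_is_s1 else base
        exp_id = f"EXP{n_done:05d}"
        rows.append((s1, round(t1, 3), exp_id))
        rows.append((s2, round(t2, 3), exp_id))
        n_done += 1
    if n_done < spec.n_pairs:
        raise ValueError(
            f"fragment alphabet exhausted at {n_done} pairs; "
            f"{spec.n_pairs} requested"
        )
    return pd.DataFrame(rows, columns=["smiles", "retention_time", "experiment_id"])


def write_library(frame: pd.DataFrame, path) -> None:
    """Write a library CSV in the exact dialect the curation stage reads."""
    frame.to_csv(path, index=False, float_format="%.3f")
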