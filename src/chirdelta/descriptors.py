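"""Descriptor computation over pluggable embedding backends.

A backend maps a SMILES string to a fixed-length real vector: the built-in
Morgan count-fingerprint backend, an external-file backend for precomputed
latent-space vectors (LSVs) from SMILES heteroencoders, or the mock
embedder from :mod:`chirdelta.synth`.  On top of any backend three
descriptor modes are defined for a chiral molecule ``m``:

* ``ori``      — the embedding ``v(m)`` itself;
* ``ori_opp``  — ``v(m) - v(enantiomer(m))``, antisymmetric within a pair;
* ``ori_ns``   — ``v(m) - v(stereo_depleted(m))``.

The delta modes amplify the (usually tiny) stereochemical component of the
embedding; ``ori_opp`` vectors of the two members of an enantiomer pair are
exact negatives of each other.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdCIPLabeler, rdFingerprintGenerator

from . import chem
from .errors import DimensionMismatchError, MissingKeyError, ParseError

MODES = ("ori", "ori_opp", "ori_ns")


def normalize_mode(mode: str) -> str:
    """Accept ``ori-opp``/``ori_ns`` spellings interchangeably."""
    m = mode.replace("-", "_")
    if m not in MODES:
        raise ValueError(f"unknown descriptor mode {mode!r}; expected one of {MODES}")
    return m


class EmbedderBackend:
    """Contract: a deterministic map from SMILES to a fixed-length vector."""

    backend_id: str
    dimension: int

    def embed(self, smiles: str) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class MorganBackend(EmbedderBackend):
    """Count-based Morgan (extended-connectivity) fingerprints.

    Defaults follow the standard chirality-aware configuration: radius 3,
    512 positions, CIP-based stereo invariants included, bond types and
    ring membership in the invariants, no count simulation.  Counts are
    non-negative integers returned as floats.
    """

    def __init__(
        self,
        radius: int = 3,
        fp_size: int = 512,
        include_chirality: bool = True,
    ):
        self.backend_id = (
            f"morgan_r{radius}_n{fp_size}" + ("" if include_chirality else "_achiral")
        )
        self.dimension = fp_size
        self.include_chirality = include_chirality
        self._gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius,
            fpSize=fp_size,
            includeChirality=include_chirality,
            useBondTypes=True,
            includeRingMembership=True,
            countSimulation=False,
        )

    def embed(self, smiles: str) -> np.ndarray:
        mol = chem._parse(smiles)
        if self.include_chirality:
            # stereo invariants are taken from full CIP labels
            rdCIPLabeler.AssignCIPLabels(mol)
        fp = self._gen.GetCountFingerprint(mol)
        vec = np.zeros(self.dimension, dtype=np.float64)
        for idx, count in fp.GetNonzeroElements().items():
            vec[idx] = count
        return vec


def morgan_backend(
    radius: int = 3, fp_size: int = 512, include_chirality: bool = True
) -> MorganBackend:
    """Build the Morgan count-fingerprint backend (see :class:`MorganBackend`)."""
    return MorganBackend(radius=radius, fp_size=fp_size, include_chirality=include_chirality)


_HEADER = re.compile(r"#\s*backend_id=(\S+)\s+dimension=(\d+)")


class ExternalVectorBackend(EmbedderBackend):
    """Precomputed vectors keyed by canonical SMILES, loaded from a TSV file.

    File layout::

        #backend_id=<id> dimension=<d>
        <smiles>\\t<v1>\\t...\\t<vd>

    Lookups are exact string matches on canonical SMILES, which is how
    externally featurized heteroencoder LSVs are plugged in.
    """

    def __init__(self, backend_id: str, vectors: dict[str, np.ndarray]):
        self.backend_id = backend_id
        if not vectors:
            raise ValueError("external backend needs at least one vector")
        dims = {v.shape[0] for v in vectors.values()}
        if len(dims) != 1:
            raise DimensionMismatchError(f"mixed vector lengths {sorted(dims)}")
        self.dimension = dims.pop()
        self._vectors = vectors

    def embed(self, smiles: str) -> np.ndarray:
        try:
            return self._vectors[smiles]
        except KeyError:
            raise MissingKeyError(smiles, self.backend_id) from None

    def __contains__(self, smiles: str) -> bool:
        return smiles in self._vectors


def external_vector_backend(path) -> ExternalVectorBackend:
    """Load an :class:`ExternalVectorBackend` from its TSV file."""
    with open(path) as fh:
        header = fh.readline()
        m = _HEADER.match(header)
        if not m:
            raise ValueError(f"bad vector-file header: {header!r}")
        backend_id, dim = m.group(1), int(m.group(2))
        vectors: dict[str, np.ndarray] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            key, vals = parts[0], parts[1:]
            if len(vals) != dim:
                raise DimensionMismatchError(
                    f"line {lineno}: {len(vals)} values, header says {dim}"
                )
            vectors[key] = np.array([float(v) for v in vals], dtype=np.float64)
    return ExternalVectorBackend(backend_id, vectors)


@dataclass
class DescriptorMatrix:
    """Descriptor vectors aligned to a record list.

    ``values[i]`` is the descriptor of the molecule with canonical SMILES
    ``row_keys[i]``; *mode* and *backend_id* record how it was computed.
    """

    backend_id: str
    mode: str
    row_keys: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.mode = normalize_mode(self.mode)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.row_keys):
            raise DimensionMismatchError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.row_keys)} row keys"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("descriptor matrix contains non-finite values")
        self._index = {k: i for i, k in enumerate(self.row_keys)}

    @property
    def dimension(self) -> int:
        return self.values.shape[1]

    def row(self, smiles: str) -> np.ndarray:
        try:
            return self.values[self._index[smiles]]
        except KeyError:
            raise MissingKeyError(smiles, self.backend_id) from None

    def subset(self, keys: Sequence[str]) -> "DescriptorMatrix":
        idx = [self._index[k] for k in keys]
        return DescriptorMatrix(
            self.backend_id, self.mode, tuple(keys), self.values[idx]
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"#backend_id={self.backend_id} dimension={self.dimension} "
                f"mode={self.mode}\n"
            )
            for key, row in zip(self.row_keys, self.values):
                fh.write(key + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "DescriptorMatrix":
        with open(path) as fh:
            header = fh.readline()
            m = re.match(
                r"#\s*backend_id=(\S+)\s+dimension=(\d+)\s+mode=(\S+)", header
            )
            if not m:
                raise ValueError(f"bad descriptor-matrix header: {header!r}")
            backend_id, dim, mode = m.group(1), int(m.group(2)), m.group(3)
            keys, rows = [], []
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) - 1 != dim:
                    raise DimensionMismatchError(
                        f"row has {len(parts) - 1} values, header says {dim}"
                    )
                keys.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        return cls(backend_id, mode, tuple(keys), np.array(rows, dtype=np.float64))


def required_keys(records: Iterable, modes: Iterable[str] = MODES) -> list[str]:
    """All SMILES keys an external backend must answer to featurize *records*.

    Includes, per requested mode, the canonical SMILES, the enantiomer's
    canonical SMILES (``ori_opp``) and the stereo-depleted SMILES
    (``ori_ns``), deduplicated in first-seen order.  Write this list out
    before featurizing with an external heteroencoder so one external pass
    covers every derived key.
    """
    modes = {normalize_mode(m) for m in modes}
    seen: dict[str, None] = {}
    for rec in records:
        s = rec.smiles_canonical if hasattr(rec, "smiles_canonical") else str(rec)
        seen.setdefault(s)
        if "ori_opp" in modes:
            seen.setdefault(chem.invert_enantiomer(s))
        if "ori_ns" in modes:
            seen.setdefault(chem.strip_stereo(s))
    return list(seen)


def compute_descriptors(records, backend: EmbedderBackend, mode: str) -> DescriptorMatrix:
    """Compute the descriptor matrix for *records* under *backend* and *mode*.

    Row order follows the input record order; row keys are canonical SMILES.
    For delta modes a stereo-blind backend (identical embeddings for both
    enantiomers) yields an all-zero matrix, which is reported as a warning
    rather than an error — zero deltas are informative about the backend.
    """
    mode = normalize_mode(mode)
    keys, rows = [], []
    for rec in records:
        s = rec.smiles_canonical if hasattr(rec, "smiles_canonical") else str(rec)
        v = backend.embed(s)
        if mode == "ori":
            row = v
        elif mode == "ori_opp":
            row = v - backend.embed(chem.invert_enantiomer(s))
        else:
            row = v - backend.embed(chem.strip_stereo(s))
        keys.append(s)
        rows.append(np.asarray(row, dtype=np.float64))
    values = np.vstack(rows) if rows else np.zeros((0, backend.dimension))
    if mode != "ori" and len(rows) and not values.any():
        warnings.warn(
            f"backend {backend.backend_id!r} appears stereo-blind: all "
            f"{mode} descriptors are zero",
            stacklevel=2,
        )
    return DescriptorMatrix(backend.backend_id, mode, tuple(keys), values)
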