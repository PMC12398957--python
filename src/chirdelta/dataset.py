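"""Enantiomer-pair construction, elution labeling and pair-aware splitting.

Random train/test splitting is done at the *pair* level: the two
enantiomers of a pair always travel together, so the test set is made
entirely of complete pairs and pair-level metrics are well defined.  The
one deliberate exception is :func:`leak_one_enantiomer`, which moves one
member of each test pair into the training set to study how enantiomer
leakage inflates test accuracy relative to the out-of-bag estimate.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem import MoleculeRecord
from .errors import MissingDataError, TieError

ELUTION_LABELS = ("First", "Last")


@dataclass(frozen=True)
class EnantiomerPair:
    """Indices of the two records forming one enantiomer pair.

    Members are ordered by canonical SMILES so the pair layout is
    deterministic; ``pair_key`` is their shared stereo-depleted canonical
    SMILES.
    """

    pair_key: str
    member_first_index: int
    member_second_index: int

    def indices(self) -> tuple[int, int]:
        return (self.member_first_index, self.member_second_index)


@dataclass(frozen=True)
class SplitAssignment:
    """A pair-level train/test partition (reproducible from *seed*)."""

    seed: int
    train_pair_keys: frozenset
    test_pair_keys: frozenset

    def partition_of(self, pair_key: str) -> str:
        if pair_key in self.train_pair_keys:
            return "train"
        if pair_key in self.test_pair_keys:
            return "test"
        raise KeyError(pair_key)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["pair_key", "partition", "seed"])
            for key in sorted(self.train_pair_keys):
                w.writerow([key, "train", self.seed])
            for key in sorted(self.test_pair_keys):
                w.writerow([key, "test", self.seed])

    @classmethod
    def from_csv(cls, path) -> "SplitAssignment":
        frame = pd.read_csv(path)
        seed = int(frame["seed"].iloc[0])
        train = frozenset(frame.loc[frame.partition == "train", "pair_key"])
        test = frozenset(frame.loc[frame.partition == "test", "pair_key"])
        return cls(seed, train, test)


@dataclass(frozen=True)
class LeakedSplit:
    """Record-level split produced by :func:`leak_one_enantiomer`.

    The test side holds single molecules (one per former test pair), so
    pair-level metrics are undefined on it.
    """

    base: SplitAssignment
    train_smiles: frozenset
    test_smiles: tuple


def build_pairs(
    records: Sequence[MoleculeRecord],
) -> tuple[list[EnantiomerPair], pd.DataFrame]:
    """Group records into enantiomer pairs by their shared pair key.

    Every group must contain exactly two distinct stereoisomers with
    opposite CIP labels; other groups are rejected with a reason
    (``group_size`` or ``not_enantiomers``), never silently.
    """
    by_key: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        by_key.setdefault(rec.pair_key, []).append(i)
    pairs, rejected = [], []
    for key, idxs in by_key.items():
        if len(idxs) != 2:
            for i in idxs:
                rejected.append((key, records[i].smiles_canonical, "group_size"))
            continue
        a, b = sorted(idxs, key=lambda i: records[i].smiles_canonical)
        ra, rb = records[a], records[b]
        if ra.smiles_canonical == rb.smiles_canonical or ra.cip_label == rb.cip_label:
            for i in (a, b):
                rejected.append((key, records[i].smiles_canonical, "not_enantiomers"))
            continue
        pairs.append(EnantiomerPair(key, a, b))
    rejections = pd.DataFrame(rejected, columns=["pair_key", "smiles", "reason"])
    return pairs, rejections


def label_elution(
    pair: EnantiomerPair, records: Sequence[MoleculeRecord]
) -> tuple[str, str]:
    """Assign First/Last elution labels to a pair from its retention times.

    Both members must carry retention times measured in the same
    experiment; the smaller time elutes First.  Ties raise
    :class:`TieError` (the pair should then be dropped rather than ordered
    arbitrarily); missing times or mismatched experiments raise
    :class:`MissingDataError`.  Labels are written onto the records and
    also returned ``(label_first_member, label_second_member)``.
    """
    ra = records[pair.member_first_index]
    rb = records[pair.member_second_index]
    if ra.retention_time is None or rb.retention_time is None:
        raise MissingDataError(f"pair {pair.pair_key!r}: missing retention time")
    if ra.experiment_id is None or ra.experiment_id != rb.experiment_id:
        raise MissingDataError(
            f"pair {pair.pair_key!r}: retention times not from one experiment"
        )
    if ra.retention_time == rb.retention_time:
        raise TieError(f"pair {pair.pair_key!r}: equal retention times")
    la, lb = ("First", "Last") if ra.retention_time < rb.retention_time else ("Last", "First")
    ra.elution_label, rb.elution_label = la, lb
    return la, lb


def label_all_elution(
    records: Sequence[MoleculeRecord], pairs: Sequence[EnantiomerPair]
) -> tuple[list[EnantiomerPair], pd.DataFrame]:
    """Label every pair, dropping (with reasons) those that cannot be labeled."""
    kept, dropped = [], []
    for pair in pairs:
        try:
            label_elution(pair, records)
        except TieError:
            dropped.append((pair.pair_key, "tie"))
        except MissingDataError:
            dropped.append((pair.pair_key, "missing_data"))
        else:
            kept.append(pair)
    return kept, pd.DataFrame(dropped, columns=["pair_key", "reason"])


def split_pairs(
    pairs: Sequence[EnantiomerPair],
    test_fraction: Optional[float] = None,
    test_count: Optional[int] = None,
    seed: int = 0,
) -> SplitAssignment:
    """Randomly assign whole pairs to train/test.

    An explicit *test_count* overrides *test_fraction*; the default is a
    9:1 split with ``round(n / 10)`` test pairs.  Selection is uniform
    without replacement and reproducible from *seed*.
    """
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least 2 pairs to split")
    if test_count is None:
        frac = 0.1 if test_fraction is None else float(test_fraction)
        test_count = int(round(n * frac))
    if not 0 < test_count < n:
        raise ValueError(f"test_count={test_count} must be in (0, {n})")
    rng = np.random.default_rng(seed)
    test_idx = set(rng.choice(n, size=test_count, replace=False).tolist())
    test_keys = frozenset(pairs[i].pair_key for i in test_idx)
    train_keys = frozenset(p.pair_key for p in pairs) - test_keys
    return SplitAssignment(seed, train_keys, frozenset(test_keys))


def leak_one_enantiomer(
    split: SplitAssignment | LeakedSplit,
    pairs: Sequence[EnantiomerPair],
    records: Sequence[MoleculeRecord],
    seed: Optional[int] = None,
) -> LeakedSplit:
    """Move one member of every test pair into the training set.

    By default the lexicographically smaller canonical SMILES of each test
    pair moves to training; passing *seed* picks the member at random per
    pair instead.  Idempotent: a :class:`LeakedSplit` is returned as is.
    """
    if isinstance(split, LeakedSplit):
        return split
    rng = np.random.default_rng(seed) if seed is not None else None
    train = {
        records[i].smiles_canonical
        for p in pairs
        if p.pair_key in split.train_pair_keys
        for i in p.indices()
    }
    test = []
    for p in sorted(
        (p for p in pairs if p.pair_key in split.test_pair_keys),
        key=lambda p: p.pair_key,
    ):
        a, b = p.indices()  # ordered by canonical SMILES already
        if rng is not None and rng.random() < 0.5:
            a, b = b, a
        train.add(records[a].smiles_canonical)
        test.append(records[b].smiles_canonical)
    return LeakedSplit(split, frozenset(train), tuple(test))
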