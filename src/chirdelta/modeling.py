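"""Random-forest classification of chirality endpoints and pair-level metrics.

Three binary endpoints are supported, each with complementary truth inside
an enantiomer pair:

* ``cip``        — CIP absolute configuration, R vs S;
* ``smiles_tag`` — parity tag of the canonical SMILES, @ (AT) vs @@ (ATAT);
* ``elution``    — chromatographic elution order, First vs Last.

Because truths are complementary, a test pair can end up in exactly one of
three states: *correct* (both members right), *undecided* (both members
given the same class — the model makes no enantiodiscrimination) or
*wrong* (both members swapped).  The three percentages partition 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .chem import MoleculeRecord
from .dataset import EnantiomerPair, LeakedSplit, SplitAssignment
from .descriptors import DescriptorMatrix, EmbedderBackend, compute_descriptors
from .errors import DimensionMismatchError, MissingDataError, MissingPredictionError

SUPPORTED_TREE_COUNTS = (50, 100, 200, 300)

ENDPOINTS: dict[str, Callable[[MoleculeRecord], Optional[str]]] = {
    "cip": lambda r: r.cip_label,
    "smiles_tag": lambda r: r.stereo_tag,
    "elution": lambda r: r.elution_label,
}


@dataclass(frozen=True)
class RFConfig:
    """Random-forest settings; everything else stays at library defaults."""

    n_trees: int = 100
    bootstrap: bool = True
    compute_oob: bool = True
    random_seed: int = 0

    def __post_init__(self):
        if self.n_trees <= 0:
            raise ValueError("n_trees must be positive")


@dataclass
class EvaluationReport:
    """One endpoint x descriptor-mode x backend evaluation.

    Accuracies are fractions in [0, 1]; pair percentages are on the 0-100
    scale and sum to 100.  Pair metrics are ``None`` for record-level
    (leaked) splits, where the test set holds single molecules.
    """

    endpoint: str
    descriptor_mode: str
    backend_id: str
    oob_accuracy: Optional[float]
    test_accuracy: float
    pct_correct_pairs: Optional[float]
    pct_undecided_pairs: Optional[float]
    pct_wrong_pairs: Optional[float]
    n_train: int = 0
    n_test: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def train_rf(
    X: np.ndarray, y: Sequence[str], config: RFConfig = RFConfig()
) -> tuple[RandomForestClassifier, Optional[float]]:
    """Fit a random forest and return it with its out-of-bag accuracy.

    The OOB accuracy aggregates, for each training object, the votes of
    the trees whose bootstrap sample left that object out.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; nothing to learn")
    if len(y) != X.shape[0]:
        raise ValueError("row count and label count differ")
    clf = RandomForestClassifier(
        n_estimators=config.n_trees,
        bootstrap=config.bootstrap,
        oob_score=config.compute_oob and config.bootstrap,
        random_state=config.random_seed,
    )
    clf.fit(X, y)
    oob = float(clf.oob_score_) if config.compute_oob and config.bootstrap else None
    return clf, oob


def predict_with_proba(
    model: RandomForestClassifier, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predict hard labels and class probabilities.

    Probabilities sum to one per row; the hard label is the argmax with
    ties broken toward the lexicographically smaller class label (the
    classifier's class order is sorted, so the first maximum wins).
    """
    if X.shape[1] != model.n_features_in_:
        raise DimensionMismatchError(
            f"matrix has {X.shape[1]} columns, model expects {model.n_features_in_}"
        )
    proba = model.predict_proba(X)
    classes = np.asarray(model.classes_)
    labels = classes[np.argmax(proba, axis=1)]
    return labels, proba, classes


@dataclass(frozen=True)
class PairMetrics:
    pct_correct: float
    pct_undecided: float
    pct_wrong: float
    n_pairs: int


def evaluate_pairs(
    predictions: Mapping[str, str],
    pairs: Sequence[tuple[str, str]],
    truth: Mapping[str, str],
) -> PairMetrics:
    """Classify each test pair as correct / undecided / wrong.

    *pairs* lists the two member keys of each pair; *truth* must be
    complementary within every pair.  Correct: both members predicted with
    their true labels.  Undecided: both members got the same predicted
    label.  Wrong: labels complementary but swapped.  The three
    percentages partition 100%.
    """
    if not pairs:
        raise ValueError("no pairs to evaluate")
    n_correct = n_undecided = n_wrong = 0
    for a, b in pairs:
        for key in (a, b):
            if key not in predictions:
                raise MissingPredictionError(key)
        ta, tb = truth[a], truth[b]
        if ta == tb:
            raise ValueError(f"pair ({a!r}, {b!r}) has non-complementary truths")
        pa, pb = predictions[a], predictions[b]
        if pa == pb:
            n_undecided += 1
        elif pa == ta and pb == tb:
            n_correct += 1
        else:
            n_wrong += 1
    n = len(pairs)
    return PairMetrics(
        100.0 * n_correct / n, 100.0 * n_undecided / n, 100.0 * n_wrong / n, n
    )


def _labels_for(records, indices, endpoint):
    getter = ENDPOINTS[endpoint]
    out = []
    for i in indices:
        label = getter(records[i])
        if label is None:
            raise MissingDataError(
                f"record {records[i].smiles_canonical!r} lacks a {endpoint} label"
            )
        out.append(label)
    return out


def run_endpoint_study(
    records: Sequence[MoleculeRecord],
    pairs: Sequence[EnantiomerPair],
    split: SplitAssignment | LeakedSplit,
    backend: EmbedderBackend,
    mode: str,
    endpoint: str,
    config: RFConfig = RFConfig(),
    matrix: Optional[DescriptorMatrix] = None,
) -> EvaluationReport:
    """Featurize, train and evaluate one endpoint/mode/backend combination.

    With a pair-level :class:`SplitAssignment` the report carries OOB and
    test accuracy plus the pair-level percentages; with a record-level
    :class:`LeakedSplit` pair metrics are disabled.  A precomputed
    *matrix* (matching backend and mode) can be passed to avoid
    re-featurizing in grid studies.
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}; expected {tuple(ENDPOINTS)}")
    if matrix is None:
        matrix = compute_descriptors(records, backend, mode)

    if isinstance(split, LeakedSplit):
        train_idx = [
            i for i, r in enumerate(records) if r.smiles_canonical in split.train_smiles
        ]
        test_idx = [
            i for i, r in enumerate(records) if r.smiles_canonical in set(split.test_smiles)
        ]
        test_pairs = None
    else:
        train_idx = [
            i
            for p in pairs
            if p.pair_key in split.train_pair_keys
            for i in p.indices()
        ]
        test_idx = [
            i for p in pairs if p.pair_key in split.test_pair_keys for i in p.indices()
        ]
        test_pairs = [
            (
                records[p.member_first_index].smiles_canonical,
                records[p.member_second_index].smiles_canonical,
            )
            for p in pairs
            if p.pair_key in split.test_pair_keys
        ]

    train_keys = [records[i].smiles_canonical for i in train_idx]
    test_keys = [records[i].smiles_canonical for i in test_idx]
    X_train = matrix.subset(train_keys).values
    X_test = matrix.subset(test_keys).values
    y_train = _labels_for(records, train_idx, endpoint)
    y_test = _labels_for(records, test_idx, endpoint)

    model, oob = train_rf(X_train, y_train, config)
    pred_labels, _, _ = predict_with_proba(model, X_test)
    test_accuracy = float(np.mean(pred_labels == np.asarray(y_test)))

    if test_pairs is None:
        pm = None
    else:
        predictions = dict(zip(test_keys, pred_labels))
        truth = dict(zip(test_keys, y_test))
        pm = evaluate_pairs(predictions, test_pairs, truth)

    return EvaluationReport(
        endpoint=endpoint,
        descriptor_mode=matrix.mode,
        backend_id=matrix.backend_id,
        oob_accuracy=oob,
        test_accuracy=test_accuracy,
        pct_correct_pairs=None if pm is None else pm.pct_correct,
        pct_undecided_pairs=None if pm is None else pm.pct_undecided,
        pct_wrong_pairs=None if pm is None else pm.pct_wrong,
        n_train=len(train_idx),
        n_test=len(test_idx),
    )


def run_study(
    records: Sequence[MoleculeRecord],
    pairs: Sequence[EnantiomerPair],
    split: SplitAssignment | LeakedSplit,
    backends: Mapping[str, EmbedderBackend],
    modes: Sequence[str],
    endpoints: Sequence[str],
    config: RFConfig = RFConfig(),
) -> pd.DataFrame:
    """Run the endpoints x modes x backends grid on one split.

    Descriptor matrices are computed once per (backend, mode) cell and
    shared across endpoints.  Returns one report row per cell.
    """
    rows = []
    for backend in backends.values():
        for mode in modes:
            matrix = compute_descriptors(records, backend, mode)
            for endpoint in endpoints:
                report = run_endpoint_study(
                    records, pairs, split, backend, mode, endpoint, config, matrix
                )
                rows.append(report.as_dict())
    return pd.DataFrame(rows)


def run_split_replicates(
    records: Sequence[MoleculeRecord],
    pairs: Sequence[EnantiomerPair],
    backends: Mapping[str, EmbedderBackend],
    modes: Sequence[str],
    endpoints: Sequence[str],
    config: RFConfig = RFConfig(),
    split_seeds: Sequence[int] = (0, 1, 2, 3, 4),
    test_fraction: Optional[float] = None,
    test_count: Optional[int] = None,
) -> pd.DataFrame:
    """Replicate the full grid over alternative random splits.

    Returns the per-replicate rows; use :func:`summarize_replicates` for
    the mean/standard-deviation table across splits.
    """
    from .dataset import split_pairs

    frames = []
    for seed in split_seeds:
        split = split_pairs(
            pairs, test_fraction=test_fraction, test_count=test_count, seed=seed
        )
        frame = run_study(records, pairs, split, backends, modes, endpoints, config)
        frame["split_seed"] = seed
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def summarize_replicates(replicates: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation per grid cell across split replicates."""
    metrics = [
        "oob_accuracy",
        "test_accuracy",
        "pct_correct_pairs",
        "pct_undecided_pairs",
        "pct_wrong_pairs",
    ]
    grouped = replicates.groupby(["endpoint", "descriptor_mode", "backend_id"])[metrics]
    summary = grouped.agg(["mean", "std"])
    summary.columns = ["_".join(c) for c in summary.columns]
    return summary.reset_index()
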