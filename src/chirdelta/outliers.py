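"""High-confidence wrong pairs and their nearest training-set neighbors.

An enantiomer pair is an *outlier* of a classification model when both
members are misclassified and both predictions are made with winning-class
probability strictly above a threshold (default 0.8).  Such pairs tend to
be "chirality cliffs": a very similar training molecule with a similar
configuration but the opposite observed behavior pulls both predictions
the wrong way.  To surface the likely culprit, each outlier member is
matched to its nearest training molecule by Euclidean distance in the same
descriptor space the model was trained in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyTrainingSetError, MissingPredictionError

DEFAULT_PROBABILITY_THRESHOLD = 0.8


@dataclass(frozen=True)
class OutlierPair:
    """One high-confidence wrong pair: member keys with their predictions."""

    pair_key: Optional[str]
    members: tuple[str, str]
    predicted: tuple[str, str]
    true: tuple[str, str]
    probabilities: tuple[float, float]


def find_outlier_pairs(
    pairs: Sequence[tuple[str, str]],
    predictions: Mapping[str, str],
    probabilities: Mapping[str, float],
    truth: Mapping[str, str],
    threshold: float = DEFAULT_PROBABILITY_THRESHOLD,
    pair_keys: Optional[Sequence[str]] = None,
) -> list[OutlierPair]:
    """Return pairs where both members are confidently misclassified.

    *probabilities* maps each member key to the probability of its
    *predicted* (winning) class.  Both members must be wrong and both
    probabilities strictly greater than *threshold*; a probability exactly
    equal to the threshold does not qualify.
    """
    out = []
    for i, (a, b) in enumerate(pairs):
        for key in (a, b):
            if key not in predictions or key not in probabilities:
                raise MissingPredictionError(key)
        both_wrong = predictions[a] != truth[a] and predictions[b] != truth[b]
        both_confident = probabilities[a] > threshold and probabilities[b] > threshold
        if both_wrong and both_confident:
            out.append(
                OutlierPair(
                    pair_key=None if pair_keys is None else pair_keys[i],
                    members=(a, b),
                    predicted=(predictions[a], predictions[b]),
                    true=(truth[a], truth[b]),
                    probabilities=(probabilities[a], probabilities[b]),
                )
            )
    return out


def nearest_training_neighbor(
    query_row: np.ndarray, training_matrix: np.ndarray
) -> tuple[int, float]:
    """Index and distance of the closest training row (exact scan).

    The full Euclidean distance profile is computed — no approximate
    index — and ties resolve to the lowest row index.
    """
    training_matrix = np.asarray(training_matrix, dtype=np.float64)
    if training_matrix.size == 0 or training_matrix.shape[0] == 0:
        raise EmptyTrainingSetError("training matrix has no rows")
    query = np.asarray(query_row, dtype=np.float64).reshape(-1)
    if query.shape[0] != training_matrix.shape[1]:
        raise ValueError(
            f"query has {query.shape[0]} components, training rows have "
            f"{training_matrix.shape[1]}"
        )
    dists = np.linalg.norm(training_matrix - query, axis=1)
    idx = int(np.argmin(dists))  # argmin returns the first (lowest) index on ties
    return idx, float(dists[idx])


def outlier_report(
    outliers: Sequence[OutlierPair],
    test_vectors: Mapping[str, np.ndarray],
    training_matrix: np.ndarray,
    training_keys: Sequence[str],
) -> pd.DataFrame:
    """Tabulate outlier members with their nearest training molecules.

    Distances are computed in the same descriptor space (backend + mode)
    used by the inspected model, one row per outlier member.
    """
    rows = []
    for op in outliers:
        for j, member in enumerate(op.members):
            idx, dist = nearest_training_neighbor(test_vectors[member], training_matrix)
            rows.append(
                {
                    "pair_key": op.pair_key,
                    "smiles": member,
                    "true_label": op.true[j],
                    "predicted_label": op.predicted[j],
                    "probability": op.probabilities[j],
                    "nearest_train_smiles": training_keys[idx],
                    "euclidean_distance": dist,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "pair_key",
            "smiles",
            "true_label",
            "predicted_label",
            "probability",
            "nearest_train_smiles",
            "euclidean_distance",
        ],
    )
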