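"""2-D t-SNE projection of descriptor matrices with labeled CSV export.

The map places each molecule at its t-SNE coordinates so that structurally
similar descriptors land close together; coloring the points by CIP label,
SMILES parity tag or elution order shows how strongly each labeling is
expressed in a given descriptor space.  The canonical artifact is a CSV
(coordinates + all three labels); a static scatter image is optional.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem import MoleculeRecord
from .descriptors import DescriptorMatrix
from .errors import AlignmentError, TooFewRowsError

#: Projection defaults: 2 components, learning rate 200, PCA
#: initialization, perplexity 30.
DEFAULT_PERPLEXITY = 30.0
DEFAULT_LEARNING_RATE = 200.0

COLOR_FIELDS = ("cip_label", "stereo_tag", "elution_label")


def tsne_project(
    matrix: DescriptorMatrix | np.ndarray,
    perplexity: float = DEFAULT_PERPLEXITY,
    learning_rate: float = DEFAULT_LEARNING_RATE,
    seed: int = 0,
    row_keys: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Project descriptor rows to 2-D with t-SNE (PCA-initialized).

    Deterministic for a fixed *seed*.  Requires at least ``3 * perplexity``
    rows (surfaced as :class:`TooFewRowsError`); pass a smaller perplexity
    for small fixtures.  Returns a frame with columns ``row_key, x, y``.
    """
    from sklearn.manifold import TSNE

    if isinstance(matrix, DescriptorMatrix):
        values = matrix.values
        keys = list(matrix.row_keys)
    else:
        values = np.asarray(matrix, dtype=np.float64)
        keys = list(row_keys) if row_keys is not None else [str(i) for i in range(len(values))]
    if not np.isfinite(values).all():
        raise ValueError("descriptor matrix contains non-finite values")
    n = values.shape[0]
    if n < 3 * perplexity:
        raise TooFewRowsError(
            f"{n} rows < 3 x perplexity ({perplexity}); lower the perplexity"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        learning_rate=learning_rate,
        init="pca",
        random_state=seed,
    )
    coords = tsne.fit_transform(values).astype(np.float64)
    return pd.DataFrame({"row_key": keys, "x": coords[:, 0], "y": coords[:, 1]})


def export_map(
    coords: pd.DataFrame,
    records: Sequence[MoleculeRecord],
    path,
    color_field: str = "cip_label",
    image_path=None,
    highlight_pairs: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Write the labeled map CSV (and optionally a static scatter image).

    *coords* must align 1:1 with *records* by canonical SMILES.  The CSV
    carries x, y, the SMILES and all three labels, plus a ``highlight``
    flag for members of *highlight_pairs* (pair keys), used to mark
    outlier pairs on the map.  Coordinates are written at full precision
    so the file round-trips bit-exactly.
    """
    if color_field not in COLOR_FIELDS:
        raise ValueError(f"color_field must be one of {COLOR_FIELDS}")
    if len(coords) != len(records):
        raise AlignmentError(
            f"{len(coords)} coordinate rows for {len(records)} records"
        )
    by_smiles = {r.smiles_canonical: r for r in records}
    highlight = set(highlight_pairs or ())
    rows = []
    for _, crow in coords.iterrows():
        rec = by_smiles.get(crow["row_key"])
        if rec is None:
            raise AlignmentError(f"no record for coordinate key {crow['row_key']!r}")
        rows.append(
            {
                "smiles": rec.smiles_canonical,
                "x": crow["x"],
                "y": crow["y"],
                "cip_label": rec.cip_label,
                "stereo_tag": rec.stereo_tag,
                "elution_label": rec.elution_label,
                "highlight": rec.pair_key in highlight,
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False, float_format="%.17g")
    if image_path is not None:
        _render_scatter(frame, color_field, image_path)
    return frame


def read_map(path) -> pd.DataFrame:
    """Read a map CSV back with round-trip float parsing.

    Coordinates are written at full precision; the default CSV float parser
    is not exact, so use this reader when bit-identical coordinates matter.
    """
    return pd.read_csv(path, float_precision="round_trip")


def _render_scatter(frame: pd.DataFrame, color_field: str, image_path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    for value, sub in frame.groupby(color_field, dropna=False):
        ax.scatter(sub["x"], sub["y"], s=8, label=str(value), alpha=0.7)
    flagged = frame[frame["highlight"]]
    if len(flagged):
        ax.scatter(
            flagged["x"], flagged["y"], s=60, facecolors="none",
            edgecolors="black", linewidths=1.2, label="highlighted",
        )
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.legend(title=color_field, fontsize=8)
    fig.tight_layout()
    fig.savefig(image_path, dpi=150)
    plt.close(fig)
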