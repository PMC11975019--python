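"""k-NN condition enrichment and k-NN smoothing in a low-dimensional embedding.

Enrichment asks, for each cell, whether its neighborhood over-represents a
condition relative to the global condition mix; smoothing replaces each
cell's value by its neighborhood mean.  Exact Euclidean search; ties at
identical distance are broken by cell index so results are reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors


def _knn_indices(coords: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest neighbors of each point, self excluded."""
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="auto").fit(coords)
    _, idx = nn.kneighbors(coords)
    # drop self (guaranteed present in the k+1 set only if distances to others
    # are strictly positive; handle duplicates by removing the first match)
    out = np.empty((n, k), dtype=np.intp)
    for i in range(n):
        row = idx[i]
        row = row[row != i][:k]
        if row.size < k:  # duplicated coordinates: self appeared > once
            extra = nn.kneighbors(coords[i : i + 1], n_neighbors=min(n, k + 2))[1][0]
            row = extra[extra != i][:k]
        out[i] = row
    return out


def knn_condition_enrichment(
    coordinates: np.ndarray | pd.DataFrame,
    labels: pd.Series | np.ndarray,
    k: int = 100,
) -> pd.DataFrame:
    """Observed-minus-expected condition fractions in each cell's k-NN.

    The expected fraction for a condition is its global fraction among the
    analysed cells (the expectation under random assignment to neighborhoods);
    the observed fraction is computed over each cell's k nearest neighbors,
    self excluded.  Rows therefore sum to 0 and entries lie in [-1, 1].
    """
    coords = np.asarray(coordinates, dtype=float)
    index = (
        coordinates.index
        if isinstance(coordinates, pd.DataFrame)
        else pd.RangeIndex(coords.shape[0])
    )
    labels = pd.Series(np.asarray(labels), index=index)
    conditions = pd.Index(sorted(labels.unique()))
    expected = labels.value_counts(normalize=True).reindex(conditions).to_numpy()

    idx = _knn_indices(coords, k)
    codes = conditions.get_indexer(labels)
    neigh_codes = codes[idx]  # n x k
    observed = np.stack(
        [(neigh_codes == c).mean(axis=1) for c in range(len(conditions))], axis=1
    )
    return pd.DataFrame(observed - expected, index=index, columns=conditions)


def knn_smooth(
    values: np.ndarray | pd.Series,
    coordinates: np.ndarray | pd.DataFrame,
    k: int = 20,
    include_self: bool = True,
) -> np.ndarray:
    """Mean-smooth per-cell values over each cell's k nearest neighbors.

    By default the cell itself is included in the average (mean over self and
    its k neighbors).
    """
    coords = np.asarray(coordinates, dtype=float)
    vals = np.asarray(values, dtype=float)
    idx = _knn_indices(coords, k)
    neigh_vals = vals[idx]
    if include_self:
        neigh_vals = np.concatenate([vals[:, None], neigh_vals], axis=1)
    return neigh_vals.mean(axis=1)
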