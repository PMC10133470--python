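"""Graph utilities for EEG channel graphs.

Channels are graph nodes; edges encode inter-channel relations.  This module
provides the static kNN initialization from 2-D electrode coordinates, the
mini-batch standardization applied to attention-score tensors, and the per-row
Top-K sparsification that keeps only the strongest learned edges.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConfigurationError, DataError

DEFAULT_TOP_K = 10  # edges kept per row in the dynamic adjacency
DEFAULT_KNN_K = 10  # neighbors in the static kNN initialization


def knn_graph(coords: np.ndarray, k: int) -> np.ndarray:
    """Binary undirected kNN adjacency from 2-D node coordinates.

    Each node is linked to its ``k`` nearest Euclidean neighbors (ties broken
    by lower index), then the directed graph is symmetrized by edge union.
    Self-loops are not stored; they are added downstream by the GAT layer.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2:
        raise ConfigurationError(f"coords must be N x d, got shape {coords.shape}")
    n = coords.shape[0]
    if not 1 <= k <= n - 1:
        raise ConfigurationError(f"k must be in [1, N-1] = [1, {n - 1}], got {k}")
    if not np.all(np.isfinite(coords)):
        raise DataError("non-finite electrode coordinates")
    dist = cdist(coords, coords)
    np.fill_diagonal(dist, np.inf)
    adj = np.zeros((n, n))
    for i in range(n):
        order = np.argsort(dist[i], kind="stable")  # stable -> lower index on ties
        adj[i, order[:k]] = 1.0
    return np.maximum(adj, adj.T)


def batch_standardize(scores: np.ndarray, eps: float = 1e-5):
    """Standardize a batch of score matrices with mini-batch statistics.

    Mean and *population* variance are computed over every entry of the
    batch; a small ``eps`` guards the degenerate constant-batch case.

    Returns ``(standardized, mean, var)`` so the transform is invertible.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise DataError("non-finite attention scores")
    mean = scores.mean()
    var = scores.var()  # population variance
    return (scores - mean) / np.sqrt(var + eps), mean, var


def topk_mask(values: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of the k largest entries per row (last axis).

    Ties are broken stably: among equal values the lower column index is
    kept.  ``k >= row length`` keeps everything.
    """
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    values = np.asarray(values)
    n = values.shape[-1]
    if k >= n:
        return np.ones(values.shape, dtype=bool)
    # stable argsort of -values keeps original order among ties
    order = np.argsort(-values, axis=-1, kind="stable")
    mask = np.zeros(values.shape, dtype=bool)
    np.put_along_axis(mask, order[..., :k], True, axis=-1)
    return mask


def topk_sparsify(adj: np.ndarray, k: int) -> np.ndarray:
    """Keep the k largest entries of each row at their values, zero the rest.

    Works on ``N x N`` matrices or ``B x N x N`` batches; idempotent.
    """
    adj = np.asarray(adj, dtype=float)
    return np.where(topk_mask(adj, k), adj, 0.0)
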