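"""Embedding-quality "distance score".

Benchmarking cell filters against a single gold-standard barcode list
inherits that list's processing biases, so this module provides a
reference-free metric: in a good embedding, cells should sit near cells
with similar feature sets and far from cells with dissimilar ones.

For each cell we take its k nearest and k farthest cells by Euclidean
distance in the embedding, compute the Levenshtein (edit) distance between
feature-identifier sequences — normalised by the larger sequence length so
it lies in [0, 1] — and score the cell as

    score = mean(norm. Levenshtein to neighbours)
            + 1 / max(mean(norm. Levenshtein to distant cells), eps).

Lower is better; the dataset-level score is the median over cells.
Feature sequences are the sorted identifiers of a cell's nonzero matrix
entries, so two cells with identical feature sets have distance 0 and two
cells with disjoint equal-length sets have distance 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "DistanceScoreResult",
    "normalized_levenshtein",
    "cohorts",
    "distance_score",
    "feature_sets_from_matrix",
]

# map feature indices into valid (non-surrogate) code points
_OFFSET = 128
_SURROGATE_LO, _SURROGATE_SPAN = 0xD800, 0x800


def _encode(features: Sequence[int]) -> str:
    chars = []
    for f in features:
        cp = int(f) + _OFFSET
        if cp >= _SURROGATE_LO:
            cp += _SURROGATE_SPAN
        if cp > 0x10FFFF:
            raise ValueError("feature index too large to encode")
        chars.append(chr(cp))
    return "".join(chars)


def normalized_levenshtein(f1: Sequence[int], f2: Sequence[int]) -> float:
    """Unit-cost edit distance between two feature sequences, divided by
    the larger sequence length; in [0, 1], symmetric. Two empty sequences
    have distance 0 by convention."""
    n1, n2 = len(f1), len(f2)
    if n1 == 0 and n2 == 0:
        return 0.0
    if n1 == 0 or n2 == 0:
        return 1.0
    dist = edlib.align(_encode(f1), _encode(f2), mode="NW", task="distance")[
        "editDistance"
    ]
    return dist / max(n1, n2)


def cohorts(
    i: int, coords: np.ndarray, barcodes: Sequence[str], k: int
) -> tuple[list[int], list[int]]:
    """Indices of the k nearest and k farthest cells from cell ``i`` (self
    excluded), by Euclidean distance; ties broken by barcode order."""
    n = len(barcodes)
    if k < 1:
        raise ValueError("k must be >= 1")
    if 2 * k + 1 > n or k >= n / 2:
        raise ValueError(f"need more than 2k cells besides the query (n={n}, k={k})")
    d = np.linalg.norm(coords - coords[i], axis=1)
    others = [j for j in range(n) if j != i]
    near = sorted(others, key=lambda j: (d[j], barcodes[j]))[:k]
    far = sorted(others, key=lambda j: (-d[j], barcodes[j]))[:k]
    return near, far


@dataclass(frozen=True)
class DistanceScoreResult:
    per_cell: dict[str, float]
    dataset_score: float  # median of per-cell scores; lower = better
    degenerate: bool = False  # distant cohort feature-identical somewhere


def distance_score(
    coords: np.ndarray,
    barcodes: Sequence[str],
    features: Mapping[str, Sequence[int]],
    k: int = 15,
    eps: float = 1e-6,
) -> DistanceScoreResult:
    """Per-cell and dataset-level distance score over an embedding.

    ``coords`` is an (n_cells, d) array aligned with ``barcodes``;
    ``features`` maps each barcode to its sorted feature-identifier
    sequence. ``eps`` guards the reciprocal when distant cells are
    feature-identical to the query (degenerate, flagged).
    """
    coords = np.asarray(coords, dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("embedding coordinates must be finite")
    n = len(barcodes)
    if coords.shape[0] != n:
        raise ValueError("coords and barcodes length mismatch")
    missing = [bc for bc in barcodes if bc not in features]
    if missing:
        raise ValueError(f"feature sets missing for {len(missing)} barcodes")
    # distance matrix once; cohort extraction reuses it
    dmat = cdist(coords, coords)
    order_key = np.argsort(np.asarray(barcodes, dtype=object), kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order_key] = np.arange(n)
    per_cell: dict[str, float] = {}
    degenerate = False
    for i, bc in enumerate(barcodes):
        if 2 * k + 1 > n or k >= n / 2:
            raise ValueError(f"need more than 2k cells besides the query (n={n}, k={k})")
        d = dmat[i].copy()
        d[i] = np.inf
        near = sorted(
            (j for j in range(n) if j != i), key=lambda j: (d[j], rank[j])
        )[:k]
        far = sorted(
            (j for j in range(n) if j != i), key=lambda j: (-d[j], rank[j])
        )[:k]
        fi = features[bc]
        near_mean = float(
            np.mean([normalized_levenshtein(fi, features[barcodes[j]]) for j in near])
        )
        far_mean = float(
            np.mean([normalized_levenshtein(fi, features[barcodes[j]]) for j in far])
        )
        if far_mean < eps:
            degenerate = True
        per_cell[bc] = near_mean + 1.0 / max(far_mean, eps)
    return DistanceScoreResult(per_cell, float(np.median(list(per_cell.values()))), degenerate)


def feature_sets_from_matrix(X, barcodes: Sequence[str], top_m: int | None = None) -> dict[str, np.ndarray]:
    """Sorted nonzero-feature indices per cell from a cells x features
    matrix (dense or scipy sparse).

    ``top_m`` optionally caps each cell to its ``top_m`` highest-signal
    features (off by default) to bound the quadratic edit-distance cost on
    very wide matrices.
    """
    import scipy.sparse as sp

    out: dict[str, np.ndarray] = {}
    if sp.issparse(X):
        X = X.tocsr()
        for i, bc in enumerate(barcodes):
            row = X.getrow(i)
            idx = row.indices
            if top_m is not None and len(idx) > top_m:
                keep = np.argsort(row.data)[::-1][:top_m]
                idx = idx[keep]
            out[bc] = np.sort(idx)
    else:
        X = np.asarray(X)
        for i, bc in enumerate(barcodes):
            idx = np.nonzero(X[i])[0]
            if top_m is not None and len(idx) > top_m:
                keep = np.argsort(X[i, idx])[::-1][:top_m]
                idx = idx[keep]
            out[bc] = np.sort(idx)
    return out
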