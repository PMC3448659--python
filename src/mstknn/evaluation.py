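"""Cluster quality metrics and Monte-Carlo permutation FDR.

Homogeneity and separation follow the microarray-clustering convention:
similarity is the Pearson correlation of raw expression rows.
Homogeneity averages each member's correlation with its cluster
centroid (the mean expression vector of the cluster, member included);
separation is the cluster-size-weighted average correlation between
centroid pairs.  Good clusterings have high homogeneity and low
separation.

The permutation FDR shuffles a progression marker across samples,
recounts how many features pass each absolute-correlation threshold,
and reports the mean null count over permutations relative to the
observed count.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .data_io import ClusteringResult

logger = logging.getLogger(__name__)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def _centroids(X: pd.DataFrame, C: ClusteringResult) -> dict[int, np.ndarray]:
    cents = {}
    for cid in range(C.n_clusters):
        members = C.members(cid)
        cents[cid] = X.loc[members].to_numpy(dtype=float).mean(axis=0)
    return cents


def homogeneity(
    X: pd.DataFrame, C: ClusteringResult, include_singletons: bool = True
) -> float:
    """Average Pearson correlation of each feature with its cluster centroid.

    A singleton's centroid is the feature itself, contributing exactly 1;
    set ``include_singletons=False`` to average over multi-member
    clusters only.  Members of a cluster whose centroid is constant
    (undefined correlation) are excluded with a warning.
    """
    missing = [f for f in C.assignment if f not in X.index]
    if missing:
        raise ValueError(f"clustered features missing from the matrix: {missing[:5]}")
    cents = _centroids(X, C)
    sizes = {cid: len(C.members(cid)) for cid in cents}
    sims = []
    for feature, cid in C.assignment.items():
        if not include_singletons and sizes[cid] == 1:
            continue
        centroid = cents[cid]
        if np.all(centroid == centroid[0]):
            logger.warning(
                "constant centroid for cluster %d; excluding %r from homogeneity",
                cid, feature,
            )
            continue
        x = X.loc[feature].to_numpy(dtype=float)
        if np.all(x == x[0]):
            logger.warning("constant feature %r excluded from homogeneity", feature)
            continue
        sims.append(_pearson(x, centroid))
    if not sims:
        raise ValueError("no scorable features for homogeneity")
    return float(np.mean(sims))


def separation(X: pd.DataFrame, C: ClusteringResult) -> float:
    """Size-weighted average Pearson correlation between cluster centroids.

    ``S_avg = sum_{i<j} |C_i||C_j| r(c_i, c_j) / sum_{i<j} |C_i||C_j|``.
    """
    if C.n_clusters < 2:
        raise ValueError("separation undefined for fewer than 2 clusters")
    cents = _centroids(X, C)
    sizes = {cid: len(C.members(cid)) for cid in cents}
    num = 0.0
    den = 0.0
    ids = sorted(cents)
    for i_pos, i in enumerate(ids):
        for j in ids[i_pos + 1:]:
            w = sizes[i] * sizes[j]
            num += w * _pearson(cents[i], cents[j])
            den += w
    return float(num / den)


def permutation_fdr(
    F: pd.DataFrame,
    marker: np.ndarray | pd.Series,
    thresholds: Sequence[float],
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Estimate the FDR of correlation-threshold feature selection.

    For each permutation the marker values are uniformly shuffled across
    samples and the number of features with ``|spearman| >= threshold``
    is recounted.  Returns one row per threshold with columns
    ``threshold, observed_count, mean_null_count, fdr`` where
    ``fdr = min(1, mean_null_count / max(observed_count, 1))``.
    """
    marker = np.asarray(marker, dtype=float)
    if np.unique(marker).size < 2:
        raise ValueError("marker vector is constant")
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    thresholds = sorted(float(t) for t in thresholds)
    if any(not 0 < t <= 1 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1]")
    rng = np.random.default_rng(seed)

    values = F.to_numpy(dtype=float)
    ranked = stats.rankdata(values, axis=1)
    rc = ranked - ranked.mean(axis=1, keepdims=True)
    rnorm = np.sqrt((rc**2).sum(axis=1))
    ok = rnorm > 0  # constant features never pass a threshold

    def abs_corr(m: np.ndarray) -> np.ndarray:
        mranked = stats.rankdata(m)
        mc = mranked - mranked.mean()
        denom = rnorm * np.sqrt((mc**2).sum())
        out = np.zeros(values.shape[0])
        out[ok] = np.abs((rc[ok] @ mc) / denom[ok])
        return out

    observed = abs_corr(marker)
    obs_counts = np.array([(observed >= t).sum() for t in thresholds])

    null_counts = np.zeros((n_perm, len(thresholds)))
    for i in range(n_perm):
        perm = rng.permutation(marker)
        null = abs_corr(perm)
        null_counts[i] = [(null >= t).sum() for t in thresholds]
    mean_null = null_counts.mean(axis=0)
    fdr = np.minimum(1.0, mean_null / np.maximum(obs_counts, 1))
    return pd.DataFrame(
        {
            "threshold": thresholds,
            "observed_count": obs_counts.astype(int),
            "mean_null_count": mean_null,
            "fdr": fdr,
        }
    )


def adjusted_rand_index(
    A: dict[str, int] | ClusteringResult, B: dict[str, int] | ClusteringResult
) -> float:
    """Adjusted Rand index between two partitions of the same element set."""
    a = A.assignment if isinstance(A, ClusteringResult) else dict(A)
    b = B.assignment if isinstance(B, ClusteringResult) else dict(B)
    if set(a) != set(b):
        raise ValueError("partitions cover different element sets")
    keys = sorted(a)
    return float(adjusted_rand_score([a[k] for k in keys], [b[k] for k in keys]))
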