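"""Jensen-Shannon disease-progression quantifiers and Spearman screening.

Each sample's expression vector over the signature features is treated
as a probability distribution (normalized to unit sum, valid because
intensities are strictly positive).  A sample's divergence from the
average profile of a reference group — the control group
(``jsd_control``) or the severe-disease group (``jsd_severe``) — is a
continuous, bounded quantifier of how far its transcriptome has shifted
along the disease axis.  Natural logarithms are used throughout, so
divergences lie in [0, ln 2]; downstream clustering uses ranks, which
are base-invariant.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import require_positive

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


def normalize_profile(x: np.ndarray | pd.Series) -> np.ndarray:
    """Normalize a strictly positive vector to a unit-sum probability profile."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize a zero-length vector")
    if np.any(x <= 0):
        bad = int(np.nonzero(x <= 0)[0][0])
        raise ValueError(f"nonpositive entry {x[bad]!r} at index {bad}")
    return x / x.sum()


def shannon_entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats, with the convention 0*ln(0) = 0."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def jensen_shannon_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """JSD(p, q) = H((p+q)/2) - (H(p) + H(q))/2, in nats.

    Symmetric, zero iff p == q, bounded above by ln 2.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"profile shape mismatch: {p.shape} vs {q.shape}")
    m = 0.5 * (p + q)
    d = shannon_entropy(m) - 0.5 * (shannon_entropy(p) + shannon_entropy(q))
    # clip tiny negative rounding noise at d == 0
    return max(d, 0.0)


def group_profile(X: pd.DataFrame, member_samples: list[str]) -> np.ndarray:
    """Average characteristic profile of a sample group.

    The arithmetic mean of the members' normalized profiles; a mean of
    unit-sum vectors is unit-sum, so each member weighs equally
    regardless of its overall intensity.
    """
    if not member_samples:
        raise ValueError("group must have at least one member sample")
    missing = [s for s in member_samples if s not in X.columns]
    if missing:
        raise ValueError(f"unknown sample ids: {missing}")
    require_positive(X[member_samples], "profile normalization")
    profiles = np.stack([
        normalize_profile(X[s].to_numpy()) for s in member_samples
    ])
    return profiles.mean(axis=0)


def jsd_scores(
    X: pd.DataFrame,
    control_ids: list[str],
    severe_ids: list[str],
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-sample divergence from the control and severe group profiles.

    Returns a samples x 2 table with columns ``jsd_control`` and
    ``jsd_severe``.  ``sample_ids`` defaults to every column of ``X``;
    the reference groups may or may not overlap the scored samples.
    """
    if sample_ids is None:
        sample_ids = list(X.columns)
    missing = [s for s in sample_ids if s not in X.columns]
    if missing:
        raise ValueError(f"unknown sample ids: {missing}")
    control = group_profile(X, control_ids)
    severe = group_profile(X, severe_ids)
    require_positive(X[sample_ids], "profile normalization")
    rows = {}
    for s in sample_ids:
        p = normalize_profile(X[s].to_numpy())
        rows[s] = (
            jensen_shannon_divergence(p, control),
            jensen_shannon_divergence(p, severe),
        )
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["jsd_control", "jsd_severe"]
    )


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def correlate_all(F: pd.DataFrame, marker: np.ndarray | pd.Series) -> pd.Series:
    """Spearman correlation of every feature row against a marker vector.

    Constant features cannot be ranked against the marker and are
    returned as NaN (logged), rather than raising.
    """
    marker = np.asarray(marker, dtype=float)
    if marker.size != F.shape[1]:
        raise ValueError(
            f"marker length {marker.size} != sample count {F.shape[1]}"
        )
    if np.unique(marker).size < 2:
        raise ValueError("marker vector is constant")
    values = F.to_numpy(dtype=float)
    constant = np.all(values == values[:, :1], axis=1)
    if constant.any():
        logger.warning(
            "%d constant feature(s) flagged as missing in correlate_all",
            int(constant.sum()),
        )
    # Spearman = Pearson on average ranks; vectorized over features
    ranked = stats.rankdata(values, axis=1)
    mranked = stats.rankdata(marker)
    rc = ranked - ranked.mean(axis=1, keepdims=True)
    mc = mranked - mranked.mean()
    denom = np.sqrt((rc**2).sum(axis=1) * (mc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rc @ mc) / denom
    rho[constant] = np.nan
    return pd.Series(rho, index=F.index, name="spearman")
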