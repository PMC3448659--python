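"""Reporting of clusters that contain disease-progression markers.

Once the analysis matrix (features + metafeatures + marker rows) has
been clustered, the clusters containing the progression-marker nodes
are the candidate biomarker groups.  This module extracts those
clusters, ranks their members by Spearman correlation with the marker,
decomposes metafeature identifiers into their constituent probes,
intersects the per-marker member lists into "robust" probes that recur
under at least two distinct markers, and re-runs the pipeline on sample
strata (e.g. one sex only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ClusteringResult
from .metafeatures import MARKER_PREFIX, MetafeatureId, is_marker_row
from .progression import spearman


@dataclass
class MarkerClusterReport:
    """Members of one progression marker's cluster, ranked by correlation."""

    marker_id: str
    members: list[tuple[str, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.members, columns=["feature_id", "spearman"])


def find_marker_clusters(
    C: ClusteringResult, marker_ids: list[str]
) -> dict[str, list[str]]:
    """Co-members of each marker node's cluster (marker rows excluded).

    ``marker_ids`` are bare marker names (``mmse``, ``nft``, ...); the
    clustering must contain the corresponding ``MARKER:`` rows, i.e. it
    must have been run on an assembled analysis matrix.
    """
    out: dict[str, list[str]] = {}
    for marker in marker_ids:
        node = f"{MARKER_PREFIX}{marker}"
        if node not in C.assignment:
            raise ValueError(f"marker {marker!r} was not part of the clustering")
        cid = C.assignment[node]
        out[marker] = [
            f for f in C.members(cid) if not is_marker_row(f)
        ]
    return out


def rank_members(
    members: list[str], F: pd.DataFrame, marker: np.ndarray | pd.Series,
    marker_id: str = "marker",
) -> MarkerClusterReport:
    """Rank cluster members by Spearman correlation with the marker.

    Most positively correlated first; ties broken lexicographically by
    feature id for determinism.
    """
    missing = [m for m in members if m not in F.index]
    if missing:
        raise ValueError(f"members missing from the matrix: {missing[:5]}")
    marker = np.asarray(marker, dtype=float)
    scored = [(m, spearman(F.loc[m].to_numpy(dtype=float), marker)) for m in members]
    scored.sort(key=lambda item: (-item[1], item[0]))
    return MarkerClusterReport(marker_id=marker_id, members=scored)


def constituent_probes(feature_id: str) -> frozenset[str]:
    """Probe ids making up a feature: two for a metafeature, one otherwise."""
    if is_marker_row(feature_id):
        raise ValueError(f"marker rows have no constituent probes: {feature_id!r}")
    try:
        mf = MetafeatureId.parse(feature_id)
    except ValueError:
        if not feature_id:
            raise ValueError("empty feature id")
        return frozenset([feature_id])
    return frozenset([mf.a, mf.b])


def robust_markers(
    reports: list[MarkerClusterReport], min_markers: int = 2
) -> dict[str, frozenset[str]]:
    """Probes whose (meta)features cluster with at least ``min_markers`` markers.

    Returns ``probe_id -> set of marker ids``; operator-blind (a probe
    counts whether it appears in ``A/B`` or ``A+B``) and invariant to
    the order of the reports.
    """
    if len(reports) < 2:
        raise ValueError("need at least two marker reports to intersect")
    seen: dict[str, set[str]] = {}
    for report in reports:
        for feature_id, _ in report.members:
            for probe in constituent_probes(feature_id):
                seen.setdefault(probe, set()).add(report.marker_id)
    return {
        probe: frozenset(markers)
        for probe, markers in seen.items()
        if len(markers) >= min_markers
    }


def stratified_recluster(
    X: pd.DataFrame,
    annotation: pd.DataFrame,
    predicate,
    min_size: int = 3,
    q: int | None = None,
    c2_policy: str = "pmax",
) -> ClusteringResult:
    """Re-run the clustering on the sample subset selected by ``predicate``.

    ``predicate`` receives each annotation row (a Series) and returns a
    boolean — e.g. ``lambda r: r["sex"] == "female"``.  At least 4
    samples must survive the selection.
    """
    from .graph_clustering import cluster

    keep = [s for s in X.columns if s in annotation.index and predicate(annotation.loc[s])]
    if len(keep) < 4:
        raise ValueError(f"predicate selects only {len(keep)} samples; need >= 4")
    return cluster(X[keep], min_size=min_size, q=q, c2_policy=c2_policy)


def membership_diff(
    baseline: dict[str, list[str]], stratified: dict[str, list[str]]
) -> pd.DataFrame:
    """Tabulate marker-cluster membership changes between two runs."""
    rows = []
    for marker in sorted(set(baseline) | set(stratified)):
        before = set(baseline.get(marker, []))
        after = set(stratified.get(marker, []))
        for feature in sorted(before - after):
            rows.append((marker, feature, "lost"))
        for feature in sorted(after - before):
            rows.append((marker, feature, "gained"))
    return pd.DataFrame(rows, columns=["marker", "feature_id", "change"])
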