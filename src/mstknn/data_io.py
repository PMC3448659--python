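"""Reading and writing expression matrices, annotations, clusterings and graphs.

An expression matrix is represented throughout the package as a
:class:`pandas.DataFrame` whose index holds feature identifiers (rows)
and whose columns hold sample identifiers.  Values are real expression
intensities; strict positivity is enforced at the point of use (ratio
metafeatures, probability profiles), not at load time, because sums,
differences and products tolerate zeros.

All writers are deterministic: fixed row ordering (lexicographic by
identifier) and fixed numeric formatting, so a given object always
serializes to identical bytes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

VALID_GROUPS = ("control", "incipient", "moderate", "severe")
VALID_SEXES = ("male", "female", "unknown")

#: number of decimal places used when printing correlations and divergences
REPORT_PRECISION = 6


@dataclass
class ClusteringResult:
    """A partition of feature identifiers into clusters.

    Parameters
    ----------
    assignment
        Mapping ``feature_id -> cluster_id``; cluster ids are contiguous
        integers starting at 0.
    split_log
        Provenance of the recursive partition: one
        ``(component_size, criterion, removed_edge_count)`` triple per
        visited component, where *criterion* is one of ``"C1"``, ``"C2"``,
        ``"C3"``, ``"MINSIZE"``.
    """

    assignment: dict[str, int]
    split_log: list[tuple[int, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = sorted(set(self.assignment.values()))
        if ids and ids != list(range(len(ids))):
            raise ValueError("cluster ids must be contiguous from 0")

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, cluster_id: int) -> list[str]:
        """Feature ids of one cluster, sorted lexicographically."""
        return sorted(f for f, c in self.assignment.items() if c == cluster_id)

    def clusters(self) -> list[list[str]]:
        """All clusters as sorted member lists, indexed by cluster id."""
        return [self.members(c) for c in range(self.n_clusters)]

    def relabel_canonical(self) -> "ClusteringResult":
        """Renumber clusters by their lexicographically smallest member."""
        reps = sorted(
            (min(members), cid)
            for cid, members in enumerate(self.clusters())
        )
        remap = {old: new for new, (_, old) in enumerate(reps)}
        return ClusteringResult(
            assignment={f: remap[c] for f, c in self.assignment.items()},
            split_log=list(self.split_log),
        )


def validate_expression(X: pd.DataFrame) -> pd.DataFrame:
    """Check expression-matrix invariants: unique ids, numeric, no NaN."""
    if X.index.has_duplicates:
        dupes = X.index[X.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids: {dupes[:5]}")
    if X.columns.has_duplicates:
        dupes = X.columns[X.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dupes[:5]}")
    if X.isna().any().any():
        feat, samp = next(
            (f, s) for f in X.index for s in X.columns if pd.isna(X.at[f, s])
        )
        raise ValueError(f"missing value at feature {feat!r}, sample {samp!r}")
    return X


def require_positive(X: pd.DataFrame, context: str = "this operation") -> None:
    """Raise with coordinates if any entry is not strictly positive."""
    bad = (X <= 0)
    if bad.any().any():
        feat = bad.any(axis=1).idxmax()
        samp = bad.loc[feat].idxmax()
        raise ValueError(
            f"{context} requires strictly positive values; "
            f"found {X.at[feat, samp]!r} at feature {feat!r}, sample {samp!r}"
        )


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated expression table (features in rows).

    First column holds feature ids, header row holds sample ids.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty expression file: {path}")
    X = pd.read_csv(path, sep="\t", index_col=0)
    if X.shape[1] == 0:
        raise ValueError(f"no sample columns in {path}")
    X.index = X.index.astype(str)
    X.columns = X.columns.astype(str)
    non_numeric = X.dtypes.apply(lambda d: d.kind not in "fiu")
    if non_numeric.any():
        col = X.columns[non_numeric.argmax()]
        coerced = pd.to_numeric(X[col], errors="coerce")
        feat = coerced.index[coerced.isna().argmax()]
        raise ValueError(
            f"non-numeric cell at feature {feat!r}, sample {col!r}: "
            f"{X.at[feat, col]!r}"
        )
    return validate_expression(X)


def write_expression(X: pd.DataFrame, path: str | Path) -> None:
    """Write an expression matrix as tab-separated text, rows sorted by id."""
    X.sort_index().to_csv(path, sep="\t", float_format="%.10g", index_label="feature_id")


def read_geo_series_matrix(path: str | Path) -> pd.DataFrame:
    """Read a GEO series-matrix text file, skipping ``!``-prefixed metadata."""
    rows = [
        line for line in Path(path).read_text().splitlines()
        if line and not line.startswith("!")
    ]
    if not rows:
        raise ValueError(f"no data rows in GEO series matrix {path}")
    from io import StringIO

    X = pd.read_csv(StringIO("\n".join(rows)), sep="\t", index_col=0)
    X.index = X.index.astype(str).str.strip('"')
    X.columns = X.columns.astype(str).str.strip('"')
    return validate_expression(X)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a sample-annotation table (CSV or TSV, sniffed from the header).

    Expected columns: ``sample_id, group, sex, mmse, nft, braak``.  A
    missing ``sex`` column defaults to ``unknown``; unknown extra columns
    are ignored with a warning.  Group labels must be one of
    control/incipient/moderate/severe; MMSE must lie in [0, 30] and Braak
    stage in [1, 6].
    """
    path = Path(path)
    first = path.read_text().splitlines()[0] if path.stat().st_size else ""
    sep = "\t" if "\t" in first else ","
    ann = pd.read_csv(path, sep=sep)
    known = {"sample_id", "group", "sex", "mmse", "nft", "braak"}
    extra = [c for c in ann.columns if c not in known]
    if extra:
        logger.warning("ignoring unknown annotation columns: %s", extra)
        ann = ann.drop(columns=extra)
    if "sample_id" not in ann.columns:
        raise ValueError("annotation must have a sample_id column")
    ann["sample_id"] = ann["sample_id"].astype(str)
    if ann["sample_id"].duplicated().any():
        dupe = ann["sample_id"][ann["sample_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate sample_id in annotation: {dupe!r}")
    if "sex" not in ann.columns:
        ann["sex"] = "unknown"
    ann["sex"] = ann["sex"].fillna("unknown")
    for i, row in ann.iterrows():
        if "group" in ann.columns and row["group"] not in VALID_GROUPS:
            raise ValueError(
                f"row {i} (sample {row['sample_id']!r}): unknown group "
                f"{row['group']!r}; expected one of {VALID_GROUPS}"
            )
        if row["sex"] not in VALID_SEXES:
            raise ValueError(
                f"row {i} (sample {row['sample_id']!r}): unknown sex {row['sex']!r}"
            )
        if "mmse" in ann.columns and not 0 <= row["mmse"] <= 30:
            raise ValueError(
                f"row {i} (sample {row['sample_id']!r}): MMSE {row['mmse']} "
                "outside [0, 30]"
            )
        if "braak" in ann.columns and not 1 <= row["braak"] <= 6:
            raise ValueError(
                f"row {i} (sample {row['sample_id']!r}): Braak stage "
                f"{row['braak']} outside [1, 6]"
            )
    return ann.set_index("sample_id", drop=False)


def write_clusters(result: ClusteringResult, path: str | Path) -> None:
    """Write a clustering as a two-column TSV (feature_id, cluster_id)."""
    with open(path, "w") as fh:
        fh.write("feature_id\tcluster_id\n")
        for feature in sorted(result.assignment):
            fh.write(f"{feature}\t{result.assignment[feature]}\n")


def read_clusters(path: str | Path) -> ClusteringResult:
    """Read a clustering written by :func:`write_clusters`."""
    table = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "cluster_id": int})
    return ClusteringResult(
        assignment=dict(zip(table["feature_id"], table["cluster_id"]))
    )


def write_graph_edgelist(G: nx.Graph, path: str | Path) -> None:
    """Write an annotated graph as ``node_a TAB node_b TAB weight TAB p``."""
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\tp\n")
        for a, b, data in sorted(
            ((min(u, v), max(u, v), d) for u, v, d in G.edges(data=True))
        ):
            w = data.get("weight", float("nan"))
            p = data.get("p", "")
            fh.write(f"{a}\t{b}\t{w:.{REPORT_PRECISION}f}\t{p}\n")


def write_graphml(G: nx.Graph, path: str | Path) -> None:
    """Export the annotated spanning forest as GraphML."""
    nx.write_graphml(G, path)
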