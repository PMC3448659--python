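"""Pairwise metafeature expansion of an expression matrix.

A *metafeature* combines two measured features with one of four
elementwise operators — ratio, sum, difference, product — giving, for
``n`` features and a set of operators ``ops``,
``|ops| * n * (n-1) / 2`` derived features.  Non-symmetric operators
(ratio, difference) are always oriented first-over-second in the
matrix's feature order, so each unordered pair appears exactly once per
operator and generation is deterministic.  Downstream clustering uses
the absolute Spearman correlation, which is orientation-invariant.

Generation is streaming-friendly: :func:`iter_metafeature_blocks`
yields blocks of at most ``block_size`` rows so the full expansion
never has to be materialized at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .data_io import validate_expression

OPERATORS = ("ratio", "sum", "diff", "prod")
_GLYPHS = {"ratio": "/", "sum": "+", "diff": "-", "prod": "*"}
_FROM_GLYPH = {v: k for k, v in _GLYPHS.items()}

#: prefix marking progression-marker rows in an assembled analysis matrix
MARKER_PREFIX = "MARKER:"


@dataclass(frozen=True)
class MetafeatureId:
    """Canonical identifier of a pairwise combined feature."""

    op: str
    a: str
    b: str

    def __post_init__(self) -> None:
        if self.op not in OPERATORS:
            raise ValueError(f"unknown operator {self.op!r}; expected one of {OPERATORS}")

    def __str__(self) -> str:
        return f"{self.a}{_GLYPHS[self.op]}{self.b}"

    @classmethod
    def parse(cls, text: str) -> "MetafeatureId":
        """Parse a serialized id like ``"A/B"`` back into its parts.

        The first operator glyph found splits the id; feature identifiers
        themselves must not contain the four glyph characters.
        """
        for glyph, op in _FROM_GLYPH.items():
            if glyph in text:
                a, _, b = text.partition(glyph)
                if not a or not b:
                    raise ValueError(f"malformed metafeature id: {text!r}")
                return cls(op=op, a=a, b=b)
        raise ValueError(f"no operator glyph in metafeature id: {text!r}")


def _check_ops(ops: Iterable[str]) -> tuple[str, ...]:
    ops = tuple(ops)
    if not ops:
        raise ValueError("operator set must be nonempty")
    unknown = [o for o in ops if o not in OPERATORS]
    if unknown:
        raise ValueError(f"unknown operators: {unknown}; expected subset of {OPERATORS}")
    # canonical operator-major order, dedup
    return tuple(o for o in OPERATORS if o in ops)


def count_metafeatures(n_features: int, ops: Iterable[str]) -> int:
    """Number of pairwise metafeatures: ``|ops| * C(n_features, 2)``.

    Four operators over 1,372 features give 3,762,024 combinations.
    """
    if n_features < 2:
        raise ValueError(f"need at least 2 features, got {n_features}")
    ops = _check_ops(ops)
    return len(ops) * n_features * (n_features - 1) // 2


def compute_metafeature(
    x_a: np.ndarray, x_b: np.ndarray, op: str
) -> np.ndarray:
    """Elementwise combination of two expression vectors under one operator."""
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if x_a.shape != x_b.shape:
        raise ValueError(f"shape mismatch: {x_a.shape} vs {x_b.shape}")
    if op == "ratio":
        zero = np.nonzero(x_b == 0)[0]
        if zero.size:
            raise ValueError(
                f"zero denominator in ratio at sample index {zero[0]}"
            )
        return x_a / x_b
    if op == "sum":
        return x_a + x_b
    if op == "diff":
        return x_a - x_b
    if op == "prod":
        return x_a * x_b
    raise ValueError(f"unknown operator {op!r}")


def iter_metafeature_blocks(
    X: pd.DataFrame, ops: Iterable[str], block_size: int = 10_000
) -> Iterator[pd.DataFrame]:
    """Yield the metafeature expansion of ``X`` in blocks of rows.

    Blocks follow a deterministic operator-major order (each operator's
    pairs in ``itertools.combinations`` order of the matrix's feature
    order); each block has at most ``block_size`` rows.
    """
    ops = _check_ops(ops)
    if block_size < 1:
        raise ValueError("block_size must be positive")
    validate_expression(X)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 features to form pairs")
    if "ratio" in ops:
        from .data_io import require_positive

        require_positive(X, "ratio metafeature generation")

    features = list(X.index)
    values = {f: X.loc[f].to_numpy(dtype=float) for f in features}

    names: list[str] = []
    rows: list[np.ndarray] = []
    for op in ops:
        for a, b in combinations(features, 2):
            names.append(str(MetafeatureId(op, a, b)))
            rows.append(compute_metafeature(values[a], values[b], op))
            if len(rows) == block_size:
                yield pd.DataFrame(rows, index=names, columns=X.columns)
                names, rows = [], []
    if rows:
        yield pd.DataFrame(rows, index=names, columns=X.columns)


def generate_metafeatures(
    X: pd.DataFrame, ops: Iterable[str] = OPERATORS, block_size: int = 10_000
) -> pd.DataFrame:
    """Materialize the full metafeature matrix (all blocks concatenated).

    Row count equals :func:`count_metafeatures`; row order is the
    deterministic block order, so two runs on the same input produce
    identical matrices.
    """
    blocks = list(iter_metafeature_blocks(X, ops, block_size))
    return pd.concat(blocks, axis=0)


def assemble_analysis_matrix(
    X: pd.DataFrame,
    meta: pd.DataFrame | None,
    markers: pd.DataFrame | None,
) -> pd.DataFrame:
    """Stack originals, metafeatures and progression-marker rows.

    ``markers`` is a samples x markers table (e.g. columns mmse, nft,
    braak, jsd_control, jsd_severe); each marker becomes one row named
    ``MARKER:<name>`` so that markers participate in clustering as
    ordinary nodes.  All inputs must share the same sample ids.
    """
    parts = [X]
    if meta is not None and len(meta):
        if list(meta.columns) != list(X.columns):
            raise ValueError("sample ids of metafeatures do not match originals")
        parts.append(meta)
    if markers is not None:
        missing = [s for s in X.columns if s not in markers.index]
        if missing:
            raise ValueError(f"marker table missing samples: {missing}")
        marker_rows = markers.loc[list(X.columns)].T
        marker_rows.index = [f"{MARKER_PREFIX}{m}" for m in marker_rows.index]
        marker_rows.columns = X.columns
        parts.append(marker_rows)
    out = pd.concat(parts, axis=0)
    return validate_expression(out)


def is_marker_row(feature_id: str) -> bool:
    return feature_id.startswith(MARKER_PREFIX)


def marker_name(feature_id: str) -> str:
    """Strip the ``MARKER:`` prefix from an assembled marker row id."""
    if not is_marker_row(feature_id):
        raise ValueError(f"not a marker row: {feature_id!r}")
    return feature_id[len(MARKER_PREFIX):]
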