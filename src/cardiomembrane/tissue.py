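"""Cardiac fold-enrichment, heatmap normalization and hierarchical clustering.

A gene is called cardiac-enriched when its strongest heart-tissue signal is
at least ``threshold``-fold (default 3, inclusive) above the aggregate of
the non-heart tissues.  The aggregator defaults to the median, which is
robust to a single non-cardiac outlier tissue; heatmap rows are normalized
to their total across tissues before clustering and rendering.
"""

from __future__ import annotations

import logging
import math
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .types import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_FOLD_THRESHOLD = 3.0

_AGGREGATORS: dict[str, Callable[[np.ndarray], float]] = {
    "median": lambda v: float(np.median(v)),
    "mean": lambda v: float(np.mean(v)),
    "max": lambda v: float(np.max(v)),
}


def cardiac_fold(
    row: pd.Series,
    heart_tissues: Sequence[str],
    aggregator: str = "median",
) -> float:
    """Heart-to-other fold enrichment for one gene.

    fold = max(heart values) / aggregator(non-heart values); a positive
    numerator over a zero denominator is +inf, 0/0 is 0.  Requires at least
    two non-heart tissues.  All-missing rows return NaN (logged).
    """
    if aggregator not in _AGGREGATORS:
        raise ValidationError(f"unknown aggregator {aggregator!r}")
    row = row.astype(float)
    if row.isna().all():
        logger.warning("gene row is all-missing; fold undefined")
        return float("nan")
    heart = row[[t for t in row.index if t in set(heart_tissues)]].dropna()
    other = row[[t for t in row.index if t not in set(heart_tissues)]].dropna()
    if heart.empty:
        raise ValidationError("no heart tissue values present")
    if len(other) < 2:
        raise ValidationError("need >= 2 non-heart tissues")
    num = float(heart.max())
    den = _AGGREGATORS[aggregator](other.to_numpy())
    if den == 0:
        return math.inf if num > 0 else 0.0
    return num / den


def cardiac_folds(matrix: ExpressionMatrix, aggregator: str = "median") -> pd.Series:
    """Vector of cardiac folds for every gene in an expression matrix."""
    return pd.Series(
        {
            gene: cardiac_fold(matrix.values.loc[gene], matrix.heart_tissues, aggregator)
            for gene in matrix.genes
        },
        name="cardiac_fold",
    )


def is_cardiac_enriched(
    fold: float, threshold: float = DEFAULT_FOLD_THRESHOLD, inclusive: bool = True
) -> bool:
    """Enrichment call at the fold threshold (inclusive by default)."""
    if math.isnan(fold):
        return False
    return fold >= threshold if inclusive else fold > threshold


def normalize_to_total(values: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Divide each row by its total across tissues.

    Nonzero rows sum to 1 afterwards; all-zero rows stay zero and are
    returned in the flag list.  Idempotent.
    """
    vals = values.astype(float)
    totals = vals.sum(axis=1)
    zero_rows = list(vals.index[totals == 0])
    if zero_rows:
        logger.warning("%d all-zero rows left unnormalized", len(zero_rows))
    safe = totals.replace(0, 1.0)
    return vals.div(safe, axis=0), zero_rows


def hierarchical_cluster(
    values: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "average",
) -> tuple[np.ndarray, list]:
    """Agglomerative clustering of rows for heatmap ordering.

    Returns the scipy linkage matrix and the leaf order (row labels).
    Deterministic for a given input; rows with missing values are an error.
    """
    if len(values) < 2:
        raise ValidationError("need >= 2 rows to cluster")
    if values.isna().to_numpy().any():
        raise ValidationError("missing values present; impute or drop before clustering")
    dists = pdist(values.to_numpy(dtype=float), metric=metric)
    linkage = hierarchy.linkage(dists, method=method)
    order = hierarchy.leaves_list(linkage)
    return linkage, [values.index[i] for i in order]


def heatmap_matrix(
    matrix: ExpressionMatrix, genes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Row-normalized expression for a gene subset, ordered by clustering."""
    vals = matrix.values if genes is None else matrix.values.loc[
        [g for g in genes if g in matrix.values.index]
    ]
    normed, _ = normalize_to_total(vals)
    if len(normed) >= 2:
        _, order = hierarchical_cluster(normed)
        normed = normed.loc[order]
    return normed
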