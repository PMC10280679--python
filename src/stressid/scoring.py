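"""Weighted stress scores, cohort summaries and factor grouping."""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .data_model import AnxietyClass, Dataset

__all__ = [
    "weighted_score",
    "athlete_scores",
    "column_summary",
    "factor_grouping",
    "factor_linkage",
    "class_proportions",
    "truncate2",
]


def weighted_score(
    scores: Sequence[float], weights: Sequence[float] | None = None
) -> float:
    """Weight-normalized score ``Q = sum(w_i e_i) / sum(w_i)``.

    Weights default to uniform (plain mean).  Q is bounded by
    ``[min(scores), max(scores)]`` and invariant under uniform rescaling of
    the weights.
    """
    e = np.asarray(scores, dtype=float).ravel()
    if e.size == 0:
        raise ValueError("empty score vector")
    if weights is None:
        w = np.ones_like(e)
    else:
        w = np.asarray(weights, dtype=float).ravel()
    if w.shape != e.shape:
        raise ValueError(f"{e.size} scores but {w.size} weights")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights sum to zero")
    return float((w * e).sum() / total)


def athlete_scores(
    ds: Dataset, weights: Sequence[float] | Mapping[str, float] | None = None
) -> dict[str, float]:
    """Per-athlete Q over all factors; weights by position or factor name."""
    if isinstance(weights, Mapping):
        try:
            weights = [weights[f] for f in ds.factor_names]
        except KeyError as exc:
            raise ValueError(f"missing weight for factor {exc.args[0]!r}") from None
    return {
        sid: weighted_score(ds.values[i], weights)
        for i, sid in enumerate(ds.ids)
    }


def truncate2(x: float) -> float:
    """Truncate (floor) to two decimals, tolerating float representation."""
    return math.floor(x * 100 + 1e-9) / 100


def column_summary(ds: Dataset) -> dict[str, float]:
    """Per-factor arithmetic mean, truncated to two decimals.

    Truncation, not rounding: the convention the bundled reference cohort's
    published averages follow.
    """
    if ds.n == 0:
        raise ValueError("empty dataset")
    means = ds.values.mean(axis=0)
    return {name: truncate2(float(m)) for name, m in zip(ds.factor_names, means)}


def factor_linkage(ds: Dataset) -> tuple[np.ndarray, list[str]]:
    """Average-linkage merge tree of factor columns under correlation
    distance (1 - Pearson r).  Zero-variance columns are excluded (their
    correlations are undefined) and reported separately by
    :func:`factor_grouping`."""
    usable = [f for f in ds.factor_names if np.std(ds.column(f)) > 0]
    if len(usable) < 2:
        raise ValueError("need at least two non-constant factor columns")
    cols = np.column_stack([ds.column(f) for f in usable])
    corr = np.corrcoef(cols, rowvar=False)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    return linkage(condensed, method="average"), usable


def factor_grouping(ds: Dataset, cut: float = 0.90) -> list[list[str]]:
    """Group factor columns by cutting the correlation dendrogram at ``cut``.

    Returns disjoint groups covering every factor.  Constant columns cannot
    be correlated and are isolated as singletons with a warning.
    """
    if ds.d < 2:
        raise ValueError("need at least two factors")
    if ds.n < 3:
        raise ValueError("need at least three samples")
    constant = [f for f in ds.factor_names if np.std(ds.column(f)) == 0]
    if constant:
        warnings.warn(
            f"constant factor columns isolated as singletons: {constant}",
            stacklevel=2,
        )
    usable = [f for f in ds.factor_names if f not in constant]
    groups: list[list[str]] = []
    if len(usable) == 1:
        groups.append([usable[0]])
    elif usable:
        Z, names = factor_linkage(ds)
        flat = fcluster(Z, t=cut, criterion="distance")
        by_label: dict[int, list[str]] = {}
        for name, lab in zip(names, flat):
            by_label.setdefault(int(lab), []).append(name)
        # deterministic order: by first factor appearance
        order = {f: i for i, f in enumerate(ds.factor_names)}
        groups.extend(
            sorted(
                (sorted(g, key=order.get) for g in by_label.values()),
                key=lambda g: order[g[0]],
            )
        )
    groups.extend([[f] for f in constant])
    return groups


def class_proportions(
    assignments: Sequence[AnxietyClass],
) -> dict[AnxietyClass, float]:
    """Percentage of athletes per anxiety class (sums to 100)."""
    assignments = list(assignments)
    if not assignments:
        raise ValueError("empty assignment list")
    n = len(assignments)
    return {
        cls: 100.0 * sum(1 for a in assignments if a == cls) / n
        for cls in AnxietyClass
    }
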