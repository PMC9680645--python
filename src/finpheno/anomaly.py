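"""Isolation-forest anomaly detection on spending-feature series.

An isolation tree recursively splits a subsample at a uniform random point
between the per-node min and max of a uniform random feature; anomalous
points isolate in few splits.  The anomaly score is

    s(x) = 2 ** (-E[h(x)] / c(psi))

where h(x) is the path length of x in a tree (terminal nodes contribute
c(size), the expected extra depth of an unbuilt subtree), psi the
subsample size, and c(n) = 2 H(n-1) - 2(n-1)/n the average path length of
an unsuccessful BST search.  Scores near 1 flag anomalies; points behaving
like the bulk score near 0.5.

Flagging is quantile-based: with contamination fraction rho, exactly
floor(rho * n) top-scoring points are flagged, earliest period first on
score ties.  Implemented in full (not wrapped) so the scoring internals
are independently assertable; the scikit-learn estimator serves only as a
cross-check in the test suite.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InsufficientDataError
from .features import FeaturePeriod

__all__ = [
    "IsolationTreeNode",
    "IsolationForestModel",
    "AnomalyReport",
    "average_path_length",
    "fit_isolation_forest",
    "anomaly_scores",
    "flag_outliers",
    "detect_anomalies",
    "write_anomaly_csv",
]

_EULER_GAMMA = 0.5772156649015329


def average_path_length(n: int | float) -> float:
    """c(n): expected path length of an unsuccessful BST search among n points."""
    if n <= 1:
        return 0.0
    if n == 2:
        return 1.0
    return 2.0 * (math.log(n - 1.0) + _EULER_GAMMA) - 2.0 * (n - 1.0) / n


@dataclass
class IsolationTreeNode:
    size: int
    feature: int | None = None
    split_value: float | None = None
    left: "IsolationTreeNode | None" = None
    right: "IsolationTreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class IsolationForestModel:
    trees: list[IsolationTreeNode]
    subsample_size: int
    n_trees: int
    seed: int
    n_features: int
    degenerate: bool = False  # constant input: no isolating split exists


def _build_tree(
    x: np.ndarray, depth: int, limit: int, rng: np.random.Generator
) -> IsolationTreeNode:
    n = x.shape[0]
    if n <= 1 or depth >= limit:
        return IsolationTreeNode(size=n)
    feat = int(rng.integers(x.shape[1]))
    lo, hi = x[:, feat].min(), x[:, feat].max()
    if lo == hi:
        # try the other features before giving up on this node
        spread = [f for f in range(x.shape[1]) if x[:, f].min() < x[:, f].max()]
        if not spread:
            return IsolationTreeNode(size=n)
        feat = spread[int(rng.integers(len(spread)))]
        lo, hi = x[:, feat].min(), x[:, feat].max()
    split = float(rng.uniform(lo, hi))
    mask = x[:, feat] < split
    return IsolationTreeNode(
        size=n,
        feature=feat,
        split_value=split,
        left=_build_tree(x[mask], depth + 1, limit, rng),
        right=_build_tree(x[~mask], depth + 1, limit, rng),
    )


def _as_matrix(values: Sequence[float] | np.ndarray) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x


def fit_isolation_forest(
    values: Sequence[float] | np.ndarray,
    n_trees: int = 100,
    subsample: int | None = None,
    seed: int = 0,
) -> IsolationForestModel:
    """Build an isolation forest on a 1-D series (or an (n, f) matrix).

    Each tree grows on a uniform random subsample of ``subsample`` points
    (default min(256, n)) to the standard height limit ceil(log2(psi)).
    Fully deterministic given ``seed``.
    """
    x = _as_matrix(values)
    n = x.shape[0]
    if n < 8:
        raise InsufficientDataError(f"need at least 8 points, got {n}")
    psi = min(256, n) if subsample is None else subsample
    if psi > n:
        raise ValueError(f"subsample {psi} exceeds n={n}")
    rng = np.random.default_rng(seed)
    limit = math.ceil(math.log2(psi))
    degenerate = bool(np.all(x == x[0]))
    trees = []
    for _ in range(n_trees):
        idx = rng.choice(n, size=psi, replace=False)
        trees.append(_build_tree(x[idx], 0, limit, rng))
    return IsolationForestModel(
        trees=trees, subsample_size=psi, n_trees=n_trees, seed=seed,
        n_features=x.shape[1], degenerate=degenerate,
    )


def _path_length(node: IsolationTreeNode, row: np.ndarray, depth: int = 0) -> float:
    while not node.is_leaf:
        node = node.left if row[node.feature] < node.split_value else node.right
        depth += 1
    return depth + average_path_length(node.size)


def anomaly_scores(
    model: IsolationForestModel, values: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Score each point: 2^(-mean path length / c(psi)), in (0, 1)."""
    x = _as_matrix(values)
    if x.shape[1] != model.n_features:
        raise ValueError("feature count mismatch with fitted model")
    if model.degenerate:
        return np.full(x.shape[0], 0.5)
    c = average_path_length(model.subsample_size)
    depths = np.array(
        [[_path_length(t, row) for t in model.trees] for row in x]
    ).mean(axis=1)
    return np.power(2.0, -depths / c)


@dataclass
class AnomalyReport:
    scores: np.ndarray
    flagged: np.ndarray  # boolean mask
    threshold: float
    contamination: float

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())


def flag_outliers(
    scores: Sequence[float] | np.ndarray, contamination: float
) -> AnomalyReport:
    """Flag the floor(contamination * n) top-scoring points.

    Score ties at the boundary break toward the earlier period (lower
    index).  The reported threshold is the (1 - contamination) empirical
    quantile of the scores.
    """
    if not 0 < contamination < 1:
        raise ValueError("contamination must be in (0, 1)")
    s = np.asarray(scores, dtype=float)
    n = s.size
    k = int(math.floor(contamination * n))
    threshold = float(np.quantile(s, 1 - contamination)) if n else float("nan")
    flagged = np.zeros(n, dtype=bool)
    if k == 0:
        warnings.warn("contamination too small: no points flagged", stacklevel=2)
    else:
        # sort by (-score, index): highest scores first, earlier index on ties
        top = sorted(range(n), key=lambda i: (-s[i], i))[:k]
        flagged[top] = True
    return AnomalyReport(scores=s, flagged=flagged, threshold=threshold,
                         contamination=contamination)


def detect_anomalies(
    periods: Sequence[FeaturePeriod],
    contamination: float = 0.05,
    n_trees: int = 100,
    subsample: int | None = None,
    seed: int = 0,
    endpoint: str = "frequency",
    exclude_partial: bool = True,
) -> AnomalyReport:
    """Fit-and-score the feature series (transductive) and flag outliers.

    Partial edge periods (clipped by the analysis span) carry mechanically
    depressed counts, so they are excluded from fitting and flagging by
    default; their entries in the returned report hold NaN scores and are
    never flagged.  The report stays index-aligned with ``periods``.
    """
    keep = [not (exclude_partial and p.partial) for p in periods]
    used = [p for p, k in zip(periods, keep) if k]
    values = [float(getattr(p, endpoint)) for p in used]
    model = fit_isolation_forest(values, n_trees=n_trees, subsample=subsample, seed=seed)
    sub_report = flag_outliers(anomaly_scores(model, values), contamination)
    if all(keep):
        return sub_report
    scores = np.full(len(periods), np.nan)
    flagged = np.zeros(len(periods), dtype=bool)
    scores[np.flatnonzero(keep)] = sub_report.scores
    flagged[np.flatnonzero(keep)] = sub_report.flagged
    return AnomalyReport(scores=scores, flagged=flagged,
                         threshold=sub_report.threshold,
                         contamination=contamination)


def write_anomaly_csv(
    periods: Sequence[FeaturePeriod], report: AnomalyReport, path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["period_start", "frequency", "score", "flagged"])
        for p, s, f in zip(periods, report.scores, report.flagged):
            w.writerow([p.period_start.isoformat(), p.frequency, repr(float(s)), bool(f)])


def flagged_periods(
    periods: Sequence[FeaturePeriod], report: AnomalyReport
) -> list[date]:
    return [p.period_start for p, f in zip(periods, report.flagged) if f]
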