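"""Conditional-inference regression tree.

Recursive partitioning in which a node is split only when some predictor
shows a permutation-test-significant association with the response after a
Bonferroni correction across predictors — the significance gate is the
stopping rule, so no pruning is needed.

This is a deliberately simplified variant of the full conditional-inference
framework: the per-predictor association statistic is |Pearson correlation|
with a Monte Carlo permutation p-value (not the general quadratic-form
influence statistic), and the cutpoint on the winning predictor maximizes
the standardized two-sample mean difference subject to a minimum node size.
Rows at a threshold route left (``x <= threshold``); thresholds are
midpoints between adjacent observed values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import DataError

logger = logging.getLogger(__name__)


@dataclass
class SplitNode:
    """A node of the fitted tree; leaves have ``predictor is None``."""

    n: int
    mean: float
    predictor: str | None = None
    threshold: float | None = None
    adj_p: float | None = None
    left: "SplitNode | None" = None
    right: "SplitNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.predictor is None


def _perm_pvalues(X: np.ndarray, y: np.ndarray, n_perm: int,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """|Pearson r| per predictor with permutation p-values (shared
    permutations across predictors). Constant predictors get r=0, p=1."""
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    yc = y - y.mean()
    sy = np.sqrt((yc ** 2).sum())
    ok = (sx > 0) & (sy > 0)
    sx_safe = np.where(sx > 0, sx, 1.0)
    r_obs = np.zeros(p)
    if sy > 0:
        r_obs = np.abs(Xc.T @ yc) / (sx_safe * sy)
    r_obs[~ok] = 0.0
    # permutation matrix of y, vectorized via argsort of uniform keys
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    Y = yc[order]                       # (n_perm, n)
    R = np.abs(Y @ Xc) / (sx_safe[None, :] * max(sy, 1e-300))  # (n_perm, p)
    pvals = (1 + (R >= r_obs[None, :] - 1e-15).sum(axis=0)) / (1 + n_perm)
    pvals[~ok] = 1.0
    return r_obs, pvals


def _best_cut(x: np.ndarray, y: np.ndarray, min_node: int) -> float | None:
    """Cutpoint on x maximizing the standardized two-sample mean difference,
    both sides holding at least ``min_node`` rows. None if no legal cut."""
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    n = len(xs)
    cum = np.cumsum(ys)
    cum2 = np.cumsum(ys ** 2)
    total, total2 = cum[-1], cum2[-1]
    best_t, best_stat = None, -np.inf
    for i in range(min_node - 1, n - min_node):
        if xs[i] == xs[i + 1]:
            continue   # cannot separate ties
        nl, nr = i + 1, n - i - 1
        ml, mr = cum[i] / nl, (total - cum[i]) / nr
        ssl = cum2[i] - nl * ml ** 2
        ssr = (total2 - cum2[i]) - nr * mr ** 2
        pooled_var = (ssl + ssr) / max(n - 2, 1)
        se = np.sqrt(max(pooled_var, 1e-300) * (1.0 / nl + 1.0 / nr))
        stat = abs(ml - mr) / se
        if stat > best_stat:
            best_stat = stat
            best_t = 0.5 * (xs[i] + xs[i + 1])
    return best_t


def fit_ctree(X: pd.DataFrame, y: np.ndarray, alpha: float = 0.05,
              n_perm: int = 9999, min_node: int = 20,
              seed: int = 0) -> SplitNode:
    """Fit the conditional-inference regression tree.

    Rows with missing predictor values are dropped (logged). At each node:
    permutation-test every predictor's |Pearson r| with the response,
    Bonferroni-adjust across predictors, stop if the best adjusted p is not
    below ``alpha`` or the node is too small to split, otherwise cut the
    winning predictor and recurse.
    """
    if n_perm < 99:
        raise DataError("n_perm < 99 gives too coarse a p resolution")
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise DataError("X and y length mismatch")
    mask = ~X.isna().any(axis=1).to_numpy() & ~np.isnan(y)
    dropped = int((~mask).sum())
    if dropped:
        logger.warning("fit_ctree: dropping %d rows with missing values", dropped)
    Xv = X.loc[mask].to_numpy(dtype=float)
    yv = y[mask]
    names = list(X.columns)
    rng = np.random.default_rng(seed)

    def grow(idx: np.ndarray) -> SplitNode:
        node = SplitNode(n=len(idx), mean=float(yv[idx].mean()))
        if len(idx) < 2 * min_node or np.allclose(yv[idx], yv[idx][0]):
            return node
        r, p = _perm_pvalues(Xv[idx], yv[idx], n_perm, rng)
        adj = np.minimum(p * len(names), 1.0)
        best = int(np.argmin(adj))
        if adj[best] >= alpha:
            return node
        t = _best_cut(Xv[idx, best], yv[idx], min_node)
        if t is None:
            return node
        go_left = Xv[idx, best] <= t
        node.predictor = names[best]
        node.threshold = float(t)
        node.adj_p = float(adj[best])
        node.left = grow(idx[go_left])
        node.right = grow(idx[~go_left])
        return node

    return grow(np.arange(len(yv)))


def predict(tree: SplitNode, row: pd.Series | dict) -> float:
    """Route one row through the tree (``<=`` goes left); returns the leaf mean."""
    node = tree
    while not node.is_leaf:
        if node.predictor not in row:
            raise DataError(f"row missing predictor {node.predictor!r}")
        node = node.left if row[node.predictor] <= node.threshold else node.right
    return node.mean


def tree_report(tree: SplitNode) -> pd.DataFrame:
    """Depth-first table of the tree's splits and leaves."""
    rows: list[dict] = []

    def walk(node: SplitNode, depth: int, path: str) -> None:
        rows.append({
            "depth": depth, "path": path or "root",
            "kind": "leaf" if node.is_leaf else "split",
            "n": node.n, "mean_response": node.mean,
            "predictor": node.predictor, "threshold": node.threshold,
            "adj_p": node.adj_p,
        })
        if not node.is_leaf:
            walk(node.left, depth + 1, path + "L")
            walk(node.right, depth + 1, path + "R")

    walk(tree, 0, "")
    return pd.DataFrame(rows)


def first_split(tree: SplitNode) -> tuple[str | None, float | None]:
    """The root split's (predictor, threshold); (None, None) for a stump."""
    return tree.predictor, tree.threshold
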