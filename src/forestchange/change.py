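"""Compositional change: Sørensen dissimilarity, per-town change between
eras, Monte Carlo / permutation tests, per-taxon abundance shifts, and
β-diversity (biotic homogenization).

The abundance-based Sørensen distance between towns j and k is

    S = Σ_i |x_ij − x_ik| / Σ_i (x_ij + x_ik)

over taxa i; with relative abundances the denominator is 2, so S is half the
L1 distance on the simplex — 0 for identical composition, 1 for disjoint
taxa. All significance tests use the (1 + exceedances) / (1 + n_rand)
permutation p-value convention so p is never exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CompositionTable, DataError

logger = logging.getLogger(__name__)


def sorensen(x: np.ndarray, y: np.ndarray) -> float:
    """Abundance-based Sørensen distance between two abundance vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError(f"length mismatch: {x.shape} vs {y.shape}")
    denom = (x + y).sum()
    if denom == 0:
        raise DataError("both vectors are identically zero")
    return float(np.abs(x - y).sum() / denom)


def sorensen_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise Sørensen distances between the rows of a composition matrix
    (rows sum to 1, so the pair denominator is 2)."""
    v = np.asarray(values, dtype=float)
    d = np.abs(v[:, None, :] - v[None, :, :]).sum(axis=2)
    d /= (v.sum(axis=1)[:, None] + v.sum(axis=1)[None, :])
    np.fill_diagonal(d, 0.0)
    return d


def _perm_p(observed: float, null: np.ndarray) -> float:
    return float((1 + int((null >= observed - 1e-15).sum())) / (1 + len(null)))


def paired_monte_carlo(pre: np.ndarray, mod: np.ndarray, n_rand: int = 10_000,
                       seed: int | np.random.Generator = 0) -> float:
    """Paired Monte Carlo test of a mean difference.

    Statistic: |mean(pre − mod)|. Null: each pair's labels are swapped
    independently with probability ½ (sign-flip null on the differences).
    Two-sided by the absolute value.
    """
    pre = np.asarray(pre, dtype=float)
    mod = np.asarray(mod, dtype=float)
    if pre.shape != mod.shape:
        raise DataError("paired vectors must have equal length")
    n = len(pre)
    if n < 2:
        raise DataError("need at least 2 pairs")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    diff = pre - mod
    observed = abs(diff.mean())
    signs = rng.choice([-1.0, 1.0], size=(n_rand, n))
    null = np.abs((signs * diff).mean(axis=1))
    return _perm_p(observed, null)


def group_permutation(values: np.ndarray, labels: np.ndarray,
                      n_rand: int = 10_000,
                      seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Pairwise group comparisons by label permutation.

    For each pair of labels, the statistic is the absolute difference of
    group means; the null shuffles the pooled values over the two groups.
    Returns a tidy frame (group_a, group_b, mean_a, mean_b, p). Pairs where
    either group is degenerate (n < 2) get p = NaN and a flag.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = sorted(pd.unique(labels).tolist())
    if len(uniq) < 2:
        raise DataError("need at least 2 groups")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    rows = []
    for i, a in enumerate(uniq):
        for b in uniq[i + 1:]:
            va, vb = values[labels == a], values[labels == b]
            row = {"group_a": a, "group_b": b,
                   "mean_a": va.mean() if len(va) else np.nan,
                   "mean_b": vb.mean() if len(vb) else np.nan,
                   "degenerate": len(va) < 2 or len(vb) < 2}
            if row["degenerate"]:
                row["p"] = np.nan
                logger.warning("group_permutation: degenerate pair (%s, %s)", a, b)
            else:
                pooled = np.concatenate([va, vb])
                na = len(va)
                observed = abs(va.mean() - vb.mean())
                # vectorized label shuffles: argsort of uniform keys
                order = np.argsort(rng.random((n_rand, len(pooled))), axis=1)
                perm = pooled[order]
                null = np.abs(perm[:, :na].mean(axis=1) - perm[:, na:].mean(axis=1))
                row["p"] = _perm_p(observed, null)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ChangeResult:
    """Per-town Sørensen change and its regional / ecoregion summaries."""

    per_town: pd.DataFrame          # town_id, change (and ecoregion if given)
    regional_mean: float
    regional_sd: float
    by_ecoregion: pd.DataFrame | None = None   # ecoregion, mean, sd, n
    ecoregion_pairs: pd.DataFrame | None = None


def change_per_town(pre: CompositionTable, mod: CompositionTable,
                    ecoregions: pd.Series | None = None,
                    n_rand: int = 10_000, seed: int = 0) -> ChangeResult:
    """Per-town Sørensen distance from pre-colonial to modern composition.

    Requires identical town sets and taxa orderings. With ``ecoregions``
    (town_id -> label) provided, adds per-ecoregion summaries and pairwise
    permutation comparisons.
    """
    if pre.taxa.codes != mod.taxa.codes:
        raise DataError("taxa orderings differ between eras")
    only_pre = sorted(set(pre.towns) - set(mod.towns))
    only_mod = sorted(set(mod.towns) - set(pre.towns))
    if only_pre or only_mod:
        raise DataError(
            f"towns present in one era only: pre-only {only_pre[:5]}, "
            f"modern-only {only_mod[:5]}")
    order = list(pre.towns)
    mv = mod.subset(order).values
    d = 0.5 * np.abs(pre.values - mv).sum(axis=1)
    per_town = pd.DataFrame({"town_id": order, "change": d})
    result = ChangeResult(per_town=per_town,
                          regional_mean=float(d.mean()),
                          regional_sd=float(d.std(ddof=1)) if len(d) > 1 else 0.0)
    if ecoregions is not None:
        eco = per_town["town_id"].map(ecoregions)
        per_town["ecoregion"] = eco
        g = per_town.groupby("ecoregion")["change"]
        result.by_ecoregion = (g.agg(mean="mean", sd=lambda s: s.std(ddof=1),
                                     n="size").reset_index())
        result.ecoregion_pairs = group_permutation(
            d, eco.to_numpy(), n_rand=n_rand, seed=seed)
    return result


@dataclass
class BetaDiversityResult:
    """Mean town-to-town dissimilarity per town and era, with the era test."""

    per_town: pd.DataFrame     # town_id, era, mean_dissimilarity
    era_summary: pd.DataFrame  # era, mean, sd, n
    p: float


def beta_diversity(pre: CompositionTable, mod: CompositionTable,
                   towns: list[str] | None = None,
                   n_rand: int = 10_000, seed: int = 0) -> BetaDiversityResult:
    """β-diversity as each town's mean Sørensen dissimilarity to all other
    towns, per era; a drop from the pre-colonial to the modern era indicates
    biotic homogenization. Eras are compared with a label permutation test
    on the per-town means."""
    towns = towns or [t for t in pre.towns if t in set(mod.towns)]
    if len(towns) < 3:
        raise DataError("beta diversity needs at least 3 towns")
    frames, means = [], {}
    for table in (pre, mod):
        sub = table.subset(towns)
        dm = sorensen_matrix(sub.values)
        m = (dm.sum(axis=1)) / (len(towns) - 1)   # excludes self (diag 0)
        means[table.era] = m
        frames.append(pd.DataFrame({"town_id": towns, "era": table.era,
                                    "mean_dissimilarity": m}))
    per_town = pd.concat(frames, ignore_index=True)
    vals = np.concatenate([means[pre.era], means[mod.era]])
    labels = np.array([pre.era] * len(towns) + [mod.era] * len(towns))
    p = float(group_permutation(vals, labels, n_rand=n_rand, seed=seed)["p"].iloc[0])
    era_summary = (per_town.groupby("era")["mean_dissimilarity"]
                   .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="size")
                   .reset_index())
    return BetaDiversityResult(per_town=per_town, era_summary=era_summary, p=p)


def abundance_change_table(pre: CompositionTable, mod: CompositionTable,
                           ecoregions: pd.Series | None = None,
                           n_rand: int = 10_000,
                           seed: int = 0) -> pd.DataFrame:
    """Per-taxon abundance change: unweighted town means per era, their
    difference, and a paired Monte Carlo p — regionally and (optionally)
    per ecoregion. No multiple-testing correction is applied across taxa."""
    towns = [t for t in pre.towns if t in set(mod.towns)]
    pv = pre.subset(towns).values
    mv = mod.subset(towns).values
    rng = np.random.default_rng(seed)
    scopes: list[tuple[str, np.ndarray]] = [("ALL", np.ones(len(towns), dtype=bool))]
    if ecoregions is not None:
        eco = pd.Series(towns).map(ecoregions)
        scopes += [(e, (eco == e).to_numpy()) for e in sorted(eco.unique())]
    rows = []
    for scope, mask in scopes:
        for i, code in enumerate(pre.taxa.codes):
            a, b = pv[mask, i], mv[mask, i]
            rows.append({
                "scope": scope, "taxon": code, "n_towns": int(mask.sum()),
                "pre_mean": a.mean(), "mod_mean": b.mean(),
                "delta": b.mean() - a.mean(),
                "p": paired_monte_carlo(a, b, n_rand=n_rand, seed=rng),
            })
    return pd.DataFrame(rows)
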