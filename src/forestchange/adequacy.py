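"""Sampling-adequacy screening.

Whether a town's trees adequately capture its compositional diversity is
decided by a bootstrap rarefaction curve: similarity (1 − Sørensen) between
a pooled bootstrap sample of n units and the full-town composition, for
n = 1..N units, repeated over many sets. A through-origin Michaelis-Menten
curve y = S_max·n/(k + n) is fit to each set; the sample size reaching
0.9·S_max is n = 9k (generally k·q/(1−q) at proportion q), and dividing by
town area gives a minimum sampling density D_min. Densities are averaged
over sets, then over the densest towns of each ecoregion, giving per-
ecoregion thresholds; a town enters the analysis only if both its
witness-tree and plot densities meet their thresholds.

Units are inventory plots on the modern side and random bins of 20 witness
trees on the pre-colonial side (bins re-randomized every set; leftover
trees beyond a multiple of 20 are dropped within the set).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .datamodel import MODERN, PRECOLONIAL, DataError, Dataset
from .taxa import UNBINNED

logger = logging.getLogger(__name__)

WT_BIN_SIZE = 20
MIN_PLOTS_ELIGIBLE = 5
MIN_WTS_ELIGIBLE = 100
TERCILE_PCT = 100.0 * 2.0 / 3.0


@dataclass
class SimilarityCurve:
    """Bootstrap similarity-vs-sample-size points for one town.

    ``points[s, n-1]`` is the similarity of set s's bootstrap sample of n
    units to the full-town composition.
    """

    unit_kind: str                # "fia_plot" | "wt_bin20"
    points: np.ndarray            # (n_sets, n_units)

    @property
    def n_sets(self) -> int:
        return self.points.shape[0]

    @property
    def n_units(self) -> int:
        return self.points.shape[1]

    def mean_curve(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class MMFit:
    """A Michaelis-Menten fit of one similarity curve set."""

    s_max: float
    k_half: float
    d_min_units: float
    rss: float
    converged: bool
    d_min_density: float | None = None   # filled once divided by town area


def _pool_similarity(counts: np.ndarray, idx: np.ndarray,
                     full: np.ndarray) -> float:
    """Similarity (1 − Sørensen) of pooled unit counts vs. the full town."""
    pooled = counts[idx].sum(axis=0).astype(float)
    total = pooled.sum()
    if total == 0:
        return 0.0
    pooled /= total
    return 1.0 - 0.5 * np.abs(pooled - full).sum()


def bootstrap_curve(unit_counts: np.ndarray, unit_kind: str = "fia_plot",
                    n_sets: int = 100,
                    seed: int | np.random.Generator = 0,
                    replace: bool = True) -> SimilarityCurve:
    """Bootstrap the similarity curve over pre-formed units.

    ``unit_counts`` is an (n_units × n_taxa) stem-count matrix, one row per
    unit (plot or witness-tree bin). For each set and each n = 1..N, one
    sample of n units is drawn (with replacement by default; ``replace=
    False`` is a census check where n = N reproduces the town exactly).
    """
    counts = np.asarray(unit_counts, dtype=float)
    n_units = counts.shape[0]
    if n_units < 1:
        raise DataError("no units to bootstrap")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    full = counts.sum(axis=0)
    full = full / full.sum()
    pts = np.empty((n_sets, n_units))
    for s in range(n_sets):
        for n in range(1, n_units + 1):
            idx = (rng.integers(0, n_units, size=n) if replace
                   else rng.choice(n_units, size=n, replace=False))
            pts[s, n - 1] = _pool_similarity(counts, idx, full)
    return SimilarityCurve(unit_kind=unit_kind, points=pts)


def wt_bin_counts(taxon_idx: np.ndarray, n_taxa: int,
                  rng: np.random.Generator,
                  bin_size: int = WT_BIN_SIZE) -> np.ndarray:
    """Randomly partition witness trees into bins of ``bin_size`` and return
    the per-bin taxon count matrix; leftover trees are dropped."""
    n_bins = len(taxon_idx) // bin_size
    if n_bins < 1:
        raise DataError(f"fewer than {bin_size} witness trees")
    perm = rng.permutation(len(taxon_idx))[: n_bins * bin_size]
    counts = np.zeros((n_bins, n_taxa))
    for b in range(n_bins):
        sel = taxon_idx[perm[b * bin_size:(b + 1) * bin_size]]
        np.add.at(counts[b], sel, 1.0)
    return counts


def bootstrap_curve_wt(taxon_idx: np.ndarray, n_taxa: int, n_sets: int = 100,
                       seed: int | np.random.Generator = 0) -> SimilarityCurve:
    """Witness-tree variant: bins are re-randomized for every set, then the
    set's curve is bootstrapped over its bins. The full-town reference uses
    all trees (not just the binned subset)."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    full = np.bincount(taxon_idx, minlength=n_taxa).astype(float)
    full /= full.sum()
    n_bins = len(taxon_idx) // WT_BIN_SIZE
    if n_bins < 1:
        raise DataError("town has fewer than one witness-tree bin")
    pts = np.empty((n_sets, n_bins))
    for s in range(n_sets):
        counts = wt_bin_counts(taxon_idx, n_taxa, rng)
        for n in range(1, n_bins + 1):
            idx = rng.integers(0, n_bins, size=n)
            pts[s, n - 1] = _pool_similarity(counts, idx, full)
    return SimilarityCurve(unit_kind="wt_bin20", points=pts)


def _mm(n, s_max, k):
    return s_max * n / (k + n)


def fit_mm(n_vals: np.ndarray, sims: np.ndarray,
           proportion: float = 0.9) -> MMFit:
    """Least-squares through-origin Michaelis-Menten fit.

    Returns the asymptote S_max ∈ (0, 1], half-saturation k, and the unit
    count reaching ``proportion``·S_max — the closed form k·q/(1−q), which
    is 9k at the default q = 0.9.
    """
    n_vals = np.asarray(n_vals, dtype=float)
    sims = np.asarray(sims, dtype=float)
    if len(np.unique(n_vals)) < 3:
        raise DataError("need at least 3 distinct sample sizes")
    try:
        (s_max, k), _ = curve_fit(
            _mm, n_vals, sims,
            p0=(min(max(sims.max(), 1e-3), 1.0), 1.0),
            bounds=([1e-9, 1e-9], [1.0, np.inf]), maxfev=2000)
        converged = True
    except RuntimeError:
        logger.warning("M-M fit failed to converge")
        return MMFit(np.nan, np.nan, np.nan, np.nan, converged=False)
    rss = float(((sims - _mm(n_vals, s_max, k)) ** 2).sum())
    d_min_units = float(k * proportion / (1.0 - proportion))
    return MMFit(float(s_max), float(k), d_min_units, rss, converged=True)


@dataclass
class AdequacyThreshold:
    """Per-ecoregion minimum sampling densities (units per km²)."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: ecoregion, d_min_plots_per_km2, n_towns_plots,
    #          d_min_wts_per_km2, n_towns_wts

    def lookup(self, ecoregion: str) -> tuple[float, float]:
        row = self.table.loc[self.table["ecoregion"] == ecoregion]
        if len(row) != 1:
            raise DataError(f"no threshold for ecoregion {ecoregion!r}")
        return (float(row["d_min_plots_per_km2"].iloc[0]),
                float(row["d_min_wts_per_km2"].iloc[0]))


def _plot_count_matrix(trees: pd.DataFrame, plot_ids: list[str],
                       taxa_codes: tuple[str, ...]) -> np.ndarray:
    sub = trees[trees["plot_id"].isin(plot_ids) & (trees["taxon_code"] != UNBINNED)]
    counts = (sub.groupby(["plot_id", "taxon_code"]).size().unstack(fill_value=0)
              .reindex(index=plot_ids, columns=list(taxa_codes), fill_value=0))
    return counts.to_numpy(dtype=float)


def town_densities(dataset: Dataset) -> pd.DataFrame:
    """Per-town unit counts and densities (plots/km², WTs/km²)."""
    towns = dataset.towns[["town_id", "ecoregion", "area_km2"]].copy()
    plot_n = dataset.plots.groupby("town_id").size()
    wt_n = (dataset.trees[dataset.trees["era"] == PRECOLONIAL]
            .groupby("town_id").size())
    towns["n_plots"] = towns["town_id"].map(plot_n).fillna(0).astype(int)
    towns["n_wts"] = towns["town_id"].map(wt_n).fillna(0).astype(int)
    towns["plot_density"] = towns["n_plots"] / towns["area_km2"]
    towns["wt_density"] = towns["n_wts"] / towns["area_km2"]
    return towns


def _eligible(towns: pd.DataFrame, count_col: str, density_col: str,
              min_count: int) -> pd.DataFrame:
    """Most densely sampled towns per ecoregion: at least ``min_count`` units
    and density at or above the upper-tercile boundary (closed)."""
    out = []
    for eco, grp in towns.groupby("ecoregion"):
        grp = grp[grp[count_col] >= min_count]
        if len(grp) == 0:
            continue
        cut = np.percentile(grp[density_col], TERCILE_PCT)
        out.append(grp[grp[density_col] >= cut])
    if not out:
        return towns.iloc[0:0]
    return pd.concat(out)


def _town_mean_dmin(curve: SimilarityCurve, area_km2: float,
                    proportion: float) -> float | None:
    """Fit each bootstrap set's curve; mean converged D_min per km²."""
    n_vals = np.arange(1, curve.n_units + 1)
    dmins = []
    for s in range(curve.n_sets):
        fit = fit_mm(n_vals, curve.points[s], proportion=proportion)
        if fit.converged:
            dmins.append(fit.d_min_units / area_km2)
    if not dmins:
        return None
    return float(np.mean(dmins))


def ecoregion_thresholds(dataset: Dataset, n_sets: int = 100,
                         proportion: float = 0.9,
                         seed: int = 0) -> AdequacyThreshold:
    """Estimate per-ecoregion minimum plot and witness-tree densities.

    Expects the dataset's plots/trees to be already filtered. Towns whose
    fits never converge are excluded from averaging with a log message; an
    ecoregion with no eligible town gets a NaN threshold and a warning.
    """
    rng = np.random.default_rng(seed)
    towns = town_densities(dataset)
    taxa_codes = dataset.taxa.codes
    n_taxa = len(taxa_codes)

    plot_elig = _eligible(towns, "n_plots", "plot_density", MIN_PLOTS_ELIGIBLE)
    wt_elig = _eligible(towns, "n_wts", "wt_density", MIN_WTS_ELIGIBLE)
    plots_by_town = dataset.plots.groupby("town_id")
    wt_trees = dataset.trees[(dataset.trees["era"] == PRECOLONIAL)
                             & (dataset.trees["taxon_code"] != UNBINNED)]
    code_index = {c: i for i, c in enumerate(taxa_codes)}

    plot_dmin: dict[str, float] = {}
    for rec in plot_elig.itertuples():
        plot_ids = plots_by_town.get_group(rec.town_id)["plot_id"].tolist()
        counts = _plot_count_matrix(dataset.trees, plot_ids, taxa_codes)
        curve = bootstrap_curve(counts, "fia_plot", n_sets=n_sets, seed=rng)
        d = _town_mean_dmin(curve, rec.area_km2, proportion)
        if d is None:
            logger.warning("town %s: no converged plot fits, excluded", rec.town_id)
        else:
            plot_dmin[rec.town_id] = d

    wt_dmin: dict[str, float] = {}
    for rec in wt_elig.itertuples():
        codes = wt_trees.loc[wt_trees["town_id"] == rec.town_id, "taxon_code"]
        idx = np.array([code_index[c] for c in codes], dtype=int)
        curve = bootstrap_curve_wt(idx, n_taxa, n_sets=n_sets, seed=rng)
        d = _town_mean_dmin(curve, rec.area_km2, proportion)
        if d is None:
            logger.warning("town %s: no converged WT fits, excluded", rec.town_id)
        else:
            wt_dmin[rec.town_id] = d

    rows = []
    for eco in sorted(dataset.towns["ecoregion"].unique()):
        eco_towns = set(towns.loc[towns["ecoregion"] == eco, "town_id"])
        pvals = [v for t, v in plot_dmin.items() if t in eco_towns]
        wvals = [v for t, v in wt_dmin.items() if t in eco_towns]
        if not pvals or not wvals:
            logger.warning("ecoregion %s: no eligible towns on some path; "
                           "threshold undefined", eco)
        rows.append({
            "ecoregion": eco,
            "d_min_plots_per_km2": float(np.mean(pvals)) if pvals else np.nan,
            "n_towns_plots": len(pvals),
            "d_min_wts_per_km2": float(np.mean(wvals)) if wvals else np.nan,
            "n_towns_wts": len(wvals),
        })
    return AdequacyThreshold(table=pd.DataFrame(rows))


def screen_towns(dataset: Dataset, thresholds: AdequacyThreshold) -> list[str]:
    """Towns whose witness-tree AND plot densities meet their ecoregion's
    thresholds (closed bounds: a town exactly at a threshold is included).
    Towns in ecoregions with undefined thresholds are excluded."""
    towns = town_densities(dataset)
    thr = thresholds.table.set_index("ecoregion")
    included = []
    for rec in towns.itertuples():
        if rec.ecoregion not in thr.index:
            continue
        p_thr = thr.loc[rec.ecoregion, "d_min_plots_per_km2"]
        w_thr = thr.loc[rec.ecoregion, "d_min_wts_per_km2"]
        if np.isnan(p_thr) or np.isnan(w_thr):
            continue
        if rec.plot_density >= p_thr and rec.wt_density >= w_thr:
            included.append(rec.town_id)
    return included
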