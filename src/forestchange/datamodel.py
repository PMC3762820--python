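"""Core data model: record schemas, composition tables, and the record-level
filtering rules applied to the modern inventory.

Records live in pandas DataFrames with fixed column schemas rather than
per-record objects; the schemas are documented by the ``*_COLUMNS`` constants
below and enforced by :func:`validate_trees` / :func:`validate_plots`.

Eras
----
``precolonial``
    Witness trees recorded by colonial lot surveyors: a town id and a raw
    name, no plot structure and no diameter.
``modern``
    Inventory trees on clustered fixed-radius plots: species, dbh (cm) and a
    plot id, the plot carrying a condition class (Forest / Nonforest).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .taxa import UNBINNED, TaxonSet, bin_taxon

logger = logging.getLogger(__name__)

PRECOLONIAL = "precolonial"
MODERN = "modern"
ERAS = (PRECOLONIAL, MODERN)

TREE_COLUMNS = ("town_id", "era", "raw_name", "taxon_code", "dbh_cm", "plot_id")
PLOT_COLUMNS = ("plot_id", "town_id", "condition_class")

#: Covariate vocabulary for the per-town predictor table: climate (growing
#: degree days, precipitation), terrain, land-use history (agricultural-census
#: derived), canopy cover, soils, and position.
COVARIATE_NAMES = (
    "gdd", "precip_mm", "elevation_m", "ruggedness_m",
    "peak_agriculture", "peak_agriculture_year", "agri_decline_rate",
    "canopy_cover_pct", "soil_sand_pct", "soil_clay_pct",
    "latitude", "longitude",
)

TOWN_BASE_COLUMNS = ("town_id", "ecoregion", "centroid_lat", "centroid_lon", "area_km2")


class DataError(ValueError):
    """Raised for malformed or referentially inconsistent input data."""


def validate_trees(trees: pd.DataFrame) -> None:
    missing = set(TREE_COLUMNS) - set(trees.columns)
    if missing:
        raise DataError(f"tree table missing columns: {sorted(missing)}")
    bad_era = set(trees["era"].unique()) - set(ERAS)
    if bad_era:
        raise DataError(f"unknown era labels: {sorted(bad_era)}")
    modern = trees[trees["era"] == MODERN]
    if modern["dbh_cm"].isna().any() or modern["plot_id"].isna().any():
        raise DataError("modern tree records must carry dbh_cm and plot_id")
    pre = trees[trees["era"] == PRECOLONIAL]
    if pre["dbh_cm"].notna().any() or pre["plot_id"].notna().any():
        raise DataError("precolonial (witness tree) records carry neither dbh_cm nor plot_id")


def validate_plots(plots: pd.DataFrame, trees: pd.DataFrame | None = None) -> None:
    missing = set(PLOT_COLUMNS) - set(plots.columns)
    if missing:
        raise DataError(f"plot table missing columns: {sorted(missing)}")
    if plots["plot_id"].duplicated().any():
        dup = plots.loc[plots["plot_id"].duplicated(), "plot_id"].tolist()
        raise DataError(f"duplicate plot ids: {dup[:5]}")
    if trees is not None:
        # every tree on a plot must share the plot's town
        modern = trees[trees["era"] == MODERN]
        merged = modern.merge(plots, on="plot_id", how="left", suffixes=("", "_plot"))
        if merged["town_id_plot"].isna().any():
            orphans = sorted(merged.loc[merged["town_id_plot"].isna(), "plot_id"].unique())
            raise DataError(f"trees reference unknown plots: {orphans[:5]}")
        clash = merged["town_id"] != merged["town_id_plot"]
        if clash.any():
            raise DataError("tree town_id disagrees with its plot's town_id")


@dataclass
class CompositionTable:
    """Town × taxon relative-abundance matrix for one era.

    Every row is a probability vector over ``taxa.codes`` (sums to 1 within
    1e-9); towns that retained zero trees are excluded before construction.
    """

    towns: list[str]
    taxa: TaxonSet
    values: np.ndarray
    era: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.towns), len(self.taxa)):
            raise DataError(
                f"composition shape {self.values.shape} != "
                f"({len(self.towns)}, {len(self.taxa)})"
            )
        if self.era not in ERAS:
            raise DataError(f"unknown era {self.era!r}")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise DataError("relative abundances must lie in [0, 1]")
        sums = self.values.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = [t for t, s in zip(self.towns, sums) if abs(s - 1.0) > 1e-9]
            raise DataError(f"composition rows must sum to 1; offending towns: {bad[:5]}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.towns, name="town_id"),
                            columns=list(self.taxa.codes))

    def row(self, town_id: str) -> np.ndarray:
        return self.values[self.towns.index(town_id)]

    def subset(self, towns: list[str]) -> "CompositionTable":
        idx = [self.towns.index(t) for t in towns]
        return CompositionTable(list(towns), self.taxa, self.values[idx], self.era)


@dataclass
class Dataset:
    """A loaded study: towns with covariates, inventory plots, and tree records."""

    towns: pd.DataFrame
    plots: pd.DataFrame
    trees: pd.DataFrame
    taxa: TaxonSet = field(default_factory=TaxonSet)

    def town_ids(self) -> list[str]:
        return self.towns["town_id"].tolist()


def bin_trees(trees: pd.DataFrame, taxon_set: TaxonSet) -> pd.DataFrame:
    """Assign ``taxon_code`` to every record; UNBINNED records are retained
    and flagged (downstream composition excludes them with a logged count)."""
    out = trees.copy()
    out["taxon_code"] = [bin_taxon(n, taxon_set) for n in out["raw_name"]]
    n_unbinned = int((out["taxon_code"] == UNBINNED).sum())
    if n_unbinned:
        logger.warning("%d tree records did not bin to any taxon group", n_unbinned)
    return out


def filter_modern(
    plots: pd.DataFrame,
    trees: pd.DataFrame,
    min_dbh_cm: float = 12.5,
    min_trees: int = 10,
    min_plots_per_town: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Apply the modern-inventory inclusion rules.

    1. Drop trees below ``min_dbh_cm`` (closed bound: dbh == threshold kept).
    2. Keep only plots classed ``Forest`` with at least ``min_trees``
       qualifying trees.
    3. Drop towns left with fewer than ``min_plots_per_town`` plots.

    Returns the surviving plots and modern trees plus the dropped town ids.
    Idempotent: re-applying to its own output is the identity.
    """
    modern = trees[trees["era"] == MODERN]
    if len(plots) == 0 or len(modern) == 0:
        logger.warning("filter_modern: empty input")
        return plots.iloc[0:0].copy(), modern.iloc[0:0].copy(), []

    big = modern[modern["dbh_cm"] >= min_dbh_cm]
    per_plot = big.groupby("plot_id").size()
    forest_ids = set(plots.loc[plots["condition_class"] == "Forest", "plot_id"])
    keep_plots = {p for p, n in per_plot.items() if n >= min_trees and p in forest_ids}

    plots2 = plots[plots["plot_id"].isin(keep_plots)]
    per_town = plots2.groupby("town_id").size()
    keep_towns = set(per_town[per_town >= min_plots_per_town].index)
    towns_dropped = sorted(set(plots["town_id"].unique()) - keep_towns)

    plots3 = plots2[plots2["town_id"].isin(keep_towns)].reset_index(drop=True)
    trees3 = big[big["plot_id"].isin(set(plots3["plot_id"]))].reset_index(drop=True)
    logger.info(
        "filter_modern: %d/%d plots, %d/%d trees retained; %d towns dropped",
        len(plots3), len(plots), len(trees3), len(modern), len(towns_dropped),
    )
    return plots3, trees3, towns_dropped


def town_composition(trees: pd.DataFrame, taxon_set: TaxonSet) -> np.ndarray:
    """Relative abundance vector for one town: pooled stem proportions.

    Stems are pooled across the town's retained trees (witness trees have no
    plot structure, so pooling keeps the two eras symmetric). UNBINNED
    records are excluded.
    """
    binned = trees[trees["taxon_code"] != UNBINNED]
    if len(binned) == 0:
        raise DataError("town has zero binned trees")
    counts = np.zeros(len(taxon_set))
    for code, n in binned.groupby("taxon_code").size().items():
        counts[taxon_set.index(code)] = n
    return counts / counts.sum()


def composition_table(
    trees: pd.DataFrame,
    taxon_set: TaxonSet,
    era: str,
    towns: list[str] | None = None,
) -> CompositionTable:
    """Build the town × taxon table for one era by pooling stems per town.

    Towns with zero binned trees are excluded with a logged count. ``towns``
    fixes the row order (towns absent from it are dropped).
    """
    sub = trees[(trees["era"] == era) & (trees["taxon_code"] != UNBINNED)]
    counts = (
        sub.groupby(["town_id", "taxon_code"]).size().unstack(fill_value=0)
        .reindex(columns=list(taxon_set.codes), fill_value=0)
    )
    if towns is not None:
        present = [t for t in towns if t in counts.index]
        skipped = [t for t in towns if t not in counts.index]
        if skipped:
            logger.warning("%s composition: %d towns with zero trees excluded",
                           era, len(skipped))
        counts = counts.loc[present]
    if len(counts) == 0:
        raise DataError(f"no towns with {era} trees")
    values = counts.to_numpy(dtype=float)
    values /= values.sum(axis=1, keepdims=True)
    return CompositionTable(list(counts.index), taxon_set, values, era)
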