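"""Readers and writers for the study's on-disk formats.

Formats
-------
Witness-tree CSV
    ``town_id, raw_name`` — one row per surveyed tree.
Modern inventory CSV
    ``town_id, plot_id, raw_name, dbh_cm, condition_class`` — one row per
    inventory tree; the plot table is derived from the per-tree plot columns.
Town GeoJSON
    FeatureCollection of (Multi)Polygons with properties ``town_id`` and
    ``ecoregion``; centroids and areas (km²) are computed from the geometry.
Covariate CSV
    ``town_id`` plus columns from the per-town predictor vocabulary
    (:data:`forestchange.datamodel.COVARIATE_NAMES`).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import shape

from . import geo
from .datamodel import (
    COVARIATE_NAMES, MODERN, PRECOLONIAL, DataError, Dataset,
    bin_trees, validate_plots, validate_trees,
)
from .taxa import TaxonSet

logger = logging.getLogger(__name__)

WITNESS_CSV_COLUMNS = ("town_id", "raw_name")
MODERN_CSV_COLUMNS = ("town_id", "plot_id", "raw_name", "dbh_cm", "condition_class")


def read_tree_csv(path: str | Path) -> pd.DataFrame:
    """Read one era's tree CSV into the shared tree schema.

    The era is inferred from the header: plot/dbh columns mark a modern
    inventory file, their absence a witness-tree file.
    """
    df = pd.read_csv(path, dtype={"town_id": str})
    cols = set(df.columns)
    if set(MODERN_CSV_COLUMNS) <= cols:
        df["plot_id"] = df["plot_id"].astype(str)
        trees = pd.DataFrame({
            "town_id": df["town_id"],
            "era": MODERN,
            "raw_name": df["raw_name"],
            "taxon_code": pd.NA,
            "dbh_cm": df["dbh_cm"].astype(float),
            "plot_id": df["plot_id"],
        })
        trees.attrs["condition"] = df[["plot_id", "town_id", "condition_class"]]
        return trees
    if set(WITNESS_CSV_COLUMNS) <= cols:
        return pd.DataFrame({
            "town_id": df["town_id"],
            "era": PRECOLONIAL,
            "raw_name": df["raw_name"],
            "taxon_code": pd.NA,
            "dbh_cm": np.nan,
            "plot_id": pd.NA,
        })
    raise DataError(f"{path}: unrecognized tree CSV header {sorted(cols)}")


def read_town_geojson(path: str | Path) -> pd.DataFrame:
    """Read the town FeatureCollection; returns the town table with
    centroids (decimal degrees) and polygon areas (km²)."""
    with open(path) as fh:
        try:
            gj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise DataError(f"{path}: malformed GeoJSON ({exc})") from exc
    if gj.get("type") != "FeatureCollection":
        raise DataError(f"{path}: expected a FeatureCollection")
    rows = []
    for feat in gj.get("features", []):
        props = feat.get("properties", {})
        if "town_id" not in props or "ecoregion" not in props:
            raise DataError(f"{path}: feature missing town_id/ecoregion properties")
        geom = shape(feat["geometry"])
        c = geom.centroid
        if geom.geom_type == "Polygon":
            rings = [geom.exterior]
        elif geom.geom_type == "MultiPolygon":
            rings = [p.exterior for p in geom.geoms]
        else:
            raise DataError(f"{path}: unsupported geometry {geom.geom_type}")
        area = sum(
            geo.polygon_area_km2(np.array(r.coords)[:, 0], np.array(r.coords)[:, 1])
            for r in rings
        )
        if area <= 0:
            raise DataError(f"town {props['town_id']}: nonpositive area")
        rows.append({
            "town_id": str(props["town_id"]),
            "ecoregion": str(props["ecoregion"]),
            "centroid_lat": c.y,
            "centroid_lon": c.x,
            "area_km2": area,
        })
    if not rows:
        raise DataError(f"{path}: no town features")
    towns = pd.DataFrame(rows)
    if towns["town_id"].duplicated().any():
        dup = towns.loc[towns["town_id"].duplicated(), "town_id"].tolist()
        raise DataError(f"duplicate town ids in GeoJSON: {dup[:5]}")
    return towns


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"town_id": str})
    if "town_id" not in df.columns:
        raise DataError(f"{path}: covariate CSV needs a town_id column")
    unknown = set(df.columns) - {"town_id"} - set(COVARIATE_NAMES)
    if unknown:
        logger.warning("covariate columns outside the standard vocabulary "
                       "ignored: %s", sorted(unknown))
        df = df.drop(columns=sorted(unknown))
    return df


def load_dataset(
    tree_csv_paths: Sequence[str | Path],
    town_geojson_path: str | Path,
    covariate_csv_path: str | Path,
    taxon_set: TaxonSet | None = None,
) -> Dataset:
    """Load and cross-validate a study from disk.

    Trees are binned to taxon groups on load. Referential integrity is
    enforced: every tree/plot town_id must exist in the town table, and the
    covariate table must cover every town.
    """
    taxon_set = taxon_set or TaxonSet()
    frames, cond_frames = [], []
    for p in tree_csv_paths:
        t = read_tree_csv(p)
        if "condition" in t.attrs:
            cond_frames.append(t.attrs["condition"])
        frames.append(t)
    trees = pd.concat(frames, ignore_index=True)
    if len(trees) == 0:
        raise DataError("no records in tree files")
    trees = bin_trees(trees, taxon_set)
    validate_trees(trees)

    if cond_frames:
        plots = (pd.concat(cond_frames, ignore_index=True)
                 .drop_duplicates(subset="plot_id").reset_index(drop=True))
    else:
        plots = pd.DataFrame(columns=["plot_id", "town_id", "condition_class"])
    validate_plots(plots, trees)

    towns = read_town_geojson(town_geojson_path)
    known = set(towns["town_id"])
    orphans = sorted(set(trees["town_id"]) - known)
    if orphans:
        raise DataError(f"tree records reference unknown towns: {orphans[:10]}")
    orphans = sorted(set(plots["town_id"]) - known)
    if orphans:
        raise DataError(f"plots reference unknown towns: {orphans[:10]}")

    cov = read_covariates(covariate_csv_path)
    missing = sorted(known - set(cov["town_id"]))
    if missing:
        raise DataError(f"covariate table missing towns: {missing[:10]}")
    towns = towns.merge(cov, on="town_id", how="left")
    # polygon-derived position wins over any loaded latitude/longitude column
    towns["latitude"] = towns["centroid_lat"]
    towns["longitude"] = towns["centroid_lon"]
    return Dataset(towns=towns, plots=plots, trees=trees, taxa=taxon_set)


def write_run_metadata(path: str | Path, **fields) -> None:
    """Write the JSON run-metadata sidecar (seed, config, filter counts)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(fields, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
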