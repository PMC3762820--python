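"""Synthetic landscapes with known ground truth.

The generator builds a grid of towns along a latitudinal temperature
gradient (growing degree days, GDD), gives every taxon group a Gaussian
niche response on that gradient, and derives each town's modern composition
from its pre-colonial one through per-taxon era-shift multipliers — constant
(chestnut extirpation: multiplier 0) or linear in the town's historical
agricultural clearing (beech/hemlock decline, maple/cherry rise). Witness
trees are multinomial draws from the pre-colonial profile; the modern
inventory draws clustered fixed-radius plots whose plot-level profiles come
from a Dirichlet around the town profile (within-town clustering), then
multinomial tree draws with diameters above the retention threshold.

Everything is deterministic under the config seed, and the generator emits
exactly the CSV/GeoJSON dialects :mod:`forestchange.io` reads.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import MODERN, PRECOLONIAL, DataError, Dataset, bin_trees
from .taxa import DEFAULT_CODES, TaxonSet

logger = logging.getLogger(__name__)

# Representative raw names used for sampled records: colloquial for witness
# trees (as surveyors wrote), Latin binomials for the modern inventory.
_WT_NAME = {
    "ASHES": "white ash", "BASSWOOD": "basswood", "BEECH": "beech",
    "BIRCHES": "yellow birch", "BLACKGUM": "black gum", "CEDAR": "white cedar",
    "CHERRIES": "black cherry", "CHESTNUT": "chestnut",
    "CYPRESS": "bald cypress", "ELMS": "white elm", "FIR": "balsam fir",
    "HEMLOCK": "hemlock", "HICKORIES": "shagbark hickory",
    "HORNBEAM": "ironwood", "MAGNOLIAS": "magnolia", "MAPLE": "red maple",
    "OAK": "white oak", "PINES": "white pine", "POPLARS": "aspen",
    "SPRUCES": "red spruce", "SYCAMORE": "sycamore", "TAMARACK": "tamarack",
    "TULIP": "tulip tree", "WALNUTS": "black walnut",
}
_FIA_NAME = {
    "ASHES": "Fraxinus americana", "BASSWOOD": "Tilia americana",
    "BEECH": "Fagus grandifolia", "BIRCHES": "Betula alleghaniensis",
    "BLACKGUM": "Nyssa sylvatica", "CEDAR": "Thuja occidentalis",
    "CHERRIES": "Prunus serotina", "CHESTNUT": "Castanea dentata",
    "CYPRESS": "Taxodium distichum", "ELMS": "Ulmus americana",
    "FIR": "Abies balsamea", "HEMLOCK": "Tsuga canadensis",
    "HICKORIES": "Carya ovata", "HORNBEAM": "Ostrya virginiana",
    "MAGNOLIAS": "Magnolia acuminata", "MAPLE": "Acer rubrum",
    "OAK": "Quercus rubra", "PINES": "Pinus strobus",
    "POPLARS": "Populus tremuloides", "SPRUCES": "Picea rubens",
    "SYCAMORE": "Platanus occidentalis", "TAMARACK": "Larix laricina",
    "TULIP": "Liriodendron tulipifera", "WALNUTS": "Juglans nigra",
}

# Gaussian niche per taxon on the GDD axis: (optimum GDD, width, peak mass).
# Optima order the taxa along the gradient (boreal spruce/fir at the cold
# end, oak/hickory/chestnut at the warm end); peaks are scaled so regional
# mean pre-colonial abundances echo a beech/oak-dominated northeastern
# forest.
DEFAULT_NICHES: dict[str, tuple[float, float, float]] = {
    "SPRUCES": (2500, 450, 0.55),
    "FIR": (2550, 400, 0.15),
    "TAMARACK": (2600, 350, 0.02),
    "CEDAR": (2800, 450, 0.08),
    "BIRCHES": (3000, 700, 0.35),
    "BEECH": (3300, 600, 1.00),
    "HEMLOCK": (3350, 650, 0.50),
    "MAPLE": (3400, 800, 0.50),
    "ASHES": (3450, 700, 0.10),
    "POPLARS": (3100, 700, 0.04),
    "BASSWOOD": (3500, 600, 0.06),
    "ELMS": (3600, 600, 0.05),
    "HORNBEAM": (3600, 650, 0.06),
    "CHERRIES": (3500, 800, 0.02),
    "PINES": (3700, 800, 0.35),
    "OAK": (4100, 550, 1.05),
    "HICKORIES": (4200, 450, 0.15),
    "CHESTNUT": (4150, 450, 0.20),
    "SYCAMORE": (4200, 450, 0.01),
    "WALNUTS": (4250, 450, 0.02),
    "BLACKGUM": (4200, 500, 0.02),
    "TULIP": (4300, 450, 0.02),
    "MAGNOLIAS": (4300, 400, 0.01),
    "CYPRESS": (4600, 300, 0.005),
}


@dataclass(frozen=True)
class ShiftRule:
    """Era-shift multiplier for one taxon: ``max(0, base + agri_slope·agri)``
    where ``agri`` is the town's peak agricultural clearing proportion."""

    base: float
    agri_slope: float = 0.0

    def multiplier(self, agri: float) -> float:
        return max(0.0, self.base + self.agri_slope * float(agri))


# Default era shift, emulating the documented four-century pattern: chestnut
# extirpated everywhere; beech, hemlock and oak losing ground in proportion
# to agricultural clearing; maple, cherry, poplar and fir rising.
DEFAULT_ERA_SHIFT: dict[str, ShiftRule] = {
    "CHESTNUT": ShiftRule(0.0),
    "BEECH": ShiftRule(1.0, -1.2),
    "HEMLOCK": ShiftRule(1.0, -0.8),
    "OAK": ShiftRule(1.0, -0.7),
    "SPRUCES": ShiftRule(0.6),
    "BASSWOOD": ShiftRule(0.5),
    "HICKORIES": ShiftRule(0.6),
    "WALNUTS": ShiftRule(0.3),
    "SYCAMORE": ShiftRule(0.3),
    "MAPLE": ShiftRule(3.0, 1.0),
    "CHERRIES": ShiftRule(9.0),
    "POPLARS": ShiftRule(2.5, 1.0),
    "BIRCHES": ShiftRule(1.8),
    "FIR": ShiftRule(2.2),
    "ASHES": ShiftRule(2.0),
}


@dataclass
class SimConfig:
    """Configuration of one synthetic landscape.

    Defaults emulate the study's final-sample scale per town: ~100 km² towns
    tiled on a grid, ≈250 witness trees and ≈4.3 inventory plots per town,
    ≈30 trees per plot, with a GDD gradient running south (warm) to north.
    """

    nx: int = 12
    ny: int = 10
    lat0: float = 41.0          # southern edge, decimal degrees
    lon0: float = -73.0         # western edge
    cell_deg: float = 0.09      # town side, degrees (~10 km)
    gdd_range: tuple[float, float] = (4400.0, 2600.0)  # south -> north
    gdd_noise_sd: float = 60.0
    taxa_niches: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_NICHES))
    era_shift: dict[str, ShiftRule] = field(
        default_factory=lambda: dict(DEFAULT_ERA_SHIFT))
    # peak agriculture rises with warmth: base + slope·gdd_norm + noise
    agri_base: float = 0.12
    agri_gdd_slope: float = 0.55
    agri_noise_sd: float = 0.10
    wt_mean: float = 250.0      # witness trees per town (negative binomial)
    wt_dispersion: float = 8.0
    wt_min: int = 40
    plots_mean: float = 4.3     # inventory plots per town (Poisson, min 2)
    plots_min: int = 2
    trees_per_plot_mean: float = 36.0
    trees_per_plot_min: int = 10
    theta: float = 60.0         # plot-level Dirichlet concentration
    dbh_min: float = 12.5
    frac_small_trees: float = 0.0   # sampled below dbh_min (filter fodder)
    nonforest_prob: float = 0.0     # plots classed Nonforest
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w <= 0 for _, w, _ in self.taxa_niches.values()):
            raise DataError("niche widths must be positive")
        if any(p < 0 for _, _, p in self.taxa_niches.values()):
            raise DataError("niche peaks must be nonnegative")
        if self.theta <= 0:
            raise DataError("Dirichlet concentration theta must be positive")

    @property
    def n_towns(self) -> int:
        return self.nx * self.ny

    def to_json(self) -> str:
        d = asdict(self)
        d["era_shift"] = {k: [v["base"], v["agri_slope"]]
                          for k, v in d["era_shift"].items()}
        return json.dumps(d, indent=2, sort_keys=True)


def true_composition(gdd: float, config: SimConfig,
                     taxa: TaxonSet | None = None) -> np.ndarray:
    """Expected relative abundances at a GDD value from the Gaussian niches:
    a_t ∝ peak_t · exp(−(GDD − opt_t)² / (2·width_t²))."""
    taxa = taxa or TaxonSet()
    a = np.zeros(len(taxa))
    for code, (opt, width, peak) in config.taxa_niches.items():
        a[taxa.index(code)] = peak * np.exp(-((gdd - opt) ** 2) / (2.0 * width ** 2))
    total = a.sum()
    if total <= 0:
        raise DataError(f"all niche abundances zero at GDD={gdd}")
    return a / total


def shift_profile(pre_profile: np.ndarray, agri: float, config: SimConfig,
                  taxa: TaxonSet | None = None) -> np.ndarray:
    """Apply the era-shift multipliers at a town's agriculture level and
    renormalize. Taxa without a rule keep multiplier 1."""
    taxa = taxa or TaxonSet()
    mult = np.ones(len(taxa))
    for code, rule in config.era_shift.items():
        mult[taxa.index(code)] = rule.multiplier(agri)
    out = np.asarray(pre_profile, dtype=float) * mult
    total = out.sum()
    if total <= 0:
        raise DataError("era shift annihilated the whole profile")
    return out / total


def _dirichlet(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    """Dirichlet draw tolerating zero concentrations (those stay zero)."""
    g = np.zeros_like(alpha)
    pos = alpha > 0
    g[pos] = rng.gamma(alpha[pos])
    return g / g.sum()


def sample_witness_trees(town_id: str, profile: np.ndarray, n: int,
                         rng: np.random.Generator,
                         taxa: TaxonSet | None = None) -> pd.DataFrame:
    """Multinomial witness-tree draw from a town profile."""
    taxa = taxa or TaxonSet()
    counts = rng.multinomial(n, profile)
    rows = []
    for code, c in zip(taxa.codes, counts):
        rows.extend({"town_id": town_id, "raw_name": _WT_NAME[code]}
                    for _ in range(int(c)))
    return pd.DataFrame(rows, columns=["town_id", "raw_name"])


def sample_fia_plots(town_id: str, profile: np.ndarray, n_plots: int,
                     m_trees: np.ndarray, config: SimConfig,
                     rng: np.random.Generator,
                     taxa: TaxonSet | None = None) -> pd.DataFrame:
    """Clustered plot sampling: per plot, a Dirichlet(θ·profile) plot profile
    then a multinomial tree draw; dbh ≥ threshold unless configured."""
    taxa = taxa or TaxonSet()
    profile = np.asarray(profile, dtype=float)
    rows = []
    for j in range(n_plots):
        plot_id = f"{town_id}-P{j + 1:02d}"
        condition = ("Nonforest" if rng.random() < config.nonforest_prob
                     else "Forest")
        plot_profile = _dirichlet(rng, config.theta * profile)
        counts = rng.multinomial(int(m_trees[j]), plot_profile)
        for code, c in zip(taxa.codes, counts):
            for _ in range(int(c)):
                if rng.random() < config.frac_small_trees:
                    dbh = config.dbh_min * rng.uniform(0.3, 0.999)
                else:
                    dbh = config.dbh_min + rng.gamma(2.0, 8.0)
                rows.append({
                    "town_id": town_id, "plot_id": plot_id,
                    "raw_name": _FIA_NAME[code], "dbh_cm": round(dbh, 1),
                    "condition_class": condition,
                })
    return pd.DataFrame(rows, columns=["town_id", "plot_id", "raw_name",
                                       "dbh_cm", "condition_class"])


@dataclass
class Landscape:
    """A generated landscape plus its ground truth."""

    config: SimConfig
    towns: pd.DataFrame           # town table incl. covariates
    witness: pd.DataFrame         # witness CSV dialect
    modern: pd.DataFrame          # modern inventory CSV dialect
    truth_pre: pd.DataFrame       # town × taxon expected pre profiles
    truth_mod: pd.DataFrame       # town × taxon expected modern profiles
    taxa: TaxonSet


def _town_grid(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Lay towns on the grid and draw their covariates."""
    rows = []
    ny, nx, cell = config.ny, config.nx, config.cell_deg
    lat_span = ny * cell
    for j in range(ny):
        for i in range(nx):
            lat = config.lat0 + (j + 0.5) * cell
            lon = config.lon0 + (i + 0.5) * cell
            frac = (lat - config.lat0) / lat_span  # 0 south -> 1 north
            gdd = (config.gdd_range[0]
                   + frac * (config.gdd_range[1] - config.gdd_range[0])
                   + rng.normal(0.0, config.gdd_noise_sd))
            rows.append({"town_id": f"T{j * nx + i + 1:04d}",
                         "row": j, "col": i,
                         "centroid_lat": lat, "centroid_lon": lon,
                         "gdd": gdd})
    towns = pd.DataFrame(rows)
    # four latitudinal ecoregion bands, warm to cold
    bands = np.minimum((towns["row"] * 4 // ny).to_numpy(), 3)
    towns["ecoregion"] = np.array(["BROAD", "APPAL", "ADIRON", "LAUREN"])[bands]
    gdd_norm = ((towns["gdd"] - config.gdd_range[1])
                / (config.gdd_range[0] - config.gdd_range[1]))
    towns["peak_agriculture"] = np.clip(
        config.agri_base + config.agri_gdd_slope * gdd_norm
        + rng.normal(0.0, config.agri_noise_sd, len(towns)), 0.01, 0.95)
    towns["precip_mm"] = 1000.0 + 40.0 * (towns["centroid_lon"] - config.lon0) \
        + rng.normal(0.0, 60.0, len(towns))
    towns["elevation_m"] = np.clip(
        200.0 + 400.0 * rng.random(len(towns)), 0.0, None)
    towns["ruggedness_m"] = rng.gamma(2.0, 30.0, len(towns))
    towns["peak_agriculture_year"] = np.round(
        rng.normal(1880.0, 12.0, len(towns)))
    towns["agri_decline_rate"] = np.clip(
        rng.normal(0.008, 0.003, len(towns)), 0.001, None)
    towns["canopy_cover_pct"] = np.clip(
        95.0 - 45.0 * towns["peak_agriculture"]
        + rng.normal(0.0, 5.0, len(towns)), 5.0, 100.0)
    towns["soil_sand_pct"] = np.clip(rng.normal(45.0, 12.0, len(towns)), 5, 95)
    towns["soil_clay_pct"] = np.clip(rng.normal(18.0, 6.0, len(towns)), 2, 60)
    towns["latitude"] = towns["centroid_lat"]
    towns["longitude"] = towns["centroid_lon"]
    return towns.drop(columns=["row", "col"])


def generate(config: SimConfig) -> Landscape:
    """Generate a full landscape: towns, covariates, both eras' tree records,
    and the ground-truth composition tables."""
    taxa = TaxonSet()
    rng = np.random.default_rng(config.seed)
    towns = _town_grid(config, rng)

    wt_frames, fia_frames = [], []
    pre_rows, mod_rows = [], []
    p_nb = config.wt_dispersion / (config.wt_dispersion + config.wt_mean)
    for rec in towns.itertuples():
        pre = true_composition(rec.gdd, config, taxa)
        mod = shift_profile(pre, rec.peak_agriculture, config, taxa)
        pre_rows.append(pre)
        mod_rows.append(mod)
        n_wt = max(config.wt_min,
                   int(rng.negative_binomial(config.wt_dispersion, p_nb)))
        wt_frames.append(sample_witness_trees(rec.town_id, pre, n_wt, rng, taxa))
        n_plots = max(config.plots_min, int(rng.poisson(config.plots_mean)))
        m_trees = np.maximum(config.trees_per_plot_min,
                             rng.poisson(config.trees_per_plot_mean, n_plots))
        fia_frames.append(sample_fia_plots(rec.town_id, mod, n_plots, m_trees,
                                           config, rng, taxa))

    idx = pd.Index(towns["town_id"], name="town_id")
    cols = list(taxa.codes)
    return Landscape(
        config=config,
        towns=towns,
        witness=pd.concat(wt_frames, ignore_index=True),
        modern=pd.concat(fia_frames, ignore_index=True),
        truth_pre=pd.DataFrame(pre_rows, index=idx, columns=cols),
        truth_mod=pd.DataFrame(mod_rows, index=idx, columns=cols),
        taxa=taxa,
    )


def write_landscape(land: Landscape, outdir: str | Path) -> dict[str, Path]:
    """Write the landscape in the dialects the loaders read; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "witness_csv": outdir / "witness_trees.csv",
        "modern_csv": outdir / "modern_trees.csv",
        "towns_geojson": outdir / "towns.geojson",
        "covariates_csv": outdir / "covariates.csv",
        "truth_pre_csv": outdir / "truth_pre.csv",
        "truth_mod_csv": outdir / "truth_modern.csv",
        "config_json": outdir / "sim_config.json",
    }
    land.witness.to_csv(paths["witness_csv"], index=False)
    land.modern.to_csv(paths["modern_csv"], index=False)

    half = land.config.cell_deg / 2.0
    features = []
    for rec in land.towns.itertuples():
        lon, lat = rec.centroid_lon, rec.centroid_lat
        ring = [[lon - half, lat - half], [lon + half, lat - half],
                [lon + half, lat + half], [lon - half, lat + half],
                [lon - half, lat - half]]
        features.append({
            "type": "Feature",
            "properties": {"town_id": rec.town_id, "ecoregion": rec.ecoregion},
            "geometry": {"type": "Polygon", "coordinates": [ring]},
        })
    with open(paths["towns_geojson"], "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)

    from .datamodel import COVARIATE_NAMES
    land.towns[["town_id", *COVARIATE_NAMES]].to_csv(
        paths["covariates_csv"], index=False, float_format="%.6f")
    land.truth_pre.to_csv(paths["truth_pre_csv"], float_format="%.8f")
    land.truth_mod.to_csv(paths["truth_mod_csv"], float_format="%.8f")
    paths["config_json"].write_text(land.config.to_json() + "\n")
    return paths


def landscape_dataset(land: Landscape) -> Dataset:
    """Assemble an in-memory :class:`Dataset` from a landscape, bypassing
    disk; areas use the exact grid-cell geometry."""
    from . import geo

    towns = land.towns.copy()
    half = land.config.cell_deg / 2.0
    areas = []
    for rec in towns.itertuples():
        lons = np.array([rec.centroid_lon - half, rec.centroid_lon + half,
                         rec.centroid_lon + half, rec.centroid_lon - half])
        lats = np.array([rec.centroid_lat - half, rec.centroid_lat - half,
                         rec.centroid_lat + half, rec.centroid_lat + half])
        areas.append(geo.polygon_area_km2(lons, lats))
    towns["area_km2"] = areas

    wt = pd.DataFrame({
        "town_id": land.witness["town_id"], "era": PRECOLONIAL,
        "raw_name": land.witness["raw_name"], "taxon_code": pd.NA,
        "dbh_cm": np.nan, "plot_id": pd.NA,
    })
    fia = pd.DataFrame({
        "town_id": land.modern["town_id"], "era": MODERN,
        "raw_name": land.modern["raw_name"], "taxon_code": pd.NA,
        "dbh_cm": land.modern["dbh_cm"].astype(float),
        "plot_id": land.modern["plot_id"],
    })
    trees = bin_trees(pd.concat([wt, fia], ignore_index=True), land.taxa)
    plots = (land.modern[["plot_id", "town_id", "condition_class"]]
             .drop_duplicates(subset="plot_id").reset_index(drop=True))
    return Dataset(towns=towns, plots=plots, trees=trees, taxa=land.taxa)
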