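"""End-to-end pipeline: load → filter → adequacy screen → change →
β-diversity → spatial structure → ordination → regression tree, with every
exclusion counted in a JSON manifest.

A single global seed deterministically derives one sub-seed per stage, so
the full run and stage-by-stage manual invocation agree.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import adequacy, change, ctree, io, ordination, spatial
from .datamodel import (COVARIATE_NAMES, MODERN, PRECOLONIAL, DataError,
                        Dataset, composition_table, filter_modern)

logger = logging.getLogger(__name__)

_STAGES = ("load", "filter", "adequacy", "change", "beta", "spatial",
           "ordination", "tree")


@dataclass
class RunConfig:
    """All pipeline parameters plus input paths and the output directory."""

    witness_csv: str | None = None
    modern_csv: str | None = None
    towns_geojson: str | None = None
    covariates_csv: str | None = None
    outdir: str = "results/pipeline"
    seed: int = 0
    # record filters
    min_dbh_cm: float = 12.5
    min_trees_per_plot: int = 10
    min_plots_per_town: int = 2
    # adequacy
    n_sets: int = 100
    proportion: float = 0.9
    # tests
    n_rand: int = 10_000
    n_perm: int = 999
    alpha: float = 0.05
    # spatial
    moran_class_km: float = 15.0
    mantel_class_km: float = 15.0
    # ordination
    nmds_k: int = 2
    nmds_starts: int = 50
    scree_ks: tuple[int, ...] = (1, 2, 3, 4)
    # tree
    tree_alpha: float = 0.05
    tree_n_perm: int = 9999
    tree_min_node: int = 20

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        d = asdict(self)
        d.pop("outdir", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    dataset: Dataset
    included_towns: list[str]
    thresholds: adequacy.AdequacyThreshold
    comp_pre: object
    comp_mod: object
    change_result: change.ChangeResult
    abundance: pd.DataFrame
    beta: change.BetaDiversityResult
    moran: spatial.CorrelogramResult
    mantel_pre: spatial.CorrelogramResult
    mantel_mod: spatial.CorrelogramResult
    env_mantel: pd.DataFrame
    nmds_result: ordination.OrdinationResult
    scree: pd.DataFrame
    env_fit: ordination.EnvFitResult
    separation: ordination.EraSeparation
    tree: ctree.SplitNode
    manifest: dict = field(default_factory=dict)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig,
                 dataset: Dataset | None = None) -> PipelineResult:
    """Execute the full analysis; any stage failure aborts with the stage
    name and cause. Pass ``dataset`` to skip the disk-loading stage."""
    manifest: dict = {"seed": config.seed, "config_hash": config.config_hash(),
                      "counts": {}}
    stage = "load"
    try:
        if dataset is None:
            if not all([config.witness_csv, config.modern_csv,
                        config.towns_geojson, config.covariates_csv]):
                raise DataError("config must name witness, modern, towns and "
                                "covariate files (or pass a dataset)")
            dataset = io.load_dataset(
                [config.witness_csv, config.modern_csv],
                config.towns_geojson, config.covariates_csv)
        n_modern0 = int((dataset.trees["era"] == MODERN).sum())
        if n_modern0 == 0:
            raise DataError("no modern tree records")
        manifest["counts"]["towns_input"] = len(dataset.towns)
        manifest["counts"]["plots_input"] = len(dataset.plots)
        manifest["counts"]["modern_trees_input"] = n_modern0
        manifest["counts"]["witness_trees_input"] = int(
            (dataset.trees["era"] == PRECOLONIAL).sum())

        stage = "filter"
        plots_f, modern_f, dropped = filter_modern(
            dataset.plots, dataset.trees,
            min_dbh_cm=config.min_dbh_cm,
            min_trees=config.min_trees_per_plot,
            min_plots_per_town=config.min_plots_per_town)
        wt = dataset.trees[dataset.trees["era"] == PRECOLONIAL]
        trees_f = pd.concat([wt, modern_f], ignore_index=True)
        dataset = Dataset(towns=dataset.towns, plots=plots_f, trees=trees_f,
                          taxa=dataset.taxa)
        manifest["counts"]["plots_retained"] = len(plots_f)
        manifest["counts"]["modern_trees_retained"] = len(modern_f)
        manifest["counts"]["towns_dropped_by_plot_filter"] = len(dropped)

        stage = "adequacy"
        thresholds = adequacy.ecoregion_thresholds(
            dataset, n_sets=config.n_sets, proportion=config.proportion,
            seed=config.stage_seed("adequacy"))
        included = adequacy.screen_towns(dataset, thresholds)
        manifest["counts"]["towns_screened_in"] = len(included)
        if len(included) < 4:
            raise DataError(f"only {len(included)} towns pass the adequacy "
                            "screen; too few to analyze")

        stage = "change"
        comp_pre = composition_table(dataset.trees, dataset.taxa,
                                     PRECOLONIAL, towns=included)
        comp_mod = composition_table(dataset.trees, dataset.taxa,
                                     MODERN, towns=included)
        shared = [t for t in comp_pre.towns if t in set(comp_mod.towns)]
        comp_pre, comp_mod = comp_pre.subset(shared), comp_mod.subset(shared)
        manifest["counts"]["towns_analyzed"] = len(shared)
        eco = dataset.towns.set_index("town_id")["ecoregion"]
        chg = change.change_per_town(comp_pre, comp_mod, ecoregions=eco,
                                     n_rand=config.n_rand,
                                     seed=config.stage_seed("change"))
        abundance = change.abundance_change_table(
            comp_pre, comp_mod, ecoregions=eco, n_rand=config.n_rand,
            seed=config.stage_seed("abundance"))

        stage = "beta"
        beta = change.beta_diversity(comp_pre, comp_mod,
                                     n_rand=config.n_rand,
                                     seed=config.stage_seed("beta"))

        stage = "spatial"
        towns_a = (dataset.towns.set_index("town_id").loc[shared]
                   .reset_index())
        geo = spatial.geo_distances(towns_a)
        moran = spatial.morans_correlogram(
            chg.per_town["change"].to_numpy(), geo,
            class_width_km=config.moran_class_km, n_perm=config.n_perm,
            alpha=config.alpha, seed=config.stage_seed("moran"))
        dm_pre = spatial.sorensen_distance_matrix(comp_pre)
        dm_mod = spatial.sorensen_distance_matrix(comp_mod)
        mant_pre = spatial.mantel_correlogram(
            dm_pre, geo, class_width_km=config.mantel_class_km,
            n_perm=config.n_perm, alpha=config.alpha,
            seed=config.stage_seed("mantel_pre"))
        mant_mod = spatial.mantel_correlogram(
            dm_mod, geo, class_width_km=config.mantel_class_km,
            n_perm=config.n_perm, alpha=config.alpha,
            seed=config.stage_seed("mantel_mod"))
        env_mant = spatial.env_mantel_table(
            dm_pre, dm_mod, towns_a, n_perm=config.n_perm,
            seed=config.stage_seed("env_mantel"))

        stage = "ordination"
        stacked = np.vstack([comp_pre.values, comp_mod.values])
        eras = np.array([PRECOLONIAL] * len(shared) + [MODERN] * len(shared))
        ids = [f"{t}:{e}" for e, tl in ((PRECOLONIAL, shared), (MODERN, shared))
               for t in tl]
        wis = ordination.wisconsin(stacked)
        dm_stack = spatial.DistanceMatrix(ids, change.sorensen_matrix(wis))
        ord_res = ordination.nmds(dm_stack, k=config.nmds_k,
                                  n_starts=config.nmds_starts,
                                  seed=config.stage_seed("nmds"))
        scree_rows = []
        for kk in config.scree_ks:
            if kk == config.nmds_k:
                scree_rows.append({"k": kk, "stress": ord_res.stress})
            else:
                rk = ordination.nmds(dm_stack, k=kk,
                                     n_starts=config.nmds_starts,
                                     seed=config.stage_seed(f"nmds{kk}"))
                scree_rows.append({"k": kk, "stress": rk.stress})
        scree = pd.DataFrame(scree_rows).sort_values("k").reset_index(drop=True)
        cov_stack = pd.concat([towns_a.set_index("town_id").loc[shared],
                               towns_a.set_index("town_id").loc[shared]],
                              ignore_index=True)
        fit = ordination.envfit(
            ord_res, cov_stack[list(spatial.ENV_MANTEL_COVARIATES)
                               + ["latitude", "peak_agriculture"]],
            n_perm=config.n_perm, seed=config.stage_seed("envfit"))
        sep = ordination.era_axis_separation(ord_res, eras)

        stage = "tree"
        Xcov = towns_a.set_index("town_id").loc[shared, list(COVARIATE_NAMES)]
        tree = ctree.fit_ctree(Xcov.reset_index(drop=True),
                               chg.per_town["change"].to_numpy(),
                               alpha=config.tree_alpha,
                               n_perm=config.tree_n_perm,
                               min_node=config.tree_min_node,
                               seed=config.stage_seed("tree"))
    except Exception as exc:   # noqa: BLE001 - re-raised with stage context
        raise StageError(stage, exc) from exc

    return PipelineResult(
        dataset=dataset, included_towns=included, thresholds=thresholds,
        comp_pre=comp_pre, comp_mod=comp_mod, change_result=chg,
        abundance=abundance, beta=beta, moran=moran,
        mantel_pre=mant_pre, mantel_mod=mant_mod, env_mantel=env_mant,
        nmds_result=ord_res, scree=scree, env_fit=fit, separation=sep,
        tree=tree, manifest=manifest,
    )


def write_report(result: PipelineResult, config: RunConfig) -> Path:
    """Write the pipeline's tables and manifest under ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.change_result.per_town.to_csv(out / "per_town_change.csv", index=False)
    if result.change_result.by_ecoregion is not None:
        result.change_result.by_ecoregion.to_csv(
            out / "change_by_ecoregion.csv", index=False)
        result.change_result.ecoregion_pairs.to_csv(
            out / "change_ecoregion_pairs.csv", index=False)
    result.abundance.to_csv(out / "abundance_change.csv", index=False)
    result.beta.per_town.to_csv(out / "beta_diversity_per_town.csv", index=False)
    result.beta.era_summary.to_csv(out / "beta_diversity_summary.csv", index=False)
    result.thresholds.table.to_csv(out / "adequacy_thresholds.csv", index=False)
    pd.DataFrame({"town_id": result.included_towns}).to_csv(
        out / "included_towns.csv", index=False)
    result.moran.table.to_csv(out / "moran_correlogram.csv", index=False)
    result.mantel_pre.table.to_csv(out / "mantel_correlogram_pre.csv", index=False)
    result.mantel_mod.table.to_csv(out / "mantel_correlogram_modern.csv", index=False)
    result.env_mantel.to_csv(out / "env_mantel.csv", index=False)
    result.nmds_result.to_frame().to_csv(out / "nmds_coords.csv", index=False)
    result.scree.to_csv(out / "nmds_scree.csv", index=False)
    result.env_fit.table.to_csv(out / "envfit.csv", index=False)
    ctree.tree_report(result.tree).to_csv(out / "tree_report.csv", index=False)
    io.write_run_metadata(out / "manifest.json", **result.manifest,
                          stages=list(_STAGES))
    return out
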