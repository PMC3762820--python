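#!/usr/bin/env python
"""Quantify compositional change between eras.

Per-town Sørensen distance from pre-colonial to modern composition,
per-taxon abundance shifts with paired Monte Carlo tests (region-wide and
by ecoregion), ecoregion comparisons, and town-to-town β-diversity per era.
Writes results/change/.
"""

import sys
from pathlib import Path

import pandas as pd

from forestchange import change, io
from forestchange.datamodel import (Dataset, MODERN, PRECOLONIAL,
                                    composition_table, filter_modern)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
DATA = Path("results/landscape")
OUT = Path("results/change")


def load_compositions():
    ds = io.load_dataset(
        [DATA / "witness_trees.csv", DATA / "modern_trees.csv"],
        DATA / "towns.geojson", DATA / "covariates.csv")
    plots_f, modern_f, _ = filter_modern(ds.plots, ds.trees)
    wt = ds.trees[ds.trees["era"] == PRECOLONIAL]
    trees = pd.concat([wt, modern_f], ignore_index=True)
    ds = Dataset(towns=ds.towns, plots=plots_f, trees=trees, taxa=ds.taxa)
    inc = Path("results/adequacy/included_towns.csv")
    towns = (pd.read_csv(inc, dtype=str)["town_id"].tolist()
             if inc.exists() else None)
    pre = composition_table(trees, ds.taxa, PRECOLONIAL, towns=towns)
    mod = composition_table(trees, ds.taxa, MODERN, towns=towns)
    shared = [t for t in pre.towns if t in set(mod.towns)]
    return ds, pre.subset(shared), mod.subset(shared), shared


def main() -> None:
    ds, pre, mod, shared = load_compositions()
    eco = ds.towns.set_index("town_id")["ecoregion"]
    OUT.mkdir(parents=True, exist_ok=True)

    res = change.change_per_town(pre, mod, ecoregions=eco,
                                 n_rand=10_000, seed=SEED)
    res.per_town.to_csv(OUT / "per_town_change.csv", index=False)
    res.by_ecoregion.to_csv(OUT / "change_by_ecoregion.csv", index=False)
    res.ecoregion_pairs.to_csv(OUT / "change_ecoregion_pairs.csv", index=False)
    print(f"Sørensen change over {len(shared)} towns: "
          f"mean {res.regional_mean:.3f} (sd {res.regional_sd:.3f}), "
          f"range {res.per_town['change'].min():.2f}-"
          f"{res.per_town['change'].max():.2f}")
    print(res.by_ecoregion.to_string(index=False))

    abund = change.abundance_change_table(pre, mod, ecoregions=eco,
                                          n_rand=10_000, seed=SEED)
    abund.to_csv(OUT / "abundance_change.csv", index=False)
    top = (abund[abund["scope"] == "ALL"]
           .assign(absd=lambda d: d["delta"].abs())
           .nlargest(6, "absd"))
    print("largest region-wide abundance shifts:")
    for _, r in top.iterrows():
        print(f"  {r['taxon']:<10} {100 * r['pre_mean']:5.1f}% -> "
              f"{100 * r['mod_mean']:5.1f}%  (p={r['p']:.4f})")

    beta = change.beta_diversity(pre, mod, n_rand=10_000, seed=SEED)
    beta.per_town.to_csv(OUT / "beta_diversity_per_town.csv", index=False)
    beta.era_summary.to_csv(OUT / "beta_diversity_summary.csv", index=False)
    s = beta.era_summary.set_index("era")["mean"]
    verdict = ("homogenization" if s[MODERN] < s[PRECOLONIAL]
               else "no homogenization")
    print(f"β-diversity: pre {s[PRECOLONIAL]:.3f} vs modern {s[MODERN]:.3f} "
          f"(p={beta.p:.4f}) -> {verdict}")


if __name__ == "__main__":
    main()
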