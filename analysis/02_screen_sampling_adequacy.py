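#!/usr/bin/env python
"""Screen towns for sampling adequacy.

Loads the landscape written by 01, applies the modern-inventory filters
(Forest-classed plots with >=10 trees >=12.5 cm dbh; towns with >=2 plots),
then estimates per-ecoregion minimum sampling densities by bootstrap
rarefaction + Michaelis-Menten asymptote fits and writes the thresholds and
the inclusion list under results/adequacy/.
"""

import sys
from pathlib import Path

import pandas as pd

from forestchange import adequacy, io
from forestchange.datamodel import Dataset, PRECOLONIAL, filter_modern

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
DATA = Path("results/landscape")
OUT = Path("results/adequacy")


def main() -> None:
    ds = io.load_dataset(
        [DATA / "witness_trees.csv", DATA / "modern_trees.csv"],
        DATA / "towns.geojson", DATA / "covariates.csv")
    plots_f, modern_f, dropped = filter_modern(ds.plots, ds.trees)
    wt = ds.trees[ds.trees["era"] == PRECOLONIAL]
    ds = Dataset(towns=ds.towns, plots=plots_f,
                 trees=pd.concat([wt, modern_f], ignore_index=True),
                 taxa=ds.taxa)
    print(f"filters: {len(plots_f)} plots retained, "
          f"{len(dropped)} towns dropped outright")

    thr = adequacy.ecoregion_thresholds(ds, n_sets=100, seed=SEED)
    included = adequacy.screen_towns(ds, thr)
    OUT.mkdir(parents=True, exist_ok=True)
    thr.table.to_csv(OUT / "adequacy_thresholds.csv", index=False)
    adequacy.town_densities(ds).to_csv(OUT / "town_densities.csv", index=False)
    pd.DataFrame({"town_id": included}).to_csv(OUT / "included_towns.csv",
                                               index=False)
    print(thr.table.to_string(index=False))
    print(f"{len(included)}/{len(ds.towns)} towns meet both the witness-tree "
          "and plot density thresholds")


if __name__ == "__main__":
    main()
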