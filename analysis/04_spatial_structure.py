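#!/usr/bin/env python
"""Spatial structure of change and composition.

Moran's I correlogram of per-town Sørensen change (is change spatially
clustered?), Mantel correlograms of composition per era (does compositional
similarity decay with distance, and has that decay weakened?), and Mantel
tests of composition against environmental covariates. Writes
results/spatial/.
"""

import importlib.util
import sys
from pathlib import Path

import pandas as pd

from forestchange import spatial

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/spatial")

_spec = importlib.util.spec_from_file_location(
    "step03", Path(__file__).parent / "03_compositional_change.py")
step03 = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(step03)


def main() -> None:
    ds, pre, mod, shared = step03.load_compositions()
    towns = ds.towns.set_index("town_id").loc[shared].reset_index()
    geo = spatial.geo_distances(towns)
    OUT.mkdir(parents=True, exist_ok=True)

    from forestchange.change import change_per_town
    chg = change_per_town(pre, mod)
    moran = spatial.morans_correlogram(chg.per_town["change"].to_numpy(),
                                       geo, class_width_km=15.0,
                                       n_perm=999, seed=SEED)
    moran.table.to_csv(OUT / "moran_correlogram.csv", index=False)
    sig = moran.table[moran.table["significant"]]
    if len(sig):
        print(f"change is spatially clustered out to "
              f"{sig['upper_km'].max():.0f} km "
              f"(lag-1 I = {moran.table['statistic'].iloc[0]:.3f})")
    else:
        print("no significant spatial clustering of change")

    for era, table in (("pre", pre), ("modern", mod)):
        dm = spatial.sorensen_distance_matrix(table)
        mc = spatial.mantel_correlogram(dm, geo, class_width_km=15.0,
                                        n_perm=999, seed=SEED)
        mc.table.to_csv(OUT / f"mantel_correlogram_{era}.csv", index=False)

    env = spatial.env_mantel_table(
        spatial.sorensen_distance_matrix(pre),
        spatial.sorensen_distance_matrix(mod),
        towns, n_perm=999, seed=SEED)
    env.to_csv(OUT / "env_mantel.csv", index=False)
    piv = env.pivot(index="covariate", columns="era", values="r_m")
    print("Mantel r_M composition vs environment (pre / modern):")
    for cov, row in piv.iterrows():
        print(f"  {cov:<14} {row['precolonial']:6.3f} / {row['modern']:6.3f}")


if __name__ == "__main__":
    main()
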