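#!/usr/bin/env python
"""Ordinate both eras in shared composition space.

NMDS (Sørensen on Wisconsin-standardized abundances, 50 random starts) of
the stacked pre-colonial + modern town compositions, environmental vector
fitting, a k=1..4 stress scree, and the era-separation readout. Writes
results/ordination/.
"""

import importlib.util
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from forestchange import ordination, spatial
from forestchange.change import sorensen_matrix

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/ordination")

_spec = importlib.util.spec_from_file_location(
    "step03", Path(__file__).parent / "03_compositional_change.py")
step03 = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(step03)


def main() -> None:
    ds, pre, mod, shared = step03.load_compositions()
    stacked = np.vstack([pre.values, mod.values])
    ids = [f"{t}:pre" for t in shared] + [f"{t}:mod" for t in shared]
    eras = np.array(["precolonial"] * len(shared) + ["modern"] * len(shared))
    dm = spatial.DistanceMatrix(ids, sorensen_matrix(ordination.wisconsin(stacked)))
    OUT.mkdir(parents=True, exist_ok=True)

    scree = []
    best = None
    for k in (1, 2, 3, 4):
        res = ordination.nmds(dm, k=k, n_starts=50, seed=SEED + k)
        scree.append({"k": k, "stress": res.stress})
        if k == 2:
            best = res
    pd.DataFrame(scree).to_csv(OUT / "nmds_scree.csv", index=False)
    print("stress scree:", ", ".join(f"k={r['k']}: {r['stress']:.3f}"
                                     for r in scree))

    coords = best.to_frame()
    coords["era"] = eras
    coords.to_csv(OUT / "nmds_coords.csv", index=False)

    towns = ds.towns.set_index("town_id")
    cov = pd.concat([towns.loc[shared], towns.loc[shared]], ignore_index=True)
    fit = ordination.envfit(
        best, cov[["gdd", "precip_mm", "elevation_m", "soil_sand_pct",
                   "latitude", "peak_agriculture"]],
        n_perm=999, seed=SEED)
    fit.table.to_csv(OUT / "envfit.csv", index=False)
    strong = fit.table[fit.table["p"] < 0.05].sort_values("r2", ascending=False)
    print("significant environmental vectors (p<0.05):")
    for _, r in strong.iterrows():
        print(f"  {r['covariate']:<17} R²={r['r2']:.2f}")

    sep = ordination.era_axis_separation(best, eras)
    pd.DataFrame([{"axis": sep.axis, "frac_pre_below": sep.frac_pre_below,
                   "frac_mod_above": sep.frac_mod_above}]).to_csv(
        OUT / "era_separation.csv", index=False)
    print(f"axis {sep.axis} separates the eras: "
          f"{sep.frac_pre_below:.0%} of pre-colonial towns score below 0, "
          f"{sep.frac_mod_above:.0%} of modern towns above 0")


if __name__ == "__main__":
    main()
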