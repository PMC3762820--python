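#!/usr/bin/env python
"""What drives the magnitude of compositional change?

Fits a conditional-inference regression tree of per-town Sørensen change on
the land-use and biophysical predictor table (peak agriculture, climate,
terrain, soils, position). Splits require a Bonferroni-corrected
permutation-significant association, so the tree size is self-limiting.
Writes results/tree/.
"""

import importlib.util
import sys
from pathlib import Path

from forestchange import ctree
from forestchange.change import change_per_town
from forestchange.datamodel import COVARIATE_NAMES

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/tree")

_spec = importlib.util.spec_from_file_location(
    "step03", Path(__file__).parent / "03_compositional_change.py")
step03 = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(step03)


def main() -> None:
    ds, pre, mod, shared = step03.load_compositions()
    chg = change_per_town(pre, mod)
    X = (ds.towns.set_index("town_id").loc[shared, list(COVARIATE_NAMES)]
         .reset_index(drop=True))
    tree = ctree.fit_ctree(X, chg.per_town["change"].to_numpy(),
                           alpha=0.05, n_perm=9999, min_node=20, seed=SEED)
    OUT.mkdir(parents=True, exist_ok=True)
    report = ctree.tree_report(tree)
    report.to_csv(OUT / "tree_report.csv", index=False)

    splits = report[report["kind"] == "split"]
    print(f"tree: {len(splits)} significant partitions, "
          f"{(report['kind'] == 'leaf').sum()} terminal nodes")
    for _, r in splits.iterrows():
        indent = "  " * int(r["depth"])
        print(f"{indent}{r['path']:<6} n={r['n']:<4} split on "
              f"{r['predictor']} at {r['threshold']:.3f} (p={r['adj_p']:.4f})")
    var, thr = ctree.first_split(tree)
    if var is not None:
        print(f"strongest driver of change: {var} (threshold {thr:.3f})")


if __name__ == "__main__":
    main()
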