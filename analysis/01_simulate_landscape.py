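#!/usr/bin/env python
"""Generate the synthetic study landscape.

Builds the default 12x10-town landscape — a latitudinal growing-degree-day
gradient, Gaussian taxon niches, and an era shift (chestnut extirpation,
agriculture-scaled beech/hemlock/oak decline, maple/cherry/poplar rise) —
and writes the witness-tree CSV, modern inventory CSV, town GeoJSON,
covariate table and ground-truth compositions under results/landscape/.
"""

import sys

from forestchange.simulate import SimConfig, generate, write_landscape

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = "results/landscape"


def main() -> None:
    cfg = SimConfig(seed=SEED)
    land = generate(cfg)
    paths = write_landscape(land, OUT)
    print(f"landscape: {cfg.n_towns} towns on a {cfg.nx}x{cfg.ny} grid, "
          f"seed {SEED}")
    print(f"  witness trees : {len(land.witness):>7,} records")
    print(f"  inventory     : {len(land.modern):>7,} tree records on "
          f"{land.modern['plot_id'].nunique()} plots")
    print(f"  GDD gradient  : {cfg.gdd_range[0]:.0f} (south) -> "
          f"{cfg.gdd_range[1]:.0f} (north)")
    print(f"files under {paths['witness_csv'].parent}/")


if __name__ == "__main__":
    main()
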