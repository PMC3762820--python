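# forestchange

Tools for asking how similar today's forests are to the forests that stood
before European colonization, at the scale of a whole region. The package
compares two snapshots of forest composition per colonial-era town:

* **Pre-colonial**: witness trees — trees that colonial lot surveyors
  recorded as corner markers, an inadvertent inventory of the forest at
  settlement;
* **Modern**: clustered fixed-radius inventory plots (FIA-style), with
  species and diameter per tree.

Both eras are collapsed onto 24 shared taxon groups and expressed as
per-town relative stem abundances. The pipeline then quantifies the
magnitude, geography and drivers of compositional change, and whether the
modern forest is more homogeneous and less climatically structured than its
predecessor. A synthetic-landscape generator with known ground truth makes
the whole analysis exercisable and testable end to end.

## Methods at a glance

* **Sampling adequacy** — a town enters the analysis only if its data
  capture its compositional diversity. For each densely sampled town,
  bootstrap samples of n units (inventory plots, or bins of 20 witness
  trees) are compared to the full-town composition by Sørensen similarity,
  a Michaelis–Menten curve `y = S_max · n / (k + n)` is fit, and the unit
  count reaching `0.9·S_max` (= `9k`) is converted to a minimum sampling
  density; ecoregion means of these densities are the inclusion thresholds.
* **Compositional change** — the abundance-based Sørensen distance
  `S = Σᵢ|xᵢⱼ − xᵢₖ| / Σᵢ(xᵢⱼ + xᵢₖ)` between a town's two eras; per-taxon
  shifts tested with paired Monte Carlo (sign-flip) tests; ecoregions
  compared by permutation.
* **β-diversity** — each town's mean Sørensen dissimilarity to all other
  towns, per era; a drop over time is biotic homogenization.
* **Spatial structure** — Moran's I correlograms of the change surface
  (15-km classes, permutation tests) and Mantel correlograms of
  composition; Mantel r_M between composition and temperature (growing
  degree days), precipitation, elevation and soil sand.
* **Ordination** — NMDS (Kruskal stress-1, isotonic regression, 50 random
  starts) of pooled pre+modern compositions on Sørensen distances of
  Wisconsin-standardized abundances, with fitted environmental vectors and
  an era-separation readout.
* **Drivers of change** — a conditional-inference regression tree: splits
  require a Bonferroni-corrected permutation-significant
  predictor–response association, so significance is the stopping rule.

## Worked example

Generate a synthetic landscape (120 towns on a growing-degree-day gradient,
with chestnut extirpation and an agriculture-scaled era shift) and run the
numbered analyses:

```bash
python analysis/01_simulate_landscape.py 1
python analysis/02_screen_sampling_adequacy.py 1
python analysis/03_compositional_change.py 1
python analysis/04_spatial_structure.py 1
python analysis/05_ordination.py 1      # ~10 min: k = 1..4 scree at 50 starts
python analysis/06_change_drivers.py 1
```

Output (seed 1, abridged):

```
106/120 towns meet both the witness-tree and plot density thresholds
Sørensen change over 106 towns: mean 0.383 (sd 0.072), range 0.19-0.52
largest region-wide abundance shifts:
  MAPLE       12.7% ->  36.9%  (p=0.0001)
  BEECH       21.4% ->   9.6%  (p=0.0001)
  OAK         18.3% ->  10.3%  (p=0.0001)
β-diversity: pre 0.300 vs modern 0.281 (p=0.0010) -> homogenization
change is spatially clustered out to 75 km (lag-1 I = 0.246)
Mantel r_M composition vs environment (pre / modern):
  gdd             0.960 /  0.829
axis 2 separates the eras: 100% of pre-colonial towns score below 0,
  96% of modern towns above 0
strongest driver of change: gdd (threshold 3149.691)
```

Read: roughly a third of each town's stems changed taxon group between
eras; maple roughly tripled while beech halved and chestnut vanished; towns
became more alike (β-diversity fell) and the temperature–composition
coupling weakened — the same qualitative signature the generator planted.

The same pipeline runs as one command over a data directory:

```bash
forestchange simulate --outdir data --seed 1
forestchange report --datadir data --outdir results/report --seed 1
```

Real data are consumed in the same dialects: witness CSV
(`town_id,raw_name`), inventory CSV
(`town_id,plot_id,raw_name,dbh_cm,condition_class`), a town GeoJSON
FeatureCollection (`town_id`, `ecoregion` properties) and a per-town
covariate CSV.

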