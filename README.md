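# guildscape

Habitat-suitability assessment for breeding-bird guilds from landscape
structure.

`guildscape` implements a complete analysis chain used in landscape
ecology to ask: *can the occurrence of a bird guild be predicted from the
spatial structure of the landscape around its survey plots?*  It targets
point-count monitoring programmes on categorical habitat maps — the
typical setting of agricultural-landscape bird studies — and provides:

* **Habitat map handling** — GeoJSON polygon + line layers merged by
  buffering lines (default 5 m) so narrow habitats such as hedgerows
  survive rasterization, then converted to a 10 m categorical raster by
  dominant-class assignment.
* **Landscape metrics** — sixteen FRAGSTATS-style landscape-level
  metrics (NP, PD, ED, LPI, LSI, MESH, DIVISION, SIDI, PRD, PLADJ, IJI,
  CONNECT, COHESION, CONTIG_MN, SHAPE_MN, PAFRAC) on any raster region,
  with eight-cell-neighbourhood patch delineation and the map border not
  treated as edge.
* **Moving-window surfaces** — exhaustive circular moving-window
  computation (default radius 250 m) producing a continuous surface per
  metric, averaged inside each circular sample plot.
* **Level of persistence (LOP)** — per plot and guild, the sum over all
  surveys of the number of guild species (of three) recorded present.
  Under the four-year design with 5 + 5 + 5 + 4 visits the range is 0–57.
* **Habitat classification** — Spearman screening selects the three
  metrics most correlated with the guild's LOP (skipping rank-collinear
  candidates); plots below the 25% and above the 75% LOP quartile form
  *less preferred* and *preferred* classes; a binary logistic regression
  (all inputs entered in one step, cut point 0.5) yields coefficients,
  Wald chi-square p-values, fully standardized coefficients, Nagelkerke
  R² and the correct-classification rate, and predicts suitability maps
  for the whole landscape.
* **Synthetic data** — a neutral-landscape generator (thresholded
  Gaussian random fields with compositional drift, scattered single-cell
  elements and linear features) and a survey simulator that drives
  per-survey Bernoulli occurrence through a logistic link on plot-level
  metrics, so the whole chain is testable end to end with known truth.

## The model

For a guild with LOP-derived binary response $y$ (preferred = 1) and three
selected landscape metrics $x_1, x_2, x_3$:

$$P(y = 1 \mid x) = \frac{1}{1 + e^{-(b_0 + b_1 x_1 + b_2 x_2 + b_3 x_3)}}$$

fitted by maximum likelihood.  Per-input significance uses the Wald
chi-square $(b_j/\mathrm{se}_j)^2 \sim \chi^2_1$; goodness of fit uses
Nagelkerke's rescaled $R^2$; comparability across inputs uses fully
standardized coefficients
$\beta^*_j = b_j s_{x_j} / \sqrt{\mathrm{var}(\hat\eta) + \pi^2/3}$.

## Worked example

```python
import numpy as np
from guildscape.simulate import (LandscapeSpec, generate_landscape,
                                 random_cell_plots, default_occurrence_spec,
                                 simulate_surveys)
from guildscape.survey import lop_table
from guildscape.classify import GuildHabitatModel

landscape = generate_landscape(LandscapeSpec(rows=64, cols=64, seed=1))
rng = np.random.default_rng(2)
plots = random_cell_plots(landscape, 120, rng, margin_cells=6)
spec = default_occurrence_spec(seed=1, window_radius=50.0)
records, metrics = simulate_surveys(landscape, plots, spec)
lop = lop_table(records, [spec.guilds[0].guild], [p.plot_id for p in plots])

results = GuildHabitatModel.from_tables(lop, metrics, "mosaic").fit()
print(results.summary())
```

prints

```
Guild habitat classification: mosaic
  plots: 120  (less preferred 28, preferred 30; LOP quartiles 8.00 / 35.25)
  input                b     std b    Wald p
  CONTIG_MN       31.755     0.782     0.001
  PRD             -0.026    -0.665     0.007
  NP               1.083     0.471     0.025
  Constant        -5.106               0.091
  Nagelkerke R2 = 0.769   correct = 87.9% at cut 0.5
  confusion [[26 2] [5 25]]   overestimation of less preferred = 3
```

Reading the table: screening picked patch contiguity (CONTIG_MN), patch
richness density (PRD) and patch number (NP) as the three metrics most
rank-correlated with this guild's LOP — the triple the surveys were in
fact simulated from.  All three are significant at the 5% level; the
standardized coefficients rank CONTIG_MN as the strongest predictor.  The
model separates preferred from less-preferred plots with 87.9% correct
classification at the 0.5 cut point, and the confusion table shows a mild
surplus of plots misclassified *into* the less-preferred class.
`results.predict_suitability(surfaces)` then maps P(preferred) over the
whole raster from moving-window metric surfaces, and
`results.plot_suitability(surfaces)` renders the map.

A command-line interface mirrors the chain:

```sh
guildscape simulate --rows 64 --cols 64 --n-plots 120 --seed 5 --out sim/
guildscape metrics  --raster sim/landscape.asc --plots sim/plots.csv --radius 50 --out plot_metrics.csv
guildscape lop      --observations sim/observations.csv --guilds guilds.yaml --out lop.csv
guildscape classify --lop lop.csv --metrics plot_metrics.csv --guild mosaic
```

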