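# nhpikit

Quantify **natal habitat preference induction (NHPI)** — the tendency of
dispersing animals to select habitat resembling the area they grew up in —
from GPS tracking data and habitat rasters, using integrated step-selection
analysis. The package targets movement ecologists studying how habitat
imprinting varies between individuals, between natal habitat types, and
across dispersal phases (multi-year prospecting vs. settlement), in systems
like raptors dispersing across an elevation gradient.

## The method

1. **Natal habitat types.** Each natal territory is summarised by seven
   descriptors over a 2 km buffer around the nest: mean elevation and the
   proportions of six land-cover classes (arable, grassland, forest, urban,
   water, mosaic). A PCA on the scaled descriptors defines a shared habitat
   space; natal areas are grouped by furthest-neighbour (complete-linkage)
   hierarchical clustering of their PC scores.

2. **Step-selection design.** Tracks are resampled to hourly fixes, cleaned
   with a 35 m/s speed filter, and decomposed into steps. Each observed step
   is matched with 10 random available steps (length ~ Exponential fitted to
   the population's observed step lengths; turning angle ~ Uniform(−π, π)),
   forming a stratum. Every step end-location gets two covariates:

   - *dissimilarity*: the Euclidean distance in (PC1, PC2) between the
     end-location's buffered composition and the natal habitat,
     `D_i = sqrt((x_o − x_i)² + (y_o − y_i)²)`;
   - *distance*: planar distance to the natal nest (km).

3. **Conditional logistic regression** per individual-year on the
   standardised covariates, maximising
   `Σ_strata [β'x_used − log Σ_j exp(β'x_j)]` by Newton iterations.
   **NHPI = −β_dissimilarity**: positive values mean preference for
   natal-like habitat. Interaction variants give one coefficient per
   dispersal phase or per prospecting year.

4. **Variation metrics** on the coefficients x_i: *average* (mean),
   *specialization* (mean |x_i|), *heterogeneity* (SD), *consistency*
   (mean |x_p − x_s| between phases), *reversal* (fraction of sign flips
   between phases) and *interannual consistency* (mean absolute change
   between consecutive prospecting years). Uncertainty is propagated by
   redrawing each coefficient from Normal(x_i, se_i) 1000 times, and groups
   are compared by ANOVA + Tukey HSD compact letter displays.

A synthetic-data module generates landscapes (elevation gradient with
elevation-dependent land cover), nests, and hourly trajectories under a
known step-selection process, so the whole chain can be validated against
ground truth without any field data.

## Worked example

`examples/02_simulate_and_fit.py` simulates one bird with a known raw-scale
dissimilarity coefficient of −0.65 (a true preference for natal-like
habitat) and refits it from the track alone:

```
strata: 999, converged: True
dissimilarity coefficient (standardised): -0.884 (SE 0.059)
back-transformed to raw scale:           -0.610 (simulated truth -0.650)
NHPI (= -dissimilarity coefficient):     +0.884
```

The fitted raw-scale coefficient (−0.610) lies within two standard errors
of the simulated truth (−0.650), and the positive NHPI says this bird
selects habitat resembling its natal area. The other examples cover natal
habitat classification (`01`), the variation metrics with uncertainty
propagation (`03`) — where a bimodal ±1 population yields average ≈ 0 but
specialization ≈ 1 — and the full pipeline with its run manifest (`04`).

The same pipeline runs from the shell:

```bash
nhpikit run --seed 7 --out demo_run          # synthetic end-to-end
nhpikit metrics --out demo_run --seed 1      # recompute metrics
```

Real data enter through `RunConfig` paths: a Movebank-style track CSV
(individual, timestamp, x, y [, phase, year]), a nest CSV and the paired
elevation/land-cover grids, all in one projected metric CRS.

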