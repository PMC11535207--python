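# Methods

This note documents the models, the numerical choices and the design
decisions behind `nhpikit`, and what the synthetic-data validation does and
does not demonstrate.

## Natal habitat characterisation

A natal territory is described by a 7-vector: buffer-mean elevation plus the
proportions of six land-cover classes within a 2 km radius of the nest (the
standard territory radius for the study system). A cell belongs to the
buffer iff its **centre** lies within the radius; proportions are over
in-buffer cells only and are renormalised where the buffer is clipped by the
raster edge. Buffer-mean elevation (not nest-cell elevation) enters the
descriptor set — with elevation gradients of a few hundred metres over
kilometres the two differ by far less than between-territory variation, and
the buffer mean is consistent with how the class proportions are defined.

The PCA is computed on centred, SD-scaled variables (n−1 denominator
everywhere, matching the heterogeneity metric). Loadings are eigenvectors of
the correlation matrix sorted by descending eigenvalue. Zero-variance
variables (e.g. no water anywhere in a small cohort's buffers) are dropped
with a warning and the reduced variable set is recorded in the model. Each
axis is oriented so its largest-magnitude loading is positive; every
downstream quantity (dissimilarity distances, cluster assignments) is
invariant to axis sign, so this is purely a reporting convention. Projection
uses the first `k_retained` axes (default 2 — the space in which the
dissimilarity index is defined).

Natal habitat types come from agglomerative clustering with **complete
linkage** (furthest neighbour) on Euclidean distances between the retained
PC scores, delegated to `scipy.cluster.hierarchy`; merge ties are resolved
by scipy's deterministic ordering. With `k="auto"` the cut is chosen as the
largest relative loss of within-cluster inertia between consecutive cuts,
scanning k in [2, min(10, n−1)]; with small or gradient-dominated cohorts
this often prefers 2–3 clusters, so a fixed k (e.g. 4) can be supplied when
a finer typology is wanted. Labels are relabelled by descending cluster
size.

## Step-selection model

Tracks are regularised to a 3600 s interval by a greedy rule: from each kept
fix, the next kept fix is the one closest to (kept + interval) within
±tolerance (default 900 s — a resampling window must be chosen and 15 min is
a common default for hourly data); when no fix falls in the window a new
burst starts, and steps never span bursts. Fixes arriving faster than
35 m/s are removed iteratively. Turn angles are wrapped differences of
successive absolute bearings; zero-length steps carry the last non-zero
bearing forward, and the first step of a burst (no reference bearing) cannot
anchor a stratum.

Available steps share the observed step's start: lengths are
Exponential(rate) with rate = 1/mean(observed lengths, zeros included)
pooled over the population, turning angles Uniform(−π, π) about the previous
bearing. Each stratum is 1 used + 10 available rows. Covariates are
extracted at step **end-locations** only; the movement-kernel updating
covariates of full iSSA (log step length, cos turn angle) are deliberately
omitted — the scientific target is the two habitat covariates, and the
synthetic validation quantifies the consequences (below). Available
end-locations falling outside the raster are redrawn up to 20 times in
synthetic mode and otherwise dropped with a log entry.

Covariate extraction goes through a precomputed **score grid**: the buffered
composition of every cell centre is obtained by convolving the
class-indicator and elevation grids with a disc kernel (overlap-add FFT
convolution; edge cells renormalised by the in-raster cell count), then
projected into (PC1, PC2). A step end-location takes the scores of the cell
containing it — a discretisation of at most one cell (100 m) inside a
2000 m buffer, identical for the simulation and the analysis, so the fitted
model remains correctly specified. The exact point-buffer extraction remains
available and the two agree exactly at cell centres.

Both covariates are z-scored over **all rows of each model's dataset**
(used + available, per individual-year or per interaction model): models are
fitted separately, so pooled standardisation would mix scales across models.
The scaling record supports raw-scale back-transformation
(β_raw = β_z / SD), which is how fits are compared across individuals and
against simulation truth. The Pearson correlation between the covariates is
reported and a warning raised at |r| ≥ 0.6.

### Conditional logit

The conditional likelihood is concave; it is maximised by Newton iterations
with step-halving, converging when the gradient max-norm drops below 1e-8
(100-iteration cap). Standard errors come from the inverse observed
information. Covariates constant within every stratum cancel from the
likelihood; they are detected up-front, pinned at zero and flagged
non-identifiable. Complete separation is flagged in two ways: |β| exceeding
50 on the standardised scale, or a log-likelihood within 1e-6·n_strata of
its upper bound of 0 (perfect prediction — the gradient flattens before β
diverges, so a norm bound alone would miss it). Separated fits report
`converged=False`. The estimator is verified against a brute-force grid
search of the conditional likelihood and against
`statsmodels.ConditionalLogit` as an independent implementation.

Phase and year interaction fits build covariate × level columns with no main
effects (each stratum lies in one level, so main effects would cancel
anyway) and return one coefficient set per level; levels with fewer than 10
strata are flagged low-information.

### Cross-validation

Strata are partitioned into k = 5 folds; each fold's model is refitted on
the rest and every held-out stratum's members ranked by fitted score. The
frequencies of the used step's rank (1..11) are correlated with the rank
index by Spearman's rho and negated, so +1 means the observed step is
consistently ranked best. This rank-frequency construction is the standard
used-habitat validation for matched designs.

## NHPI variation metrics

With x_i the per-individual-year NHPI coefficient (−β_dissimilarity):
average = mean(x); specialization = mean|x| (≥ |average|, informative for
bimodal populations); heterogeneity = SD(x, n−1); consistency =
mean|x_p − x_s| over phase pairs (0 = perfectly consistent); reversal =
fraction of pairs with sign(x_p) ≠ sign(x_s), where sign(0) counts as
positive (a fixed convention; exact zeros have measure zero after
perturbation); interannual consistency = the per-individual mean absolute
change over consecutive prospecting years, averaged over individuals (the
inner mean normalises individuals with different numbers of years).
Metrics weight individual-years equally; non-converged fits are excluded by
default (flag to include).

Uncertainty is propagated by simulation: 1000 replicates redraw every
coefficient independently from Normal(x_i, se_i) and recompute each metric
per group (natal habitat × phase, plus the pooled set). As all SEs → 0
every replicate equals the point estimate exactly. Group comparisons run
ANOVA (one- or two-way on habitat and phase) over replicate values with
Tukey HSD compact letter displays, letters omitted when the omnibus
p ≥ 0.05. Because replicates are perturbations rather than independent
samples this is **anti-conservative**; p-values are descriptive and should
be read alongside the replicate quantile overlaps, which are always
reported. A related artefact: metrics built from absolute values
(specialization, consistency, reversal, interannual consistency) are biased
upward under perturbation — adding noise inflates |differences| — so their
replicate distributions can sit entirely above the point estimate; the
point estimate, computed on the unperturbed coefficients, is the headline
value and the replicates quantify spread.

## Synthetic data: what it emulates

The landscape is elevation = linear gradient (default 500→1100 m over a
12 km grid of 100 m cells, matching the nest elevation range of the study
system) + smoothed Gaussian noise; land cover is drawn per cell from
elevation-dependent class weights (urban/arable/water concentrated low,
forest mid, grassland/mosaic high) and modal-smoothed into patches. A
24-nest cohort on the default landscape supports four separated natal
habitat types (low urban/arable, low farmland, mid pasture–forest, high
mosaic). Nests are stratified across the elevation gradient with a minimum
spacing (default 1 km, a realistic breeding density) and kept one buffer
radius clear of the raster edge.

Trajectories follow a step-selection process: 50 proposals per step
(Exponential lengths, mean 2 km per hour; uniform turns), scored by
exp(β_dissim·D + β_dist·dist) and softmax-sampled; out-of-raster proposals
are redrawn. Fifty proposals approximate the continuous availability
distribution far better than the 10-alternative analysis design, keeping
the generative and fitted models aligned. Simulation coefficients are
defined on the **raw** covariate scale; the standardised-scale truth for an
individual is β_raw × SD(covariate) over that individual's realised design.
The recovery studies use raw effects of −0.65/0/+0.25 (dissimilarity) and
−0.25 km⁻¹ (distance), calibrated once against the default landscape to
give standardised magnitudes near ±1 and −0.5 — strong but realistic
selection.

What the synthetic validation does **not** capture: GPS measurement error
(beyond what the speed filter removes), memory and site fidelity other than
the distance covariate, migration and seasonal structure, habitat-dependent
movement kernels, and landscape change over years. Passing tests therefore
demonstrate the estimator and metric chain is correct under its own model,
not that the model is adequate for any particular field system. One known
consequence visible in the full pipeline: because the availability rate is
refitted from *observed* (selected) steps — whose lengths are shortened when
selection favours staying in good habitat — pipeline estimates show mild
attenuation relative to the matched-kernel recovery studies; this mirrors
the same approximation in the field workflow.

## Problem sizes and numerics

The validation studies use 50 individuals × 1000 hourly steps (recovery),
40–50 replicates of 200-step tracks (null calibration) and a 20-bird, two
prospecting-year pipeline — sizes at which Monte-Carlo error on the reported
biases is ~0.01–0.02 and each study completes in seconds to tens of seconds
on one core. Determinism: every stage derives its RNG stream by hashing
(master seed, stage name, individual id), so cohorts can grow without
perturbing existing individuals' draws, and a rerun with the same
configuration and seed is bit-identical.

## Known limitations

- Real-data mode requires planar, metre-scaled coordinates in one projected
  CRS; no geographic-coordinate support.
- Phase/season labels are inputs; the package does not segment migratory
  periods or detect settlement events.
- No consolidation step after the hierarchical cut (no k-means refinement),
  and no spatial-autocorrelation diagnostics for model residuals.
- The ANOVA/Tukey layer inherits the anti-conservatism of operating on
  simulation replicates, as noted above.
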