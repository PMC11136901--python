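# Methods

## The plateau model

The response of occurrence probability to each predictor is a trapezoid
on the 0–1 normalized predictor scale: flat between edges `c1 ≤ c2`,
declining linearly outside with non-negative slopes `b1` (ascending
side) and `b2` (descending side). A single global intercept `β₀` caps
the linear predictor (the apex); labels are Bernoulli through a logistic
link:

    p = logistic(β₀ + Σⱼ fⱼ(xⱼ)),   fⱼ(x) = −b1ⱼ max(0, c1ⱼ−x) − b2ⱼ max(0, x−c2ⱼ)

A per-predictor apex is not jointly identifiable with an intercept, so
the apex is global. The equivalent "two intersecting lines capped at a
maximum" geometry maps onto this parameterization with `c1, c2` the
points where the cap meets the two lines. Probabilities are clamped to
`[1e−12, 1−1e−12]` inside the likelihood so extreme draws keep the
log-likelihood finite. Only the logistic link is implemented; the
qualitative behaviour of the model does not depend on the link.

### Priors

* **Naïve:** `β₀ ~ Normal(0, 5)`; `b1, b2 ~ half-Normal(10)` (on the
  normalized scale a slope of 10 moves the log-odds by 10 across the
  full observed predictor range — effectively vague); `(c1, c2)` are the
  order statistics of two independent `Uniform(0, 1)` draws.
* **Physiologically informed:** for each constrained predictor, the
  physical optimal range `[o₁, o₂]` and upper hard limit `ℓ` are mapped
  through the shared min–max transform. The edges are sampled uniformly
  inside the normalized `[o₁, o₂]` (pinned when the optimum starts at or
  below the observed minimum, as for depth 0–40 m), and the descending
  slope is a deterministic link

      b2 = (β₀ − L) / (x_ℓ − c2),   L = logit(floor), floor = 0.01,

  so presence probability at the hard limit is exactly the configured
  "effectively absent" floor whenever the other predictors are on their
  plateaus. `β₀` is restricted to `β₀ ≥ L` in informed mode so the
  linked slope is never negative. An optimum whose lower end falls below
  the observed minimum is clamped to the observed floor; an optimum
  whose upper end falls outside the observed range is an error (the
  plateau would not be locatable). The default constraint table is the
  Japanese sea cucumber's: temperature optimum 15–18 °C / limit 26 °C;
  depth optimum 0–40 m / limit 200 m; no constraints on salinity,
  current velocity, annual temperature range, or distance to shore.

### Sampler

Component-wise adaptive random-walk Metropolis. Per-parameter step sizes
adapt every 50 iterations during warm-up toward a 0.44 acceptance rate
and are frozen afterwards, preserving detailed balance for the retained
draws. Proposals violating a support (edge ordering, slope positivity,
informed bounds, linked-slope positivity) are rejected. Both chains
start from the same initial values by default (`jitter_inits` is
available but weakens the value of the identical-inits convention the
default follows); chains differ only in their random streams. The
study-default configuration is 2 chains × 5000 iterations with 4000
warm-up (1000 retained per chain). Split-R̂ and bulk effective sample
size are computed with `arviz`; R̂ above 1.1 warns but does not fail,
since short reduced-MCMC runs are used deliberately in scaled
experiments.

## Data preparation

* **Cleaning:** records on land or off-grid are dropped; one presence is
  kept per grid cell (first in input order). Counts are logged.
* **Thinning (20 km default):** repeat `n_rep` randomized runs of
  "while any pair is closer than the threshold, remove one record chosen
  uniformly among those with the most too-close neighbours"; the run
  retaining the most records wins. This reproduces the behaviour of the
  standard randomized max-retention thinning tools.
* **Calibration areas:** great-circle buffers (haversine, spherical
  Earth R = 6371 km) around the retained presences, evaluated at cell
  centers, intersected with the domain mask (an EEZ analogue: sea within
  370 km of shore). Areas nest monotonically in the radius.
* **Pseudo-absences:** drawn uniformly without replacement from the
  calibration-area cells, excluding presence cells and cells with any
  missing predictor. One set per (buffer, replicate), shared by the
  naïve and informed fits so model-type contrasts are paired.
* **Normalization:** per-layer min–max over the **largest** calibration
  area, stored as an affine transform reused for every model variant,
  for physical constraint constants, and for future layers (values may
  leave [0, 1]; they are not clipped).
* **Collinearity:** VIFs from OLS (with intercept) of each predictor on
  the others over the calibration area; ≥ 10 warns.
* **Regridding:** bilinear interpolation between regular lon/lat grids
  with no-data propagation (any missing corner ⇒ missing output).

## Evaluation

* **Spatial block cross-validation:** the record bounding box is split
  into 10 × 10 lat/lon blocks; non-empty blocks are greedily allocated
  to 5 folds balancing per-fold presence counts with random tie-breaks;
  records in a block share a fold.
* **Boyce index:** continuous formulation — 100 window centers spanning
  the background suitability range, window width = range/10, P/E =
  presence share over background share per window, zero-expected windows
  dropped, duplicated P/E values collapsed to their first window, then
  Spearman correlation of P/E against the window center. The duplicate
  collapse matches the reference implementation's default and is what
  makes concentrated-presence configurations approach ±1. Background =
  all calibration-area cells (the metric is presence-only; using the
  full background avoids pseudo-absence noise).
* **Permutation importance:** 1 − Pearson correlation between
  posterior-mean predictions on intact data and on data with one
  predictor column permuted, averaged over 5 permutations, clipped to
  [0, 1].
* **Response curves:** one predictor varied from its observed minimum to
  max(observed maximum, hard-limit constant), the others at their median
  over the calibration area; posterior mean with a central 95 % band.

## Projection and comparison

All models are projected onto the largest calibration buffer.
Binarization threshold = the 10 % (linear-interpolation) quantile of the
suitability at the model's own training presences. Jaccard similarity is
computed over all cross-buffer replicate pairs (25 × 25 = 625 under the
default design). Range expansion/contraction are percentages of the
current suitable cell count under unlimited dispersal; cells are counted
without area weighting (an equal-area `cos(lat)` weighting would change
values by < 1 part in 10 at these latitudes and is easy to add).
The "paired Wilcoxon" contrast is the signed-rank test (the V statistic
identifies it): zero differences dropped, mid-ranks for ties, exact p by
convolution of the signed-rank null for n ≤ 25 (including tied ranks),
normal approximation with continuity correction otherwise.

## The synthetic landscape

The generator emulates the statistical structure of a temperate
western-Pacific coastal margin on a regular degree grid (equirectangular
projection):

* a connected north–south coastline (land west, sea east) whose
  east–west excursion scales with `coast_complexity`;
* distance to shore = haversine distance to the nearest land cell;
* bathymetry deepening monotonically offshore with a **broad southern /
  narrow northern shelf** and smooth random shelf-width variation (so
  depth is correlated with, but not a deterministic function of,
  distance to shore; realized VIFs are ~4–5);
* mean benthic temperature declining linearly from 28 °C at the southern
  edge to 2 °C at the northern edge, plus smooth noise (default SD
  0.5 °C);
* annual temperature range low (~2 °C) over the thermally stable warm
  south, rising across mid-latitudes to a ~10–12 °C northern plateau —
  i.e. spatially confounded with mean temperature at the warm end, as in
  real marginal seas;
* salinity (29–35) and current velocity (0–1.5 m/s) as smoothed random
  fields.

The default ground truth is the tolerance table itself: temperature
plateau 15–18 °C declining to the 1 % floor at 26 °C (and below ~8 °C on
the cold side), depth plateau 0–40 m declining to the floor at 200 m, no
effect of the other predictors, apex logit 2.5. Presences are sampled
without replacement with probability proportional to suitability times a
smooth spatial bias field (`bias_strength = 0` ⇒ unbiased); future
stacks add a spatially smooth warming field (configurable mean and SD)
to the temperature layers only — depth and distance to shore are copied
bitwise.

What the generator does **not** emulate: ocean dynamics (currents advect
nothing), dispersal barriers, observation error in coordinates, real
bathymetric texture, or climate-model disagreement (the future stack is
a single additive scenario). Passing tests therefore demonstrate that
the inference and comparison machinery behaves correctly when its
assumptions hold, not that those assumptions hold for any particular
real dataset.

## Scaled experiment sizes

The package's own test experiments run at desk scale, chosen once:

* parameter recovery: 20 datasets × 600 points, 2 predictors, MCMC
  2 × 1500 (1000 warm-up);
* truncated-sampling response contrast: 500 points with temperature
  observed only below 18 °C, MCMC 2 × 800;
* calibration-area stability directions: 100 × 96 grid over 22–50 °N,
  90 presences, buffers 250/800 km, 5 pseudo-absence replicates, MCMC
  2 × 1000 (700 warm-up), +1.5 °C smooth warming, five replications with
  master seeds 1–5;
* design-cardinality check: the full 3-buffer × 2-type × 25-replicate
  design on a tiny 24 × 30 landscape with a sharply reduced sampler.

## Known limitations

* The naïve model's attribution of warm-edge absences is bimodal
  (mean temperature vs. annual range); short chains can stick in one
  mode per replicate, which adds replicate-to-replicate variance to the
  naïve range-change estimates in the scaled stability experiment.
* The linked informed slope ties `b2` to `β₀`; when the data are nearly
  separable, `β₀` (and hence the informed slope) can drift large under
  the vague intercept prior. The response at the hard limit is pinned to
  the floor regardless, which is the property that matters downstream.
* Buffer membership is evaluated at cell centers; cells whose center
  lies just outside a radius are excluded even if most of their area is
  inside.
* Block cross-validation balances presence counts only approximately
  (greedy assignment), and folds with zero presences trigger bounded
  reshuffles before erroring.
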