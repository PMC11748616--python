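# Methods

## The modeling problem

`nichemap` estimates environmental suitability for a species from
presence-only occurrence records and gridded climate predictors, and
projects that suitability onto future climate scenarios. The central
assumptions are the standard ones of presence–background niche modeling:
occurrences are (after thinning) an approximately suitability-biased
sample of the cells the species can reach; the **accessible area M**
supplied by the user bounds both model calibration and background
sampling; and the fitted environment–suitability relationship is
transferable to climates that remain within the calibration range —
which is why predictions outside that range are masked rather than
extrapolated, and why climatic novelty is mapped explicitly.

## Pipeline stages

1. **Occurrences.** Records with missing, unparseable, or out-of-bounds
   coordinates are dropped; exact (lon, lat) duplicates collapse to the
   first occurrence; records are rarefied to at most one per grid cell
   (the grid-cell reading of ~5 km spatial thinning at 2.5 arcminutes);
   the thinned set is split 50/50 at random into calibration and
   evaluation halves. Every step logs a reconciling
   input = kept + removed provenance entry.
2. **Climate predictors.** Artifact-prone layers (bio8/9/18/19 in the
   standard 19-variable bioclim set) are dropped by name. The remaining
   layers are standardized (centered, divided by standard deviation —
   they mix °C and mm units) and decomposed by PCA fitted **once**, by
   default on cells inside M (configurable to all valid cells). The
   transform is frozen — means, scales, loadings serialized to JSON —
   and applied unchanged to every future layer set; the component count
   is the smallest k whose cumulative explained variance reaches 99.9%.
3. **MaxEnt model.** See below.
4. **Aggregation.** Bootstrap replicate predictions are summarized by
   cell-wise median and max−min range (the replicate-level uncertainty);
   future scenarios are summarized again as the median across per-GCM
   medians, with the GCM range as scenario uncertainty.
5. **Thresholding and change.** The continuous median map is binarized
   at the E = 5% omission threshold: the (⌊E·n⌋+1)-th smallest suitability
   among the n calibration records, i.e. the largest order statistic that
   still omits at most E·n of them. Future maps reuse the historical
   threshold (change maps must compare like with like). Each jointly
   valid cell is then classed stable absence / stable presence /
   expansion / contraction, with percentage increase/decrease reported
   against the historical suitable area (optionally all valid cells,
   optionally cos-latitude area weighting).
6. **Evaluation.** Partial ROC with bootstrap resampling of the test
   points; one-tailed cumulative binomial test of independent records
   against the map's suitable fraction; ExDet Type-1 novelty of the
   projection extent relative to the calibration region.

## The maximum-entropy model

Among all densities on the background whose feature expectations match
the presence sample, the model selects the maximum-entropy (Gibbs) one,
fitted by maximizing the L1-penalized presence log-likelihood
(1/m)Σᵢ λ·f(xᵢ) − log Z_λ − Σⱼ βⱼ|λⱼ|. Implementation choices:

- **Features**: linear, quadratic, pairwise products, and forward hinge
  with 10 knots per variable at training-value deciles. Which families
  are active follows the classic sample-size schedule (linear below 10
  presences; +quadratic at 10; +hinge at 15; +product at 80), unless the
  user fixes them. Every expanded feature is min–max scaled to [0, 1] on
  the training sample; hinge features are in [0, 1] by construction.
- **Penalty**: βⱼ = multiplier(class) · max(sd of feature j over
  presences, 10⁻⁴)/√m, with class multipliers 1.0
  (linear/quadratic/product) and 0.5 (hinge), all configurable, plus a
  global `beta_multiplier`.
- **Solver**: the objective is convex; λ is split into positive and
  negative parts so the L1 term becomes linear and the problem a smooth
  bound-constrained program, solved by L-BFGS-B to projected-gradient
  tolerance 10⁻⁵ (default cap 1000 iterations — the default synthetic
  scenario needs ~400–600; a non-zero solver status within 10× the
  tolerance is accepted, anything worse raises a convergence error).
  Coefficients below 10⁻¹² are snapped to zero.
- **Normalization sample**: the background (default 10,000 cells sampled
  uniformly without replacement from M, or all of M when smaller) with
  the presence sample appended; the raw density sums to 1 over it.
- **Output**: logistic by default — e^H·raw/(1 + e^H·raw), H the entropy
  of the fitted density — matching the output of MaxEnt 3.3.3-era
  software rather than the later cloglog.
- **Out-of-range policy**: with clamping and extrapolation both off (the
  default), any cell whose raw predictor leaves the training range
  becomes nodata; `clamp=True` truncates to the range instead; the two
  are mutually exclusive.
- **Replicates**: each of the (default 10) bootstrap replicates
  resamples presence cells with replacement at full size, refits against
  the shared background, and predicts; all replicate seeds derive from
  one master seed.

## Partial ROC

The curve plots fractional predicted area (fraction of valid cells at or
above a threshold) against sensitivity over the test points, at every
unique prediction value (or 2000 equal-quantile bins when there are
more — the quantile rule converges to the exact curve while bounding
cost). Each of the (default 1000) iterations resamples ⌈0.5·n⌉ test
points with replacement; model and null (1:1 line) partial AUCs are
integrated by the trapezoid rule over the curve region with sensitivity
≥ 1−E, and the reported statistic is their ratio, with
p = fraction of iterations with ratio ≤ 1. The ratio is a rank statistic:
it is invariant under any strictly increasing transform of the
prediction layer.

## Evaluation domain of the binomial test

The suitable-cell fraction (the test's success probability) is computed
over all valid cells of the evaluated map's grid, not over M: the
independent records this test is designed for typically lie outside the
calibration area, so the evaluation domain must be the projection
extent. This is configurable in principle by masking the input map.

## Synthetic scenario

The generator stands in for real climate layers, occurrence databases,
and GCM futures. Defaults (one choice, made on realism grounds):

| parameter | default | why |
|---|---|---|
| grid | 120 × 160 cells at 2.5′ | desk-scale analogue of a regional extent |
| latent fields | 4, Gaussian-smoothed (σ = 6 cells), unit variance | realistically autocorrelated "climate" |
| raw layers | 15 = mixing × latents + 2% smooth noise, heterogeneous offsets/scales | inter-correlated like bioclim variables; low-rank so component selection is meaningful |
| N–S gradient on latent 1 | amplitude 3 | the global temperature gradient analogue; makes warming move suitability poleward |
| truth | logistic(0.5 + 1.0·z₂ − 6.0·z₁²) | an interior optimum in latent 1; ~15% of the landscape suitable, the prevalence regime where niche models are typically applied |
| accessible area | southern 85% of rows × western 60% of columns | strictly smaller than the grid, so transfer and novelty are non-trivial |
| occurrences | 600 sampled ∝ truth inside M, with replacement, uniform within cell | duplicates and near-duplicates exercise cleaning and thinning |
| pseudo-GCM shifts | +1.2 mean on latent 1, ±0.25 smooth between-GCM spread, scaled by period (¼…1) and SSP (0.55…1) index | warming-like forcing that grows with scenario strength and differs between GCMs |

What it deliberately does **not** emulate: real marginal distributions of
bioclim variables, sampling bias beyond the region restriction,
observation error in coordinates, spatial sorting bias between
calibration and evaluation halves, or GCM physics. Passing tests
therefore demonstrate that the machinery is correct and the statistics
calibrated — not that any particular real-world prediction is right.

## Numerical choices and degenerate inputs

- Cell membership is half-open ([x, x+s) × [y, y+s), row 0 northernmost);
  polygon rasterization tests cell centers, boundary counting as inside.
- Grids align iff all GridSpec fields agree within 10⁻⁹ degrees; every
  cross-grid operation raises a single alignment error otherwise.
- ESRI ASCII is written with 6 significant digits; GeoTIFF with float64
  and the pixel-scale/tiepoint/nodata tags. Invalid cells are excluded
  from every statistic.
- Zero-variance predictors raise errors naming the layer (PCA fit, ExDet
  reference, feature expansion); constant prediction layers make the
  partial ROC undefined and raise, rather than returning a ratio of 1.
- PCA loading signs follow a deterministic convention (largest-magnitude
  loading positive) so outputs are backend-independent.
- Thinning keeps the first record per cell; the classification splits
  suprathreshold cells at quartiles by default (scale-free) with
  equal-interval as the alternative; degenerate distributions warn.
- All stage seeds expand deterministically from one master seed
  (SeedSequence), so a single integer reproduces a run; manifests record
  config, seeds, timings, and SHA-256 content hashes per stage.

## Known limitations

- Geographic (WGS84) grids only; no reprojection or resampling.
- Area percentages use plain cell counts unless cos-latitude weighting
  is switched on; on global grids the unweighted numbers overweight high
  latitudes.
- The per-cell thinning is the grid-cell reading of distance-based
  rarefaction; no additional distance radius is applied.
- Only ExDet Type-1 (univariate range) novelty is computed; Type-2
  (Mahalanobis) correlation novelty is out of scope.
- The future ensemble assumes one historical model projected everywhere;
  no per-scenario recalibration is offered by design.
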