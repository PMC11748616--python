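# nichemap

Ecological niche modeling with climate-change ensemble projection.

`nichemap` is a reusable, tested implementation of the presence–background
species distribution modeling workflow used in vector-borne disease risk
mapping — for example, mapping where environmental conditions are suitable
for an invasive tick today and under future climate scenarios. It covers
the full chain: occurrence cleaning and spatial thinning, principal-
component transfer of climate layers to future scenarios, maximum-entropy
suitability modeling with bootstrap replicates, ensemble aggregation
across replicates / climate models (GCMs) / emission pathways (SSPs),
omission-based thresholding, range change/stability mapping, and the
standard evaluation statistics (partial ROC, cumulative binomial test,
ExDet Type-1 climatic novelty).

## The model

Given presence cells $x_1,\dots,x_m$ and a background sample drawn from
an accessible area $M$, the maximum-entropy model estimates a Gibbs
density over environmental feature space

$$p_\lambda(x) = \frac{e^{\lambda \cdot f(x)}}{Z_\lambda},$$

where $f(x)$ are linear, quadratic, product, and hinge features of the
environmental predictors (principal components of the climate layers),
scaled to $[0,1]$ on the training sample. Coefficients maximize the
L1-penalized presence log-likelihood

$$\frac{1}{m}\sum_{i} \lambda \cdot f(x_i) \;-\; \log Z_\lambda
\;-\; \sum_j \beta_j |\lambda_j|,$$

a convex problem. The logistic output
$e^H p_\lambda / (1 + e^H p_\lambda)$ (with $H$ the entropy of
$p_\lambda$ over the background) maps the density to a 0–1 suitability
scale. Suitability maps are binarized at the $E$-percent omission
threshold — the largest order statistic of the calibration-point
suitabilities that still omits at most a fraction $E$ (default 5%) of
them — and evaluated by the partial-ROC AUC ratio (model vs null partial
AUC over the sensitivity $\ge 1-E$ region), the one-tailed cumulative
binomial test of independent records, and ExDet NT1 novelty
$\mathrm{NT1} = \sum_i \mathrm{ud}_i \le 0$, the sum of range-normalized
exceedances of projection conditions beyond the reference ranges.

Future scenarios reuse the frozen PCA transform and the fitted replicate
models (no refitting): replicate predictions are medianed per GCM, GCM
medians are medianed per (SSP, period), and each scenario map is
binarized with the historical threshold to classify every cell as stable
absence, stable presence, expansion, or contraction.

## Worked example

The package ships a synthetic scenario generator (correlated smooth
climate layers, a known true suitability surface, biased presence
sampling, pseudo-GCM future shifts), so the whole pipeline runs without
downloading anything:

```python
from nichemap import RunConfig, run_historical, run_future_ensemble

cfg = RunConfig(mode="synthetic", outdir="demo_run", seed=1,
                n_occurrences=600, n_replicates=10,
                n_gcms=2, n_ssps=2, n_periods=2)
hist = run_historical(cfg)
print(f"components kept: {hist.n_components}")
print(f"omission threshold (E=5%): {hist.threshold:.4f}")
print(f"partial ROC mean ratio: {hist.proc.mean_ratio:.3f} "
      f"(p = {hist.proc.p_value:.4f})")
print(f"independent records correct: {hist.binomial.pct_correct:.1f}%")

fut = run_future_ensemble(cfg, hist)
print(fut.area_table[["ssp", "period", "pct_increase", "pct_decrease"]])
```

prints

```
components kept: 4
omission threshold (E=5%): 0.3121
partial ROC mean ratio: 1.578 (p = 0.0000)
independent records correct: 90.3%
    ssp   period  pct_increase  pct_decrease
0  ssp1  period1     25.409299     33.944554
1  ssp1  period2     52.759527     65.002190
2  ssp2  period1     37.691299     48.076082
3  ssp2  period2     67.704451     85.376014
```

Four principal components carry >99.9% of the climatic variance (the
generator mixes 15 layers from 4 latent fields). The partial-ROC ratio of
1.58 means the model's high-sensitivity ROC region has 60% more area than
random ranking; none of the 1000 bootstrap iterations fell at or below 1.
90.3% of held-out records land on cells the binarized map calls suitable.
The area table shows the warming-forced scenario: suitable area expands
poleward (increase) while the historical suitable belt erodes (decrease),
and both effects strengthen with period and SSP index.

The same run is available from the shell:

```bash
nichemap run-all --config demo.yaml
```

with the configuration in a single YAML file (see
`nichemap.workflow.RunConfig` for every key).

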