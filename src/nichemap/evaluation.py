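"""Niche-model evaluation statistics.

Three complementary checks of a presence-background suitability model:

* **Partial ROC** — the ROC curve of fractional predicted area (x) versus
  sensitivity over test occurrences (y), integrated only over the
  high-sensitivity region (sensitivity >= 1 - E) and expressed as the
  ratio of the model's partial AUC to that of the 1:1 null line; ratios
  above 1 indicate better-than-random discrimination. Significance comes
  from bootstrap resamples of the test points: the p-value is the fraction
  of iterations with ratio <= 1.

* **Cumulative binomial omission test** — given a binary suitability map
  whose suitable fraction is p, the probability of k or more of n
  independent occurrence points landing on suitable cells by chance,
  i.e. the one-tailed upper binomial tail.

* **ExDet Type-1 novelty (NT1)** — per-cell sum of range-normalized
  univariate exceedances of projection conditions beyond the reference
  (calibration-region) minima/maxima; NT1 < 0 flags non-analogous climate
  where model extrapolation is untrustworthy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .grids import RasterLayer, RasterStack, RegionMask
from .occurrences import OccurrenceSet
from .suitability_maps import BinaryMap

__all__ = [
    "PartialROCResult",
    "BinomialTestResult",
    "NoveltyMap",
    "DegenerateCurveError",
    "partial_roc",
    "binomial_omission_test",
    "exdet_nt1",
]


class DegenerateCurveError(ValueError):
    """The prediction layer is constant; no ROC curve exists."""


@dataclass
class PartialROCResult:
    auc_ratios: np.ndarray
    mean_ratio: float
    min_ratio: float
    max_ratio: float
    p_value: float
    E: float
    iterations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "mean_ratio": self.mean_ratio,
            "min_ratio": self.min_ratio,
            "max_ratio": self.max_ratio,
            "p_value": self.p_value,
            "E": self.E,
            "iterations": self.iterations,
            "seed": self.seed,
        }


@dataclass
class BinomialTestResult:
    n_points: int
    n_correct: int
    success_prob: float
    p_value: float

    @property
    def pct_correct(self) -> float:
        return 100.0 * self.n_correct / self.n_points

    def to_dict(self) -> dict:
        return {
            "n_points": self.n_points,
            "n_correct": self.n_correct,
            "pct_correct": self.pct_correct,
            "success_prob": self.success_prob,
            "p_value": self.p_value,
        }


@dataclass
class NoveltyMap:
    """NT1 layer (values <= 0) with the strictly-novel cell mask."""

    layer: RasterLayer
    novel_mask: np.ndarray

    @property
    def n_novel(self) -> int:
        return int(self.novel_mask.sum())


def _partial_auc_curve(area, sens, min_sens):
    """Partial AUCs (model, null) over the curve region with sens >= min_sens.

    ``area`` ascending fractional predicted area, ``sens`` the matching
    sensitivities. The null is the 1:1 line integrated over the same
    area subdomain.
    """
    keep = sens >= min_sens
    if keep.sum() < 2:
        return np.nan, np.nan
    a = area[keep]
    s = sens[keep]
    model = np.trapezoid(s, a)
    null = 0.5 * (a[-1] ** 2 - a[0] ** 2)
    return model, null


def partial_roc(
    prediction: RasterLayer,
    test_points: OccurrenceSet,
    E: float = 0.05,
    iterations: int = 1000,
    resample_fraction: float = 0.5,
    seed: int = 0,
    max_thresholds: int = 2000,
) -> PartialROCResult:
    """Bootstrap partial-ROC AUC ratio of a suitability map against test points.

    Each iteration resamples ceil(resample_fraction * n) test points with
    replacement, rebuilds the sensitivity-vs-area curve over descending
    prediction thresholds, and integrates model and null partial AUCs over
    the sensitivity >= 1 - E region. Thresholds are the unique prediction
    values when few, else ``max_thresholds`` equal-quantile bins.
    """
    vals = prediction.valid_values
    uniq = np.unique(vals)
    if uniq.size < 2:
        raise DegenerateCurveError("prediction layer is constant over valid cells")
    spec = prediction.spec
    inside = spec.contains(test_points.lon, test_points.lat)
    row, col = spec.cell_of(test_points.lon[inside], test_points.lat[inside])
    flat = row * spec.n_cols + col
    on_valid = prediction.valid_mask.ravel()[flat]
    pt_vals = prediction.values.ravel()[flat[on_valid]]
    n_dropped = len(test_points) - int(on_valid.sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} test point(s) off valid cells were dropped")
    n = pt_vals.size
    if n < 5:
        raise ValueError(f"need at least 5 test points on valid cells, got {n}")

    if uniq.size > max_thresholds:
        thresholds = np.unique(np.quantile(vals, np.linspace(0, 1, max_thresholds)))
    else:
        thresholds = uniq
    # fractional predicted area at each threshold (fraction of cells >= t)
    sorted_vals = np.sort(vals)
    area = 1.0 - np.searchsorted(sorted_vals, thresholds, side="left") / vals.size
    # ascending area = descending threshold
    order = np.argsort(area, kind="stable")
    thresholds_desc = thresholds[order]
    area_asc = area[order]

    # per-point threshold bin: count of points >= t via cumulative histogram
    pt_sorted = np.sort(pt_vals)
    m = int(np.ceil(resample_fraction * n))
    rng = np.random.default_rng(seed)
    min_sens = 1.0 - E
    ratios = np.empty(iterations)
    # precompute, per original point, how many thresholds it reaches
    counts_ge = np.empty((iterations, thresholds_desc.size))
    for it in range(iterations):
        sample = rng.choice(pt_vals, size=m, replace=True)
        ssort = np.sort(sample)
        n_ge = m - np.searchsorted(ssort, thresholds_desc, side="left")
        counts_ge[it] = n_ge
    sens = counts_ge / m
    for it in range(iterations):
        model, null = _partial_auc_curve(area_asc, sens[it], min_sens)
        ratios[it] = model / null if null and np.isfinite(null) else np.nan
    ok = np.isfinite(ratios)
    if not ok.any():
        raise DegenerateCurveError("no iteration produced a defined partial AUC")
    ratios = ratios[ok]
    return PartialROCResult(
        auc_ratios=ratios,
        mean_ratio=float(ratios.mean()),
        min_ratio=float(ratios.min()),
        max_ratio=float(ratios.max()),
        p_value=float((ratios <= 1.0).mean()),
        E=E,
        iterations=iterations,
        seed=seed,
    )


def binomial_omission_test(
    binary: BinaryMap, independent_points: OccurrenceSet
) -> BinomialTestResult:
    """One-tailed cumulative binomial test of independent-record prediction.

    success_prob is the suitable fraction of the map's valid cells (the
    chance a random point lands on a suitable cell); the p-value is
    P[X >= k] for X ~ Binomial(n, success_prob), computed with the
    numerically stable survival function.
    """
    layer = binary.layer
    spec = layer.spec
    inside = spec.contains(independent_points.lon, independent_points.lat)
    row, col = spec.cell_of(
        independent_points.lon[inside], independent_points.lat[inside]
    )
    flat = row * spec.n_cols + col
    on_valid = layer.valid_mask.ravel()[flat]
    if not on_valid.any():
        raise ValueError("no independent points fall on valid cells")
    suitable = layer.values.ravel()[flat[on_valid]] >= 0.5
    n = int(on_valid.sum())
    k = int(suitable.sum())
    n_valid_cells = int(layer.valid_mask.sum())
    p = float(binary.suitable_mask.sum()) / n_valid_cells
    p_value = float(binom.sf(k - 1, n, p)) if k > 0 else 1.0
    return BinomialTestResult(n_points=n, n_correct=k, success_prob=p, p_value=p_value)


def exdet_nt1(
    reference: RasterStack,
    projection: RasterStack,
    region: RegionMask | None = None,
) -> NoveltyMap:
    """ExDet Type-1 univariate novelty of projection vs reference conditions.

    For each variable with reference range [min_i, max_i] over the
    reference cells (optionally restricted to ``region``), the per-cell
    exceedance is (x - min_i)/(max_i - min_i) below the range,
    (max_i - x)/(max_i - min_i) above it, and 0 inside; NT1 is the sum of
    these non-positive terms, and cells with NT1 < 0 are non-analogous.
    """
    if set(reference.names) != set(projection.names):
        raise KeyError(
            f"variable mismatch: {sorted(reference.names)} vs {sorted(projection.names)}"
        )
    ref_mask = reference.joint_valid_mask()
    if region is not None:
        reference.spec.require_aligned(region.spec, "reference stack and region")
        ref_mask = ref_mask & region.inside
    proj_mask = projection.joint_valid_mask()
    nt1 = np.zeros(projection.spec.shape)
    for name in reference.names:
        ref_vals = reference[name].values[ref_mask]
        if ref_vals.size < 2:
            raise ValueError(f"variable {name!r}: fewer than 2 reference cells")
        lo, hi = float(ref_vals.min()), float(ref_vals.max())
        if hi <= lo:
            raise ValueError(f"variable {name!r} has zero range over the reference")
        x = projection[name].values
        span = hi - lo
        ud = np.where(x < lo, (x - lo) / span, np.where(x > hi, (hi - x) / span, 0.0))
        nt1 += np.where(proj_mask, ud, 0.0)
    vals = np.where(proj_mask, nt1, np.nan)
    layer = RasterLayer(projection.spec, "NT1", vals, proj_mask)
    return NoveltyMap(layer=layer, novel_mask=proj_mask & (nt1 < 0))
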