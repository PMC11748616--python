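"""Ensemble aggregation, omission thresholding, and change/stability maps.

Replicate predictions are summarized by their cell-wise median plus a
(max - min) range layer as the uncertainty estimate; future scenarios are
summarized a second time as the median across per-GCM medians, with the
GCM range as the scenario uncertainty. Continuous suitability is binarized
at the E-percent omission threshold — the largest order statistic of the
calibration-point suitabilities that still omits at most a fraction E of
them — and historical/future binary maps are compared cell by cell into
stable-absence / stable-presence / expansion / contraction categories with
area-change percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids import RasterLayer, RasterStack

__all__ = [
    "EnsembleSummary",
    "BinaryMap",
    "ClassifiedMap",
    "ChangeMap",
    "AreaStats",
    "summarize_members",
    "aggregate_gcms",
    "omission_threshold",
    "binarize",
    "classify_suitability",
    "change_categories",
    "area_change_stats",
]

SUITABILITY_CLASSES = ("unsuitable", "minimal", "low", "medium", "high")
CHANGE_CATEGORIES = ("stable_absence", "expansion", "contraction", "stable_presence")


@dataclass
class EnsembleSummary:
    """Cell-wise median and (max - min) range over ensemble members."""

    member_names: list[str]
    median_layer: RasterLayer
    range_layer: RasterLayer


@dataclass
class BinaryMap:
    """0/1 suitability map with the threshold that produced it."""

    layer: RasterLayer
    threshold_used: float
    E: float

    @property
    def suitable_mask(self) -> np.ndarray:
        return self.layer.valid_mask & (self.layer.values >= 0.5)

    @property
    def n_suitable(self) -> int:
        return int(self.suitable_mask.sum())


@dataclass
class ClassifiedMap:
    """Five-category suitability map (unsuitable + 4 graded classes).

    Category codes 0..4 follow :data:`SUITABILITY_CLASSES`.
    """

    layer: RasterLayer
    class_breaks: tuple[float, float, float]
    threshold: float

    def counts(self) -> dict[str, int]:
        v = self.layer.values[self.layer.valid_mask].astype(int)
        return {name: int((v == i).sum()) for i, name in enumerate(SUITABILITY_CLASSES)}


@dataclass
class ChangeMap:
    """Per-cell historical-vs-future comparison of binary suitability.

    Category codes 0..3 follow :data:`CHANGE_CATEGORIES`.
    """

    layer: RasterLayer
    counts: dict[str, int] = field(default_factory=dict)


@dataclass
class AreaStats:
    pct_increase: float
    pct_decrease: float
    denominator_mode: str
    latitude_weighted: bool


def summarize_members(stack: RasterStack) -> EnsembleSummary:
    """Cell-wise median and max-min range over members, valid where all are."""
    cube = stack.as_array()
    joint = stack.joint_valid_mask()
    med = np.full(stack.spec.shape, np.nan)
    rng = np.full(stack.spec.shape, np.nan)
    med[joint] = np.median(cube[:, joint], axis=0)
    rng[joint] = cube[:, joint].max(axis=0) - cube[:, joint].min(axis=0)
    return EnsembleSummary(
        member_names=stack.names,
        median_layer=RasterLayer(stack.spec, "median", med, joint),
        range_layer=RasterLayer(stack.spec, "range", rng, joint),
    )


def aggregate_gcms(per_gcm_medians: RasterStack) -> EnsembleSummary:
    """Median-of-medians across GCMs plus the GCM max-min uncertainty range."""
    return summarize_members(per_gcm_medians)


def omission_threshold(calibration_suitability, E: float = 0.05) -> float:
    """E-percent omission threshold over calibration-point suitabilities.

    Returns the (floor(E*n) + 1)-th smallest value: binarizing at it omits
    at most E*n calibration points (treated as potentially erroneous
    records), and it is the largest order statistic with that property.
    """
    vals = np.sort(np.asarray(calibration_suitability, dtype=float))
    if vals.size == 0:
        raise ValueError("no calibration suitability values")
    if not 0 <= E < 1:
        raise ValueError("E must lie in [0, 1)")
    k = int(np.floor(E * vals.size))
    return float(vals[k])


def binarize(suitability: RasterLayer, threshold: float, E: float = 0.05) -> BinaryMap:
    """Threshold a suitability layer: 1 iff value >= threshold; nodata kept."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    vals = np.where(
        suitability.valid_mask, (suitability.values >= threshold).astype(float), np.nan
    )
    return BinaryMap(
        layer=RasterLayer(suitability.spec, f"{suitability.name}_binary", vals,
                          suitability.valid_mask),
        threshold_used=float(threshold),
        E=E,
    )


def classify_suitability(
    suitability: RasterLayer, threshold: float, breaks_mode: str = "quartile"
) -> ClassifiedMap:
    """Split suprathreshold suitability into minimal/low/medium/high classes.

    Cells below the omission threshold are unsuitable; the rest are split
    at the quartiles of the suprathreshold value distribution (default) or
    into four equal-width intervals.
    """
    valid = suitability.valid_mask
    v = suitability.values
    above = valid & (v >= threshold)
    if not above.any():
        warnings.warn("no cells at or above threshold; classification is degenerate")
        vals = np.where(valid, 0.0, np.nan)
        return ClassifiedMap(
            RasterLayer(suitability.spec, f"{suitability.name}_classes", vals, valid),
            class_breaks=(threshold, threshold, threshold),
            threshold=threshold,
        )
    sup = v[above]
    if breaks_mode == "quartile":
        breaks = tuple(np.quantile(sup, [0.25, 0.5, 0.75]))
    elif breaks_mode == "equal_interval":
        lo, hi = sup.min(), sup.max()
        breaks = tuple(lo + (hi - lo) * q for q in (0.25, 0.5, 0.75))
    else:
        raise ValueError(f"unknown breaks_mode {breaks_mode!r}")
    if len(set(breaks)) < 3:
        warnings.warn("degenerate suprathreshold distribution; class breaks collapse")
    cat = np.zeros(suitability.spec.shape)
    # classes 1..4 over the suprathreshold cells
    cat[above] = 1.0 + np.searchsorted(np.asarray(breaks), sup, side="left").clip(0, 3)
    vals = np.where(valid, cat, np.nan)
    return ClassifiedMap(
        RasterLayer(suitability.spec, f"{suitability.name}_classes", vals, valid),
        class_breaks=breaks,
        threshold=threshold,
    )


def change_categories(historical: BinaryMap, future: BinaryMap) -> ChangeMap:
    """Cross historical and future binary maps into change categories.

    (0,0) stable_absence, (0,1) expansion, (1,0) contraction,
    (1,1) stable_presence; only jointly valid cells are categorized. The
    resulting counts always reconcile: expansion + stable_presence equals
    the future suitable count and contraction + stable_presence the
    historical one.
    """
    h, f = historical.layer, future.layer
    h.spec.require_aligned(f.spec, "historical and future binary maps")
    joint = h.valid_mask & f.valid_mask
    hs = h.values >= 0.5
    fs = f.values >= 0.5
    code = np.zeros(h.spec.shape)
    code[joint & ~hs & fs] = 1.0  # expansion
    code[joint & hs & ~fs] = 2.0  # contraction
    code[joint & hs & fs] = 3.0  # stable_presence
    vals = np.where(joint, code, np.nan)
    counts = {
        name: int((code[joint] == i).sum()) for i, name in enumerate(CHANGE_CATEGORIES)
    }
    assert counts["expansion"] + counts["stable_presence"] == int((fs & joint).sum())
    assert counts["contraction"] + counts["stable_presence"] == int((hs & joint).sum())
    return ChangeMap(
        layer=RasterLayer(h.spec, "change", vals, joint),
        counts=counts,
    )


def area_change_stats(
    change: ChangeMap,
    denominator_mode: str = "historical_suitable",
    latitude_weighted: bool = False,
) -> AreaStats:
    """Percent suitable-area increase (expansion) and decrease (contraction).

    The denominator is the historical suitable area by default, or all
    jointly valid cells. With ``latitude_weighted`` each cell counts as
    cos(latitude of its center), the geographic-grid area correction.
    """
    layer = change.layer
    joint = layer.valid_mask
    code = layer.values
    if latitude_weighted:
        w_row = np.cos(np.deg2rad(layer.spec.latitudes()))
        weights = np.broadcast_to(w_row[:, None], layer.spec.shape)
    else:
        weights = np.ones(layer.spec.shape)

    def wsum(mask):
        return float(weights[mask & joint].sum())

    w_exp = wsum(code == 1.0)
    w_con = wsum(code == 2.0)
    w_stp = wsum(code == 3.0)
    if denominator_mode == "historical_suitable":
        denom = w_con + w_stp
    elif denominator_mode == "all_valid":
        denom = float(weights[joint].sum())
    else:
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    if denom <= 0:
        raise ZeroDivisionError("zero-area denominator for percentage change")
    return AreaStats(
        pct_increase=100.0 * w_exp / denom,
        pct_decrease=100.0 * w_con / denom,
        denominator_mode=denominator_mode,
        latitude_weighted=latitude_weighted,
    )
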