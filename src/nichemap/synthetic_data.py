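"""Self-contained synthetic scenarios for exercising the whole pipeline.

A scenario plays the role of a real study's inputs: a set of smooth,
inter-correlated "climate" layers on a geographic grid, a known true
suitability surface, presence records sampled proportionally to that
truth inside an accessible area, and per-pseudo-GCM additive climate
shifts for future periods. Everything is a pure function of the scenario
parameters and a seed, so every pipeline stage is testable without
downloading climate or occurrence data.

Construction
------------
Latent environmental fields are white noise smoothed with a Gaussian
kernel (default sd 6 cells, giving realistically autocorrelated fields at
the default 120 x 160 grid); the first latent additionally carries a
north-south gradient, the synthetic analogue of the global temperature
gradient. Raw layers are linear mixtures of the latents plus small
independent smooth noise, then given heterogeneous offsets and scales to
mimic the mixed units of bioclimatic variables — so a standardized PCA
has genuine low-rank structure to find. The true suitability is a
logistic function with an interior optimum in the first latent, so a
positive climate shift on that latent moves the suitable belt poleward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import CELL_2P5_ARCMIN, GridSpec, RasterLayer, RasterStack, RegionMask
from .occurrences import OccurrenceSet

__all__ = [
    "SyntheticScenario",
    "make_climate_stack",
    "true_suitability",
    "sample_occurrences",
    "make_future_stacks",
]


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic study system.

    The defaults define the standard test conditions: a 120 x 160 grid of
    2.5-arcminute cells, 15 raw climate layers mixed from 4 latent fields,
    an accessible area covering the south-western part of the grid, and a
    warming-like positive shift on the first latent whose magnitude grows
    with SSP and period index.
    """

    n_rows: int = 120
    n_cols: int = 160
    cell_size: float = CELL_2P5_ARCMIN
    x_min: float = 110.0
    y_min: float = -25.0
    n_raw_layers: int = 15
    n_latents: int = 4
    smoothness: float = 6.0       # Gaussian kernel sd, in cells
    lat_gradient: float = 3.0     # amplitude of the N-S gradient on latent 1
    noise_scale: float = 0.02     # sd of per-layer independent smooth noise
    truth_intercept: float = 0.5  # a in logistic(a + sum b_k z_k + c z_1^2)
    truth_linear: tuple[float, ...] = (0.0, 1.0, 0.0, 0.0)
    truth_quadratic: float = -6.0
    region_row_frac: float = 0.85   # accessible area: southern rows ...
    region_col_frac: float = 0.60   # ... and western columns
    shift_mean: float = 1.2       # mean latent-1 shift of a pseudo-GCM at full scale
    shift_spread: float = 0.25    # between-GCM variation of the shift field
    # explicit (n_raw_layers x n_latents) mixing weights; None draws them from the seed
    mixing_matrix: tuple | None = None
    seed: int = 20240101

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            x_min=self.x_min,
            y_min=self.y_min,
            cell_size=self.cell_size,
        )

    @property
    def accessible_region(self) -> RegionMask:
        """Accessible area M: strictly smaller than the grid (rows from the
        south, columns from the west)."""
        inside = np.zeros((self.n_rows, self.n_cols), dtype=bool)
        r0 = int(round(self.n_rows * (1 - self.region_row_frac)))
        c1 = int(round(self.n_cols * self.region_col_frac))
        inside[r0:, :c1] = True
        return RegionMask(self.grid, inside)


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    return f / f.std()


def _latent_fields(scenario: SyntheticScenario) -> np.ndarray:
    """(n_latents, n_rows, n_cols) smooth unit-variance fields; latent 0
    carries the north-south gradient (larger values toward the south)."""
    rng = np.random.default_rng(scenario.seed)
    shape = (scenario.n_rows, scenario.n_cols)
    z = np.stack(
        [_smooth_field(rng, shape, scenario.smoothness) for _ in range(scenario.n_latents)]
    )
    # row 0 is north; lat_norm runs -1 (south) .. +1 (north)
    lat_norm = np.linspace(1.0, -1.0, scenario.n_rows)[:, None]
    z[0] = z[0] - scenario.lat_gradient * lat_norm
    return z


def _mixing(scenario: SyntheticScenario) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-scenario mixing matrix, per-layer offsets and scales."""
    rng = np.random.default_rng(scenario.seed + 1)
    if scenario.mixing_matrix is not None:
        W = np.asarray(scenario.mixing_matrix, dtype=float)
        if W.shape != (scenario.n_raw_layers, scenario.n_latents):
            raise ValueError(
                f"mixing_matrix must be {scenario.n_raw_layers} x {scenario.n_latents}"
            )
        rng.normal(size=W.shape)  # keep the offset/scale draws seed-stable
    else:
        W = rng.normal(size=(scenario.n_raw_layers, scenario.n_latents))
    # heterogeneous magnitudes, like degC vs mm layers
    scales = 10.0 ** rng.uniform(-0.5, 2.0, size=scenario.n_raw_layers)
    offsets = rng.uniform(-20.0, 200.0, size=scenario.n_raw_layers)
    return W, offsets, scales


def make_climate_stack(scenario: SyntheticScenario) -> RasterStack:
    """Historical climate: correlated smooth layers mixed from the latents."""
    z = _latent_fields(scenario)
    W, offsets, scales = _mixing(scenario)
    rng = np.random.default_rng(scenario.seed + 2)
    shape = (scenario.n_rows, scenario.n_cols)
    layers = []
    for l in range(scenario.n_raw_layers):
        vals = np.tensordot(W[l], z, axes=1)
        vals = vals + scenario.noise_scale * _smooth_field(rng, shape, scenario.smoothness)
        vals = offsets[l] + scales[l] * vals
        layers.append(RasterLayer(scenario.grid, f"clim{l + 1:02d}", vals))
    return RasterStack(layers)


def true_suitability(
    scenario: SyntheticScenario, latent_shift: np.ndarray | None = None
) -> RasterLayer:
    """The known truth s = logistic(a + sum_k b_k z_k + c z_1^2).

    ``latent_shift`` (n_latents, n_rows, n_cols), if given, is added to
    the latent fields first — the truth under a shifted climate.
    """
    z = _latent_fields(scenario)
    if latent_shift is not None:
        z = z + latent_shift
    b = np.asarray(scenario.truth_linear, float)
    if b.size != scenario.n_latents:
        raise ValueError("truth_linear length must equal n_latents")
    eta = (
        scenario.truth_intercept
        + np.tensordot(b, z, axes=1)
        + scenario.truth_quadratic * z[0] ** 2
    )
    s = 1.0 / (1.0 + np.exp(-eta))
    return RasterLayer(scenario.grid, "true_suitability", s)


def sample_occurrences(
    scenario: SyntheticScenario,
    n: int,
    restrict_to_region: bool = True,
    seed: int = 0,
) -> OccurrenceSet:
    """Presence records sampled proportionally to the true suitability.

    Cells are drawn with replacement with probability proportional to the
    truth (restricted to the accessible area by default); each drawn cell
    gets one point placed uniformly inside it, so repeated draws of a cell
    produce near-duplicate records for the thinning stage to remove.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    truth = true_suitability(scenario).values
    if restrict_to_region:
        usable = scenario.accessible_region.inside
    else:
        usable = np.ones_like(truth, dtype=bool)
    p = np.where(usable, truth, 0.0).ravel()
    total = p.sum()
    if total <= 0:
        raise ValueError("zero total suitability over the sampling region")
    rng = np.random.default_rng(seed)
    cells = rng.choice(p.size, size=n, replace=True, p=p / total)
    spec = scenario.grid
    rows, cols = np.divmod(cells, spec.n_cols)
    u = rng.uniform(size=n)
    v = rng.uniform(size=n)
    lon = spec.x_min + (cols + u) * spec.cell_size
    lat = spec.y_min + (spec.n_rows - rows - 1 + v) * spec.cell_size
    return OccurrenceSet(
        pd.DataFrame({"lon": lon, "lat": lat, "source": "synthetic"})
    )


def _gcm_latent_shift(scenario: SyntheticScenario, gcm_index: int) -> np.ndarray:
    """Full-scale latent shift field of one pseudo-GCM (latent 0 only):
    a smooth positive field differing between GCMs."""
    rng = np.random.default_rng(scenario.seed + 1000 + gcm_index)
    shape = (scenario.n_rows, scenario.n_cols)
    shift = np.zeros((scenario.n_latents,) + shape)
    shift[0] = scenario.shift_mean + scenario.shift_spread * _smooth_field(
        rng, shape, scenario.smoothness
    )
    return shift


def period_scale(period_index: int, n_periods: int) -> float:
    return (period_index + 1) / n_periods


def ssp_scale(ssp_index: int, n_ssps: int) -> float:
    return 0.4 + 0.6 * (ssp_index + 1) / n_ssps


def make_future_stacks(
    scenario: SyntheticScenario,
    n_gcms: int = 8,
    n_ssps: int = 4,
    n_periods: int = 4,
) -> dict[tuple[str, str, str], RasterStack]:
    """Future layer sets keyed by (gcm, ssp, period).

    future layer = historical + scale * (mixing @ latent shift of the GCM),
    with scale = period_scale * ssp_scale, so later periods and stronger
    SSPs move the climate further. Deterministic given the scenario seed.
    """
    hist = make_climate_stack(scenario)
    W, _, scales = _mixing(scenario)
    out: dict[tuple[str, str, str], RasterStack] = {}
    for g in range(n_gcms):
        shift = _gcm_latent_shift(scenario, g)
        # per-layer delta at full scale: scales_l * (W @ shift)_l
        delta = np.tensordot(W, shift, axes=1) * scales[:, None, None]
        for s in range(n_ssps):
            for p in range(n_periods):
                factor = period_scale(p, n_periods) * ssp_scale(s, n_ssps)
                layers = [
                    lyr.with_values(lyr.values + factor * delta[l])
                    for l, lyr in enumerate(hist.layers)
                ]
                key = (f"gcm{g + 1}", f"ssp{s + 1}", f"period{p + 1}")
                out[key] = RasterStack(layers)
    return out


def future_latent_shift(
    scenario: SyntheticScenario,
    gcm_index: int,
    ssp_index: int,
    period_index: int,
    n_ssps: int = 4,
    n_periods: int = 4,
) -> np.ndarray:
    """Latent shift applied in one (gcm, ssp, period) combination, for
    computing the true future suitability in tests."""
    factor = period_scale(period_index, n_periods) * ssp_scale(ssp_index, n_ssps)
    return factor * _gcm_latent_shift(scenario, gcm_index)
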