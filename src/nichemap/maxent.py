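"""Maximum-entropy presence-background suitability model.

The model estimates a Gibbs density over environmental space: among all
densities on the background sample whose feature expectations match the
presence sample, it picks the one of maximum entropy, i.e.

    p_lambda(x) = exp(lambda . f(x)) / Z_lambda,

fitted by maximizing the L1-penalized presence log-likelihood

    (1/m) sum_presences lambda . f(x_i) - log Z_lambda(background)
        - sum_j beta_j |lambda_j|,

a convex problem solved here by L-BFGS-B on the split positive/negative
parameterization (exact L1, smooth objective). Features follow the classic
MaxEnt families — linear, quadratic, pairwise product, and forward hinge —
each min-max scaled to [0, 1] on the training sample; the per-feature
penalty is beta_j = multiplier(class) * std_j(presences) / sqrt(m).

The "logistic" output rescales the raw density by e^H (H the entropy of
the fitted density over the background) so a typical presence scores near
0.5. Predictions outside the training range of any variable are masked out
by default (extrapolation off) or truncated to the range (clamping), the
two options classic MaxEnt exposes for non-analogous environments.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .grids import RasterLayer, RasterStack, RegionMask
from .occurrences import OccurrenceSet

__all__ = [
    "FeatureSpec",
    "FeatureExpander",
    "MaxEntModel",
    "ReplicateSet",
    "ConfigurationError",
    "ConvergenceError",
    "default_feature_classes",
    "sample_background",
    "fit_maxent",
    "predict_suitability",
    "run_replicates",
]

_FEATURE_CLASSES = ("linear", "quadratic", "product", "hinge")

DEFAULT_REG_MULTIPLIERS = {
    "linear": 1.0,
    "quadratic": 1.0,
    "product": 1.0,
    "hinge": 0.5,
}


class ConfigurationError(ValueError):
    """Mutually exclusive or invalid model options."""


class ConvergenceError(RuntimeError):
    """The convex solver hit its iteration limit before the gradient tolerance."""


def default_feature_classes(n_presences: int) -> tuple[str, ...]:
    """Feature classes as a function of calibration sample size.

    Mirrors the classic MaxEnt 3.3.3 schedule: tiny samples get linear
    features only; hinge enters at 15 presences and products at 80.
    """
    if n_presences < 10:
        return ("linear",)
    if n_presences < 15:
        return ("linear", "quadratic")
    if n_presences < 80:
        return ("linear", "quadratic", "hinge")
    return ("linear", "quadratic", "product", "hinge")


@dataclass(frozen=True)
class FeatureSpec:
    """Which feature families to expand and how hard to penalize each.

    hinge_knots: knots per variable, placed at training-value deciles.
    reg_multipliers: per-class multiplier on the default penalty scale.
    """

    classes: tuple[str, ...] = ("linear", "quadratic", "product", "hinge")
    hinge_knots: int = 10
    reg_multipliers: tuple[tuple[str, float], ...] = tuple(
        sorted(DEFAULT_REG_MULTIPLIERS.items())
    )

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("at least one feature class is required")
        unknown = set(self.classes) - set(_FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")
        if "hinge" in self.classes and self.hinge_knots < 2:
            raise ValueError("hinge features need at least 2 knots")
        for _, v in self.reg_multipliers:
            if v < 0:
                raise ValueError("regularization multipliers must be non-negative")

    def multiplier(self, cls: str) -> float:
        return dict(self.reg_multipliers)[cls]


class FeatureExpander:
    """Expands raw predictor values into scaled MaxEnt features.

    fit() records per-variable training ranges, hinge knots (deciles of
    the training values) and per-feature min/max so that every expanded
    feature lies in [0, 1] for inputs within the training range.
    """

    def __init__(self, spec: FeatureSpec):
        self.spec = spec

    def fit(self, X: np.ndarray) -> "FeatureExpander":
        X = np.asarray(X, dtype=float)
        p = X.shape[1]
        self.n_variables_ = p
        self.mins_ = X.min(axis=0)
        self.maxs_ = X.max(axis=0)
        if np.any(self.maxs_ <= self.mins_):
            bad = np.flatnonzero(self.maxs_ <= self.mins_)
            raise ValueError(f"constant predictor column(s) {bad.tolist()}")
        self.hinge_knots_: list[tuple[int, float]] = []
        if "hinge" in self.spec.classes:
            k = self.spec.hinge_knots
            qs = np.arange(k) / k
            for v in range(p):
                knots = np.unique(np.quantile(X[:, v], qs))
                for t in knots:
                    if self.maxs_[v] - t > 1e-12:
                        self.hinge_knots_.append((v, float(t)))
        raw = self._raw_scalable(X)
        self._raw_min = raw.min(axis=0) if raw.shape[1] else np.zeros(0)
        self._raw_max = raw.max(axis=0) if raw.shape[1] else np.zeros(0)
        span = self._raw_max - self._raw_min
        self._raw_span = np.where(span > 0, span, 1.0)
        self.feature_classes_ = np.array(self._class_labels())
        self.n_features_ = len(self.feature_classes_)
        return self

    def _raw_scalable(self, X: np.ndarray) -> np.ndarray:
        """Linear/quadratic/product raw features (hinge is scaled separately)."""
        cols = []
        if "linear" in self.spec.classes:
            cols.append(X)
        if "quadratic" in self.spec.classes:
            cols.append(X**2)
        if "product" in self.spec.classes:
            p = X.shape[1]
            prods = [X[:, i] * X[:, j] for i in range(p) for j in range(i + 1, p)]
            if prods:
                cols.append(np.column_stack(prods))
        if not cols:
            return np.empty((X.shape[0], 0))
        return np.column_stack(cols)

    def _class_labels(self) -> list[str]:
        p = self.n_variables_
        labels: list[str] = []
        if "linear" in self.spec.classes:
            labels += ["linear"] * p
        if "quadratic" in self.spec.classes:
            labels += ["quadratic"] * p
        if "product" in self.spec.classes:
            labels += ["product"] * (p * (p - 1) // 2)
        labels += ["hinge"] * len(getattr(self, "hinge_knots_", []))
        return labels

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        raw = self._raw_scalable(X)
        scaled = (raw - self._raw_min) / self._raw_span
        parts = [scaled] if scaled.shape[1] else []
        if self.hinge_knots_:
            hcols = np.empty((X.shape[0], len(self.hinge_knots_)))
            for c, (v, t) in enumerate(self.hinge_knots_):
                hcols[:, c] = np.maximum(0.0, X[:, v] - t) / (self.maxs_[v] - t)
            parts.append(hcols)
        if not parts:
            return np.empty((X.shape[0], 0))
        return np.column_stack(parts)

    def to_dict(self) -> dict:
        return {
            "spec": {
                "classes": list(self.spec.classes),
                "hinge_knots": self.spec.hinge_knots,
                "reg_multipliers": dict(self.spec.reg_multipliers),
            },
            "n_variables": self.n_variables_,
            "mins": self.mins_.tolist(),
            "maxs": self.maxs_.tolist(),
            "hinge_knot_list": [[v, t] for v, t in self.hinge_knots_],
            "raw_min": self._raw_min.tolist(),
            "raw_max": self._raw_max.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureExpander":
        spec = FeatureSpec(
            classes=tuple(d["spec"]["classes"]),
            hinge_knots=d["spec"]["hinge_knots"],
            reg_multipliers=tuple(sorted(d["spec"]["reg_multipliers"].items())),
        )
        obj = cls(spec)
        obj.n_variables_ = d["n_variables"]
        obj.mins_ = np.asarray(d["mins"], float)
        obj.maxs_ = np.asarray(d["maxs"], float)
        obj.hinge_knots_ = [(int(v), float(t)) for v, t in d["hinge_knot_list"]]
        obj._raw_min = np.asarray(d["raw_min"], float)
        obj._raw_max = np.asarray(d["raw_max"], float)
        span = obj._raw_max - obj._raw_min
        obj._raw_span = np.where(span > 0, span, 1.0)
        obj.feature_classes_ = np.array(obj._class_labels())
        obj.n_features_ = len(obj.feature_classes_)
        return obj


class MaxEntModel(BaseEstimator):
    """L1-regularized maximum-entropy presence-background estimator.

    scikit-learn style: ``fit(X, y)`` with y = 1 for presence rows and
    y = 0 for background rows (raw predictor values, e.g. principal-
    component scores); ``predict(X)`` returns logistic-scale suitability.

    Parameters
    ----------
    feature_classes : tuple of str or None
        None selects the sample-size-based default schedule.
    hinge_knots : int
        Knots per variable for hinge features.
    reg_multipliers : mapping or None
        Per-class penalty multipliers (default linear/quadratic/product 1.0,
        hinge 0.5).
    beta_multiplier : float
        Global scale on all penalties.
    output : {'logistic', 'raw'}
        Default prediction scale.
    tol : float
        Projected-gradient tolerance of the solver.
    max_iter : int
        Solver iteration cap; exceeding it raises :class:`ConvergenceError`.

    Attributes
    ----------
    coef_ : per-expanded-feature coefficients (lambda).
    entropy_ : entropy H of the fitted density over the normalization sample.
    feature_mins_, feature_maxs_ : training range per raw predictor.
    expander_ : fitted :class:`FeatureExpander`.
    """

    def __init__(
        self,
        feature_classes: tuple[str, ...] | None = None,
        hinge_knots: int = 10,
        reg_multipliers: dict | None = None,
        beta_multiplier: float = 1.0,
        output: str = "logistic",
        tol: float = 1e-5,
        max_iter: int = 1000,
    ):
        self.feature_classes = feature_classes
        self.hinge_knots = hinge_knots
        self.reg_multipliers = reg_multipliers
        self.beta_multiplier = beta_multiplier
        self.output = output
        self.tol = tol
        self.max_iter = max_iter

    def _resolved_spec(self, m: int) -> FeatureSpec:
        classes = (
            tuple(self.feature_classes)
            if self.feature_classes is not None
            else default_feature_classes(m)
        )
        mult = dict(DEFAULT_REG_MULTIPLIERS)
        if self.reg_multipliers:
            mult.update(self.reg_multipliers)
        return FeatureSpec(
            classes=classes,
            hinge_knots=self.hinge_knots,
            reg_multipliers=tuple(sorted(mult.items())),
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        pres = X[y == 1]
        m = pres.shape[0]
        if m < 2:
            raise ValueError("need at least 2 presence rows")
        if (y == 0).sum() < 1:
            raise ValueError("need at least 1 background row")
        spec = self._resolved_spec(m)
        expander = FeatureExpander(spec).fit(X)
        # normalization sample = background with presences appended, i.e. all rows
        F_norm = expander.transform(X)
        F_pres = F_norm[y == 1]
        mean_pres = F_pres.mean(axis=0)
        class_mult = np.array([spec.multiplier(c) for c in expander.feature_classes_])
        beta = (
            self.beta_multiplier
            * class_mult
            * np.maximum(F_pres.std(axis=0), 1e-4)
            / np.sqrt(m)
        )
        coef, grad_norm, converged = _solve_l1_maxent(
            F_norm, mean_pres, beta, tol=self.tol, max_iter=self.max_iter
        )
        if not converged:
            raise ConvergenceError(
                f"solver stopped before tolerance (projected gradient norm {grad_norm:.3g})"
            )
        self.expander_ = expander
        self.feature_spec_ = spec
        self.coef_ = coef
        self.feature_mins_ = expander.mins_.copy()
        self.feature_maxs_ = expander.maxs_.copy()
        scores = F_norm @ coef
        self.log_z_ = float(logsumexp(scores))
        logp = scores - self.log_z_
        self.entropy_ = float(-np.sum(np.exp(logp) * logp))
        self.n_presences_ = int(m)
        self.n_background_ = int((y == 0).sum())
        return self

    def predict_raw(self, X, clamp: bool = False) -> np.ndarray:
        """Raw Gibbs density normalized over the training sample."""
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if clamp:
            X = np.clip(X, self.feature_mins_, self.feature_maxs_)
        F = self.expander_.transform(X)
        return np.exp(F @ self.coef_ - self.log_z_)

    def predict(self, X, output: str | None = None, clamp: bool = False) -> np.ndarray:
        """Suitability on the requested output scale ('logistic' or 'raw')."""
        output = output or self.output
        raw = self.predict_raw(X, clamp=clamp)
        if output == "raw":
            return raw
        if output == "logistic":
            s = np.exp(self.entropy_) * raw
            return s / (1.0 + s)
        raise ConfigurationError(f"unknown output mode {output!r}")

    def out_of_range(self, X) -> np.ndarray:
        """True where any predictor falls outside its training range."""
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return ((X < self.feature_mins_) | (X > self.feature_maxs_)).any(axis=1)

    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "expander": self.expander_.to_dict(),
            "coef": self.coef_.tolist(),
            "log_z": self.log_z_,
            "entropy": self.entropy_,
            "n_presences": self.n_presences_,
            "n_background": self.n_background_,
            "output": self.output,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "MaxEntModel":
        obj = cls(output=d.get("output", "logistic"))
        obj.expander_ = FeatureExpander.from_dict(d["expander"])
        obj.feature_spec_ = obj.expander_.spec
        obj.coef_ = np.asarray(d["coef"], float)
        obj.log_z_ = float(d["log_z"])
        obj.entropy_ = float(d["entropy"])
        obj.feature_mins_ = obj.expander_.mins_.copy()
        obj.feature_maxs_ = obj.expander_.maxs_.copy()
        obj.n_presences_ = d["n_presences"]
        obj.n_background_ = d["n_background"]
        return obj

    @classmethod
    def from_json(cls, path: str) -> "MaxEntModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _solve_l1_maxent(F, mean_pres, beta, tol=1e-5, max_iter=500):
    """Minimize -mean_pres.lam + logsumexp(F lam) + beta.|lam| exactly.

    Split lam = a - b with a, b >= 0 so the L1 term is linear and the
    problem is a smooth bound-constrained convex program.
    """
    n, J = F.shape

    def obj(theta):
        a, b = theta[:J], theta[J:]
        lam = a - b
        scores = F @ lam
        lz = logsumexp(scores)
        p = np.exp(scores - lz)
        e_f = p @ F
        val = -mean_pres @ lam + lz + beta @ (a + b)
        g = e_f - mean_pres
        grad = np.concatenate([g + beta, -g + beta])
        return val, grad

    theta0 = np.zeros(2 * J)
    res = minimize(
        obj,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0, None)] * (2 * J),
        options={"maxiter": max_iter, "maxfun": 20 * max_iter, "gtol": tol,
                 "ftol": 1e-14},
    )
    lam = res.x[:J] - res.x[J:]
    lam[np.abs(lam) < 1e-12] = 0.0
    # projected gradient norm at the solution
    val, grad = obj(res.x)
    pg = grad.copy()
    at_bound = (res.x <= 0) & (grad > 0)
    pg[at_bound] = 0.0
    grad_norm = float(np.max(np.abs(pg)))
    converged = res.status == 0 or grad_norm <= 10 * tol
    return lam, grad_norm, converged


# ---------------------------------------------------------------------------
# raster-level wrappers
# ---------------------------------------------------------------------------

@dataclass
class ReplicateSet:
    """Bootstrap replicate predictions and their cell-wise median."""

    predictions: RasterStack
    seeds: list[int]
    median_layer: RasterLayer
    models: list[MaxEntModel] = field(default_factory=list)
    background_cells: np.ndarray | None = None
    presence_cells: np.ndarray | None = None
    bootstrap_samples: list[np.ndarray] = field(default_factory=list)
    n_dropped_presences: int = 0


def sample_background(
    region: RegionMask,
    n: int = 10000,
    seed: int = 0,
    valid_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Uniform background cell sample (flat raveled indices) within a region.

    Samples without replacement; if the region holds fewer than ``n``
    usable cells, all of them are returned. Reproducible given ``seed``.
    """
    usable = region.inside
    if valid_mask is not None:
        usable = usable & valid_mask
    pool = np.flatnonzero(usable)
    if pool.size == 0:
        raise ValueError("no usable background cells in region")
    if pool.size <= n:
        return pool.copy()
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(pool, size=n, replace=False))


def _extract(pc_stack: RasterStack, cells: np.ndarray) -> np.ndarray:
    cube = pc_stack.as_array().reshape(len(pc_stack), -1)
    return cube[:, cells].T


def fit_maxent(
    presence_cells: np.ndarray,
    background: np.ndarray,
    pc_stack: RasterStack,
    spec: FeatureSpec | None = None,
    beta_multiplier: float = 1.0,
) -> MaxEntModel:
    """Fit the maximum-entropy model from presence and background cell indices."""
    presence_cells = np.asarray(presence_cells)
    if np.unique(presence_cells).size < 2:
        raise ValueError("need at least 2 distinct presence cells")
    X = np.vstack([_extract(pc_stack, background), _extract(pc_stack, presence_cells)])
    y = np.concatenate([np.zeros(len(background)), np.ones(len(presence_cells))])
    model = MaxEntModel(
        feature_classes=spec.classes if spec else None,
        hinge_knots=spec.hinge_knots if spec else 10,
        reg_multipliers=dict(spec.reg_multipliers) if spec else None,
        beta_multiplier=beta_multiplier,
    )
    return model.fit(X, y)


def predict_suitability(
    model: MaxEntModel,
    pc_stack: RasterStack,
    clamp: bool = False,
    extrapolate: bool = False,
    output: str | None = None,
    name: str = "suitability",
) -> RasterLayer:
    """Predict suitability over a stack, honoring the extrapolation policy.

    With both flags off (the default, matching deactivated clamping and
    extrapolation), cells where any predictor leaves the training range
    become nodata. ``clamp=True`` instead truncates values to the range;
    the two options are mutually exclusive.
    """
    if clamp and extrapolate:
        raise ConfigurationError("clamp and extrapolate are mutually exclusive")
    mask = pc_stack.joint_valid_mask()
    X, idx = pc_stack.table()
    if clamp:
        preds = model.predict(X, output=output, clamp=True)
    elif extrapolate:
        preds = model.predict(X, output=output)
    else:
        oor = model.out_of_range(X)
        preds = np.full(X.shape[0], np.nan)
        if (~oor).any():
            preds[~oor] = model.predict(X[~oor], output=output)
        new_mask = mask.copy()
        new_mask.ravel()[idx[oor]] = False
        mask = new_mask
    vals = np.full(pc_stack.spec.shape, np.nan)
    vals.ravel()[idx] = preds
    return RasterLayer(pc_stack.spec, name, vals, mask)


def occurrences_to_cells(
    occ: OccurrenceSet, pc_stack: RasterStack, region: RegionMask | None = None
) -> tuple[np.ndarray, int]:
    """Map occurrence records to distinct valid cell indices.

    Returns (flat cell indices, number of records dropped for lying
    outside the region or on invalid cells).
    """
    spec = pc_stack.spec
    inside = spec.contains(occ.lon, occ.lat)
    row, col = spec.cell_of(occ.lon[inside], occ.lat[inside])
    flat = row * spec.n_cols + col
    usable = pc_stack.joint_valid_mask().ravel()
    if region is not None:
        spec.require_aligned(region.spec, "occurrence grid and region")
        usable = usable & region.inside.ravel()
    keep = usable[flat]
    cells = np.unique(flat[keep])
    n_dropped = len(occ) - int(keep.sum())
    return cells, n_dropped


def run_replicates(
    presences: OccurrenceSet,
    region: RegionMask,
    pc_stack: RasterStack,
    spec: FeatureSpec | None = None,
    n_replicates: int = 10,
    seed: int = 0,
    background_n: int = 10000,
    output: str = "logistic",
) -> ReplicateSet:
    """Bootstrap the presence sample, refit, and predict per replicate.

    Each replicate resamples the presence cells with replacement (same
    size), refits the model against a shared background sample, and
    predicts over the stack; the replicate median is the cell-wise median
    where all replicates are valid. Fully reproducible given ``seed``.
    """
    cells, n_dropped = occurrences_to_cells(presences, pc_stack, region)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} presence record(s) outside the accessible area or on "
            "nodata cells were ignored for calibration"
        )
    if cells.size < 2:
        raise ValueError("fewer than 2 usable presence cells in the region")
    background = sample_background(
        region, n=background_n, seed=seed, valid_mask=pc_stack.joint_valid_mask()
    )
    master = np.random.default_rng(seed)
    rep_seeds = [int(s) for s in master.integers(0, 2**31 - 1, size=n_replicates)]
    layers, models, boots = [], [], []
    for r, rs in enumerate(rep_seeds):
        rng = np.random.default_rng(rs)
        boot = rng.choice(cells, size=cells.size, replace=True)
        boots.append(boot)
        try:
            model = fit_maxent(boot, background, pc_stack, spec=spec)
        except (ValueError, ConvergenceError) as exc:
            raise type(exc)(f"replicate {r}: {exc}") from exc
        layer = predict_suitability(
            model, pc_stack, output=output, name=f"replicate_{r}"
        )
        layers.append(layer)
        models.append(model)
    stack = RasterStack(layers)
    cube = stack.as_array()
    joint = stack.joint_valid_mask()
    med = np.full(stack.spec.shape, np.nan)
    med[joint] = np.median(cube[:, joint], axis=0)
    median_layer = RasterLayer(stack.spec, "median_suitability", med, joint)
    return ReplicateSet(
        predictions=stack,
        seeds=rep_seeds,
        median_layer=median_layer,
        models=models,
        background_cells=background,
        presence_cells=cells,
        bootstrap_samples=boots,
        n_dropped_presences=n_dropped,
    )
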