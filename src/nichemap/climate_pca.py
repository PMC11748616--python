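"""Principal-component transform of bioclimatic layers, frozen for transfer.

Bioclimatic predictor sets are strongly inter-correlated; the pipeline
replaces them with principal components fitted once on *historical* climate
and then applies the identical frozen transform (same means, scales,
loadings) to every future layer set. Layers with known spatial artifacts
(bio8, bio9, bio18, bio19 in the standard 19-variable set) are dropped
before fitting. Variables are standardized before the eigen-decomposition
because the inputs mix units (degrees C vs mm); an unscaled PCA would be
dominated by precipitation magnitudes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .grids import RasterLayer, RasterStack, RegionMask

__all__ = [
    "ClimatePCA",
    "DegenerateVariableError",
    "drop_artifact_layers",
    "fit_pca",
    "project_pca",
    "select_components",
]

#: Bioclim layers excluded for known spatial artifacts.
DEFAULT_ARTIFACT_LAYERS = frozenset({"bio8", "bio9", "bio18", "bio19"})


class DegenerateVariableError(ValueError):
    """A variable has zero variance over the fit region."""


class ClimatePCA(TransformerMixin, BaseEstimator):
    """Standardized PCA with a deterministic sign convention.

    scikit-learn style transformer: :meth:`fit` learns per-variable means
    and standard deviations plus orthonormal loadings on standardized data;
    :meth:`transform` applies the frozen transform without refitting, which
    is what makes historical-to-future transfer well defined.

    Parameters
    ----------
    n_components : int or None
        Components to keep (default: all).
    standardize : bool
        Divide by per-variable standard deviation after centering.

    Attributes
    ----------
    variable_names_ : list of str
    means_, scales_ : ndarray (n_variables,)
    loadings_ : ndarray (n_components, n_variables), orthonormal rows,
        each row signed so its largest-magnitude entry is positive.
    explained_variance_ratio_ : ndarray (n_components,)
    fit_region_ : str, description of the cells used.
    """

    def __init__(self, n_components: int | None = None, standardize: bool = True):
        self.n_components = n_components
        self.standardize = standardize

    def fit(self, X, y=None, variable_names=None, fit_region: str = "unspecified"):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x variables)")
        n, p = X.shape
        if p < 2:
            raise ValueError("PCA needs at least 2 variables")
        if n < p:
            raise ValueError(f"need at least {p} samples for {p} variables, got {n}")
        names = list(variable_names) if variable_names is not None else [
            f"x{i}" for i in range(p)
        ]
        means = X.mean(axis=0)
        stds = X.std(axis=0, ddof=1)
        zero = stds <= 0
        if zero.any():
            bad = [names[i] for i in np.flatnonzero(zero)]
            raise DegenerateVariableError(f"zero-variance variable(s): {bad}")
        scales = stds if self.standardize else np.ones(p)
        Z = (X - means) / scales
        pca = PCA(n_components=self.n_components, svd_solver="full")
        pca.fit(Z)
        loadings = pca.components_.copy()
        # sign convention: the largest-magnitude loading of each component positive
        for k in range(loadings.shape[0]):
            j = np.argmax(np.abs(loadings[k]))
            if loadings[k, j] < 0:
                loadings[k] = -loadings[k]
        self.variable_names_ = names
        self.means_ = means
        self.scales_ = scales
        self.loadings_ = loadings
        self.explained_variance_ratio_ = pca.explained_variance_ratio_.copy()
        self.fit_region_ = fit_region
        return self

    def transform(self, X, variable_names=None):
        """Project samples onto the frozen components.

        If ``variable_names`` is given, columns of X are matched to the
        training variables by name (order-insensitive); unknown or missing
        names raise KeyError.
        """
        check_is_fitted(self, "loadings_")
        X = np.asarray(X, dtype=float)
        if variable_names is not None:
            names = list(variable_names)
            missing = [v for v in self.variable_names_ if v not in names]
            if missing:
                raise KeyError(f"projection stack missing variable(s) {missing}")
            order = [names.index(v) for v in self.variable_names_]
            X = X[:, order]
        if X.shape[1] != len(self.variable_names_):
            raise ValueError("variable count mismatch")
        Z = (X - self.means_) / self.scales_
        return Z @ self.loadings_.T

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "loadings_")
        return {
            "variable_names": self.variable_names_,
            "means": self.means_.tolist(),
            "scales": self.scales_.tolist(),
            "loadings": self.loadings_.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio_.tolist(),
            "fit_region": self.fit_region_,
            "standardize": self.standardize,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "ClimatePCA":
        obj = cls(standardize=d.get("standardize", True))
        obj.variable_names_ = list(d["variable_names"])
        obj.means_ = np.asarray(d["means"], float)
        obj.scales_ = np.asarray(d["scales"], float)
        obj.loadings_ = np.asarray(d["loadings"], float)
        obj.explained_variance_ratio_ = np.asarray(d["explained_variance_ratio"], float)
        obj.fit_region_ = d.get("fit_region", "unspecified")
        return obj

    @classmethod
    def from_json(cls, path: str) -> "ClimatePCA":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


#: Alias: a fitted ClimatePCA is the frozen transform object shared between
#: historical fitting and future projection.
PCATransform = ClimatePCA


def drop_artifact_layers(
    stack: RasterStack, drop_names=DEFAULT_ARTIFACT_LAYERS
) -> RasterStack:
    """Remove artifact-prone layers by name, preserving order."""
    drop = set(drop_names)
    unknown = drop - set(stack.names)
    if unknown:
        raise KeyError(f"drop_names not in stack: {sorted(unknown)}")
    kept = [lyr for lyr in stack.layers if lyr.name not in drop]
    if not kept:
        raise ValueError("dropping all layers leaves an empty stack")
    return RasterStack(kept)


def fit_pca(
    stack: RasterStack,
    region: RegionMask | None = None,
    n_components: int | None = None,
    standardize: bool = True,
) -> ClimatePCA:
    """Fit the frozen PCA transform on a climate stack.

    By default the fit uses cells inside the accessible area ``region``
    (the model's calibration domain); pass ``region=None`` to fit on all
    jointly valid cells.
    """
    if region is not None:
        stack.spec.require_aligned(region.spec, "PCA stack and region")
        mask = region.inside
        region_desc = f"region mask ({region.n_inside} cells)"
    else:
        mask = None
        region_desc = "all valid cells"
    X, _ = stack.table(mask)
    est = ClimatePCA(n_components=n_components, standardize=standardize)
    est.fit(X, variable_names=stack.names, fit_region=region_desc)
    return est


def project_pca(stack: RasterStack, transform: ClimatePCA) -> RasterStack:
    """Apply a frozen transform to a (historical or future) stack.

    Variables are matched by name; the output stack has one layer per
    component, named PC1..PCk, valid on the joint input mask. The transform
    is never refit here.
    """
    X, idx = stack.table()
    scores = transform.transform(X, variable_names=stack.names)
    mask = stack.joint_valid_mask()
    spec = stack.spec
    layers = []
    for k in range(scores.shape[1]):
        vals = np.full(spec.shape, np.nan)
        vals.ravel()[idx] = scores[:, k]
        layers.append(RasterLayer(spec, f"PC{k + 1}", vals, mask))
    return RasterStack(layers)


def select_components(transform: ClimatePCA, cum_threshold: float = 0.999) -> int:
    """Smallest k whose cumulative explained variance reaches the threshold.

    The default 99.9% threshold mirrors retaining the leading components
    that carry essentially all climatic variance. If the threshold is
    unreachable, all components are returned with a warning.
    """
    if not 0 < cum_threshold <= 1:
        raise ValueError("cum_threshold must lie in (0, 1]")
    cum = np.cumsum(transform.explained_variance_ratio_)
    hit = np.flatnonzero(cum >= cum_threshold - 1e-12)
    if hit.size == 0:
        warnings.warn(
            f"cumulative explained variance {cum[-1]:.6f} never reaches "
            f"{cum_threshold}; keeping all {cum.size} components"
        )
        return int(cum.size)
    return int(hit[0] + 1)
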