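"""Orchestration: historical run, future ensemble, evaluation, reporting.

A single declarative :class:`RunConfig` (YAML-loadable) drives the whole
pipeline: occurrence cleaning/thinning/splitting, PCA fit inside the
accessible area and frozen transfer, bootstrap MaxEnt replicates, median
aggregation, E-percent omission thresholding, evaluation statistics, and
the GCM x SSP x period future ensemble with change maps and an area-
statistics table. Every stochastic stage draws its seed deterministically
from one master seed, and a JSON manifest records config, seeds, per-stage
output hashes and timings so identical configs reproduce identical
outputs.

Inputs come either from files (occurrence CSV, climate rasters, GeoJSON
accessible-area polygon) or from the built-in synthetic scenario, which
generates the same objects in memory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .climate_pca import ClimatePCA, drop_artifact_layers, fit_pca, project_pca, select_components
from .evaluation import (
    BinomialTestResult,
    NoveltyMap,
    PartialROCResult,
    binomial_omission_test,
    exdet_nt1,
    partial_roc,
)
from .grids import (
    RasterLayer,
    RasterStack,
    RegionMask,
    load_geojson_geometry,
    rasterize_region,
    read_raster,
    write_raster,
)
from .maxent import FeatureSpec, ReplicateSet, predict_suitability, run_replicates
from .occurrences import (
    OccurrenceSet,
    SplitResult,
    clean_records,
    load_occurrences,
    partition_records,
    thin_to_grid,
)
from .suitability_maps import (
    AreaStats,
    BinaryMap,
    ChangeMap,
    ClassifiedMap,
    EnsembleSummary,
    aggregate_gcms,
    area_change_stats,
    binarize,
    change_categories,
    classify_suitability,
    omission_threshold,
    summarize_members,
)
from .synthetic_data import (
    SyntheticScenario,
    make_climate_stack,
    make_future_stacks,
    sample_occurrences,
)

__all__ = [
    "RunConfig",
    "RunManifest",
    "HistoricalArtifacts",
    "FutureArtifacts",
    "MissingCombinationError",
    "plan_combinations",
    "run_historical",
    "run_future_ensemble",
]


class MissingCombinationError(ValueError):
    """The declared GCM x SSP x period grid of future layers has gaps."""


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run.

    mode 'synthetic' generates inputs from the built-in scenario;
    mode 'files' reads occurrence CSV, climate rasters, and an accessible-
    area polygon from the given paths.
    """

    mode: str = "synthetic"
    outdir: str = "nichemap_run"
    seed: int = 1

    # synthetic-mode inputs
    scenario: dict = field(default_factory=dict)
    n_occurrences: int = 600
    n_gcms: int = 2
    n_ssps: int = 2
    n_periods: int = 2

    # file-mode inputs
    occurrences_path: str | None = None
    lon_col: str = "longitude"
    lat_col: str = "latitude"
    historical_layers: list = field(default_factory=list)
    m_polygon_path: str | None = None
    # mapping gcm -> ssp -> period -> list of layer paths
    future_layers: dict = field(default_factory=dict)

    # parameters
    drop_names: list = field(default_factory=list)
    cum_threshold: float = 0.999
    E: float = 0.05
    n_replicates: int = 10
    background_n: int = 10000
    feature_classes: list | None = None
    hinge_knots: int = 10
    reg_multipliers: dict | None = None
    beta_multiplier: float = 1.0
    pca_fit_on_region: bool = True
    pca_standardize: bool = True
    proc_iterations: int = 1000
    proc_resample_fraction: float = 0.5
    breaks_mode: str = "quartile"
    denominator_mode: str = "historical_suitable"
    latitude_weighted: bool = False
    write_outputs: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def build_scenario(self) -> SyntheticScenario:
        return SyntheticScenario(**{"seed": self.seed, **self.scenario})

    def stage_seeds(self) -> dict[str, int]:
        """Deterministic per-stage seeds expanded from the master seed."""
        ss = np.random.SeedSequence(self.seed)
        state = ss.generate_state(6) % (2**31 - 1)
        names = ["occurrences", "partition", "background", "replicates", "proc", "spare"]
        return {k: int(v) for k, v in zip(names, state)}


@dataclass
class RunManifest:
    """Reproducibility record of one run."""

    config: dict
    version: str = __version__
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, seconds: float, hashes: dict, **extra) -> None:
        self.stages[stage] = {"seconds": round(seconds, 3), "hashes": hashes, **extra}

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "version": self.version,
                       "stages": self.stages}, fh, indent=1, default=str)


def _hash_array(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def _hash_layer(layer: RasterLayer) -> str:
    return _hash_array(layer.values[layer.valid_mask], layer.valid_mask)


@dataclass
class HistoricalArtifacts:
    stack: RasterStack
    region: RegionMask
    split: SplitResult
    transform: ClimatePCA
    n_components: int
    pc_stack: RasterStack
    replicates: ReplicateSet
    summary: EnsembleSummary
    threshold: float
    binary: BinaryMap
    classified: ClassifiedMap
    proc: PartialROCResult
    binomial: BinomialTestResult
    novelty: NoveltyMap
    manifest: RunManifest


@dataclass
class FutureArtifacts:
    per_scenario: dict
    area_table: pd.DataFrame
    manifest: RunManifest


def plan_combinations(config: RunConfig) -> list[tuple[str, str, str]]:
    """All (gcm, ssp, period) projection tasks in stable (ssp, period, gcm) order.

    In file mode the declared grid must be complete; gaps raise
    :class:`MissingCombinationError` listing every missing combination.
    """
    if config.mode == "synthetic":
        gcms = [f"gcm{i + 1}" for i in range(config.n_gcms)]
        ssps = [f"ssp{i + 1}" for i in range(config.n_ssps)]
        periods = [f"period{i + 1}" for i in range(config.n_periods)]
    else:
        gcms = sorted(config.future_layers)
        ssps = sorted({s for g in config.future_layers.values() for s in g})
        periods = sorted(
            {p for g in config.future_layers.values() for s in g.values() for p in s}
        )
        missing = [
            (g, s, p)
            for s in ssps
            for p in periods
            for g in gcms
            if p not in config.future_layers.get(g, {}).get(s, {})
        ]
        if missing:
            raise MissingCombinationError(f"missing future layer sets: {missing}")
    return [(g, s, p) for s in ssps for p in periods for g in gcms]


def _load_inputs(config: RunConfig):
    """(climate stack, accessible region, raw occurrences) for either mode."""
    seeds = config.stage_seeds()
    if config.mode == "synthetic":
        scenario = config.build_scenario()
        stack = make_climate_stack(scenario)
        region = scenario.accessible_region
        occ = sample_occurrences(
            scenario, config.n_occurrences, seed=seeds["occurrences"]
        )
        return stack, region, occ
    if config.mode != "files":
        raise ValueError(f"unknown mode {config.mode!r}")
    if not config.historical_layers:
        raise ValueError("file mode requires historical_layers")
    if config.occurrences_path is None:
        raise ValueError("file mode requires occurrences_path")
    if config.m_polygon_path is None:
        raise ValueError("file mode requires m_polygon_path (accessible area M)")
    stack = RasterStack([read_raster(p) for p in config.historical_layers])
    region = rasterize_region(load_geojson_geometry(config.m_polygon_path), stack.spec)
    occ = load_occurrences(
        config.occurrences_path, lon_col=config.lon_col, lat_col=config.lat_col
    )
    return stack, region, occ


def _suitability_at_records(layer: RasterLayer, occ: OccurrenceSet) -> np.ndarray:
    spec = layer.spec
    inside = spec.contains(occ.lon, occ.lat)
    row, col = spec.cell_of(occ.lon[inside], occ.lat[inside])
    flat = row * spec.n_cols + col
    ok = layer.valid_mask.ravel()[flat]
    return layer.values.ravel()[flat[ok]]


def run_historical(config: RunConfig) -> HistoricalArtifacts:
    """Execute the historical pipeline end to end.

    Stages: load/generate inputs -> clean -> thin -> split -> (drop
    artifact layers) -> PCA on the accessible area -> component selection
    -> bootstrap MaxEnt replicates -> median/range -> omission threshold
    -> binary + classified maps -> partial ROC, binomial test, NT1 novelty.
    All artifacts plus a manifest are written to ``config.outdir``.
    """
    seeds = config.stage_seeds()
    manifest = RunManifest(config=config.to_dict())
    outdir = config.outdir
    if config.write_outputs:
        os.makedirs(outdir, exist_ok=True)

    t0 = time.time()
    stack, region, occ_raw = _load_inputs(config)
    stack.spec.require_aligned(region.spec, "climate stack and accessible area")
    manifest.record(
        "inputs",
        time.time() - t0,
        {"stack": _hash_array(stack.as_array()), "region": _hash_array(region.inside)},
        n_layers=len(stack),
        n_records=len(occ_raw),
    )

    t0 = time.time()
    occ = clean_records(occ_raw)
    occ = thin_to_grid(occ, stack.spec)
    split = partition_records(occ, seed=seeds["partition"])
    manifest.record(
        "occurrences",
        time.time() - t0,
        {"thinned": _hash_array(occ.lon, occ.lat)},
        provenance=occ.provenance_log,
        n_calibration=len(split.calibration),
        n_evaluation=len(split.evaluation),
    )

    t0 = time.time()
    if config.drop_names:
        stack = drop_artifact_layers(stack, set(config.drop_names))
    transform = fit_pca(
        stack,
        region=region if config.pca_fit_on_region else None,
        standardize=config.pca_standardize,
    )
    k = select_components(transform, config.cum_threshold)
    pc_all = project_pca(stack, transform)
    pc_stack = pc_all.subset([f"PC{i + 1}" for i in range(k)])
    manifest.record(
        "pca",
        time.time() - t0,
        {"transform": _hash_array(transform.loadings_, transform.means_),
         "pc_stack": _hash_array(pc_stack.as_array())},
        n_components=k,
        explained_variance_ratio=transform.explained_variance_ratio_.tolist(),
    )
    if config.write_outputs:
        transform.to_json(os.path.join(outdir, "pca_transform.json"))

    t0 = time.time()
    fspec = None
    if config.feature_classes:
        mult = dict(config.reg_multipliers or {})
        base = FeatureSpec().reg_multipliers
        fspec = FeatureSpec(
            classes=tuple(config.feature_classes),
            hinge_knots=config.hinge_knots,
            reg_multipliers=tuple(sorted({**dict(base), **mult}.items())),
        )
    replicates = run_replicates(
        split.calibration,
        region,
        pc_stack,
        spec=fspec,
        n_replicates=config.n_replicates,
        seed=seeds["replicates"],
        background_n=config.background_n,
    )
    summary = summarize_members(replicates.predictions)
    summary.median_layer.name = "historical_median"
    summary.range_layer.name = "historical_range"
    manifest.record(
        "maxent",
        time.time() - t0,
        {"median": _hash_layer(summary.median_layer),
         "range": _hash_layer(summary.range_layer)},
        n_replicates=config.n_replicates,
        replicate_seeds=replicates.seeds,
        n_presence_cells=int(replicates.presence_cells.size),
        n_background=int(replicates.background_cells.size),
    )

    t0 = time.time()
    cal_vals = _suitability_at_records(summary.median_layer, split.calibration)
    threshold = omission_threshold(cal_vals, E=config.E)
    binary = binarize(summary.median_layer, threshold, E=config.E)
    classified = classify_suitability(
        summary.median_layer, threshold, breaks_mode=config.breaks_mode
    )
    manifest.record(
        "threshold",
        time.time() - t0,
        {"binary": _hash_layer(binary.layer)},
        threshold=threshold,
        E=config.E,
        n_suitable=binary.n_suitable,
    )

    t0 = time.time()
    proc = partial_roc(
        summary.median_layer,
        split.evaluation,
        E=config.E,
        iterations=config.proc_iterations,
        resample_fraction=config.proc_resample_fraction,
        seed=seeds["proc"],
    )
    binom_res = binomial_omission_test(binary, split.evaluation)
    novelty = exdet_nt1(pc_stack, pc_stack, region=region)
    manifest.record(
        "evaluation",
        time.time() - t0,
        {"nt1": _hash_layer(novelty.layer)},
        proc=proc.to_dict(),
        binomial=binom_res.to_dict(),
        n_novel_cells=novelty.n_novel,
    )

    if config.write_outputs:
        write_raster(summary.median_layer, os.path.join(outdir, "historical_median.asc"))
        write_raster(summary.range_layer, os.path.join(outdir, "historical_range.asc"))
        write_raster(binary.layer, os.path.join(outdir, "historical_binary.asc"))
        write_raster(classified.layer, os.path.join(outdir, "historical_classes.asc"))
        write_raster(novelty.layer, os.path.join(outdir, "novelty_nt1.asc"))
        with open(os.path.join(outdir, "evaluation.json"), "w") as fh:
            json.dump(
                {"partial_roc": proc.to_dict(), "binomial": binom_res.to_dict(),
                 "threshold": threshold, "E": config.E,
                 "class_breaks": list(classified.class_breaks)},
                fh, indent=1,
            )
        manifest.write(os.path.join(outdir, "manifest.json"))

    return HistoricalArtifacts(
        stack=stack,
        region=region,
        split=split,
        transform=transform,
        n_components=k,
        pc_stack=pc_stack,
        replicates=replicates,
        summary=summary,
        threshold=threshold,
        binary=binary,
        classified=classified,
        proc=proc,
        binomial=binom_res,
        novelty=novelty,
        manifest=manifest,
    )


def _future_stack_for(config: RunConfig, key: tuple[str, str, str],
                      cache: dict) -> RasterStack:
    if config.mode == "synthetic":
        if "stacks" not in cache:
            cache["stacks"] = make_future_stacks(
                config.build_scenario(),
                n_gcms=config.n_gcms,
                n_ssps=config.n_ssps,
                n_periods=config.n_periods,
            )
        return cache["stacks"][key]
    g, s, p = key
    paths = config.future_layers[g][s][p]
    stack = RasterStack([read_raster(path) for path in paths])
    if config.drop_names:
        drop = set(config.drop_names) & set(stack.names)
        if drop:
            stack = drop_artifact_layers(stack, drop)
    return stack


def run_future_ensemble(
    config: RunConfig, historical: HistoricalArtifacts
) -> FutureArtifacts:
    """Project the historical model to every (gcm, ssp, period) combination.

    The PCA transform and the replicate models are *never* refit: each
    future stack is projected with the frozen transform, every replicate
    model predicts on it (extrapolation off), replicates are medianed per
    GCM, GCMs are medianed per (ssp, period), and the historical E-percent
    threshold binarizes each scenario for the change map and the area-
    statistics table (one row per ssp x period).
    """
    tasks = plan_combinations(config)
    transform_hash = _hash_array(historical.transform.loadings_, historical.transform.means_)
    model_hash = _hash_array(*[m.coef_ for m in historical.replicates.models])
    manifest = RunManifest(config=config.to_dict())
    cache: dict = {}
    t_start = time.time()

    # per-GCM replicate medians, grouped by (ssp, period)
    per_scenario_gcm: dict[tuple[str, str], list[RasterLayer]] = {}
    for key in tasks:
        g, s, p = key
        future_stack = _future_stack_for(config, key, cache)
        pc_future = project_pca(future_stack, historical.transform)
        pc_future = pc_future.subset(historical.pc_stack.names)
        preds = [
            predict_suitability(m, pc_future, name=f"{g}_{s}_{p}_rep{i}")
            for i, m in enumerate(historical.replicates.models)
        ]
        med = summarize_members(RasterStack(preds)).median_layer
        med.name = f"{g}_{s}_{p}_median"
        per_scenario_gcm.setdefault((s, p), []).append(med)

    assert transform_hash == _hash_array(
        historical.transform.loadings_, historical.transform.means_
    ), "PCA transform mutated during projection"
    assert model_hash == _hash_array(
        *[m.coef_ for m in historical.replicates.models]
    ), "replicate models mutated during projection"

    per_scenario: dict[tuple[str, str], dict] = {}
    rows = []
    for (s, p), gcm_medians in per_scenario_gcm.items():
        ens = aggregate_gcms(RasterStack(gcm_medians))
        ens.median_layer.name = f"{s}_{p}_median"
        ens.range_layer.name = f"{s}_{p}_gcm_range"
        fut_binary = binarize(ens.median_layer, historical.threshold, E=config.E)
        change = change_categories(historical.binary, fut_binary)
        stats = area_change_stats(
            change,
            denominator_mode=config.denominator_mode,
            latitude_weighted=config.latitude_weighted,
        )
        per_scenario[(s, p)] = {
            "ensemble": ens,
            "binary": fut_binary,
            "change": change,
            "stats": stats,
        }
        rows.append(
            {
                "ssp": s,
                "period": p,
                "pct_increase": stats.pct_increase,
                "pct_decrease": stats.pct_decrease,
                **{f"n_{k}": v for k, v in change.counts.items()},
            }
        )
        if config.write_outputs:
            outdir = config.outdir
            os.makedirs(outdir, exist_ok=True)
            write_raster(ens.median_layer, os.path.join(outdir, f"future_{s}_{p}_median.asc"))
            write_raster(ens.range_layer, os.path.join(outdir, f"future_{s}_{p}_range.asc"))
            write_raster(change.layer, os.path.join(outdir, f"change_{s}_{p}.asc"))

    table = pd.DataFrame(rows).sort_values(["ssp", "period"]).reset_index(drop=True)
    manifest.record(
        "future_ensemble",
        time.time() - t_start,
        {f"{s}_{p}": _hash_layer(d["ensemble"].median_layer)
         for (s, p), d in per_scenario.items()},
        n_tasks=len(tasks),
        transform_hash=transform_hash,
        model_hash=model_hash,
    )
    if config.write_outputs:
        table.to_csv(os.path.join(config.outdir, "area_stats.csv"), index=False)
        manifest.write(os.path.join(config.outdir, "manifest_future.json"))
    return FutureArtifacts(per_scenario=per_scenario, area_table=table, manifest=manifest)
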