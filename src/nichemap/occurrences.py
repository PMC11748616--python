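"""Load, clean, spatially thin, and partition species occurrence records.

Occurrence tables (longitude/latitude in WGS84 decimal degrees, plus a
source label) pass through a fixed pipeline: drop unparseable or
out-of-bounds coordinates, collapse exact duplicates, rarefy to at most one
record per grid cell (the 2.5-arcminute analogue of ~5 km spatial
thinning), and split 50/50 into calibration and evaluation halves. Every
step appends a reconciling entry to the set's provenance log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GridSpec

__all__ = [
    "OccurrenceSet",
    "SplitResult",
    "SchemaError",
    "InsufficientDataError",
    "load_occurrences",
    "clean_records",
    "thin_to_grid",
    "partition_records",
]

_COLUMNS = ["lon", "lat", "source"]


class SchemaError(ValueError):
    """Input table lacks the required coordinate columns."""


class InsufficientDataError(ValueError):
    """Too few records for the requested operation."""


@dataclass
class OccurrenceSet:
    """Point records with a provenance log of applied filters.

    ``records`` is a DataFrame with columns lon, lat, source. Each
    provenance entry records {step, n_in, n_kept, n_removed} and must
    reconcile (n_in == n_kept + n_removed).
    """

    records: pd.DataFrame
    provenance_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in ("lon", "lat") if c not in df.columns]
        if missing:
            raise SchemaError(f"occurrence table missing columns {missing}")
        if "source" not in df.columns:
            df = df.assign(source="unknown")
        self.records = df[_COLUMNS].reset_index(drop=True)
        if len(self.records):
            lon = self.records["lon"].to_numpy(float)
            lat = self.records["lat"].to_numpy(float)
            if not (
                (lon >= -180).all() and (lon <= 180).all()
                and (lat >= -90).all() and (lat <= 90).all()
            ):
                raise ValueError("coordinates outside WGS84 bounds")
        for entry in self.provenance_log:
            if entry["n_in"] != entry["n_kept"] + entry["n_removed"]:
                raise ValueError(f"provenance entry does not reconcile: {entry}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lon(self) -> np.ndarray:
        return self.records["lon"].to_numpy(float)

    @property
    def lat(self) -> np.ndarray:
        return self.records["lat"].to_numpy(float)

    def logged(self, step: str, n_in: int, n_kept: int) -> None:
        self.provenance_log.append(
            {"step": step, "n_in": int(n_in), "n_kept": int(n_kept),
             "n_removed": int(n_in - n_kept)}
        )

    def to_csv(self, path: str) -> None:
        self.records.to_csv(path, index=False)


@dataclass
class SplitResult:
    """Disjoint calibration/evaluation halves of an occurrence set."""

    calibration: OccurrenceSet
    evaluation: OccurrenceSet
    seed: int


def load_occurrences(
    path: str,
    lon_col: str = "longitude",
    lat_col: str = "latitude",
    source_col: str = "source",
) -> OccurrenceSet:
    """Read an occurrence CSV, dropping rows with missing, non-numeric, or
    out-of-bounds coordinates (counted in the provenance log)."""
    df = pd.read_csv(path)
    missing = [c for c in (lon_col, lat_col) if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    n_in = len(df)
    lon = pd.to_numeric(df[lon_col], errors="coerce")
    lat = pd.to_numeric(df[lat_col], errors="coerce")
    ok = (
        lon.notna() & lat.notna()
        & (lon >= -180) & (lon <= 180) & (lat >= -90) & (lat <= 90)
    )
    out = pd.DataFrame(
        {
            "lon": lon[ok].to_numpy(float),
            "lat": lat[ok].to_numpy(float),
            "source": (
                df.loc[ok, source_col].astype(str).to_numpy()
                if source_col in df.columns
                else "unknown"
            ),
        }
    )
    occ = OccurrenceSet(out)
    occ.logged("load", n_in, len(out))
    return occ


def clean_records(occ: OccurrenceSet) -> OccurrenceSet:
    """Collapse exact (lon, lat) duplicates, keeping first appearance order."""
    kept = occ.records.drop_duplicates(subset=["lon", "lat"], keep="first")
    out = OccurrenceSet(kept.reset_index(drop=True), list(occ.provenance_log))
    out.logged("dedupe_exact", len(occ), len(kept))
    return out


def thin_to_grid(occ: OccurrenceSet, spec: GridSpec) -> OccurrenceSet:
    """Spatially rarefy to at most one record per grid cell.

    Records outside the grid extent are dropped (and logged) first; within
    each cell the first record encountered is kept, so the result is
    deterministic for a fixed input order. Idempotent.
    """
    df = occ.records
    inside = spec.contains(occ.lon, occ.lat) if len(df) else np.zeros(0, bool)
    n_in = len(df)
    df_in = df[inside].reset_index(drop=True)
    out = OccurrenceSet(df_in, list(occ.provenance_log))
    out.logged("drop_outside_grid", n_in, len(df_in))

    row, col = spec.cell_of(out.lon, out.lat)
    cell_id = row * spec.n_cols + col
    _, first_idx = np.unique(cell_id, return_index=True)
    keep = np.sort(first_idx)
    thinned = OccurrenceSet(df_in.iloc[keep].reset_index(drop=True), out.provenance_log)
    thinned.logged("thin_to_grid", len(df_in), len(keep))
    return thinned


def partition_records(
    occ: OccurrenceSet, fraction: float = 0.5, seed: int = 0
) -> SplitResult:
    """Uniform random split without replacement into calibration/evaluation.

    With the default fraction 0.5 the halves differ in size by at most one
    record. Reproducible given ``seed``.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    n = len(occ)
    if n < 2:
        raise InsufficientDataError(f"cannot partition {n} record(s)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_cal = int(round(fraction * n))
    n_cal = min(max(n_cal, 1), n - 1)
    cal_idx = np.sort(perm[:n_cal])
    eva_idx = np.sort(perm[n_cal:])
    cal = OccurrenceSet(occ.records.iloc[cal_idx].reset_index(drop=True),
                        list(occ.provenance_log))
    cal.logged("partition_calibration", n, len(cal_idx))
    eva = OccurrenceSet(occ.records.iloc[eva_idx].reset_index(drop=True),
                        list(occ.provenance_log))
    eva.logged("partition_evaluation", n, len(eva_idx))
    return SplitResult(calibration=cal, evaluation=eva, seed=seed)
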