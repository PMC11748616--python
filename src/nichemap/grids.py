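"""Raster/vector data model and file I/O shared by all pipeline stages.

The pipeline operates on geographic (WGS84, decimal-degree) grids with a
north-up, unrotated geotransform. Cell (row, col) covers the half-open
rectangle [x_min + col*s, x_min + (col+1)*s) x [y_top - (row+1)*s, y_top - row*s),
with row 0 the northernmost row; points are assigned to cells by this
convention, and polygon rasterization tests cell *centers*.

Supported file formats: single-band GeoTIFF (via tifffile with GeoTIFF
tags) and the ESRI ASCII grid exchanged by classic MaxEnt-era tooling.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import shape as _geojson_shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "GridSpec",
    "RasterLayer",
    "RasterStack",
    "RegionMask",
    "GridAlignmentError",
    "RasterFormatError",
    "UnsupportedGeometryError",
    "EmptyMaskError",
    "read_raster",
    "write_raster",
    "rasterize_region",
    "load_geojson_geometry",
]

#: 2.5 arcminutes in decimal degrees, the working resolution of the pipeline.
CELL_2P5_ARCMIN = 2.5 / 60.0

_ALIGN_TOL = 1e-9


class GridAlignmentError(ValueError):
    """Two grids that must share one GridSpec do not."""


class RasterFormatError(ValueError):
    """A raster file could not be parsed in the named format."""


class UnsupportedGeometryError(ValueError):
    """Rotated/sheared geotransforms are not supported."""


class EmptyMaskError(ValueError):
    """A region rasterized to zero cells."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up geographic grid.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid shape; row 0 is the northernmost row.
    x_min, y_min : float
        Coordinates (degrees) of the lower-left *corner* of the grid.
    cell_size : float
        Square cell edge in degrees (default 2.5 arcminutes).
    nodata_value : float
        Sentinel written for invalid cells on output.
    """

    n_rows: int
    n_cols: int
    x_min: float
    y_min: float
    cell_size: float = CELL_2P5_ARCMIN
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y_min + self.n_rows * self.cell_size

    def aligned_with(self, other: "GridSpec", tol: float = _ALIGN_TOL) -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.x_min - other.x_min) <= tol
            and abs(self.y_min - other.y_min) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.nodata_value - other.nodata_value) <= tol
        )

    def require_aligned(self, other: "GridSpec", what: str = "grids") -> None:
        if not self.aligned_with(other):
            raise GridAlignmentError(f"{what} are not on aligned grids: {self} vs {other}")

    def cell_of(self, lon, lat):
        """Map coordinates to (row, col) under the half-open cell convention.

        Returns integer arrays; out-of-extent points get row/col outside
        [0, n_rows) / [0, n_cols).
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.x_min) / self.cell_size).astype(np.int64)
        row_from_bottom = np.floor((lat - self.y_min) / self.cell_size).astype(np.int64)
        row = self.n_rows - 1 - row_from_bottom
        return row, col

    def contains(self, lon, lat):
        row, col = self.cell_of(lon, lat)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def cell_center(self, row, col):
        """Longitude/latitude of the center of cell (row, col)."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.x_min + (col + 0.5) * self.cell_size
        lat = self.y_min + (self.n_rows - np.asarray(row, dtype=float) - 0.5) * self.cell_size
        return lon, lat

    def center_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of every cell center, each shaped (n_rows, n_cols)."""
        rows, cols = np.meshgrid(
            np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij"
        )
        return self.cell_center(rows, cols)

    def latitudes(self) -> np.ndarray:
        """Cell-center latitude per row (length n_rows, north first)."""
        return self.y_min + (self.n_rows - np.arange(self.n_rows) - 0.5) * self.cell_size


@dataclass
class RasterLayer:
    """One named grid of values plus a validity mask.

    Cells where ``valid_mask`` is False are excluded from every statistic
    and are written as the spec's nodata value.
    """

    spec: GridSpec
    name: str
    values: np.ndarray
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"layer {self.name!r}: values shape {self.values.shape} != grid {self.spec.shape}"
            )
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.values)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.spec.shape:
                raise ValueError(f"layer {self.name!r}: mask shape mismatch")
        # non-finite cells can never be valid
        self.valid_mask = self.valid_mask & np.isfinite(self.values)

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def with_values(self, values: np.ndarray, name: str | None = None,
                    valid_mask: np.ndarray | None = None) -> "RasterLayer":
        return RasterLayer(
            self.spec,
            self.name if name is None else name,
            values,
            self.valid_mask if valid_mask is None else valid_mask,
        )


@dataclass
class RasterStack:
    """Ordered collection of aligned, uniquely named layers."""

    layers: list[RasterLayer]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("a RasterStack needs at least one layer")
        spec = self.layers[0].spec
        for lyr in self.layers[1:]:
            spec.require_aligned(lyr.spec, f"stack layers {self.layers[0].name!r}/{lyr.name!r}")
        names = [lyr.name for lyr in self.layers]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate layer names in stack: {names}")

    @property
    def spec(self) -> GridSpec:
        return self.layers[0].spec

    @property
    def names(self) -> list[str]:
        return [lyr.name for lyr in self.layers]

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> RasterLayer:
        for lyr in self.layers:
            if lyr.name == name:
                return lyr
        raise KeyError(name)

    def joint_valid_mask(self) -> np.ndarray:
        mask = self.layers[0].valid_mask.copy()
        for lyr in self.layers[1:]:
            mask &= lyr.valid_mask
        return mask

    def subset(self, names: list[str]) -> "RasterStack":
        return RasterStack([self[n] for n in names])

    def as_array(self) -> np.ndarray:
        """(n_layers, n_rows, n_cols) value cube."""
        return np.stack([lyr.values for lyr in self.layers])

    def table(self, mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Flatten valid cells to a design matrix.

        Returns (X, flat_index): X has one row per cell where ``mask`` (default
        the joint valid mask) holds, one column per layer; flat_index are the
        raveled cell indices of those rows.
        """
        if mask is None:
            mask = self.joint_valid_mask()
        else:
            mask = mask & self.joint_valid_mask()
        idx = np.flatnonzero(mask)
        X = np.column_stack([lyr.values.ravel()[idx] for lyr in self.layers])
        return X, idx


@dataclass
class RegionMask:
    """Boolean accessible-area ('M') mask aligned with the working grid."""

    spec: GridSpec
    inside: np.ndarray

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside, dtype=bool)
        if self.inside.shape != self.spec.shape:
            raise ValueError("region mask shape does not match its grid")
        if not self.inside.any():
            raise EmptyMaskError("region mask has no cells inside")

    @property
    def n_inside(self) -> int:
        return int(self.inside.sum())


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _read_esri_ascii(path: str) -> RasterLayer:
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        lines = iter(fh)
        n_header = 0
        data_lines = []
        for line in lines:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if n_header < 6 and key in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[key] = float(parts[1])
                n_header += 1
            else:
                data_lines.append(line)
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    if not required <= set(header):
        missing = sorted(required - set(header))
        raise RasterFormatError(f"ESRI ASCII header missing {missing} in {path}")
    nodata = header.get("nodata_value", -9999.0)
    try:
        values = np.array(" ".join(data_lines).split(), dtype=float)
    except ValueError as exc:
        raise RasterFormatError(f"cannot parse grid body of {path}: {exc}") from exc
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if values.size != n_rows * n_cols:
        raise RasterFormatError(
            f"{path}: expected {n_rows * n_cols} values, found {values.size}"
        )
    values = values.reshape(n_rows, n_cols)
    spec = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        x_min=header["xllcorner"],
        y_min=header["yllcorner"],
        cell_size=header["cellsize"],
        nodata_value=nodata,
    )
    mask = values != nodata
    import os
    name = os.path.splitext(os.path.basename(path))[0]
    return RasterLayer(spec, name, values, mask)


def _write_esri_ascii(layer: RasterLayer, path: str) -> None:
    spec = layer.spec
    out = np.where(layer.valid_mask, layer.values, spec.nodata_value)
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {spec.x_min!r}\n")
        fh.write(f"yllcorner {spec.y_min!r}\n")
        fh.write(f"cellsize {spec.cell_size!r}\n")
        fh.write(f"NODATA_value {spec.nodata_value!r}\n")
        for row in out:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_MODEL_TRANSFORMATION = 34264
_TAG_GDAL_NODATA = 42113


def _read_geotiff(path: str) -> RasterLayer:
    import tifffile

    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            values = page.asarray().astype(float)
            tags = page.tags
            if _TAG_MODEL_TRANSFORMATION in tags:
                m = np.asarray(tags[_TAG_MODEL_TRANSFORMATION].value, float).reshape(4, 4)
                if m[0, 1] != 0 or m[1, 0] != 0:
                    raise UnsupportedGeometryError(
                        f"{path}: rotated/sheared geotransform not supported"
                    )
                sx, sy = m[0, 0], -m[1, 1]
                x0, y_top = m[0, 3], m[1, 3]
            elif _TAG_MODEL_PIXEL_SCALE in tags and _TAG_MODEL_TIEPOINT in tags:
                sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
                tie = tags[_TAG_MODEL_TIEPOINT].value
                # tiepoint maps raster (i, j) -> model (x, y); we require (0, 0)
                x0 = tie[3] - tie[0] * sx
                y_top = tie[4] + tie[1] * sy
            else:
                raise RasterFormatError(f"{path}: no GeoTIFF georeferencing tags")
            nodata = -9999.0
            if _TAG_GDAL_NODATA in tags:
                nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00"))
    except (tifffile.TiffFileError, OSError) as exc:
        raise RasterFormatError(f"cannot read GeoTIFF {path}: {exc}") from exc
    if values.ndim != 2:
        raise RasterFormatError(f"{path}: expected a single-band raster")
    if abs(sx - sy) > 1e-9:
        raise UnsupportedGeometryError(f"{path}: non-square cells ({sx} x {sy})")
    n_rows, n_cols = values.shape
    spec = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        x_min=x0,
        y_min=y_top - n_rows * sy,
        cell_size=sx,
        nodata_value=nodata,
    )
    mask = (values != nodata) & np.isfinite(values)
    import os
    name = os.path.splitext(os.path.basename(path))[0]
    return RasterLayer(spec, name, np.where(mask, values, nodata), mask)


def _write_geotiff(layer: RasterLayer, path: str) -> None:
    import tifffile

    spec = layer.spec
    out = np.where(layer.valid_mask, layer.values, spec.nodata_value)
    s = spec.cell_size
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (s, s, 0.0), True),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.x_min, spec.y_max, 0.0), True),
        (_TAG_GDAL_NODATA, "s", 0, str(spec.nodata_value), True),
    ]
    tifffile.imwrite(path, out.astype(np.float64), extratags=extratags)


def read_raster(path: str, format: str | None = None) -> RasterLayer:
    """Read a single-band raster as a :class:`RasterLayer`.

    ``format`` is ``'geotiff'`` or ``'esri_ascii'``; if omitted it is
    inferred from the file extension (.tif/.tiff vs .asc/.txt). Nodata cells
    come back with ``valid_mask`` False; row 0 is the northernmost row.
    """
    if format is None:
        lower = str(path).lower()
        format = "geotiff" if lower.endswith((".tif", ".tiff")) else "esri_ascii"
    if format == "geotiff":
        return _read_geotiff(str(path))
    if format == "esri_ascii":
        return _read_esri_ascii(str(path))
    raise ValueError(f"unknown raster format {format!r}")


def write_raster(layer: RasterLayer, path: str, format: str | None = None) -> str:
    """Write a layer so that :func:`read_raster` round-trips values, mask, grid."""
    if format is None:
        lower = str(path).lower()
        format = "geotiff" if lower.endswith((".tif", ".tiff")) else "esri_ascii"
    if format == "geotiff":
        _write_geotiff(layer, str(path))
    elif format == "esri_ascii":
        _write_esri_ascii(layer, str(path))
    else:
        raise ValueError(f"unknown raster format {format!r}")
    return str(path)


def load_geojson_geometry(path: str) -> BaseGeometry:
    """Load the first geometry found in a GeoJSON file (Feature[Collection] or bare geometry)."""
    with open(path) as fh:
        obj = json.load(fh)
    if obj.get("type") == "FeatureCollection":
        geoms = [_geojson_shape(f["geometry"]) for f in obj["features"]]
        return shapely.unary_union(geoms)
    if obj.get("type") == "Feature":
        return _geojson_shape(obj["geometry"])
    return _geojson_shape(obj)


def rasterize_region(polygon, spec: GridSpec) -> RegionMask:
    """Rasterize an accessible-area polygon onto a grid.

    A cell is inside iff its *center* falls within the polygon (boundary
    points count as inside). ``polygon`` may be a shapely geometry or a
    GeoJSON-style mapping.
    """
    if not isinstance(polygon, BaseGeometry):
        polygon = _geojson_shape(polygon)
    if polygon.is_empty:
        raise ValueError("polygon is empty")
    lon, lat = spec.center_grids()
    inside = shapely.intersects_xy(polygon, lon.ravel(), lat.ravel()).reshape(spec.shape)
    if not inside.any():
        raise EmptyMaskError("polygon covers no cell centers of the grid")
    return RegionMask(spec, inside)
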