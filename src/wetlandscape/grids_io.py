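"""Raster data model and GeoTIFF I/O.

All rasters in the pipeline are north-up, 0-based row/col, origin at the
top-left corner, half-open cell intervals.  Area arithmetic assumes the CRS is
equal-area (the continental default is an Albers equal-area definition;
synthetic fixtures use an abstract Cartesian CRS where a map unit is a metre).

GeoTIFF files are written with the standard georeferencing tags
(ModelPixelScale, ModelTiepoint, a minimal GeoKeyDirectory, GDAL_NODATA) so
they open in common GIS software; auxiliary metadata (CRS name, value kind,
band names) is carried as JSON in the ImageDescription tag.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "Transform",
    "RasterLayer",
    "GridSpec",
    "ClimateZoneMap",
    "CLIMATE_ZONES",
    "DEFAULT_EQUAL_AREA_CRS",
    "SYNTHETIC_CRS",
    "read_raster",
    "write_raster",
    "read_stack",
    "write_stack",
    "make_grid",
]

#: Equal-area CRS used for continental area math (Africa Albers equal-area).
DEFAULT_EQUAL_AREA_CRS = "ESRI:102022"
#: Abstract Cartesian CRS used by synthetic fixtures (unit = metre, equal-area
#: by construction).
SYNTHETIC_CRS = "synthetic:cartesian"

#: Climate-zone codes: tropical wet, tropical wet-and-dry, semi-arid,
#: arid/desert, mediterranean subtropical.
CLIMATE_ZONES = ("TW", "TWD", "SARD", "ARD", "MED")

# GeoTIFF tag ids
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GEO_ASCII = 34737
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class Transform:
    """North-up affine geotransform without rotation.

    ``x = x0 + col * dx`` and ``y = y0 - row * dy`` map the top-left corner of
    cell (row, col) to map coordinates; ``dx``/``dy`` are positive cell sizes.
    """

    x0: float
    y0: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0):
            raise ValueError(f"cell size must be strictly positive, got dx={self.dx}, dy={self.dy}")

    def cell_area(self) -> float:
        return self.dx * self.dy

    def xy(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinate of the top-left corner of cell (row, col)."""
        return self.x0 + col * self.dx, self.y0 - row * self.dy

    def rowcol(self, x: float, y: float) -> tuple[int, int]:
        """Cell containing point (x, y) under half-open cell intervals."""
        return int(math.floor((self.y0 - y) / self.dy)), int(math.floor((x - self.x0) / self.dx))


@dataclass
class RasterLayer:
    """A single-band raster: 2-D values plus georeferencing.

    ``nodata`` marks missing cells; it must never collide with a valid
    category code in a categorical layer.
    """

    values: np.ndarray
    transform: Transform
    crs: str = SYNTHETIC_CRS
    nodata: float | int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster values must be a non-empty 2-D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata) cells."""
        if self.nodata is None:
            if np.issubdtype(self.values.dtype, np.floating):
                return ~np.isnan(self.values)
            return np.ones(self.shape, dtype=bool)
        if np.issubdtype(self.values.dtype, np.floating) and np.isnan(self.nodata):
            return ~np.isnan(self.values)
        return self.values != self.nodata

    def like(self, values: np.ndarray, nodata=None) -> "RasterLayer":
        """New layer with the same georeferencing and fresh values."""
        return RasterLayer(values, self.transform, self.crs, nodata)

    def same_frame(self, other: "RasterLayer") -> bool:
        return self.shape == other.shape and self.transform == other.transform and self.crs == other.crs


@dataclass(frozen=True)
class GridSpec:
    """A coarse analysis grid anchored at a fine raster's origin.

    The grid tiles the raster extent with half-open square cells of
    ``cell_size`` map units; every fine cell belongs to exactly one coarse
    cell (the one containing its top-left corner).
    """

    cell_size: float
    origin: tuple[float, float]
    nrows: int
    ncols: int
    crs: str = SYNTHETIC_CRS
    fine_factor: int = field(default=1)  # fine cells per coarse cell edge

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("grid cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def transform(self) -> Transform:
        return Transform(self.origin[0], self.origin[1], self.cell_size, self.cell_size)

    def assign(self, shape: tuple[int, int], factor: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Coarse (row, col) index arrays for every fine cell of ``shape``."""
        f = self.fine_factor if factor is None else factor
        rows = np.arange(shape[0]) // f
        cols = np.arange(shape[1]) // f
        return np.meshgrid(rows, cols, indexing="ij")

    def area_km2(self) -> float:
        """Area of one coarse cell in km² (CRS unit assumed to be metres)."""
        return (self.cell_size / 1000.0) ** 2


class ClimateZoneMap(RasterLayer):
    """Categorical raster of climate-zone codes (1..5 → TW..MED)."""

    CODES = {name: i + 1 for i, name in enumerate(CLIMATE_ZONES)}

    def zone_name(self, code: int) -> str:
        for name, c in self.CODES.items():
            if c == code:
                return name
        raise KeyError(f"unknown climate-zone code {code}")


def _check_categorical(values: np.ndarray) -> np.ndarray:
    if np.issubdtype(values.dtype, np.integer):
        return values
    rounded = np.round(values)
    valid = ~np.isnan(values)
    if not np.all(values[valid] == rounded[valid]):
        raise ValueError("categorical raster contains non-integer values")
    return rounded.astype(np.int32)


def read_raster(path: str | os.PathLike, expected_kind: str = "continuous") -> RasterLayer:
    """Read a single-band GeoTIFF into a :class:`RasterLayer`.

    ``expected_kind`` is ``"continuous"`` or ``"categorical"``; categorical
    layers are returned with integer codes and reading fails if the file
    holds non-integer values.
    """
    if expected_kind not in ("continuous", "categorical"):
        raise ValueError(f"expected_kind must be continuous|categorical, got {expected_kind!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(f"raster file not found: {path}")
    values, transform, crs, nodata, _ = _read_tiff(path)
    if values.ndim == 3:
        if values.shape[0] != 1:
            raise ValueError(f"{path} is multiband; use read_stack")
        values = values[0]
    if expected_kind == "categorical":
        values = _check_categorical(values)
        if nodata is not None:
            nodata = int(nodata)
    return RasterLayer(values, transform, crs, nodata)


def write_raster(layer: RasterLayer, path: str | os.PathLike) -> None:
    """Write a :class:`RasterLayer` as a GeoTIFF (lossless for integers,
    float32/float64 preserved bit-for-bit for continuous layers)."""
    _write_tiff(np.asarray(layer.values)[None, ...], layer.transform, layer.crs, layer.nodata, path, band_names=None)


def write_stack(layers: Sequence[RasterLayer], names: Sequence[str], path: str | os.PathLike) -> None:
    """Write co-registered layers as a multiband GeoTIFF with band names."""
    if len(layers) != len(names):
        raise ValueError("one name per layer required")
    first = layers[0]
    for lyr in layers[1:]:
        if not first.same_frame(lyr):
            raise ValueError("stack layers are not co-registered")
    data = np.stack([np.asarray(l.values) for l in layers])
    _write_tiff(data, first.transform, first.crs, first.nodata, path, band_names=list(names))


def read_stack(path: str | os.PathLike) -> tuple[list[RasterLayer], list[str]]:
    """Read a multiband GeoTIFF written by :func:`write_stack`."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"raster file not found: {path}")
    values, transform, crs, nodata, meta = _read_tiff(path)
    if values.ndim == 2:
        values = values[None, ...]
    names = meta.get("band_names") or [f"band_{i + 1}" for i in range(values.shape[0])]
    return [RasterLayer(v, transform, crs, nodata) for v in values], list(names)


def _write_tiff(data: np.ndarray, transform: Transform, crs: str, nodata, path, band_names) -> None:
    meta = {"crs": crs, "band_names": band_names}
    # Minimal GeoKeyDirectory: version 1.1.0, 2 keys — raster type PixelIsArea
    # and a citation key pointing at the ASCII CRS string.
    crs_ascii = crs + "|"
    geokeys = (1, 1, 0, 2, 1025, 0, 1, 1, 1026, _TAG_GEO_ASCII, len(crs_ascii), 0)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (transform.dx, transform.dy, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, transform.x0, transform.y0, 0.0)),
        (_TAG_GEO_KEYS, "H", len(geokeys), geokeys),
        (_TAG_GEO_ASCII, "s", 0, crs_ascii),
    ]
    if nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, str(nodata)))
    try:
        tifffile.imwrite(
            path,
            data,
            photometric="minisblack",
            planarconfig="separate" if data.shape[0] > 1 else None,
            description=json.dumps(meta),
            extratags=extratags,
        )
    except (OSError, PermissionError) as exc:
        raise OSError(f"cannot write raster to {path}: {exc}") from exc


def _read_tiff(path):
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = tif.asarray()
        tags = page.tags
        scale = tags.valueof(_TAG_PIXEL_SCALE)
        tiepoint = tags.valueof(_TAG_TIEPOINT)
        if scale is None or tiepoint is None:
            raise ValueError(f"{path} lacks georeferencing tags; cannot use for georeferenced operations")
        transform = Transform(float(tiepoint[3]), float(tiepoint[4]), float(scale[0]), float(scale[1]))
        meta: dict = {}
        desc = page.description
        if desc:
            try:
                meta = json.loads(desc)
            except (json.JSONDecodeError, TypeError):
                meta = {}
        crs = meta.get("crs")
        if crs is None:
            ascii_params = tags.valueof(_TAG_GEO_ASCII)
            crs = ascii_params.rstrip("|\x00") if ascii_params else None
        if crs is None:
            raise ValueError(f"{path} carries no CRS; georeferenced operations are undefined")
        nodata_raw = tags.valueof(_TAG_GDAL_NODATA)
        nodata = None
        if nodata_raw is not None:
            nodata = float(nodata_raw)
            if np.issubdtype(values.dtype, np.integer):
                nodata = int(nodata)
    return values, transform, crs, nodata, meta


def make_grid(template: RasterLayer, cell_size: float) -> GridSpec:
    """Coarse analysis grid tiling ``template``, anchored at its origin.

    ``cell_size`` must be an exact positive multiple of the template cell
    size; every fine cell then maps to exactly one coarse cell.
    """
    t = template.transform
    if t.dx != t.dy:
        raise ValueError("make_grid requires square template cells")
    if cell_size < t.dx:
        raise ValueError(f"grid cell_size {cell_size} is smaller than template resolution {t.dx}")
    factor = cell_size / t.dx
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"grid cell_size {cell_size} is not an exact multiple of template cell size {t.dx}")
    factor = int(round(factor))
    nrows = -(-template.shape[0] // factor)
    ncols = -(-template.shape[1] // factor)
    return GridSpec(
        cell_size=float(cell_size),
        origin=(t.x0, t.y0),
        nrows=nrows,
        ncols=ncols,
        crs=template.crs,
        fine_factor=factor,
    )
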