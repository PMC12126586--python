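"""Seasonal composites and optical/SAR predictor variables.

The classifier's inputs are per-zone seasonal composites of Sentinel-2-style
reflectance bands (B2 blue, B3 green, B4 red, B8 NIR, B11/B12 SWIR) and
Sentinel-1-style dual-polarisation backscatter (VV, VH), plus normalized
difference indices computed from them:

    NDVI  = (B8 - B4) / (B8 + B4)
    NDWI  = (B3 - B8) / (B3 + B8)
    MNDWI = (B3 - SWIR) / (B3 + SWIR)      SWIR = B11 (default) or B12
    TCWI  = sum_b c_b * band_b             tasseled-cap wetness
    Ndiff = (VH - VV) / (VH + VV)
    Nratio = VV / VH

Backscatter is handled in linear power for the ratio indices; dB inputs are
converted first (ratios of dB values are not physically meaningful).
Composites over arid and semi-arid zones use the per-cell maximum, other
zones the median (mean also supported); the zone→statistic policy lives in
the pipeline configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grids_io import RasterLayer

__all__ = [
    "OPTICAL_BANDS",
    "SAR_BANDS",
    "DEFAULT_TCWI_COEFFICIENTS",
    "ZONE_COMPOSITE_STATISTIC",
    "CompositeScene",
    "FeatureStack",
    "seasonal_composite",
    "compute_optical_index",
    "tasseled_cap_wetness",
    "compute_sar_index",
    "compute_variable",
    "build_feature_stack",
]

OPTICAL_BANDS = ("B2", "B3", "B4", "B8", "B11", "B12")
SAR_BANDS = ("VV", "VH")

#: Sentinel-2 tasseled-cap wetness coefficients (Nedkov 2017); configuration,
#: not ground truth — override per run if a different set is preferred.
DEFAULT_TCWI_COEFFICIENTS = {
    "B2": 0.2578,
    "B3": 0.2305,
    "B4": 0.0883,
    "B8": 0.1071,
    "B11": -0.7611,
    "B12": -0.5308,
}

#: Default composite statistic per climate zone: maximum for arid and
#: semi-arid zones (seasonality is the wetland signal there), median
#: elsewhere.  Mean is accepted anywhere via configuration.
ZONE_COMPOSITE_STATISTIC = {"TW": "median", "TWD": "median", "SARD": "max", "ARD": "max", "MED": "median"}


@dataclass
class CompositeScene:
    """Co-registered band layers for one climate zone and season.

    ``sar_scale`` declares whether VV/VH are linear power or dB.
    """

    bands: dict[str, RasterLayer]
    season: str = "annual"
    zone: str = "TW"
    sar_scale: str = "linear"  # "linear" | "db"

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("scene has no bands")
        if self.season not in ("wet", "dry", "annual"):
            raise ValueError(f"season must be wet|dry|annual, got {self.season!r}")
        if self.sar_scale not in ("linear", "db"):
            raise ValueError("sar_scale must be 'linear' or 'db'")
        first = next(iter(self.bands.values()))
        for name, layer in self.bands.items():
            if not first.same_frame(layer):
                raise ValueError(f"band {name} is not co-registered with the rest of the scene")

    @property
    def frame(self) -> RasterLayer:
        return next(iter(self.bands.values()))

    def band(self, name: str) -> RasterLayer:
        try:
            return self.bands[name]
        except KeyError:
            raise KeyError(f"band {name!r} missing from scene (has {sorted(self.bands)})") from None

    def sar_linear(self, name: str) -> np.ndarray:
        """Backscatter band in linear power regardless of stored scale."""
        layer = self.band(name)
        vals = np.asarray(layer.values, dtype=float)
        if self.sar_scale == "db":
            vals = 10.0 ** (vals / 10.0)
        return vals


@dataclass
class FeatureStack:
    """Ordered, uniquely named predictor layers for one climate zone."""

    features: list[tuple[str, RasterLayer]]
    zone: str = "TW"

    def __post_init__(self) -> None:
        names = [n for n, _ in self.features]
        if len(names) != len(set(names)):
            raise ValueError("feature names must be unique")
        if not self.features:
            raise ValueError("feature stack is empty")
        first = self.features[0][1]
        for name, layer in self.features:
            if not first.same_frame(layer):
                raise ValueError(f"feature {name} is not co-registered")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.features]

    @property
    def frame(self) -> RasterLayer:
        return self.features[0][1]

    def array(self) -> np.ndarray:
        """(n_cells, n_features) matrix with NaN where any source is nodata."""
        cols = []
        for _, layer in self.features:
            vals = np.asarray(layer.values, dtype=float).ravel().copy()
            vals[~layer.mask().ravel()] = np.nan
            cols.append(vals)
        return np.column_stack(cols)


def _masked_band_stack(scenes, band: str) -> np.ndarray:
    out = []
    for scene in scenes:
        layer = scene.band(band)
        vals = np.asarray(layer.values, dtype=float).copy()
        vals[~layer.mask()] = np.nan
        out.append(vals)
    return np.stack(out)


def seasonal_composite(stack: list[CompositeScene], statistic: str = "median") -> CompositeScene:
    """Per-cell composite over same-season scenes.

    Each output cell is the chosen statistic (``median``, ``mean`` or
    ``max``) of the non-nodata inputs at that cell; a cell that is nodata in
    every scene stays nodata (NaN).
    """
    if not stack:
        raise ValueError("cannot composite an empty scene stack")
    if statistic not in ("median", "mean", "max"):
        raise ValueError(f"statistic must be median|mean|max, got {statistic!r}")
    first = stack[0]
    for scene in stack[1:]:
        if scene.bands.keys() != first.bands.keys() or not first.frame.same_frame(scene.frame):
            raise ValueError("scenes in the stack are misaligned or carry different bands")
        if scene.sar_scale != first.sar_scale:
            raise ValueError("mixed SAR scales in composite stack")
    reducer = {"median": np.nanmedian, "mean": np.nanmean, "max": np.nanmax}[statistic]
    out_bands = {}
    frame = first.frame
    for band in first.bands:
        cube = _masked_band_stack(stack, band)
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
            vals = reducer(cube, axis=0)
        out_bands[band] = RasterLayer(vals, frame.transform, frame.crs, nodata=np.nan)
    return CompositeScene(out_bands, season=first.season, zone=first.zone, sar_scale=first.sar_scale)


def _normalized_difference(a: np.ndarray, b: np.ndarray, valid: np.ndarray) -> np.ndarray:
    denom = a + b
    out = np.full(a.shape, np.nan)
    ok = valid & (denom != 0)
    out[ok] = (a[ok] - b[ok]) / denom[ok]
    return out


def compute_optical_index(scene: CompositeScene, name: str, mndwi_swir: str = "B11") -> RasterLayer:
    """NDVI, NDWI or MNDWI from a composite scene.

    Values are in [-1, 1] where both bands are valid and their sum is
    non-zero; elsewhere nodata (NaN).
    """
    name = name.upper()
    if name == "NDVI":
        num_band, den_band = "B8", "B4"
        a, b = scene.band(num_band), scene.band(den_band)
        vals = _normalized_difference(
            np.asarray(a.values, float), np.asarray(b.values, float), a.mask() & b.mask()
        )
    elif name == "NDWI":
        a, b = scene.band("B3"), scene.band("B8")
        vals = _normalized_difference(
            np.asarray(a.values, float), np.asarray(b.values, float), a.mask() & b.mask()
        )
    elif name == "MNDWI":
        if mndwi_swir not in ("B11", "B12"):
            raise ValueError("MNDWI SWIR band must be B11 or B12")
        a, b = scene.band("B3"), scene.band(mndwi_swir)
        vals = _normalized_difference(
            np.asarray(a.values, float), np.asarray(b.values, float), a.mask() & b.mask()
        )
    else:
        raise ValueError(f"unknown optical index {name!r} (NDVI|NDWI|MNDWI)")
    frame = scene.frame
    return RasterLayer(vals, frame.transform, frame.crs, nodata=np.nan)


def tasseled_cap_wetness(scene: CompositeScene, coefficients: dict[str, float] | None = None) -> RasterLayer:
    """Tasseled-cap wetness: per-cell weighted sum of reflectance bands."""
    coeffs = DEFAULT_TCWI_COEFFICIENTS if coefficients is None else coefficients
    missing = [b for b in coeffs if b not in scene.bands]
    if missing:
        raise ValueError(f"TCWI coefficients reference bands absent from scene: {missing}")
    frame = scene.frame
    out = np.zeros(frame.shape, dtype=float)
    valid = np.ones(frame.shape, dtype=bool)
    for band, c in coeffs.items():
        layer = scene.band(band)
        valid &= layer.mask()
        out = out + c * np.asarray(layer.values, dtype=float)
    out[~valid] = np.nan
    return RasterLayer(out, frame.transform, frame.crs, nodata=np.nan)


def compute_sar_index(scene: CompositeScene, name: str) -> RasterLayer:
    """Ndiff = (VH-VV)/(VH+VV) or Nratio = VV/VH, in linear power."""
    name_l = name.lower()
    vv = scene.sar_linear("VV")
    vh = scene.sar_linear("VH")
    valid = scene.band("VV").mask() & scene.band("VH").mask()
    out = np.full(vv.shape, np.nan)
    if name_l == "ndiff":
        denom = vh + vv
        ok = valid & (denom != 0)
        out[ok] = (vh[ok] - vv[ok]) / denom[ok]
    elif name_l == "nratio":
        ok = valid & (vh != 0)
        out[ok] = vv[ok] / vh[ok]
    else:
        raise ValueError(f"unknown SAR index {name!r} (Ndiff|Nratio)")
    frame = scene.frame
    return RasterLayer(out, frame.transform, frame.crs, nodata=np.nan)


_INDEX_NAMES = {"NDVI", "NDWI", "MNDWI", "TCWI", "NDIFF", "NRATIO"}


def compute_variable(scene: CompositeScene, name: str, *, mndwi_swir: str = "B11",
                     tcwi_coefficients: dict[str, float] | None = None) -> RasterLayer:
    """One predictor layer — a raw band or a derived index — from a scene."""
    if name in scene.bands:
        layer = scene.band(name)
        if name in SAR_BANDS:
            vals = scene.sar_linear(name)
            vals = vals.copy()
            vals[~layer.mask()] = np.nan
            return RasterLayer(vals, layer.transform, layer.crs, nodata=np.nan)
        return layer
    upper = name.upper()
    if upper in ("NDVI", "NDWI", "MNDWI"):
        return compute_optical_index(scene, upper, mndwi_swir=mndwi_swir)
    if upper == "TCWI":
        return tasseled_cap_wetness(scene, tcwi_coefficients)
    if upper in ("NDIFF", "NRATIO"):
        return compute_sar_index(scene, upper)
    raise ValueError(f"unknown variable {name!r}")


def build_feature_stack(composites: dict[str, CompositeScene], variables: list[str], *,
                        mndwi_swir: str = "B11",
                        tcwi_coefficients: dict[str, float] | None = None) -> FeatureStack:
    """Assemble the classifier's predictor stack from seasonal composites.

    ``variables`` are season-qualified names such as ``"NDVI_wet"`` or
    ``"B8_dry"``; an unqualified name is resolved against the ``"annual"``
    composite.  Order is preserved; duplicates are an error.
    """
    if not variables:
        raise ValueError("empty feature set requested")
    if len(set(variables)) != len(variables):
        raise ValueError("duplicate variable names requested")
    features: list[tuple[str, RasterLayer]] = []
    zone = next(iter(composites.values())).zone if composites else "TW"
    for var in variables:
        base, sep, season = var.rpartition("_")
        if sep and season in composites:
            scene = composites[season]
            raw = base
        elif "annual" in composites:
            scene, raw = composites["annual"], var
        else:
            raise ValueError(f"variable {var!r} names no available season (have {sorted(composites)})")
        layer = compute_variable(scene, raw, mndwi_swir=mndwi_swir, tcwi_coefficients=tcwi_coefficients)
        features.append((var, layer))
    return FeatureStack(features, zone=zone)
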