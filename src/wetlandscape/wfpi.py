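"""Wetland Fragmentation and Population Index (WFPI).

The index asks where wetland patchiness coincides with people.  Both inputs
live on the same coarse grid (10 km in the continental setting): a fragment
count per cell and a population per cell.  Each is rescaled to [0, 1] with a
fuzzy linear membership (0 at the layer minimum, 1 at the maximum), and the
two memberships are combined with the fuzzy AND — the cellwise minimum — so
a cell scores high only when it is BOTH highly fragmented and densely
populated.  Threat categories follow fixed index thresholds: heavy above
0.5, moderate in the closed interval [0.3, 0.5], low below.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids_io import GridSpec, RasterLayer

__all__ = [
    "MembershipLayer",
    "aggregate_population",
    "fuzzy_linear_membership",
    "fuzzy_and_overlay",
    "fuzzy_or_overlay",
    "wetland_area_per_cell",
    "threat_summary",
    "ThreatSummary",
]


@dataclass
class MembershipLayer:
    """A grid layer rescaled to [0, 1], with the bounds used on record."""

    layer: RasterLayer
    source: str  # "population" | "fragmentation" | other
    bounds: tuple[float, float]


def aggregate_population(pop: RasterLayer, grid: GridSpec, method: str = "sum") -> RasterLayer:
    """Population per coarse grid cell from a fine persons-per-cell raster.

    Default is the sum of constituent counts; ``method="mean"`` gives the
    average instead (under auto membership bounds both yield the same WFPI,
    the two being related by a positive linear rescaling).  Nodata fine
    cells are treated as 0 persons and a warning is emitted.
    """
    if method not in ("sum", "mean"):
        raise ValueError("method must be sum|mean")
    t = pop.transform
    if t.dx != t.dy:
        raise ValueError("population raster cells must be square")
    factor = grid.cell_size / t.dx
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError("grid cell size must be a positive multiple of the population cell size")
    factor = int(round(factor))
    vals = np.asarray(pop.values, dtype=float)
    if np.any(vals[pop.mask()] < 0):
        raise ValueError("negative population counts")
    invalid = ~pop.mask()
    if invalid.any():
        warnings.warn(f"{int(invalid.sum())} nodata population cells treated as 0 persons")
        vals = np.where(invalid, 0.0, vals)
    nrows, ncols = vals.shape
    out = np.zeros((grid.nrows, grid.ncols), dtype=float)
    denom = np.zeros_like(out)
    rr = np.arange(nrows) // factor
    cc = np.arange(ncols) // factor
    np.add.at(out, (rr[:, None].repeat(ncols, 1), cc[None, :].repeat(nrows, 0)), vals)
    np.add.at(denom, (rr[:, None].repeat(ncols, 1), cc[None, :].repeat(nrows, 0)), 1.0)
    if method == "mean":
        out = np.divide(out, denom, out=np.zeros_like(out), where=denom > 0)
    return RasterLayer(out, grid.transform(), grid.crs, nodata=None)


def fuzzy_linear_membership(layer: RasterLayer, bounds: tuple[float, float] | str = "auto",
                            source: str = "layer") -> MembershipLayer:
    """Linear rescale of a grid layer onto [0, 1].

    With ``bounds="auto"`` the layer's own non-nodata minimum maps to 0 and
    its maximum to 1; explicit ``(min, max)`` bounds are clamped, so values
    outside them saturate at 0 or 1.  A constant layer has no defined linear
    membership and is rejected.
    """
    vals = np.asarray(layer.values, dtype=float)
    valid = layer.mask()
    if bounds == "auto":
        lo, hi = float(np.min(vals[valid])), float(np.max(vals[valid]))
    else:
        lo, hi = float(bounds[0]), float(bounds[1])
    if not lo < hi:
        raise ValueError(
            f"degenerate membership bounds for {source!r} layer: min == max == {lo} (constant layer?)"
        )
    mu = np.clip((vals - lo) / (hi - lo), 0.0, 1.0)
    mu[~valid] = np.nan
    out = RasterLayer(mu, layer.transform, layer.crs, nodata=np.nan)
    return MembershipLayer(out, source=source, bounds=(lo, hi))


def _combine(a: MembershipLayer, b: MembershipLayer, op) -> RasterLayer:
    la, lb = a.layer, b.layer
    if la.shape != lb.shape or la.transform != lb.transform:
        raise ValueError("membership layers are not co-registered")
    va = np.asarray(la.values, dtype=float)
    vb = np.asarray(lb.values, dtype=float)
    out = op(va, vb)
    out[~(la.mask() & lb.mask())] = np.nan
    return RasterLayer(out, la.transform, la.crs, nodata=np.nan)


def fuzzy_and_overlay(a: MembershipLayer, b: MembershipLayer) -> RasterLayer:
    """Fuzzy AND: the cellwise minimum of the two memberships (the WFPI when
    the inputs are the fragmentation and population memberships)."""
    return _combine(a, b, np.minimum)


def fuzzy_or_overlay(a: MembershipLayer, b: MembershipLayer) -> RasterLayer:
    """Fuzzy OR (cellwise maximum) — provided for contrast experiments."""
    return _combine(a, b, np.maximum)


def wetland_area_per_cell(wetland_map: RasterLayer, grid: GridSpec) -> RasterLayer:
    """Wetland area (km²) per coarse cell from the fine classified map."""
    vals = np.asarray(wetland_map.values)
    wet = wetland_map.mask() & (vals > 0)
    f = grid.fine_factor
    out = np.zeros((grid.nrows, grid.ncols), dtype=float)
    rr, cc = np.nonzero(wet)
    cell_km2 = wetland_map.transform.cell_area() / 1e6
    np.add.at(out, (rr // f, cc // f), cell_km2)
    return RasterLayer(out, grid.transform(), grid.crs, nodata=None)


@dataclass
class ThreatSummary:
    """Wetland area by threat category plus the top-ranked cells table."""

    heavy_km2: float
    moderate_km2: float
    low_km2: float
    top_cells: pd.DataFrame  # row, col, population, fragments, wfpi

    def to_json_dict(self) -> dict:
        return {
            "heavy_km2": self.heavy_km2,
            "moderate_km2": self.moderate_km2,
            "low_km2": self.low_km2,
            "top_cells": self.top_cells.to_dict(orient="records"),
        }


def threat_summary(wfpi: RasterLayer, wetland_area: RasterLayer,
                   population: RasterLayer | None = None,
                   fragments: RasterLayer | None = None,
                   thresholds: tuple[float, float] = (0.3, 0.5),
                   top_n: int = 10) -> ThreatSummary:
    """Wetland area under heavy / moderate / low human-interaction threat.

    Heavy: WFPI strictly above the upper threshold.  Moderate: WFPI in the
    closed interval [lower, upper].  Low: below the lower threshold.  Also
    returns the ``top_n`` cells ranked by WFPI with their population and
    fragment counts, in the shape of a hotspot table.
    """
    lo, hi = thresholds
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("thresholds must be strictly increasing within [0, 1]")
    w = np.asarray(wfpi.values, dtype=float)
    area = np.asarray(wetland_area.values, dtype=float)
    if w.shape != area.shape:
        raise ValueError("WFPI and wetland-area layers are not co-registered")
    valid = wfpi.mask()
    heavy = valid & (w > hi)
    moderate = valid & (w >= lo) & (w <= hi)
    low = valid & (w < lo)
    order = np.argsort(np.where(valid, w, -np.inf), axis=None)[::-1][:top_n]
    rows, cols = np.unravel_index(order, w.shape)
    table = pd.DataFrame({
        "row": rows,
        "col": cols,
        "population": (np.asarray(population.values).ravel()[order] if population is not None else np.nan),
        "fragments": (np.asarray(fragments.values).ravel()[order] if fragments is not None else np.nan),
        "wfpi": w.ravel()[order],
    })
    return ThreatSummary(
        heavy_km2=float(area[heavy].sum()),
        moderate_km2=float(area[moderate].sum()),
        low_km2=float(area[low].sum()),
        top_cells=table,
    )
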