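"""Carbon stock and flux accounting for wetland areas.

Three bookkeeping operations, all linear in area and in the per-hectare
factors:

* stock:       C [t]        = area [ha] x stock factor [t C ha-1]
* condition:   flux [t yr-1] = sum over (zone, type) of EF x area, with the
               wetland either pristine (factors typically negative = uptake)
               or drained (positive = release);
* water table: flux as above but with the emission factor keyed by a
               six-level water-table code, -3 (deepest drainage, <= -70 cm)
               through 2 (ponding above +40 cm).

Factors are user-supplied tables (per climate zone and wetland type); the
package ships clearly labelled example tables only.  The sign convention is
positive = release to atmosphere, negative = net uptake.  CO2 equivalents of
carbon mass use the molecular-mass ratio 44/12 exactly, with no greenhouse
gas weighting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids_io import RasterLayer

__all__ = [
    "CO2_PER_C",
    "KM2_TO_HA",
    "WTL_CODES",
    "AreaTable",
    "FactorTable",
    "CarbonReport",
    "area_table_from_map",
    "area_shares",
    "carbon_stock",
    "emissions_ipcc",
    "emissions_wtl",
    "classify_wtl",
]

#: Exact molecular-mass ratio converting t C to t CO2.
CO2_PER_C = 44.0 / 12.0
KM2_TO_HA = 100.0
WTL_CODES = (-3, -2, -1, 0, 1, 2)

# Water-table class boundaries (cm; negative below surface, positive ponding).
# Code c applies on the half-open interval (lower, upper]; -3 is unbounded
# below, 2 unbounded above.
_WTL_UPPER_BOUNDS = [(-3, -70.0), (-2, -50.0), (-1, -30.0), (0, -5.0), (1, 40.0)]


@dataclass
class AreaTable:
    """Rows of (zone, wetland type, area km²), optionally per year."""

    frame: pd.DataFrame  # columns: zone, wetland_type, area_km2 [, year]

    def __post_init__(self) -> None:
        required = {"zone", "wetland_type", "area_km2"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"area table lacks columns {sorted(missing)}")
        if (self.frame["area_km2"] < 0).any():
            raise ValueError("areas must be non-negative")
        keys = [c for c in ("zone", "wetland_type", "year") if c in self.frame.columns]
        if self.frame.duplicated(subset=keys).any():
            raise ValueError("duplicate (zone, wetland_type[, year]) rows")

    @property
    def total_km2(self) -> float:
        return float(self.frame["area_km2"].sum())

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AreaTable":
        return cls(pd.read_csv(path, comment="#"))


@dataclass
class FactorTable:
    """Per (zone, wetland type, key) factor lookup with declared units.

    ``key`` is ``"stock"`` (t C ha-1), a condition name (``"pristine"`` or
    ``"drained"``, t C ha-1 yr-1) or a water-table code in -3..2 (units as
    declared per row).  ``"*"`` in the zone or type column is a wildcard.
    """

    frame: pd.DataFrame  # columns: zone, wetland_type, key, value, units

    def __post_init__(self) -> None:
        required = {"zone", "wetland_type", "key", "value", "units"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"factor table lacks columns {sorted(missing)}")
        for k in self.frame["key"]:
            ks = str(k)
            if ks in ("stock", "pristine", "drained"):
                continue
            try:
                code = int(ks)
            except ValueError:
                raise ValueError(f"unknown factor key {k!r}") from None
            if code not in WTL_CODES:
                raise ValueError(f"water-table code {code} outside {WTL_CODES}")

    def lookup(self, zone: str, wetland_type: str, key) -> float:
        f = self.frame
        key = str(key)
        match = f[(f["key"].astype(str) == key)
                  & (f["zone"].isin([zone, "*"]))
                  & (f["wetland_type"].isin([wetland_type, "*"]))]
        if match.empty:
            raise KeyError(f"no factor for (zone={zone}, type={wetland_type}, key={key})")
        # Specific rows beat wildcards
        exact = match[(match["zone"] == zone) & (match["wetland_type"] == wetland_type)]
        row = exact.iloc[0] if not exact.empty else match.iloc[0]
        return float(row["value"])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FactorTable":
        return cls(pd.read_csv(path, comment="#"))


@dataclass
class CarbonReport:
    """Per-(zone, type) carbon quantities plus totals.

    ``kind`` is "stock" (t C) or "flux" (t C yr-1 with a t CO2-eq yr-1
    companion).  Positive flux = release to atmosphere; negative = uptake.
    """

    rows: pd.DataFrame  # zone, wetland_type, area_ha, factor, value
    kind: str
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = float(self.rows["value"].sum())

    @property
    def total_co2e(self) -> float:
        if self.kind != "flux":
            raise ValueError("CO2 equivalents are defined for flux reports only")
        return self.total * CO2_PER_C

    def to_frame(self) -> pd.DataFrame:
        out = self.rows.copy()
        if self.kind == "flux":
            out["value_co2e"] = out["value"] * CO2_PER_C
        return out


def area_table_from_map(wetland_map: RasterLayer, zones: RasterLayer,
                        class_names: dict[int, str], zone_names: dict[int, str],
                        allow_non_equal_area: bool = False) -> AreaTable:
    """Tabulate wetland area per (climate zone, wetland type) from rasters.

    Both rasters must be co-registered and in an equal-area CRS (cell count
    x cell area is only an area there); pass ``allow_non_equal_area=True``
    to override at your own risk.
    """
    if not wetland_map.same_frame(zones):
        raise ValueError("wetland map and zone map are not co-registered")
    from .grids_io import DEFAULT_EQUAL_AREA_CRS, SYNTHETIC_CRS

    if wetland_map.crs not in (DEFAULT_EQUAL_AREA_CRS, SYNTHETIC_CRS) and not allow_non_equal_area:
        raise ValueError(
            f"CRS {wetland_map.crs!r} is not a recognised equal-area CRS; area arithmetic would be wrong"
        )
    wet_vals = np.asarray(wetland_map.values)
    zone_vals = np.asarray(zones.values)
    cell_km2 = wetland_map.transform.cell_area() / 1e6
    sel = wetland_map.mask() & zones.mask() & (wet_vals > 0)
    rows = []
    if sel.any():
        pairs, counts = np.unique(np.stack([zone_vals[sel], wet_vals[sel]]), axis=1, return_counts=True)
        for (z, c), n in zip(pairs.T, counts):
            rows.append({
                "zone": zone_names.get(int(z), str(int(z))),
                "wetland_type": class_names.get(int(c), str(int(c))),
                "area_km2": float(n) * cell_km2,
            })
    frame = pd.DataFrame(rows, columns=["zone", "wetland_type", "area_km2"])
    return AreaTable(frame)


def area_shares(table: AreaTable) -> pd.DataFrame:
    """Percentage of total wetland area per wetland type.

    Returns one row per type with the unrounded share and its nearest-integer
    rounding (the form such figures are usually quoted in).
    """
    total = table.total_km2
    if total <= 0:
        raise ValueError("total wetland area is zero; shares undefined")
    per_type = table.frame.groupby("wetland_type", sort=False)["area_km2"].sum()
    share = 100.0 * per_type / total
    return pd.DataFrame({
        "wetland_type": per_type.index,
        "area_km2": per_type.values,
        "share_pct": share.values,
        "share_pct_rounded": np.round(share.values).astype(int),
    }).reset_index(drop=True)


def _accumulate(areas: AreaTable, factors: FactorTable, key, kind: str) -> CarbonReport:
    rows = []
    missing = []
    for _, r in areas.frame.iterrows():
        try:
            factor = factors.lookup(r["zone"], r["wetland_type"], key)
        except KeyError:
            missing.append((r["zone"], r["wetland_type"]))
            continue
        area_ha = float(r["area_km2"]) * KM2_TO_HA
        rows.append({
            "zone": r["zone"],
            "wetland_type": r["wetland_type"],
            "area_ha": area_ha,
            "factor": factor,
            "value": factor * area_ha,
        })
    if missing:
        raise KeyError(f"missing factor (key={key}) for: {missing}")
    frame = pd.DataFrame(rows, columns=["zone", "wetland_type", "area_ha", "factor", "value"])
    return CarbonReport(frame, kind=kind)


def carbon_stock(areas: AreaTable, stocks: FactorTable) -> CarbonReport:
    """Total stored carbon: area [ha] x per-hectare stock, per (zone, type)."""
    return _accumulate(areas, stocks, "stock", kind="stock")


def emissions_ipcc(areas: AreaTable, efs: FactorTable, condition: str) -> CarbonReport:
    """Condition-based annual flux: EF(zone, type, condition) x area.

    ``condition`` is ``"pristine"`` or ``"drained"``.  Factors carry their
    sign, so pristine uptake comes out negative from the same sum.
    """
    if condition not in ("pristine", "drained"):
        raise ValueError(f"condition must be pristine|drained, got {condition!r}")
    return _accumulate(areas, efs, condition, kind="flux")


def emissions_wtl(areas: AreaTable, efs: FactorTable, wtl: int) -> CarbonReport:
    """Water-table-level annual flux: EF(zone, type, WTL code) x area."""
    if wtl not in WTL_CODES:
        raise ValueError(f"water-table code must be one of {WTL_CODES}, got {wtl}")
    return _accumulate(areas, efs, int(wtl), kind="flux")


def classify_wtl(depth_cm: float) -> int:
    """Six-level water-table code for a depth in cm (negative below surface).

    Boundaries attach to the drier interval: -70 maps to -3 (the deepest
    class is depth <= -70), -50 to -2, and so on; anything above +40 cm of
    ponding is code 2.  Deeper water tables never map to a wetter code.
    """
    if not math.isfinite(depth_cm):
        raise ValueError("water-table depth must be finite")
    for code, upper in _WTL_UPPER_BOUNDS:
        if depth_cm <= upper:
            return code
    return 2
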