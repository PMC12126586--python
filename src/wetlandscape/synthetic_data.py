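"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates, at desk scale, the inputs of a continental wetland
survey: patchy multi-class wetland truth maps with a known fragment
inventory, class-conditional optical/SAR scenes with wet/dry seasonal
contrast, population surfaces clustered around city centres, and labelled
control points.  Every operation takes an explicit seed and is exactly
reproducible.

The truth map's fragment inventory is computed by an internal iterative
flood fill — a deliberately independent code path from the production
fragment labeling — so pipeline fragment counts can be checked against an
oracle that shares no code with them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .classify import CLASS_CODES, WETLAND_CLASSES, ControlPointSet
from .grids_io import RasterLayer, SYNTHETIC_CRS, Transform
from .indices import CompositeScene, OPTICAL_BANDS, SAR_BANDS

__all__ = [
    "SceneModel",
    "PopulationModel",
    "TruthInventory",
    "default_scene_model",
    "generate_truth_map",
    "generate_scene",
    "generate_population",
    "generate_control_points",
]

ALL_BANDS = OPTICAL_BANDS + SAR_BANDS


@dataclass
class SceneModel:
    """Class-conditional band signatures and the patch process.

    ``class_means[cls][season][band]`` are reflectance / linear-power
    backscatter means; ``class_sds[cls][band]`` the within-class standard
    deviations (independent Gaussian noise per band, truncated at 0).
    ``prevalences`` give each wetland class's areal fraction; the remainder
    is non-wetland background.  ``smoothing_length`` (cells) controls patch
    size in the smoothed-noise truth process.
    """

    class_means: dict[str, dict[str, dict[str, float]]]
    class_sds: dict[str, dict[str, float]]
    prevalences: dict[str, float]
    smoothing_length: float = 3.0
    cell_size: float = 50.0  # metres

    def __post_init__(self) -> None:
        for cls, sds in self.class_sds.items():
            for band, sd in sds.items():
                if sd <= 0:
                    raise ValueError(f"sd must be > 0 (class {cls}, band {band})")
        for cls, p in self.prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {cls} outside [0, 1]")
        if sum(self.prevalences.values()) > 1.0 + 1e-9:
            raise ValueError("class prevalences sum to more than 1")


@dataclass
class PopulationModel:
    """Gaussian city kernels over a uniform background, with additive noise.

    ``centers`` rows are (row, col, peak persons per cell at the centre);
    ``kernel_scale`` is the kernel sigma in cells.
    """

    centers: list[tuple[float, float, float]] = field(default_factory=list)
    kernel_scale: float = 3.0
    background: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for r, c, peak in self.centers:
            if peak < 0:
                raise ValueError("city peak density must be >= 0")
        if self.background < 0 or self.noise_sd < 0:
            raise ValueError("background density and noise sd must be >= 0")


def default_scene_model(separation_sd: float = 8.0, prevalence: float = 0.09,
                        cell_size: float = 50.0, smoothing_length: float = 2.5) -> SceneModel:
    """The default study conditions: 5 wetland classes plus background with
    class-mean band separation of ``separation_sd`` within-class standard
    deviations, and a wet/dry contrast on the water-sensitive bands.

    Reflectance means live on a plausible [0.02, 0.6] scale; VV/VH are linear
    power.  Each class occupies a distinct corner of band space (means are
    staggered across bands so no two classes share a signature).
    """
    sd = 0.02
    classes = list(WETLAND_CLASSES)  # background first, then the 5 wetland types
    means: dict[str, dict[str, dict[str, float]]] = {}
    sds: dict[str, dict[str, float]] = {}
    step = separation_sd * sd
    for ci, cls in enumerate(classes):
        means[cls] = {}
        sds[cls] = {band: sd for band in ALL_BANDS}
        for season in ("wet", "dry"):
            band_means = {}
            for bi, band in enumerate(ALL_BANDS):
                # stagger class means across bands; keep everything positive
                level = 0.05 + step * (((ci * 3 + bi) % (len(classes) + 1)))
                if season == "wet" and cls in ("marsh", "seasonal", "mangrove") and band in ("B8", "B11", "VV"):
                    level += 2.0 * step  # wet-season contrast for flood-driven classes
                band_means[band] = level
            means[cls][season] = band_means
    prevalences = {cls: prevalence for cls in classes if cls != "non-wetland"}
    return SceneModel(means, sds, prevalences, smoothing_length=smoothing_length, cell_size=cell_size)


# --------------------------------------------------------------------------
# Independent fragment oracle (iterative flood fill; no shared code with the
# fragmentation module).

def _flood_fill_label(values: np.ndarray, connectivity: int) -> tuple[np.ndarray, dict[int, int]]:
    nrows, ncols = values.shape
    labels = np.zeros((nrows, ncols), dtype=np.int32)
    if connectivity == 4:
        neighbours = ((-1, 0), (1, 0), (0, -1), (0, 1))
    else:
        neighbours = tuple((dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0))
    next_id = 0
    id_class: dict[int, int] = {}
    for r0 in range(nrows):
        for c0 in range(ncols):
            if values[r0, c0] <= 0 or labels[r0, c0] != 0:
                continue
            next_id += 1
            cls = int(values[r0, c0])
            id_class[next_id] = cls
            stack = [(r0, c0)]
            labels[r0, c0] = next_id
            while stack:
                r, c = stack.pop()
                for dr, dc in neighbours:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nrows and 0 <= cc < ncols and labels[rr, cc] == 0 and values[rr, cc] == cls:
                        labels[rr, cc] = next_id
                        stack.append((rr, cc))
    return labels, id_class


@dataclass
class TruthInventory:
    """Exact fragment bookkeeping for a generated truth map (oracle path)."""

    labels: np.ndarray
    id_class: dict[int, int]
    connectivity: int

    @property
    def n_fragments(self) -> int:
        return len(self.id_class)

    def fragments_per_class(self) -> dict[str, int]:
        names = {code: name for name, code in CLASS_CODES.items()}
        out: dict[str, int] = {}
        for cls in self.id_class.values():
            name = names[cls]
            out[name] = out.get(name, 0) + 1
        return out

    def counts_per_cell(self, factor: int, nrows: int, ncols: int) -> np.ndarray:
        """Distinct fragments per coarse cell (presence counting)."""
        counts = np.zeros((nrows, ncols), dtype=np.int32)
        seen: set[tuple[int, int, int]] = set()
        fr, fc = self.labels.shape
        for r in range(fr):
            for c in range(fc):
                fid = int(self.labels[r, c])
                if fid > 0:
                    key = (r // factor, c // factor, fid)
                    if key not in seen:
                        seen.add(key)
                        counts[r // factor, c // factor] += 1
        return counts


def flood_fill_oracle(values: np.ndarray, connectivity: int = 4) -> TruthInventory:
    """Label same-class fragments by iterative flood fill (oracle path)."""
    labels, id_class = _flood_fill_label(np.asarray(values), connectivity)
    return TruthInventory(labels, id_class, connectivity)


# --------------------------------------------------------------------------
# Generators

def _transform_for(shape: tuple[int, int], cell_size: float) -> Transform:
    return Transform(0.0, shape[0] * cell_size, cell_size, cell_size)


def generate_truth_map(model: SceneModel, shape: tuple[int, int], seed: int = 0,
                       connectivity: int = 4,
                       rectangles: list[tuple[int, int, int, int, str]] | None = None
                       ) -> tuple[RasterLayer, TruthInventory]:
    """A categorical truth raster plus its exact fragment inventory.

    Default mode thresholds per-class smoothed Gaussian noise fields at each
    class's prevalence quantile (earlier classes claim contested cells).
    ``rectangles`` switches to a constructive mode placing axis-aligned
    patches ``(row0, row1, col0, col1, class)`` (half-open bounds) on empty
    background — handy when a test needs an exactly known fragment count.
    """
    rng = np.random.default_rng(seed)
    values = np.zeros(shape, dtype=np.int16)
    if rectangles is not None:
        for r0, r1, c0, c1, cls in rectangles:
            values[r0:r1, c0:c1] = CLASS_CODES[cls]
    else:
        claimed = np.zeros(shape, dtype=bool)
        for cls, prevalence in model.prevalences.items():
            if prevalence <= 0:
                continue
            fld = ndimage.gaussian_filter(rng.standard_normal(shape), model.smoothing_length)
            threshold = np.quantile(fld, 1.0 - prevalence)
            sel = (fld > threshold) & ~claimed
            values[sel] = CLASS_CODES[cls]
            claimed |= sel
    layer = RasterLayer(values, _transform_for(shape, model.cell_size), SYNTHETIC_CRS, nodata=-1)
    return layer, flood_fill_oracle(values, connectivity)


def generate_scene(truth: RasterLayer, model: SceneModel, season: str = "wet",
                   seed: int = 0, zone: str = "TW") -> CompositeScene:
    """Class-conditional Gaussian band values for every truth cell.

    Per cell, each band draws from N(mean(class, season, band), sd); optical
    reflectance and linear-power backscatter are truncated at 0.
    """
    if season not in ("wet", "dry"):
        raise ValueError("season must be wet|dry")
    rng = np.random.default_rng(seed)
    values = np.asarray(truth.values)
    names = {code: name for name, code in CLASS_CODES.items()}
    present = np.unique(values[truth.mask()])
    for code in present:
        cls = names.get(int(code))
        if cls is None or cls not in model.class_means:
            raise ValueError(f"truth class code {code} has no band parameters in the scene model")
        if season not in model.class_means[cls]:
            raise ValueError(f"class {cls} lacks {season}-season parameters")
    bands: dict[str, RasterLayer] = {}
    some_band_list = next(iter(model.class_means.values()))[season].keys()
    for band in some_band_list:
        out = np.empty(values.shape, dtype=np.float32)
        for code in present:
            cls = names[int(code)]
            mean = model.class_means[cls][season][band]
            sd = model.class_sds[cls][band]
            sel = values == code
            out[sel] = mean + sd * rng.standard_normal(int(sel.sum()))
        np.maximum(out, 0.0, out=out)
        bands[band] = RasterLayer(out, truth.transform, truth.crs, nodata=None)
    return CompositeScene(bands, season=season, zone=zone, sar_scale="linear")


def generate_population(model: PopulationModel, shape: tuple[int, int],
                        cell_size: float = 1000.0, seed: int = 0) -> RasterLayer:
    """Persons-per-cell raster: sum of Gaussian city kernels plus a uniform
    background and optional Gaussian noise, floored at 0."""
    rng = np.random.default_rng(seed)
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    out = np.full(shape, float(model.background))
    for r0, c0, peak in model.centers:
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        out += peak * np.exp(-d2 / (2.0 * model.kernel_scale**2))
    if model.noise_sd > 0:
        out += model.noise_sd * rng.standard_normal(shape)
    np.maximum(out, 0.0, out=out)
    return RasterLayer(out, _transform_for(shape, cell_size), SYNTHETIC_CRS, nodata=None)


def generate_control_points(truth: RasterLayer, n_per_class: int, seed: int = 0,
                            zone: str = "TW", label_noise: float = 0.0,
                            include_background: bool = True) -> ControlPointSet:
    """Sample ``n_per_class`` cells per class, uniformly without replacement.

    Points take the class of their cell (optional label noise flips a seeded
    fraction to a random other class).  Coordinates are cell centres.
    """
    rng = np.random.default_rng(seed)
    values = np.asarray(truth.values)
    t = truth.transform
    names = {code: name for name, code in CLASS_CODES.items()}
    codes = [int(c) for c in np.unique(values[truth.mask()])]
    if not include_background:
        codes = [c for c in codes if c != 0]
    rows = []
    for code in codes:
        rset = np.argwhere(values == code)
        if len(rset) < n_per_class:
            raise ValueError(
                f"class {names.get(code, code)} has only {len(rset)} cells; cannot draw {n_per_class}"
            )
        pick = rset[rng.choice(len(rset), size=n_per_class, replace=False)]
        for r, c in pick:
            x = t.x0 + (c + 0.5) * t.dx
            y = t.y0 - (r + 0.5) * t.dy
            rows.append({"x": x, "y": y, "cls": names[code], "zone": zone})
    frame = pd.DataFrame(rows)
    if label_noise > 0:
        flip = rng.random(len(frame)) < label_noise
        legend = list(WETLAND_CLASSES)
        for i in np.nonzero(flip)[0]:
            current = frame.at[i, "cls"]
            others = [c for c in legend if c != current]
            frame.at[i, "cls"] = others[rng.integers(len(others))]
    return ControlPointSet(frame)
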