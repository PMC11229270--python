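"""Tiles, label maps and the global segmentation map (GSM).

The GSM is a class-labeled raster over a whole-slide image with one
cell per non-overlapping tile: each 256x256 tile (configurable for
small synthetic slides) is classified into one of six tissue classes
and the argmax class becomes the cell value. All architectural analysis
operates on this raster.

Conventions: coordinates are 0-based and row-major; tile windows are
half-open ``[row0, row0+size) x [col0, col0+size)``; connected
components use 8-connectivity; argmax ties break to the lowest class
code.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import color as skcolor
from skimage.filters import threshold_otsu

__all__ = [
    "TissueClass",
    "LabelMap",
    "TileRef",
    "SlideRecord",
    "PatientRecord",
    "Component",
    "LabelMapFormatError",
    "SamplingError",
    "tissue_mask",
    "tile_grid",
    "assemble_gsm",
    "connected_components",
    "boundary_pixels",
    "sample_tiles",
    "read_label_map",
    "write_label_map",
    "read_cohort_csv",
    "write_cohort_csv",
    "BASE_SCALE",
]

#: Scanner base magnification assumed for scale arithmetic. A tile at
#: scale s covers (size_px * BASE_SCALE / s)^2 source pixels resampled
#: to size_px^2.
BASE_SCALE = 20.0


class TissueClass(enum.IntEnum):
    """Fixed six-class tissue legend.

    BG = background / glass, LT = peri-tumor liver tissue,
    TT_P / TT_S = tumor parenchyma / stroma (together: tumor tissue TT),
    HN = hemorrhage and necrosis, TLS = tertiary lymphoid structure.
    """

    BG = 0
    LT = 1
    TT_P = 2
    TT_S = 3
    HN = 4
    TLS = 5


#: Tumor tissue is the union of parenchyma and stroma.
TT_CLASSES = (TissueClass.TT_P, TissueClass.TT_S)

_CANONICAL_LEGEND = {c.name: int(c) for c in TissueClass}


class LabelMapFormatError(ValueError):
    """Raised on malformed label-map files or invalid class codes."""


class SamplingError(RuntimeError):
    """Raised when a tile-sampling strategy has no eligible cells."""


@dataclass
class LabelMap:
    """A 2-D grid of tissue-class codes.

    ``cell_size_px`` is the number of source pixels per grid cell: 1 for
    a pixel-level ground-truth map, the tile size for a GSM.
    """

    grid: np.ndarray
    cell_size_px: int = 1
    scale: float = BASE_SCALE
    slide_id: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise LabelMapFormatError("label-map grid must be 2-D")
        if self.cell_size_px < 1:
            raise LabelMapFormatError("cell_size_px must be >= 1")
        valid = np.isin(self.grid, [int(c) for c in TissueClass])
        if not valid.all():
            bad = np.unique(self.grid[~valid])
            raise LabelMapFormatError(f"invalid class codes in grid: {bad.tolist()}")
        self.grid = self.grid.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def class_counts(self) -> np.ndarray:
        """Pixel/cell count per class code (length 6)."""
        return np.bincount(self.grid.ravel(), minlength=len(TissueClass))

    def mask(self, classes) -> np.ndarray:
        """Boolean mask of cells whose class is in ``classes``."""
        codes = [int(c) for c in np.atleast_1d(classes)]
        return np.isin(self.grid, codes)


@dataclass(frozen=True)
class TileRef:
    """Reference to one non-overlapping tile window of a slide."""

    slide_id: str
    row0: int
    col0: int
    size_px: int = 256
    scale: float = BASE_SCALE
    label: TissueClass | None = None


@dataclass
class SlideRecord:
    slide_id: str
    patient_id: str
    image_path: str = ""
    label_map: LabelMap | None = None


@dataclass
class PatientRecord:
    """Survival ground truth for one patient."""

    patient_id: str
    time_months: float
    event: int
    slide_ids: list = field(default_factory=list)
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.time_months) or self.time_months <= 0:
            raise ValueError("time_months must be finite and > 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")
        if not self.slide_ids:
            raise ValueError("patient must own at least one slide")


@dataclass
class Component:
    """A connected component of one tissue class."""

    tissue_class: TissueClass
    pixels: np.ndarray  # (k, 2) array of (row, col)
    centroid: tuple[float, float]
    area_px: int


# ---------------------------------------------------------------------------
# Foreground detection
# ---------------------------------------------------------------------------

def tissue_mask(rgb: np.ndarray) -> np.ndarray:
    """Foreground mask by Otsu thresholding of the HSV saturation channel.

    Glass background is bright and unsaturated; stained tissue is
    saturated. Pixels with saturation above the Otsu threshold are
    foreground. A constant image has no defined threshold and yields an
    all-background mask with a warning.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    sat = skcolor.rgb2hsv(rgb)[:, :, 1]
    if np.ptp(sat) == 0:
        warnings.warn("constant image: Otsu threshold undefined; all background")
        return np.zeros(sat.shape, dtype=bool)
    thr = threshold_otsu(sat)
    return sat > thr


# ---------------------------------------------------------------------------
# Tiling and GSM assembly
# ---------------------------------------------------------------------------

def tile_grid(slide_h: int, slide_w: int, size_px: int = 256,
              scale: float = BASE_SCALE, slide_id: str = "") -> list[TileRef]:
    """Non-overlapping tile windows in row-major order.

    Partial windows at the right/bottom edges are dropped.
    """
    if size_px < 1:
        raise ValueError("size_px must be >= 1")
    n_rows, n_cols = slide_h // size_px, slide_w // size_px
    if n_rows == 0 or n_cols == 0:
        warnings.warn("slide smaller than one tile; empty grid")
        return []
    return [
        TileRef(slide_id=slide_id, row0=r * size_px, col0=c * size_px,
                size_px=size_px, scale=scale)
        for r in range(n_rows) for c in range(n_cols)
    ]


def assemble_gsm(tile_refs: list[TileRef], class_probs: np.ndarray,
                 scale: float | None = None) -> LabelMap:
    """Build the GSM from per-tile class probability vectors.

    One cell per tile; the cell value is the argmax class, with ties
    broken to the lowest class code. Tile order is irrelevant: cells are
    placed by tile coordinates.
    """
    if not tile_refs:
        raise ValueError("no tiles")
    class_probs = np.asarray(class_probs, dtype=float)
    if class_probs.shape[0] != len(tile_refs):
        raise ValueError("one probability vector per tile required")
    if np.any(np.abs(class_probs.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probability vectors must sum to 1")
    slide_ids = {t.slide_id for t in tile_refs}
    if len(slide_ids) > 1:
        raise ValueError(f"tiles from mixed slides: {sorted(slide_ids)}")
    size = tile_refs[0].size_px
    rows = np.array([t.row0 // size for t in tile_refs])
    cols = np.array([t.col0 // size for t in tile_refs])
    grid = np.zeros((rows.max() + 1, cols.max() + 1), dtype=np.uint8)
    # np.argmax returns the first maximum -> lowest class code on ties
    grid[rows, cols] = np.argmax(class_probs, axis=1).astype(np.uint8)
    return LabelMap(grid=grid, cell_size_px=size,
                    scale=scale if scale is not None else tile_refs[0].scale,
                    slide_id=tile_refs[0].slide_id)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

_STRUCT8 = np.ones((3, 3), dtype=bool)


def connected_components(label_map: LabelMap, cls: TissueClass) -> list[Component]:
    """8-connected components of one class, ordered by (min row, min col).

    Centroids are unweighted means of the component's pixel coordinates.
    """
    mask = label_map.mask(cls)
    labeled, n = ndimage.label(mask, structure=_STRUCT8)
    comps = []
    for obj_slice, lab in zip(ndimage.find_objects(labeled), range(1, n + 1)):
        sub = labeled[obj_slice] == lab
        rr, cc = np.nonzero(sub)
        rr = rr + obj_slice[0].start
        cc = cc + obj_slice[1].start
        comps.append(Component(
            tissue_class=TissueClass(int(cls)),
            pixels=np.column_stack([rr, cc]),
            centroid=(float(rr.mean()), float(cc.mean())),
            area_px=int(rr.size),
        ))
    comps.sort(key=lambda c: (int(c.pixels[:, 0].min()), int(c.pixels[:, 1].min())))
    return comps


def boundary_pixels(label_map: LabelMap, region) -> np.ndarray:
    """Boundary of a region: its cells with an 8-neighbor outside it.

    The image frame is treated as inside the region, so a region that
    reaches the map border contributes no frame-edge pixels. Returns a
    boolean mask. Warns (and returns an empty mask) when the region is
    absent from the map.
    """
    mask = label_map.mask(region)
    if not mask.any():
        warnings.warn("region absent from map; empty boundary")
        return np.zeros(mask.shape, dtype=bool)
    return boundary_of_mask(mask)


def boundary_of_mask(mask: np.ndarray) -> np.ndarray:
    """Inner 8-neighborhood boundary of a boolean mask (frame excluded)."""
    eroded = ndimage.minimum_filter(mask.astype(np.uint8), size=3,
                                    mode="constant", cval=1)
    return mask & (eroded == 0)


# ---------------------------------------------------------------------------
# Tile sampling
# ---------------------------------------------------------------------------

_STRATEGIES = {
    "global_random": (TissueClass.LT, TissueClass.TT_P, TissueClass.TT_S,
                      TissueClass.HN, TissueClass.TLS),
    "tumor_only": TT_CLASSES,
    "parenchyma_only": (TissueClass.TT_P,),
}


def sample_tiles(label_map: LabelMap, strategy: str, n: int,
                 scale: float = 4.0, seed: int = 0) -> list[TileRef]:
    """Sample tile references from a GSM by region eligibility.

    Strategies: ``global_random`` (any non-background cell),
    ``tumor_only`` (TT-p or TT-s), ``parenchyma_only`` (TT-p).
    Sampling is without replacement; if fewer than ``n`` cells are
    eligible, sampling falls back to with-replacement with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if strategy not in _STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    eligible = np.flatnonzero(label_map.mask(_STRATEGIES[strategy]).ravel())
    if eligible.size == 0:
        raise SamplingError(f"no eligible cells for strategy {strategy!r}")
    rng = np.random.default_rng(seed)
    if eligible.size >= n:
        chosen = rng.choice(eligible, size=n, replace=False)
    else:
        warnings.warn(
            f"only {eligible.size} eligible cells for n={n}; "
            "sampling with replacement")
        chosen = rng.choice(eligible, size=n, replace=True)
    n_cols = label_map.shape[1]
    size = label_map.cell_size_px
    refs = []
    for flat in chosen:
        r, c = int(flat) // n_cols, int(flat) % n_cols
        refs.append(TileRef(
            slide_id=label_map.slide_id, row0=r * size, col0=c * size,
            size_px=size, scale=scale,
            label=TissueClass(int(label_map.grid[r, c]))))
    return refs


# ---------------------------------------------------------------------------
# I/O: indexed PNG + JSON sidecar; cohort CSV
# ---------------------------------------------------------------------------

_PALETTE = {
    TissueClass.BG: (245, 245, 245),
    TissueClass.LT: (180, 120, 160),
    TissueClass.TT_P: (230, 200, 60),
    TissueClass.TT_S: (70, 90, 180),
    TissueClass.HN: (140, 90, 50),
    TissueClass.TLS: (60, 170, 80),
}


def write_label_map(label_map: LabelMap, path) -> None:
    """Write a label map as an indexed PNG with a JSON sidecar.

    The sidecar (``<path>.json``) carries the class legend, cell size,
    scale and slide id; round-trips are bit-exact.
    """
    path = Path(path)
    img = Image.fromarray(label_map.grid, mode="P")
    palette = []
    for c in TissueClass:
        palette.extend(_PALETTE[c])
    img.putpalette(palette)
    img.save(path)
    sidecar = {
        "legend": _CANONICAL_LEGEND,
        "cell_size_px": label_map.cell_size_px,
        "scale": label_map.scale,
        "slide_id": label_map.slide_id,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_label_map(path) -> LabelMap:
    """Read an indexed-PNG label map with its JSON sidecar.

    A legend whose names are permuted relative to the canonical codes is
    remapped; unknown class names or codes raise
    :class:`LabelMapFormatError`.
    """
    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise LabelMapFormatError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    legend = meta.get("legend")
    if legend is None:
        raise LabelMapFormatError("sidecar missing class legend")
    grid = np.asarray(Image.open(path).convert("P"), dtype=np.uint8)
    unknown = set(legend) - set(_CANONICAL_LEGEND)
    if unknown:
        raise LabelMapFormatError(f"unknown class names in legend: {sorted(unknown)}")
    remap = {}
    for name, code in legend.items():
        remap[int(code)] = _CANONICAL_LEGEND[name]
    present = np.unique(grid)
    bad = [int(v) for v in present if int(v) not in remap]
    if bad:
        raise LabelMapFormatError(f"file contains codes absent from legend: {bad}")
    if any(remap[k] != k for k in remap):
        lut = np.zeros(256, dtype=np.uint8)
        for src, dst in remap.items():
            lut[src] = dst
        grid = lut[grid]
    return LabelMap(grid=grid, cell_size_px=int(meta["cell_size_px"]),
                    scale=float(meta["scale"]), slide_id=meta.get("slide_id", ""))


_COHORT_COLUMNS = ["patient_id", "slide_id", "time_months", "event"]


def write_cohort_csv(patients: list[PatientRecord], path) -> None:
    """Write a patient/slide table: one row per slide, fixed columns
    patient_id, slide_id, time_months, event, then covariates."""
    import pandas as pd

    rows = []
    for p in patients:
        for sid in p.slide_ids:
            row = {"patient_id": p.patient_id, "slide_id": sid,
                   "time_months": p.time_months, "event": p.event}
            row.update(p.covariates)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort_csv(path) -> list[PatientRecord]:
    import pandas as pd

    df = pd.read_csv(path)
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    extra = [c for c in df.columns if c not in _COHORT_COLUMNS]
    patients = []
    for pid, grp in df.groupby("patient_id", sort=False):
        first = grp.iloc[0]
        patients.append(PatientRecord(
            patient_id=str(pid),
            time_months=float(first["time_months"]),
            event=int(first["event"]),
            slide_ids=[str(s) for s in grp["slide_id"]],
            covariates={c: first[c] for c in extra},
        ))
    return patients
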