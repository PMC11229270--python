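"""Post hoc interpretation of the GSM-based risk model.

Two complementary views of what drives the GSM score:

* occlusion sensitivity maps — slide a window over the GSM, replace it
  with background, and record the risk change; positive values mark
  risk-elevating regions ("red"), negative values protective ones
  ("blue");
* predefined architectural parameters — area ratios of HN/TLS/TT-p/TT-s
  to tumor or liver tissue, spatial dispersion of TLS and HN
  components, invasive-margin smoothness, and TLS-to-margin distances —
  each tested for survival association in univariate Cox models.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import cdist

from . import survival_stats as ss
from .segmap import (Component, LabelMap, TissueClass, boundary_of_mask,
                     connected_components)

__all__ = [
    "OcclusionConfig",
    "OcclusionMap",
    "ArchFeatureVector",
    "occlusion_map",
    "split_tls",
    "area_ratio",
    "distribution_variance",
    "margin_smoothness",
    "tls_margin_distances",
    "architectural_features",
    "feature_cox_table",
    "filled_tumor_mask",
    "ARCH_FEATURE_NAMES",
]

ARCH_FEATURE_NAMES = (
    "ratio_tls_intra_TT", "ratio_tls_peri_LT", "ratio_hn_TT",
    "ratio_ttp_TT", "ratio_tts_TT", "var_tls_intra", "var_hn",
    "margin_smoothness", "tls_margin_dist_min",
)


@dataclass
class OcclusionConfig:
    window_cells: int = 4
    stride_cells: int = 2
    replacement_class: TissueClass = TissueClass.BG

    def __post_init__(self) -> None:
        if self.window_cells < 1 or self.stride_cells < 1:
            raise ValueError("window and stride must be >= 1")
        if self.stride_cells > self.window_cells:
            raise ValueError("stride must not exceed window (full coverage)")


@dataclass
class OcclusionMap:
    """Per-cell risk attribution aligned to the GSM grid.

    value = risk(original) - risk(occluded): positive cells elevate
    risk when present, negative cells are protective.
    """

    grid: np.ndarray
    config: OcclusionConfig = field(default_factory=OcclusionConfig)


@dataclass
class ArchFeatureVector:
    ratio_tls_intra_TT: float = math.nan
    ratio_tls_peri_LT: float = math.nan
    ratio_hn_TT: float = math.nan
    ratio_ttp_TT: float = math.nan
    ratio_tts_TT: float = math.nan
    var_tls_intra: float = math.nan
    var_hn: float = math.nan
    margin_smoothness: float = math.nan
    tls_margin_dist_min: float = math.nan

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in ARCH_FEATURE_NAMES}


# ---------------------------------------------------------------------------
# Tumor mask and TLS split
# ---------------------------------------------------------------------------

def filled_tumor_mask(label_map: LabelMap) -> np.ndarray:
    """Tumor region: fill-holes of TT and HN cells.

    Intra-tumoral structures of other classes (TLS, enclosed liver)
    become part of the tumor zone via hole filling.
    """
    base = label_map.mask([TissueClass.TT_P, TissueClass.TT_S, TissueClass.HN])
    return ndimage.binary_fill_holes(base)


def split_tls(label_map: LabelMap) -> tuple[list[Component], list[Component]]:
    """Partition TLS components into intra- and peri-tumoral.

    A TLS component is intra-tumoral iff its centroid lies inside the
    filled tumor mask. Returns ``(intra, peri)``.
    """
    tumor = filled_tumor_mask(label_map)
    intra, peri = [], []
    for comp in connected_components(label_map, TissueClass.TLS):
        r = int(round(comp.centroid[0]))
        c = int(round(comp.centroid[1]))
        r = min(max(r, 0), tumor.shape[0] - 1)
        c = min(max(c, 0), tumor.shape[1] - 1)
        (intra if tumor[r, c] else peri).append(comp)
    return intra, peri


# ---------------------------------------------------------------------------
# Occlusion sensitivity
# ---------------------------------------------------------------------------

def _window_starts(extent: int, window: int, stride: int) -> list[int]:
    starts = list(range(0, extent - window + 1, stride))
    if starts and starts[-1] != extent - window:
        starts.append(extent - window)
    return starts


def occlusion_map(model, gsm: LabelMap, config: OcclusionConfig | None = None
                  ) -> OcclusionMap:
    """Occlusion sensitivity map of a GSM-scoring model.

    Each window is replaced with the replacement class (background by
    default, so no tissue signal is injected), the risk is recomputed,
    and the risk difference is recorded; cells covered by several
    windows average their deltas.
    """
    config = config or OcclusionConfig()
    h, w = gsm.shape
    if config.window_cells > h or config.window_cells > w:
        raise ValueError("occlusion window larger than the GSM grid")
    base_risk = float(model.score_gsm(gsm))
    acc = np.zeros((h, w), dtype=float)
    cnt = np.zeros((h, w), dtype=int)
    win = config.window_cells
    rep = np.uint8(int(config.replacement_class))
    for r0 in _window_starts(h, win, config.stride_cells):
        for c0 in _window_starts(w, win, config.stride_cells):
            occluded = gsm.grid.copy()
            occluded[r0:r0 + win, c0:c0 + win] = rep
            occ_map = LabelMap(grid=occluded, cell_size_px=gsm.cell_size_px,
                               scale=gsm.scale, slide_id=gsm.slide_id)
            delta = base_risk - float(model.score_gsm(occ_map))
            acc[r0:r0 + win, c0:c0 + win] += delta
            cnt[r0:r0 + win, c0:c0 + win] += 1
    assert (cnt > 0).all(), "stride invariant guarantees full coverage"
    return OcclusionMap(grid=acc / cnt, config=config)


# ---------------------------------------------------------------------------
# Architectural parameters
# ---------------------------------------------------------------------------

def area_ratio(label_map: LabelMap, numerator, denominator) -> float:
    """Pixel-count area ratio |numerator cells| / |denominator cells|.

    Returns NaN (missing) when the denominator is empty.
    """
    num = int(label_map.mask(numerator).sum())
    den = int(label_map.mask(denominator).sum())
    if den == 0:
        return math.nan
    return num / den


def distribution_variance(components: list[Component],
                          map_area: int) -> float:
    """Spatial dispersion of components over the map.

    Mean squared Euclidean distance of component centroids from their
    barycenter, normalized by the total map area so values are
    comparable across map sizes. One component gives 0; none gives NaN.
    """
    if not components:
        return math.nan
    cents = np.array([c.centroid for c in components], dtype=float)
    bary = cents.mean(axis=0)
    msd = float(np.mean(np.sum((cents - bary) ** 2, axis=1)))
    return msd / float(map_area)


def _boundary_path_length(mask: np.ndarray) -> float:
    """Euclidean length estimate of a mask's boundary (Crofton formula).

    A raw boundary-pixel count overestimates diagonal sections; the
    Crofton estimator is unbiased for smooth digital curves.
    """
    from skimage.measure import perimeter_crofton

    return float(perimeter_crofton(mask, directions=4))


def margin_smoothness(label_map: LabelMap) -> float:
    """Smoothness of the invasive margin, in (0, 1]; higher = smoother.

    Ratio of the convex-hull perimeter of the tumor mask to the length
    of its boundary pixel path. A convex tumor scores near 1;
    protrusions and depressions (tumor-budding-like irregularity)
    lengthen the boundary and lower the score.
    """
    tumor = filled_tumor_mask(label_map)
    if not tumor.any():
        return math.nan
    h, w = tumor.shape
    if (tumor[0, :].any() and tumor[-1, :].any()
            and tumor[:, 0].any() and tumor[:, -1].any()):
        warnings.warn("tumor mask touches all borders; hull degenerate")
    boundary = boundary_of_mask(tumor)
    blen = _boundary_path_length(tumor)
    if blen == 0:
        return 1.0
    pts = np.column_stack(np.nonzero(boundary)).astype(float)
    if pts.shape[0] < 3:
        return 1.0
    try:
        hull = ConvexHull(pts)
        hull_perimeter = float(hull.area)  # in 2-D, .area is the perimeter
    except Exception:
        return 1.0
    return float(min(1.0, max(1e-9, hull_perimeter / blen)))


def tls_margin_distances(label_map: LabelMap) -> list[float]:
    """Minimum distance from each TLS centroid to the invasive margin.

    The margin is the boundary pixel set of the filled tumor mask.
    Returns one distance per TLS component (ordered as
    :func:`segmap.connected_components`); empty when no TLS exists.
    """
    comps = connected_components(label_map, TissueClass.TLS)
    if not comps:
        return []
    tumor = filled_tumor_mask(label_map)
    boundary = boundary_of_mask(tumor)
    bp = np.column_stack(np.nonzero(boundary)).astype(float)
    if bp.size == 0:
        raise ValueError("tumor boundary empty; distances undefined")
    cents = np.array([c.centroid for c in comps], dtype=float)
    d = cdist(cents, bp).min(axis=1)
    return [float(x) for x in d]


def architectural_features(label_map: LabelMap) -> ArchFeatureVector:
    """The full predefined architectural parameter set for one GSM.

    Denominators: TT = TT-p + TT-s pixels for intra-tumoral ratios, LT
    pixels for the peri-TLS ratio. Undefined parameters (empty
    denominator, no components) are NaN-coded missing.
    """
    intra, peri = split_tls(label_map)
    tt_px = int(label_map.mask([TissueClass.TT_P, TissueClass.TT_S]).sum())
    lt_px = int(label_map.mask(TissueClass.LT).sum())
    area = label_map.grid.size
    intra_px = sum(c.area_px for c in intra)
    peri_px = sum(c.area_px for c in peri)
    fv = ArchFeatureVector()
    if tt_px > 0:
        fv.ratio_tls_intra_TT = intra_px / tt_px
        fv.ratio_hn_TT = area_ratio(label_map, TissueClass.HN,
                                    [TissueClass.TT_P, TissueClass.TT_S])
        fv.ratio_ttp_TT = area_ratio(label_map, TissueClass.TT_P,
                                     [TissueClass.TT_P, TissueClass.TT_S])
        fv.ratio_tts_TT = area_ratio(label_map, TissueClass.TT_S,
                                     [TissueClass.TT_P, TissueClass.TT_S])
    if lt_px > 0:
        fv.ratio_tls_peri_LT = peri_px / lt_px
    fv.var_tls_intra = distribution_variance(intra, area)
    fv.var_hn = distribution_variance(
        connected_components(label_map, TissueClass.HN), area)
    fv.margin_smoothness = margin_smoothness(label_map)
    dists = tls_margin_distances(label_map) if (intra or peri) else []
    fv.tls_margin_dist_min = min(dists) if dists else math.nan
    return fv


def feature_cox_table(features: pd.DataFrame, surv: ss.SurvivalData,
                      min_n: int = 10) -> pd.DataFrame:
    """Univariate Cox association of each architectural parameter.

    Each feature column is z-scored over its non-missing values and fit
    alone; the output table (feature, hr, ci_low, ci_high, p, n) is
    ready for forest plotting. Features with fewer than ``min_n``
    non-missing patients or no variance are skipped.
    """
    rows = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        keep = np.isfinite(x)
        if keep.sum() < min_n:
            warnings.warn(f"feature {col!r} skipped: <{min_n} usable values")
            continue
        xs = x[keep]
        if np.ptp(xs) == 0:
            warnings.warn(f"feature {col!r} skipped: constant")
            continue
        z = (xs - xs.mean()) / xs.std()
        sub = ss.SurvivalData(surv.times[keep], surv.events[keep])
        fit = ss.cox_fit(z[:, None], sub, names=[col])
        rows.append({
            "feature": col, "hr": float(fit.hr[0]),
            "ci_low": float(fit.ci95[0, 0]), "ci_high": float(fit.ci95[0, 1]),
            "p": float(fit.wald_p[0]), "beta": float(fit.beta[0]),
            "n": int(keep.sum()),
        })
    return pd.DataFrame(rows)
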