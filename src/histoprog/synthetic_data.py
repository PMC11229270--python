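"""Synthetic slides, cohorts and omics with planted ground truth.

Every downstream stage (segmentation maps, risk models, architectural
and nuclear interpretation, omics correlation) is exercised on data
from this module, which plants recoverable structure:

* label maps with a perturbed-ellipse tumor in liver background,
  necrosis and a stroma/parenchyma mosaic inside the tumor, and TLS
  discs placed intra- or peri-tumorally;
* H&E-like renders in which parenchyma nucleus size grows with a
  planted risk value;
* survival times drawn from an exponential model whose log-hazard is a
  linear combination of planted architectural/nuclear features, with
  independent censoring calibrated to a target rate;
* expression matrices in which chosen gene sets shift linearly with
  risk.

All randomness flows from a single root seed through named substreams,
so equal seeds give byte-identical outputs.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from .segmap import LabelMap, PatientRecord, SlideRecord, TissueClass, TileRef

__all__ = [
    "SlideSpec",
    "RenderSpec",
    "CohortSpec",
    "ExpressionSpec",
    "PlacementError",
    "generate_label_map",
    "render_slide",
    "render_tile",
    "generate_cohort",
    "generate_expression",
    "CohortTileSource",
    "substream",
    "NUCLEUS_RISK_COEF",
    "PLANTED_FEATURES",
]

#: Relative increase of mean parenchyma nucleus area per unit risk:
#: rendered area = nucleus_mean_area_px2 * (1 + NUCLEUS_RISK_COEF * risk).
NUCLEUS_RISK_COEF = 0.30

#: Names of the planted per-patient features the cohort hazard may load on.
PLANTED_FEATURES = (
    "intra_tls_ratio", "peri_tls_ratio", "necrosis_ratio",
    "stroma_ratio", "margin_irregularity", "nucleus_mean_area",
)


class PlacementError(RuntimeError):
    """Raised when slide geometry cannot be realized (e.g. TLS placement)."""


def substream(seed: int, *names) -> np.random.Generator:
    """Named, independent random substream derived from a root seed."""
    keys = [zlib.crc32(str(n).encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *keys]))


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class SlideSpec:
    """Geometry of one synthetic slide.

    The tumor is an ellipse with a radially perturbed contour
    ``rho(theta) <= 1 + a*sin(f*theta + phi)`` where the amplitude ``a``
    is ``boundary_irregularity`` (the planted margin-irregularity ground
    truth). Fractions partition the tumor: ``necrosis_fraction`` of
    tumor pixels become HN; of the remainder, ``stroma_fraction``
    becomes TT-s and the rest TT-p (as a smoothed random mosaic, so
    parenchyma and stroma interleave as in desmoplastic tumors).
    """

    height_px: int = 256
    width_px: int = 256
    tumor_axes: tuple[float, float] = (80.0, 70.0)
    boundary_irregularity: float = 0.08
    n_tls_intra: int = 1
    n_tls_peri: int = 1
    tls_radius_px: float = 10.0
    necrosis_fraction: float = 0.1
    stroma_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boundary_irregularity < 0:
            raise ValueError("boundary_irregularity must be >= 0")
        if not (0 <= self.necrosis_fraction <= 1):
            raise ValueError("necrosis_fraction must be in [0, 1]")
        if not (0 <= self.stroma_fraction <= 1):
            raise ValueError("stroma_fraction must be in [0, 1]")
        ar, ac = self.tumor_axes
        margin = 2 * self.tls_radius_px
        max_r = ar * (1 + self.boundary_irregularity)
        max_c = ac * (1 + self.boundary_irregularity)
        if (max_r + margin > self.height_px / 2
                or max_c + margin > self.width_px / 2):
            raise ValueError(
                "tumor ellipse (with irregularity) must fit inside the canvas "
                "with a liver margin of at least 2*tls_radius_px")


@dataclass
class RenderSpec:
    """Appearance of the H&E-like render.

    ``nucleus_density`` is nuclei per 256x256-pixel tile of each class
    (defaults give TLS at least 3x the LT density, mimicking lymphocyte
    aggregates). ``nucleus_shape_distortion`` is the amplitude of a
    third-order sinusoidal contour perturbation of each nucleus.
    """

    base_colors: dict = field(default_factory=lambda: {
        int(TissueClass.BG): (245, 245, 245),
        int(TissueClass.LT): (225, 170, 200),
        int(TissueClass.TT_P): (210, 150, 190),
        int(TissueClass.TT_S): (235, 185, 215),
        int(TissueClass.HN): (200, 120, 110),
        int(TissueClass.TLS): (215, 160, 200),
    })
    speckle_sd: dict = field(default_factory=lambda: {
        int(TissueClass.BG): 2.0,
        int(TissueClass.LT): 8.0,
        int(TissueClass.TT_P): 8.0,
        int(TissueClass.TT_S): 8.0,
        int(TissueClass.HN): 10.0,
        int(TissueClass.TLS): 8.0,
    })
    nucleus_density: dict = field(default_factory=lambda: {
        int(TissueClass.LT): 60.0,
        int(TissueClass.TT_P): 150.0,
        int(TissueClass.TT_S): 40.0,
        int(TissueClass.TLS): 500.0,
    })
    nucleus_mean_area_px2: float = 120.0
    nucleus_shape_distortion: float = 0.12
    intensity_contrast: float = 10.0
    tile_heterogeneity_sd: float = 0.15
    nucleus_color: tuple = (90, 60, 150)

    def __post_init__(self) -> None:
        for rgb in self.base_colors.values():
            if any(not (0 <= v <= 255) for v in rgb):
                raise ValueError("base colors must be in [0, 255]")
        if any(d < 0 for d in self.nucleus_density.values()):
            raise ValueError("nucleus densities must be >= 0")


@dataclass
class CohortSpec:
    """Survival cohort with a planted linear log-hazard.

    ``beta`` maps planted feature names (see :data:`PLANTED_FEATURES`)
    to coefficients applied to the standardized feature; survival times
    are Exponential(baseline_hazard * exp(eta)). Censoring is
    independent exponential, with its rate calibrated by bisection so
    the realized censored fraction is within +/-0.05 of
    ``censor_rate_target``.
    """

    n_patients: int = 100
    slides_per_patient: int = 1
    baseline_hazard: float = 0.02
    beta: dict = field(default_factory=dict)
    censor_rate_target: float = 0.3
    slide_jitter_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.slides_per_patient < 1:
            raise ValueError("slides_per_patient must be >= 1")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if not (0 < self.censor_rate_target < 1):
            raise ValueError("censor_rate_target must be in (0, 1)")
        unknown = set(self.beta) - set(PLANTED_FEATURES)
        if unknown:
            raise ValueError(f"unknown planted features: {sorted(unknown)}")


@dataclass
class ExpressionSpec:
    """Expression matrix with risk-linked gene-set shifts.

    Genes in set ``s`` get a mean log-expression shift of
    ``effect[s] * risk`` per sample; background genes are pure noise.
    """

    n_genes: int = 500
    gene_sets: dict = field(default_factory=dict)
    effect: dict = field(default_factory=dict)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for name, genes in self.gene_sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")
        names = set(self.gene_names())
        for sname, genes in self.gene_sets.items():
            missing = set(genes) - names
            if missing:
                raise ValueError(
                    f"set {sname!r} references unknown genes: {sorted(missing)}")

    def gene_names(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


# ---------------------------------------------------------------------------
# Label-map generation
# ---------------------------------------------------------------------------

def _smooth_noise(shape, rng, sigma):
    field_ = rng.standard_normal(shape)
    return ndimage.gaussian_filter(field_, sigma=sigma)


def generate_label_map(spec: SlideSpec) -> tuple[LabelMap, dict]:
    """Generate a pixel-level label map and its planted ground truth.

    Returns ``(label_map, ground_truth)`` where the ground truth records
    realized per-class area fractions, necrosis/stroma ratios, TLS
    centroids (intra and peri) and the contour irregularity amplitude.
    """
    rng = substream(spec.seed, "label_map")
    h, w = spec.height_px, spec.width_px
    cy, cx = h / 2.0, w / 2.0
    ar, ac = spec.tumor_axes

    rr, cc = np.mgrid[0:h, 0:w]
    dr = (rr - cy) / ar
    dc = (cc - cx) / ac
    rho = np.hypot(dr, dc)
    theta = np.arctan2(dr, dc)
    freq = int(rng.integers(5, 8))  # high enough that amplitude maps to concavity
    phase = rng.uniform(0, 2 * np.pi)
    tumor = rho <= 1.0 + spec.boundary_irregularity * np.sin(freq * theta + phase)

    grid = np.full((h, w), int(TissueClass.LT), dtype=np.uint8)
    frame = max(2, min(h, w) // 32)
    grid[:frame, :] = int(TissueClass.BG)
    grid[-frame:, :] = int(TissueClass.BG)
    grid[:, :frame] = int(TissueClass.BG)
    grid[:, -frame:] = int(TissueClass.BG)
    tumor &= grid == int(TissueClass.LT)

    n_tumor = int(tumor.sum())
    if n_tumor == 0:
        raise PlacementError("tumor ellipse produced no pixels")

    # necrosis: low-pass noise thresholded at the exact quantile
    hn_mask = np.zeros_like(tumor)
    if spec.necrosis_fraction > 0:
        noise = _smooth_noise((h, w), substream(spec.seed, "necrosis"), sigma=8)
        vals = noise[tumor]
        thr = np.quantile(vals, 1.0 - spec.necrosis_fraction)
        hn_mask = tumor & (noise > thr)

    # stroma/parenchyma mosaic over non-necrotic tumor
    viable = tumor & ~hn_mask
    stroma_mask = np.zeros_like(tumor)
    if spec.stroma_fraction > 0 and viable.any():
        noise = _smooth_noise((h, w), substream(spec.seed, "stroma"), sigma=4)
        vals = noise[viable]
        thr = np.quantile(vals, 1.0 - spec.stroma_fraction)
        stroma_mask = viable & (noise > thr)

    grid[viable] = int(TissueClass.TT_P)
    grid[stroma_mask] = int(TissueClass.TT_S)
    grid[hn_mask] = int(TissueClass.HN)

    # TLS placement by rejection sampling
    r_tls = spec.tls_radius_px
    dist_in = ndimage.distance_transform_edt(tumor)       # depth inside tumor
    lt_mask = grid == int(TissueClass.LT)
    dist_lt = ndimage.distance_transform_edt(lt_mask)     # depth inside liver
    intra_ok = dist_in > r_tls + 2
    peri_ok = dist_lt > r_tls + 2
    placed: list[tuple[float, float, bool]] = []
    rng_tls = substream(spec.seed, "tls")

    def _place(n, ok_mask, intra):
        coords = np.column_stack(np.nonzero(ok_mask))
        if n > 0 and coords.size == 0:
            raise PlacementError(
                f"no admissible {'intra' if intra else 'peri'}-tumor TLS "
                f"centers (radius {r_tls}px)")
        for _ in range(n):
            for _attempt in range(1000):
                y, x = coords[rng_tls.integers(coords.shape[0])]
                if all((y - py) ** 2 + (x - px) ** 2 > (2 * r_tls + 2) ** 2
                       for py, px, _ in placed):
                    placed.append((float(y), float(x), intra))
                    break
            else:
                raise PlacementError(
                    f"could not place {'intra' if intra else 'peri'}-tumor TLS "
                    "without overlap after 1000 attempts")

    _place(spec.n_tls_intra, intra_ok, True)
    _place(spec.n_tls_peri, peri_ok, False)
    for y, x, _ in placed:
        disc = (rr - y) ** 2 + (cc - x) ** 2 <= r_tls ** 2
        grid[disc] = int(TissueClass.TLS)

    label_map = LabelMap(grid=grid, cell_size_px=1, slide_id=f"slide-{spec.seed}")
    counts = label_map.class_counts().astype(float)
    tt_px = counts[int(TissueClass.TT_P)] + counts[int(TissueClass.TT_S)]
    tumor_px = float(tumor.sum())
    gt = {
        "class_fractions": counts / counts.sum(),
        "necrosis_ratio": counts[int(TissueClass.HN)] / max(tumor_px, 1),
        "stroma_ratio": (counts[int(TissueClass.TT_S)] / tt_px) if tt_px else 0.0,
        "tls_centroids_intra": [(y, x) for y, x, i in placed if i],
        "tls_centroids_peri": [(y, x) for y, x, i in placed if not i],
        "boundary_irregularity": spec.boundary_irregularity,
        "tumor_mask_area": tumor_px,
    }
    return label_map, gt


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _draw_nucleus(img, y, x, area, distortion, rng, color, contrast):
    """Paint one perturbed-ellipse nucleus onto the image."""
    r0 = np.sqrt(area / np.pi)
    axis_ratio = rng.uniform(0.65, 1.0)
    a_axis = r0 / np.sqrt(axis_ratio)
    b_axis = r0 * np.sqrt(axis_ratio)
    rot = rng.uniform(0, np.pi)
    phase = rng.uniform(0, 2 * np.pi)
    th = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    rad = 1.0 + distortion * np.sin(3 * th + phase)
    py = y + rad * (a_axis * np.cos(th) * np.sin(rot)
                    + b_axis * np.sin(th) * np.cos(rot))
    px = x + rad * (a_axis * np.cos(th) * np.cos(rot)
                    - b_axis * np.sin(th) * np.sin(rot))
    rr_, cc_ = draw_polygon(py, px, shape=img.shape[:2])
    if rr_.size == 0:
        return
    base = np.array(color, dtype=float)
    tex = rng.normal(0, contrast, size=(rr_.size, 1))
    img[rr_, cc_] = np.clip(base[None, :] + tex, 0, 255)


def _render(grid: np.ndarray, render: RenderSpec, risk: float,
            rng: np.random.Generator, area_factor: float = 1.0) -> np.ndarray:
    h, w = grid.shape
    img = np.zeros((h, w, 3), dtype=float)
    present = np.unique(grid)
    for code in present:
        code = int(code)
        if code not in render.base_colors:
            raise ValueError(f"unknown class code {code} in label map")
        mask = grid == code
        n_px = int(mask.sum())
        base = np.array(render.base_colors[code], dtype=float)
        noise = rng.normal(0, render.speckle_sd.get(code, 0.0), size=(n_px, 3))
        img[mask] = np.clip(base[None, :] + noise, 0, 255)
    # nuclei per class, density expressed per 256x256 tile area
    for code in present:
        code = int(code)
        dens = render.nucleus_density.get(code, 0.0)
        if dens <= 0:
            continue
        mask = grid == code
        coords = np.column_stack(np.nonzero(mask))
        if coords.size == 0:
            continue
        expected = dens * coords.shape[0] / (256.0 * 256.0)
        n_nuc = int(rng.poisson(expected))
        mean_area = render.nucleus_mean_area_px2 * area_factor
        if code == int(TissueClass.TT_P):
            mean_area *= max(0.1, 1.0 + NUCLEUS_RISK_COEF * risk)
        elif code == int(TissueClass.TLS):
            mean_area *= 0.45  # lymphocytes are small
        for _ in range(n_nuc):
            y, x = coords[rng.integers(coords.shape[0])]
            area = mean_area * rng.lognormal(0, 0.18)
            _draw_nucleus(img, y, x, area, render.nucleus_shape_distortion,
                          rng, render.nucleus_color, render.intensity_contrast)
    return img.astype(np.uint8)


def render_slide(label_map: LabelMap, render: RenderSpec, risk: float = 0.0,
                 seed: int = 0) -> np.ndarray:
    """Render a label map as an H&E-like RGB image.

    Parenchyma nuclei are perturbed ellipses whose mean area scales as
    ``nucleus_mean_area_px2 * (1 + NUCLEUS_RISK_COEF * risk)``.
    """
    if not np.isfinite(risk):
        raise ValueError("risk must be finite")
    rng = substream(seed, "render", label_map.slide_id)
    return _render(label_map.grid, render, risk, rng)


def render_tile(label_map: LabelMap, ref: TileRef, render: RenderSpec,
                risk: float = 0.0, seed: int = 0) -> np.ndarray:
    """Render one tile window of a pixel-level label map.

    A per-tile lognormal jitter (``tile_heterogeneity_sd``) on nucleus
    area models within-slide heterogeneity between sections of the same
    tumor.
    """
    if not np.isfinite(risk):
        raise ValueError("risk must be finite")
    rng = substream(seed, "tile", ref.slide_id, ref.row0, ref.col0)
    window = label_map.grid[ref.row0:ref.row0 + ref.size_px,
                            ref.col0:ref.col0 + ref.size_px]
    jitter = rng.lognormal(0, render.tile_heterogeneity_sd)
    return _render(window, render, risk, rng, area_factor=jitter)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

# Population mean/sd of each planted feature's sampling distribution,
# used to standardize before applying beta (keeps eta scale-stable).
_FEATURE_DISTS = {
    "necrosis_ratio": ("uniform", 0.0, 0.40),
    "stroma_ratio": ("uniform", 0.20, 0.70),
    "margin_irregularity": ("uniform", 0.0, 0.22),
    "n_tls_intra": ("randint", 0, 4),
    "n_tls_peri": ("randint", 0, 4),
    "nucleus_size_z": ("normal", 0.0, 1.0),
}


def _uniform_stats(lo, hi):
    return (lo + hi) / 2.0, (hi - lo) / np.sqrt(12.0)


def generate_cohort(cohort: CohortSpec, slide: SlideSpec, render: RenderSpec,
                    materialize: bool = True
                    ) -> tuple[list[PatientRecord], list[SlideRecord], pd.DataFrame]:
    """Generate a survival cohort of synthetic slides.

    Per patient, planted features are drawn from documented
    distributions (uniform necrosis/stroma/irregularity, 0-4 TLS counts,
    standard-normal nucleus-size factor), standardized, combined by the
    ``beta`` coefficients into the linear predictor ``eta``, and an
    exponential survival time with rate ``baseline_hazard * exp(eta)``
    is drawn. Slides inherit the patient's features with small
    multiplicative jitter, modelling inter-section discrepancies.

    Returns ``(patients, slides, ground_truth)``; the ground-truth table
    has one row per slide with all planted features, ``eta``, the
    nucleus-size render risk, and observed time/event.
    """
    rng = substream(cohort.seed, "cohort")
    n = cohort.n_patients

    draws = {}
    for name, (kind, a, b) in _FEATURE_DISTS.items():
        if kind == "uniform":
            draws[name] = rng.uniform(a, b, size=n)
        elif kind == "randint":
            draws[name] = rng.integers(a, b + 1, size=n).astype(float)
        else:
            draws[name] = rng.normal(a, b, size=n)

    # geometric TLS area ratios implied by counts (standardized below)
    tls_area = np.pi * slide.tls_radius_px ** 2
    tumor_area_nominal = np.pi * slide.tumor_axes[0] * slide.tumor_axes[1]
    feats = {
        "necrosis_ratio": draws["necrosis_ratio"],
        "stroma_ratio": draws["stroma_ratio"],
        "margin_irregularity": draws["margin_irregularity"],
        "intra_tls_ratio": draws["n_tls_intra"] * tls_area / tumor_area_nominal,
        "peri_tls_ratio": draws["n_tls_peri"] * tls_area / tumor_area_nominal,
        "nucleus_mean_area": render.nucleus_mean_area_px2
                             * (1 + NUCLEUS_RISK_COEF * draws["nucleus_size_z"]),
    }

    def _standardize(name):
        x = feats[name]
        if name in ("necrosis_ratio", "stroma_ratio", "margin_irregularity"):
            kind, a, b = _FEATURE_DISTS[name]
            mu, sd = _uniform_stats(a, b)
        elif name in ("intra_tls_ratio", "peri_tls_ratio"):
            key = "n_tls_intra" if name == "intra_tls_ratio" else "n_tls_peri"
            _, a, b = _FEATURE_DISTS[key]
            mu, sd = _uniform_stats(a, b)  # discrete uniform approx
            scale = tls_area / tumor_area_nominal
            mu, sd = mu * scale, sd * scale
        else:  # nucleus_mean_area
            mu = render.nucleus_mean_area_px2
            sd = render.nucleus_mean_area_px2 * NUCLEUS_RISK_COEF
        return (x - mu) / sd

    eta = np.zeros(n)
    for name, coef in cohort.beta.items():
        eta += coef * _standardize(name)

    rate = cohort.baseline_hazard * np.exp(eta)
    true_times = rng.exponential(1.0 / rate)
    u = rng.uniform(size=n)

    def censored_frac(c):
        return float(np.mean(-np.log(u) / c < true_times))

    lo, hi = 1e-8, 1e6
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if censored_frac(mid) < cohort.censor_rate_target:
            lo = mid
        else:
            hi = mid
    c_rate = np.sqrt(lo * hi)
    censor_times = -np.log(u) / c_rate
    obs_times = np.minimum(true_times, censor_times)
    events = (true_times <= censor_times).astype(int)
    obs_times = np.maximum(obs_times, 1e-6)

    realized = 1.0 - events.mean()
    if abs(realized - cohort.censor_rate_target) > 0.05:
        warnings.warn(
            f"realized censoring {realized:.2f} off target "
            f"{cohort.censor_rate_target:.2f}")

    patients, slides, rows = [], [], []
    jrng = substream(cohort.seed, "slide_jitter")
    for i in range(n):
        pid = f"P{i:04d}"
        slide_ids = []
        for s in range(cohort.slides_per_patient):
            sid = f"{pid}-S{s}"
            slide_ids.append(sid)
            jit = (jrng.lognormal(0, cohort.slide_jitter_sd, size=4)
                   if cohort.slides_per_patient > 1 else np.ones(4))
            spec_s = SlideSpec(
                height_px=slide.height_px, width_px=slide.width_px,
                tumor_axes=slide.tumor_axes,
                boundary_irregularity=min(
                    0.35, draws["margin_irregularity"][i] * jit[0]),
                n_tls_intra=int(draws["n_tls_intra"][i]),
                n_tls_peri=int(draws["n_tls_peri"][i]),
                tls_radius_px=slide.tls_radius_px,
                necrosis_fraction=min(0.95, draws["necrosis_ratio"][i] * jit[1]),
                stroma_fraction=min(0.95, draws["stroma_ratio"][i] * jit[2]),
                seed=int(substream(cohort.seed, "slide_seed", sid)
                         .integers(0, 2 ** 31)),
            )
            label_map = None
            gt_slide = {}
            if materialize:
                label_map, gt_slide = generate_label_map(spec_s)
                label_map.slide_id = sid
            rec = SlideRecord(slide_id=sid, patient_id=pid, label_map=label_map)
            slides.append(rec)
            nucleus_risk = draws["nucleus_size_z"][i] * jit[3]
            row = {
                "patient_id": pid, "slide_id": sid,
                "time_months": float(obs_times[i]), "event": int(events[i]),
                "eta": float(eta[i]), "true_time": float(true_times[i]),
                "render_risk": float(nucleus_risk),
                **{k: float(feats[k][i]) for k in feats},
            }
            for key in ("necrosis_ratio", "stroma_ratio",
                        "boundary_irregularity"):
                if key in gt_slide:
                    row[f"realized_{key}"] = float(gt_slide[key])
            rows.append(row)
        patients.append(PatientRecord(
            patient_id=pid, time_months=float(obs_times[i]),
            event=int(events[i]), slide_ids=slide_ids,
            covariates={k: float(feats[k][i]) for k in feats} | {"eta": float(eta[i])},
        ))
    return patients, slides, pd.DataFrame(rows)


def oracle_gsm(label_map: LabelMap, tile_size: int) -> LabelMap:
    """GSM from a pixel-level truth map via a perfect tile classifier.

    Each tile's probability vector is its true class histogram, so the
    assembled GSM is the tile-majority downsampling of the truth map
    (argmax ties to the lowest class code).
    """
    from .segmap import assemble_gsm, tile_grid

    refs = tile_grid(*label_map.shape, size_px=tile_size,
                     slide_id=label_map.slide_id)
    probs = []
    for r in refs:
        win = label_map.grid[r.row0:r.row0 + tile_size,
                             r.col0:r.col0 + tile_size]
        counts = np.bincount(win.ravel(), minlength=len(TissueClass))
        probs.append(counts / counts.sum())
    return assemble_gsm(refs, np.asarray(probs))


class CohortTileSource:
    """Renders tiles for a generated cohort on demand.

    Holds the slide label maps and the per-slide nucleus-size render
    risk from the ground-truth table; ``get_tiles`` renders the
    requested tile windows deterministically from the cohort seed.
    """

    def __init__(self, slides: list[SlideRecord], ground_truth: pd.DataFrame,
                 render: RenderSpec, seed: int = 0):
        self.maps = {s.slide_id: s.label_map for s in slides}
        self.render = render
        self.seed = seed
        self.risk = dict(zip(ground_truth["slide_id"],
                             ground_truth["render_risk"]))

    def label_map(self, slide_id: str) -> LabelMap:
        return self.maps[slide_id]

    def get_tiles(self, slide_id: str, refs: list[TileRef]) -> np.ndarray:
        lm = self.maps[slide_id]
        risk = self.risk.get(slide_id, 0.0)
        return np.stack([
            render_tile(lm, ref, self.render, risk=risk, seed=self.seed)
            for ref in refs])


# ---------------------------------------------------------------------------
# Expression generation
# ---------------------------------------------------------------------------

def generate_expression(spec: ExpressionSpec, risks) -> pd.DataFrame:
    """Gene-by-sample log-expression matrix with planted set shifts.

    Genes in set ``s`` have mean ``effect[s] * risk_j`` in sample ``j``;
    all genes carry i.i.d. Gaussian noise with sd ``noise_sd``.
    """
    risks = np.asarray(risks, dtype=float)
    if np.any(~np.isfinite(risks)):
        raise ValueError("risks must be finite")
    rng = substream(spec.seed, "expression")
    genes = spec.gene_names()
    n_samples = risks.size
    mat = rng.normal(0, spec.noise_sd, size=(spec.n_genes, n_samples))
    index = {g: i for i, g in enumerate(genes)}
    for sname, effect in spec.effect.items():
        if sname not in spec.gene_sets:
            raise ValueError(f"effect on unknown set {sname!r}")
        for g in spec.gene_sets[sname]:
            mat[index[g]] += effect * risks
    cols = [f"S{j:04d}" for j in range(n_samples)]
    return pd.DataFrame(mat, index=genes, columns=cols)
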