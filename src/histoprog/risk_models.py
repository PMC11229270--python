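"""Survival-trained risk scores: GS, TiRS and CRS.

Three prognostic models share one objective — the negative log Cox
partial likelihood with Breslow tie handling — and differ in their
input representation:

* GS (GSM score): the global segmentation map is one-hot encoded by
  class and pooled into class-composition fractions within the
  tumor-interior and tumor-exterior zones; a linear risk head maps the
  pooled representation to a score. The zonal pooling keeps the model
  translation-invariant while letting it separate intra- from
  peri-tumoral structures.
* TiRS (tile risk score): tiles sampled from the slide (strategy,
  count and magnification configurable) are embedded with the fixed
  tile-descriptor bank, mean-pooled per slide (a simple
  multiple-instance scheme), and mapped by a linear risk head.
* CRS (consensus risk score): the two branch representations are
  concatenated and a shared risk head is trained jointly.

All scores are z-scored on the training cohort (they are relative
risks) and are emitted per slide; patient-level min/max/mean/sd
aggregates use the mean as the representative score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import survival_stats as ss
from .segmap import LabelMap, PatientRecord, TissueClass, sample_tiles
from .tissue_classifier import tile_features

__all__ = [
    "RiskScore",
    "PatientScore",
    "RiskTrainConfig",
    "cox_partial_loss",
    "train_gs_model",
    "train_tile_model",
    "train_consensus",
    "linear_combination",
    "aggregate_patient",
    "gsm_features",
    "GSModel",
    "TileModel",
    "ConsensusModel",
]


@dataclass
class RiskScore:
    slide_id: str
    kind: str  # GS | TiRS | CRS
    value: float


@dataclass
class PatientScore:
    patient_id: str
    kind: str
    min: float
    max: float
    mean: float
    sd: float
    representative: float


@dataclass
class RiskTrainConfig:
    epochs: int = 200
    batch: int = 32  # patients per batch (full-batch likelihood used below)
    learning_rate: float = 0.1
    tile_count: int = 32
    tile_scale: float = 4.0
    strategy: str = "parenchyma_only"
    ridge: float = 1e-2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tile_count < 1:
            raise ValueError("tile_count must be >= 1")


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def cox_partial_loss(scores, times, events) -> float:
    """Negative log Cox partial likelihood (Breslow ties).

    ``sum over events i of [log(sum_{j: t_j >= t_i} e^{s_j}) - s_i]``
    with tied event times sharing one risk-set denominator. Invariant
    under adding a constant to all scores.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() == 0:
        raise ValueError("partial likelihood undefined with zero events")
    # stabilize: subtract max (invariance makes this exact)
    s = scores - scores.max()
    order = np.argsort(-times, kind="stable")
    so, to, eo = s[order], times[order], events[order]
    exp_s = np.exp(so)
    cum = np.cumsum(exp_s)
    # risk set for subject k (sorted by decreasing time): all j with t_j >= t_k,
    # i.e. the largest cumulative index among ties of t_k
    loss = 0.0
    i = 0
    n = len(to)
    while i < n:
        j = i
        while j < n and to[j] == to[i]:
            j += 1
        denom = cum[j - 1]
        for k in range(i, j):
            if eo[k] == 1:
                loss += np.log(denom) - so[k]
        i = j
    return float(loss)


def _fit_linear_head(X, times, events, ridge, seed=0):
    """Minimize the Breslow partial likelihood over a linear head.

    The objective is convex; L-BFGS from a zero start is deterministic.
    A small ridge penalty keeps ill-conditioned feature sets stable.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape

    def obj(w):
        s = X @ w
        return (cox_partial_loss(s, times, events) / max(1, n)
                + 0.5 * ridge * float(w @ w))

    res = minimize(obj, np.zeros(p), method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-12})
    return res.x


class _ZScore:
    """Freeze training-cohort mean/sd; apply to later scores."""

    def fit(self, values):
        values = np.asarray(values, dtype=float)
        self.mean = float(values.mean())
        self.sd = float(values.std())
        if self.sd == 0:
            self.sd = 1.0
        return self

    def __call__(self, v):
        return (np.asarray(v, dtype=float) - self.mean) / self.sd


# ---------------------------------------------------------------------------
# GSM representation
# ---------------------------------------------------------------------------

def gsm_features(label_map: LabelMap) -> np.ndarray:
    """Zonal class-composition pooling of the one-hot encoded GSM.

    Twelve numbers: the fraction of all cells carrying each of the six
    classes inside the filled tumor zone, and the same outside it.
    """
    from .interpret_architecture import filled_tumor_mask

    grid = label_map.grid
    total = grid.size
    zone_in = filled_tumor_mask(label_map)
    feats = np.zeros(2 * len(TissueClass))
    for c in TissueClass:
        m = grid == int(c)
        feats[int(c)] = (m & zone_in).sum() / total
        feats[len(TissueClass) + int(c)] = (m & ~zone_in).sum() / total
    return feats


def _patient_survival(patients: list[PatientRecord]):
    t = np.array([p.time_months for p in patients])
    e = np.array([p.event for p in patients])
    return t, e


@dataclass
class GSModel:
    weights: np.ndarray
    zscore: _ZScore
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray

    def _raw(self, label_map: LabelMap) -> float:
        f = (gsm_features(label_map) - self.scaler_mean) / self.scaler_sd
        return float(f @ self.weights)

    def score_gsm(self, label_map: LabelMap) -> float:
        """Raw (pre-z-score) risk of a GSM; used by occlusion analysis."""
        return self._raw(label_map)

    def score_slide(self, label_map: LabelMap) -> float:
        return float(self.zscore(self._raw(label_map)))


def _standardize_columns(X):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mean) / sd, mean, sd


def train_gs_model(maps: dict, patients: list[PatientRecord],
                   config: RiskTrainConfig) -> GSModel:
    """Train the GSM-score model.

    ``maps`` maps slide_id to a GSM :class:`LabelMap`; a patient's input
    is the mean of their slides' pooled representations.
    """
    feats = []
    for p in patients:
        fs = [gsm_features(maps[sid]) for sid in p.slide_ids if sid in maps]
        if not fs:
            raise ValueError(f"patient {p.patient_id} has no GSM")
        feats.append(np.mean(fs, axis=0))
    X = np.asarray(feats)
    if np.all(np.ptp(X, axis=0) == 0):
        warnings.warn("all GSMs identical: degenerate input, zero-weight model")
        Xs, mean, sd = _standardize_columns(X)
        model = GSModel(np.zeros(X.shape[1]), _ZScore().fit([0.0]), mean, sd)
        return model
    Xs, mean, sd = _standardize_columns(X)
    t, e = _patient_survival(patients)
    w = _fit_linear_head(Xs, t, e, config.ridge, config.seed)
    raw = Xs @ w
    return GSModel(weights=w, zscore=_ZScore().fit(raw),
                   scaler_mean=mean, scaler_sd=sd)


# ---------------------------------------------------------------------------
# Tile model
# ---------------------------------------------------------------------------

def _slide_embedding(gsm: LabelMap, tile_source, config: RiskTrainConfig,
                     seed: int) -> np.ndarray:
    refs = sample_tiles(gsm, config.strategy, config.tile_count,
                        scale=config.tile_scale, seed=seed)
    tiles = tile_source.get_tiles(gsm.slide_id, refs)
    emb = np.stack([tile_features(t) for t in tiles])
    return emb.mean(axis=0)


@dataclass
class TileModel:
    weights: np.ndarray
    zscore: _ZScore
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    config: RiskTrainConfig

    def embed_slide(self, gsm: LabelMap, tile_source) -> np.ndarray:
        seed = _slide_seed(self.config.seed, gsm.slide_id)
        return _slide_embedding(gsm, tile_source, self.config, seed)

    def score_slide(self, gsm: LabelMap, tile_source) -> float:
        f = (self.embed_slide(gsm, tile_source) - self.scaler_mean) / self.scaler_sd
        return float(self.zscore(f @ self.weights))


def _slide_seed(root: int, slide_id: str) -> int:
    import zlib

    return (int(root) * 1000003 + zlib.crc32(slide_id.encode())) % (2 ** 31)


def train_tile_model(patients: list[PatientRecord], maps: dict, tile_source,
                     config: RiskTrainConfig) -> TileModel:
    """Train the tile-risk model.

    Each slide contributes the mean descriptor embedding of its sampled
    tiles; a patient's input is the mean over their slides. Supports the
    global-random / tumor-only / parenchyma-only sampling strategies.
    """
    feats = []
    for p in patients:
        es = []
        for sid in p.slide_ids:
            if sid not in maps:
                continue
            seed = _slide_seed(config.seed, sid)
            es.append(_slide_embedding(maps[sid], tile_source, config, seed))
        if not es:
            raise ValueError(f"patient {p.patient_id} has no slides with maps")
        feats.append(np.mean(es, axis=0))
    X = np.asarray(feats)
    Xs, mean, sd = _standardize_columns(X)
    t, e = _patient_survival(patients)
    w = _fit_linear_head(Xs, t, e, config.ridge, config.seed)
    raw = Xs @ w
    return TileModel(weights=w, zscore=_ZScore().fit(raw),
                     scaler_mean=mean, scaler_sd=sd, config=config)


# ---------------------------------------------------------------------------
# Consensus model
# ---------------------------------------------------------------------------

@dataclass
class ConsensusModel:
    weights: np.ndarray
    zscore: _ZScore
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    config: RiskTrainConfig

    def _features(self, gsm: LabelMap, tile_source) -> np.ndarray:
        seed = _slide_seed(self.config.seed, gsm.slide_id)
        emb = _slide_embedding(gsm, tile_source, self.config, seed)
        return np.concatenate([gsm_features(gsm), emb])

    def score_slide(self, gsm: LabelMap, tile_source) -> float:
        f = (self._features(gsm, tile_source) - self.scaler_mean) / self.scaler_sd
        return float(self.zscore(f @ self.weights))


def train_consensus(maps: dict, tile_source, patients: list[PatientRecord],
                    config: RiskTrainConfig) -> ConsensusModel:
    """Train the consensus model on concatenated branch representations."""
    if maps is None or tile_source is None:
        raise ValueError("consensus model needs both GSM and tile inputs")
    feats = []
    for p in patients:
        fs = []
        for sid in p.slide_ids:
            if sid not in maps:
                continue
            gsm = maps[sid]
            seed = _slide_seed(config.seed, sid)
            emb = _slide_embedding(gsm, tile_source, config, seed)
            fs.append(np.concatenate([gsm_features(gsm), emb]))
        if not fs:
            raise ValueError(f"patient {p.patient_id} has no usable slides")
        feats.append(np.mean(fs, axis=0))
    X = np.asarray(feats)
    Xs, mean, sd = _standardize_columns(X)
    t, e = _patient_survival(patients)
    w = _fit_linear_head(Xs, t, e, config.ridge, config.seed)
    raw = Xs @ w
    return ConsensusModel(weights=w, zscore=_ZScore().fit(raw),
                          scaler_mean=mean, scaler_sd=sd, config=config)


# ---------------------------------------------------------------------------
# Linear combination baseline and patient aggregation
# ---------------------------------------------------------------------------

def linear_combination(gs, tirs, surv: ss.SurvivalData):
    """Hazard linear combination of GS and TiRS.

    Weights are the coefficients of a two-covariate Cox fit; the
    combined score is ``b1*GS + b2*TiRS``. Warns on near-collinear
    scores.
    """
    gs = np.asarray(gs, dtype=float)
    tirs = np.asarray(tirs, dtype=float)
    if gs.shape != tirs.shape or gs.size != len(surv):
        raise ValueError("both scores required for every patient")
    r = np.corrcoef(gs, tirs)[0, 1]
    if abs(r) > 0.999:
        warnings.warn("GS and TiRS nearly collinear; weights ill-conditioned")
    fit = ss.cox_fit(np.column_stack([gs, tirs]), surv, names=["GS", "TiRS"])
    combined = fit.beta[0] * gs + fit.beta[1] * tirs
    return combined, fit


def aggregate_patient(slide_scores, patient_id: str = "",
                      kind: str = "GS") -> PatientScore:
    """Min/max/mean/sd of a patient's slide scores (population sd).

    The representative per-patient score is the mean across sections.
    """
    v = np.asarray(slide_scores, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one slide score")
    return PatientScore(
        patient_id=patient_id, kind=kind,
        min=float(v.min()), max=float(v.max()), mean=float(v.mean()),
        sd=float(v.std()),  # population convention (divide by n)
        representative=float(v.mean()),
    )
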