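"""Tile classification feeding GSM assembly.

Two-stage scheme mirroring the dichotomized annotation protocol: a
top-level classifier over five regions (background, liver, tumor
tissue, hemorrhage/necrosis, TLS), and a second classifier that splits
tumor-tissue tiles into parenchyma and stroma. The two are composed at
inference.

The classifier itself is a compact, CPU-trainable network: a fixed
bank of color/stain/texture tile descriptors feeding a small
multi-layer perceptron head. Probabilities are softmax outputs; GSM
cells take the argmax class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import color as skcolor
from skimage.filters import sobel, threshold_otsu
from scipy import ndimage
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .segmap import TissueClass

__all__ = [
    "ClassifierConfig",
    "EvalReport",
    "TOPLEVEL_CLASSES",
    "SUBTYPE_CLASSES",
    "tile_features",
    "train_classifier",
    "predict_tiles",
    "evaluate",
    "HierarchicalTileClassifier",
    "one_vs_rest_auc",
]

TOPLEVEL_CLASSES = ("BG", "LT", "TT", "HN", "TLS")
SUBTYPE_CLASSES = ("TT_P", "TT_S")


@dataclass
class ClassifierConfig:
    stage: str = "toplevel"  # "toplevel" | "tt_subtype"
    epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    input_size: int = 256
    hidden_units: tuple = (64, 32)

    def __post_init__(self) -> None:
        if self.stage not in ("toplevel", "tt_subtype"):
            raise ValueError("stage must be 'toplevel' or 'tt_subtype'")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class EvalReport:
    """Confusion matrices, per-class one-vs-rest AUC and accuracy."""

    confusion: np.ndarray
    confusion_normalized: np.ndarray
    per_class_auc: dict
    accuracy: float
    classes: tuple = ()


# ---------------------------------------------------------------------------
# Tile descriptors
# ---------------------------------------------------------------------------

def tile_features(tile: np.ndarray) -> np.ndarray:
    """Descriptor vector for one RGB tile.

    Color statistics, HSV saturation/value, hematoxylin-channel stain
    statistics, edge energy, and nucleus-scale blob statistics from an
    Otsu threshold of the hematoxylin channel. These summarize the cues
    that separate tissue compartments: stain density (cellularity),
    stain hue (hemorrhage vs. basophilic tissue) and object granularity
    (lymphocyte aggregates vs. large epithelial nuclei).
    """
    tile = np.asarray(tile)
    if tile.ndim != 3 or tile.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB tile")
    rgbf = tile.astype(float) / 255.0
    feats = []
    feats.extend(rgbf.reshape(-1, 3).mean(axis=0))
    feats.extend(rgbf.reshape(-1, 3).std(axis=0))
    hsv = skcolor.rgb2hsv(rgbf)
    feats.append(hsv[:, :, 1].mean())
    feats.append(hsv[:, :, 2].mean())
    hed = skcolor.rgb2hed(rgbf)
    h_chan = hed[:, :, 0]
    feats.append(h_chan.mean())
    feats.append(h_chan.std())
    gray = rgbf.mean(axis=2)
    feats.append(float(sobel(gray).mean()))
    # blob statistics on the stain channel
    if np.ptp(h_chan) > 1e-9:
        thr = threshold_otsu(h_chan)
        mask = h_chan > thr
        frac = mask.mean()
        labeled, n_obj = ndimage.label(mask)
        areas = (np.bincount(labeled.ravel())[1:] if n_obj else np.array([0.0]))
        feats.append(frac)
        feats.append(n_obj / mask.size * 1000.0)
        feats.append(float(np.mean(areas)) if areas.size else 0.0)
        feats.append(float(np.std(areas)) if areas.size else 0.0)
    else:
        feats.extend([0.0, 0.0, 0.0, 0.0])
    return np.asarray(feats, dtype=float)


def _featurize(tiles) -> np.ndarray:
    return np.stack([tile_features(t) for t in tiles])


# ---------------------------------------------------------------------------
# Training / prediction
# ---------------------------------------------------------------------------

@dataclass
class TileClassifier:
    """Trained single-stage classifier handle."""

    classes: tuple
    scaler: StandardScaler
    net: MLPClassifier
    config: ClassifierConfig
    loss_curve: list = field(default_factory=list)
    tile_shape: tuple = ()

    def predict_proba(self, tiles) -> np.ndarray:
        return predict_tiles(self, tiles)

    def predict_labels(self, tiles) -> list:
        probs = self.predict_proba(tiles)
        return [self.classes[i] for i in probs.argmax(axis=1)]

    def save_meta(self, path) -> None:
        meta = {"classes": list(self.classes), "stage": self.config.stage,
                "seed": self.config.seed, "epochs": self.config.epochs}
        Path(path).write_text(json.dumps(meta, indent=1))


def _valid_labels(stage: str) -> tuple:
    return TOPLEVEL_CLASSES if stage == "toplevel" else SUBTYPE_CLASSES


def train_classifier(tiles, labels, config: ClassifierConfig) -> TileClassifier:
    """Train one stage of the tile classifier.

    Class imbalance is handled by per-class uniform resampling of the
    training set to the majority-class count before fitting. Training is
    deterministic for a fixed seed.
    """
    labels = np.asarray([str(l) for l in labels])
    valid = _valid_labels(config.stage)
    bad = sorted(set(labels) - set(valid))
    if bad:
        raise ValueError(f"labels invalid for stage {config.stage!r}: {bad}")
    present = sorted(set(labels), key=valid.index)
    if len(present) < 2:
        raise ValueError("need at least 2 classes to train")
    X = _featurize(tiles)
    rng = np.random.default_rng(config.seed)
    # balanced resampling
    idx_all = []
    n_max = max(int((labels == c).sum()) for c in present)
    for c in present:
        idx_c = np.flatnonzero(labels == c)
        if idx_c.size < n_max:
            extra = rng.choice(idx_c, size=n_max - idx_c.size, replace=True)
            idx_c = np.concatenate([idx_c, extra])
        idx_all.append(idx_c)
    idx_all = rng.permutation(np.concatenate(idx_all))
    Xb, yb = X[idx_all], labels[idx_all]
    scaler = StandardScaler().fit(Xb)
    net = MLPClassifier(
        hidden_layer_sizes=tuple(np.atleast_1d(config.hidden_units)),
        max_iter=config.epochs,
        batch_size=min(config.batch_size, len(yb)),
        learning_rate_init=config.learning_rate,
        random_state=config.seed,
        solver="adam",
        early_stopping=False,
    )
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")  # convergence warnings are expected at small epochs
        net.fit(scaler.transform(Xb), yb)
    handle = TileClassifier(classes=tuple(present), scaler=scaler, net=net,
                            config=config, loss_curve=list(net.loss_curve_),
                            tile_shape=tuple(np.asarray(tiles[0]).shape[:2]))
    return handle


def predict_tiles(handle: TileClassifier, tiles) -> np.ndarray:
    """Per-tile class probability vectors (rows on the simplex)."""
    tiles = list(tiles)
    if not tiles:
        return np.zeros((0, len(handle.classes)))
    shapes = {np.asarray(t).shape for t in tiles}
    if any(len(s) != 3 or s[2] != 3 for s in shapes):
        raise ValueError("tiles must be H x W x 3")
    if handle.tile_shape and shapes != {(*handle.tile_shape, 3)}:
        raise ValueError(
            f"tile shape mismatch: trained on {handle.tile_shape}, "
            f"got {sorted(s[:2] for s in shapes)}")
    X = handle.scaler.transform(_featurize(tiles))
    probs = handle.net.predict_proba(X)
    # net class order -> handle order
    order = [list(handle.net.classes_).index(c) for c in handle.classes]
    return probs[:, order]


class HierarchicalTileClassifier:
    """Two-stage composition: top-level call, then TT dichotomization.

    Produces six-way labels in :class:`TissueClass` order. Non-TT calls
    are exactly the top-level stage's calls; TT calls are split by the
    subtype stage.
    """

    def __init__(self, toplevel: TileClassifier, tt_subtype: TileClassifier):
        self.toplevel = toplevel
        self.tt_subtype = tt_subtype

    def predict_codes(self, tiles) -> np.ndarray:
        top = self.toplevel.predict_labels(tiles)
        codes = np.empty(len(top), dtype=np.uint8)
        tt_idx = [i for i, lab in enumerate(top) if lab == "TT"]
        for i, lab in enumerate(top):
            if lab != "TT":
                codes[i] = int(TissueClass[lab])
        if tt_idx:
            sub = self.tt_subtype.predict_labels([tiles[i] for i in tt_idx])
            for i, lab in zip(tt_idx, sub):
                codes[i] = int(TissueClass[lab])
        return codes

    def predict_proba6(self, tiles) -> np.ndarray:
        """Six-way probabilities: p(TT subtype) = p(TT) * p(subtype | TT)."""
        p_top = self.toplevel.predict_proba(tiles)
        p_sub = self.tt_subtype.predict_proba(tiles)
        top_ix = {c: i for i, c in enumerate(self.toplevel.classes)}
        sub_ix = {c: i for i, c in enumerate(self.tt_subtype.classes)}
        n = p_top.shape[0]
        out = np.zeros((n, len(TissueClass)))
        for name in ("BG", "LT", "HN", "TLS"):
            if name in top_ix:
                out[:, int(TissueClass[name])] = p_top[:, top_ix[name]]
        if "TT" in top_ix:
            p_tt = p_top[:, top_ix["TT"]]
            out[:, int(TissueClass.TT_P)] = p_tt * p_sub[:, sub_ix["TT_P"]]
            out[:, int(TissueClass.TT_S)] = p_tt * p_sub[:, sub_ix["TT_S"]]
        return out


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def one_vs_rest_auc(scores: np.ndarray, positives: np.ndarray) -> float:
    """One-vs-rest AUC as the Mann-Whitney rank statistic.

    Ties between a positive and a negative score count 0.5.
    """
    pos = scores[positives]
    neg = scores[~positives]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC undefined: a group is empty")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (pos.size * neg.size))


def evaluate(probs: np.ndarray, labels, classes=None) -> EvalReport:
    """Confusion matrices, per-class AUC and accuracy.

    ``labels`` are class names matching the probability columns (order
    given by ``classes``). A class absent from the labels has no defined
    AUC and is reported as ``None``.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray([str(l) for l in labels])
    if classes is None:
        classes = tuple(sorted(set(labels)))
    if probs.shape[0] != labels.size:
        raise ValueError("probs and labels must have equal length")
    if len(set(labels)) < 2:
        raise ValueError("need at least 2 classes in labels")
    k = len(classes)
    ix = {c: i for i, c in enumerate(classes)}
    y_true = np.array([ix[l] for l in labels])
    y_pred = probs.argmax(axis=1)
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        confusion[t, p] += 1
    row_sums = confusion.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(row_sums > 0, confusion / row_sums, 0.0)
    auc = {}
    for c, i in ix.items():
        positives = y_true == i
        if positives.sum() == 0:
            auc[c] = None
        else:
            auc[c] = one_vs_rest_auc(probs[:, i], positives)
    accuracy = float((y_true == y_pred).mean())
    return EvalReport(confusion=confusion, confusion_normalized=normalized,
                      per_class_auc=auc, accuracy=accuracy,
                      classes=tuple(classes))
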