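"""Fusing pixel- and graph-classifier outputs; metrics and topology checks.

Two fusion rules: agreement voting (a class is assigned only where both
sources' argmax labels coincide; disagreements fall back to background) and
convex weighting of the two probability fields followed by a strict 0.5
threshold.  Evaluation treats artery as the positive class and vein as the
negative class, restricted to a stated pixel support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .synth import ARTERY, BACKGROUND, VEIN

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class FusionConfig:
    mode: str = "agreement"  # {"agreement", "weighted"}
    w_cnn: float = 0.5
    w_gcn: float = 0.5
    threshold: float = 0.5
    disagreement_class: int = BACKGROUND

    def __post_init__(self) -> None:
        if self.mode not in ("agreement", "weighted"):
            raise ValueError(f"unknown fusion mode {self.mode!r}")
        if self.w_cnn < 0 or self.w_gcn < 0:
            raise ValueError("fusion weights must be >= 0")
        if self.mode == "weighted" and not np.isclose(self.w_cnn + self.w_gcn, 1.0):
            raise ValueError("weighted fusion needs w_cnn + w_gcn = 1")


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int
    support: str = "gt_vessels"

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "support": self.support,
        }


def _as_pixel_probs(probs: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Accept (P, Q, CL) rasters or (N, CL) node matrices (row-major)."""
    probs = np.asarray(probs)
    if probs.ndim == 2:
        if probs.shape[0] != shape[0] * shape[1]:
            raise ValueError(
                f"node matrix has {probs.shape[0]} rows, expected {shape[0] * shape[1]}"
            )
        return probs.reshape(shape[0], shape[1], -1)
    if probs.shape[:2] != shape:
        raise ValueError(f"probability raster {probs.shape[:2]} != expected {shape}")
    return probs


def fuse_agreement(
    cnn_probs: np.ndarray,
    gcn_probs: np.ndarray,
    shape: tuple[int, int] | None = None,
    disagreement_class: int = BACKGROUND,
) -> np.ndarray:
    """Per-pixel agreement voting on the two argmax label maps."""
    cnn_probs = np.asarray(cnn_probs)
    if shape is None:
        shape = cnn_probs.shape[:2]
    cnn = _as_pixel_probs(cnn_probs, shape)
    gcn = _as_pixel_probs(gcn_probs, shape)
    a = cnn.argmax(axis=-1)
    b = gcn.argmax(axis=-1)
    out = np.where(a == b, a, disagreement_class)
    return out.astype(np.int64)


def fuse_weighted(
    cnn_probs: np.ndarray,
    gcn_probs: np.ndarray,
    config: FusionConfig,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Convex combination of the probability fields, strict-threshold argmax.

    A class is asserted where its fused probability strictly exceeds the
    threshold; with several candidates the largest wins; with none the pixel
    is background.
    """
    if not np.isclose(config.w_cnn + config.w_gcn, 1.0):
        raise ValueError("weighted fusion needs w_cnn + w_gcn = 1")
    cnn_probs = np.asarray(cnn_probs)
    if shape is None:
        shape = cnn_probs.shape[:2]
    cnn = _as_pixel_probs(cnn_probs, shape)
    gcn = _as_pixel_probs(gcn_probs, shape)
    fused = config.w_cnn * cnn + config.w_gcn * gcn
    best = fused.argmax(axis=-1)
    best_val = np.take_along_axis(fused, best[..., None], axis=-1)[..., 0]
    out = np.where(best_val > config.threshold, best, BACKGROUND)
    return out.astype(np.int64)


def fused_probabilities(
    cnn_probs: np.ndarray,
    gcn_probs: np.ndarray,
    config: FusionConfig,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """The convex per-class combination itself (before thresholding)."""
    cnn_probs = np.asarray(cnn_probs)
    if shape is None:
        shape = cnn_probs.shape[:2]
    cnn = _as_pixel_probs(cnn_probs, shape)
    gcn = _as_pixel_probs(gcn_probs, shape)
    return config.w_cnn * cnn + config.w_gcn * gcn


def evaluate(
    pred: np.ndarray, gt: np.ndarray, eval_set: str = "gt_vessels"
) -> MetricsReport:
    """Artery-positive / vein-negative confusion metrics on a pixel support.

    'gt_vessels': all pixels whose ground truth is artery or vein;
    'pred_and_gt': additionally requires the prediction to be a vessel
    class.  Inside the support, a prediction other than the pixel's true
    class counts against that class (artery mislabeled in any way is a
    false negative; vein mislabeled is a false positive).
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"prediction {pred.shape} and ground truth {gt.shape} differ")
    if eval_set not in ("gt_vessels", "pred_and_gt"):
        raise ValueError(f"unknown eval_set {eval_set!r}")
    support = (gt == ARTERY) | (gt == VEIN)
    if eval_set == "pred_and_gt":
        support &= (pred == ARTERY) | (pred == VEIN)
    g = gt[support]
    p = pred[support]
    tp = int(np.sum((g == ARTERY) & (p == ARTERY)))
    fn = int(np.sum((g == ARTERY) & (p != ARTERY)))
    tn = int(np.sum((g == VEIN) & (p == VEIN)))
    fp = int(np.sum((g == VEIN) & (p != VEIN)))
    total = tp + fp + tn + fn
    return MetricsReport(
        accuracy=(tp + tn) / total if total else float("nan"),
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        support=eval_set,
    )


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> MetricsReport:
    """Metrics directly from confusion counts (for constructed cases)."""
    total = tp + fp + tn + fn
    return MetricsReport(
        accuracy=(tp + tn) / total if total else float("nan"),
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        support="counts",
    )


def topology_diagnostics(pred: np.ndarray, gt: np.ndarray) -> dict:
    """Connectivity and per-segment class-purity diagnostics.

    A ground-truth segment is a maximal 8-connected run of a single vessel
    class (artery or vein); crossings separate segments.
    ``multiclass_segment_count`` counts segments whose predicted artery/vein
    labels are mixed.  ``fragmentation_ratio`` compares 8-connected vessel
    component counts (any non-background class) between prediction and
    ground truth.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError("shape mismatch")

    multiclass = 0
    for cls in (ARTERY, VEIN):
        seg_labels, n_seg = ndimage.label(gt == cls, structure=_EIGHT)
        for s in range(1, n_seg + 1):
            in_seg = pred[seg_labels == s]
            classes = {int(c) for c in np.unique(in_seg) if c in (ARTERY, VEIN)}
            if len(classes) > 1:
                multiclass += 1

    _, n_pred = ndimage.label(pred != BACKGROUND, structure=_EIGHT)
    _, n_gt = ndimage.label(gt != BACKGROUND, structure=_EIGHT)
    ratio = n_pred / n_gt if n_gt else float("nan")
    return {
        "multiclass_segment_count": int(multiclass),
        "fragmentation_ratio": float(ratio),
        "pred_components": int(n_pred),
        "gt_components": int(n_gt),
    }
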