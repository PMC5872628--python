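"""Evaluation utilities: mask precision/recall/F-measure and recognition accuracy.

The F-measure follows the saliency-benchmark convention that weights precision
over recall with beta^2 = 0.3:

    F = (1 + beta^2) * P * R / (beta^2 * P + R)

Note the convention subtlety: some papers write "beta = 0.3" while using the
formula above with beta^2 in the weights; the default here sets beta^2 = 0.3.

Recognition scoring follows the 0/1/2 object-naming scale (2 = correctly
named, 1 = described but not named, 0 = neither), normalized to a percentage
RA = RS / 2 * 100.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from prosthvis.errors import InvalidInputError

DEFAULT_BETA_SQ = 0.3


@dataclass(frozen=True)
class PRF:
    precision: float
    recall: float
    f_measure: float
    beta_sq: float = DEFAULT_BETA_SQ


def _as_mask(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    return arr.astype(bool)


def precision_recall(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """Pixelwise precision and recall of a predicted mask against ground truth.

    An empty prediction yields precision 0 with a warning; an empty truth mask
    is an error (recall undefined).
    """
    pred = _as_mask(pred, "pred")
    truth = _as_mask(truth, "truth")
    if pred.shape != truth.shape:
        raise InvalidInputError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    n_truth = int(truth.sum())
    if n_truth == 0:
        raise InvalidInputError("ground-truth mask is empty; recall is undefined")
    n_pred = int(pred.sum())
    overlap = int((pred & truth).sum())
    if n_pred == 0:
        warnings.warn("empty predicted mask: precision reported as 0", stacklevel=2)
        return 0.0, 0.0
    return overlap / n_pred, overlap / n_truth


def f_measure(precision: float, recall: float, beta_sq: float = DEFAULT_BETA_SQ) -> float:
    """Weighted harmonic mean of precision and recall; F(p, p) = p for any beta^2."""
    if not 0 <= precision <= 1 or not 0 <= recall <= 1:
        raise InvalidInputError("precision and recall must lie in [0, 1]")
    if beta_sq <= 0:
        raise InvalidInputError(f"beta_sq must be positive, got {beta_sq}")
    denom = beta_sq * precision + recall
    if denom == 0:
        warnings.warn("precision and recall both zero: F-measure reported as 0", stacklevel=2)
        return 0.0
    return (1.0 + beta_sq) * precision * recall / denom


def prf(pred: np.ndarray, truth: np.ndarray, beta_sq: float = DEFAULT_BETA_SQ) -> PRF:
    """Precision, recall and F-measure of a mask pair in one call."""
    p, r = precision_recall(pred, truth)
    return PRF(precision=p, recall=r, f_measure=f_measure(p, r, beta_sq), beta_sq=beta_sq)


def iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """Intersection over union of two binary masks (1.0 when both empty)."""
    pred = _as_mask(pred, "pred")
    truth = _as_mask(truth, "truth")
    if pred.shape != truth.shape:
        raise InvalidInputError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    union = int((pred | truth).sum())
    if union == 0:
        return 1.0
    return int((pred & truth).sum()) / union


def recognition_accuracy(rs: int) -> float:
    """Normalize a recognition score in {0, 1, 2} to a percentage."""
    if rs not in (0, 1, 2):
        raise InvalidInputError(f"recognition score must be 0, 1 or 2, got {rs!r}")
    return rs / 2.0 * 100.0


def adaptive_threshold_binarize(saliency: np.ndarray) -> np.ndarray:
    """Binarize a saliency map at twice its mean (standard benchmark rule).

    The threshold is clipped to the map maximum; pixels strictly above it are
    foreground, so a constant map gives an empty mask (flagged).
    """
    saliency = np.asarray(saliency, dtype=float)
    if saliency.min() < 0 or saliency.max() > 1:
        raise InvalidInputError("saliency values must lie in [0, 1]")
    thresh = min(2.0 * float(saliency.mean()), float(saliency.max()))
    mask = saliency > thresh
    if not mask.any() or mask.all():
        warnings.warn("adaptive binarization produced an empty or full mask", stacklevel=2)
    return mask


def evaluate_mask_pairs(
    pairs: list[tuple[np.ndarray, np.ndarray, str]],
    csv_path: str | Path | None = None,
    beta_sq: float = DEFAULT_BETA_SQ,
) -> dict[str, PRF]:
    """Batch P/R/F over (pred, truth, name) triples; optional CSV report.

    The CSV carries one row per pair plus a ``mean`` row.
    """
    results = {name: prf(pred, truth, beta_sq) for pred, truth, name in pairs}
    if csv_path is not None:
        rows = [(k, v.precision, v.recall, v.f_measure) for k, v in results.items()]
        means = np.mean([[r[1], r[2], r[3]] for r in rows], axis=0) if rows else (0, 0, 0)
        with open(csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["name", "precision", "recall", "f_measure"])
            writer.writerows(rows)
            writer.writerow(["mean", *means])
    return results
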