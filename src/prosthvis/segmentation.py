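"""Saliency-map to binary-mask conversion: dual thresholds, connectivity, morphology.

A single global threshold on a saliency map tends to either bleed into the
background or truncate the object.  The scheme here keeps *strong* pixels
(above a high threshold) unconditionally and *weak* pixels (between the two
thresholds) only when their connected component touches a strong pixel —
hysteresis segmentation — then removes small components and smooths the mask
morphologically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import closing, opening

from prosthvis.errors import DegenerateInputError, InvalidInputError, InvalidParameterError

DEFAULT_MIN_AREA_FRAC = 0.001
DEFAULT_STRUCT_SIZE = 3
DEFAULT_CONNECTIVITY = 8


@dataclass(frozen=True)
class ThresholdPair:
    """Low/high hysteresis thresholds, both in [0, 1] with t_low <= t_high."""

    t_low: float
    t_high: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.t_low <= self.t_high <= 1.0:
            raise InvalidParameterError(
                f"need 0 <= t_low <= t_high <= 1, got ({self.t_low}, {self.t_high})"
            )


def select_thresholds(saliency: np.ndarray, low_ratio: float = 0.5) -> ThresholdPair:
    """Adaptive threshold pair: Otsu for t_high, ``low_ratio * t_high`` for t_low.

    Raises :class:`DegenerateInputError` on a constant map, where no
    between-class separation exists.
    """
    saliency = np.asarray(saliency, dtype=float)
    if saliency.min() < 0 or saliency.max() > 1:
        raise InvalidInputError("saliency values must lie in [0, 1]")
    if np.ptp(saliency) <= 0:
        raise DegenerateInputError("constant saliency map has no Otsu threshold")
    t_high = float(threshold_otsu(saliency, nbins=256))
    return ThresholdPair(t_low=low_ratio * t_high, t_high=min(t_high, 1.0))


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndi.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndi.generate_binary_structure(2, 2)
    raise InvalidParameterError(f"connectivity must be 4 or 8, got {connectivity}")


def hysteresis_segment(
    saliency: np.ndarray, t: ThresholdPair, connectivity: int = DEFAULT_CONNECTIVITY
) -> np.ndarray:
    """Dual-threshold segmentation with connectivity analysis.

    Pixels >= t_high are kept outright; pixels in [t_low, t_high) are kept iff
    their connected component of the >= t_low support (under the chosen
    connectivity) contains a strong pixel.  With t_low == t_high this reduces
    to plain single-threshold segmentation.
    """
    saliency = np.asarray(saliency, dtype=float)
    structure = _structure(connectivity)
    support = saliency >= t.t_low
    strong = saliency >= t.t_high
    if not strong.any():
        return np.zeros(saliency.shape, dtype=bool)
    labels, n_comp = ndi.label(support, structure=structure)
    keep = np.zeros(n_comp + 1, dtype=bool)
    keep[np.unique(labels[strong])] = True
    keep[0] = False
    return keep[labels]


def clean_mask(
    mask: np.ndarray,
    min_area_frac: float = DEFAULT_MIN_AREA_FRAC,
    struct_size: int = DEFAULT_STRUCT_SIZE,
    largest_only: bool = False,
) -> np.ndarray:
    """Morphological cleanup: opening, closing, then small-component removal.

    ``min_area_frac`` is the fraction of total image pixels below which a
    connected component is discarded (isolated specks).  ``largest_only``
    keeps only the largest surviving component, for scenes assumed to hold a
    single main object.
    """
    mask = np.asarray(mask).astype(bool)
    if not 0 <= min_area_frac < 1:
        raise InvalidParameterError(f"min_area_frac must lie in [0, 1), got {min_area_frac}")
    if struct_size < 1 or struct_size % 2 == 0:
        raise InvalidParameterError(f"struct_size must be a positive odd integer, got {struct_size}")

    footprint = np.ones((struct_size, struct_size), dtype=bool)
    out = closing(opening(mask, footprint), footprint)

    cutoff = min_area_frac * mask.size
    labels, n_comp = ndi.label(out, structure=_structure(8))
    if n_comp == 0:
        return out
    areas = np.bincount(labels.ravel())
    keep = areas >= cutoff
    keep[0] = False
    if largest_only and keep.any():
        best = int(np.argmax(np.where(keep, areas, -1)))
        keep = np.zeros_like(keep)
        keep[best] = True
    return keep[labels]


@dataclass(frozen=True)
class SegmentationConfig:
    low_ratio: float = 0.5
    connectivity: int = DEFAULT_CONNECTIVITY
    min_area_frac: float = DEFAULT_MIN_AREA_FRAC
    struct_size: int = DEFAULT_STRUCT_SIZE
    largest_only: bool = False


def segment_saliency(
    saliency: np.ndarray, config: SegmentationConfig = SegmentationConfig()
) -> tuple[np.ndarray, ThresholdPair]:
    """Full mask extraction: threshold selection, hysteresis, cleanup."""
    t = select_thresholds(saliency, config.low_ratio)
    raw = hysteresis_segment(saliency, t, config.connectivity)
    return clean_mask(raw, config.min_area_frac, config.struct_size, config.largest_only), t
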