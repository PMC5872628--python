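"""Foreground presentation strategies for low-resolution prosthetic vision.

Two strategies raise the figure/ground contrast before phosphene pixelization:

FEBR (Foreground Edge detection + Background Reduction)
    The foreground (inside the object mask) is replaced by its binarized
    multiscale edge map, g_F = E(f_F), drawn at full intensity 255; the
    background gray values are linearly halved, g_B = f_B / 2, confining them
    to 0-127; the two are summed over their disjoint supports.

FZE (Foreground Zoom + Edge detection)
    The minimal bounding box of the object mask is cropped, rescaled to fill
    the presented field (aspect-preserving, zero letterbox), the background
    is removed entirely, and the zoomed foreground is edge-detected.  The
    output is binary {0, 255}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from prosthvis.edges import DEFAULT_KERNEL_SIZES, multiscale_edge_magnitude, threshold_edges
from prosthvis.errors import DegenerateInputError, InvalidInputError


@dataclass(frozen=True)
class EdgeConfig:
    """Edge-detection settings shared by both strategies."""

    kernel_sizes: tuple[int, ...] = DEFAULT_KERNEL_SIZES
    threshold: str = "otsu"  # "otsu" or "fixed"
    value: float | None = None


@dataclass(frozen=True)
class ZoomWindow:
    """Inclusive pixel bounds of the zoom crop."""

    top: int
    left: int
    bottom: int
    right: int

    def __post_init__(self) -> None:
        if self.top > self.bottom or self.left > self.right:
            raise InvalidInputError(f"degenerate zoom window {self}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.bottom - self.top + 1, self.right - self.left + 1)


def _check_shapes(image: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    image = np.asarray(image)
    mask = np.asarray(mask).astype(bool)
    if image.shape != mask.shape:
        raise InvalidInputError(f"image shape {image.shape} != mask shape {mask.shape}")
    return image, mask


def split_foreground_background(image: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split into (f_F, f_B): object pixels and background pixels, zero elsewhere."""
    image, mask = _check_shapes(image, mask)
    f_f = np.where(mask, image, 0)
    f_b = np.where(mask, 0, image)
    return f_f, f_b


def _binary_edges(image: np.ndarray, cfg: EdgeConfig) -> np.ndarray:
    mag = multiscale_edge_magnitude(image, cfg.kernel_sizes)
    return threshold_edges(mag, cfg.threshold, cfg.value)


def febr(image: np.ndarray, mask: np.ndarray, edge_cfg: EdgeConfig = EdgeConfig()) -> np.ndarray:
    """Foreground edges at 255 over a background halved into 0-127.

    An empty mask triggers a warning and returns the halved image (background
    reduction only).  Halving uses floor division so 8-bit inputs stay within
    0-127 exactly.
    """
    image, mask = _check_shapes(image, mask)
    image = image.astype(np.uint8)
    g_b = np.where(mask, 0, image // 2).astype(np.uint8)
    if not mask.any():
        warnings.warn("empty object mask: FEBR reduces the whole image", stacklevel=2)
        return g_b
    f_f, _ = split_foreground_background(image, mask)
    edge = _binary_edges(f_f.astype(float), edge_cfg) & mask
    g_f = np.where(edge, 255, 0).astype(np.uint8)
    return (g_f + g_b).astype(np.uint8)  # disjoint supports, no overflow


def zoom_window(mask: np.ndarray, pad_frac: float = 0.0) -> ZoomWindow:
    """Minimal bounding box of the mask's 1-pixels, padded and clipped.

    ``pad_frac`` expands each side by that fraction of the box's extent along
    the corresponding axis, then clips to the image bounds.
    """
    mask = np.asarray(mask).astype(bool)
    if pad_frac < 0:
        raise InvalidInputError(f"pad_frac must be >= 0, got {pad_frac}")
    if not mask.any():
        raise DegenerateInputError("cannot compute a zoom window for an empty mask")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    top, bottom = int(rows[0]), int(rows[-1])
    left, right = int(cols[0]), int(cols[-1])
    pad_r = int(round(pad_frac * (bottom - top + 1)))
    pad_c = int(round(pad_frac * (right - left + 1)))
    return ZoomWindow(
        top=max(0, top - pad_r),
        left=max(0, left - pad_c),
        bottom=min(mask.shape[0] - 1, bottom + pad_r),
        right=min(mask.shape[1] - 1, right + pad_c),
    )


def zoom_to_field(
    image: np.ndarray,
    mask: np.ndarray,
    field_size: tuple[int, int],
    pad_frac: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Crop to the zoom window and rescale to fill ``field_size``.

    The aspect ratio is preserved; the rescaled crop is centered on a zero
    letterbox.  Image resampling is bilinear, mask resampling nearest-neighbor.
    Returns (zoomed_image float, zoomed_mask bool).
    """
    image, mask = _check_shapes(image, mask)
    win = zoom_window(mask, pad_frac)
    crop_img = image[win.top : win.bottom + 1, win.left : win.right + 1].astype(float)
    crop_mask = mask[win.top : win.bottom + 1, win.left : win.right + 1]

    H, W = field_size
    ch, cw = crop_img.shape
    scale = min(H / ch, W / cw)
    oh = max(1, min(H, int(round(ch * scale))))
    ow = max(1, min(W, int(round(cw * scale))))
    if (oh, ow) == (ch, cw):
        scaled_img, scaled_mask = crop_img, crop_mask
    else:
        scaled_img = resize(crop_img, (oh, ow), order=1, anti_aliasing=scale < 1, preserve_range=True)
        scaled_mask = resize(crop_mask.astype(float), (oh, ow), order=0, preserve_range=True) > 0.5

    out_img = np.zeros((H, W))
    out_mask = np.zeros((H, W), dtype=bool)
    r0 = (H - oh) // 2
    c0 = (W - ow) // 2
    out_img[r0 : r0 + oh, c0 : c0 + ow] = scaled_img
    out_mask[r0 : r0 + oh, c0 : c0 + ow] = scaled_mask
    return out_img, out_mask


def fze(
    image: np.ndarray,
    mask: np.ndarray,
    field_size: tuple[int, int] | None = None,
    edge_cfg: EdgeConfig = EdgeConfig(),
    pad_frac: float = 0.05,
) -> np.ndarray:
    """Zoom the object to fill the field, drop the background, edge-detect.

    ``field_size`` defaults to the input shape.  Output is uint8 {0, 255}:
    edge pixels of the zoomed foreground at 255, everything else 0.
    """
    image, mask = _check_shapes(image, mask)
    if field_size is None:
        field_size = image.shape
    zoom_img, zoom_mask = zoom_to_field(image, mask, field_size, pad_frac)
    zoom_img = np.where(zoom_mask, zoom_img, 0.0)  # background clutter removal
    edge = _binary_edges(zoom_img, edge_cfg) & zoom_mask
    return np.where(edge, 255, 0).astype(np.uint8)
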