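"""Multiscale Sobel edge detection with geometric-mean fusion.

A small Sobel kernel localizes edges precisely but fires on noise; a large one
is noise-robust but blurs localization.  Computing gradient magnitudes at
several kernel sizes and fusing them by the pointwise geometric mean keeps
only responses present at *every* scale, suppressing spurious single-scale
edges.

The 3x3 kernel is the classic Sobel operator.  Larger kernels follow the same
smoothed-derivative construction: the separable outer product of a binomial
smoothing vector of length N and a central-difference derivative convolved
with a binomial of length N-2.  For N=7 this gives, bit-exactly,

    smoothing  s7 = [1, 6, 15, 20, 15, 6, 1]
    derivative d7 = [-1, -4, -5, 0, 5, 4, 1]      # conv([1,4,6,4,1], [-1,0,1])
    Gx kernel     = outer(s7, d7),   Gy kernel = outer(d7, s7)

which reduces to the ordinary Sobel kernel at N=3 (s3=[1,2,1], d3=[-1,0,1]).
Borders are handled by reflect-101 (mirror without repeating the edge sample).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from prosthvis.errors import InvalidInputError, InvalidParameterError

DEFAULT_KERNEL_SIZES = (3, 7)


def _smoothing_and_derivative(size: int) -> tuple[np.ndarray, np.ndarray]:
    if size < 3 or size % 2 == 0:
        raise InvalidParameterError(f"kernel size must be an odd integer >= 3, got {size}")
    smooth = np.array([1.0])
    for _ in range(size - 1):
        smooth = np.convolve(smooth, [1.0, 1.0])
    inner = np.array([1.0])
    for _ in range(size - 3):
        inner = np.convolve(inner, [1.0, 1.0])
    deriv = np.convolve(inner, [-1.0, 0.0, 1.0])
    return smooth, deriv


def sobel_kernels(size: int) -> tuple[np.ndarray, np.ndarray]:
    """Return the (Gx, Gy) derivative kernels of the given odd size."""
    smooth, deriv = _smoothing_and_derivative(size)
    return np.outer(smooth, deriv), np.outer(deriv, smooth)


@dataclass(frozen=True)
class GradientField:
    """Horizontal/vertical gradients with magnitude and direction.

    ``direction`` is informational; by default it is the conventional
    ``arctan2(Gy, Gx)``.
    """

    Gx: np.ndarray
    Gy: np.ndarray
    magnitude: np.ndarray
    direction: np.ndarray
    kernel_size: int


def sobel_gradient(
    image: np.ndarray,
    kernel_size: int = 3,
    direction_convention: str = "math",
) -> GradientField:
    """Convolve a grayscale image with the Sobel derivative kernels.

    ``direction_convention``: ``"math"`` gives arctan2(Gy, Gx); ``"swapped"``
    gives arctan2(Gx, Gy), the axis-swapped variant some texts print.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InvalidInputError(f"expected a 2-D grayscale image, got shape {img.shape}")
    if kernel_size not in (3, 7):
        raise InvalidParameterError(f"kernel_size must be 3 or 7, got {kernel_size}")
    kx, ky = sobel_kernels(kernel_size)
    gx = ndi.correlate(img, kx, mode="mirror")
    gy = ndi.correlate(img, ky, mode="mirror")
    if direction_convention == "math":
        direction = np.arctan2(gy, gx)
    elif direction_convention == "swapped":
        direction = np.arctan2(gx, gy)
    else:
        raise InvalidParameterError(f"unknown direction convention {direction_convention!r}")
    return GradientField(
        Gx=gx, Gy=gy, magnitude=np.hypot(gx, gy), direction=direction, kernel_size=kernel_size
    )


def multiscale_magnitude(fields: Sequence[GradientField | np.ndarray]) -> np.ndarray:
    """Pointwise geometric mean of per-scale gradient magnitudes."""
    if len(fields) < 1:
        raise InvalidInputError("need at least one gradient field")
    mags = [f.magnitude if isinstance(f, GradientField) else np.asarray(f, dtype=float) for f in fields]
    shape = mags[0].shape
    if any(m.shape != shape for m in mags):
        raise InvalidInputError("all magnitude rasters must share one shape")
    prod = np.ones(shape)
    for m in mags:
        prod *= m
    return prod ** (1.0 / len(mags))


def multiscale_edge_magnitude(
    image: np.ndarray, kernel_sizes: Iterable[int] = DEFAULT_KERNEL_SIZES
) -> np.ndarray:
    """Fused multiscale gradient magnitude of a grayscale image."""
    sizes = tuple(kernel_sizes)
    return multiscale_magnitude([sobel_gradient(image, k) for k in sizes])


def threshold_edges(
    magnitude: np.ndarray, method: str = "otsu", value: float | None = None
) -> np.ndarray:
    """Binarize a gradient magnitude raster.

    ``method="otsu"`` picks the threshold from the magnitude histogram;
    ``method="fixed"`` uses ``value``.  Pixels strictly above the threshold
    are edges.  A constant magnitude raster yields an empty mask.
    """
    magnitude = np.asarray(magnitude, dtype=float)
    if magnitude.min() < 0:
        raise InvalidInputError("gradient magnitudes must be nonnegative")
    if method == "fixed":
        if value is None:
            raise InvalidParameterError("fixed thresholding requires a value")
        thresh = float(value)
    elif method == "otsu":
        if np.ptp(magnitude) <= 0:
            return np.zeros(magnitude.shape, dtype=bool)
        thresh = float(threshold_otsu(magnitude, nbins=256))
    else:
        raise InvalidParameterError(f"unknown thresholding method {method!r}")
    return magnitude > thresh
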