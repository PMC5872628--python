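"""Gaussian phosphene rendering: Lowering Resolution with Gaussian dots (LRG).

A retinal implant with an N×N electrode array can convey at most N×N
luminance samples.  LRG emulates that percept: the image is partitioned into
an N×N grid of near-equal tiles, the mean gray of each tile drives one
phosphene, and each phosphene is drawn as a radially symmetric Gaussian
luminance profile

    I(x, y) = A(u) * exp(-((x - u_x)^2 + (y - u_y)^2) / (2 sigma^2))

centered at the tile center u (snapped to the nearest pixel), truncated at
3 sigma.  Phosphenes are
peak-normalized (peak luminance equals the tile amplitude) so a constant
image produces a constant-brightness dot array independent of sigma; the
density-normalized variant, which scales peaks by 1/(2 pi sigma^2), is
available via ``normalization="density"``.  Overlapping phosphenes combine
by pointwise maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from prosthvis.errors import InvalidInputError, InvalidParameterError

#: The resolutions an implant simulation sweeps by default.
DEFAULT_RESOLUTIONS = (8, 16, 24, 32, 48, 64)
#: Default Gaussian spread as a fraction of the dot pitch (visually separated dots).
DEFAULT_SIGMA_RATIO = 1.0 / 6.0


@dataclass(frozen=True)
class PhospheneGrid:
    """N×N phosphene amplitudes with the geometry used to render them.

    ``pitch`` is the (row, col) tile size in pixels; ``sigma`` the Gaussian
    spread in pixels.
    """

    amplitudes: np.ndarray
    resolution: int
    pitch: tuple[float, float]
    sigma: float


@dataclass(frozen=True)
class PhosphenePercept:
    """Rendered percept raster plus the amplitude grid that produced it."""

    raster: np.ndarray
    grid: PhospheneGrid


def _tile_bounds(length: int, n: int) -> np.ndarray:
    """n+1 integer tile boundaries splitting ``length`` as evenly as possible."""
    return np.floor(np.linspace(0, length, n + 1) + 0.5).astype(int)


def block_amplitudes(
    image: np.ndarray,
    resolution: int,
    sigma_ratio: float = DEFAULT_SIGMA_RATIO,
) -> PhospheneGrid:
    """Partition the image into an N×N tile grid and average each tile.

    Tiles differ by at most one pixel per axis when the image side is not
    divisible by N.  ``sigma`` is recorded as ``sigma_ratio`` times the
    smaller pitch.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InvalidInputError(f"expected a 2-D grayscale image, got shape {img.shape}")
    h, w = img.shape
    if resolution < 1 or resolution > min(h, w):
        raise InvalidParameterError(
            f"resolution must lie in [1, min(H, W)] = [1, {min(h, w)}], got {resolution}"
        )
    rb = _tile_bounds(h, resolution)
    cb = _tile_bounds(w, resolution)
    # mean per tile via two reduceat passes (rows then cols), then per-tile area
    row_sums = np.add.reduceat(img, rb[:-1], axis=0)
    tile_sums = np.add.reduceat(row_sums, cb[:-1], axis=1)
    areas = np.outer(np.diff(rb), np.diff(cb)).astype(float)
    amplitudes = tile_sums / areas
    pitch = (h / resolution, w / resolution)
    return PhospheneGrid(
        amplitudes=amplitudes,
        resolution=resolution,
        pitch=pitch,
        sigma=sigma_ratio * min(pitch),
    )


def render_phosphenes(
    grid: PhospheneGrid,
    field_size: tuple[int, int],
    normalization: str = "peak",
) -> PhosphenePercept:
    """Draw each amplitude as a truncated Gaussian dot at its tile center.

    Dots are truncated at 3 sigma and combined by maximum; the raster is
    clipped to [0, 255].
    """
    if grid.sigma <= 0:
        raise InvalidParameterError(f"sigma must be positive, got {grid.sigma}")
    if normalization not in ("peak", "density"):
        raise InvalidParameterError(f"unknown normalization {normalization!r}")
    H, W = field_size
    n = grid.resolution
    rb = _tile_bounds(H, n)
    cb = _tile_bounds(W, n)
    # tile centers snapped to the nearest pixel so each dot's peak sample
    # equals its amplitude exactly
    r_centers = np.round((rb[:-1] + rb[1:] - 1) / 2.0).astype(int)
    c_centers = np.round((cb[:-1] + cb[1:] - 1) / 2.0).astype(int)

    sigma = grid.sigma
    radius = int(np.ceil(3.0 * sigma))
    peak_scale = 1.0 if normalization == "peak" else 1.0 / (2.0 * np.pi * sigma**2)

    out = np.zeros((H, W))
    for i in range(n):
        cy = r_centers[i]
        r0 = max(0, int(np.floor(cy)) - radius)
        r1 = min(H, int(np.ceil(cy)) + radius + 1)
        dy2 = (np.arange(r0, r1) - cy) ** 2
        for j in range(n):
            amp = grid.amplitudes[i, j] * peak_scale
            if amp <= 0:
                continue
            cx = c_centers[j]
            c0 = max(0, int(np.floor(cx)) - radius)
            c1 = min(W, int(np.ceil(cx)) + radius + 1)
            dx2 = (np.arange(c0, c1) - cx) ** 2
            d2 = dy2[:, None] + dx2[None, :]
            dot = amp * np.exp(-d2 / (2.0 * sigma**2))
            dot[d2 > (3.0 * sigma) ** 2] = 0.0
            patch = out[r0:r1, c0:c1]
            np.maximum(patch, dot, out=patch)
    return PhosphenePercept(raster=np.clip(out, 0.0, 255.0), grid=grid)


def lrg(
    image: np.ndarray,
    resolution: int,
    sigma_ratio: float = DEFAULT_SIGMA_RATIO,
    normalization: str = "peak",
) -> PhosphenePercept:
    """Full LRG pixelization: tile averaging followed by Gaussian rendering."""
    if sigma_ratio <= 0:
        raise InvalidParameterError(f"sigma_ratio must be positive, got {sigma_ratio}")
    grid = block_amplitudes(image, resolution, sigma_ratio)
    return render_phosphenes(grid, np.asarray(image).shape, normalization)


def lrg_batch(
    image: np.ndarray,
    resolutions: tuple[int, ...] = DEFAULT_RESOLUTIONS,
    sigma_ratio: float = DEFAULT_SIGMA_RATIO,
    normalization: str = "peak",
) -> dict[int, PhosphenePercept]:
    """One percept per configured resolution (default sweep: 8..64)."""
    return {n: lrg(image, n, sigma_ratio, normalization) for n in resolutions}
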