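"""Two-stage salient-object detection via manifold ranking on a superpixel graph.

The image is partitioned into SLIC superpixels, each of which becomes a node of
a weighted undirected graph.  Saliency is posed as semi-supervised graph
labeling: given a binary query indicator ``y`` over the nodes, the manifold
ranking vector is the solution of the regularized linear system

    f = (1 - alpha) (D - alpha W)^{-1} y

where ``W`` is the affinity matrix, ``D`` the degree matrix and
``alpha`` in (0, 1) trades the initial label term against neighborhood
propagation.

Stage one exploits the boundary prior: superpixels touching each of the four
image sides are used in turn as *background* queries, yielding four maps
``S_side(i) = 1 - f_norm(i)`` whose pointwise product is the stage-one map.
Stage two thresholds that map at its mean, takes the super-threshold nodes as
*foreground* queries, and ranks again; the normalized ranking vector is the
final saliency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from skimage.color import gray2rgb, rgb2lab
from skimage.segmentation import slic
from skimage.util import img_as_float

from prosthvis.errors import (
    DegenerateInputError,
    InvalidInputError,
    InvalidParameterError,
    NumericalError,
)

#: Default propagation parameter of the ranking system.
DEFAULT_ALPHA = 0.99
#: Default superpixel count requested from SLIC.
DEFAULT_N_TARGET = 200
#: Default color bandwidth of the affinity weights (on [0,1]-scaled Lab channels).
DEFAULT_SIGMA_C = 0.1
#: Default SLIC compactness (space/color trade-off).
DEFAULT_COMPACTNESS = 10.0


@dataclass(frozen=True)
class Superpixels:
    """SLIC partition of an image plus per-superpixel summary statistics.

    ``labels`` holds one contiguous integer label ``0..n-1`` per pixel;
    ``mean_color`` is the mean CIELAB color of each superpixel with every
    channel rescaled to [0, 1] (L/100, (a+128)/255, (b+128)/255) so that
    color distances are commensurate with the affinity bandwidth ``sigma_c``.
    The four boundary flag arrays mark superpixels owning at least one pixel
    on the corresponding image side.
    """

    labels: np.ndarray
    n: int
    mean_color: np.ndarray
    centroid: np.ndarray
    is_boundary_top: np.ndarray
    is_boundary_bottom: np.ndarray
    is_boundary_left: np.ndarray
    is_boundary_right: np.ndarray


@dataclass(frozen=True)
class AffinityGraph:
    """Weighted undirected graph over superpixels.

    ``W`` is symmetric with zero diagonal and nonnegative weights; ``degrees``
    are its row sums.  ``edges`` is the boolean connectivity mask that was used
    to sparsify ``W`` (adjacent + two-hop + boundary closure).
    """

    W: np.ndarray
    degrees: np.ndarray
    edges: np.ndarray

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def D(self) -> np.ndarray:
        """Dense diagonal degree matrix (small graphs only; prefer ``degrees``)."""
        return np.diag(self.degrees)


@dataclass(frozen=True)
class RankingVector:
    """Raw manifold-ranking values ``f`` and their min-max normalization."""

    f: np.ndarray
    f_norm: np.ndarray


@dataclass(frozen=True)
class SaliencyField:
    """Per-superpixel saliency scores in [0, 1] and their pixel-level upsampling."""

    scores: np.ndarray
    pixel_map: np.ndarray


def _as_float_rgb(image: np.ndarray) -> np.ndarray:
    """Return a float RGB copy in [0, 1]; grayscale inputs are replicated."""
    img = img_as_float(np.asarray(image))
    if img.ndim == 2:
        img = gray2rgb(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidInputError(f"expected 2-D grayscale or 3-channel image, got shape {img.shape}")
    return img


def scaled_lab(image: np.ndarray) -> np.ndarray:
    """CIELAB conversion with all channels rescaled to [0, 1].

    L spans [0, 100] and a/b span roughly [-128, 127]; fixed affine rescaling
    keeps distances comparable across channels and images.
    """
    lab = rgb2lab(_as_float_rgb(image))
    out = np.empty_like(lab)
    out[..., 0] = lab[..., 0] / 100.0
    out[..., 1] = (lab[..., 1] + 128.0) / 255.0
    out[..., 2] = (lab[..., 2] + 128.0) / 255.0
    return out


def compute_superpixels(
    image: np.ndarray,
    n_target: int = DEFAULT_N_TARGET,
    compactness: float = DEFAULT_COMPACTNESS,
    seed: int = 0,
) -> Superpixels:
    """Partition ``image`` into SLIC superpixels.

    Parameters
    ----------
    image:
        2-D grayscale or RGB raster, at least 2x2.
    n_target:
        Requested superpixel count (>= 4); the achieved count ``n`` may differ
        and is recorded on the result.
    compactness:
        SLIC space/color trade-off; larger values give squarer superpixels.
    seed:
        Accepted for interface stability; the SLIC initialization used here is
        deterministic, so the output is identical for any seed.
    """
    img = np.asarray(image)
    if img.ndim < 2 or img.shape[0] < 2 or img.shape[1] < 2:
        raise InvalidInputError(f"image must be at least 2x2, got shape {img.shape}")
    if n_target < 4:
        raise InvalidParameterError(f"n_target must be >= 4, got {n_target}")
    if compactness <= 0:
        raise InvalidParameterError(f"compactness must be positive, got {compactness}")
    del seed  # determinism contract: SLIC k-means init is grid-based

    rgb = _as_float_rgb(img)
    labels = slic(
        rgb,
        n_segments=n_target,
        compactness=compactness,
        start_label=0,
        enforce_connectivity=True,
        convert2lab=True,
        channel_axis=-1,
    )
    # relabel to contiguous 0..n-1 (SLIC can skip labels after merging)
    uniq, labels = np.unique(labels, return_inverse=True)
    labels = labels.reshape(rgb.shape[:2]).astype(np.int64)
    n = uniq.size

    lab = scaled_lab(rgb)
    flat = labels.ravel()
    counts = np.bincount(flat, minlength=n).astype(float)
    mean_color = np.stack(
        [np.bincount(flat, weights=lab[..., c].ravel(), minlength=n) / counts for c in range(3)],
        axis=1,
    )
    rows, cols = np.indices(labels.shape)
    centroid = np.stack(
        [
            np.bincount(flat, weights=rows.ravel(), minlength=n) / counts,
            np.bincount(flat, weights=cols.ravel(), minlength=n) / counts,
        ],
        axis=1,
    )

    def side_flags(side_labels: np.ndarray) -> np.ndarray:
        out = np.zeros(n, dtype=bool)
        out[np.unique(side_labels)] = True
        return out

    return Superpixels(
        labels=labels,
        n=n,
        mean_color=mean_color,
        centroid=centroid,
        is_boundary_top=side_flags(labels[0, :]),
        is_boundary_bottom=side_flags(labels[-1, :]),
        is_boundary_left=side_flags(labels[:, 0]),
        is_boundary_right=side_flags(labels[:, -1]),
    )


def _adjacency(labels: np.ndarray, n: int) -> np.ndarray:
    """Boolean superpixel adjacency from 8-connected pixel neighborhoods."""
    adj = np.zeros((n, n), dtype=bool)
    pairs = [
        (labels[:, :-1], labels[:, 1:]),
        (labels[:-1, :], labels[1:, :]),
        (labels[:-1, :-1], labels[1:, 1:]),
        (labels[:-1, 1:], labels[1:, :-1]),
    ]
    for a, b in pairs:
        a = a.ravel()
        b = b.ravel()
        diff = a != b
        adj[a[diff], b[diff]] = True
    adj |= adj.T
    np.fill_diagonal(adj, False)
    return adj


def build_closed_loop_graph(sp_: Superpixels, sigma_c: float = DEFAULT_SIGMA_C) -> AffinityGraph:
    """Build the closed-loop affinity graph over superpixels.

    Edges connect (a) spatially adjacent superpixels, (b) superpixels sharing
    a common neighbor (two-hop), and (c) every pair of image-boundary
    superpixels, closing the border into a loop so background regions on
    opposite sides communicate.  Connected pairs are weighted by

        w_ij = exp(-||c_i - c_j|| / sigma_c^2)

    with ``c`` the [0,1]-scaled mean Lab color.
    """
    if sp_.n < 2:
        raise InvalidInputError(f"graph needs at least 2 superpixels, got {sp_.n}")
    if sigma_c <= 0:
        raise InvalidParameterError(f"sigma_c must be positive, got {sigma_c}")

    n = sp_.n
    adj = _adjacency(sp_.labels, n)
    two_hop = (adj.astype(np.uint8) @ adj.astype(np.uint8)) > 0
    edges = adj | two_hop
    boundary = sp_.is_boundary_top | sp_.is_boundary_bottom | sp_.is_boundary_left | sp_.is_boundary_right
    edges[np.ix_(boundary, boundary)] = True
    np.fill_diagonal(edges, False)

    diff = sp_.mean_color[:, None, :] - sp_.mean_color[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=2))
    W = np.where(edges, np.exp(-dist / sigma_c**2), 0.0)
    np.fill_diagonal(W, 0.0)
    return AffinityGraph(W=W, degrees=W.sum(axis=1), edges=edges)


def _minmax(f: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(f)), float(np.max(f))
    if hi - lo <= 0:
        warnings.warn("constant ranking vector; normalization maps it to all-zeros", stacklevel=3)
        return np.zeros_like(f)
    return (f - lo) / (hi - lo)


def manifold_rank(graph: AffinityGraph, y: np.ndarray, alpha: float = DEFAULT_ALPHA) -> RankingVector:
    """Solve the manifold-ranking system ``f = (1-alpha)(D - alpha W)^{-1} y``.

    ``y`` must be a binary query indicator of length ``graph.n``.  The system
    is symmetric positive definite for ``alpha`` in (0, 1) on a connected
    graph; a singular or non-finite solve raises :class:`NumericalError`.
    """
    if not 0 < alpha < 1:
        raise InvalidParameterError(f"alpha must lie in (0, 1), got {alpha}")
    y = np.asarray(y, dtype=float).ravel()
    if y.size != graph.n:
        raise InvalidInputError(f"query indicator length {y.size} != graph size {graph.n}")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise InvalidInputError("query indicator must be binary")

    M = sp.csr_matrix(np.diag(graph.degrees) - alpha * graph.W)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", spla.MatrixRankWarning)
            f = spla.spsolve(M, (1.0 - alpha) * y)
    except (spla.MatrixRankWarning, RuntimeError) as exc:
        raise NumericalError(f"ranking system (D - alpha W) is singular: {exc}") from exc
    if not np.all(np.isfinite(f)):
        raise NumericalError("ranking solve produced non-finite values (disconnected or degenerate graph)")
    return RankingVector(f=f, f_norm=_minmax(f))


def upsample_saliency(scores: np.ndarray, sp_: Superpixels) -> np.ndarray:
    """Broadcast per-superpixel ``scores`` to a pixel raster via the label map."""
    scores = np.asarray(scores, dtype=float).ravel()
    if scores.size != sp_.n:
        raise InvalidInputError(f"score vector length {scores.size} != superpixel count {sp_.n}")
    return scores[sp_.labels]


def boundary_stage_saliency(
    graph: AffinityGraph, sp_: Superpixels, alpha: float = DEFAULT_ALPHA
) -> SaliencyField:
    """Stage one: background queries from each image side, fused by product.

    For each side the boundary superpixels are the queries; the side map is
    ``1 - f_norm`` so nodes similar to that border score low.  The four side
    maps are multiplied, which keeps only nodes dissimilar from *every* border.
    """
    sides = {
        "top": sp_.is_boundary_top,
        "bottom": sp_.is_boundary_bottom,
        "left": sp_.is_boundary_left,
        "right": sp_.is_boundary_right,
    }
    product = np.ones(graph.n)
    for name, flags in sides.items():
        if not flags.any():
            raise InvalidInputError(f"no boundary superpixels on side '{name}'")
        ranking = manifold_rank(graph, flags.astype(float), alpha)
        product *= 1.0 - ranking.f_norm
    return SaliencyField(scores=product, pixel_map=upsample_saliency(product, sp_))


def foreground_query_saliency(
    graph: AffinityGraph,
    sp_: Superpixels,
    stage1: SaliencyField,
    alpha: float = DEFAULT_ALPHA,
    zero_inverse_diagonal: bool = True,
) -> SaliencyField:
    """Stage two: re-rank with foreground queries seeded from the stage-one map.

    Seeds are the nodes scoring at or above the stage-one mean.  By default
    the diagonal of ``(D - alpha W)^{-1}`` is zeroed before applying it to the
    query vector, so a query node's own label does not dominate its score:
    without this, a single low-degree seed's self-term can dwarf every other
    ranking value and the min-max normalization collapses the map.  Pass
    ``zero_inverse_diagonal=False`` for the plain solve.
    """
    scores = np.asarray(stage1.scores, dtype=float)
    if scores.size != graph.n:
        raise InvalidInputError("stage-one field does not match graph size")
    if np.ptp(scores) <= 0:
        raise DegenerateInputError("stage-one saliency is constant; cannot seed foreground queries")
    y = (scores >= scores.mean()).astype(float)

    if zero_inverse_diagonal:
        if not 0 < alpha < 1:
            raise InvalidParameterError(f"alpha must lie in (0, 1), got {alpha}")
        A = np.linalg.inv(np.diag(graph.degrees) - alpha * graph.W)
        np.fill_diagonal(A, 0.0)
        f = (1.0 - alpha) * (A @ y)
        final = _minmax(f)
    else:
        final = manifold_rank(graph, y, alpha).f_norm
    return SaliencyField(scores=final, pixel_map=upsample_saliency(final, sp_))


@dataclass(frozen=True)
class SaliencyConfig:
    """Parameters of the full two-stage detector."""

    alpha: float = DEFAULT_ALPHA
    n_target: int = DEFAULT_N_TARGET
    compactness: float = DEFAULT_COMPACTNESS
    sigma_c: float = DEFAULT_SIGMA_C
    zero_inverse_diagonal: bool = True
    seed: int = 0


def detect_salient_object(
    image: np.ndarray, config: SaliencyConfig = SaliencyConfig()
) -> tuple[SaliencyField, SaliencyField, Superpixels]:
    """Run both stages; returns (final field, stage-one field, superpixels)."""
    sp_ = compute_superpixels(image, config.n_target, config.compactness, config.seed)
    graph = build_closed_loop_graph(sp_, config.sigma_c)
    stage1 = boundary_stage_saliency(graph, sp_, config.alpha)
    stage2 = foreground_query_saliency(
        graph, sp_, stage1, config.alpha, config.zero_inverse_diagonal
    )
    return stage2, stage1, sp_
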