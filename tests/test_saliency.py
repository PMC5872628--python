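"""Superpixel graph construction and two-stage manifold-ranking saliency."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from prosthvis import saliency
from prosthvis.errors import (
    DegenerateInputError,
    InvalidInputError,
    InvalidParameterError,
    NumericalError,
)

from conftest import random_connected_graph


class TestSuperpixels:
    def test_labels_contiguous_and_connected(self, disc_scene):
        img, _, _ = disc_scene
        sp_ = saliency.compute_superpixels(img, n_target=100)
        assert sorted(np.unique(sp_.labels)) == list(range(sp_.n))
        for lbl in range(sp_.n):
            _, n_comp = ndi.label(sp_.labels == lbl, structure=np.ones((3, 3)))
            assert n_comp == 1, f"superpixel {lbl} is disconnected"

    def test_deterministic_for_fixed_inputs(self, disc_scene):
        img, _, _ = disc_scene
        a = saliency.compute_superpixels(img, n_target=80, seed=1)
        b = saliency.compute_superpixels(img, n_target=80, seed=1)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_uniform_image_gives_near_equal_blocks(self):
        sp_ = saliency.compute_superpixels(np.full((64, 64), 100, np.uint8), n_target=4)
        assert sp_.n == 4
        areas = np.bincount(sp_.labels.ravel())
        assert areas.min() > 0.8 * areas.max()

    def test_disc_majority_superpixels_match_disc_color(self, disc_scene):
        """Superpixels majority-inside the disc carry the disc's color, not the background's."""
        img, mask, spec = disc_scene
        sp_ = saliency.compute_superpixels(img, n_target=100)
        # brute-force per-superpixel majority vote against the ground-truth mask
        inside = np.bincount(sp_.labels.ravel(), weights=mask.ravel(), minlength=sp_.n)
        total = np.bincount(sp_.labels.ravel(), minlength=sp_.n)
        majority = inside / total > 0.5
        assert majority.any()
        for lbl in np.flatnonzero(majority):
            l_val = sp_.mean_color[lbl, 0]
            assert abs(l_val - _gray_to_scaled_l(spec.object_gray)) < abs(
                l_val - _gray_to_scaled_l(spec.background_gray)
            )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            saliency.compute_superpixels(np.zeros((1, 5)))
        with pytest.raises(InvalidParameterError):
            saliency.compute_superpixels(np.zeros((32, 32)), n_target=3)


def _gray_to_scaled_l(gray: int) -> float:
    img = np.full((1, 1), gray, np.uint8)
    return float(saliency.scaled_lab(img)[0, 0, 0])


def _block_superpixels(n_side: int, block: int = 4) -> saliency.Superpixels:
    """Hand-built Superpixels: an n_side x n_side grid of uniform blocks."""
    size = n_side * block
    rows = np.repeat(np.arange(n_side), block)
    labels = (rows[:, None] * n_side + rows[None, :]).astype(np.int64)
    n = n_side * n_side
    colors = np.tile(np.linspace(0.2, 0.8, n)[:, None], (1, 3))
    cent = np.array([[(l // n_side) * block + block / 2, (l % n_side) * block + block / 2] for l in range(n)])
    flags = {
        "is_boundary_top": np.isin(np.arange(n), np.arange(n_side)),
        "is_boundary_bottom": np.isin(np.arange(n), np.arange(n * 1 - n_side, n)),
        "is_boundary_left": np.arange(n) % n_side == 0,
        "is_boundary_right": np.arange(n) % n_side == n_side - 1,
    }
    return saliency.Superpixels(labels=labels, n=n, mean_color=colors, centroid=cent, **flags)


class TestClosedLoopGraph:
    def test_identical_colors_weight_one(self):
        sp_ = _block_superpixels(2)
        sp_ = saliency.Superpixels(
            labels=sp_.labels, n=sp_.n, mean_color=np.full((4, 3), 0.5), centroid=sp_.centroid,
            is_boundary_top=sp_.is_boundary_top, is_boundary_bottom=sp_.is_boundary_bottom,
            is_boundary_left=sp_.is_boundary_left, is_boundary_right=sp_.is_boundary_right,
        )
        g = saliency.build_closed_loop_graph(sp_)
        assert g.W[0, 1] == pytest.approx(1.0)

    def test_corner_blocks_joined_by_boundary_closure(self):
        # 3x3 block grid: corners 0 and 8 are not adjacent, not two-hop-adjacent
        # through interior alone, but both lie on the image boundary
        g = saliency.build_closed_loop_graph(_block_superpixels(3))
        assert g.edges[0, 8] and g.W[0, 8] > 0

    def test_degrees_match_independent_row_summation(self, disc_scene):
        img, _, _ = disc_scene
        sp_ = saliency.compute_superpixels(img, n_target=12)
        g = saliency.build_closed_loop_graph(sp_)
        oracle = np.array([sum(g.W[i, j] for j in range(g.n)) for i in range(g.n)])
        np.testing.assert_allclose(g.degrees, oracle, rtol=0, atol=1e-12)
        assert np.allclose(g.W, g.W.T) and np.all(np.diag(g.W) == 0)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(InvalidParameterError):
            saliency.build_closed_loop_graph(_block_superpixels(2), sigma_c=0.0)


class TestManifoldRank:
    def test_zero_query_gives_zero_ranking(self):
        g = random_connected_graph(np.random.default_rng(0), 8)
        r = saliency.manifold_rank(g, np.zeros(8))
        np.testing.assert_allclose(r.f, 0.0)

    def test_two_node_hand_solution(self):
        """(D - 0.5 W)^{-1} for W=[[0,1],[1,0]], D=I gives f=[2/3, 1/3] on y=[1,0]."""
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        g = saliency.AffinityGraph(W=W, degrees=W.sum(1), edges=W > 0)
        r = saliency.manifold_rank(g, np.array([1.0, 0.0]), alpha=0.5)
        np.testing.assert_allclose(r.f, [2.0 / 3.0, 1.0 / 3.0], atol=1e-12)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_dense_direct_solve(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(5, 51))
        g = random_connected_graph(rng, n)
        y = (rng.random(n) < 0.3).astype(float)
        alpha = float(rng.uniform(0.5, 0.99))
        r = saliency.manifold_rank(g, y, alpha)
        oracle = (1 - alpha) * np.linalg.solve(np.diag(g.degrees) - alpha * g.W, y)
        np.testing.assert_allclose(r.f, oracle, atol=1e-10)

    def test_isolated_node_raises_numerical_error(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0  # node 2 has degree zero -> singular system
        g = saliency.AffinityGraph(W=W, degrees=W.sum(1), edges=W > 0)
        with pytest.raises(NumericalError):
            saliency.manifold_rank(g, np.array([1.0, 0.0, 0.0]))

    def test_parameter_validation(self):
        g = random_connected_graph(np.random.default_rng(0), 5)
        with pytest.raises(InvalidParameterError):
            saliency.manifold_rank(g, np.zeros(5), alpha=1.0)
        with pytest.raises(InvalidInputError):
            saliency.manifold_rank(g, np.full(5, 0.5))


class TestTwoStageSaliency:
    def test_stage_one_bounded_by_each_side_map(self, disc_saliency):
        sp_, graph, stage1, _ = disc_saliency
        for flags in (sp_.is_boundary_top, sp_.is_boundary_bottom, sp_.is_boundary_left, sp_.is_boundary_right):
            side = 1.0 - saliency.manifold_rank(graph, flags.astype(float)).f_norm
            assert np.all(stage1.scores <= side + 1e-12)
        assert stage1.scores.min() >= 0 and stage1.scores.max() <= 1

    def test_object_scores_above_background(self, disc_scene, disc_saliency):
        _, mask, _ = disc_scene
        sp_, _, stage1, stage2 = disc_saliency
        inside = np.bincount(sp_.labels.ravel(), weights=mask.ravel(), minlength=sp_.n)
        majority = inside / np.bincount(sp_.labels.ravel(), minlength=sp_.n) > 0.5
        sep1 = stage1.scores[majority].mean() - stage1.scores[~majority].mean()
        sep2 = stage2.scores[majority].mean() - stage2.scores[~majority].mean()
        assert sep1 > 0
        # the foreground re-ranking highlights the object at least as uniformly
        assert sep2 >= sep1

    def test_stage_two_matches_dense_oracle(self, disc_saliency):
        """Default stage two applies the zero-diagonal inverse to the seed vector."""
        sp_, graph, stage1, stage2 = disc_saliency
        alpha = saliency.DEFAULT_ALPHA
        y = (stage1.scores >= stage1.scores.mean()).astype(float)
        A = np.linalg.inv(np.diag(graph.degrees) - alpha * graph.W)
        A[np.diag_indices_from(A)] = 0.0
        f = (1 - alpha) * (A @ y)
        oracle = (f - f.min()) / (f.max() - f.min())
        np.testing.assert_allclose(stage2.scores, oracle, atol=1e-9)

    def test_plain_solve_variant_available(self, disc_saliency):
        sp_, graph, stage1, _ = disc_saliency
        alpha = saliency.DEFAULT_ALPHA
        plain = saliency.foreground_query_saliency(
            graph, sp_, stage1, zero_inverse_diagonal=False
        )
        y = (stage1.scores >= stage1.scores.mean()).astype(float)
        f = (1 - alpha) * np.linalg.solve(np.diag(graph.degrees) - alpha * graph.W, y)
        oracle = (f - f.min()) / (f.max() - f.min())
        np.testing.assert_allclose(plain.scores, oracle, atol=1e-9)

    def test_constant_stage_one_is_degenerate(self, disc_saliency):
        sp_, graph, _, _ = disc_saliency
        flat = saliency.SaliencyField(scores=np.full(graph.n, 0.4), pixel_map=np.full(sp_.labels.shape, 0.4))
        with pytest.raises(DegenerateInputError):
            saliency.foreground_query_saliency(graph, sp_, flat)

    def test_missing_boundary_side_rejected(self):
        sp_ = _block_superpixels(2)
        broken = saliency.Superpixels(
            labels=sp_.labels, n=sp_.n, mean_color=sp_.mean_color, centroid=sp_.centroid,
            is_boundary_top=np.zeros(4, bool), is_boundary_bottom=sp_.is_boundary_bottom,
            is_boundary_left=sp_.is_boundary_left, is_boundary_right=sp_.is_boundary_right,
        )
        g = saliency.build_closed_loop_graph(sp_)
        with pytest.raises(InvalidInputError):
            saliency.boundary_stage_saliency(g, broken)


class TestUpsample:
    def test_pixel_map_consistent_with_labels(self, disc_saliency):
        sp_, _, _, stage2 = disc_saliency
        raster = saliency.upsample_saliency(stage2.scores, sp_)
        np.testing.assert_array_equal(raster, stage2.scores[sp_.labels])

    def test_value_histogram_weighted_by_areas(self, disc_saliency):
        """Counting oracle: each score appears exactly its superpixel's area times."""
        sp_, _, _, _ = disc_saliency
        rng = np.random.default_rng(3)
        scores = rng.random(sp_.n)
        raster = saliency.upsample_saliency(scores, sp_)
        areas = np.bincount(sp_.labels.ravel(), minlength=sp_.n)
        for lbl in range(sp_.n):
            assert int((raster == scores[lbl]).sum()) == areas[lbl]

    def test_length_mismatch_rejected(self, disc_saliency):
        sp_, _, _, _ = disc_saliency
        with pytest.raises(InvalidInputError):
            saliency.upsample_saliency(np.zeros(sp_.n + 1), sp_)
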