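import numpy as np
import pytest

from prosthvis import saliency, scenes


@pytest.fixture(scope="session")
def disc_scene():
    """A 160x160 bright disc on cluttered background with exact ground truth."""
    spec = scenes.SceneSpec(
        size=(160, 160),
        object_shape="disc",
        object_gray=210,
        object_bbox=(36, 32, 131, 127),
        background="clutter",
        background_gray=60,
        clutter_scale=8.0,
        clutter_contrast=25.0,
        noise_sigma=5.0,
        seed=11,
    )
    img, mask = scenes.generate_scene(spec)
    return img, mask, spec


@pytest.fixture(scope="session")
def disc_saliency(disc_scene):
    """Superpixels, graph and both saliency stages of the disc scene."""
    img, mask, _ = disc_scene
    sp_ = saliency.compute_superpixels(img, n_target=150)
    graph = saliency.build_closed_loop_graph(sp_)
    stage1 = saliency.boundary_stage_saliency(graph, sp_)
    stage2 = saliency.foreground_query_saliency(graph, sp_, stage1)
    return sp_, graph, stage1, stage2


def random_connected_graph(rng: np.random.Generator, n: int) -> saliency.AffinityGraph:
    """Random sparse symmetric affinities with a ring backbone for connectivity."""
    edges = rng.random((n, n)) < 0.2
    idx = np.arange(n)
    edges[idx, (idx + 1) % n] = True  # ring keeps the graph connected
    edges |= edges.T
    np.fill_diagonal(edges, False)
    W = np.where(edges, rng.uniform(0.05, 1.0, (n, n)), 0.0)
    W = (W + W.T) / 2.0
    return saliency.AffinityGraph(W=W, degrees=W.sum(axis=1), edges=edges)
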