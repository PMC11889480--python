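"""Skeletonization, graph extraction, spur pruning and cycle resolution."""

import numpy as np
import pytest

from vascmorph.centerline import (CenterlineEdge, CenterlineGraph,
                                  CenterlineNode, RootMatchError,
                                  centerline_tree, prune_spurs,
                                  resolve_to_tree, skeleton_to_graph,
                                  skeletonize)
from vascmorph.phantom import rasterize_mask
from vascmorph.volio import ROIMask


VOX = 10.0


def graph_of(mask):
    skel = skeletonize(ROIMask(mask))
    return skel, skeleton_to_graph(skel, ROIMask(mask), VOX)


@pytest.fixture
def cylinder_mask(cylinder_tree):
    return rasterize_mask(cylinder_tree, (70, 70, 70), VOX)


@pytest.fixture
def y_mask(y_tree):
    return rasterize_mask(y_tree, (90, 95, 95), VOX)


class TestSkeletonize:
    def test_cylinder_single_path_two_endpoints(self, cylinder_mask):
        skel, graph = graph_of(cylinder_mask)
        kinds = [n.kind for n in graph.nodes.values()]
        assert kinds.count("endpoint") == 2
        assert kinds.count("junction") == 0
        assert len(graph.edges) == 1
        assert np.all(cylinder_mask[skel])  # skeleton subset of ROI

    def test_y_three_endpoints_one_junction(self, y_mask):
        _, graph = graph_of(y_mask)
        kinds = [n.kind for n in graph.nodes.values()]
        assert kinds.count("endpoint") == 3
        assert kinds.count("junction") == 1
        assert len(graph.edges) == 3
        assert len(graph.nodes) == 4

    def test_single_voxel_mask(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        skel = skeletonize(ROIMask(mask))
        assert np.array_equal(skel, mask)
        graph = skeleton_to_graph(skel, ROIMask(mask), VOX)
        assert len(graph.nodes) == 1 and not graph.edges
        assert graph.nodes[0].kind == "isolated"

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            skeletonize(ROIMask(np.zeros((4, 4, 4), bool)))

    @pytest.mark.parametrize("seed", range(4))
    def test_component_count_preserved_on_random_blobs(self, seed):
        rng = np.random.default_rng(seed)
        mask = np.zeros((40, 40, 40), bool)
        z, y, x = np.ogrid[:40, :40, :40]
        for _ in range(rng.integers(2, 5)):
            c = rng.uniform(8, 32, size=3)
            r = rng.uniform(3, 6)
            mask |= ((z - c[0]) ** 2 + (y - c[1]) ** 2
                     + (x - c[2]) ** 2) <= r * r
        from scipy import ndimage

        n_in = ndimage.label(mask, np.ones((3, 3, 3)))[1]
        skel = skeletonize(ROIMask(mask))
        n_out = ndimage.label(skel, np.ones((3, 3, 3)))[1]
        assert n_in == n_out


class TestSkeletonToGraph:
    def test_cylinder_radius_within_one_voxel(self, cylinder_mask,
                                              cylinder_tree):
        _, graph = graph_of(cylinder_mask)
        edge = graph.edges[0]
        true_r = cylinder_tree.root.radius
        assert abs(edge.radius - true_r) <= VOX / 1000.0

    def test_two_disjoint_cylinders_two_components(self, cylinder_tree):
        m1 = rasterize_mask(cylinder_tree, (70, 70, 70), VOX)
        mask = np.zeros((70, 140, 70), bool)
        mask[:, :70, :] = m1
        mask[:, 70:, :] = m1
        _, graph = graph_of(mask)
        assert graph.n_components() == 2
        assert len(graph.edges) == 2

    def test_voxel_accounting_exact(self, y_mask):
        skel, graph = graph_of(y_mask)
        assert graph.skeleton_voxel_count() == int(skel.sum())
        # no voxel owned twice
        seen = set()
        for nd in graph.nodes.values():
            for v in nd.voxels:
                assert v not in seen
                seen.add(v)
        for e in graph.edges:
            for v in e.path:
                assert v not in seen
                seen.add(v)

    def test_pure_cycle_detected(self):
        # a Manhattan-diamond ring: every voxel has exactly two 26-neighbours
        mask = np.zeros((3, 14, 14), bool)
        c, r = 7, 4
        for dy in range(-r, r + 1):
            dx = r - abs(dy)
            mask[1, c + dy, c + dx] = True
            mask[1, c + dy, c - dx] = True
        graph = skeleton_to_graph(mask, None, VOX)
        assert len(graph.edges) == 1
        assert graph.edges[0].a == graph.edges[0].b  # self-loop


class TestPruneSpurs:
    def test_spur_free_tree_unchanged(self, y_mask):
        _, graph = graph_of(y_mask)
        pruned = prune_spurs(graph, 2.0)
        assert len(pruned.edges) == len(graph.edges)
        assert pruned.pruned_spur_count == 0

    def test_artificial_spur_removed(self, cylinder_mask):
        skel = skeletonize(ROIMask(cylinder_mask))
        # graft a 2-voxel side spur onto the middle of the path
        voxels = sorted(zip(*np.nonzero(skel)))
        mid = voxels[len(voxels) // 2]
        skel2 = skel.copy()
        skel2[mid[0], mid[1] + 1, mid[2] + 1] = True
        skel2[mid[0], mid[1] + 2, mid[2] + 2] = True
        graph = skeleton_to_graph(skel2, ROIMask(cylinder_mask), VOX)
        assert len(graph.edges) == 3
        pruned = prune_spurs(graph, 2.0)
        assert len(pruned.edges) == 1
        assert pruned.pruned_spur_count == 1
        kinds = [n.kind for n in pruned.nodes.values()]
        assert kinds.count("endpoint") == 2

    def test_factor_zero_is_identity(self, cylinder_mask):
        skel = skeletonize(ROIMask(cylinder_mask))
        voxels = sorted(zip(*np.nonzero(skel)))
        mid = voxels[len(voxels) // 2]
        skel2 = skel.copy()
        skel2[mid[0], mid[1] + 1, mid[2] + 1] = True
        graph = skeleton_to_graph(skel2, ROIMask(cylinder_mask), VOX)
        pruned = prune_spurs(graph, 0.0)
        assert len(pruned.edges) == len(graph.edges)


def toy_graph(with_loop=False):
    """Hand-built graph: 0 -1- 1 -2- 2, plus optional loop edge 0-2."""
    nodes = {
        0: CenterlineNode(0, [(0, 0, 0)], np.array([0.0, 0, 0]), "endpoint"),
        1: CenterlineNode(1, [(5, 0, 0)], np.array([0.05, 0, 0]), "junction"),
        2: CenterlineNode(2, [(9, 0, 0)], np.array([0.09, 0, 0]), "endpoint"),
    }
    edges = [
        CenterlineEdge(0, 0, 1, (0, 0, 0), (5, 0, 0), [], 0.05, 0.02),
        CenterlineEdge(1, 1, 2, (5, 0, 0), (9, 0, 0), [], 0.04, 0.02),
    ]
    if with_loop:
        edges.append(
            CenterlineEdge(2, 0, 2, (0, 0, 0), (9, 0, 0), [], 0.2, 0.02))
    return CenterlineGraph(nodes, edges, (10.0, 10.0, 10.0), (10, 1, 1))


class TestResolveToTree:
    def test_acyclic_graph_identical_topology(self):
        tree, removed = resolve_to_tree(toy_graph(), [0.0, 0, 0])
        assert removed == 0
        assert len(tree) == 2
        # path directed away from the root
        root = tree.root
        assert root.parent is None
        child = tree.children(root.id)
        assert len(child) == 1

    def test_loop_edge_removed_nodes_reachable(self):
        # brute-force shortest paths from node 0: 0-1 (0.05), 1-2 (0.09 total)
        # beat the direct 0-2 edge (0.2), so exactly that edge is dropped
        tree, removed = resolve_to_tree(toy_graph(with_loop=True), [0.0, 0, 0])
        assert removed == 1
        assert len(tree) == 2
        lengths = sorted(round(s.length, 6) for s in tree)
        assert lengths == [0.04, 0.05]

    def test_far_root_raises_with_diagnostics(self):
        with pytest.raises(RootMatchError, match="nearest node"):
            resolve_to_tree(toy_graph(), [5.0, 5.0, 5.0])

    def test_end_to_end_phantom_chain(self, y_tree):
        mask = rasterize_mask(y_tree, (90, 95, 95), VOX)
        root = y_tree.root
        u = (root.end - root.start) / np.linalg.norm(root.end - root.start)
        tree, qc = centerline_tree(ROIMask(mask), VOX,
                                   root.start + 0.5 * root.radius * u)
        assert len(tree) == 3
        assert qc["removed_cycle_edges"] == 0
        assert qc["graph_components"] == 1
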