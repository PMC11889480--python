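"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from collections import deque

import numpy as np
import pytest

from vascmorph.trees import Segment, VesselTree


# ---------------------------------------------------------------------------
# independent brute-force flood fill (the oracle for region growing)
# ---------------------------------------------------------------------------

def bfs_flood_fill(data: np.ndarray, seed, reference: float, tolerance: float,
                   connectivity: int = 26) -> np.ndarray:
    """Breadth-first flood fill written independently of the package."""
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dz, dy, dx))
    mask = np.zeros(data.shape, dtype=bool)
    seed = tuple(seed)
    if abs(float(data[seed]) - reference) > tolerance:
        return mask
    mask[seed] = True
    queue = deque([seed])
    while queue:
        z, y, x = queue.popleft()
        for dz, dy, dx in offsets:
            w = (z + dz, y + dy, x + dx)
            if any(c < 0 or c >= s for c, s in zip(w, data.shape)):
                continue
            if mask[w]:
                continue
            if abs(float(data[w]) - reference) <= tolerance:
                mask[w] = True
                queue.append(w)
    return mask


# ---------------------------------------------------------------------------
# independent recursive depth oracle and random trees
# ---------------------------------------------------------------------------

def recursive_depth(tree: VesselTree) -> int:
    """Maximum generation by naive recursion, independent of labels."""

    def depth(sid, g):
        kids = tree.children(sid)
        if not kids:
            return g
        return max(depth(k.id, g + 1) for k in kids)

    return depth(tree.root.id, 0)


def random_tree(rng: np.random.Generator, max_segments: int = 200) -> VesselTree:
    """A random rooted tree with arbitrary geometry (topology-focused)."""
    n = int(rng.integers(1, max_segments + 1))
    segs = [Segment(0, None, np.zeros(3), np.array([1.0, 0, 0]), 0.1)]
    for i in range(1, n):
        parent = int(rng.integers(0, i))
        start = segs[parent].end
        end = start + rng.normal(0, 1, 3)
        segs.append(Segment(i, parent, start, end, 0.1))
    return VesselTree(segs)


# ---------------------------------------------------------------------------
# geometric fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def cylinder_tree():
    """A single oblique segment, radius 3 voxels at 10 um, length 50 voxels."""
    d = np.array([1.0, 0.12, 0.08])
    d /= np.linalg.norm(d)
    start = np.array([0.08, 0.3, 0.3])
    return VesselTree([
        Segment(0, None, start, start + d * 0.5, 0.03)
    ])


@pytest.fixture
def y_tree():
    """A Y: trunk plus two children 40 degrees off, tilted off-grid."""
    d = np.array([1.0, 0.1, 0.06])
    d /= np.linalg.norm(d)
    start = np.array([0.1, 0.45, 0.45])
    end = start + d * 0.4
    segs = [Segment(0, None, start, end, 0.04)]
    for i, phi in enumerate((0.3, 0.3 + math.pi)):
        u = np.array([-d[1], d[0], 0.0])
        u /= np.linalg.norm(u)
        v = np.cross(d, u)
        cd = (math.cos(math.radians(40)) * d
              + math.sin(math.radians(40))
              * (math.cos(phi) * u + math.sin(phi) * v))
        segs.append(Segment(i + 1, 0, end, end + cd * 0.3, 0.028))
    return VesselTree(segs)


def perfect_binary_tree(depth: int) -> VesselTree:
    """Perfect binary tree of the given depth with separated geometry."""
    segs = [Segment(0, None, np.zeros(3), np.array([1.0, 0, 0]), 1.0)]
    frontier = [(0, np.array([1.0, 0, 0]), 0)]
    nid = 1
    while frontier:
        pid, pend, g = frontier.pop(0)
        if g >= depth:
            continue
        for k in (-1, 1):
            end = pend + np.array([1.0, k * 0.5 ** (g + 1), 0.1 * k])
            segs.append(Segment(nid, pid, pend, end, 1.0 / (g + 2)))
            frontier.append((nid, end, g + 1))
            nid += 1
    return VesselTree(segs)


def caterpillar_tree(max_leaf_generation: int) -> VesselTree:
    """A spine with one leaf per spine node: terminal generations are
    exactly {1, ..., max_leaf_generation}."""
    segs = [Segment(0, None, np.zeros(3), np.array([1.0, 0, 0]), 1.0)]
    prev = 0
    nid = 1
    for _ in range(max_leaf_generation - 1):  # spine segments 1..G-1
        start = segs[prev].end
        segs.append(Segment(nid, prev, start, start + np.array([1.0, 0, 0]),
                            1.0))
        prev = nid
        nid += 1
    spine = list(range(max_leaf_generation))  # spine segment of generation g
    for g in range(1, max_leaf_generation + 1):
        parent = spine[g - 1]
        start = segs[parent].end
        segs.append(Segment(nid, parent, start,
                            start + np.array([0.0, 1.0, 0]), 0.5))
        nid += 1
    return VesselTree(segs)
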