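"""Synthetic vascular phantoms with known ground truth.

Three pieces live here:

* :func:`generate_tree` — a parametric branching-tree generator (binary or
  mixed bi/trifurcating, Murray-type radius law, geometric length decay,
  stochastic pruning) producing a :class:`~vascmorph.trees.VesselTree` whose
  topology, coordinates and radii are exactly known.

* :func:`generate_preset_tree` — a constructive generator that hits a
  prescribed (median end-branch generation, maximum generation, segment
  count) triple *exactly*.  The bundled stage presets encode the published
  whole-lung statistics of the developing opossum pulmonary arterial and
  venous trees (neonate, 21, 35 and 57 days post natum).

* :func:`rasterize` — renders a tree into a noisy 16-bit volume that mimics
  a contrast-stained lung micro-CT scan: bright vessel lumina on darker
  parenchyma, optional darkest air spaces, i.i.d. Gaussian sensor noise.

Coordinates are physical mm with the origin at the volume corner; voxel
index order is (z, y, x), 0-based; voxel centres sit at (index + 0.5) times
the voxel size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .trees import Segment, VesselTree

__all__ = [
    "TreeSpec",
    "IntensityModel",
    "StagePreset",
    "ParameterError",
    "PresetInfeasibleError",
    "GeometryError",
    "generate_tree",
    "generate_preset_tree",
    "min_self_clearance",
    "rasterize",
    "rasterize_mask",
    "fit_tree_to_grid",
    "stage_preset",
    "available_presets",
    "load_branching_table",
]


class ParameterError(ValueError):
    """Invalid phantom parameters."""


class PresetInfeasibleError(ValueError):
    """No tree can satisfy the requested (median, maximum, count) triple."""


class GeometryError(ValueError):
    """Tree does not fit inside the raster grid."""

    def __init__(self, message: str, segment_ids: Sequence[int] = ()):
        super().__init__(message)
        self.segment_ids = list(segment_ids)


# ---------------------------------------------------------------------------
# parametric trees
# ---------------------------------------------------------------------------


@dataclass
class TreeSpec:
    """Parameters of a random branching tree.

    ``radius_exponent`` k is the Murray-type conservation exponent: the n
    children of a segment of radius r all get radius r * n**(-1/k), so that
    r**k is conserved across the branch point.  k = 3 is the classical
    energy-optimal value for laminar flow; the vessel calibres of the real
    trees were not measured, so this is a modelling default.
    """

    root_position: Sequence[float] = (0.0, 0.0, 0.0)  # (z, y, x) mm
    root_direction: Sequence[float] = (1.0, 0.0, 0.0)
    root_radius: float = 0.055  # mm
    root_length: float = 0.45  # mm
    branching_mode: str = "binary"  # "binary" | "mixed"
    max_generation: int = 4
    length_ratio: float = 0.8
    radius_exponent: float = 3.0
    branch_angle: float = 40.0  # degrees off the parent axis
    angle_jitter: float = 8.0  # degrees, uniform
    prune_probability: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.max_generation < 0:
            raise ParameterError("max_generation must be >= 0")
        if not (0.0 < self.length_ratio <= 1.0):
            raise ParameterError("length_ratio must be in (0, 1]")
        if not self.radius_exponent > 0:
            raise ParameterError("radius_exponent must be > 0")
        if not (0.0 <= self.prune_probability < 1.0):
            raise ParameterError("prune_probability must be in [0, 1)")
        if self.branching_mode not in ("binary", "mixed"):
            raise ParameterError(f"unknown branching_mode {self.branching_mode!r}")
        if not (self.root_radius > 0 and self.root_length > 0):
            raise ParameterError("root radius and length must be > 0")
        if not (0.0 <= self.branch_angle <= 90.0):
            raise ParameterError("branch_angle must be in [0, 90] degrees")
        if np.linalg.norm(np.asarray(self.root_direction, float)) == 0:
            raise ParameterError("root_direction must be a nonzero vector")


def _orthonormal_frame(direction: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to ``direction`` (deterministic)."""
    d = direction / np.linalg.norm(direction)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, d)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def _tilted(direction: np.ndarray, theta: float, phi: float) -> np.ndarray:
    """Unit vector at polar angle ``theta`` from ``direction``, azimuth ``phi``."""
    d = direction / np.linalg.norm(direction)
    u, v = _orthonormal_frame(d)
    w = math.cos(theta) * d + math.sin(theta) * (math.cos(phi) * u + math.sin(phi) * v)
    return w / np.linalg.norm(w)


def generate_tree(spec: TreeSpec) -> VesselTree:
    """Generate a random rooted tree; deterministic for a fixed spec + seed.

    The root segment is generation 0; each child increments the generation.
    With ``prune_probability`` > 0 individual children are independently
    dropped, so subtrees may terminate before ``max_generation``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    root_dir = np.asarray(spec.root_direction, float)
    root_dir = root_dir / np.linalg.norm(root_dir)

    segments: List[Segment] = []
    counter = 0

    def grow(parent_id: Optional[int], start: np.ndarray, direction: np.ndarray,
             length: float, radius: float, generation: int) -> None:
        nonlocal counter
        sid = counter
        counter += 1
        end = start + direction * length
        segments.append(
            Segment(id=sid, parent=parent_id, start=start, end=end,
                    radius=radius, generation=generation)
        )
        if generation >= spec.max_generation:
            return
        if spec.branching_mode == "binary":
            n_children = 2
        else:
            n_children = int(rng.choice([2, 3], p=[0.7, 0.3]))
        base_phi = rng.uniform(0.0, 2.0 * math.pi)
        child_radius = radius * n_children ** (-1.0 / spec.radius_exponent)
        child_length = length * spec.length_ratio
        for i in range(n_children):
            keep = rng.uniform() >= spec.prune_probability
            theta = math.radians(
                spec.branch_angle + rng.uniform(-1.0, 1.0) * spec.angle_jitter
            )
            phi = base_phi + 2.0 * math.pi * i / n_children + math.radians(
                rng.uniform(-1.0, 1.0) * spec.angle_jitter
            )
            if not keep:
                continue
            grow(sid, end, _tilted(direction, theta, phi),
                 child_length, child_radius, generation + 1)

    grow(None, np.asarray(spec.root_position, float), root_dir,
         spec.root_length, spec.root_radius, 0)
    return VesselTree(segments)


# ---------------------------------------------------------------------------
# stage presets constrained to the published whole-lung statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StagePreset:
    """Target whole-lung branching triple for one stage and vessel."""

    name: str  # "neonate" | "21dpn" | "35dpn" | "57dpn"
    vessel: str  # "PA" | "PV"
    target_median_generation: float
    target_max_generation: int
    target_vessel_count: int

    def __post_init__(self):
        if self.target_median_generation > self.target_max_generation:
            raise ParameterError("target median must be <= target maximum")
        if self.target_vessel_count < 1:
            raise ParameterError("target vessel count must be >= 1")


def load_branching_table() -> pd.DataFrame:
    """The bundled per-stage branching statistics (all scopes)."""
    with resources.files("vascmorph.data").joinpath("table2.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def available_presets() -> List[Tuple[str, str]]:
    df = load_branching_table()
    df = df[df["scope"] == "total"]
    return [(r.stage, r.vessel) for r in df.itertuples()]


def stage_preset(name: str, vessel: str) -> StagePreset:
    """Look up the whole-lung preset for a stage ('neonate', '21dpn', ...)."""
    df = load_branching_table()
    row = df[(df["stage"] == name) & (df["vessel"] == vessel)
             & (df["scope"] == "total")]
    if row.empty:
        raise KeyError(f"no preset for stage={name!r} vessel={vessel!r}")
    r = row.iloc[0]
    return StagePreset(
        name=name,
        vessel=vessel,
        target_median_generation=float(r["median_generation"]),
        target_max_generation=int(r["maximum_generation"]),
        target_vessel_count=int(r["vessel_count"]),
    )


def _terminal_generations(median: float, max_gen: int, n_extra: int,
                          rng: np.random.Generator) -> List[int]:
    """Choose generations for ``n_extra`` side-branch terminals so that the
    multiset {side terminals} + {max_gen} (the spine tip) has exactly the
    requested median.

    The construction fixes the order statistics that pin the median and
    fills the remaining slots with seeded draws near the median, keeping the
    trees varied without ever perturbing the target statistics.
    """
    T = n_extra + 1  # total number of terminals, spine tip included

    def draw_low(k: int, hi: int) -> List[int]:
        lo = max(1, hi - 4)
        return [int(v) for v in rng.integers(lo, hi + 1, size=k)] if k > 0 else []

    def draw_high(k: int, lo: int) -> List[int]:
        hi = min(max_gen, lo + 4)
        return [int(v) for v in rng.integers(lo, hi + 1, size=k)] if k > 0 else []

    if T == 2:
        # {v, max_gen} must average to the median
        v = 2 * median - max_gen
        if v != int(v) or not (1 <= v <= max_gen):
            raise PresetInfeasibleError(
                f"median {median} unreachable with two terminals "
                f"(needs a terminal at generation {v})"
            )
        vals = [int(v)]
    elif T % 2 == 1:
        if median != int(median):
            raise PresetInfeasibleError(
                f"median {median} impossible with an odd number of "
                f"terminals ({T})"
            )
        m = int(median)
        mid = (T - 1) // 2
        lows = draw_low(mid, m)  # the mid values below the median slot
        highs = draw_high(T - 1 - mid, m)  # >= m; spine tip fills the last slot
        highs[0] = m  # order statistic at the median position
        vals = lows + highs
    elif median == int(median):
        m = int(median)
        lows = draw_low(T // 2 - 1, m)
        highs = draw_high(T // 2 - 2, m)
        vals = lows + [m, m] + highs  # middle two values both m
    else:
        h = int(math.floor(median))
        if median * 2 != h * 2 + 1:
            raise PresetInfeasibleError(
                f"median {median} is not an integer or half-integer"
            )
        if h < 1 or h + 1 > max_gen:
            raise PresetInfeasibleError(
                f"half-integer median {median} needs terminals at "
                f"generations {h} and {h + 1} within [1, {max_gen}]"
            )
        # lowest T/2 values top out at h, highest T/2 values bottom out at h+1
        lows = draw_low(T // 2 - 1, h) + [h]
        highs = [h + 1] + draw_high(T // 2 - 2, h + 1)
        vals = lows + highs

    if len(vals) != n_extra:
        raise PresetInfeasibleError(
            f"internal construction error: built {len(vals)} side terminals, "
            f"needed {n_extra}"
        )
    for v in vals:
        if not (1 <= v <= max_gen):
            raise PresetInfeasibleError(
                f"terminal generation {v} outside [1, {max_gen}]"
            )
    return vals


def generate_preset_tree(preset: StagePreset, seed: int = 0) -> VesselTree:
    """Construct a ground-truth tree whose whole-lung statistics equal the
    preset triple exactly.

    Construction: a spine of ``max_generation + 1`` segments (generations
    0..max) carries the maximum; the remaining ``count - (max + 1)`` segments
    are single terminal side branches attached to the spine segment one
    generation up, with their generations chosen so the median over all
    end branches (side terminals + the spine tip) equals the target.
    Multifurcations at spine nodes are allowed — some published counts are
    unreachable with strictly binary branching.
    """
    m = preset.target_median_generation
    M = preset.target_max_generation
    N = preset.target_vessel_count
    rng = np.random.default_rng(seed)

    if N == 1:
        if not (m == 0 and M == 0):
            raise PresetInfeasibleError(
                "a single-segment tree has median 0 and maximum 0"
            )
        return VesselTree([
            Segment(id=0, parent=None, start=np.zeros(3),
                    end=np.array([1.0, 0.0, 0.0]), radius=0.15, generation=0)
        ])

    n_extra = N - (M + 1)
    if n_extra < 0:
        raise PresetInfeasibleError(
            f"count {N} too small for maximum generation {M} "
            f"(spine alone needs {M + 1} segments)"
        )
    if n_extra == 0:
        if m != M:
            raise PresetInfeasibleError(
                f"a pure spine has median = maximum; median {m} != {M}"
            )
        leaf_gens: List[int] = []
    else:
        if not (1 <= m <= M):
            raise PresetInfeasibleError(
                f"median {m} outside attainable range [1, {M}]"
            )
        leaf_gens = _terminal_generations(m, M, n_extra, rng)

    # ---- geometry: gently curving spine, side branches fanned in azimuth
    root_len, len_ratio = 1.0, 0.82
    root_rad, rad_ratio = 0.15, 0.85
    segments: List[Segment] = []
    direction = np.array([1.0, 0.0, 0.0])
    pos = np.zeros(3)
    spine_ids: List[int] = []
    spine_ends: List[np.ndarray] = []
    spine_dirs: List[np.ndarray] = []
    sid = 0
    for g in range(M + 1):
        length = max(root_len * len_ratio**g, 0.05)
        radius = max(root_rad * rad_ratio**g, 0.004)
        # small deterministic wiggle so the spine is not a perfect line
        direction = _tilted(direction, math.radians(6.0), rng.uniform(0, 2 * math.pi))
        end = pos + direction * length
        segments.append(
            Segment(id=sid, parent=spine_ids[-1] if spine_ids else None,
                    start=pos, end=end, radius=radius, generation=g)
        )
        spine_ids.append(sid)
        spine_ends.append(end)
        spine_dirs.append(direction.copy())
        sid += 1
        pos = end

    # group side terminals by generation, attach to the spine node one up
    by_gen: Dict[int, int] = {}
    for g in leaf_gens:
        by_gen[g] = by_gen.get(g, 0) + 1
    for g in sorted(by_gen):
        k = by_gen[g]
        parent_idx = g - 1  # spine segment of generation g-1
        parent_id = spine_ids[parent_idx]
        origin = spine_ends[parent_idx]
        pdir = spine_dirs[parent_idx]
        base_phi = rng.uniform(0, 2 * math.pi)
        length = max(root_len * len_ratio**g * 0.8, 0.05)
        radius = max(root_rad * rad_ratio**g * 0.6, 0.003)
        for i in range(k):
            phi = base_phi + 2 * math.pi * i / k
            d = _tilted(pdir, math.radians(65.0), phi)
            segments.append(
                Segment(id=sid, parent=parent_id, start=origin,
                        end=origin + d * length, radius=radius, generation=g)
            )
            sid += 1

    tree = VesselTree(segments)
    assert len(tree) == N
    return tree


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IntensityModel:
    """Gray-value model of a contrast-stained lung micro-CT scan.

    Defaults put 28 000 gray levels between lumen and parenchyma, so a
    tolerance window of order 1000 gray levels around the lumen value
    segments cleanly against sensor noise of a few hundred gray levels.
    """

    background_gray: int = 12000  # parenchyma
    vessel_gray: int = 40000  # stained lumen
    airspace_gray: int = 2000
    noise_sd: float = 300.0
    bit_depth: int = 16

    def validate(self) -> None:
        for name, g in (("background_gray", self.background_gray),
                        ("vessel_gray", self.vessel_gray),
                        ("airspace_gray", self.airspace_gray)):
            if not (0 <= g <= 65535):
                raise ParameterError(f"{name} must be within [0, 65535]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if abs(self.vessel_gray - self.background_gray) <= 3 * self.noise_sd:
            raise ParameterError(
                "vessel/background contrast must exceed 3 x noise_sd for "
                "tolerance-window segmentation to be well posed"
            )


def _as_voxel_size(voxel_size_um) -> np.ndarray:
    vs = np.asarray(voxel_size_um, dtype=float)
    if vs.ndim == 0:
        vs = np.repeat(vs, 3)
    if vs.shape != (3,) or np.any(vs <= 0):
        raise ParameterError("voxel size must be a positive scalar or 3-vector")
    return vs


def rasterize_mask(tree: VesselTree, grid_shape, voxel_size_um) -> np.ndarray:
    """Boolean lumen mask of the tree on the given grid.

    Segments are rendered as capsules (cylinders with spherical caps), which
    closes the gaps that plain cylinders would leave at branch points.
    Raises :class:`GeometryError` (listing the offending segment ids) if any
    segment, inflated by its radius, leaves the physical extent of the grid.
    """
    shape = tuple(int(s) for s in grid_shape)
    if len(shape) != 3 or any(s <= 0 for s in shape):
        raise ParameterError("grid_shape must be three positive integers")
    vs_mm = _as_voxel_size(voxel_size_um) / 1000.0
    extent = np.array(shape) * vs_mm

    bad = [
        seg.id
        for seg in tree
        if np.any(np.minimum(seg.start, seg.end) - seg.radius < 0)
        or np.any(np.maximum(seg.start, seg.end) + seg.radius > extent)
    ]
    if bad:
        raise GeometryError(
            f"segments outside the grid extent {extent} mm: {bad}", bad
        )

    mask = np.zeros(shape, dtype=bool)
    for seg in tree:
        a, b, r = seg.start, seg.end, seg.radius
        lo = np.maximum(np.floor((np.minimum(a, b) - r) / vs_mm - 0.5), 0).astype(int)
        hi = np.minimum(
            np.ceil((np.maximum(a, b) + r) / vs_mm + 0.5), shape
        ).astype(int)
        if np.any(hi <= lo):
            continue
        zz = (np.arange(lo[0], hi[0]) + 0.5) * vs_mm[0]
        yy = (np.arange(lo[1], hi[1]) + 0.5) * vs_mm[1]
        xx = (np.arange(lo[2], hi[2]) + 0.5) * vs_mm[2]
        P = np.stack(np.meshgrid(zz, yy, xx, indexing="ij"), axis=-1)
        ab = b - a
        denom = float(np.dot(ab, ab))
        if denom == 0:
            dist2 = np.sum((P - a) ** 2, axis=-1)
        else:
            t = np.clip(np.einsum("zyxc,c->zyx", P - a, ab) / denom, 0.0, 1.0)
            closest = a + t[..., None] * ab
            dist2 = np.sum((P - closest) ** 2, axis=-1)
        sub = dist2 <= r * r
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= sub
    return mask


def rasterize(tree: VesselTree, grid_shape, voxel_size_um,
              model: IntensityModel = IntensityModel(), seed: int = 0,
              air_spaces: Optional[Sequence[Tuple[Sequence[float], Sequence[float]]]] = None):
    """Render the tree into a noisy 16-bit volume.

    ``air_spaces`` is an optional list of ellipsoids ((centre mm), (semi-axes
    mm)) rendered at ``airspace_gray`` underneath the vessels.  Returns a
    :class:`~vascmorph.volio.VoxelVolume`; use :func:`rasterize_mask` for the
    matching noise-free ground-truth lumen mask.
    """
    from .volio import VoxelVolume  # local import to avoid a cycle

    model.validate()
    shape = tuple(int(s) for s in grid_shape)
    vs_mm = _as_voxel_size(voxel_size_um) / 1000.0
    lumen = rasterize_mask(tree, shape, voxel_size_um)

    img = np.full(shape, float(model.background_gray))
    if air_spaces:
        zz = (np.arange(shape[0]) + 0.5) * vs_mm[0]
        yy = (np.arange(shape[1]) + 0.5) * vs_mm[1]
        xx = (np.arange(shape[2]) + 0.5) * vs_mm[2]
        Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
        for centre, semi in air_spaces:
            c = np.asarray(centre, float)
            s = np.asarray(semi, float)
            inside = ((Z - c[0]) / s[0]) ** 2 + ((Y - c[1]) / s[1]) ** 2 + (
                (X - c[2]) / s[2]
            ) ** 2 <= 1.0
            img[inside] = float(model.airspace_gray)
    img[lumen] = float(model.vessel_gray)

    if model.noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, model.noise_sd, size=shape)
    data = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    return VoxelVolume(data=data, voxel_size=tuple(_as_voxel_size(voxel_size_um)),
                       provenance="vascmorph.phantom.rasterize")


def _segment_distance(a0: np.ndarray, a1: np.ndarray,
                      b0: np.ndarray, b1: np.ndarray) -> float:
    """Minimum distance between two 3D line segments."""
    u = a1 - a0
    v = b1 - b0
    w0 = a0 - b0
    a = float(np.dot(u, u))
    b = float(np.dot(u, v))
    c = float(np.dot(v, v))
    d = float(np.dot(u, w0))
    e = float(np.dot(v, w0))
    denom = a * c - b * b
    if denom > 1e-12:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:
        s = 0.0
    # refine t for the clamped s, then re-clamp s
    t = np.clip((b * s + e) / c, 0.0, 1.0) if c > 1e-12 else 0.0
    s = np.clip((b * t - d) / a, 0.0, 1.0) if a > 1e-12 else 0.0
    p = a0 + s * u
    q = b0 + t * v
    return float(np.linalg.norm(p - q))


def min_self_clearance(tree: VesselTree) -> float:
    """Smallest surface-to-surface clearance between topologically
    non-adjacent segments (negative = self-collision).

    Pairs sharing a branch point (parent-child and siblings) legitimately
    overlap there and are exempt.  A tree whose subtrees touch rasterizes
    into a looped lumen that no centerline method can resolve back into the
    original topology, so phantom studies reject such trees.
    """
    segs = list(tree)
    best = np.inf
    for i in range(len(segs)):
        for j in range(i + 1, len(segs)):
            si, sj = segs[i], segs[j]
            if si.parent == sj.id or sj.parent == si.id:
                continue
            if si.parent is not None and si.parent == sj.parent:
                continue
            d = _segment_distance(si.start, si.end, sj.start, sj.end)
            best = min(best, d - si.radius - sj.radius)
    return float(best)


def fit_tree_to_grid(tree: VesselTree, voxel_size_um, margin_um: float = 50.0):
    """Translate ``tree`` into the positive octant and return (tree, shape)
    of the smallest grid that contains it with the given physical margin.

    The translation adds a fixed 0.37-voxel grid phase.  A vessel running
    exactly along a grid axis with its centerline exactly midway between
    voxel columns rasterizes to an even-width tube whose two-voxel core has
    no protected line end under parallel thinning; a sub-voxel phase breaks
    that degeneracy (the grid phase of a real scan is arbitrary anyway).
    """
    vs_mm = _as_voxel_size(voxel_size_um) / 1000.0
    margin_mm = float(margin_um) / 1000.0
    lo, hi = tree.bounding_box()
    shifted = tree.translated(margin_mm - lo + 0.37 * vs_mm)
    size = (hi - lo) + 2 * margin_mm
    shape = tuple(int(math.ceil(s / v)) + 2 for s, v in zip(size, vs_mm))
    return shifted, shape
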