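"""Rooted vessel-tree container shared by the phantom generator, the
centerline extractor and the branch-statistics code.

A tree is a set of straight segments.  Each segment runs from ``start`` to
``end`` (physical coordinates in mm, axis order (z, y, x)) and carries a
radius in mm.  Exactly one segment has ``parent is None``; every other
segment attaches to the end point of its parent.  Branch generation follows
the convention used throughout the package: the main trunk is generation 0
and every child increments its parent's generation by exactly 1, regardless
of how many siblings it has.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional

import numpy as np

__all__ = ["Segment", "VesselTree", "TreeStructureError"]


class TreeStructureError(ValueError):
    """Raised when segments do not form a single-rooted acyclic tree."""


@dataclass
class Segment:
    """One vessel segment (a centerline edge between two branch points)."""

    id: int
    parent: Optional[int]
    start: np.ndarray  # (z, y, x) mm
    end: np.ndarray  # (z, y, x) mm
    radius: float  # mm
    length: Optional[float] = None  # arc length mm; None -> Euclidean
    generation: Optional[int] = None
    side: Optional[str] = None  # "trunk" | "left" | "right"

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.end = np.asarray(self.end, dtype=float)
        if self.start.shape != (3,) or self.end.shape != (3,):
            raise ValueError("segment endpoints must be 3-vectors (z, y, x)")
        if not self.radius > 0:
            raise TreeStructureError(
                f"segment {self.id}: radius must be > 0, got {self.radius}"
            )

    @property
    def arc_length(self) -> float:
        if self.length is not None:
            return float(self.length)
        return float(np.linalg.norm(self.end - self.start))

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.start + self.end)


class VesselTree:
    """A validated, single-rooted, acyclic collection of :class:`Segment`.

    Segment ids are arbitrary integers; insertion order is preserved so that
    repeated construction from the same inputs yields identical iteration
    order (important for reproducible file output).
    """

    def __init__(self, segments: Iterable[Segment]):
        self.segments: Dict[int, Segment] = {}
        for seg in segments:
            if seg.id in self.segments:
                raise TreeStructureError(f"duplicate segment id {seg.id}")
            self.segments[seg.id] = seg
        if not self.segments:
            raise TreeStructureError("tree has no segments")

        roots = [s.id for s in self.segments.values() if s.parent is None]
        if len(roots) != 1:
            raise TreeStructureError(
                f"tree must have exactly one root, found {len(roots)}: {roots}"
            )
        self._root_id = roots[0]

        self._children: Dict[int, List[int]] = {sid: [] for sid in self.segments}
        for seg in self.segments.values():
            if seg.parent is None:
                continue
            if seg.parent not in self.segments:
                raise TreeStructureError(
                    f"segment {seg.id} references missing parent {seg.parent}"
                )
            self._children[seg.parent].append(seg.id)

        # acyclicity + connectivity: walk down from the root
        seen = set()
        stack = [self._root_id]
        while stack:
            sid = stack.pop()
            if sid in seen:
                raise TreeStructureError(f"cycle detected at segment {sid}")
            seen.add(sid)
            stack.extend(self._children[sid])
        if len(seen) != len(self.segments):
            orphans = sorted(set(self.segments) - seen)
            raise TreeStructureError(
                f"segments not reachable from root (cycle or forest): {orphans}"
            )

    # ---- topology -----------------------------------------------------
    @property
    def root(self) -> Segment:
        return self.segments[self._root_id]

    def children(self, sid: int) -> List[Segment]:
        return [self.segments[c] for c in self._children[sid]]

    def is_terminal(self, sid: int) -> bool:
        return not self._children[sid]

    def terminals(self) -> List[Segment]:
        return [s for s in self.segments.values() if self.is_terminal(s.id)]

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments.values())

    def preorder(self) -> List[Segment]:
        """Segments in depth-first preorder (parent before child)."""
        out: List[Segment] = []
        stack = [self._root_id]
        while stack:
            sid = stack.pop()
            out.append(self.segments[sid])
            stack.extend(reversed(self._children[sid]))
        return out

    def subtree_ids(self, sid: int) -> List[int]:
        out: List[int] = []
        stack = [sid]
        while stack:
            cur = stack.pop()
            out.append(cur)
            stack.extend(self._children[cur])
        return out

    # ---- geometry -----------------------------------------------------
    def bounding_box(self) -> tuple:
        """(min, max) corners in mm, inflated by each segment's radius."""
        lo = np.full(3, np.inf)
        hi = np.full(3, -np.inf)
        for seg in self:
            r = seg.radius
            lo = np.minimum(lo, np.minimum(seg.start, seg.end) - r)
            hi = np.maximum(hi, np.maximum(seg.start, seg.end) + r)
        return lo, hi

    def translated(self, offset) -> "VesselTree":
        """A copy with every coordinate shifted by ``offset`` (mm)."""
        offset = np.asarray(offset, dtype=float)
        return VesselTree(
            replace(s, start=s.start + offset, end=s.end + offset)
            for s in self.segments.values()
        )

    # ---- equality of topology (used by phantom-recovery checks) -------
    def generation_multiset(self) -> List[int]:
        return sorted(
            s.generation for s in self.segments.values() if s.generation is not None
        )
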