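"""Volume, mask, tree and table I/O with voxel-size metadata preserved.

Supported volume formats: multi-page TIFF (voxel size in a JSON sidecar),
NIfTI ``.nii``/``.nii.gz`` (voxel size in the header zooms, stored in mm)
and MetaImage ``.mhd``/``.raw`` (ElementSpacing, stored in mm).  A volume
without a recoverable voxel size is an error — never silently assumed.

Trees are written as SWC (one sample per branch point, parent precedes
child) with the structure-type column carrying the vessel label via the
package's own integer codes (5 other, 6 pulmonary artery, 7 pulmonary vein,
8 bronchial tree).  SWC has no field for generation or side labels, so those
go to a companion CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .trees import Segment, TreeStructureError, VesselTree

__all__ = [
    "VoxelVolume",
    "ROIMask",
    "MetadataError",
    "read_volume",
    "write_volume",
    "write_swc",
    "read_swc",
    "write_segment_table",
    "SWC_TYPE_CODES",
]

SWC_TYPE_CODES = {
    "other": 5,
    "pulmonary_artery": 6,
    "pulmonary_vein": 7,
    "bronchial_tree": 8,
}
_CODE_TO_LABEL = {v: k for k, v in SWC_TYPE_CODES.items()}


class MetadataError(IOError):
    """Voxel-size metadata missing or unusable."""


@dataclass
class VoxelVolume:
    """A 3D 16-bit grayscale volume with physical voxel size.

    ``voxel_size`` is (dz, dy, dx) in micrometres; ``data`` axis order is
    (z, y, x).
    """

    data: np.ndarray
    voxel_size: Tuple[float, float, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.data.ndim}D")
        vs = tuple(float(v) for v in np.atleast_1d(self.voxel_size))
        if len(vs) == 1:
            vs = vs * 3
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be 3 positive values, got {vs}")
        self.voxel_size = vs

    @property
    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx * 1e-9

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape


@dataclass
class ROIMask:
    """Binary region-of-interest mask congruent with a :class:`VoxelVolume`."""

    mask: np.ndarray
    label: str = "other"
    seeds: list = field(default_factory=list)
    tolerance: Optional[float] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("ROI mask must be 3D")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def _round_um(value: float) -> float:
    # voxel sizes cross a mm<->um float conversion on disk; snap to nm
    return float(np.round(value, 6))


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------


def write_volume(volume: VoxelVolume, path) -> Path:
    """Write a volume; format chosen from the file suffix."""
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    data = np.ascontiguousarray(volume.data)
    if suffixes.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, data)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({
            "voxel_size_um": list(volume.voxel_size),
            "axis_order": "zyx",
            "provenance": volume.provenance,
        }, indent=1))
    elif suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        vs_mm = [v / 1000.0 for v in volume.voxel_size]
        # NIfTI is x-fastest; store the array transposed so that on-disk
        # spatial axes line up with (dx, dy, dz) zooms
        affine = np.diag([vs_mm[2], vs_mm[1], vs_mm[0], 1.0])
        img = nib.Nifti1Image(np.ascontiguousarray(data.T), affine)
        img.header.set_zooms((vs_mm[2], vs_mm[1], vs_mm[0]))
        img.header.set_xyzt_units(xyz="mm")
        nib.save(img, str(path))
    elif suffixes.endswith(".mhd"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(data)  # keeps (z, y, x) order
        img.SetSpacing(tuple(v / 1000.0 for v in volume.voxel_size[::-1]))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    return path


def read_volume(path, format_hint: Optional[str] = None) -> VoxelVolume:
    """Read a volume with bit-exact gray values and its voxel size.

    Raises :class:`MetadataError` if the voxel size cannot be recovered
    (e.g. TIFF stack without its JSON sidecar).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint or "".join(path.suffixes).lower()
    if fmt.endswith((".tif", ".tiff", "tiff", "tif")):
        import tifffile

        data = tifffile.imread(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise MetadataError(
                f"no voxel-size metadata for {path.name}: sidecar "
                f"{sidecar.name} is missing (a voxel size of 1 um is never "
                f"assumed)"
            )
        meta = json.loads(sidecar.read_text())
        if "voxel_size_um" not in meta:
            raise MetadataError(f"sidecar {sidecar.name} lacks 'voxel_size_um'")
        vs = tuple(_round_um(v) for v in meta["voxel_size_um"])
        return VoxelVolume(data=data, voxel_size=vs,
                           provenance=meta.get("provenance", str(path)))
    if fmt.endswith((".nii", ".nii.gz", "nifti")):
        import nibabel as nib

        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]  # (dx, dy, dz) in mm
        if any(not np.isfinite(z) or z <= 0 for z in zooms):
            raise MetadataError(f"{path.name}: non-positive voxel size in header")
        data = np.asarray(img.dataobj).T  # back to (z, y, x)
        vs = tuple(_round_um(z * 1000.0) for z in zooms[::-1])
        return VoxelVolume(data=np.ascontiguousarray(data), voxel_size=vs,
                           provenance=str(path))
    if fmt.endswith((".mhd", "metaimage", "mha", ".mha")):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        spacing = img.GetSpacing()  # (dx, dy, dz) mm
        if any(s <= 0 for s in spacing):
            raise MetadataError(f"{path.name}: non-positive ElementSpacing")
        data = sitk.GetArrayFromImage(img)  # (z, y, x)
        vs = tuple(_round_um(s * 1000.0) for s in spacing[::-1])
        return VoxelVolume(data=data, voxel_size=vs, provenance=str(path))
    raise ValueError(f"unsupported volume format: {path.name}")


# ---------------------------------------------------------------------------
# trees (SWC + companion CSV)
# ---------------------------------------------------------------------------


def write_swc(tree: VesselTree, path, label: str = "other") -> Path:
    """Write a tree as SWC.

    One sample marks the root segment's start (parent -1); every segment
    contributes one sample at its end point whose SWC parent is the sample
    of the segment it branches from.  Coordinates and radii share the same
    physical unit (mm).  SWC columns are id, type, x, y, z, radius, parent;
    note the x-y-z column order versus the package's (z, y, x) arrays.
    """
    if label not in SWC_TYPE_CODES:
        raise ValueError(f"unknown vessel label {label!r}")
    code = SWC_TYPE_CODES[label]
    path = Path(path)

    lines = ["# SWC vessel centerline tree (units mm)",
             f"# type code {code} = {label}"]
    sample_of: Dict[int, int] = {}  # segment id -> swc sample id of its end
    root = tree.root
    z, y, x = root.start
    lines.append(f"1 {code} {x:.9g} {y:.9g} {z:.9g} {root.radius:.9g} -1")
    next_id = 2
    for seg in tree.preorder():  # parent precedes child
        parent_sample = 1 if seg.parent is None else sample_of[seg.parent]
        z, y, x = seg.end
        lines.append(
            f"{next_id} {code} {x:.9g} {y:.9g} {z:.9g} {seg.radius:.9g} "
            f"{parent_sample}"
        )
        sample_of[seg.id] = next_id
        next_id += 1
    path.write_text("\n".join(lines) + "\n")
    return path


def read_swc(path) -> Tuple[VesselTree, str]:
    """Read an SWC file back into a tree; returns (tree, vessel label).

    The first sample is taken as the root position; every further sample
    becomes a segment from its parent sample's position to its own.
    """
    path = Path(path)
    samples: Dict[int, tuple] = {}
    order: List[int] = []
    label = "other"
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"malformed SWC row: {line!r}")
        sid, code = int(parts[0]), int(parts[1])
        x, y, z, radius = (float(p) for p in parts[2:6])
        parent = int(parts[6])
        samples[sid] = (code, np.array([z, y, x]), radius, parent)
        order.append(sid)
        label = _CODE_TO_LABEL.get(code, "other")
    if not samples:
        raise ValueError(f"{path.name}: no SWC samples")
    roots = [sid for sid in order if samples[sid][3] == -1]
    if len(roots) != 1:
        raise TreeStructureError(
            f"{path.name}: expected exactly one SWC root, found {len(roots)}"
        )
    root_sample = roots[0]
    segments = []
    for sid in order:
        code, pos, radius, parent = samples[sid]
        if sid == root_sample:
            continue
        if parent not in samples:
            raise TreeStructureError(f"{path.name}: sample {sid} has missing "
                                     f"parent {parent}")
        ppos = samples[parent][1]
        segments.append(Segment(
            id=sid, parent=None if parent == root_sample else parent,
            start=ppos, end=pos, radius=radius,
        ))
    return VesselTree(segments), label


def write_segment_table(tree: VesselTree, path) -> Path:
    """Companion CSV with per-segment topology and labels (units in header)."""
    import csv

    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write("# per-segment vessel tree table; lengths and radii in mm\n")
        writer = csv.writer(fh)
        writer.writerow(["segment_id", "parent_id", "generation", "side",
                         "length_mm", "radius_mm"])
        for seg in tree.preorder():
            writer.writerow([
                seg.id,
                "" if seg.parent is None else seg.parent,
                "" if seg.generation is None else seg.generation,
                "" if seg.side is None else seg.side,
                f"{seg.arc_length:.9g}",
                f"{seg.radius:.9g}",
            ])
    return path
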