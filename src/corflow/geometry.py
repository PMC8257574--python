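"""Data model and I/O for coronary trees, lesions, LV masks and patient records.

Conventions
-----------
* All coordinates are in the world/patient frame, in millimetres.
* Voxel indices are 0-based; the centre of voxel ``(i, j, k)`` sits at
  ``origin + index * spacing``.
* A coronary tree is a rooted collection of branches. Each branch is a
  centerline polyline with a per-point lumen radius; child branches attach at
  an interior (or terminal) point of their parent's polyline.
* Lumen radii are interpolated linearly between centerline samples. A lesion
  narrows the lumen multiplicatively with a C0-continuous cosine bump that
  peaks mid-lesion, so the radius is continuous at both lesion ends.

Trees, lesions and patient records travel as versioned JSON documents
(see ``docs/formats.md``); the LV myocardium mask travels as NIfTI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "MAIN_LABELS",
    "SIDE_LABEL",
    "TREE_SCHEMA",
    "ValidationError",
    "BranchGeometry",
    "CoronaryTree",
    "Lesion",
    "MyocardiumMask",
    "PatientRecord",
    "arc_length",
    "arc_position",
    "radius_at",
    "lesion_radius_at",
    "resample_centerline",
    "load_tree",
    "save_tree",
    "load_trees",
    "save_trees",
    "load_mask",
    "save_mask",
    "load_lesions",
    "save_lesions",
    "load_patient",
    "save_patient",
]

MAIN_LABELS = ("LAD", "LCx", "RCA")
SIDE_LABEL = "SIDE"
TREE_SCHEMA = "corflow-tree/1"


class ValidationError(ValueError):
    """An input object violates a structural invariant."""


def _as_float_array(x, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != ndim:
        raise ValidationError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class BranchGeometry:
    """A single branch: an ordered centerline polyline with per-point radii.

    ``parent_id`` is ``None`` for a root branch; ``attach_index`` is the index
    into the parent's centerline where this branch originates.
    """

    branch_id: str
    parent_id: str | None
    attach_index: int | None
    label: str
    points: np.ndarray  # (n, 3) mm
    radii: np.ndarray  # (n,) mm

    def __post_init__(self) -> None:
        self.points = _as_float_array(self.points, f"branch {self.branch_id!r} points", 2)
        self.radii = _as_float_array(self.radii, f"branch {self.branch_id!r} radii", 1)
        bid = self.branch_id
        if self.points.shape[1] != 3:
            raise ValidationError(f"branch {bid!r}: points must be (n, 3)")
        if len(self.points) != len(self.radii):
            raise ValidationError(f"branch {bid!r}: len(points) != len(radii)")
        if len(self.points) < 2:
            raise ValidationError(f"branch {bid!r}: needs at least 2 centerline points")
        if not np.all(self.radii > 0):
            raise ValidationError(f"branch {bid!r}: all radii must be positive")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if not np.all(seg > 0):
            raise ValidationError(f"branch {bid!r}: consecutive centerline points must be distinct")
        if self.parent_id is None:
            if self.label not in MAIN_LABELS:
                raise ValidationError(
                    f"branch {bid!r}: root branches must carry a main-artery label "
                    f"(one of {MAIN_LABELS}), got {self.label!r}"
                )
            if self.attach_index is not None:
                raise ValidationError(f"branch {bid!r}: root branch cannot have an attach_index")
        else:
            if self.attach_index is None:
                raise ValidationError(f"branch {bid!r}: non-root branch requires attach_index")
        if self.label not in MAIN_LABELS + (SIDE_LABEL,):
            raise ValidationError(f"branch {bid!r}: unknown label {self.label!r}")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def arc_positions(self) -> np.ndarray:
        """Cumulative chord length at each centerline point (mm); starts at 0."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass
class CoronaryTree:
    """A rooted tree of branches for one main coronary artery."""

    artery_label: str
    branches: dict[str, BranchGeometry]

    def __post_init__(self) -> None:
        if self.artery_label not in MAIN_LABELS:
            raise ValidationError(f"artery_label must be one of {MAIN_LABELS}")
        roots = [b for b in self.branches.values() if b.parent_id is None]
        if len(roots) != 1:
            raise ValidationError(
                f"tree {self.artery_label}: expected exactly one root branch, found {len(roots)}"
            )
        root = roots[0]
        if root.label != self.artery_label:
            raise ValidationError(
                f"tree {self.artery_label}: root branch {root.branch_id!r} is labelled {root.label!r}"
            )
        for b in self.branches.values():
            if b.parent_id is None:
                continue
            if b.parent_id not in self.branches:
                raise ValidationError(
                    f"branch {b.branch_id!r}: parent_id {b.parent_id!r} does not resolve"
                )
            parent = self.branches[b.parent_id]
            if not (1 <= b.attach_index <= parent.n_points - 1):
                raise ValidationError(
                    f"branch {b.branch_id!r}: attach_index {b.attach_index} outside "
                    f"parent {b.parent_id!r} valid range [1, {parent.n_points - 1}]"
                )
        # cycle check: every branch must reach the root by following parents
        for b in self.branches.values():
            seen: set[str] = set()
            cur = b
            while cur.parent_id is not None:
                if cur.branch_id in seen:
                    raise ValidationError(f"cycle detected at branch {cur.branch_id!r}")
                seen.add(cur.branch_id)
                cur = self.branches[cur.parent_id]

    @property
    def root(self) -> BranchGeometry:
        return next(b for b in self.branches.values() if b.parent_id is None)

    def children_of(self, branch_id: str) -> dict[int, list[BranchGeometry]]:
        """Children of a branch, grouped by attach index, deterministically ordered."""
        out: dict[int, list[BranchGeometry]] = {}
        for b in sorted(self.branches.values(), key=lambda x: x.branch_id):
            if b.parent_id == branch_id:
                out.setdefault(b.attach_index, []).append(b)
        return out

    def all_points(self) -> np.ndarray:
        """All centerline points of all branches, stacked (n, 3)."""
        return np.vstack([b.points for b in sorted(self.branches.values(), key=lambda x: x.branch_id)])


@dataclass
class Lesion:
    """A stenosis on a branch: an arc-length interval with a severity.

    ``severity`` is the percent diameter reduction at the lesion midpoint
    (clinical convention), in [0, 100). The default ``cosine`` profile narrows
    the lumen by ``severity/100 * w(s)`` with
    ``w(s) = 0.5 * (1 - cos(2*pi*(s - s_start)/(s_end - s_start)))``,
    which is 0 at both ends and 1 mid-lesion.
    """

    branch_id: str
    s_start: float
    s_end: float
    severity: float
    profile: str = "cosine"

    def __post_init__(self) -> None:
        if not (0 <= self.s_start < self.s_end):
            raise ValidationError(
                f"lesion on {self.branch_id!r}: need 0 <= s_start < s_end, "
                f"got [{self.s_start}, {self.s_end}]"
            )
        if not (0 <= self.severity < 100):
            raise ValidationError(
                f"lesion on {self.branch_id!r}: severity must be in [0, 100), got {self.severity}"
            )
        if self.profile != "cosine":
            raise ValidationError(f"unknown lesion profile {self.profile!r}")


@dataclass
class MyocardiumMask:
    """Binary LV-myocardium voxel mask with world-frame geometry."""

    voxels: np.ndarray  # (nx, ny, nz) bool
    spacing: np.ndarray  # (3,) mm per axis
    origin: np.ndarray  # (3,) world coordinate of voxel (0,0,0) centre

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValidationError(f"mask must be 3-D, got {self.voxels.ndim}-D")
        self.spacing = _as_float_array(self.spacing, "spacing", 1)
        self.origin = _as_float_array(self.origin, "origin", 1)
        if self.spacing.shape != (3,) or self.origin.shape != (3,):
            raise ValidationError("spacing and origin must be length-3")
        if not np.all(self.spacing > 0):
            raise ValidationError("voxel spacing must be positive on all axes")
        if not self.voxels.any():
            raise ValidationError("mask has no occupied voxel")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_occupied(self) -> int:
        return int(self.voxels.sum())

    def occupied_indices(self) -> np.ndarray:
        return np.argwhere(self.voxels)

    def occupied_centers(self) -> np.ndarray:
        """World coordinates (mm) of the centres of all occupied voxels, (n, 3)."""
        return self.origin + self.occupied_indices() * self.spacing


@dataclass
class PatientRecord:
    """Per-patient scalars: cuff pressures and optional per-vessel measurements."""

    patient_id: str
    sbp_mmhg: float
    dbp_mmhg: float
    measured_ffr: dict[str, float] = field(default_factory=dict)
    frame_counts: dict[str, int] = field(default_factory=dict)
    vessel_lengths_mm: dict[str, float] = field(default_factory=dict)
    myocardial_mass_g: float | None = None

    def __post_init__(self) -> None:
        if not (self.sbp_mmhg >= self.dbp_mmhg > 0):
            raise ValidationError(
                f"patient {self.patient_id!r}: need SBP >= DBP > 0, "
                f"got {self.sbp_mmhg}/{self.dbp_mmhg}"
            )
        for vessel, v in self.measured_ffr.items():
            if not (0 < v <= 1):
                raise ValidationError(
                    f"patient {self.patient_id!r}: measured FFR for {vessel!r} "
                    f"must be in (0, 1], got {v}"
                )
        if self.myocardial_mass_g is not None and self.myocardial_mass_g <= 0:
            raise ValidationError("myocardial_mass_g override must be positive")


# ---------------------------------------------------------------------------
# arc-length parameterization and radius interpolation
# ---------------------------------------------------------------------------

def arc_length(branch: BranchGeometry) -> float:
    """Total centerline chord length of a branch (mm)."""
    return float(branch.arc_positions[-1])


def arc_position(branch: BranchGeometry, i: int) -> float:
    """Cumulative chord length (mm) at centerline point ``i``."""
    return float(branch.arc_positions[i])


def _check_s(branch: BranchGeometry, s) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    total = arc_length(branch)
    if np.any(s < -1e-9) or np.any(s > total + 1e-9):
        raise ValidationError(
            f"arc position outside [0, {total:.6g}] on branch {branch.branch_id!r}"
        )
    return np.clip(s, 0.0, total)


def radius_at(branch: BranchGeometry, s):
    """Baseline lumen radius (mm) at arc position(s) ``s`` by linear interpolation."""
    sv = _check_s(branch, s)
    r = np.interp(sv, branch.arc_positions, branch.radii)
    return float(r) if np.isscalar(s) or np.ndim(s) == 0 else r


def lesion_radius_at(branch: BranchGeometry, lesions: Sequence[Lesion], s):
    """Lumen radius (mm) at ``s`` with lesion narrowing applied.

    Equals :func:`radius_at` exactly outside all lesion intervals.
    """
    sv = _check_s(branch, s)
    r = np.interp(sv, branch.arc_positions, branch.radii)
    factor = np.ones_like(r)
    for les in lesions:
        if les.branch_id != branch.branch_id:
            continue
        if les.s_end > arc_length(branch) + 1e-9:
            raise ValidationError(
                f"lesion [{les.s_start}, {les.s_end}] extends past branch "
                f"{branch.branch_id!r} (length {arc_length(branch):.6g} mm)"
            )
        inside = (sv >= les.s_start) & (sv <= les.s_end)
        u = (sv - les.s_start) / (les.s_end - les.s_start)
        w = 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
        factor = np.where(inside, factor * (1.0 - les.severity / 100.0 * w), factor)
    out = r * factor
    return float(out) if np.isscalar(s) or np.ndim(s) == 0 else out


def resample_centerline(branch: BranchGeometry, step_mm: float):
    """Resample a branch centerline at a fixed arc-length step.

    Returns ``(s, points, radii)`` where ``s`` includes both endpoints. Used
    for point-cloud purposes (territory distances); it does not remap child
    attach indices and therefore does not return a BranchGeometry.
    """
    if step_mm <= 0:
        raise ValidationError("resampling step must be positive")
    total = arc_length(branch)
    s = np.unique(np.concatenate([np.arange(0.0, total, step_mm), [total]]))
    s0 = branch.arc_positions
    pts = np.column_stack([np.interp(s, s0, branch.points[:, k]) for k in range(3)])
    radii = np.interp(s, s0, branch.radii)
    return s, pts, radii


# ---------------------------------------------------------------------------
# JSON / NIfTI I/O
# ---------------------------------------------------------------------------

def _dump_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def tree_to_dict(tree: CoronaryTree) -> dict:
    return {
        "schema": TREE_SCHEMA,
        "artery_label": tree.artery_label,
        "branches": [
            {
                "branch_id": b.branch_id,
                "parent_id": b.parent_id,
                "attach_index": b.attach_index,
                "label": b.label,
                "points": b.points.tolist(),
                "radii": b.radii.tolist(),
            }
            for b in sorted(tree.branches.values(), key=lambda x: x.branch_id)
        ],
    }


def tree_from_dict(doc: Mapping) -> CoronaryTree:
    if doc.get("schema") != TREE_SCHEMA:
        raise ValidationError(f"unsupported tree schema {doc.get('schema')!r}")
    branches = {}
    for entry in doc["branches"]:
        b = BranchGeometry(
            branch_id=entry["branch_id"],
            parent_id=entry.get("parent_id"),
            attach_index=entry.get("attach_index"),
            label=entry["label"],
            points=entry["points"],
            radii=entry["radii"],
        )
        branches[b.branch_id] = b
    return CoronaryTree(artery_label=doc["artery_label"], branches=branches)


def save_tree(tree: CoronaryTree, path) -> None:
    _dump_json(tree_to_dict(tree), path)


def load_tree(path) -> CoronaryTree:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValidationError(f"malformed tree JSON at {path}: {e}") from e
    return tree_from_dict(doc)


def save_trees(trees: Mapping[str, CoronaryTree], path) -> None:
    """Save several trees (keyed by artery label) into one JSON document."""
    _dump_json(
        {"schema": "corflow-trees/1", "trees": {k: tree_to_dict(t) for k, t in sorted(trees.items())}},
        path,
    )


def load_trees(path) -> dict[str, CoronaryTree]:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != "corflow-trees/1":
        raise ValidationError(f"unsupported trees schema {doc.get('schema')!r}")
    return {k: tree_from_dict(v) for k, v in doc["trees"].items()}


def save_mask(mask: MyocardiumMask, path) -> None:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(mask.spacing)
    affine[:3, 3] = mask.origin
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine)
    nib.save(img, str(path))


def load_mask(path) -> MyocardiumMask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValidationError(f"mask volume must be 3-D, got {data.ndim}-D")
    affine = img.affine
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    origin = affine[:3, 3]
    return MyocardiumMask(voxels=data != 0, spacing=spacing, origin=origin)


def save_lesions(lesions: Iterable[Lesion], path) -> None:
    _dump_json(
        {
            "schema": "corflow-lesions/1",
            "lesions": [
                {
                    "branch_id": l.branch_id,
                    "s_start": l.s_start,
                    "s_end": l.s_end,
                    "severity": l.severity,
                    "profile": l.profile,
                }
                for l in lesions
            ],
        },
        path,
    )


def load_lesions(path) -> list[Lesion]:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != "corflow-lesions/1":
        raise ValidationError(f"unsupported lesions schema {doc.get('schema')!r}")
    return [Lesion(**entry) for entry in doc["lesions"]]


def save_patient(record: PatientRecord, path) -> None:
    _dump_json(
        {
            "schema": "corflow-patient/1",
            "patient_id": record.patient_id,
            "sbp_mmhg": record.sbp_mmhg,
            "dbp_mmhg": record.dbp_mmhg,
            "measured_ffr": record.measured_ffr,
            "frame_counts": record.frame_counts,
            "vessel_lengths_mm": record.vessel_lengths_mm,
            "myocardial_mass_g": record.myocardial_mass_g,
        },
        path,
    )


def load_patient(path) -> PatientRecord:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != "corflow-patient/1":
        raise ValidationError(f"unsupported patient schema {doc.get('schema')!r}")
    doc = dict(doc)
    doc.pop("schema")
    return PatientRecord(**doc)
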