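"""Seeded synthetic phantoms: LV shell masks, coronary trees, lesions, patients.

The left ventricle is emulated as a truncated ellipsoid shell — the simplest
shape with the topology the territory method needs. Coronary trees grow on a
slightly inflated copy of the epicardial (outer) surface, each main artery in
its own azimuthal sector (LAD anterior, LCx lateral, RCA inferior), so
territory fractions are controllable by construction. Daughter radii at every
generated bifurcation satisfy Murray's radius relation
``r_parent**3 = r_d1**3 + r_d2**3`` with a random split fraction.

All randomness flows through a single ``numpy`` Generator seeded from the
spec, so every output is a pure function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    MAIN_LABELS,
    SIDE_LABEL,
    BranchGeometry,
    CoronaryTree,
    Lesion,
    MyocardiumMask,
    PatientRecord,
    ValidationError,
    arc_length,
)

__all__ = [
    "TreeParams",
    "LesionParams",
    "PhantomSpec",
    "PhantomCase",
    "generate_lv_mask",
    "generate_tree",
    "generate_patient",
]

# azimuthal sectors (radians) in which each artery's root starts
ARTERY_SECTORS = {"LAD": (-0.6, 0.6), "LCx": (1.3, 2.3), "RCA": (3.4, 4.4)}
# how far outside the epicardial surface the centerlines sit
SURFACE_INFLATION = 1.02


@dataclass
class TreeParams:
    """Controls for one synthetic coronary tree."""

    depth: int = 3
    root_radius_mm: float = 1.5
    branch_length_mm: tuple[float, float] = (15.0, 30.0)
    spread_deg: float = 28.0
    step_mm: float = 2.0
    split_range: tuple[float, float] = (0.35, 0.65)

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValidationError("tree depth must be >= 0")
        if not (0.5 <= self.root_radius_mm <= 3.0):
            raise ValidationError("root radius outside plausible coronary range")
        lo, hi = self.split_range
        if not (0 < lo <= hi < 1):
            raise ValidationError("split_range must lie strictly inside (0, 1)")


@dataclass
class LesionParams:
    """Controls for synthetic stenoses placed on each artery's root branch."""

    severity_range: tuple[float, float] = (30.0, 85.0)
    length_mm: tuple[float, float] = (8.0, 12.0)
    start_frac: tuple[float, float] = (0.2, 0.45)

    def __post_init__(self) -> None:
        lo, hi = self.severity_range
        if not (0 <= lo <= hi < 100):
            raise ValidationError("severity_range must lie inside [0, 100)")


@dataclass
class PhantomSpec:
    """Full description of one synthetic case.

    The LV shell defaults (outer 30x30x40 mm, inner 22x22x32 mm semi-axes,
    basal cut 20 mm above the centre, 2 mm voxels) give a myocardial mass
    near 90 g at the default tissue density — within the range of a real
    cohort. SBP/DBP ranges put the weighted mean aortic pressure near the
    low-90s mmHg typical of rest measurements. ``ffr_noise_sd`` is the
    standard deviation of the synthetic catheter-measurement noise added to
    the model FFR to produce a "measured" reference value.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    outer_semi_axes_mm: tuple[float, float, float] = (30.0, 30.0, 40.0)
    inner_semi_axes_mm: tuple[float, float, float] = (22.0, 22.0, 32.0)
    basal_cut_mm: float = 20.0
    tree: TreeParams = field(default_factory=TreeParams)
    lesion: LesionParams = field(default_factory=LesionParams)
    sbp_range_mmhg: tuple[float, float] = (100.0, 140.0)
    dbp_range_mmhg: tuple[float, float] = (60.0, 90.0)
    ffr_noise_sd: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        outer = np.asarray(self.outer_semi_axes_mm, dtype=float)
        inner = np.asarray(self.inner_semi_axes_mm, dtype=float)
        if not np.all(outer > 0):
            raise ValidationError("outer semi-axes must be positive")
        if np.any(inner < 0):
            raise ValidationError("inner semi-axes must be non-negative")
        if np.any(inner >= outer):
            raise ValidationError("inner semi-axes must be strictly smaller than outer")


@dataclass
class PhantomCase:
    """One generated case plus the ground-truth generator parameters."""

    record: PatientRecord
    mask: MyocardiumMask
    trees: dict[str, CoronaryTree]
    lesions: list[Lesion]
    truth: dict


def _centered_origin(spec: PhantomSpec) -> np.ndarray:
    shape = np.asarray(spec.shape, dtype=float)
    spacing = np.asarray(spec.spacing, dtype=float)
    return -(shape - 1) / 2.0 * spacing


def generate_lv_mask(spec: PhantomSpec) -> MyocardiumMask:
    """Voxelize the truncated ellipsoid shell (deterministic, no RNG).

    A voxel is occupied iff its centre lies inside the outer ellipsoid,
    outside the inner ellipsoid (or the inner cavity is absent when any inner
    semi-axis is zero), and at or below the basal cut plane ``z <= basal_cut``.
    The grid is centred on the ellipsoid centre.
    """
    origin = _centered_origin(spec)
    spacing = np.asarray(spec.spacing, dtype=float)
    xs = origin[0] + np.arange(spec.shape[0]) * spacing[0]
    ys = origin[1] + np.arange(spec.shape[1]) * spacing[1]
    zs = origin[2] + np.arange(spec.shape[2]) * spacing[2]
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    outer = np.asarray(spec.outer_semi_axes_mm, dtype=float)
    inner = np.asarray(spec.inner_semi_axes_mm, dtype=float)
    in_outer = (X / outer[0]) ** 2 + (Y / outer[1]) ** 2 + (Z / outer[2]) ** 2 <= 1.0
    if np.all(inner > 0):
        in_inner = (X / inner[0]) ** 2 + (Y / inner[1]) ** 2 + (Z / inner[2]) ** 2 <= 1.0
    else:
        in_inner = np.zeros_like(in_outer)
    occupied = in_outer & ~in_inner & (Z <= spec.basal_cut_mm)
    if not occupied.any():
        raise ValidationError("phantom spec produced an empty LV shell")
    return MyocardiumMask(voxels=occupied, spacing=spacing, origin=origin)


def _surface_point(spec: PhantomSpec, theta: float, phi: float) -> np.ndarray:
    """Map surface parameters (azimuth theta, polar phi from +z) to world mm."""
    a, b, c = (SURFACE_INFLATION * v for v in spec.outer_semi_axes_mm)
    return np.array(
        [
            a * math.sin(phi) * math.cos(theta),
            b * math.sin(phi) * math.sin(theta),
            c * math.cos(phi),
        ]
    )


def generate_tree(spec: PhantomSpec, artery_label: str, rng: np.random.Generator) -> CoronaryTree:
    """Grow one bifurcating tree on the inflated epicardial surface.

    Branches walk in (theta, phi) parameter space from near the base toward
    the apex with a random heading drift; at each bifurcation the two
    daughters take headings split by ``spread_deg`` and radii satisfying
    ``r1**3 + r2**3 = r_parent**3`` with split fraction drawn from
    ``split_range``. Depth 0 yields a single root branch.
    """
    if artery_label not in MAIN_LABELS:
        raise ValidationError(f"artery_label must be one of {MAIN_LABELS}")
    tp = spec.tree
    mean_semi = float(np.mean(spec.outer_semi_axes_mm))
    dphi_step = tp.step_mm / mean_semi  # angular step giving ~step_mm arc steps
    branches: dict[str, BranchGeometry] = {}

    def grow(
        branch_id: str,
        parent_id: str | None,
        attach_index: int | None,
        label: str,
        theta: float,
        phi: float,
        heading: float,
        radius: float,
        depth_left: int,
    ) -> None:
        length = rng.uniform(*tp.branch_length_mm)
        n_steps = max(2, int(round(length / tp.step_mm)))
        pts = [_surface_point(spec, theta, phi)]
        for _ in range(n_steps):
            heading += rng.normal(0.0, 0.08)
            phi = min(phi + dphi_step * math.cos(heading), 2.9)
            theta = theta + dphi_step * math.sin(heading) / max(math.sin(phi), 0.25)
            pts.append(_surface_point(spec, theta, phi))
        points = np.asarray(pts)
        branches[branch_id] = BranchGeometry(
            branch_id=branch_id,
            parent_id=parent_id,
            attach_index=attach_index,
            label=label,
            points=points,
            radii=np.full(len(points), radius),
        )
        if depth_left > 0:
            u = rng.uniform(*tp.split_range)
            r1 = radius * u ** (1.0 / 3.0)
            r2 = radius * (1.0 - u) ** (1.0 / 3.0)
            spread = math.radians(tp.spread_deg)
            tip = len(points) - 1
            grow(f"{branch_id}.0", branch_id, tip, SIDE_LABEL, theta, phi,
                 heading - spread, r1, depth_left - 1)
            grow(f"{branch_id}.1", branch_id, tip, SIDE_LABEL, theta, phi,
                 heading + spread, r2, depth_left - 1)

    theta0 = rng.uniform(*ARTERY_SECTORS[artery_label])
    phi0 = rng.uniform(0.35, 0.55)
    grow(artery_label, None, None, artery_label, theta0, phi0, 0.0,
         tp.root_radius_mm, tp.depth)
    return CoronaryTree(artery_label=artery_label, branches=branches)


def generate_patient(
    spec: PhantomSpec,
    rng: np.random.Generator | None = None,
    severities: dict[str, float] | None = None,
) -> PhantomCase:
    """Bundle a full synthetic case: mask, three trees, lesions and scalars.

    ``severities`` optionally pins the per-artery lesion severity (percent
    diameter reduction); otherwise severities are drawn from the spec range.
    The returned ``truth`` dict records every generator draw for recovery
    tests.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.rng_seed)
    mask = generate_lv_mask(spec)
    trees = {lab: generate_tree(spec, lab, rng) for lab in MAIN_LABELS}

    lesions: list[Lesion] = []
    truth_lesions: dict[str, dict] = {}
    for lab in MAIN_LABELS:
        root = trees[lab].root
        total = arc_length(root)
        sev = (
            severities[lab]
            if severities is not None
            else float(rng.uniform(*spec.lesion.severity_range))
        )
        start = float(rng.uniform(*spec.lesion.start_frac)) * total
        length = float(rng.uniform(*spec.lesion.length_mm))
        # keep the +5 mm distal sampling station on the lesion's own branch
        max_end = total - 6.0
        start = min(start, max_end - 4.0)
        end = min(start + length, max_end)
        lesions.append(
            Lesion(branch_id=root.branch_id, s_start=start, s_end=end, severity=sev)
        )
        truth_lesions[lab] = {"severity": sev, "s_start": start, "s_end": end}

    sbp = float(rng.uniform(*spec.sbp_range_mmhg))
    dbp = float(rng.uniform(*spec.dbp_range_mmhg))
    if dbp > sbp:
        sbp, dbp = dbp, sbp
    record = PatientRecord(
        patient_id=f"phantom-{spec.rng_seed}",
        sbp_mmhg=sbp,
        dbp_mmhg=dbp,
    )
    truth = {
        "rng_seed": spec.rng_seed,
        "lesions": truth_lesions,
        "sbp_mmhg": sbp,
        "dbp_mmhg": dbp,
        "n_occupied_voxels": mask.n_occupied,
    }
    return PhantomCase(record=record, mask=mask, trees=trees, lesions=lesions, truth=truth)
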