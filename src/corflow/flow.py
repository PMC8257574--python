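"""Coronary flow estimation: allometric total flow, territory/Windkessel/
frame-count allocation to arteries, and Murray's-law splitting inside a tree.

Three independent routes produce the outlet flow boundary condition:

* **Territory-based** — total flow from the allometric law Q = a * M^b
  (a = 0.64 ml/min/g^b, b = 0.75), allocated to LAD/LCx/RCA in proportion to
  their myocardial territory fractions, then split down each tree by
  Murray's law (flow proportional to radius cubed at every bifurcation).
* **Windkessel-model-based** — per-artery flow inversely proportional to its
  lumped microvascular resistance; hyperemic resistance is the rest
  resistance times the total coronary resistance index (TCRI).
* **Frame-count-based** — velocity from the cine-frame transit time of
  contrast (15 frames/s acquisition), mass flow = density x velocity x area.

All three emit the same :class:`FlowAssignment` shape so the pressure solver
is agnostic to the method that produced its boundary condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import BranchGeometry, CoronaryTree, ValidationError

__all__ = [
    "BLOOD_DENSITY_KG_M3",
    "ScalingParams",
    "ResistanceSpec",
    "FlowAssignment",
    "total_flow_allometric",
    "allocate_main_arteries",
    "murray_split",
    "windkessel_allocation",
    "frame_count_flow",
    "mass_flow",
]

BLOOD_DENSITY_KG_M3 = 1060.0


@dataclass
class ScalingParams:
    """Allometric scaling Q = a * M^b with Q in ml/min and M in g.

    a is the characteristic constant of the cardiovascular system
    (experimentally derived); b is the theoretical 3/4 scaling exponent.
    """

    a: float = 0.64
    b: float = 0.75

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValidationError("scaling constant a must be positive")
        if not (0 < self.b <= 1):
            raise ValidationError("scaling exponent b must be in (0, 1]")


@dataclass
class ResistanceSpec:
    """Per-artery rest resistances and the hyperemia multiplier.

    ``resistances`` maps artery label to rest resistance in mmHg·min/ml.
    The shipped defaults are placeholders in a plausible range — published
    rest-state resistance tables should be supplied explicitly for any real
    analysis. TCRI (total coronary resistance index) converts rest to
    hyperemic resistance; 0.24 is the commonly cited hyperemic/rest ratio.
    """

    resistances: dict[str, float] = field(
        default_factory=lambda: {"LAD": 2.0, "LCx": 3.0, "RCA": 3.5}
    )
    tcri: float = 0.24
    venous_pressure_mmhg: float = 0.0

    def __post_init__(self) -> None:
        if not self.resistances:
            raise ValidationError("ResistanceSpec requires at least one artery")
        for lab, r in self.resistances.items():
            if r <= 0:
                raise ValidationError(f"rest resistance for {lab!r} must be positive")
        if not (0 < self.tcri <= 1):
            raise ValidationError("TCRI must be in (0, 1]")


@dataclass
class FlowAssignment:
    """Per-segment volumetric flows (ml/min) on one or more trees.

    ``segment_flows`` maps ``(branch_id, i)`` — the centerline interval from
    point ``i`` to ``i+1`` — to the volumetric flow carried by that interval.
    ``terminal_outflows`` is the flow leaving the distal end of each branch
    (zero where the entire flow is handed to children attached at the tip).
    """

    method: str
    root_flows: dict[str, float] = field(default_factory=dict)
    segment_flows: dict[tuple[str, int], float] = field(default_factory=dict)
    terminal_outflows: dict[str, float] = field(default_factory=dict)
    rho_kg_m3: float = BLOOD_DENSITY_KG_M3

    def branch_flow_at(self, branch: BranchGeometry, s) -> np.ndarray:
        """Flow (ml/min) at arc position(s) ``s`` on ``branch`` (piecewise constant)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        pos = branch.arc_positions
        seg = np.clip(np.searchsorted(pos, s, side="right") - 1, 0, branch.n_points - 2)
        out = np.array([self.segment_flows[(branch.branch_id, int(i))] for i in seg])
        return out

    def merged_with(self, other: "FlowAssignment") -> "FlowAssignment":
        """Combine assignments for disjoint trees into one."""
        return FlowAssignment(
            method=self.method,
            root_flows={**self.root_flows, **other.root_flows},
            segment_flows={**self.segment_flows, **other.segment_flows},
            terminal_outflows={**self.terminal_outflows, **other.terminal_outflows},
            rho_kg_m3=self.rho_kg_m3,
        )


def total_flow_allometric(mass_g: float, params: ScalingParams | None = None) -> float:
    """Total coronary volumetric flow (ml/min) from LV mass via Q = a * M^b."""
    if mass_g <= 0:
        raise ValidationError("myocardial mass must be positive")
    p = params or ScalingParams()
    return p.a * mass_g**p.b


def allocate_main_arteries(q_total: float, fractions: dict[str, float]) -> dict[str, float]:
    """Split total flow across main arteries in proportion to territory fractions."""
    if q_total < 0:
        raise ValidationError("total flow must be non-negative")
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValidationError(f"territory fractions must sum to 1, got {sum(fractions.values())}")
    return {lab: q_total * f for lab, f in fractions.items()}


def murray_split(tree: CoronaryTree, q_root: float, exponent: float = 3.0) -> FlowAssignment:
    """Distribute a tree's root inflow down all branches by Murray's law.

    At every bifurcation, daughter subtree ``i`` receives
    ``Q_parent * r_i**exponent / sum_j r_j**exponent`` where ``r_i`` is the
    daughter's first-point radius; the continuation of the parent branch past
    an interior attachment competes with its own local radius. Within a
    branch the flow is constant between bifurcations, so flow is conserved at
    every node by construction.
    """
    if q_root < 0:
        raise ValidationError("root flow must be non-negative")
    fa = FlowAssignment(method="murray", root_flows={tree.artery_label: q_root})

    def descend(branch: BranchGeometry, q_in: float) -> None:
        kids = tree.children_of(branch.branch_id)
        q = q_in
        n = branch.n_points
        for i in range(n - 1):
            if i in kids:  # interior attachment before this interval
                q = _split(branch, i, kids[i], q, continuation=True)
            fa.segment_flows[(branch.branch_id, i)] = q
        if (n - 1) in kids:  # bifurcation at the branch tip: no continuation
            q = _split(branch, n - 1, kids[n - 1], q, continuation=False)
        fa.terminal_outflows[branch.branch_id] = q

    def _split(
        branch: BranchGeometry,
        index: int,
        children: list[BranchGeometry],
        q: float,
        continuation: bool,
    ) -> float:
        radii = [child.radii[0] for child in children]
        if continuation:
            radii.append(branch.radii[index])
        if any(r <= 0 for r in radii):
            raise ValidationError(
                f"zero radius at bifurcation (branch {branch.branch_id!r}, point {index})"
            )
        weights = np.asarray(radii, dtype=float) ** exponent
        denom = weights.sum()
        for child, w in zip(children, weights):
            descend(child, q * w / denom)
        return q * weights[-1] / denom if continuation else 0.0

    descend(tree.root, q_root)
    return fa


def windkessel_allocation(spec: ResistanceSpec, abp_mmhg: float) -> dict[str, float]:
    """Per-artery flow (ml/min) from lumped resistances under hyperemia.

    Hyperemic resistance is ``R_a * TCRI``; each artery carries
    ``(ABP - P_v) / R_h``, so the relative allocation is inversely
    proportional to the rest resistance and independent of TCRI.
    """
    dp = abp_mmhg - spec.venous_pressure_mmhg
    if dp <= 0:
        raise ValidationError("driving pressure must exceed venous pressure")
    return {lab: dp / (r * spec.tcri) for lab, r in spec.resistances.items()}


def frame_count_flow(
    n_frames: int,
    length_mm: float,
    area_mm2: float,
    fps: float = 15.0,
    rho_kg_m3: float = BLOOD_DENSITY_KG_M3,
) -> tuple[float, float]:
    """Mass flow (kg/s) and velocity (mm/s) from a cine frame count.

    Transit time is ``n_frames / fps`` (cine acquisition at 15 frames/s by
    default); velocity is the 3-D vessel length over the transit time, and
    mass flow is density x velocity x cross-sectional area in SI units.
    Returns ``(mass_flow_kg_s, velocity_mm_s)``.
    """
    if n_frames < 1:
        raise ValidationError("frame count must be at least 1")
    if fps <= 0 or length_mm <= 0 or area_mm2 <= 0 or rho_kg_m3 <= 0:
        raise ValidationError("fps, length, area and density must be positive")
    velocity_mm_s = length_mm / (n_frames / fps)
    mdot = rho_kg_m3 * (velocity_mm_s * 1e-3) * (area_mm2 * 1e-6)
    return mdot, velocity_mm_s


def mass_flow(q_ml_min: float, rho_kg_m3: float = BLOOD_DENSITY_KG_M3) -> float:
    """Convert volumetric flow (ml/min) to mass flow (kg/s)."""
    if q_ml_min < 0:
        raise ValidationError("volumetric flow must be non-negative")
    return q_ml_min * 1e-6 / 60.0 * rho_kg_m3
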