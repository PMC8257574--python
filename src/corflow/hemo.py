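"""Reduced-order steady hemodynamics: pressure profiles, FFR and wall shear.

The model is one-dimensional and steady. Along each branch, the viscous
pressure gradient follows Poiseuille flow in a slowly varying lumen,

    dP/ds = 8 * mu * Q / (pi * r(s)**4),

accumulated by the composite trapezoid rule on a fixed arc-length grid.
At the exit of each stenosis an irreversible Borda–Carnot expansion loss

    dP_e = K_e * (rho / 2) * (Q/A_s - Q/A_d)**2

is added, where ``A_s`` is the minimum lumen area inside the lesion and
``A_d`` the reference lumen area at the station 5 mm past the lesion end
(the same station at which FFR samples the distal pressure). Wall shear
stress is the Poiseuille value ``tau = 4 * mu * Q / (pi * r**3)``, which in
a 1-D model is circumferentially uniform, so the circumferential average is
tau itself.

FFR for a lesion is the pressure 5 mm past the lesion end divided by the
inlet (aortic) pressure. WSS_prox is the arc-length mean of tau over the
proximal third of the lesion interval.

Walls are rigid and the fluid Newtonian (viscosity 0.03 poise = 0.003 Pa·s,
density 1060 kg/m³). Interfaces use mmHg and ml/min; internals are SI with
1 mmHg = 133.322 Pa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flow import BLOOD_DENSITY_KG_M3, FlowAssignment
from .geometry import (
    BranchGeometry,
    CoronaryTree,
    Lesion,
    ValidationError,
    arc_length,
    lesion_radius_at,
)

__all__ = [
    "MMHG_TO_PA",
    "FFR_SAMPLE_OFFSET_MM",
    "FluidProperties",
    "BoundaryConditions",
    "BranchProfile",
    "HemoResult",
    "inlet_pressure",
    "solve_pressure",
    "ffr",
    "wss_profile",
    "wss_prox",
]

MMHG_TO_PA = 133.322
ML_MIN_TO_M3_S = 1e-6 / 60.0
# distal pressure is sampled this far past the lesion end
FFR_SAMPLE_OFFSET_MM = 5.0


@dataclass
class FluidProperties:
    """Newtonian blood: viscosity 0.03 poise, density 1060 kg/m³."""

    viscosity_pa_s: float = 0.003
    density_kg_m3: float = BLOOD_DENSITY_KG_M3

    def __post_init__(self) -> None:
        if self.viscosity_pa_s <= 0 or self.density_kg_m3 <= 0:
            raise ValidationError("viscosity and density must be positive")


@dataclass
class BoundaryConditions:
    """Inlet pressure (mmHg) plus the per-segment outlet flow assignment."""

    inlet_pressure_mmhg: float
    flows: FlowAssignment

    def __post_init__(self) -> None:
        if self.inlet_pressure_mmhg <= 0:
            raise ValidationError("inlet pressure must be positive")


@dataclass
class BranchProfile:
    """Sampled arrays along one branch's arc length."""

    s_mm: np.ndarray
    pressure_mmhg: np.ndarray
    wss_pa: np.ndarray
    flow_ml_min: np.ndarray
    radius_mm: np.ndarray


@dataclass
class HemoResult:
    """Solved pressure/WSS profiles for one tree plus bookkeeping."""

    inlet_pressure_mmhg: float
    branches: dict[str, BranchProfile] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def inlet_pressure(sbp_mmhg: float, dbp_mmhg: float) -> float:
    """Average aortic pressure ABP = SBP/3 + 2*DBP/3 (mmHg).

    Diastole occupies two-thirds of the cardiac cycle and systole one-third,
    hence the 1/3–2/3 weighting of the cuff pressures.
    """
    if not (sbp_mmhg >= dbp_mmhg > 0):
        raise ValidationError(f"need SBP >= DBP > 0, got {sbp_mmhg}/{dbp_mmhg}")
    return sbp_mmhg / 3.0 + 2.0 * dbp_mmhg / 3.0


def _lesions_by_branch(tree: CoronaryTree, lesions: list[Lesion]) -> dict[str, list[Lesion]]:
    out: dict[str, list[Lesion]] = {}
    for les in lesions:
        if les.branch_id not in tree.branches:
            continue
        branch = tree.branches[les.branch_id]
        if les.s_end > arc_length(branch) + 1e-9:
            raise ValidationError(
                f"lesion [{les.s_start}, {les.s_end}] extends past branch "
                f"{les.branch_id!r} (length {arc_length(branch):.6g} mm)"
            )
        out.setdefault(les.branch_id, []).append(les)
    for bid, ll in out.items():
        ll.sort(key=lambda l: l.s_start)
        for a, b in zip(ll, ll[1:]):
            if b.s_start < a.s_end:
                raise ValidationError(f"overlapping lesions on branch {bid!r}")
    return out


def _branch_grid(
    branch: BranchGeometry,
    branch_lesions: list[Lesion],
    attach_s: list[float],
    step_mm: float,
) -> np.ndarray:
    total = arc_length(branch)
    specials = [total] + list(attach_s)
    for les in branch_lesions:
        mid = 0.5 * (les.s_start + les.s_end)
        specials += [les.s_start, mid, les.s_end, min(les.s_end + FFR_SAMPLE_OFFSET_MM, total)]
    grid = np.unique(np.concatenate([np.arange(0.0, total, step_mm), specials]))
    return grid


def solve_pressure(
    tree: CoronaryTree,
    lesions: list[Lesion],
    bc: BoundaryConditions,
    fluid: FluidProperties | None = None,
    step_mm: float = 0.25,
    expansion_k: float = 1.0,
) -> HemoResult:
    """Integrate the 1-D pressure and WSS profiles over a whole tree.

    Branches are processed root-first; each child branch inherits the parent
    pressure interpolated at its attachment point. A zero-severity lesion is
    a no-op: it neither narrows the lumen nor triggers an expansion loss.
    """
    fluid = fluid or FluidProperties()
    mu = fluid.viscosity_pa_s
    rho = fluid.density_kg_m3
    by_branch = _lesions_by_branch(tree, lesions)
    result = HemoResult(inlet_pressure_mmhg=bc.inlet_pressure_mmhg)

    def solve_branch(branch: BranchGeometry, p_in_mmhg: float) -> None:
        kids = tree.children_of(branch.branch_id)
        attach_s = [float(branch.arc_positions[i]) for i in kids]
        bl = by_branch.get(branch.branch_id, [])
        grid = _branch_grid(branch, bl, attach_s, step_mm)
        r_mm = lesion_radius_at(branch, bl, grid)
        if np.any(r_mm <= 1e-9):
            s_bad = grid[np.argmin(r_mm)]
            raise ValidationError(
                f"lumen radius vanishes on branch {branch.branch_id!r} at s = {s_bad:.3g} mm"
            )
        r_m = r_mm * 1e-3
        mids = 0.5 * (grid[:-1] + grid[1:])
        q_mid = bc.flows.branch_flow_at(branch, mids) * ML_MIN_TO_M3_S  # m³/s per interval
        inv_r4 = 1.0 / r_m**4
        ds = np.diff(grid) * 1e-3
        dp = (8.0 * mu / np.pi) * q_mid * 0.5 * (inv_r4[:-1] + inv_r4[1:]) * ds
        p_pa = p_in_mmhg * MMHG_TO_PA - np.concatenate([[0.0], np.cumsum(dp)])

        # Borda–Carnot expansion loss at each stenosis exit
        for les in bl:
            if les.severity == 0:
                continue
            in_les = (grid >= les.s_start) & (grid <= les.s_end)
            r_min = r_mm[in_les].min()
            a_s = np.pi * (r_min * 1e-3) ** 2
            s_ref = min(les.s_end + FFR_SAMPLE_OFFSET_MM, arc_length(branch))
            r_ref = lesion_radius_at(branch, bl, s_ref)
            a_d = np.pi * (r_ref * 1e-3) ** 2
            q_les = float(bc.flows.branch_flow_at(branch, 0.5 * (les.s_start + les.s_end))[0])
            q_si = q_les * ML_MIN_TO_M3_S
            dp_e = expansion_k * 0.5 * rho * (q_si / a_s - q_si / a_d) ** 2
            p_pa = np.where(grid >= les.s_end, p_pa - dp_e, p_pa)

        q_point = bc.flows.branch_flow_at(branch, grid) * ML_MIN_TO_M3_S
        tau = 4.0 * mu * q_point / (np.pi * r_m**3)
        p_mmhg = p_pa / MMHG_TO_PA
        result.branches[branch.branch_id] = BranchProfile(
            s_mm=grid,
            pressure_mmhg=p_mmhg,
            wss_pa=tau,
            flow_ml_min=q_point / ML_MIN_TO_M3_S,
            radius_mm=r_mm,
        )
        for idx, children in kids.items():
            s_at = float(branch.arc_positions[idx])
            p_at = float(np.interp(s_at, grid, p_mmhg))
            for child in children:
                solve_branch(child, p_at)

    solve_branch(tree.root, bc.inlet_pressure_mmhg)
    return result


def _profile_for(result: HemoResult, lesion: Lesion) -> BranchProfile:
    if lesion.branch_id not in result.branches:
        raise ValidationError(f"lesion branch {lesion.branch_id!r} not present in solved result")
    return result.branches[lesion.branch_id]


def ffr(result: HemoResult, lesion: Lesion) -> float:
    """FFR = P(s_end + 5 mm) / P_a for one lesion on a solved branch.

    If the branch ends within 5 mm of the lesion, the distal pressure is
    sampled at the branch end and a warning is recorded on the result.
    """
    prof = _profile_for(result, lesion)
    s_target = lesion.s_end + FFR_SAMPLE_OFFSET_MM
    s_max = float(prof.s_mm[-1])
    if s_target > s_max + 1e-9:
        result.warnings.append(
            f"branch {lesion.branch_id!r} ends {s_max - lesion.s_end:.2f} mm past the "
            f"lesion; distal pressure sampled at the branch end instead of +5 mm"
        )
        s_target = s_max
    p_d = float(np.interp(s_target, prof.s_mm, prof.pressure_mmhg))
    return p_d / result.inlet_pressure_mmhg


def wss_profile(result: HemoResult, branch_id: str) -> tuple[np.ndarray, np.ndarray]:
    """Arc positions (mm) and wall shear stress (Pa) along a solved branch."""
    if branch_id not in result.branches:
        raise ValidationError(f"branch {branch_id!r} not present in solved result")
    prof = result.branches[branch_id]
    return prof.s_mm, prof.wss_pa


def wss_prox(result: HemoResult, lesion: Lesion) -> float:
    """Mean WSS (Pa) over the proximal third of the lesion interval."""
    prof = _profile_for(result, lesion)
    s_lo = lesion.s_start
    s_hi = lesion.s_start + (lesion.s_end - lesion.s_start) / 3.0
    if s_hi > prof.s_mm[-1] + 1e-9 or s_lo < -1e-9:
        raise ValidationError(f"lesion window outside branch {lesion.branch_id!r}")
    inner = prof.s_mm[(prof.s_mm > s_lo) & (prof.s_mm < s_hi)]
    s_w = np.concatenate([[s_lo], inner, [s_hi]])
    tau_w = np.interp(s_w, prof.s_mm, prof.wss_pa)
    return float(np.trapezoid(tau_w, s_w) / (s_hi - s_lo))
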