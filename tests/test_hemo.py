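"""Reduced-order solver: analytic Poiseuille limits, FFR, WSS, monotonicity."""

import numpy as np
import pytest

from corflow.flow import FlowAssignment, murray_split
from corflow.geometry import CoronaryTree, Lesion, ValidationError
from corflow.hemo import (
    MMHG_TO_PA,
    BoundaryConditions,
    ffr,
    inlet_pressure,
    solve_pressure,
    wss_profile,
    wss_prox,
)

from conftest import single_branch_tree, straight_branch

MU = 0.003  # Pa s
Q60_SI = 1e-6  # 60 ml/min in m^3/s


def uniform_flow(tree: CoronaryTree, q_ml_min: float) -> FlowAssignment:
    fa = FlowAssignment(method="manual", root_flows={tree.artery_label: q_ml_min})
    for b in tree.branches.values():
        for i in range(b.n_points - 1):
            fa.segment_flows[(b.branch_id, i)] = q_ml_min
    return fa


def solve_tube(length=100.0, radius=1.5, q=60.0, lesions=(), p_in=93.0, step=0.25, **kw):
    tree = single_branch_tree(length=length, radius=radius)
    bc = BoundaryConditions(p_in, uniform_flow(tree, q))
    return tree, solve_pressure(tree, list(lesions), bc, step_mm=step, **kw)


class TestInletPressure:
    @pytest.mark.parametrize(
        "sbp,dbp,expected", [(120, 80, 280 / 3), (90, 90, 90.0), (150, 60, 90.0)]
    )
    def test_weighted_average(self, sbp, dbp, expected):
        assert inlet_pressure(sbp, dbp) == pytest.approx(expected, rel=1e-12)

    def test_sbp_below_dbp_rejected(self):
        with pytest.raises(ValidationError):
            inlet_pressure(80, 120)


class TestPoiseuilleLimits:
    def test_uniform_tube_matches_closed_form(self):
        # dP = 8 mu L Q / (pi r^4): trapezoid is exact for a constant integrand
        _, res = solve_tube(step=0.05)
        expected_pa = 8 * MU * 0.1 * Q60_SI / (np.pi * (1.5e-3) ** 4)
        drop_pa = (res.branches["LAD"].pressure_mmhg[0] - res.branches["LAD"].pressure_mmhg[-1]) * MMHG_TO_PA
        assert drop_pa == pytest.approx(expected_pa, rel=1e-3)
        assert expected_pa == pytest.approx(150.9, rel=2e-3)  # hand-checked value

    def test_zero_flow_constant_pressure(self):
        _, res = solve_tube(q=0.0)
        assert np.allclose(res.branches["LAD"].pressure_mmhg, 93.0)

    def test_pressure_monotone_nonincreasing(self):
        les = Lesion("LAD", 30, 45, severity=60.0)
        _, res = solve_tube(lesions=[les])
        p = res.branches["LAD"].pressure_mmhg
        assert np.all(np.diff(p) <= 1e-12)

    def test_grid_convergence_half_step(self):
        les = Lesion("LAD", 30, 45, severity=75.0)
        _, res1 = solve_tube(lesions=[les], step=0.25)
        _, res2 = solve_tube(lesions=[les], step=0.125)
        p1 = res1.branches["LAD"]
        p2 = res2.branches["LAD"]
        common = np.linspace(0, 100, 401)
        d = np.interp(common, p1.s_mm, p1.pressure_mmhg) - np.interp(
            common, p2.s_mm, p2.pressure_mmhg
        )
        assert np.max(np.abs(d)) <= 0.05

    def test_zero_severity_lesion_identical_to_none(self):
        les = Lesion("LAD", 30, 45, severity=0.0)
        _, res0 = solve_tube()
        _, resl = solve_tube(lesions=[les])
        common = np.linspace(0, 100, 201)
        p0 = np.interp(common, res0.branches["LAD"].s_mm, res0.branches["LAD"].pressure_mmhg)
        pl = np.interp(common, resl.branches["LAD"].s_mm, resl.branches["LAD"].pressure_mmhg)
        assert np.allclose(p0, pl, atol=1e-12)

    def test_vanishing_radius_named_error(self):
        tree = single_branch_tree(length=50, radius=1.0)
        les = Lesion("LAD", 10, 20, severity=99.9999999)
        bc = BoundaryConditions(93.0, uniform_flow(tree, 60.0))
        with pytest.raises(ValidationError, match="LAD"):
            solve_pressure(tree, [les], bc)

    def test_child_inherits_parent_pressure_at_attachment(self):
        root = straight_branch(branch_id="LAD", n_pts=11, length=50)
        child = straight_branch(branch_id="LAD.0", label="SIDE", parent_id="LAD",
                                attach_index=5, origin=(25, 1, 0), direction=(0, 1, 0),
                                length=20, radius=1.0, n_pts=5)
        tree = CoronaryTree("LAD", {"LAD": root, "LAD.0": child})
        fa = murray_split(tree, 60.0)
        res = solve_pressure(tree, [], BoundaryConditions(93.0, fa))
        prof = res.branches["LAD"]
        p_at = np.interp(25.0, prof.s_mm, prof.pressure_mmhg)
        assert res.branches["LAD.0"].pressure_mmhg[0] == pytest.approx(p_at, abs=1e-9)


class TestFFR:
    def test_unity_at_zero_flow(self):
        _, res = solve_tube(q=0.0)
        assert ffr(res, Lesion("LAD", 30, 45, severity=0.0)) == pytest.approx(1.0)

    def test_straight_tube_analytic_value(self):
        _, res = solve_tube(p_in=280 / 3, step=0.05)
        expected_drop_mmhg = 8 * MU * 0.1 * Q60_SI / (np.pi * (1.5e-3) ** 4) / MMHG_TO_PA
        # lesion-free: pressure at any station follows the linear profile
        les = Lesion("LAD", 30, 45, severity=0.0)
        s_station = 50.0  # s_end + 5
        expected = 1 - expected_drop_mmhg * (s_station / 100.0) / (280 / 3)
        assert ffr(res, les) == pytest.approx(expected, rel=1e-4)
        assert ffr(res, les) == pytest.approx(1 - 1.13 / 93.33 * 0.5, abs=2e-4)

    def test_strictly_nonincreasing_in_severity(self):
        values = []
        for sev in np.linspace(0, 90, 19):
            _, res = solve_tube(lesions=[Lesion("LAD", 30, 45, severity=float(sev))])
            values.append(ffr(res, Lesion("LAD", 30, 45, severity=float(sev))))
        assert all(b < a + 1e-15 for a, b in zip(values, values[1:]))
        assert all(b < a for a, b in zip(values[1:], values[2:]))  # strict once sev > 0

    def test_nonincreasing_in_flow_and_lesion_length(self):
        les = Lesion("LAD", 30, 45, severity=70.0)
        ffr_by_q = [
            ffr(solve_tube(q=q, lesions=[les])[1], les) for q in (10.0, 30.0, 60.0, 120.0)
        ]
        assert all(b < a for a, b in zip(ffr_by_q, ffr_by_q[1:]))
        ffr_by_len = []
        for s_end in (35.0, 45.0, 60.0):
            l2 = Lesion("LAD", 30, s_end, severity=70.0)
            ffr_by_len.append(ffr(solve_tube(lesions=[l2])[1], l2))
        assert all(b < a for a, b in zip(ffr_by_len, ffr_by_len[1:]))

    def test_short_branch_samples_at_end_with_warning(self):
        les = Lesion("LAD", 30, 48, severity=40.0)
        _, res = solve_tube(length=50.0, lesions=[les])
        value = ffr(res, les)
        assert 0 < value <= 1
        assert any("branch end" in w for w in res.warnings)

    def test_overlapping_lesions_rejected(self):
        l1 = Lesion("LAD", 30, 45, severity=40.0)
        l2 = Lesion("LAD", 40, 55, severity=40.0)
        with pytest.raises(ValidationError, match="overlap"):
            solve_tube(lesions=[l1, l2])


class TestWSS:
    def test_poiseuille_wall_shear_formula(self):
        # tau = 4 mu Q / (pi r^3), hand-checked: 0.477 Pa at r = 2 mm, Q = 60 ml/min
        _, res = solve_tube(radius=2.0)
        s, tau = wss_profile(res, "LAD")
        expected = 4 * MU * Q60_SI / (np.pi * (2e-3) ** 3)
        assert np.allclose(tau, expected, rtol=1e-12)
        assert expected == pytest.approx(0.477, abs=5e-4)

    def test_radius_halving_multiplies_tau_by_eight(self):
        _, res1 = solve_tube(radius=2.0)
        _, res2 = solve_tube(radius=1.0)
        assert res2.branches["LAD"].wss_pa[0] == pytest.approx(
            8 * res1.branches["LAD"].wss_pa[0], rel=1e-12
        )

    def test_wss_prox_of_uniform_window_equals_pointwise_tau(self):
        les = Lesion("LAD", 30, 45, severity=0.0)
        _, res = solve_tube(lesions=[les])
        s, tau = wss_profile(res, "LAD")
        assert wss_prox(res, les) == pytest.approx(tau[0], rel=1e-12)

    def test_wss_prox_rises_with_severity(self):
        values = []
        for sev in (0.0, 40.0, 70.0, 85.0):
            les = Lesion("LAD", 30, 45, severity=sev)
            _, res = solve_tube(lesions=[les])
            values.append(wss_prox(res, les))
        assert all(b > a for a, b in zip(values, values[1:]))
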