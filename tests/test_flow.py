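"""Flow estimation: allometric scaling, Murray splitting, Windkessel, frame count."""

import numpy as np
import pytest

from corflow.flow import (
    ResistanceSpec,
    ScalingParams,
    allocate_main_arteries,
    frame_count_flow,
    mass_flow,
    murray_split,
    total_flow_allometric,
    windkessel_allocation,
)
from corflow.geometry import CoronaryTree, ValidationError

from conftest import random_tree, straight_branch


class TestAllometric:
    @pytest.mark.parametrize("mass,expected", [(1.0, 0.64), (16.0, 5.12)])
    def test_closed_form_points(self, mass, expected):
        assert total_flow_allometric(mass) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValidationError):
            total_flow_allometric(0.0)

    def test_strictly_increasing_and_concave(self):
        m = np.linspace(20, 200, 50)
        q = np.array([total_flow_allometric(x) for x in m])
        assert np.all(np.diff(q) > 0)
        assert np.all(np.diff(q, 2) < 0)

    def test_custom_params(self):
        assert total_flow_allometric(10.0, ScalingParams(a=2.0, b=1.0)) == pytest.approx(20.0)


class TestMainAllocation:
    def test_proportional_split(self):
        q = allocate_main_arteries(100.0, {"LAD": 0.5, "LCx": 0.3, "RCA": 0.2})
        assert q == {"LAD": 50.0, "LCx": 30.0, "RCA": 20.0}
        assert sum(q.values()) == pytest.approx(100.0, rel=1e-15)

    def test_zero_fraction_artery(self):
        q = allocate_main_arteries(10.0, {"LAD": 1.0, "LCx": 0.0})
        assert q["LCx"] == 0.0

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValidationError, match="sum to 1"):
            allocate_main_arteries(10.0, {"LAD": 0.5, "LCx": 0.4})


def tip_bifurcation_tree(r1: float, r2: float) -> CoronaryTree:
    root = straight_branch(branch_id="LAD", n_pts=5, length=40)
    c1 = straight_branch(branch_id="LAD.0", label="SIDE", parent_id="LAD", attach_index=4,
                         origin=(41, 1, 0), direction=(1, 1, 0), length=20, radius=r1, n_pts=4)
    c2 = straight_branch(branch_id="LAD.1", label="SIDE", parent_id="LAD", attach_index=4,
                         origin=(41, -1, 0), direction=(1, -1, 0), length=20, radius=r2, n_pts=4)
    return CoronaryTree("LAD", {b.branch_id: b for b in (root, c1, c2)})


def oracle_split(tree, q_root, exponent=3.0):
    """Independent recomputation: each segment's flow is the root flow times
    the product of split fractions of all bifurcations on the path upstream."""

    def split_events(branch):
        # (index, [(child_or_None, weight)]) per attachment on this branch
        events = []
        kids = {}
        for b in tree.branches.values():
            if b.parent_id == branch.branch_id:
                kids.setdefault(b.attach_index, []).append(b)
        for idx in sorted(kids):
            entries = [(c, c.radii[0] ** exponent) for c in sorted(kids[idx], key=lambda x: x.branch_id)]
            if idx < branch.n_points - 1:
                entries.append((None, branch.radii[idx] ** exponent))
            events.append((idx, entries))
        return events

    flows = {}

    def inflow_of(branch):
        if branch.parent_id is None:
            return q_root
        parent = tree.branches[branch.parent_id]
        q = inflow_of(parent)
        for idx, entries in split_events(parent):
            if idx > branch.attach_index:
                break
            total = sum(w for _, w in entries)
            if idx == branch.attach_index:
                mine = next(w for c, w in entries if c is not None and c.branch_id == branch.branch_id)
                return q * mine / total
            cont = next(w for c, w in entries if c is None)
            q = q * cont / total
        raise AssertionError("unreachable")

    for branch in tree.branches.values():
        q = inflow_of(branch)
        events = dict(split_events(branch))
        for i in range(branch.n_points - 1):
            if i in events:
                entries = events[i]
                total = sum(w for _, w in entries)
                cont = next(w for c, w in entries if c is None)
                q = q * cont / total
            flows[(branch.branch_id, i)] = q
    return flows


class TestMurray:
    def test_equal_daughters_split_evenly(self):
        fa = murray_split(tip_bifurcation_tree(1.0, 1.0), 10.0)
        assert fa.segment_flows[("LAD.0", 0)] == pytest.approx(5.0)
        assert fa.segment_flows[("LAD.1", 0)] == pytest.approx(5.0)

    def test_cubed_radius_ratio(self):
        fa = murray_split(tip_bifurcation_tree(2.0, 1.0), 9.0)
        assert fa.segment_flows[("LAD.0", 0)] == pytest.approx(8.0)
        assert fa.segment_flows[("LAD.1", 0)] == pytest.approx(1.0)

    def test_terminal_outflows_conserve_root_flow(self, rng):
        for _ in range(20):
            tree = random_tree(rng, n_branches=int(rng.integers(2, 10)))
            q0 = float(rng.uniform(5, 100))
            fa = murray_split(tree, q0)
            assert sum(fa.terminal_outflows.values()) == pytest.approx(q0, rel=1e-12)

    def test_matches_independent_recursion_oracle(self, rng):
        for _ in range(10):
            tree = random_tree(rng, n_branches=int(rng.integers(3, 9)))
            q0 = float(rng.uniform(5, 100))
            fa = murray_split(tree, q0)
            expected = oracle_split(tree, q0)
            assert set(fa.segment_flows) == set(expected)
            for key in expected:
                assert fa.segment_flows[key] == pytest.approx(expected[key], rel=1e-12)

    def test_configurable_exponent(self):
        fa = murray_split(tip_bifurcation_tree(2.0, 1.0), 9.0, exponent=7 / 3)
        w1, w2 = 2 ** (7 / 3), 1.0
        assert fa.segment_flows[("LAD.0", 0)] == pytest.approx(9.0 * w1 / (w1 + w2))

    def test_branch_flow_lookup_piecewise(self):
        tree = tip_bifurcation_tree(1.0, 1.0)
        fa = murray_split(tree, 10.0)
        root = tree.branches["LAD"]
        assert fa.branch_flow_at(root, [0.0, 20.0, 39.9])[2] == pytest.approx(10.0)


class TestWindkessel:
    def test_equal_resistances_equal_flows(self):
        spec = ResistanceSpec(resistances={"LAD": 2.0, "LCx": 2.0, "RCA": 2.0})
        q = windkessel_allocation(spec, 90.0)
        assert len(set(round(v, 9) for v in q.values())) == 1

    def test_inverse_proportionality(self):
        spec = ResistanceSpec(resistances={"LAD": 1.0, "LCx": 2.0, "RCA": 2.0})
        q = windkessel_allocation(spec, 90.0)
        total = sum(q.values())
        assert q["LAD"] / total == pytest.approx(0.5)
        assert q["LCx"] / total == pytest.approx(0.25)

    def test_tcri_scales_flows_but_not_fractions(self):
        base = {"LAD": 1.5, "LCx": 3.0, "RCA": 4.0}
        q1 = windkessel_allocation(ResistanceSpec(resistances=base, tcri=0.24), 90.0)
        q2 = windkessel_allocation(ResistanceSpec(resistances=base, tcri=0.12), 90.0)
        for lab in base:
            assert q2[lab] == pytest.approx(2 * q1[lab])
        t1, t2 = sum(q1.values()), sum(q2.values())
        for lab in base:
            assert q1[lab] / t1 == pytest.approx(q2[lab] / t2)

    def test_uniform_resistance_scaling_preserves_fractions(self):
        base = {"LAD": 1.5, "LCx": 3.0, "RCA": 4.0}
        q1 = windkessel_allocation(ResistanceSpec(resistances=base), 90.0)
        q2 = windkessel_allocation(
            ResistanceSpec(resistances={k: 3 * v for k, v in base.items()}), 90.0
        )
        t1, t2 = sum(q1.values()), sum(q2.values())
        for lab in base:
            assert q1[lab] / t1 == pytest.approx(q2[lab] / t2)

    def test_nonpositive_driving_pressure_rejected(self):
        spec = ResistanceSpec(venous_pressure_mmhg=10.0)
        with pytest.raises(ValidationError):
            windkessel_allocation(spec, 10.0)


class TestFrameCount:
    def test_one_second_transit(self):
        _, v = frame_count_flow(15, length_mm=100.0, area_mm2=10.0)
        assert v == pytest.approx(100.0)

    def test_mass_flow_hand_calculation(self):
        # v = 100 mm/s = 0.1 m/s; A = 10 mm^2 = 1e-5 m^2; rho = 1060 kg/m^3
        mdot, _ = frame_count_flow(15, length_mm=100.0, area_mm2=10.0)
        assert mdot == pytest.approx(1.06e-3, rel=1e-12)

    def test_doubling_frames_halves_velocity_and_flow(self):
        m1, v1 = frame_count_flow(10, length_mm=80.0, area_mm2=7.0)
        m2, v2 = frame_count_flow(20, length_mm=80.0, area_mm2=7.0)
        assert v2 == pytest.approx(v1 / 2) and m2 == pytest.approx(m1 / 2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            frame_count_flow(0, length_mm=10, area_mm2=1)
        with pytest.raises(ValidationError):
            frame_count_flow(5, length_mm=-1, area_mm2=1)


class TestMassFlow:
    def test_sixty_ml_per_min(self):
        # 60 ml/min = 1e-6 m^3/s -> x 1060 kg/m^3 = 1.06e-3 kg/s
        assert mass_flow(60.0) == pytest.approx(1.06e-3, rel=1e-12)

    def test_zero_and_linearity(self):
        assert mass_flow(0.0) == 0.0
        assert mass_flow(120.0) == pytest.approx(2 * mass_flow(60.0))
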