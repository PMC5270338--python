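"""Decentralized load passing: target sets, transfer caps, conservation, descent."""

import numpy as np
import pytest

from taskdilemma import (
    ContractViolationError,
    apply_passes,
    balance_loads,
    complete_topology,
    compute_passes,
    line_topology,
    reservoir_exchange,
    select_targets,
    water_filling,
)


class TestSelectTargets:
    def test_empty_when_all_gains_equal(self):
        top = complete_topology(3)
        assert select_targets(1, top, [1.0, 1.0, 1.0]) == frozenset()

    def test_tie_at_the_max_selects_both(self):
        top = complete_topology(4)
        assert select_targets(1, top, [1.5, 2.5, 2.5, 1.0]) == frozenset({2, 3})

    def test_single_better_neighbour(self):
        top = line_topology(3)
        assert select_targets(1, top, [1.0, 2.0, 5.0]) == frozenset({2})  # 3 not a neighbour

    def test_larger_but_not_max_neighbour_excluded(self):
        top = complete_topology(3)
        # neighbour 2 has a larger gain than 1 but is not the neighbourhood max
        assert select_targets(1, top, [1.0, 2.0, 3.0]) == frozenset({3})


class TestComputePasses:
    def test_all_equal_gains_give_empty_plan(self):
        top = complete_topology(3)
        plan = compute_passes([0.3, 0.3, 0.4], [1.0, 1.0, 1.0], [1.0, 1.0, 1.0], top, 0.5)
        assert plan.is_empty()

    def test_two_node_worked_example(self):
        # donor 2 (g = 0.25) passes to 1 (g = 3): theta-rate cap binds
        top = line_topology(2)
        b, c, theta = np.array([3.0, 2.25]), np.array([3.0, 2.0]), 0.005
        p = np.array([0.0, 1.0])
        g = b - c * p
        plan = compute_passes(p, g, c, top, theta)
        expected = theta * (3.0 - 0.25) / 3.0  # min(1, 2.75/5, 0.005*2.75/3)
        assert plan.as_dict() == {(1, 2): pytest.approx(expected)}
        # algorithm constraints: budget, no overshoot, theta-rate reduction
        L = plan.transfers[1, 0]
        assert L <= p[1]
        g1_after = b[0] - c[0] * (p[0] + L)
        g2_after = b[1] - c[1] * (p[1] - L)
        assert g2_after <= g1_after + 1e-12
        assert g1_after <= g[0] - theta * (g[0] - g[1]) + 1e-12

    def test_empty_handed_donor_passes_nothing(self):
        # node 1 has the lower gain (it is the donor) but holds no load
        top = line_topology(2)
        plan = compute_passes([0.0, 1.0], [1.0, 3.0], [1.0, 1.0], top, 0.5)
        assert plan.is_empty()

    def test_equalization_cap_prevents_overshoot(self):
        # theta = 1 with ample donor budget: transfer lands exactly on the
        # pairwise equal-gain point, never beyond
        top = line_topology(2)
        b, c = np.array([5.0, 2.0]), np.array([1.0, 1.0])
        p = np.array([0.0, 3.0])
        g = b - c * p
        plan = compute_passes(p, g, c, top, 1.0)
        L = plan.transfers[1, 0]
        assert L == pytest.approx(3.0)
        assert b[0] - c[0] * (p[0] + L) == pytest.approx(b[1] - c[1] * (p[1] - L))

    def test_tied_targets_split_donor_budget(self):
        top = complete_topology(3)
        b = np.array([1.0, 4.0, 4.0])
        c = np.array([1.0, 1.0, 1.0])
        p = np.array([0.001, 0.0, 0.0])  # tiny budget: the share cap binds
        g = b - c * p
        plan = compute_passes(p, g, c, top, 1.0)
        assert plan.transfers[0, 1] == pytest.approx(0.0005)
        assert plan.transfers[0, 2] == pytest.approx(0.0005)

    def test_zero_slope_target_is_a_contract_violation(self):
        top = line_topology(2)
        with pytest.raises(ContractViolationError):
            compute_passes([0.5, 0.5], [0.0, 1.0], [1.0, 0.0], top, 0.5)

    def test_negative_slope_rejected(self):
        top = line_topology(2)
        with pytest.raises(ContractViolationError):
            compute_passes([0.5, 0.5], [1.0, 2.0], [-1.0, 1.0], top, 0.5)

    def test_bisection_path_matches_linear_closed_form(self):
        top = line_topology(3)
        b = np.array([3.0, 2.25, 4.5])
        c = np.array([3.0, 2.0, 4.0])
        p = np.array([0.2, 0.5, 0.3])
        g = b - c * p
        linear = compute_passes(p, g, c, top, 0.3)
        fns = [lambda x, bi=bi, ci=ci: bi - ci * x for bi, ci in zip(b, c)]
        bisected = compute_passes(p, g, c, top, 0.3, gain_fns=fns)
        assert np.allclose(linear.transfers, bisected.transfers, atol=1e-10)


class TestApplyPasses:
    def test_empty_plan_is_identity(self):
        top = complete_topology(2)
        plan = compute_passes([0.5, 0.5], [1.0, 1.0], [1.0, 1.0], top, 0.5)
        assert np.array_equal(apply_passes([0.5, 0.5], plan), [0.5, 0.5])

    def test_single_transfer_conserves_total(self):
        top = line_topology(2)
        b, c = np.array([3.0, 2.25]), np.array([3.0, 2.0])
        p = np.array([0.0, 1.0])
        plan = compute_passes(p, b - c * p, c, top, 0.005)
        new_p = apply_passes(p, plan)
        expected = 0.005 * 2.75 / 3.0
        assert new_p[0] == pytest.approx(expected)
        assert new_p.sum() == pytest.approx(1.0, abs=1e-15)

    def test_rejects_plan_exceeding_budget(self):
        from taskdilemma import PassingPlan

        plan = PassingPlan(transfers=np.array([[0.0, 0.9], [0.0, 0.0]]), theta=0.5)
        with pytest.raises(ValueError):
            apply_passes([0.5, 0.5], plan)


class TestReservoir:
    def test_no_eligible_individuals_nothing_moves(self):
        p, res = reservoir_exchange([0.0, 0.0], 1.0, [0.0, 0.0], [0.0, 0.0], 0.5)
        assert np.array_equal(p, [0.0, 0.0]) and res == 1.0

    def test_empty_reservoir_is_noop(self):
        p, res = reservoir_exchange([0.4, 0.6], 0.0, [1.0, 1.0], [1.0, 1.0], 0.5)
        assert np.array_equal(p, [0.4, 0.6]) and res == 0.0

    def test_single_drawer_rate_cap(self):
        p, res = reservoir_exchange([0.0], 1.0, [3.0], [3.0], 0.005)
        assert p[0] == pytest.approx(0.005)
        assert res == pytest.approx(0.995)

    def test_share_cap_drains_reservoir_exactly(self):
        p, res = reservoir_exchange([0.0, 0.0], 1e-6, [3.0, 2.0], [1.0, 1.0], 1.0)
        assert p.sum() + res == pytest.approx(1e-6, abs=1e-18)
        assert res == pytest.approx(0.0, abs=1e-18)

    def test_conservation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = rng.uniform(0, 3, 4)
            c = rng.uniform(0.5, 2, 4)
            p0 = rng.uniform(0, 0.2, 4)
            res0 = float(rng.uniform(0, 1))
            p, res = reservoir_exchange(p0, res0, g, c, 0.3)
            assert p.sum() + res == pytest.approx(p0.sum() + res0, abs=1e-12)
            assert np.all(p >= 0) and res >= 0


from helpers import draw_interior_instance


class TestRoundIteration:
    @pytest.mark.parametrize("topology_factory", [line_topology, complete_topology])
    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_fixed_point_matches_water_filling(self, topology_factory, n):
        # equalization holds under the positive-maximizer assumption
        rng = np.random.default_rng(n)
        top = topology_factory(n)
        for _ in range(5):
            b, c, sol = draw_interior_instance(rng, n)
            p0 = rng.dirichlet(np.ones(n))
            result = balance_loads(p0, b, c, 1.0, top, theta=0.25)
            assert result.converged
            assert np.abs(result.p - sol.p_star).max() < 1e-6

    def test_water_filling_point_is_invariant(self):
        b = np.array([3.0, 2.25, 4.5])
        c = np.array([3.0, 2.0, 4.0])
        sol = water_filling(b, c, 1.0)
        top = line_topology(3)
        g = b - c * sol.p_star
        plan = compute_passes(sol.p_star, g, c, top, 0.5)
        assert plan.is_empty()

    def test_gain_gap_descent_and_conservation(self):
        rng = np.random.default_rng(3)
        top = line_topology(4)
        b, c, _ = draw_interior_instance(rng, 4)
        p = rng.dirichlet(np.ones(4))
        gaps = []
        for _ in range(200):
            g = b - c * p
            gaps.append(g.max() - g.min())
            plan = compute_passes(p, g, c, top, 0.1)
            p = apply_passes(p, plan)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(p >= 0)
        diffs = np.diff(gaps)
        assert np.all(diffs <= 1e-12)

    def test_gated_donors_shed_their_load(self):
        # an ineligible individual (gain identically 0) drains toward an
        # eligible neighbour and is never selected as a target
        top = line_topology(2)
        b = np.array([0.5, 2.0])   # individual 1 fails the b >= cP gate
        c = np.array([1.0, 1.0])
        result = balance_loads([0.8, 0.2], b, c, 1.0, top, theta=0.5)
        assert result.p[0] == pytest.approx(0.0, abs=1e-8)
        assert result.p[1] == pytest.approx(1.0, abs=1e-8)
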