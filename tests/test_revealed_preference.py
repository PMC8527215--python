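import itertools

import numpy as np
import pytest

from conftest import random_chooser_obs
from mavc.revealed_preference import (
    ObservationSet,
    ccei,
    ccei_breakpoint,
    consistency_report,
    cost_matrix,
    count_inconsistent_choices,
    garp_violations,
    houtman_maks,
    minimum_cost_index,
    money_pump_index,
    relations_at_efficiency,
)
from mavc.synthetic_data import ChooserSpec, simulate_chooser_block


def brute_force_houtman_maks(obs):
    """Exhaustive search over all subsets of observations (oracle)."""
    n = obs.n
    for k in range(n + 1):
        for drop in itertools.combinations(range(n), k):
            keep = np.setdiff1d(np.arange(n), drop)
            if keep.size == 0 or not garp_violations(obs.subset(keep)):
                return k
    return n


class TestCostMatrix:
    def test_diagonal_is_budget(self, rng):
        obs = random_chooser_obs(rng, 10)
        assert np.allclose(np.diag(cost_matrix(obs)), obs.budgets)

    def test_cross_costs(self, two_obs_cycle):
        C = cost_matrix(two_obs_cycle)
        assert C[0, 1] == pytest.approx(100.0 / 3.0)
        assert C[1, 0] == pytest.approx(100.0 / 3.0)

    def test_single_observation(self):
        obs = ObservationSet(
            bundles=np.array([[50.0, 50.0]]),
            prices=np.array([[1.0, 1.0]]),
            budgets=np.array([100.0]),
        )
        assert cost_matrix(obs).shape == (1, 1)
        assert cost_matrix(obs)[0, 0] == pytest.approx(100.0)

    def test_budget_exhaustion_enforced(self):
        with pytest.raises(ValueError, match="exhaust"):
            ObservationSet(
                bundles=np.array([[1.0, 1.0]]),
                prices=np.array([[1.0, 1.0]]),
                budgets=np.array([100.0]),
            )


class TestRelations:
    def test_zero_efficiency_empty(self, two_obs_cycle):
        rel = relations_at_efficiency(two_obs_cycle, 0.0)
        assert not rel.r_direct.any()

    def test_full_efficiency_two_cycle(self, two_obs_cycle):
        rel = relations_at_efficiency(two_obs_cycle, 1.0)
        assert rel.r_direct[0, 1] and rel.r_direct[1, 0]
        assert rel.p_direct[0, 1] and rel.p_direct[1, 0]

    def test_identical_bundles_unrelated(self):
        obs = ObservationSet(
            bundles=np.array([[50.0, 50.0], [50.0, 50.0]]),
            prices=np.array([[1.0, 1.0], [1.0, 1.0]]),
            budgets=np.array([100.0, 100.0]),
        )
        rel = relations_at_efficiency(obs, 1.0)
        assert not rel.r_direct[0, 1] and not rel.r_direct[1, 0]

    def test_closure_contains_direct_and_is_transitive(self, rng):
        obs = random_chooser_obs(rng, 12)
        rel = relations_at_efficiency(obs, 1.0)
        assert np.all(rel.r_closure >= rel.r_direct)
        composed = rel.r_closure @ rel.r_closure
        assert np.all(rel.r_closure[composed > 0])

    def test_efficiency_out_of_range(self, two_obs_cycle):
        with pytest.raises(ValueError):
            relations_at_efficiency(two_obs_cycle, 1.5)


class TestGarpAndCcei:
    def test_single_observation_consistent(self):
        obs = ObservationSet(
            bundles=np.array([[100.0, 0.0]]),
            prices=np.array([[1.0, 1.0]]),
            budgets=np.array([100.0]),
        )
        assert garp_violations(obs) == []
        assert ccei(obs) == 1.0

    def test_two_cycle_violations(self, two_obs_cycle):
        assert set(garp_violations(two_obs_cycle)) == {(0, 1), (1, 0)}
        assert count_inconsistent_choices(two_obs_cycle) == 2
        assert count_inconsistent_choices(two_obs_cycle, mode="pairs") == 2

    def test_two_cycle_ccei_is_one_third(self, two_obs_cycle):
        """Violations exist iff e > (100/3)/100, so the CCEI is exactly 1/3."""
        assert ccei(two_obs_cycle) == pytest.approx(1.0 / 3.0, abs=1e-6)
        assert ccei_breakpoint(two_obs_cycle) == pytest.approx(1.0 / 3.0)

    @pytest.mark.parametrize("kind,kwargs", [
        ("linear-utility", {"w": 0.3}),
        ("linear-utility", {"w": 0.7}),
        ("ces-utility", {"w": 0.5, "rho": 0.5}),
        ("ces-utility", {"w": 0.4, "rho": 0.8}),
    ])
    def test_maximizers_are_consistent(self, rng, kind, kwargs):
        """Deterministic monotone-utility choosers never violate GARP."""
        for _ in range(10):
            block = simulate_chooser_block(
                rng, ChooserSpec(kind=kind, **kwargs), t=float(rng.uniform(0, 30))
            )
            obs = ObservationSet.from_block(block)
            assert garp_violations(obs) == []
            assert ccei(obs) == 1.0

    def test_bisect_matches_breakpoint_oracle(self, rng):
        for _ in range(60):
            obs = random_chooser_obs(rng, int(rng.integers(3, 13)))
            assert ccei(obs, tol=1e-7) == pytest.approx(ccei_breakpoint(obs), abs=1e-6)

    def test_paper_literal_variant_not_larger(self, rng):
        """Keeping relations at full budgets can only find more violations."""
        for _ in range(30):
            obs = random_chooser_obs(rng, 8)
            assert ccei(obs, variant="paper-literal") <= ccei(obs) + 1e-6

    def test_reordering_invariance(self, rng):
        obs = random_chooser_obs(rng, 10)
        perm = rng.permutation(10)
        shuffled = ObservationSet(
            bundles=obs.bundles[perm], prices=obs.prices[perm], budgets=obs.budgets[perm]
        )
        assert ccei(shuffled) == pytest.approx(ccei(obs), abs=1e-6)
        assert count_inconsistent_choices(shuffled) == count_inconsistent_choices(obs)

    def test_joint_rescaling_invariance(self, rng):
        """Scaling (p_i, m_i) jointly leaves all relations unchanged."""
        obs = random_chooser_obs(rng, 10)
        scale = rng.uniform(0.5, 2.0, size=10)
        scaled = ObservationSet(
            bundles=obs.bundles,
            prices=obs.prices * scale[:, None],
            budgets=obs.budgets * scale,
        )
        assert ccei(scaled) == pytest.approx(ccei(obs), abs=1e-6)
        assert garp_violations(scaled) == garp_violations(obs)


class TestHoutmanMaks:
    def test_consistent_data(self, rng):
        block = simulate_chooser_block(rng, ChooserSpec(kind="linear-utility", w=0.5), t=1.0)
        obs = ObservationSet.from_block(block)
        assert houtman_maks(obs) == (0, 0.0, True)

    def test_two_cycle(self, two_obs_cycle):
        removed, fraction, exact = houtman_maks(two_obs_cycle)
        assert (removed, fraction, exact) == (1, 0.5, True)

    def test_matches_brute_force(self, rng):
        for _ in range(25):
            obs = random_chooser_obs(rng, int(rng.integers(4, 9)))
            res = houtman_maks(obs)
            assert res.exact
            assert res.removed == brute_force_houtman_maks(obs)


class TestMoneyPump:
    def test_consistent_data_zero(self, rng):
        block = simulate_chooser_block(rng, ChooserSpec(kind="linear-utility", w=0.4), t=1.0)
        assert money_pump_index(ObservationSet.from_block(block)) == 0.0

    def test_two_cycle_value(self, two_obs_cycle):
        """Single 2-cycle: extractable fraction = 2*(100 - 100/3)/200 = 2/3."""
        assert money_pump_index(two_obs_cycle) == pytest.approx(2.0 / 3.0)

    def test_bounded_on_random_data(self, rng):
        for _ in range(20):
            obs = random_chooser_obs(rng, 8)
            assert 0.0 <= money_pump_index(obs) <= 1.0


class TestMinimumCost:
    def test_consistent_data_zero(self, rng):
        block = simulate_chooser_block(rng, ChooserSpec(kind="linear-utility", w=0.6), t=1.0)
        assert minimum_cost_index(ObservationSet.from_block(block)) == 0.0

    def test_two_cycle_value(self, two_obs_cycle):
        """Remove one of two symmetric weight-2/3 edges; normalize by n=2."""
        assert minimum_cost_index(two_obs_cycle) == pytest.approx(1.0 / 3.0)

    def test_exact_not_above_greedy_edge_costs(self, rng):
        """The branch-and-bound result never exceeds a feasible removal cost."""
        for _ in range(10):
            obs = random_chooser_obs(rng, 7)
            mci = minimum_cost_index(obs)
            viols = garp_violations(obs)
            if not viols:
                assert mci == 0.0
            else:
                assert 0.0 < mci <= 1.0


class TestConsistencyReport:
    def test_consistent_block_all_zero(self, rng):
        block = simulate_chooser_block(rng, ChooserSpec(kind="linear-utility", w=0.5), t=2.0)
        rep = consistency_report(block)
        assert rep.ccei == 1.0
        assert rep.n_violating_pairs == 0
        assert rep.n_inconsistent_choices == 0
        assert rep.hmi_removed == 0 and rep.mpi == 0.0 and rep.mci == 0.0

    def test_matches_individual_operations(self, rng):
        block = simulate_chooser_block(rng, ChooserSpec(kind="random"), t=2.0, n_trials=8)
        obs = ObservationSet.from_block(block)
        rep = consistency_report(block)
        assert rep.ccei == pytest.approx(ccei(obs))
        assert rep.n_violating_pairs == len(garp_violations(obs))
        assert rep.hmi_removed == houtman_maks(obs).removed
        assert rep.mpi == pytest.approx(money_pump_index(obs))
        assert rep.mci == pytest.approx(minimum_cost_index(obs))

    def test_missing_choice_rejected(self, rng):
        from mavc.core_task import generate_block

        block = generate_block(rng, 1, t=1.0)
        with pytest.raises(ValueError):
            consistency_report(block)
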