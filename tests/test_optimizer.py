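import numpy as np
import pytest

from efmcost import (
    ConstraintSet,
    KineticModel,
    NumericalError,
    OptimizeOptions,
    ReactionKinetics,
    SaturationSpec,
    ValidationError,
    analyze_active_sets,
    brute_force_optimize,
    enumerate_lp_vertices,
    optimize_growth,
    solve_inner_lp,
    steady_state_for_enzymes,
    verify_extremum_principle,
)
from efmcost.optimizer import inner_objective
from efmcost.synth import GeneratorConfig, generate_instance


class TestInnerLP:
    def test_single_column_bound_by_larger_cost(self):
        res = solve_inner_lp(np.array([[0.5], [1.0]]))
        np.testing.assert_allclose(res.lambdas, [1.0])
        assert res.objective == pytest.approx(1.0)
        assert res.basis_support == {0}

    def test_both_pools_tight_mixture(self):
        res = solve_inner_lp(np.array([[1.0, 0.2], [0.2, 1.0]]))
        np.testing.assert_allclose(res.lambdas, [5 / 6, 5 / 6], atol=1e-9)
        assert res.objective == pytest.approx(5 / 3)

    def test_dominated_column_left_out(self):
        res = solve_inner_lp(np.array([[0.4, 0.3], [0.9, 0.8]]))
        np.testing.assert_allclose(res.lambdas, [0.0, 1.25], atol=1e-9)
        assert res.basis_support == {1}
        # first pool is slack: 0.3 * 1.25 < 1
        A, z = res.lp_matrix
        assert np.max(A @ res.lambdas - z) <= 1e-9

    def test_cost_free_column_rejected(self):
        with pytest.raises(ValidationError, match="cost-free"):
            solve_inner_lp(np.array([[0.5, 0.0], [1.0, 0.0]]))

    @pytest.mark.parametrize("seed", range(8))
    def test_vertex_property_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            K = int(rng.integers(1, 4))
            M = int(rng.integers(1, 9))
            D = 10 ** rng.uniform(-1, 1, (K, M))
            res = solve_inner_lp(D)
            assert len(res.basis_support) <= K
            best, _ = enumerate_lp_vertices(D)
            assert res.objective == pytest.approx(best, abs=1e-9)
            # the fast value path agrees with the vertex solve
            assert inner_objective(D) == pytest.approx(best, abs=1e-9)


class TestOptimizeGrowth:
    def test_chain_matches_closed_form(self, chain_model):
        S = 2.0
        f_T = S / (1.0 + S)
        f_2 = 1e3 / (1.0 + 1e3)  # x_A at its upper bound
        expected = 3.0 * f_T * 2.0 * f_2 / (3.0 * f_T + 2.0 * f_2)
        res = optimize_growth(
            chain_model, {"S": S}, OptimizeOptions(n_starts=6, seed=0)
        )
        assert res.objective == pytest.approx(expected, rel=1e-6)
        # enzyme split is proportional to demands and saturates the pool
        assert np.sum(res.enzyme_profile) == pytest.approx(1.0, rel=1e-9)

    def test_uniform_pool_shrink_scales_objective_exactly(self, chain_model):
        from efmcost import perturb_pool_bounds

        res = optimize_growth(chain_model, {"S": 2.0}, OptimizeOptions(n_starts=4, seed=1))
        shrunk = perturb_pool_bounds(chain_model, [0.35])
        res2 = optimize_growth(shrunk, {"S": 2.0}, OptimizeOptions(n_starts=4, seed=1))
        assert res2.objective == pytest.approx(0.35 * res.objective, rel=1e-12)

    def test_overflow_high_glucose_activates_both(self, overflow_model):
        res = optimize_growth(
            overflow_model,
            {"glucose_ext": 8.0, "acetate_ext": 1.0},
            OptimizeOptions(n_starts=6, seed=0),
        )
        assert len(res.active_efms) == 2
        assert set(res.active_constraints) == {"cytosol", "membrane"}

    def test_missing_external_concentration_errors(self, overflow_model):
        with pytest.raises(ValidationError, match="external"):
            optimize_growth(overflow_model, {"glucose_ext": 1.0})

    def test_monotone_in_substrate(self, overflow_model):
        values = []
        for s in (0.1, 0.5, 2.0, 8.0):
            res = optimize_growth(
                overflow_model,
                {"glucose_ext": s, "acetate_ext": 1.0},
                OptimizeOptions(n_starts=4, seed=0),
            )
            values.append(res.objective)
        assert all(b > a for a, b in zip(values, values[1:]))


class TestSteadyStateOracle:
    def test_chain_fixed_point_matches_analytics(self, chain_model):
        e = np.array([0.3, 0.7])
        state, flag = steady_state_for_enzymes(chain_model, e, {"S": 2.0})
        assert flag == "converged"
        # e1 k1 fT = e2 k2 xA/(1+xA) with fT = 2/3: xA = 0.75
        assert state["A"] == pytest.approx(0.75, rel=1e-5)

    def test_demand_exceeding_capacity_diverges(self, chain_model):
        e = np.array([0.9, 0.1])  # production 1.8 > capacity 0.2
        _, flag = steady_state_for_enzymes(chain_model, e, {"S": 2.0})
        assert flag == "diverged"

    def test_zero_enzymes_is_steady(self, chain_model):
        state, flag = steady_state_for_enzymes(chain_model, np.zeros(2), {"S": 2.0})
        assert flag == "converged"

    def test_negative_enzymes_rejected(self, chain_model):
        with pytest.raises(ValidationError):
            steady_state_for_enzymes(chain_model, np.array([-1.0, 1.0]), {"S": 2.0})


class TestBruteForce:
    def test_chain_matches_lp_within_two_percent(self, chain_model):
        lp = optimize_growth(chain_model, {"S": 2.0}, OptimizeOptions(n_starts=6, seed=0))
        bf = brute_force_optimize(chain_model, {"S": 2.0}, n_random=60, seed=1)
        assert bf.objective == pytest.approx(lp.objective, rel=0.02)
        assert bf.objective <= lp.objective * (1 + 1e-6)

    def test_single_efm_allocation_proportional_to_demands(self, chain_model):
        from efmcost import enumerate_efms, enzyme_demand

        bf = brute_force_optimize(chain_model, {"S": 2.0}, n_random=60, seed=1)
        efm = enumerate_efms(chain_model.network)[0]
        demand = enzyme_demand(
            efm,
            {"S": 2.0, "A": bf.x_internal["A"]},
            chain_model,
        )
        ratio = bf.enzyme_profile / demand
        assert ratio[0] == pytest.approx(ratio[1], rel=0.05)

    def test_size_guard(self, overflow_model):
        big = generate_instance(GeneratorConfig(seed=0, n_reactions=8))
        with pytest.raises(ValidationError, match="r <= 6"):
            brute_force_optimize(big, {m: 1.0 for m in big.network.external_metabolite_ids})


class TestActiveSets:
    def test_single_pool_counts(self, chain_model):
        res = optimize_growth(chain_model, {"S": 2.0}, OptimizeOptions(n_starts=4, seed=0))
        n_efms, n_constraints, n_collapsed = analyze_active_sets(res)
        assert (n_efms, n_constraints, n_collapsed) == (1, 1, 1)
        ok, report = verify_extremum_principle(res)
        assert ok and report["holds"]

    def test_overflow_post_switch_counts(self, overflow_model):
        res = optimize_growth(
            overflow_model,
            {"glucose_ext": 8.0, "acetate_ext": 1.0},
            OptimizeOptions(n_starts=6, seed=0),
        )
        n_efms, n_constraints, n_collapsed = analyze_active_sets(res)
        assert (n_efms, n_constraints, n_collapsed) == (2, 2, 2)
        ok, _ = verify_extremum_principle(res)
        assert ok

    def test_equivalent_efms_collapse(self, diamond_network):
        # both routes cost-identical: only the shared objective enzyme pooled
        kin = {
            rid: ReactionKinetics(kcat=2.0, saturation=SaturationSpec())
            for rid in diamond_network.reaction_ids
        }
        model = KineticModel(
            network=diamond_network,
            kinetics=kin,
            constraints=ConstraintSet(np.array([[1.0, 1.0, 1.0]]), np.array([1.0])),
        )
        res = optimize_growth(model, {"S": 1.0}, OptimizeOptions(n_starts=2, seed=0))
        _, _, n_collapsed = analyze_active_sets(res)
        n_active = len(res.active_efms)
        assert n_collapsed <= n_active
        ok, _ = verify_extremum_principle(res)
        assert ok
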