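import numpy as np
import pandas as pd
import pytest

from efmcost import (
    OptimizeOptions,
    SweepTable,
    ValidationError,
    build_overflow_model,
    detect_critical_point,
    enumerate_efms,
    enzyme_demand,
    fit_proportional_breakpoint,
    optimize_growth,
    perturb_catalytic_rates,
    perturb_pool_bounds,
    sweep_external_substrate,
)
from efmcost.casestudies import LACTIS_SWEEP_GRID, OVERFLOW_SWEEP_GRID


@pytest.fixture(scope="module")
def overflow_sweep(overflow_model):
    return sweep_external_substrate(
        overflow_model,
        OVERFLOW_SWEEP_GRID,
        options=OptimizeOptions(n_starts=4, seed=1),
    )


class TestPackagedModels:
    def test_overflow_pool_bounds(self, overflow_model):
        assert dict(
            zip(overflow_model.constraints.pool_ids, overflow_model.constraints.bounds)
        ) == {"cytosol": 1.0, "membrane": 0.3}

    def test_overflow_two_objective_efms(self, overflow_model):
        efms = enumerate_efms(overflow_model.network)
        assert sum(e.has_objective for e in efms) == 2

    def test_overflow_yields(self, overflow_model):
        # respiration: 1 intermediate per biomass; overflow: 2 per biomass
        efms = {tuple(sorted(e.support)): e for e in enumerate_efms(overflow_model.network)}
        resp = efms[(0, 1, 3)]
        ovf = efms[(0, 2, 3)]
        assert resp.values[0] == pytest.approx(1.0)
        assert ovf.values[0] == pytest.approx(2.0)

    def test_lactis_two_pathway_efms(self, lactis_model):
        efms = enumerate_efms(lactis_model.network)
        assert sum(e.has_objective for e in efms) == 2


class TestOverflowSweep:
    def test_growth_nondecreasing(self, overflow_sweep):
        mu = overflow_sweep.frame["mu"].to_numpy()
        assert np.all(np.diff(mu) >= -1e-9)

    def test_low_substrate_pure_respiration_membrane_limited(self, overflow_sweep):
        row = overflow_sweep.frame.iloc[0]
        assert row["lambda_efm_0+1+3"] > 0
        assert row["lambda_efm_0+2+3"] == pytest.approx(0.0, abs=1e-9)
        assert row["active_constraints"] == "membrane"

    def test_high_substrate_mixture_both_pools(self, overflow_sweep):
        row = overflow_sweep.frame.iloc[-1]
        assert row["lambda_efm_0+1+3"] > 0 and row["lambda_efm_0+2+3"] > 0
        assert set(row["active_constraints"].split("+")) == {"cytosol", "membrane"}

    def test_unique_critical_point(self, overflow_sweep):
        critical = detect_critical_point(overflow_sweep)
        assert critical is not None
        lam2 = overflow_sweep.frame["lambda_efm_0+2+3"].to_numpy()
        grid = overflow_sweep.frame["substrate"].to_numpy()
        # zero strictly below, positive at and above: a single crossing
        assert np.all(lam2[grid < critical] <= 1e-9)
        assert np.all(lam2[grid >= critical] > 1e-9)

    def test_respiration_cost_vector_crosses_diagonal(self, overflow_sweep):
        # membrane-heavy (above diagonal) at low glucose, cytosol-heavy below
        first = overflow_sweep.results[0].cost_matrix
        last = overflow_sweep.results[-1].cost_matrix
        resp = first.efm_ids.index("efm_0+1+3")
        assert first.D[1, resp] > first.D[0, resp]
        assert last.D[1, resp] < last.D[0, resp]

    def test_detect_critical_point_no_second_efm(self):
        frame = pd.DataFrame(
            {
                "substrate": [1.0, 2.0, 3.0, 4.0],
                "mu": [0.1, 0.2, 0.3, 0.4],
                "lambda_a": [0.1, 0.2, 0.3, 0.4],
                "lambda_b": [0.0, 0.0, 0.0, 0.0],
                "uptake_a": [0.1, 0.2, 0.3, 0.4],
                "uptake_b": [0.0, 0.0, 0.0, 0.0],
            }
        )
        sweep = SweepTable(substrate_id="S", efm_ids=("a", "b"), frame=frame)
        assert detect_critical_point(sweep) is None

    def test_detect_critical_point_synthetic_row(self):
        lam_b = [0.0, 0.0, 0.0, 0.0, 0.2, 0.4]
        frame = pd.DataFrame(
            {
                "substrate": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "mu": np.linspace(0.1, 0.6, 6),
                "lambda_a": [0.5] * 6,
                "lambda_b": lam_b,
                "uptake_a": [0.5] * 6,
                "uptake_b": lam_b,
            }
        )
        sweep = SweepTable(substrate_id="S", efm_ids=("a", "b"), frame=frame)
        assert detect_critical_point(sweep) == pytest.approx(5.0)

    def test_unsorted_grid_rejected(self, overflow_model):
        with pytest.raises(ValidationError, match="ascending"):
            sweep_external_substrate(overflow_model, [2.0, 1.0])


class TestLactisSweep:
    def test_fraction_crossover_with_stable_enzymes(self, lactis_model):
        sweep = sweep_external_substrate(
            lactis_model,
            LACTIS_SWEEP_GRID,
            options=OptimizeOptions(n_starts=6, seed=1),
        )
        frame = sweep.frame
        uptake = frame[list(sweep.uptake_columns())].to_numpy()
        frac_mixed_acid = uptake[:, 0] / uptake.sum(axis=1)
        assert frac_mixed_acid[0] > 0.5  # low substrate: mixed acid dominates
        assert frac_mixed_acid[-1] < 0.5  # high substrate: homolactic dominates
        E = np.array([r.enzyme_profile for r in sweep.results])
        variation = (E.max(axis=0) - E.min(axis=0)) / E.max(axis=0)
        assert float(variation.max()) < 0.20


class TestPerturbations:
    def test_identity_factors(self, overflow_model):
        out = perturb_pool_bounds(overflow_model, [1.0, 1.0])
        np.testing.assert_array_equal(out.constraints.bounds, overflow_model.constraints.bounds)
        out = perturb_catalytic_rates(overflow_model, {"respiration": 1.0})
        assert out.kinetics["respiration"].kcat == overflow_model.kinetics["respiration"].kcat

    def test_nonpositive_factors_rejected(self, overflow_model):
        with pytest.raises(ValidationError):
            perturb_pool_bounds(overflow_model, [0.5, 0.0])
        with pytest.raises(ValidationError):
            perturb_catalytic_rates(overflow_model, {"respiration": -2.0})

    def test_halving_kcat_doubles_demand(self, overflow_model):
        slow = perturb_catalytic_rates(overflow_model, {"respiration": 0.5})
        efm = next(
            e
            for e in enumerate_efms(overflow_model.network)
            if e.has_objective and 1 in e.support
        )
        x = {"glucose_ext": 1.0, "acetate_ext": 1.0, "intermediate": 1.0, "precursor": 1.0}
        e_fast = enzyme_demand(efm, x, overflow_model)
        e_slow = enzyme_demand(efm, x, slow)
        assert e_slow[1] == pytest.approx(2 * e_fast[1])
        np.testing.assert_allclose(np.delete(e_slow, 1), np.delete(e_fast, 1))

    def test_uniform_kcat_factor_equals_pool_shrink(self, overflow_model):
        xe = {"glucose_ext": 3.0, "acetate_ext": 1.0}
        opts = OptimizeOptions(n_starts=4, seed=2)
        slow = perturb_catalytic_rates(
            overflow_model, {rid: 0.6 for rid in overflow_model.network.reaction_ids}
        )
        shrunk = perturb_pool_bounds(overflow_model, [0.6, 0.6])
        res_slow = optimize_growth(slow, xe, opts)
        res_shrunk = optimize_growth(shrunk, xe, opts)
        assert res_slow.objective == pytest.approx(res_shrunk.objective, rel=1e-9)


class TestProportionalityDiagnostic:
    def test_exactly_proportional_has_no_breakpoint(self):
        mu = np.linspace(0.1, 1.0, 8)
        fit = fit_proportional_breakpoint(mu, 2.0 * mu)
        assert fit.slope == pytest.approx(2.0)
        assert fit.critical_rate is None

    def test_two_segment_data_recovered(self):
        mu = np.array([0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0])
        q = np.where(mu <= 0.6, 3.0 * mu, 3.0 * 0.6 + 0.5 * (mu - 0.6))
        fit = fit_proportional_breakpoint(mu, q)
        assert fit.critical_rate == pytest.approx(0.6)
        assert fit.slope == pytest.approx(3.0)
        assert fit.second_slope == pytest.approx(0.5)
        assert fit.sse == pytest.approx(0.0, abs=1e-20)

    def test_negative_uptake_rejected(self):
        with pytest.raises(ValidationError):
            fit_proportional_breakpoint([0.1, 0.2, 0.3, 0.4], [1.0, -1.0, 1.0, 1.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError, match="4"):
            fit_proportional_breakpoint([0.1, 0.2, 0.3], [1.0, 2.0, 3.0])
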