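import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from efmcost import (
    EFM,
    ConstraintSet,
    InfeasibleStateError,
    KineticModel,
    ReactionKinetics,
    SaturationSpec,
    ValidationError,
    constraint_usage,
    enzyme_demand,
    normalize_to_objective,
    reaction_rate,
)
from efmcost.kinetics import register_saturation_kind

concentrations = st.floats(
    min_value=0.0, max_value=1e6, allow_nan=False, allow_infinity=False
)


class TestSaturation:
    def test_constant_rate_is_product(self):
        rk = ReactionKinetics(kcat=3.0, saturation=SaturationSpec(kind="constant"))
        assert reaction_rate(rk, 2.0, {}) == pytest.approx(6.0)

    def test_mm_half_saturation(self):
        rk = ReactionKinetics(
            kcat=1.0,
            saturation=SaturationSpec(
                kind="michaelis_menten", substrate_ids=("s",), Km={"s": 2.0}
            ),
        )
        assert reaction_rate(rk, 1.0, {"s": 2.0}) == pytest.approx(0.5)

    def test_product_inhibition_quarter(self):
        spec = SaturationSpec(
            kind="mm_product_inhibition",
            substrate_ids=("s",),
            Km={"s": 1.0},
            inhibitor_id="p",
            Ki=2.0,
        )
        assert spec.evaluate({"s": 1.0, "p": 2.0}) == pytest.approx(0.25)

    def test_missing_metabolite_errors(self):
        spec = SaturationSpec(
            kind="michaelis_menten", substrate_ids=("s",), Km={"s": 1.0}
        )
        with pytest.raises(ValidationError, match="missing"):
            spec.evaluate({})

    @settings(max_examples=60, derandomize=True)
    @given(x=concentrations, inh=concentrations, km=st.floats(0.01, 100), ki=st.floats(0.01, 100))
    def test_saturation_bounded_in_unit_interval(self, x, inh, km, ki):
        for spec in (
            SaturationSpec(kind="constant"),
            SaturationSpec(kind="michaelis_menten", substrate_ids=("s",), Km={"s": km}),
            SaturationSpec(
                kind="mm_product_inhibition",
                substrate_ids=("s",),
                Km={"s": km},
                inhibitor_id="p",
                Ki=ki,
            ),
        ):
            f = spec.evaluate({"s": x, "p": inh})
            assert 0.0 <= f <= 1.0

    def test_rate_linear_in_enzyme(self):
        rk = ReactionKinetics(
            kcat=4.0,
            saturation=SaturationSpec(
                kind="michaelis_menten", substrate_ids=("s",), Km={"s": 1.0}
            ),
        )
        x = {"s": 3.0}
        assert reaction_rate(rk, 4.0, x) == pytest.approx(4 * reaction_rate(rk, 1.0, x))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError, match="unknown saturation kind"):
            SaturationSpec(kind="hill")

    def test_registered_custom_kind_accepted(self):
        register_saturation_kind("half", lambda spec, x: 0.5)
        assert SaturationSpec(kind="half").evaluate({}) == 0.5

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            ReactionKinetics(kcat=-1.0)
        with pytest.raises(ValidationError, match="Km"):
            SaturationSpec(kind="michaelis_menten", substrate_ids=("s",), Km={"s": -2.0})
        with pytest.raises(ValidationError, match="Ki"):
            SaturationSpec(
                kind="mm_product_inhibition", substrate_ids=("s",), Km={"s": 1.0}
            )


class TestEnzymeDemand:
    def test_demand_arithmetic(self, chain_model):
        # V_j = 2 at kcat = 4 and f = 0.5 needs e_j = 1
        rk = ReactionKinetics(
            kcat=4.0,
            saturation=SaturationSpec(
                kind="michaelis_menten", substrate_ids=("S",), Km={"S": 1.0}
            ),
        )
        e = 2.0 / (rk.kcat * rk.saturation.evaluate({"S": 1.0}))
        assert e == pytest.approx(1.0)

    def test_chain_demand_values(self, chain_network):
        # kcat = (10, 1), f = (0.5, 1) for the unit chain EFM -> e = (0.2, 1.0)
        kinetics = {
            "uptake": ReactionKinetics(
                kcat=10.0,
                saturation=SaturationSpec(
                    kind="michaelis_menten", substrate_ids=("S",), Km={"S": 1.0}
                ),
            ),
            "objective": ReactionKinetics(kcat=1.0, saturation=SaturationSpec()),
        }
        model = KineticModel(
            network=chain_network,
            kinetics=kinetics,
            constraints=ConstraintSet(np.array([[1.0, 1.0]]), np.array([1.0])),
        )
        efm = EFM(values=np.array([1.0, 1.0]), support={0, 1}, has_objective=True)
        e = enzyme_demand(efm, {"S": 1.0, "A": 1.0}, model)
        np.testing.assert_allclose(e, [0.2, 1.0])

    def test_doubling_saturation_halves_demand(self, chain_model):
        efm = EFM(values=np.array([1.0, 1.0]), support={0, 1}, has_objective=True)
        e_low = enzyme_demand(efm, {"S": 1.0, "A": 1.0}, chain_model)
        e_high = enzyme_demand(efm, {"S": 1e9, "A": 1.0}, chain_model)
        # f for uptake goes from 0.5 to ~1.0: demand halves
        assert e_high[0] == pytest.approx(e_low[0] / 2, rel=1e-6)

    def test_zero_saturation_is_infeasible(self, chain_model):
        efm = EFM(values=np.array([1.0, 1.0]), support={0, 1}, has_objective=True)
        with pytest.raises(InfeasibleStateError, match="infeasible"):
            enzyme_demand(efm, {"S": 0.0, "A": 1.0}, chain_model)

    def test_demand_invariant_under_prenormalization_scale(self, chain_network, chain_model):
        x = {"S": 2.0, "A": 3.0}
        scaled = EFM(values=np.array([5.0, 5.0]), support={0, 1}, has_objective=True)
        e1 = enzyme_demand(normalize_to_objective(scaled, chain_network), x, chain_model)
        unit = EFM(values=np.array([1.0, 1.0]), support={0, 1}, has_objective=True)
        np.testing.assert_allclose(e1, enzyme_demand(unit, x, chain_model))


class TestConstraints:
    def test_zero_enzymes_zero_usage(self):
        cs = ConstraintSet(np.array([[1.0, 1.0]]), np.array([1.0]))
        np.testing.assert_array_equal(constraint_usage(np.zeros(2), cs), [0.0])

    def test_one_hot_row_reads_single_enzyme(self):
        cs = ConstraintSet(np.array([[0.0, 1.0]]), np.array([1.0]))
        assert constraint_usage(np.array([9.0, 0.3]), cs)[0] == pytest.approx(0.3)

    def test_pooled_enzymes_sum(self):
        cs = ConstraintSet(np.array([[1.0, 1.0]]), np.array([1.0]))
        assert constraint_usage(np.array([0.3, 0.2]), cs)[0] == pytest.approx(0.5)

    def test_dimension_mismatch_errors(self):
        cs = ConstraintSet(np.array([[1.0, 1.0]]), np.array([1.0]))
        with pytest.raises(ValidationError):
            constraint_usage(np.ones(3), cs)

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValidationError, match="all-zero"):
            ConstraintSet(np.array([[0.0, 0.0]]), np.array([1.0]))

    def test_scaled_weights_fold_bounds(self):
        cs = ConstraintSet(np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([2.0, 0.5]))
        np.testing.assert_allclose(cs.scaled_weights, [[0.5, 0.0], [0.0, 2.0]])
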