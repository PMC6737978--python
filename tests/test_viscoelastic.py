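import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msicd.viscoelastic import (
    ViscoelasticModel,
    complex_modulus,
    dissipation_oracle,
    energy_per_cycle,
    frequency_response,
    relaxation_modulus,
    total_energy,
)

ONE_BRANCH = ViscoelasticModel(g_inst=2000, g_relaxed=1000, relax_times=(1.0,))
TWO_BRANCH = ViscoelasticModel(
    g_inst=2500, g_relaxed=500, relax_times=(0.1, 2.0), weights=(800.0, 1200.0)
)
ELASTIC = ViscoelasticModel(g_inst=1500, g_relaxed=1500, relax_times=(1.0,), weights=(0.0,))


class TestRelaxationModulus:
    def test_instantaneous_and_equilibrium_limits(self):
        assert relaxation_modulus(ONE_BRANCH, 0.0) == pytest.approx(2000.0)
        assert relaxation_modulus(ONE_BRANCH, 1e6) == pytest.approx(1000.0)

    def test_single_branch_closed_form(self):
        # 1000 + 1000*exp(-1) Pa
        assert relaxation_modulus(ONE_BRANCH, 1.0) == pytest.approx(
            1000.0 + 1000.0 * np.exp(-1.0)
        )

    def test_non_increasing(self):
        t = np.linspace(0, 20, 500)
        for m in (ONE_BRANCH, TWO_BRANCH):
            g = relaxation_modulus(m, t)
            assert np.all(np.diff(g) <= 1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            relaxation_modulus(ONE_BRANCH, -1.0)


class TestComplexModulus:
    def test_static_limit(self):
        m = complex_modulus(ONE_BRANCH, 0.0)
        assert m.g1 == pytest.approx(1000.0)
        assert m.g2 == 0.0
        assert m.delta == 0.0

    def test_glassy_limit(self):
        m = complex_modulus(ONE_BRANCH, 1e9)
        assert m.g1 == pytest.approx(2000.0, rel=1e-6)
        assert m.g2 == pytest.approx(0.0, abs=1e-3)

    def test_branch_peak_at_unit_omega_tau(self):
        m = complex_modulus(ONE_BRANCH, 1.0)  # omega*tau = 1
        assert m.g1 == pytest.approx(1500.0)
        assert m.g2 == pytest.approx(500.0)
        assert m.g_abs == pytest.approx(np.hypot(1500.0, 500.0))
        assert np.tan(m.delta) == pytest.approx(500.0 / 1500.0)

    def test_storage_modulus_non_decreasing_and_loss_non_negative(self):
        omegas = np.geomspace(1e-4, 1e4, 200)
        for model in (ONE_BRANCH, TWO_BRANCH):
            g1 = np.array([complex_modulus(model, w).g1 for w in omegas])
            g2 = np.array([complex_modulus(model, w).g2 for w in omegas])
            assert np.all(np.diff(g1) >= -1e-9)
            assert np.all(g2 >= 0)
            assert g2[0] < 1e-2 * g2.max() and g2[-1] < 1e-2 * g2.max()


class TestEnergyPerCycle:
    def test_zero_strain_gives_zero(self):
        assert energy_per_cycle(ONE_BRANCH, 1.0, 0.0) == 0.0

    def test_closed_form_value(self):
        # pi * 0.1^2 * g2 with g2 = 500 Pa at omega*tau = 1
        assert energy_per_cycle(ONE_BRANCH, 1.0, 0.1) == pytest.approx(
            np.pi * 0.01 * 500.0
        )

    def test_purely_elastic_model_dissipates_nothing(self):
        for omega in (0.1, 1.0, 100.0):
            assert energy_per_cycle(ELASTIC, omega, 0.1) == 0.0

    @pytest.mark.parametrize("model", [ONE_BRANCH, TWO_BRANCH], ids=["1br", "2br"])
    @pytest.mark.parametrize("omega", [0.05, 1.0, 6.28, 188.5])
    @pytest.mark.parametrize("eps0", [0.005, 0.065])
    def test_matches_cycle_integral_oracle(self, model, omega, eps0):
        closed = energy_per_cycle(model, omega, eps0)
        oracle = dissipation_oracle(model, omega, eps0, cycles=3)
        assert oracle == pytest.approx(closed, rel=1e-6)

    def test_oracle_quadratic_in_strain(self):
        w1 = dissipation_oracle(ONE_BRANCH, 2.0, 0.01)
        w2 = dissipation_oracle(ONE_BRANCH, 2.0, 0.02)
        assert w2 == pytest.approx(4.0 * w1, rel=1e-9)

    def test_oracle_elastic_model_near_zero(self):
        assert abs(dissipation_oracle(ELASTIC, 1.0, 0.1)) < 1e-10


class TestTotalEnergy:
    def test_zero_duration_gives_zero(self):
        assert total_energy(ONE_BRANCH, 30.0, 0.0, 0.02).w_total == 0.0

    @pytest.mark.parametrize("variant", ["loss-modulus", "paper-tan-delta"])
    @pytest.mark.parametrize("model", [ONE_BRANCH, TWO_BRANCH], ids=["1br", "2br"])
    def test_linear_in_time_quadratic_in_strain(self, variant, model):
        base = total_energy(model, 5.0, 100.0, 0.01, variant).w_total
        assert total_energy(model, 5.0, 200.0, 0.01, variant).w_total == pytest.approx(
            2 * base, rel=1e-12
        )
        assert total_energy(model, 5.0, 100.0, 0.02, variant).w_total == pytest.approx(
            4 * base, rel=1e-12
        )

    def test_known_value_at_branch_peak(self):
        # omega*tau = 1 at f = 30 Hz needs tau = 1/(60*pi); then g2 = 500 Pa
        # and W = pi * 0.02^2 * 500 * 30 * 300
        tau = 1.0 / (60.0 * np.pi)
        m = ViscoelasticModel(g_inst=2000, g_relaxed=1000, relax_times=(tau,))
        w = total_energy(m, 30.0, 300.0, 0.02).w_total
        assert w == pytest.approx(np.pi * 4e-4 * 500.0 * 9000.0, rel=1e-12)
        assert w == pytest.approx(5654.9, abs=0.1)

    def test_total_consistent_with_cycle_oracle(self):
        f, t, eps0 = 7.0, 50.0, 0.03
        per_cycle = dissipation_oracle(ONE_BRANCH, 2 * np.pi * f, eps0)
        assert total_energy(ONE_BRANCH, f, t, eps0).w_total == pytest.approx(
            per_cycle * f * t, rel=1e-6
        )

    def test_tan_delta_variant_exceeds_loss_modulus_variant(self):
        # tan(delta) >= sin(delta) always, with equality only at zero loss
        lm = total_energy(ONE_BRANCH, 1.0, 10.0, 0.02, "loss-modulus").w_total
        td = total_energy(ONE_BRANCH, 1.0, 10.0, 0.02, "paper-tan-delta").w_total
        assert td > lm

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            total_energy(ONE_BRANCH, 1.0, 1.0, 0.01, "bogus")


class TestFrequencyResponse:
    def test_single_branch_monotone_to_plateau(self):
        grid = np.geomspace(1e-3, 1000.0, 400)
        resp = frequency_response(ONE_BRANCH, grid)
        assert np.all(np.diff(resp.response) > 0)
        assert not resp.is_interior
        assert resp.f_at_max == grid[-1]
        assert resp.plateau_value == pytest.approx(1000.0 / (2 * np.pi))

    def test_plateau_reached_within_tenth_percent(self):
        tau = ONE_BRANCH.relax_times[0]
        resp = frequency_response(ONE_BRANCH, [10.0, 100.0, 1000.0 / tau])
        assert resp.response[-1] == pytest.approx(resp.plateau_value, rel=1e-3)

    def test_elastic_model_ties_break_to_lowest_frequency(self):
        resp = frequency_response(ELASTIC, [0.1, 1.0, 10.0])
        assert resp.f_at_max == 0.1
        assert not resp.is_interior

    def test_two_branch_curve_approaches_analytic_plateau(self):
        grid = np.geomspace(0.01, 5000.0, 300)
        resp = frequency_response(TWO_BRANCH, grid)
        limit = sum(
            w / (2 * np.pi * tau)
            for w, tau in zip(TWO_BRANCH.weights, TWO_BRANCH.relax_times)
        )
        assert resp.response[-1] == pytest.approx(limit, rel=1e-3)

    def test_bad_grids_rejected(self):
        with pytest.raises(ValueError):
            frequency_response(ONE_BRANCH, [1.0, 0.5, 2.0])
        with pytest.raises(ValueError):
            frequency_response(ONE_BRANCH, [-1.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            frequency_response(ONE_BRANCH, [1.0, 2.0])


@given(
    g_rel=st.floats(100.0, 2000.0),
    weight=st.floats(10.0, 3000.0),
    tau=st.floats(0.01, 10.0),
    omega=st.floats(0.01, 500.0),
    eps0=st.floats(0.001, 0.1),
)
@settings(max_examples=30, deadline=None)
def test_oracle_equivalence_property(g_rel, weight, tau, omega, eps0):
    """Closed-form per-cycle dissipation equals the stress x strain-rate integral."""
    m = ViscoelasticModel(
        g_inst=g_rel + weight, g_relaxed=g_rel, relax_times=(tau,), weights=(weight,)
    )
    closed = energy_per_cycle(m, omega, eps0)
    assert dissipation_oracle(m, omega, eps0) == pytest.approx(closed, rel=1e-6)


def test_invalid_model_parameters_rejected():
    with pytest.raises(ValueError):
        ViscoelasticModel(g_inst=500, g_relaxed=1000)
    with pytest.raises(ValueError):
        ViscoelasticModel(relax_times=(0.0,))
    with pytest.raises(ValueError):
        ViscoelasticModel(g_inst=2000, g_relaxed=1000, relax_times=(1.0,), weights=(1.0, 2.0))
    with pytest.raises(ValueError):
        ViscoelasticModel(g_inst=2000, g_relaxed=1000, relax_times=(1.0,), weights=(500.0,))
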