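"""Kinetic simulators versus closed forms and a fixed-step reference integrator."""

import numpy as np
import pytest

from synkin.aggregation_kinetics import (
    ElongationSetup,
    LipidNucleationModel,
    SecondaryNucleationModel,
    free_monomer,
    max_mass_rate_secondary,
    predict_relative_elongation_rate,
    predict_relative_lipid_rate,
    relative_max_rate_curve,
    simulate_lipid_induced,
    simulate_secondary_nucleation,
)
from synkin.equilibrium import CompetitiveLipidSystem, solve_competitive

SECONDARY = SecondaryNucleationModel(
    monomer_total=70.0,
    fibril_mass_0=0.07,
    fibril_number_0=1.4e-4,
    k_plus=10.0,
    k2=3.6e-8,
    n2=2.0,
)

LIPID = LipidNucleationModel(
    system=CompetitiveLipidSystem(70.0, 0.0, 100.0, 0.5, 0.24, 30.0),
    kn=1.0e-3,
    nc=1.0,
    k_plus=10.0,
)


def rk4_reference(model, t_end, n_steps):
    """Fixed-step RK4 reference integrator; returns (t, P, M, max dM/dt)."""

    def rhs(y):
        p, m = y
        mf = free_monomer(model.monomer_total + model.fibril_mass_0 - m,
                          model.as69_total, model.kd)
        return np.array([model.k2 * mf**model.n2 * m, 2.0 * model.k_plus * mf * p])

    dt = t_end / n_steps
    y = np.array([model.fibril_number_0, model.fibril_mass_0])
    max_rate = rhs(y)[1]
    traj = [y.copy()]
    for _ in range(n_steps):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * dt * k1)
        k3 = rhs(y + 0.5 * dt * k2)
        k4 = rhs(y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        traj.append(y.copy())
        max_rate = max(max_rate, rhs(y)[1])
    traj = np.array(traj)
    return np.linspace(0, t_end, n_steps + 1), traj[:, 0], traj[:, 1], max_rate


class TestElongationPrediction:
    def test_no_inhibitor_gives_unity(self):
        assert predict_relative_elongation_rate(ElongationSetup(30.0, 5.0, 1.0, 0.0)) == 1.0

    def test_tight_binding_full_sequestration(self):
        setup = ElongationSetup(30.0, 5.0, 1.0, 30.0, 1e-9)
        assert predict_relative_elongation_rate(setup) < 1e-4

    def test_equimolar_example_against_quadratic_root(self):
        setup = ElongationSetup(30.0, 5.0, 1.0, 30.0, 0.24)
        s = 30.0 + 30.0 + 0.24
        complex_ = (s - np.sqrt(s * s - 4 * 30.0 * 30.0)) / 2.0
        expected = (30.0 - complex_) / 30.0
        assert predict_relative_elongation_rate(setup) == pytest.approx(expected, rel=1e-10)
        assert expected == pytest.approx(0.0855, abs=2e-4)

    def test_prediction_is_free_monomer_fraction_pointwise(self):
        """Definitional identity: the curve IS the free-monomer fraction."""
        for a in np.linspace(0.0, 60.0, 13):
            setup = ElongationSetup(30.0, 5.0, 1.0, float(a), 0.24)
            assert predict_relative_elongation_rate(setup) == pytest.approx(
                free_monomer(30.0, float(a), 0.24) / 30.0, rel=1e-12
            )


class TestSecondaryNucleation:
    def test_initial_rate_closed_form_without_amplification(self):
        model = SecondaryNucleationModel(70.0, 5.0, 0.02, 10.0, 0.0, 2.0)
        assert max_mass_rate_secondary(model) == pytest.approx(
            2.0 * 10.0 * 70.0 * 0.02, rel=1e-12
        )

    def test_unseeded_without_amplification_stays_flat(self):
        model = SecondaryNucleationModel(70.0, 0.0, 0.0, 10.0, 0.0, 2.0)
        trace = simulate_secondary_nucleation(model, np.linspace(0, 40, 50))
        assert np.allclose(trace.fibril_mass, 0.0, atol=1e-10)

    def test_sigmoid_matches_reference_integrator(self):
        """LSODA trajectory and max rate vs fixed-step RK4 at high resolution."""
        t_end = 40.0
        t_ref, _, m_ref, rate_ref = rk4_reference(SECONDARY, t_end, 8000)
        trace = simulate_secondary_nucleation(SECONDARY, t_ref)
        err = np.max(np.abs(trace.fibril_mass - m_ref)) / m_ref.max()
        assert err < 1e-3
        assert max_mass_rate_secondary(SECONDARY) == pytest.approx(rate_ref, rel=1e-3)

    def test_total_protein_conserved_under_sequestration(self):
        model = SecondaryNucleationModel(70.0, 0.07, 1.4e-4, 10.0, 3.6e-8, 2.0, 7.0, 0.24)
        trace = simulate_secondary_nucleation(model, np.linspace(0, 60, 80))
        unaggregated = 70.0 + 0.07 - trace.fibril_mass
        for mt, mf in zip(unaggregated, trace.free_monomer):
            bound = 7.0 * mf / (0.24 + mf)
            assert mf + bound == pytest.approx(max(mt, 0.0), abs=1e-6 * 70.0)
        assert np.all(np.diff(trace.fibril_mass) >= -1e-9)
        assert trace.fibril_mass[-1] <= 70.07 + 1e-6

    def test_mass_monotone_and_bounded(self):
        trace = simulate_secondary_nucleation(SECONDARY, np.linspace(0, 40, 120))
        assert np.all(np.diff(trace.fibril_mass) >= -1e-10)
        assert np.all(trace.free_monomer >= 0)
        assert trace.fibril_mass.max() <= 70.07 * (1 + 1e-9)


@pytest.fixture(scope="module")
def matrix():
    orders = [1, 2, 3, 4, 5]
    grid = [0.0, 3.5, 7.0, 14.0]
    return orders, grid, relative_max_rate_curve(SECONDARY, grid, orders)


class TestRelativeMaxRate:

    def test_zero_inhibitor_column_is_unity(self, matrix):
        _, _, mat = matrix
        assert np.allclose(mat[:, 0], 1.0)

    def test_monotone_in_inhibitor_and_order(self, matrix):
        orders, grid, mat = matrix
        assert np.all(np.diff(mat, axis=1) <= 1e-9)  # down each row with as69
        assert np.all(np.diff(mat, axis=0) <= 1e-9)  # down the n2 = 1..5 family

    def test_sequestration_floor_at_high_order(self, matrix):
        """At 7 µM inhibitor vs 70 µM monomer the sequestration-only ratio
        exceeds the analytic early-time floor (m_free/m_tot)^(n2+1)."""
        orders, grid, mat = matrix
        mf = free_monomer(70.07, 7.0, 0.24)
        for i, n2 in enumerate(orders):
            floor = (mf / 70.07) ** (n2 + 1)
            assert mat[i, grid.index(7.0)] >= floor

    def test_substoichiometric_ratio_stays_above_half(self, matrix):
        """Monomer sequestration alone cannot produce the observed
        near-complete inhibition at a 1:10 inhibitor:monomer ratio: the
        predicted ratio stays above 0.5 at every order up to 5."""
        orders, grid, mat = matrix
        j = grid.index(7.0)
        assert np.all(mat[:, j] > 0.5)

    def test_order_zero_limited_by_elongation_only(self):
        """With n2 = 0 the nucleation flux is monomer-independent: the
        inhibition is set by the elongation monomer dependence alone, so
        the ratio lies between the early-time growth-rate bound
        (m_free/m_tot)^(3/2) and the pure elongation ratio m_free/m_tot."""
        mat = relative_max_rate_curve(SECONDARY, [0.0, 7.0], [0])
        x = free_monomer(70.07, 7.0, 0.24) / 70.07
        assert x**1.5 - 1e-3 <= mat[0, 1] <= x + 1e-3


class TestLipidInduced:
    def test_no_lipid_means_no_nucleation(self):
        model = LipidNucleationModel(
            CompetitiveLipidSystem(70.0, 0.0, 0.0, 0.5, 0.24, 30.0), 1e-3, 1.0, 10.0
        )
        trace = simulate_lipid_induced(model, np.linspace(0, 10, 30))
        assert np.allclose(trace.fibril_mass, 0.0, atol=1e-12)
        assert np.allclose(trace.fibril_number, 0.0, atol=1e-12)

    def test_no_nucleation_rate_means_flat(self):
        model = LipidNucleationModel(LIPID.system, 0.0, 1.0, 10.0)
        trace = simulate_lipid_induced(model, np.linspace(0, 10, 30))
        assert np.allclose(trace.fibril_mass, 0.0, atol=1e-12)

    def test_early_time_quadratic_law(self):
        """M(t) = kn * k+ * b0^nc * f0 * t^2 within 1% well before depletion."""
        spec0 = solve_competitive(LIPID.system)
        coeff = LIPID.kn * LIPID.k_plus * spec0.alpha_lipid_bound**LIPID.nc * spec0.alpha_free
        t_dep = np.sqrt(70.0 / coeff)  # depletion timescale
        t = np.linspace(0, 0.01 * t_dep, 30)
        trace = simulate_lipid_induced(LIPID, t, rtol=1e-10, atol=1e-14)
        expected = coeff * t[1:] ** 2
        assert np.allclose(trace.fibril_mass[1:], expected, rtol=0.01)

    def test_total_protein_conserved(self):
        sys_ = CompetitiveLipidSystem(70.0, 7.0, 100.0, 0.5, 0.24, 30.0)
        model = LipidNucleationModel(sys_, 1e-3, 1.0, 10.0)
        trace = simulate_lipid_induced(model, np.linspace(0, 8, 40))
        for mass, mf in zip(trace.fibril_mass, trace.free_monomer):
            spec = solve_competitive(
                CompetitiveLipidSystem(max(70.0 - mass, 0.0), 7.0, 100.0, 0.5, 0.24, 30.0)
            )
            total = spec.alpha_free + spec.alpha_lipid_bound + spec.alpha_as69_bound + mass
            assert total == pytest.approx(70.0, abs=1e-6 * 70.0)
            assert mf == pytest.approx(spec.alpha_free, abs=1e-6 * 70.0)


class TestRelativeLipidRate:
    def test_unity_at_zero_and_monotone(self):
        ratios = predict_relative_lipid_rate(LIPID, [0.0, 7.0, 35.0, 70.0])
        assert ratios[0] == 1.0
        assert np.all(np.diff(ratios) < 0)

    def test_non_binding_inhibitor_has_no_effect(self):
        model = LipidNucleationModel(
            CompetitiveLipidSystem(70.0, 0.0, 100.0, 0.5, 1e12, 30.0), 1e-3, 1.0, 10.0
        )
        ratios = predict_relative_lipid_rate(model, [0.0, 35.0, 70.0])
        assert np.allclose(ratios, 1.0, atol=1e-6)

    def test_large_excess_inhibitor_suppresses_fully(self):
        model = LipidNucleationModel(
            CompetitiveLipidSystem(20.0, 0.0, 600.0, 0.5, 0.5, 30.0), 1e-3, 1.0, 10.0
        )
        ratios = predict_relative_lipid_rate(model, [0.0, 2000.0])
        assert ratios[1] < 1e-3

    def test_ratio_matches_early_rate_of_simulated_traces(self):
        """The speciation-based ratio agrees with the ratio of simulated
        early-time quadratic coefficients."""
        as69 = 7.0
        t = np.linspace(0, 0.05, 20)
        base = simulate_lipid_induced(LIPID, t, rtol=1e-10, atol=1e-14)
        inhibited_model = LipidNucleationModel(
            CompetitiveLipidSystem(70.0, as69, 100.0, 0.5, 0.24, 30.0), 1e-3, 1.0, 10.0
        )
        inh = simulate_lipid_induced(inhibited_model, t, rtol=1e-10, atol=1e-14)
        sim_ratio = inh.fibril_mass[-1] / base.fibril_mass[-1]
        pred = predict_relative_lipid_rate(LIPID, [0.0, as69])[1]
        assert sim_ratio == pytest.approx(pred, rel=5e-3)
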