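"""Competitive-binding ODE simulation and the three-stage k_d estimator."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from compchip import (
    BiasTable,
    InductionCurve,
    KineticModel,
    build_bias_table,
    correct_bias,
    estimate_residence_time,
    fit_ideal,
    ideal_induction_solution,
    make_scaled_series,
    newton_refine,
    residence_time,
    simulate_occupancy,
)
from compchip.kinetics import dissociation_rate

LN2 = np.log(2.0)


def step_curve(rho: float) -> InductionCurve:
    """Effectively instantaneous induction saturating at rho."""
    return InductionCurve(rho_inf=rho, t_ind=1e-9, hill_n=4)


class TestSimulate:
    def test_equilibrium_ratio_equals_rho_inf(self, induction):
        for t_half in (1.0, 10.0, 70.0):
            ratio = simulate_occupancy(
                KineticModel(0.01, LN2 / t_half), induction, [0.0, 5000.0])
            assert ratio[-1] == pytest.approx(induction.rho_inf, rel=1e-4)

    def test_fast_exchange_tracks_induction(self, induction, time_grid):
        model = KineticModel(0.01, LN2 / 0.005)  # t_half well below 1/k_d time scales
        ratio = simulate_occupancy(model, induction, time_grid)
        rho = induction(time_grid)
        late = time_grid >= 5.0
        np.testing.assert_allclose(ratio[late], rho[late], rtol=0.01)

    def test_matches_closed_form_under_step_induction(self, time_grid):
        for k_a in (0.001, 0.01, 0.1):
            for t_half in (1.0, 10.0, 70.0):
                for rho in (0.5, 1.5, 2.23):
                    model = KineticModel(k_a, LN2 / t_half)
                    num = simulate_occupancy(model, step_curve(rho), time_grid)
                    ana = ideal_induction_solution(model, step_curve(rho), time_grid)
                    np.testing.assert_allclose(num[1:], ana[1:], atol=1e-6)

    def test_curves_shift_right_with_residence_time(self, induction):
        """Half-crossing times of the occupancy ratio increase with t_1/2."""
        t = np.linspace(0.0, 400.0, 2000)
        crossings = []
        for t_half in (1.0, 3.0, 10.0, 30.0, 70.0):
            ratio = simulate_occupancy(KineticModel(0.01, LN2 / t_half), induction, t)
            half = induction.rho_inf / 2
            crossings.append(t[np.argmax(ratio >= half)])
        assert np.all(np.diff(crossings) > 0)

    def test_ka_insensitivity_in_dilute_regime(self, induction, time_grid):
        # dilute condition k_a (1 + rho_inf) << k_d: two decades of k_a
        kd = LN2 / 3.0
        base = simulate_occupancy(KineticModel(1e-4, kd), induction, time_grid)
        wide = simulate_occupancy(KineticModel(1e-2, kd), induction, time_grid)
        np.testing.assert_allclose(wide[1:], base[1:], rtol=0.02)

    def test_invalid_times_rejected(self, induction):
        with pytest.raises(ValueError):
            simulate_occupancy(KineticModel(0.01, 0.1), induction, [5.0, 10.0])


class TestIdealSolution:
    def test_zero_at_origin(self, induction):
        model = KineticModel(0.01, 0.1)
        assert ideal_induction_solution(model, induction, 0.0) == 0.0

    def test_constant_rho_equilibrium(self):
        model = KineticModel(0.01, 0.5)
        assert ideal_induction_solution(model, step_curve(1.5), 1e5) == pytest.approx(
            1.5, rel=1e-6)


class TestFitIdeal:
    def test_self_consistent_recovery(self, induction, time_grid):
        model = KineticModel(0.01, 0.1)
        values = ideal_induction_solution(model, induction, time_grid)
        from compchip import ScaledLocusSeries

        series = ScaledLocusSeries("s", time_grid, values)
        assert fit_ideal(series, induction) == pytest.approx(0.1, rel=1e-6)

    def test_insensitive_to_nuisance_ka(self, induction, time_grid):
        # doubling the nuisance k_a in the dilute regime barely moves k_d_ideal
        series = make_scaled_series(10.0, induction, time_grid, k_a=0.001)
        kd1 = fit_ideal(series, induction, k_a=0.001)
        kd2 = fit_ideal(series, induction, k_a=0.002)
        assert kd2 == pytest.approx(kd1, rel=0.02)

    def test_bias_reproduced_by_table(self, induction, time_grid, bias_table):
        """The ideal fit of exact-ODE data is biased; the table records it."""
        series = make_scaled_series(10.0, induction, time_grid)
        kd_ideal = fit_ideal(series, induction)
        kd_true = LN2 / 10.0
        assert kd_ideal != pytest.approx(kd_true, rel=0.02)  # bias is real
        tabulated = np.exp(np.interp(np.log(kd_true),
                                     np.log(bias_table.k_d_true),
                                     np.log(bias_table.k_d_ideal)))
        assert kd_ideal == pytest.approx(tabulated, rel=0.01)


class TestBiasTable:
    def test_identity_when_data_are_ideal(self, induction, time_grid):
        """Fitting ideal-solution data with the ideal solution is unbiased."""
        from compchip import ScaledLocusSeries

        # below ~2 min the ideal curve degenerates to tracking rho(t) and the
        # residual becomes flat in k_d, so the identity is only meaningful on
        # the resolvable part of the range
        kds = np.geomspace(LN2 / 60, LN2 / 2, 8)
        for kd in kds:
            values = ideal_induction_solution(KineticModel(0.01, kd),
                                              induction, time_grid)
            series = ScaledLocusSeries("s", time_grid, values)
            assert fit_ideal(series, induction) == pytest.approx(kd, rel=1e-6)

    def test_monotone_and_covers_range(self, bias_table):
        assert np.all(np.diff(bias_table.k_d_true) > 0)
        assert np.all(np.diff(bias_table.k_d_ideal) > 0)
        assert residence_time(bias_table.k_d_true[-1]) <= 0.5
        assert residence_time(bias_table.k_d_true[0]) >= 120.0

    def test_interpolation_matches_direct_computation(self, induction, time_grid,
                                                      bias_table):
        kd_true = LN2 / 7.3  # off-grid
        series = make_scaled_series(residence_time(kd_true), induction, time_grid)
        kd_ideal_direct = fit_ideal(series, induction)
        interp = np.exp(np.interp(np.log(kd_true), np.log(bias_table.k_d_true),
                                  np.log(bias_table.k_d_ideal)))
        assert interp == pytest.approx(kd_ideal_direct, rel=0.01)

    def test_non_monotone_rejected(self, induction, time_grid):
        with pytest.raises(ValueError, match="monotone"):
            BiasTable(k_d_true=np.array([0.1, 0.2, 0.15]),
                      k_d_ideal=np.array([0.1, 0.2, 0.3]),
                      k_a=0.01, times=time_grid, induction=induction)


class TestCorrectBias:
    def test_identity_table(self, induction, time_grid):
        grid = np.geomspace(0.01, 1.0, 50)
        table = BiasTable(grid, grid, 0.01, time_grid, induction)
        assert correct_bias(0.05, table) == pytest.approx(0.05)

    def test_exact_table_entry(self, bias_table):
        i = 30
        assert correct_bias(bias_table.k_d_ideal[i], bias_table) == pytest.approx(
            bias_table.k_d_true[i], rel=1e-9)

    def test_roundtrip_off_grid(self, induction, time_grid, bias_table):
        rng = np.random.default_rng(2)
        for kd_true in np.exp(rng.uniform(np.log(LN2 / 80), np.log(LN2 / 1.0), 20)):
            series = make_scaled_series(residence_time(kd_true), induction, time_grid)
            kd_ideal = fit_ideal(series, induction)
            assert correct_bias(kd_ideal, bias_table) == pytest.approx(
                kd_true, rel=0.02)

    def test_out_of_range_rejected(self, bias_table):
        with pytest.raises(ValueError, match="beyond 2x"):
            correct_bias(bias_table.k_d_ideal[-1] * 5, bias_table)


class TestNewtonRefine:
    def test_converges_immediately_from_truth(self, induction, time_grid):
        series = make_scaled_series(10.0, induction, time_grid)
        res = newton_refine(series, induction, LN2 / 10.0)
        assert res.converged
        assert res.n_iter <= 2
        assert res.t_half == pytest.approx(10.0, rel=1e-3)

    def test_shortest_reported_residence_time_roundtrip(self, induction,
                                                        time_grid, bias_table):
        series = make_scaled_series(1.3, induction, time_grid)
        res = estimate_residence_time(series, induction, bias_table)
        assert res.converged
        assert res.t_half == pytest.approx(1.3, rel=0.05)

    def test_noisy_median_error_within_ten_percent(self, induction, time_grid,
                                                   bias_table):
        errors = []
        for seed in range(100):
            series = make_scaled_series(10.0, induction, time_grid,
                                        sigma_log2=0.1, seed=seed)
            res = estimate_residence_time(series, induction, bias_table)
            errors.append(abs(res.t_half - 10.0) / 10.0)
        assert np.median(errors) <= 0.10


def test_full_grid_recovery(induction, time_grid, bias_table):
    """Noiseless loci across the reported residence-time range, within 5%."""
    for t_half in (1.3, 3.0, 5.0, 9.0, 20.0, 53.0):
        series = make_scaled_series(t_half, induction, time_grid)
        res = estimate_residence_time(series, induction, bias_table)
        assert res.converged
        assert res.t_half == pytest.approx(t_half, rel=0.05)
        assert res.method_trace[:2] == ["ideal", "lookup"]


class TestResidenceTime:
    @pytest.mark.parametrize(("k_d", "expected"),
                             [(LN2, 1.0), (LN2 / 53, 53.0), (LN2 / 1.3, 1.3)])
    def test_examples(self, k_d, expected):
        assert residence_time(k_d) == pytest.approx(expected)

    @given(st.floats(1e-6, 1e3))
    def test_algebraic_identity(self, k_d):
        assert residence_time(k_d) * k_d == pytest.approx(LN2, rel=1e-12)

    def test_inverse_pair(self):
        assert dissociation_rate(residence_time(0.37)) == pytest.approx(0.37)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            residence_time(0.0)
        with pytest.raises(ValueError):
            dissociation_rate(-1.0)
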