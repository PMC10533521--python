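import numpy as np
import pytest

from flagrd.kymograph import Kymograph
from flagrd.params import NondimParams
from flagrd.solver import (EXP_CAP, FlagellumState, GrowthWindowError, assemble_rhs,
                           assemble_jacobian, default_initial_condition,
                           diffusion_closed_form, diffusion_limit_solution,
                           find_hopf_mu_a, measure_frequency, measure_growth_rate,
                           simulate_no_feedback, simulate_rd)
from flagrd.stability import critical_activity, equilibrium_attachment


P_DIFF = NondimParams(mu_a=500.0, mu=10.0, eta=0.14, zeta=0.3, fstar=2.0)


def independent_residual(state, deriv, params, w2):
    """Direct transcription of the discretized governing equations as residuals.

    Base row: gamma_t,0 + gamma_0 = 0.  Interior rows:
    mu*g_i - w2*(g_{i+1}-2g_i+g_{i-1}) + mu_a*(zeta*nbar_i*g_t,i - ntilde_i) = 0.
    Tip row: mu*g_{m-1} - 2*w2*(g_{m-2}-g_{m-1}) + mu_a*(...) = 0.
    Motor rows: n±_t - eta*(1-n±) + (1-eta)*n±*exp(f*(1±zeta*g_t)) = 0.
    """
    g, gp = state.gamma, deriv.gamma
    nb = state.n_plus + state.n_minus
    nt = state.n_minus - state.n_plus
    m = g.size
    mu_a, mu, zeta, eta, f = params.mu_a, params.mu, params.zeta, params.eta, params.fstar
    res = np.empty(3 * m)
    res[0] = gp[0] + g[0]
    for i in range(1, m - 1):
        res[i] = (mu * g[i] - w2 * (g[i + 1] - 2 * g[i] + g[i - 1])
                  + mu_a * (zeta * nb[i] * gp[i] - nt[i]))
    res[m - 1] = (mu * g[m - 1] - 2 * w2 * (g[m - 2] - g[m - 1])
                  + mu_a * (zeta * nb[m - 1] * gp[m - 1] - nt[m - 1]))
    for i in range(m):
        res[m + i] = (deriv.n_plus[i] - eta * (1 - state.n_plus[i])
                      + (1 - eta) * state.n_plus[i] * np.exp(f * (1 + zeta * gp[i])))
        res[2 * m + i] = (deriv.n_minus[i] - eta * (1 - state.n_minus[i])
                          + (1 - eta) * state.n_minus[i] * np.exp(f * (1 - zeta * gp[i])))
    return res


class TestAssembleRhs:
    def test_homogeneous_equilibrium_is_stationary(self):
        st = default_initial_condition(m=31, params=P_DIFF)
        st.gamma[:] = 0.0
        deriv = assemble_rhs(st, P_DIFF)
        np.testing.assert_allclose(deriv.pack(), 0.0, atol=1e-14)

    def test_matches_independent_residual_to_machine_precision(self):
        rng = np.random.default_rng(7)
        m = 41
        s = np.linspace(0, 1, m)
        n0 = equilibrium_attachment(P_DIFF.eta, P_DIFF.fstar)
        smooth = 0.05 * np.sin(2 * np.pi * s) + 0.02 * s
        st = FlagellumState(gamma=smooth,
                            n_plus=n0 * (1 + 0.2 * rng.random(m)),
                            n_minus=n0 * (1 + 0.2 * rng.random(m)),
                            s_grid=s)
        deriv = assemble_rhs(st, P_DIFF)
        res = independent_residual(st, deriv, P_DIFF, float((m - 1) ** 2))
        assert np.abs(res).max() < 1e-9

    def test_no_feedback_reduces_to_diffusion_form(self):
        m = 31
        s = np.linspace(0, 1, m)
        n0 = equilibrium_attachment(P_DIFF.eta, P_DIFF.fstar)
        gamma = 0.1 * np.sin(np.pi * s / 2)
        st = FlagellumState(gamma=gamma, n_plus=np.full(m, n0),
                            n_minus=np.full(m, n0), s_grid=s)
        deriv = assemble_rhs(st, P_DIFF, feedback=False)
        w2 = (m - 1) ** 2
        lap = np.zeros(m)
        lap[1:-1] = gamma[2:] - 2 * gamma[1:-1] + gamma[:-2]
        lap[-1] = 2 * (gamma[-2] - gamma[-1])
        expected = (w2 * lap - P_DIFF.mu * gamma) / (2 * n0 * P_DIFF.mu_a * P_DIFF.zeta)
        expected[0] = -gamma[0]
        np.testing.assert_allclose(deriv.gamma, expected, rtol=1e-12)
        np.testing.assert_allclose(deriv.n_plus, 0.0, atol=1e-14)

    def test_vanishing_motor_population_is_regularized(self):
        # both teams fully detached: the friction floor keeps the shear
        # velocity finite instead of dividing by zero
        m = 11
        s = np.linspace(0, 1, m)
        st = FlagellumState(gamma=np.zeros(m), n_plus=np.zeros(m),
                            n_minus=np.zeros(m), s_grid=s)
        deriv = assemble_rhs(st, P_DIFF)
        assert np.all(np.isfinite(deriv.pack()))

    def test_analytic_jacobian_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        m = 21
        s = np.linspace(0, 1, m)
        n0 = equilibrium_attachment(P_DIFF.eta, P_DIFF.fstar)
        st = FlagellumState(gamma=0.1 * rng.standard_normal(m),
                            n_plus=np.abs(n0 * (1 + 0.3 * rng.standard_normal(m))),
                            n_minus=np.abs(n0 * (1 + 0.3 * rng.standard_normal(m))),
                            s_grid=s)
        J = assemble_jacobian(st, P_DIFF).toarray()
        y0 = st.pack()
        h = 1e-8
        J_fd = np.empty_like(J)
        for j in range(3 * m):
            e = np.zeros(3 * m)
            e[j] = h
            plus = assemble_rhs(FlagellumState.unpack(y0 + e, s), P_DIFF).pack()
            minus = assemble_rhs(FlagellumState.unpack(y0 - e, s), P_DIFF).pack()
            J_fd[:, j] = (plus - minus) / (2 * h)
        assert np.abs(J - J_fd).max() < 1e-4 * max(1.0, np.abs(J_fd).max())


class TestInitialCondition:
    def test_gaussian_perturbation_values(self):
        st = default_initial_condition(m=101, n0=0.02)
        s = st.s_grid
        i_mid = 50
        assert st.gamma[i_mid] == pytest.approx(1e-3)
        assert st.gamma.max() == pytest.approx(1e-3)
        i_off = np.argmin(np.abs(s - 0.6))
        assert st.gamma[i_off] == pytest.approx(1e-3 / np.e, rel=1e-6)
        np.testing.assert_allclose(st.n_plus, 0.02)


class TestSimulateRd:
    def test_subcritical_decays_to_homogeneous_equilibrium(self):
        crit = critical_activity(10.0, 0.14, 0.3, 2.0)
        p = NondimParams(mu_a=0.8 * crit, mu=10.0, eta=0.14, zeta=0.3, fstar=2.0)
        kyms = simulate_rd(p, t_end=60.0, m=51, method="semi", dt_out=0.02)
        g = kyms["shear_angle"].values
        assert np.abs(g[-1]).max() < 1e-6
        n0 = equilibrium_attachment(0.14, 2.0)
        assert kyms["n_plus"].values[-1] == pytest.approx(n0, rel=1e-4)

    def test_motor_fractions_bounded(self, mbo2ish_run):
        for name in ("n_plus", "n_minus"):
            v = mbo2ish_run[name].values
            assert v.min() >= 0.0 and v.max() <= 1.0

    def test_basal_shear_pinned_to_zero(self, mbo2ish_run):
        g0 = mbo2ish_run["shear_angle"].values[:, 0]
        assert np.abs(g0[-1000:]).max() < 1e-3

    def test_semi_and_bdf_paths_agree(self):
        crit = critical_activity(100.0, 0.14, 0.3, 2.0)
        p = NondimParams(mu_a=1.2 * crit, mu=100.0, eta=0.14, zeta=0.3, fstar=2.0)
        ks = simulate_rd(p, t_end=40.0, method="semi", dt_out=0.02)["shear_angle"]
        kb = simulate_rd(p, t_end=40.0, method="bdf", dt_out=0.02,
                         rtol=1e-6, atol=1e-8)["shear_angle"]
        fs = measure_frequency(ks, t_start=25.0)
        fb = measure_frequency(kb, t_start=25.0)
        assert fs == pytest.approx(fb, rel=0.01)

    def test_grid_convergence_of_fundamental_frequency(self):
        crit = critical_activity(100.0, 0.14, 0.3, 2.0)
        p = NondimParams(mu_a=1.2 * crit, mu=100.0, eta=0.14, zeta=0.3, fstar=2.0)
        freqs = []
        for m in (101, 201):
            k = simulate_rd(p, t_end=60.0, m=m, method="semi", dt_out=0.02)["shear_angle"]
            freqs.append(measure_frequency(k, t_start=40.0))
        assert abs(freqs[1] - freqs[0]) / freqs[0] < 0.005

    def test_legacy_grid_factor_selectable(self):
        p = P_DIFF
        st = default_initial_condition(m=21, params=p)
        d_default = assemble_rhs(st, p, grid_factor="spacing")
        d_legacy = assemble_rhs(st, p, grid_factor="legacy_m2")
        assert not np.allclose(d_default.gamma, d_legacy.gamma)
        with pytest.raises(ValueError):
            assemble_rhs(st, p, grid_factor="bogus")


class TestDiffusionLimit:
    def test_eigenfunction_decays_at_closed_form_rate(self):
        m = 101
        s = np.linspace(0, 1, m)
        g0 = np.sin(np.pi * s / 2)
        sol = diffusion_limit_solution(g0, s, P_DIFF)
        # only the k=0 coefficient is non-negligible
        assert sol.coefficients[0] == pytest.approx(1.0, abs=1e-6)
        assert np.abs(sol.coefficients[1:]).max() < 1e-6
        rate0 = sol.E_nd + sol.D_nd * np.pi**2 / 4
        assert sol.decay_rates[0] == pytest.approx(rate0)
        assert np.all(np.diff(sol.decay_rates) > 0)
        t = 0.7 / rate0
        out = diffusion_closed_form(g0, s, P_DIFF, t)
        np.testing.assert_allclose(out, np.exp(-rate0 * t) * g0, atol=1e-7)

    def test_series_matches_time_stepped_solver(self):
        m = 101
        s = np.linspace(0, 1, m)
        g0 = (1 - np.cos(2 * np.pi * s)) / 4
        sol = diffusion_limit_solution(g0, s, P_DIFF)
        t_dec = 1.0 / sol.decay_rates[0]
        kym = simulate_no_feedback(P_DIFF, g0, s, t_end=5 * t_dec, dt_out=t_dec / 10)
        series = diffusion_closed_form(g0, s, P_DIFF, kym.times)
        assert np.abs(kym.values - series).max() < 1e-4

    def test_l2_norm_non_increasing_without_feedback(self):
        m = 51
        s = np.linspace(0, 1, m)
        rng = np.random.default_rng(5)
        # smooth random initial profile with gamma(0) = 0
        g0 = np.sin(np.pi * s / 2) * (0.5 + 0.5 * rng.random())
        g0 += 0.3 * np.sin(3 * np.pi * s / 2)
        kym = simulate_no_feedback(P_DIFF, g0, s, t_end=1.0, dt_out=0.01)
        norms = np.sqrt(np.trapezoid(kym.values**2, s, axis=1))
        assert np.all(np.diff(norms) <= 1e-12)

    def test_dissipation_to_straight_filament(self):
        # static elastica: without motor forcing the only steady state is
        # gamma == 0 under these boundary conditions
        m = 51
        s = np.linspace(0, 1, m)
        g0 = (1 - np.cos(2 * np.pi * s)) / 4
        sol = diffusion_limit_solution(g0, s, P_DIFF)
        kym = simulate_no_feedback(P_DIFF, g0, s, t_end=20.0 / sol.decay_rates[0],
                                   dt_out=2.0 / sol.decay_rates[0])
        assert np.abs(kym.values[-1]).max() < 1e-8


class TestGrowthMeasurement:
    def test_constructed_exponential_signal(self):
        s = np.linspace(0, 1, 101)
        t = np.arange(0, 60, 0.01)
        omega = 1.3
        vals = (1e-3 * np.exp(0.1 * t)[:, None]
                * np.sin(omega * t)[:, None] * np.sin(np.pi * s / 2)[None, :])
        kym = Kymograph(values=vals, times=t, s_grid=s)
        assert measure_growth_rate(kym) == pytest.approx(0.1, abs=1e-3)

    def test_subcritical_rate_negative(self):
        crit = critical_activity(100.0, 0.14, 0.3, 2.0)
        p = NondimParams(mu_a=0.9 * crit, mu=100.0, eta=0.14, zeta=0.3, fstar=2.0)
        kym = simulate_rd(p, t_end=40.0, method="semi", dt_out=0.02)["shear_angle"]
        assert measure_growth_rate(kym) < 0

    def test_flat_record_has_no_window(self):
        s = np.linspace(0, 1, 21)
        t = np.arange(0, 10, 0.01)
        kym = Kymograph(values=np.ones((t.size, s.size)), times=t, s_grid=s)
        with pytest.raises(GrowthWindowError):
            measure_growth_rate(kym)


class TestHopfLocation:
    def test_bisection_brackets_closed_form_critical_activity(self):
        mu, eta, zeta, f = 100.0, 0.14, 0.3, 2.0
        crit = critical_activity(mu, eta, zeta, f)
        onset, _ = find_hopf_mu_a(mu, eta, zeta, f, bracket=(0.5 * crit, 2.0 * crit),
                                  m=51, tol=1e-3)
        assert onset == pytest.approx(crit, rel=0.02)
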