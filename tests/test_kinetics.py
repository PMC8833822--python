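"""Exact telegraph-model statistics: steady state, stationary law, transients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.stats import poisson

from genedose.kinetics import (
    GeneKinetics,
    MomentState,
    classify_regime,
    derived_params,
    moment_ode_rhs,
    moment_system,
    stationary_distribution,
    steady_moment_state,
    steady_state_moments,
    transient_moments,
)

RHO = 1.0 / 6.0


class TestDerivedParams:
    def test_slow_switching_fixture_values(self):
        # post-treatment rates of the fast-switching single-drug design
        p = derived_params(GeneKinetics(k=18.5, rho=RHO, f=0.15, h=1.5167))
        assert p.N == pytest.approx(111.0)
        assert abs(p.N - 110.0) / 110.0 < 0.01  # printed rounded value
        assert p.A == pytest.approx(0.09, abs=1e-4)
        assert p.eps == pytest.approx(10.0, rel=1e-3)

    def test_symmetric_switching_gives_half_on(self):
        for fh in (0.008, 0.17, 5.0):
            p = derived_params(GeneKinetics(k=3.3, rho=RHO, f=fh, h=fh))
            assert p.A == 0.5

    def test_synthesis_ladder_fixture(self):
        p = derived_params(GeneKinetics(k=3.3, rho=RHO, f=0.83, h=0.83))
        assert p.eps == pytest.approx(10.0, rel=0.01)
        assert p.N == pytest.approx(20.0, rel=0.01)

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(k=-1, rho=0.2, f=0.1, h=0.1), "k"),
            (dict(k=1, rho=0.0, f=0.1, h=0.1), "rho"),
            (dict(k=1, rho=0.2, f=-0.1, h=0.1), "f"),
            (dict(k=1, rho=0.2, f=0.1, h=-0.1), "h"),
            (dict(k=1, rho=0.2, f=0.0, h=0.0), "promoter must switch"),
        ],
    )
    def test_invalid_kinetics_name_offending_field(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            GeneKinetics(**kwargs)


class TestSteadyState:
    def test_pretreatment_mean_near_ten(self):
        ss = steady_state_moments(GeneKinetics(k=RHO * 110, rho=RHO, f=0.09, h=0.91))
        assert ss.mean == pytest.approx(9.9)

    def test_always_on_is_poisson(self):
        kin = GeneKinetics(k=4.0, rho=0.2, f=1.0, h=0.0)
        ss = steady_state_moments(kin)
        assert ss.mean == pytest.approx(20.0)
        assert ss.var == pytest.approx(20.0)

    def test_symmetric_slow_switching_value(self):
        # A=0.5, N=20, eps=1: mean 10, var 10*(1 + 20*0.5/2) = 60
        rho = 0.25
        kin = GeneKinetics(k=20 * rho, rho=rho, f=0.125, h=0.125)
        ss = steady_state_moments(kin)
        assert ss.mean == pytest.approx(10.0)
        assert ss.var == pytest.approx(60.0)

    def test_moment_state_consistent_with_closed_form(self, kinetics_grid):
        for kin in kinetics_grid:
            ss = steady_state_moments(kin)
            st_ = steady_moment_state(kin)
            assert st_.m1 == pytest.approx(ss.mean, rel=1e-10)
            assert st_.var == pytest.approx(ss.var, rel=1e-9)

    def test_fano_approaches_one_at_fast_switching(self):
        # var/mean -> 1 as eps grows at fixed A, N
        A, N = 0.3, 40.0
        eps = 100.0 * N
        kin = GeneKinetics(k=N * RHO, rho=RHO, f=A * eps * RHO, h=(1 - A) * eps * RHO)
        ss = steady_state_moments(kin)
        assert ss.var / ss.mean == pytest.approx(1.0, rel=0.01)

    @given(
        N=st.floats(0.1, 300),
        A=st.floats(0.01, 1.0),
        eps=st.floats(1e-3, 1e3),
        rho=st.floats(0.01, 2.0),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_super_poissonian_bound(self, N, A, eps, rho):
        kin = GeneKinetics(k=N * rho, rho=rho, f=A * eps * rho, h=(1 - A) * eps * rho)
        ss = steady_state_moments(kin)
        assert ss.var >= ss.mean * (1 - 1e-12)


class TestStationaryDistribution:
    def test_always_on_matches_poisson_termwise(self):
        kin = GeneKinetics(k=4.0, rho=0.2, f=1.0, h=0.0)
        d = stationary_distribution(kin, tail_tol=1e-12)
        expected = poisson.pmf(np.arange(d.n_max + 1), 20.0)
        assert np.abs(d.probs - expected).max() < 1e-10

    def test_normalization_within_tail_tol(self, kinetics_grid):
        for kin in kinetics_grid[:10]:
            d = stationary_distribution(kin, tail_tol=1e-9)
            assert 1.0 - d.probs.sum() < 1e-9
            assert (d.probs >= 0).all()

    def test_moments_match_closed_form(self, kinetics_grid):
        for kin in kinetics_grid:
            ss = steady_state_moments(kin)
            d = stationary_distribution(kin, tail_tol=1e-12)
            assert d.mean() == pytest.approx(ss.mean, rel=1e-6)
            assert d.var() == pytest.approx(ss.var, rel=1e-6)

    def test_slow_switching_law_is_bimodal_with_mode_at_zero(self):
        # eps0=0.1, A0=0.09, N0=110 regime
        kin = GeneKinetics(k=18.5, rho=RHO, f=0.0015, h=0.015)
        d = stationary_distribution(kin, tail_tol=1e-10)
        q = d.probs
        assert q[0] > q[1]  # boundary mode at n = 0
        interior = np.nonzero((q[1:-1] > q[:-2]) & (q[1:-1] >= q[2:]))[0]
        assert interior.size >= 1  # plus a high-expression mode

    def test_large_burst_regime_is_stable(self):
        # N = 1000 with rare ON periods: log-space/arbitrary-precision path
        kin = GeneKinetics(k=166.7, rho=RHO, f=0.017, h=1.65)
        d = stationary_distribution(kin, tail_tol=1e-9)
        ss = steady_state_moments(kin)
        assert d.mean() == pytest.approx(ss.mean, rel=1e-6)

    def test_bad_tail_raises_instead_of_renormalizing(self):
        kin = GeneKinetics(k=5.0, rho=0.5, f=0.5, h=0.5)
        with pytest.raises(RuntimeError, match="n_max"):
            stationary_distribution(kin, tail_tol=1e-12, n_max_cap=5)


class TestMomentDynamics:
    def test_rhs_vanishes_at_fixed_point(self, kinetics_grid):
        for kin in kinetics_grid[:8]:
            s = steady_moment_state(kin)
            scale = max(1.0, s.m2)
            assert np.abs(moment_ode_rhs(kin, s)).max() / scale < 1e-12

    def test_no_synthesis_is_pure_decay(self):
        kin = GeneKinetics(k=0.0, rho=0.3, f=0.2, h=0.1)
        s = MomentState(A=0.5, m1=7.0, m1on=3.0, m2=60.0, m2on=25.0)
        rhs = moment_ode_rhs(kin, s)
        assert rhs[1] == pytest.approx(-0.3 * 7.0)

    def test_transient_at_zero_returns_initial_state(self):
        kin = GeneKinetics(k=5.0, rho=0.2, f=0.3, h=0.6)
        init = MomentState(A=0.2, m1=4.0, m1on=1.0, m2=30.0, m2on=8.0)
        mean, sd, _ = transient_moments(kin, init, [0.0])
        assert mean[0] == pytest.approx(init.m1)
        assert sd[0] == pytest.approx(np.sqrt(init.m2 - init.m1**2))

    def test_long_time_limit_is_steady_state(self):
        kin = GeneKinetics(k=5.0, rho=0.2, f=0.3, h=0.6)
        init = MomentState(A=1.0, m1=40.0, m1on=40.0, m2=1700.0, m2on=1700.0)
        t_long = 60.0 / (kin.rho * min(1.0, (kin.f + kin.h) / kin.rho))
        mean, sd, _ = transient_moments(kin, init, [t_long])
        ss = steady_state_moments(kin)
        assert mean[0] == pytest.approx(ss.mean, abs=1e-8)
        assert sd[0] == pytest.approx(ss.sd, abs=1e-8)

    @pytest.mark.parametrize("eps", [0.1, 1.0, 1.0 + 5e-7, 2.0, 30.0])
    def test_matches_adaptive_integration(self, eps):
        # includes the degenerate eps = 1 case where closed-form partial
        # fractions of the two slowest exponentials collide
        rho = 0.25
        kin = GeneKinetics(k=8.0, rho=rho, f=0.4 * eps * rho, h=0.6 * eps * rho)
        init = steady_moment_state(GeneKinetics(k=2.0, rho=rho, f=0.1, h=0.4))
        times = [0.5, 2.0, 5.0, 15.0]
        mean, sd, _ = transient_moments(kin, init, times)
        M, b = moment_system(kin)
        sol = solve_ivp(
            lambda t, x: M @ x + b, (0, times[-1]), init.as_array(),
            t_eval=times, rtol=1e-12, atol=1e-12, method="LSODA",
        )
        assert np.abs(sol.y[1] - mean).max() / np.abs(mean).max() < 1e-8
        ref_sd = np.sqrt(sol.y[3] - sol.y[1] ** 2)
        assert np.abs(ref_sd - sd).max() / ref_sd.max() < 1e-8

    def test_invalid_initial_state_rejected(self):
        with pytest.raises(ValueError):
            MomentState(A=0.5, m1=5.0, m1on=6.0, m2=30.0, m2on=8.0)
        with pytest.raises(ValueError):
            MomentState(A=1.5, m1=5.0, m1on=2.0, m2=30.0, m2on=8.0)


class TestRegimeClassifier:
    @pytest.mark.parametrize(
        "kin, label",
        [
            # the five pre-treatment regimes of the synthesis-rate design
            (GeneKinetics(k=3.3, rho=RHO, f=0.008, h=0.008), "bimodal"),
            (GeneKinetics(k=3.3, rho=RHO, f=0.17, h=0.17), "table-shaped"),
            (GeneKinetics(k=3.3, rho=RHO, f=0.83, h=0.83), "quasi-poissonian"),
            (GeneKinetics(k=166.7, rho=RHO, f=0.017, h=1.65), "burst"),
            # slow-switching bimodal regime of the f-drug design
            (GeneKinetics(k=18.5, rho=RHO, f=0.0015, h=0.015), "bimodal"),
        ],
    )
    def test_fixture_regimes(self, kin, label):
        assert classify_regime(kin) == label

    def test_always_on_is_quasi_poissonian(self):
        assert classify_regime(GeneKinetics(k=4.0, rho=0.2, f=1.0, h=0.0)) == \
            "quasi-poissonian"

    def test_strong_burst_example(self):
        rho = 0.2
        kin = GeneKinetics(k=1000 * rho, rho=rho, f=0.01 * 10 * rho, h=0.99 * 10 * rho)
        assert classify_regime(kin) == "burst"
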