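"""System-size-expansion engine: rate equations, LNA, EMRE/IOS blocks,
equation counts, and convergence of the time course to the algebraic
steady state.

The EMRE/IOS moment systems are not asserted against printed formulas;
they are validated against independent oracles: symbolic solutions of
small Lyapunov systems, exactness on first-order networks, and the
brute-force stationary master equation (see test_acceptance for the
order-of-accuracy fits).
"""

import numpy as np
import pytest
import sympy as sp

import inoise
from inoise import models
from inoise.netmodel import NetworkError
from inoise.sse import (MonostabilityError, SSESystem, equation_count,
                        lna_covariance, macroscopic_rates, moments, re_rhs,
                        solve_re, solve_steady_state, sse_steady_state,
                        sse_timecourse)


class TestMacroscopicRates:
    def test_linear_reaction_is_exact(self):
        net = inoise.build_network([("X", 2.0)], [({"X": 1}, {}, 3.0)])
        f0, f1 = macroscopic_rates(net, [2.0])
        assert f0[0] == pytest.approx(6.0)
        assert f1[0] == 0.0

    def test_homodimer_carries_order_correction(self):
        """2A -> 0: the n(n-1)/Omega^2 propensity expands to
        k X^2 - k X / Omega, so f1 = -k X (symbolic oracle)."""
        n, om, k = sp.symbols("n Omega k", positive=True)
        X = sp.Symbol("X", positive=True)
        expansion = sp.expand((k * n * (n - 1) / om ** 2).subs(n, om * X))
        assert expansion == k * X ** 2 - k * X / om
        net = inoise.build_network([("A", 1.5)], [({"A": 2}, {}, 2.0)])
        f0, f1 = macroscopic_rates(net, [1.5])
        assert f0[0] == pytest.approx(2.0 * 1.5 ** 2)
        assert f1[0] == pytest.approx(-2.0 * 1.5)

    def test_heterodimer_has_no_order_correction(self):
        net = inoise.build_network([("A", 2.0), ("B", 3.0)],
                                   [({"A": 1, "B": 1}, {}, 0.5)])
        f0, f1 = macroscopic_rates(net, [2.0, 3.0])
        assert f0[0] == pytest.approx(3.0)
        assert f1[0] == 0.0

    def test_custom_propensity_rejected(self):
        net = inoise.build_network([("A", 1.0)], [])
        net.reactions.append(inoise.Reaction({"A": 1}, {}, 1.0,
                                             propensity_expr="A**4"))
        with pytest.raises(NetworkError, match="mass action"):
            macroscopic_rates(net, [1.0])


class TestRateEquations:
    def test_birth_death_fixed_point(self, birth_death):
        # X* = k_in / k_out
        X = solve_re(birth_death, [0.0], np.linspace(0, 200, 50))
        assert X[-1, 0] == pytest.approx(10.0, rel=1e-6)
        assert re_rhs(birth_death, [10.0])[0] == pytest.approx(0.0, abs=1e-12)

    def test_srna_crossover_equalises_transcripts(self):
        """At the crossover (equal transcription, equal decay rates) the
        stationary mRNA and sRNA concentrations coincide exactly."""
        net = models.srna_model("i", alpha=1.0)
        st = sse_steady_state(net, order="re")
        mean, _ = moments(st, order="re")
        ids = net.species_ids()
        assert mean[ids.index("S")] == pytest.approx(mean[ids.index("M")],
                                                     rel=1e-9)

    def test_conservation_totals_constant_along_trajectory(self, enzyme):
        red = inoise.conservation_analysis(enzyme)
        X0 = enzyme.initial_concentrations() * 0 + 0.1
        X = solve_re(enzyme, X0, np.linspace(0, 30, 40))
        totals = X @ red.gamma.T
        np.testing.assert_allclose(totals - totals[0], 0.0, atol=1e-7)


class TestSteadyState:
    def test_birth_death(self, birth_death):
        ss = solve_steady_state(birth_death)
        assert ss.X_star[0] == pytest.approx(10.0, rel=1e-10)
        assert ss.jacobian_eigenvalues[0].real == pytest.approx(-0.1)
        assert ss.stable
        assert ss.residual_norm < 1e-10

    def test_autoreg_reduced_residual(self, autoreg):
        ss = solve_steady_state(autoreg)
        sys_ = ss.system
        assert sys_.n == 9
        rhs = sys_.re_rhs_reduced(ss.y_star)
        assert np.linalg.norm(rhs) < 1e-10 * max(1.0, np.max(np.abs(ss.y_star)))
        assert np.max(ss.jacobian_eigenvalues.real) < 0

    def test_symmetric_toggle_is_rejected(self):
        """A perfectly symmetric mutual-repression toggle relaxes onto the
        unstable symmetric fixed point, which the monostability gate must
        reject (naming the offending eigenvalue)."""
        # autocatalysis plus mutual annihilation: the symmetric point is a
        # saddle, and the symmetric initial condition relaxes onto it
        net = inoise.build_network(
            [("A", 1.0), ("B", 1.0)],
            [({}, {"A": 1}, 1.0), ({}, {"B": 1}, 1.0),
             ({"A": 1}, {"A": 2}, 2.0), ({"B": 1}, {"B": 2}, 2.0),
             ({"A": 1, "B": 1}, {}, 2.0)],
            name="toggle")
        with pytest.raises(MonostabilityError, match="eigenvalue"):
            solve_steady_state(net)


class TestLNA:
    def test_birth_death_is_poisson(self, birth_death):
        st = sse_steady_state(birth_death, order="lna")
        sig = st.sigma_matrix()
        assert sig[0, 0] == pytest.approx(10.0, rel=1e-9)  # sigma = X*, Fano 1

    def test_lyapunov_residual_defining_property(self, srna_i):
        ss = solve_steady_state(srna_i)
        t = ss.system.tensors(ss.y_star)
        sig = lna_covariance(t.J, t.D)
        resid = np.linalg.norm(t.J @ sig + sig @ t.J.T + t.D)
        assert resid <= 1e-10 * np.linalg.norm(t.D)

    def test_unstable_jacobian_rejected(self):
        with pytest.raises(MonostabilityError):
            lna_covariance([[1.0]], [[1.0]])

    def test_linear_gene_protein_fano_closed_form(self):
        """Protein Fano factor of two-stage expression from an independent
        symbolic Lyapunov solve: 1 + ks/(kdM + kdp)."""
        k0v, ksv, kdMv, kdpv = 1.0, 5.0, 1.0, 0.2
        k0s, kss, kdMs, kdps = sp.symbols("k0 ks kdM kdp", positive=True)
        M, P = k0s / kdMs, k0s * kss / (kdMs * kdps)
        J = sp.Matrix([[-kdMs, 0], [kss, -kdps]])
        D = sp.Matrix([[2 * k0s, 0], [0, 2 * kss * M]])
        s11, s12, s22 = sp.symbols("s11 s12 s22")
        S = sp.Matrix([[s11, s12], [s12, s22]])
        eqs = J * S + S * J.T + D
        sol = sp.solve([eqs[0, 0], eqs[0, 1], eqs[1, 1]], [s11, s12, s22])
        fano_sym = sp.simplify(sol[s22] / P)
        assert sp.simplify(fano_sym - (1 + kss / (kdMs + kdps))) == 0
        net = models.linear_gene(k0v, ksv, kdMv, kdpv)
        st = sse_steady_state(net, order="lna")
        summ = inoise.lna_measures(st)
        assert summ.get("P", "fano") == pytest.approx(
            1 + ksv / (kdMv + kdpv), rel=1e-9)

    def test_diffusion_matrix_psd_and_d3_symmetric(self, srna_i):
        ss = solve_steady_state(srna_i)
        t = ss.system.tensors(ss.y_star)
        assert np.min(np.linalg.eigvalsh(t.D)) > -1e-12
        np.testing.assert_allclose(t.D3, t.D3.transpose(1, 0, 2))
        np.testing.assert_allclose(t.D3, t.D3.transpose(2, 1, 0))


class TestEmreIos:
    def test_first_order_network_has_zero_corrections(self, linear_gene):
        st = sse_steady_state(linear_gene, order="ios")
        np.testing.assert_allclose(st.eps1, 0.0, atol=1e-12)
        np.testing.assert_allclose(st.sigma2, 0.0, atol=1e-12)

    def test_birth_death_third_moment_is_poisson(self, birth_death):
        # Poisson third central moment equals the mean: [eps^3]_1 = X*
        st = sse_steady_state(birth_death, order="ios")
        assert st.T[0] == pytest.approx(10.0, rel=1e-9)

    def test_dimerization_emre_tracks_cme(self, dimer):
        dist = inoise.cme_oracle(dimer, bounds=200)
        mean_n, var_n = dist.moments()[0][0], dist.moments()[1][0, 0]
        st = sse_steady_state(dimer, order="ios")
        om = dimer.omega
        m_re = moments(st, order="re")[0][0] * om
        m_emre = moments(st, order="emre")[0][0] * om
        v_lna = moments(st, order="lna")[1][0, 0] * om ** 2
        v_ios = moments(st, order="ios")[1][0, 0] * om ** 2
        # EMRE/IOS land much closer to the exact stationary moments than
        # RE/LNA, and on the correct side
        assert abs(m_emre - mean_n) < 0.05 * abs(m_re - mean_n)
        assert abs(v_ios - var_n) < 0.05 * abs(v_lna - var_n)

    def test_srna_discreteness_induced_inversion(self):
        """At weak sRNA control the rate equations put mRNA above protein;
        the mean corrections invert the ordering (confirmed by stochastic
        simulation in test_ssa)."""
        net = models.srna_model("i", alpha=0.01)
        st = sse_steady_state(net, order="emre")
        ids = net.species_ids()
        m_re, _ = moments(st, order="re")
        m_emre, _ = moments(st, order="emre")
        iM, iP = ids.index("M"), ids.index("P")
        assert m_re[iM] > m_re[iP]
        assert m_emre[iP] > m_emre[iM]
        # the inversion fades once the sRNA level passes ~a single copy
        st2 = sse_steady_state(models.srna_model("i", alpha=0.3), order="emre")
        m2, _ = moments(st2, order="emre")
        assert m2[iM] > m2[iP]

    def test_ios_minus_lna_variance_scales_as_omega_minus_two(self):
        """The covariance correction enters at exactly Omega^-2: the
        fitted log-log slope of Sigma_ios - Sigma_lna vs Omega is -2."""
        oms = np.array([5.0, 10.0, 20.0, 40.0, 80.0])
        gaps = []
        for om in oms:
            st = sse_steady_state(models.dimerization(omega=om), order="ios")
            _, c_lna = moments(st, order="lna")
            _, c_ios = moments(st, order="ios")
            gaps.append(abs(c_ios[0, 0] - c_lna[0, 0]))
        slope = np.polyfit(np.log(oms), np.log(gaps), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.05)


class TestEquationCount:
    @pytest.mark.parametrize("N,expected", [
        (9, (273, 9, 264)),
        (1, (5, 1, 4)),
        (2, (14, 2, 12)),
        (14, (798, 14, 784)),
    ])
    def test_counts(self, N, expected):
        assert equation_count(N) == expected

    @pytest.mark.parametrize("builder,n_indep", [
        (lambda: models.birth_death(1.0, 0.1, omega=100.0), 1),
        (models.linear_gene, 2),
        (models.enzyme_cycle, 2),
        (lambda: models.srna_model("i"), 4),
        (models.autoreg_model, 9),
    ])
    def test_time_course_integrates_exactly_that_many_equations(
            self, builder, n_indep):
        net = builder()
        tc = sse_timecourse(net, [0.0, 1e-3], order="ios")
        assert tc.n_equations == equation_count(n_indep)[0]


class TestMoments:
    def test_re_order_zero_covariance(self, birth_death):
        st = sse_steady_state(birth_death, order="re")
        mean, cov = moments(st, order="re")
        assert mean[0] == pytest.approx(10.0)
        assert np.all(cov == 0)

    def test_lna_molecule_variance_is_poisson(self, birth_death):
        st = sse_steady_state(birth_death, order="lna")
        _, cov = moments(st, order="lna")
        var_n = birth_death.omega ** 2 * cov[0, 0]
        assert var_n == pytest.approx(birth_death.omega * 10.0, rel=1e-9)

    def test_ios_equals_lna_for_first_order_network(self, linear_gene):
        st = sse_steady_state(linear_gene, order="ios")
        m_l, c_l = moments(st, order="lna")
        m_i, c_i = moments(st, order="ios")
        np.testing.assert_allclose(c_i, c_l, atol=1e-14)
        np.testing.assert_allclose(moments(st, order="emre")[0], m_l,
                                   atol=1e-14)

    def test_order_mismatch_rejected(self, birth_death):
        st = sse_steady_state(birth_death, order="lna")
        with pytest.raises(ValueError, match="cannot report"):
            moments(st, order="ios")


class TestTimecourse:
    @pytest.mark.parametrize("builder,t_end", [
        (lambda: models.birth_death(1.0, 0.1, omega=100.0), 120.0),
        (models.linear_gene, 60.0),
        (lambda: models.dimerization(omega=10.0), 30.0),
        (lambda: models.enzyme_cycle(omega=20.0), 60.0),
    ])
    def test_long_time_limit_matches_algebraic_steady_state(self, builder,
                                                            t_end):
        net = builder()
        tc = sse_timecourse(net, [0.0, t_end], order="ios")
        final = tc.final()
        ss = sse_steady_state(net, order="ios")
        np.testing.assert_allclose(final.X, ss.X, rtol=1e-5, atol=1e-10)
        np.testing.assert_allclose(final.sigma, ss.sigma, rtol=1e-4, atol=1e-8)
        np.testing.assert_allclose(final.eps1, ss.eps1, rtol=1e-4, atol=1e-8)
        np.testing.assert_allclose(final.sigma2, ss.sigma2, rtol=1e-3,
                                   atol=1e-7)

    def test_deterministic_initial_conditions_start_at_zero(self, dimer):
        tc = sse_timecourse(dimer, [0.0, 0.5], order="ios")
        first = tc.state(0)
        assert np.all(first.sigma == 0) and np.all(first.eps1 == 0)
        assert np.all(first.T == 0) and np.all(first.sigma2 == 0)

    def test_packed_state_export(self, dimer):
        tc = sse_timecourse(dimer, [0.0, 1.0], order="ios")
        df = tc.final().to_dataframe()
        assert list(df.block.unique()) == ["X", "sigma", "eps1", "T", "sigma2"]
        assert len(df) == equation_count(1)[0]
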