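"""Unit and property tests for the core kinetic model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import clsecretion as cs
from clsecretion.constants import DEFAULT_G_A0, DEFAULT_V0, FARADAY


class TestBoltzmannFactor:
    @pytest.mark.parametrize(
        "v_mV, expected",
        [(-40, 0.2104), (-70, 0.0654)],
    )
    def test_reference_factors(self, tissue, v_mV, expected):
        """At the default temperature the factors match the published
        worked-example values to ~3 decimals."""
        assert cs.boltzmann_factor(v_mV * 1e-3, tissue.temperature) == pytest.approx(
            expected, abs=2e-4
        )

    def test_identity_at_zero_potential(self, tissue):
        assert cs.boltzmann_factor(0.0, tissue.temperature) == 1.0

    def test_rejects_non_finite(self, tissue):
        with pytest.raises(cs.InvalidInputError):
            cs.boltzmann_factor(float("nan"), tissue.temperature)
        with pytest.raises(cs.InvalidInputError):
            cs.boltzmann_factor(-0.04, float("inf"))


class TestClEquilibrium:
    def test_derived_value_at_minus_40(self, tissue):
        # 127.5 mM * 0.2104 = 26.8 mM
        assert cs.cl_equilibrium(127.5, -40e-3, tissue.temperature) == pytest.approx(
            26.8, abs=0.05
        )

    def test_degenerate_cases(self, tissue):
        assert cs.cl_equilibrium(127.5, 0.0, tissue.temperature) == 127.5
        assert cs.cl_equilibrium(0.0, -40e-3, tissue.temperature) == 0.0


class TestMembraneCurrent:
    def test_zero_exactly_at_equilibrium(self, tissue):
        eq = cs.cl_equilibrium(tissue.cl_out, -40e-3, tissue.temperature)
        assert cs.membrane_current(1e-5, -40e-3, eq, tissue.cl_out, tissue.temperature) == 0.0

    def test_baseline_roundtrip(self, tissue):
        """Inverting the baseline current for cl_in and re-evaluating
        forward reproduces -0.080 uA/cm^2 (and cl_in ~ 32 mM)."""
        g = DEFAULT_G_A0
        i_total = -0.08e-6 * tissue.area
        cl0 = cs.model.cl_in_from_current(g, DEFAULT_V0, i_total, tissue.cl_out, tissue.temperature)
        assert cl0 == pytest.approx(32.0, abs=0.1)
        i_back = cs.membrane_current(g, DEFAULT_V0, cl0, tissue.cl_out, tissue.temperature)
        assert i_back * 1e6 / tissue.area == pytest.approx(-0.080, rel=1e-12)

    def test_voltage_step_worked_example(self, tissue):
        """Re-evaluating the apical chord current at -70 mV from the
        -40 mV baseline state gives -0.5418 uA/cm^2."""
        g = DEFAULT_G_A0
        cl0 = cs.model.cl_in_from_current(
            g, DEFAULT_V0, -0.08e-6 * tissue.area, tissue.cl_out, tissue.temperature
        )
        i = cs.membrane_current(g, -70e-3, cl0, tissue.cl_out, tissue.temperature)
        assert i * 1e6 / tissue.area == pytest.approx(-0.5418, abs=1e-3)

    def test_linear_in_g_and_cl_in(self, tissue):
        i1 = cs.membrane_current(1e-5, -40e-3, 40.0, tissue.cl_out, tissue.temperature)
        assert cs.membrane_current(2e-5, -40e-3, 40.0, tissue.cl_out, tissue.temperature) == pytest.approx(2 * i1)
        eq = cs.cl_equilibrium(tissue.cl_out, -40e-3, tissue.temperature)
        i2 = cs.membrane_current(1e-5, -40e-3, eq + 10, tissue.cl_out, tissue.temperature)
        i3 = cs.membrane_current(1e-5, -40e-3, eq + 20, tissue.cl_out, tissue.temperature)
        assert i3 == pytest.approx(2 * i2, rel=1e-12)

    def test_v0_directs_to_limit(self, tissue):
        with pytest.raises(cs.InvalidInputError):
            cs.membrane_current(1e-5, 0.0, 30.0, tissue.cl_out, tissue.temperature)
        with pytest.raises(cs.InvalidInputError):
            cs.membrane_current(1e-5, -40e-3, -1.0, tissue.cl_out, tissue.temperature)

    @given(
        g=st.floats(1e-7, 1e-3),
        cl_in=st.floats(1.0, 60.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_limit_agreement_near_zero_volt(self, g, cl_in):
        """The chord current converges to its analytic V->0 limit.

        cl_in stays away from the equilibrium crossing at cl_out, where
        the current itself vanishes and a relative measure degenerates.
        """
        T, cl_out = 297.8, 127.5
        lim = cs.membrane_current_v0_limit(g, cl_in, cl_out, T)
        for v in (1e-6, -1e-6):
            i = cs.membrane_current(g, v, cl_in, cl_out, T)
            assert i == pytest.approx(lim, rel=1e-4, abs=1e-30)

    def test_v0_limit_trivia(self, tissue):
        assert cs.membrane_current_v0_limit(1e-5, tissue.cl_out, tissue.cl_out, tissue.temperature) == 0.0
        assert cs.membrane_current_v0_limit(0.0, 30.0, tissue.cl_out, tissue.temperature) == 0.0


class TestFluxConversion:
    def test_sign_and_scale(self):
        assert cs.current_to_molar_flux(-0.0965) == pytest.approx(1.0e-6, rel=1e-3)
        assert cs.current_to_molar_flux(0.0) == 0.0
        assert cs.current_to_molar_flux(-1.0) > 0

    def test_display_flip_once(self, tissue):
        # secretory (negative internal) current displays positive
        assert cs.to_display_current(-0.08e-6 * 0.33, 0.33) == pytest.approx(0.08)


class TestTransporterKinetics:
    def test_fixed_point_and_decay(self):
        p = cs.TransporterParams(ct_total=2.0, alpha=0.3, beta=0.1, flux_per_unit=1.0)
        assert cs.transporter_timecourse(p, 0.5, 1e9) == pytest.approx(
            0.3 * 2.0 / 0.4
        )
        decay = cs.TransporterParams(ct_total=1.0, alpha=0.0, beta=0.2, flux_per_unit=1.0)
        t = np.array([0.0, 1.0, 5.0])
        assert cs.transporter_timecourse(decay, 1.0, t) == pytest.approx(np.exp(-0.2 * t))

    def test_value_at_one_tau2(self):
        p = cs.TransporterParams(ct_total=2.0, alpha=0.3, beta=0.1, flux_per_unit=1.0)
        ct_inf = p.ct_act_inf
        expected = ct_inf + (0.5 - ct_inf) / math.e
        assert cs.transporter_timecourse(p, 0.5, p.tau2) == pytest.approx(expected, rel=1e-12)

    @given(
        alpha=st.floats(1e-4, 1.0),
        beta=st.floats(1e-4, 1.0),
        frac=st.floats(0.0, 1.0),
        t=st.floats(0.0, 1e4),
    )
    @settings(max_examples=100, deadline=None)
    def test_conservation(self, alpha, beta, frac, t):
        """CT_Act + CT_Inact = CT_T at all times (machine precision)."""
        ct_total = 3.7
        p = cs.TransporterParams(ct_total=ct_total, alpha=alpha, beta=beta, flux_per_unit=1.0)
        ct_act = cs.transporter_timecourse(p, frac * ct_total, t)
        ct_inact = ct_total - ct_act
        assert 0 <= ct_act <= ct_total * (1 + 1e-12)
        assert ct_act + ct_inact == pytest.approx(ct_total, rel=1e-15)

    def test_uptake_linearity(self):
        p = cs.TransporterParams(ct_total=2.0, alpha=0.3, beta=0.1, flux_per_unit=2.5)
        assert cs.uptake_flux(p, 0.0) == 0.0
        assert cs.uptake_flux(p, 1.2) == pytest.approx(2 * cs.uptake_flux(p, 0.6))

    def test_invalid_initial_amount(self):
        p = cs.TransporterParams(ct_total=1.0, alpha=0.1, beta=0.1, flux_per_unit=1.0)
        with pytest.raises(cs.InvalidInputError):
            cs.transporter_timecourse(p, 1.5, 0.0)


class TestTauCl:
    def test_plug_in_oracle(self, tissue):
        """Direct arithmetic from the formula's factors."""
        g_total = 372.87e-6
        state = cs.PathwayState(12.87e-6, 360.0e-6, -40e-3)
        e_u = cs.boltzmann_factor(-40e-3, tissue.temperature)
        expected = tissue.cell_volume * FARADAY * (e_u - 1) * tissue.cl_out / (
            -40e-3 * g_total
        )
        assert cs.tau_cl(tissue, state) == pytest.approx(expected, rel=1e-12)
        assert expected > 0

    def test_case1_prefactor(self, tissue):
        """With G_A = 20*G_A0 and G_B = 30*G_A0 the time constant is
        1/50 of the single-conductance reference value."""
        g0 = DEFAULT_G_A0
        ref = cs.tau_cl(tissue, cs.PathwayState(g0, 1e-30, DEFAULT_V0))
        state = cs.PathwayState(20 * g0, 30 * g0, DEFAULT_V0)
        assert cs.tau_cl(tissue, state) == pytest.approx(ref / 50, rel=1e-9)

    @given(
        scale_v=st.floats(0.2, 5.0),
        scale_g=st.floats(0.2, 5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_scaling(self, tissue, baseline_state, scale_v, scale_g):
        """tau1 is proportional to cell volume and inversely
        proportional to total conductance."""
        tau0 = cs.tau_cl(tissue, baseline_state)
        t2 = cs.TissueParams(
            cell_volume=tissue.cell_volume * scale_v,
            area=tissue.area,
            cl_out=tissue.cl_out,
            temperature=tissue.temperature,
        )
        assert cs.tau_cl(t2, baseline_state) == pytest.approx(tau0 * scale_v, rel=1e-12)
        s2 = cs.PathwayState(
            baseline_state.g_apical * scale_g,
            baseline_state.g_basolateral * scale_g,
            baseline_state.v_membrane,
        )
        assert cs.tau_cl(tissue, s2) == pytest.approx(tau0 / scale_g, rel=1e-12)

    def test_positive_for_either_sign_of_v(self, tissue, baseline_state):
        depol = cs.PathwayState(
            baseline_state.g_apical, baseline_state.g_basolateral, +40e-3
        )
        assert cs.tau_cl(tissue, baseline_state) > 0
        assert cs.tau_cl(tissue, depol) > 0


class TestSteadyStateCl:
    def test_passive_equilibrium_without_uptake(self, tissue, baseline_state):
        eq = cs.cl_equilibrium(tissue.cl_out, baseline_state.v_membrane, tissue.temperature)
        assert cs.steady_state_cl(tissue, baseline_state, 0.0) == eq

    def test_baseline_near_32_mM(self, tissue, baseline_state):
        """The uptake flux sustaining 0.08 uA/cm^2 through the baseline
        conductances holds [Cl-]i at ~32 mM."""
        i_total = -0.08e-6 * tissue.area
        j_c = -i_total * 31 / (1 * FARADAY)  # J_C = -I_A*(G_A+G_B)/(G_A*F), ratio 31
        f_inf = cs.steady_state_cl(tissue, baseline_state, j_c)
        assert f_inf == pytest.approx(32.0, abs=0.1)
        # flux balance at the root
        i_tot = cs.membrane_current(
            baseline_state.g_total, baseline_state.v_membrane, f_inf,
            tissue.cl_out, tissue.temperature,
        )
        assert cs.current_to_molar_flux(i_tot) == pytest.approx(j_c, rel=1e-10)

    def test_monotone_in_gb(self, tissue):
        j_c = 1e-11
        lo = cs.steady_state_cl(tissue, cs.PathwayState(1e-5, 3e-4, -40e-3), j_c)
        hi = cs.steady_state_cl(tissue, cs.PathwayState(1e-5, 6e-4, -40e-3), j_c)
        assert hi < lo

    def test_rejects_negative_uptake(self, tissue, baseline_state):
        with pytest.raises(cs.InvalidInputError):
            cs.steady_state_cl(tissue, baseline_state, -1e-12)


class TestSteadyStateRatio:
    @pytest.mark.parametrize(
        "ga, gb, r, jc, expected",
        [
            (20, 1, 30, 1, 12.4),
            (2.5, 1.5, 30, 1, 77.5 / 47.5),
            (18, 18, 30, 1, 1.0),
            (1, 2, 30, 1, 31 / 61),
            (1, 1, 30, 2, 2.0),
        ],
    )
    def test_published_fold_changes(self, ga, gb, r, jc, expected):
        assert cs.steady_state_current_ratio(ga, gb, r, jc) == pytest.approx(
            expected, rel=1e-12
        )

    def test_identity_when_nothing_changes_relatively(self):
        assert cs.steady_state_current_ratio(3.0, 3.0, 17.0, 1.0) == pytest.approx(1.0)

    def test_rejects_nonpositive(self):
        with pytest.raises(cs.InvalidInputError):
            cs.steady_state_current_ratio(0.0, 1.0, 30.0, 1.0)


class TestInstantaneousCurrent:
    @pytest.mark.parametrize("ga_rel, expected_fold", [(20, 20), (5, 5), (18, 18)])
    def test_conductance_step_scales_exactly(self, tissue, baseline_state, ga_rel, expected_fold):
        post = cs.PathwayState(
            baseline_state.g_apical * ga_rel,
            baseline_state.g_basolateral,
            baseline_state.v_membrane,
        )
        i0 = -0.08
        assert cs.instantaneous_current(baseline_state, post, tissue, i0) == pytest.approx(
            expected_fold * i0, rel=1e-12
        )

    @given(gb_rel=st.floats(0.1, 50.0), jc_rel=st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_gb_and_jc(self, tissue, baseline_state, gb_rel, jc_rel):
        """With V fixed the jump depends only on the apical conductance
        change, never on G_B or on uptake."""
        post = cs.PathwayState(
            baseline_state.g_apical * 5,
            baseline_state.g_basolateral * gb_rel,
            baseline_state.v_membrane,
        )
        i = cs.instantaneous_current(baseline_state, post, tissue, -0.08)
        assert i == pytest.approx(5 * -0.08, rel=1e-12)

    def test_voltage_step_value(self, tissue, baseline_state):
        post = cs.PathwayState(
            baseline_state.g_apical, baseline_state.g_basolateral, -70e-3
        )
        i = cs.instantaneous_current(baseline_state, post, tissue, -0.08)
        assert i == pytest.approx(-0.5418, abs=1e-3)
        assert abs(i) / 0.08 == pytest.approx(6.8, abs=0.1)

    def test_rejects_zero_baseline(self, tissue, baseline_state):
        with pytest.raises(cs.InvalidInputError):
            cs.instantaneous_current(baseline_state, baseline_state, tissue, 0.0)


class TestAnalyticSolution:
    def test_constant_uptake_is_single_exponential(self, tissue):
        """With dCT = 0 the relaxation of [Cl-]i is a single exponential
        with time constant tau1."""
        p = cs.build_protocol(tissue, ga_rel=20, gb_rel=1)
        tau1 = cs.tau_cl(tissue, p.post)
        trace = cs.analytic_solution(tissue, p, np.linspace(0, 10 * tau1, 400))
        f_inf = cs.steady_state_cl(tissue, p.post, p.jc_inf)
        resid = trace.cl_in - f_inf
        logr = np.log(np.abs(resid[np.abs(resid) > 1e-9]))
        slope = np.polyfit(trace.t[: len(logr)], logr, 1)[0]
        assert -1 / slope == pytest.approx(tau1, rel=1e-6)

    def test_biphasic_genistein_shape(self, tissue):
        """Five-fold jump, dip below the eventual plateau, then rise to
        3.72-fold."""
        p = cs.build_scenario("genistein", tissue)
        trace = cs.analytic_solution(tissue, p)
        post = trace.i_apical[trace.t >= 0]
        i0 = trace.i_apical[trace.t < 0][0]
        assert post[0] / i0 == pytest.approx(5.0, rel=1e-9)
        assert post[-1] / i0 == pytest.approx(
            cs.steady_state_current_ratio(5, 4, 30, 3), rel=1e-6
        )
        k_min = np.argmin(post)
        assert 0 < k_min < len(post) - 1  # interior minimum: dip then rise
        assert post[k_min] < post[-1]

    def test_confluent_equal_tau_limit(self, tissue, caplog):
        """When tau2 = tau1 the confluent t*exp(-t/tau) branch engages
        and matches a nearby non-degenerate solution."""
        tau1 = cs.tau_cl(
            tissue, cs.PathwayState(DEFAULT_G_A0, 30 * DEFAULT_G_A0, DEFAULT_V0)
        )
        grid = np.linspace(0, 5 * tau1, 200)
        p_eq = cs.build_protocol(tissue, ga_rel=1, gb_rel=1, jc_rel=2, tau2=tau1)
        with caplog.at_level("INFO", logger="clsecretion.model"):
            trace_eq = cs.analytic_solution(tissue, p_eq, grid)
        assert any("confluent" in r.message for r in caplog.records)
        p_near = cs.build_protocol(tissue, ga_rel=1, gb_rel=1, jc_rel=2, tau2=tau1 * (1 + 1e-7))
        trace_near = cs.analytic_solution(tissue, p_near, grid)
        np.testing.assert_allclose(trace_eq.cl_in, trace_near.cl_in, rtol=1e-5)

    def test_steady_ratio_identity_at_long_horizon(self, tissue):
        """The t -> horizon fold-change of the trace agrees with the
        closed-form steady-state ratio when horizon >= 20 max(tau)."""
        for name, (ga, gb, r, jc) in {
            "forskolin_pki": (20, 1, 30, 1),
            "apigenin": (1, 1, 30, 2),
            "genistein": (5, 4, 30, 3),
        }.items():
            p = cs.build_scenario(name, tissue)
            trace = cs.analytic_solution(tissue, p)
            fold = trace.i_apical[-1] / trace.i_apical[trace.t < 0][0]
            assert fold == pytest.approx(
                cs.steady_state_current_ratio(ga, gb, r, jc), rel=1e-6
            )


class TestTypeInvariants:
    def test_tissue_params_validation(self):
        with pytest.raises(cs.InvalidInputError):
            cs.TissueParams(temperature=250.0)
        with pytest.raises(cs.InvalidInputError):
            cs.TissueParams(cell_volume=-1.0)

    def test_pathway_state_validation(self):
        with pytest.raises(cs.InvalidInputError):
            cs.PathwayState(0.0, 0.0, -40e-3)
        with pytest.raises(cs.InvalidInputError):
            cs.PathwayState(-1e-6, 1e-6, -40e-3)

    def test_trace_requires_increasing_time(self):
        t = np.array([0.0, 1.0, 1.0])
        arr = np.ones(3)
        with pytest.raises(cs.InvalidInputError):
            cs.SecretionTrace(t=t, cl_in=arr, i_apical=arr, i_basolateral=arr, i_uptake=arr)
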