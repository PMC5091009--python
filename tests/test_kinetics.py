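"""Trace normalization, exponential fitting, chevron assembly and fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barrelkit import kinetics, synth
from barrelkit.io import Arm, KineticTrace, R_KCAL, SignalKind, ValidationError

RT25 = R_KCAL * 298.15


def aniso_trace(k=0.005, r_F=0.25, r_U=0.15, n=96, t_max=1500.0, dead=25.0):
    t = np.linspace(0.0, t_max, n)
    r = r_F - (r_F - r_U) * np.exp(-k * t)
    keep = t >= dead
    return KineticTrace(time=t[keep], signal=r[keep],
                        signal_kind=SignalKind.ANISOTROPY, dead_time=dead)


class TestNormalizeAnisotropy:
    @pytest.mark.parametrize("r,expected", [(0.25, 1.0), (0.15, 0.0), (0.20, 0.5)])
    def test_endpoint_mapping(self, r, expected):
        trace = KineticTrace(time=np.linspace(0, 9, 10), signal=np.full(10, r),
                             signal_kind=SignalKind.ANISOTROPY)
        ep = kinetics.AnisotropyEndpoints(r_F=0.25, r_U=0.15)
        out = kinetics.normalize_anisotropy(trace, ep)
        np.testing.assert_allclose(out.signal, expected, atol=1e-12)

    def test_equal_endpoints_rejected(self):
        with pytest.raises(ValidationError):
            kinetics.AnisotropyEndpoints(r_F=0.2, r_U=0.2)

    def test_intensity_trace_rejected(self):
        trace = KineticTrace(time=np.linspace(0, 9, 10), signal=np.ones(10))
        with pytest.raises(ValidationError):
            kinetics.normalize_anisotropy(trace, kinetics.AnisotropyEndpoints(0.25, 0.15))


class TestFitExponential:
    def test_single_phase_exact(self):
        t = np.linspace(0, 600, 80)
        trace = KineticTrace(time=t, signal=0.3 + 0.5 * np.exp(-0.01 * t))
        fit = kinetics.fit_exponential(trace, 1)
        assert fit.phases[0][0] == pytest.approx(0.01, rel=1e-8)
        assert fit.phases[0][1] == pytest.approx(0.5, rel=1e-8)
        assert fit.offset == pytest.approx(0.3, rel=1e-8)

    def test_double_phase_exact(self):
        t = np.linspace(0, 300, 200)
        trace = KineticTrace(
            time=t, signal=0.1 + 0.4 * np.exp(-0.5 * t) + 0.3 * np.exp(-0.02 * t))
        fit = kinetics.fit_exponential(trace, 2)
        (k1, a1), (k2, a2) = fit.phases          # sorted fast -> slow
        assert k1 == pytest.approx(0.5, rel=1e-6)
        assert k2 == pytest.approx(0.02, rel=1e-6)
        assert a1 == pytest.approx(0.4, rel=1e-6)
        assert a2 == pytest.approx(0.3, rel=1e-6)

    def test_constant_trace_degenerate(self):
        trace = KineticTrace(time=np.linspace(0, 100, 20), signal=np.full(20, 2.0))
        with pytest.warns(UserWarning, match="constant"):
            fit = kinetics.fit_exponential(trace, 1)
        assert fit.phases[0][1] == 0.0

    def test_dead_time_rate_unbiased(self):
        """Losing the first 25 s of a slow anisotropy rise leaves the rate intact."""
        fit = kinetics.fit_exponential(aniso_trace(k=0.005), 1)
        assert fit.phases[0][0] == pytest.approx(0.005, rel=0.02)

    def test_f_test_model_comparison(self):
        t = np.linspace(0, 300, 150)
        rng = np.random.default_rng(5)
        two = 0.1 + 0.4 * np.exp(-0.5 * t) + 0.3 * np.exp(-0.02 * t)
        one = 0.1 + 0.5 * np.exp(-0.05 * t)
        noise = 0.002 * rng.standard_normal(t.size)
        n2, _ = kinetics.compare_exponential_models(KineticTrace(time=t, signal=two + noise))
        n1, _ = kinetics.compare_exponential_models(KineticTrace(time=t, signal=one + noise))
        assert n2 == 2
        assert n1 == 1


def chevron_data(**truth):
    dataset, sidecar = synth.generate(synth.GeneratorSpec(stage="chevron", truth=truth))
    return dataset, sidecar


class TestAssembleChevron:
    def _fits(self):
        out = []
        for i, D in enumerate(np.linspace(0.8, 1.68, 6)):
            fit = kinetics.ExponentialFit(phases=[(0.5, 0.6), (0.02, 0.4)], offset=0.0,
                                          n_phases=2)
            out.append((D, fit, Arm.FOLDING))
        for D in np.linspace(1.72, 3.0, 6):
            fit = kinetics.ExponentialFit(phases=[(0.01, 1.0)], offset=0.0, n_phases=1)
            out.append((D, fit, Arm.UNFOLDING))
        return out

    def test_count_conserved(self):
        dataset = kinetics.assemble_chevron(self._fits())
        assert len(dataset) == 12

    def test_dominant_amplitude_rule(self):
        dataset = kinetics.assemble_chevron(self._fits(), "dominant_amplitude")
        D, rates = dataset.arm(Arm.FOLDING)
        np.testing.assert_allclose(rates, 0.5)   # amplitude 0.6 beats 0.4

    def test_slowest_rule(self):
        dataset = kinetics.assemble_chevron(self._fits(), "slowest")
        _, rates = dataset.arm(Arm.FOLDING)
        np.testing.assert_allclose(rates, 0.02)

    def test_duplicate_denaturant_retained_with_warning(self):
        fits = self._fits()
        fits.append(fits[0])
        with pytest.warns(UserWarning, match="duplicate"):
            dataset = kinetics.assemble_chevron(fits)
        assert len(dataset) == 13


class TestFitChevron:
    def test_noiseless_linear_recovery(self):
        dataset, truth = chevron_data(ln_kf_H2O=0.0, mF_kin=-1.5,
                                      ln_ku_H2O=-6.0, mU_kin=1.5)
        fit = kinetics.fit_chevron(dataset)
        assert fit.ln_kf_H2O == pytest.approx(0.0, abs=1e-9)
        assert fit.mF_kin == pytest.approx(-1.5, rel=1e-9)
        assert fit.ln_ku_H2O == pytest.approx(-6.0, rel=1e-9)
        assert fit.mU_kin == pytest.approx(1.5, rel=1e-9)

    def test_quadratic_recovery_with_rollover(self):
        dataset, _ = chevron_data(mU1_kin=-0.3)
        fit = kinetics.fit_chevron(dataset, model="quadratic_unfolding")
        assert fit.mU1_kin == pytest.approx(-0.3, rel=1e-8)

    def test_quadratic_nests_linear(self):
        # on data generated without curvature the quadratic term vanishes
        dataset, _ = chevron_data(mU1_kin=0.0)
        lin = kinetics.fit_chevron(dataset, model="linear")
        quad = kinetics.fit_chevron(dataset, model="quadratic_unfolding")
        assert quad.mU1_kin == pytest.approx(0.0, abs=1e-9)
        D = np.linspace(1.72, 3.0, 50)
        pred_l = lin.ln_ku_H2O + lin.mU_kin * D / RT25
        pred_q = quad.ln_ku_H2O + quad.mU_kin * D / RT25 + quad.mU1_kin * D ** 2
        np.testing.assert_allclose(pred_l, pred_q, atol=1e-6)

    def test_quadratic_residual_never_larger(self):
        dataset, _ = chevron_data(mU1_kin=-0.3)
        lin = kinetics.fit_chevron(dataset, model="linear")
        quad = kinetics.fit_chevron(dataset, model="quadratic_unfolding")
        assert quad.residual_norm <= lin.residual_norm + 1e-12

    def test_window_excluding_all_points_errors(self):
        dataset, _ = chevron_data()
        with pytest.raises(ValidationError, match="window"):
            kinetics.fit_chevron(dataset, folding_window=(5.0, 6.0))

    def test_chevron_minimum_closed_form(self):
        dataset, _ = chevron_data()
        fit = kinetics.fit_chevron(dataset)
        D_star = kinetics.chevron_minimum(fit)
        # arms predict equal rates at the minimum
        ln_kf = fit.ln_kf_H2O + fit.mF_kin * D_star / RT25
        ln_ku = fit.ln_ku_H2O + fit.mU_kin * D_star / RT25
        assert ln_kf == pytest.approx(ln_ku, abs=1e-6)


class TestDgKinAndBeta:
    def test_equal_intercepts_zero_energy(self):
        fit = _fit_with(ln_kf=2.0, ln_ku=2.0)
        assert kinetics.dg_kin(fit) == pytest.approx(0.0, abs=1e-12)

    def test_rate_ratio_e_gives_minus_rt(self):
        fit = _fit_with(ln_kf=1.0, ln_ku=0.0)
        assert kinetics.dg_kin(fit) == pytest.approx(-0.5925, abs=5e-4)

    def test_swapping_rates_flips_sign(self):
        a = kinetics.dg_kin(_fit_with(ln_kf=1.3, ln_ku=-0.7))
        b = kinetics.dg_kin(_fit_with(ln_kf=-0.7, ln_ku=1.3))
        assert a == pytest.approx(-b, rel=1e-12)

    def test_dg_consistency_with_arm_lines_at_zero_denaturant(self):
        dataset, _ = chevron_data()
        fit = kinetics.fit_chevron(dataset)
        expected = -(RT25 * fit.ln_kf_H2O - RT25 * fit.ln_ku_H2O)
        assert fit.dG0_kin == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("mF,mU,expected", [(-1.5, 1.5, 0.5), (-3.0, 1.0, 0.75)])
    def test_tanford_beta_values(self, mF, mU, expected):
        fit = _fit_with(mF=mF, mU=mU)
        assert kinetics.tanford_beta(fit) == pytest.approx(expected, rel=1e-12)

    def test_symmetric_chevron_beta_half(self):
        # symmetric arms place the transition state midway, beta_T = 0.5
        dataset, _ = chevron_data(mF_kin=-1.5, mU_kin=1.5)
        fit = kinetics.fit_chevron(dataset)
        assert fit.beta_T == pytest.approx(0.5, abs=1e-9)

    def test_equal_slopes_rejected(self):
        with pytest.raises(ZeroDivisionError):
            kinetics.tanford_beta(_fit_with(mF=1.0, mU=1.0))

    @given(st.floats(min_value=-5.0, max_value=-0.01),
           st.floats(min_value=0.01, max_value=5.0))
    @settings(max_examples=100, deadline=None)
    def test_beta_in_unit_interval_for_canonical_slopes(self, mF, mU):
        beta = kinetics.tanford_beta(_fit_with(mF=mF, mU=mU))
        assert 0.0 < beta < 1.0


def _fit_with(ln_kf=0.0, ln_ku=-6.0, mF=-1.5, mU=1.5):
    return kinetics.ChevronFit(ln_kf_H2O=ln_kf, ln_ku_H2O=ln_ku, mF_kin=mF,
                               mU_kin=mU, mU1_kin=0.0, dG0_kin=float("nan"),
                               beta_T=float("nan"), temperature=298.15,
                               model="linear")
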