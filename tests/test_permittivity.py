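import math

import numpy as np
import pytest
from scipy import special

from mwdebye.errors import ParameterDomainError, SpectrumValidationError
from mwdebye.mwdist import MWParameters, SpeciesComponent
from mwdebye.permittivity import (
    EPS0_PAPER,
    ColeParameters,
    DielectricModel,
    Spectrum,
    cole_eps,
    convert_amplitude,
    convert_amplitude_inverse,
    eps_complex,
    eps_imag,
    eps_imag_ac,
    eps_real,
    legacy_eps_imag,
)
from tests.conftest import BLOOD

SQRT2 = math.sqrt(2.0)


def debye_complex(w, eps_inf, delta_eps, tau, sigma_dc, eps0=EPS0_PAPER):
    return eps_inf + delta_eps / (1 + 1j * w * tau) - 1j * sigma_dc / (w * eps0)


def make_model(ts, tau_c, delta_eps=100.0, eps_inf=5.0, sigma_dc=0.0):
    return DielectricModel.single_species(
        eps_inf=eps_inf, delta_eps=delta_eps, sigma_dc=sigma_dc, ts=ts, tau_c=tau_c
    )


class TestModelValidation:
    def test_invariants_enforced(self, blood_params):
        comp = SpeciesComponent(params=blood_params, weight=1.0)
        with pytest.raises(ParameterDomainError):
            DielectricModel(eps_inf=0.5, delta_eps=1.0, sigma_dc=0.0, components=(comp,))
        with pytest.raises(ParameterDomainError):
            DielectricModel(eps_inf=2.0, delta_eps=-1.0, sigma_dc=0.0, components=(comp,))
        with pytest.raises(ParameterDomainError):
            DielectricModel(eps_inf=2.0, delta_eps=1.0, sigma_dc=-0.1, components=(comp,))
        bad = SpeciesComponent(params=blood_params, weight=0.6)
        with pytest.raises(ParameterDomainError):
            DielectricModel(eps_inf=2.0, delta_eps=1.0, sigma_dc=0.0, components=(bad,))

    def test_spectrum_validation(self):
        f = np.array([1.0, 2.0, 3.0])
        ones = np.ones(3)
        with pytest.raises(SpectrumValidationError):
            Spectrum(frequency_hz=f[::-1], eps_real=ones, eps_imag=ones)
        with pytest.raises(SpectrumValidationError):
            Spectrum(frequency_hz=np.array([-1.0, 2.0, 3.0]), eps_real=ones, eps_imag=ones)
        with pytest.raises(SpectrumValidationError):
            Spectrum(frequency_hz=f, eps_real=ones, eps_imag=ones, eps_imag_ac=2 * ones)
        spec = Spectrum(frequency_hz=f, eps_real=ones, eps_imag=ones, eps_imag_ac=0.5 * ones)
        assert len(spec) == 3


class TestEpsRealImag:
    def test_static_limit(self, blood_model):
        value = eps_real(1.0, blood_model, method="oracle")
        assert value == pytest.approx(blood_model.eps_dc, rel=1e-10)

    def test_high_frequency_limits(self, blood_model):
        w = 2 * math.pi * 1e14
        assert eps_real(w, blood_model) == pytest.approx(blood_model.eps_inf, rel=1e-6)
        no_dc = DielectricModel.single_species(
            eps_inf=10.0, delta_eps=BLOOD["delta_eps"], sigma_dc=0.0,
            ts=BLOOD["ts"], tau_c=BLOOD["tau_c"],
        )
        assert eps_imag(w, no_dc) < 1e-3

    @pytest.mark.parametrize("f", [1e5, 1e6, 1e7, 1e8, 1e9])
    def test_series_matches_oracle(self, blood_model, f):
        w = 2 * math.pi * f
        assert eps_real(w, blood_model, "series") == pytest.approx(
            eps_real(w, blood_model, "oracle"), rel=1e-4
        )
        assert eps_imag(w, blood_model, "series") == pytest.approx(
            eps_imag(w, blood_model, "oracle"), rel=1e-4
        )

    def test_point_mass_debye_limit(self):
        tau = 2.434e-8
        model = make_model(ts=tau * 1e-3, tau_c=tau, delta_eps=1000.0)
        for f in np.logspace(5, 9, 9):
            w = 2 * math.pi * f
            ref = debye_complex(w, 5.0, 1000.0, tau, 0.0)
            assert eps_real(w, model) == pytest.approx(ref.real, rel=0.01)
            assert eps_imag(w, model) == pytest.approx(-ref.imag, rel=0.01)

    def test_real_monotone_and_bounded(self, rng):
        for _ in range(3):
            model = make_model(
                ts=10 ** rng.uniform(-8, -7),
                tau_c=10 ** rng.uniform(-8.5, -7.5),
                delta_eps=10 ** rng.uniform(2, 4),
                sigma_dc=rng.uniform(0, 1),
            )
            w = 2 * math.pi * np.logspace(4, 10, 50)
            er = np.asarray(eps_real(w, model))
            assert np.all(np.diff(er) < 0)
            assert np.all(er <= model.eps_dc + 1e-9 * model.eps_dc)
            assert np.all(er >= model.eps_inf - 1e-12)

    def test_domain_errors(self, blood_model):
        with pytest.raises(ParameterDomainError):
            eps_real(0.0, blood_model)
        with pytest.raises(ParameterDomainError):
            eps_real(1.0, blood_model, method="approx")
        with pytest.raises(ParameterDomainError):
            eps_imag(-1.0, blood_model)


class TestEpsImagAc:
    def test_sigma_zero_equals_imag(self):
        model = make_model(ts=1e-7, tau_c=3e-8)
        w = 2 * math.pi * np.logspace(5, 9, 10)
        np.testing.assert_allclose(
            np.asarray(eps_imag_ac(w, model)), np.asarray(eps_imag(w, model)), rtol=1e-12
        )

    def test_bounded_where_conductivity_dominates(self, blood_model):
        w = 2 * math.pi * 1e3
        raw = eps_imag(w, blood_model, method="oracle")
        ac = eps_imag_ac(w, blood_model, method="oracle")
        sigma_term = blood_model.sigma_dc / (w * blood_model.eps0)
        assert raw > 0.9 * sigma_term  # conductivity dominates
        assert 0.0 <= ac < 0.05 * raw

    def test_nonnegative_and_vanishing_at_extremes(self, blood_model):
        w = 2 * math.pi * np.logspace(2, 12, 40)
        ac = np.asarray(eps_imag_ac(w, blood_model))
        assert np.all(ac >= -1e-9)
        peak = ac.max()
        assert ac[0] < 0.02 * peak and ac[-1] < 0.02 * peak

    def test_peak_not_at_inverse_tau_c(self, blood_model):
        # asymmetry of the relaxation-time law shifts the loss peak away
        # from w = 1/tau_c
        f = np.logspace(5, 8, 400)
        ac = np.asarray(eps_imag_ac(2 * math.pi * f, blood_model))
        f_peak = f[np.argmax(ac)]
        w_peak = 2 * math.pi * f_peak
        assert abs(w_peak * BLOOD["tau_c"] - 1.0) > 0.5


class TestApproxMethod:
    def test_error_within_propagated_kernel_bound(self, blood_model):
        # |eps''_ac(approx) - eps''_ac(oracle)| <= delta_eps * 0.0185
        #   * sqrt(pi) * (1 + erf(r)) * sqrt(2) / (2 * w * Ts * c)
        params = blood_model.components[0].params
        r = params.ratio
        for f in np.logspace(5, 9, 25):
            w = 2 * math.pi * f
            approx = eps_imag_ac(w, blood_model, method="approx")
            oracle = eps_imag_ac(w, blood_model, method="oracle")
            bound = (
                0.0185 * blood_model.delta_eps * math.sqrt(math.pi)
                * (1 + special.erf(r)) * SQRT2 / (2 * w * params.ts * params.c)
            )
            assert abs(approx - oracle) <= bound

    def test_approx_tracks_oracle_near_peak(self, blood_model):
        w = 2 * math.pi * 2e6
        approx = eps_imag_ac(w, blood_model, method="approx")
        oracle = eps_imag_ac(w, blood_model, method="oracle")
        assert approx == pytest.approx(oracle, rel=0.02)


class TestEpsComplex:
    def test_components_match(self, blood_model):
        w = 2 * math.pi * 3e6
        z = eps_complex(w, blood_model)
        assert z.real == eps_real(w, blood_model)
        assert -z.imag == eps_imag(w, blood_model)

    def test_single_debye_identity(self):
        tau = 5e-8
        model = make_model(ts=tau * 1e-3, tau_c=tau, delta_eps=500.0, sigma_dc=0.2)
        w = 2 * math.pi * 1e7
        ref = debye_complex(w, 5.0, 500.0, tau, 0.2)
        z = eps_complex(w, model)
        assert z.real == pytest.approx(ref.real, rel=0.01)
        assert z.imag == pytest.approx(ref.imag, rel=0.01)

    def test_methods_agree(self, blood_model):
        w = 2 * math.pi * 1e7
        z_series = eps_complex(w, blood_model, method="series")
        z_oracle = eps_complex(w, blood_model, method="oracle")
        assert z_series.real == pytest.approx(z_oracle.real, rel=1e-4)
        assert z_series.imag == pytest.approx(z_oracle.imag, rel=1e-4)


class TestCole:
    def test_alpha_one_is_debye(self):
        params = ColeParameters(eps_inf=4.0, delta_eps=80.0, tau=1e-8, alpha=1.0)
        w = 2 * math.pi * np.logspace(6, 9, 10)
        expected = 4.0 + 80.0 / (1 + 1j * w * 1e-8)
        np.testing.assert_allclose(np.asarray(cole_eps(w, params)), expected, rtol=1e-13)

    def test_alpha_to_zero_flattens(self):
        params = ColeParameters(eps_inf=4.0, delta_eps=80.0, tau=1e-8, alpha=1e-8)
        for f in (1e5, 1e7, 1e9):
            z = cole_eps(2 * math.pi * f, params)
            assert z == pytest.approx(4.0 + 40.0, rel=1e-6)

    def test_against_direct_complex_arithmetic(self):
        params = ColeParameters(eps_inf=3.0, delta_eps=50.0, tau=2e-9, alpha=0.8)
        w = 2 * math.pi * 5e7
        expected = 3.0 + 50.0 / (1 + (1j * w * 2e-9) ** 0.8)
        assert cole_eps(w, params) == pytest.approx(expected)
        assert params.cole_parameter == pytest.approx(0.2)

    def test_alpha_domain(self):
        with pytest.raises(ParameterDomainError):
            ColeParameters(eps_inf=4.0, delta_eps=80.0, tau=1e-8, alpha=1.5)
        with pytest.raises(ParameterDomainError):
            ColeParameters(eps_inf=4.0, delta_eps=80.0, tau=1e-8, alpha=0.0)


class TestLegacyModel:
    def test_converted_amplitude_reproduces_corrected_curve(self, blood_model):
        comp = blood_model.components[0]
        legacy_amp = convert_amplitude(blood_model.delta_eps, comp)
        f = np.logspace(5, 9, 50)
        w = 2 * math.pi * f
        legacy = np.asarray(legacy_eps_imag(w, blood_model, legacy_amp))
        corrected = np.asarray(eps_imag(w, blood_model, method="oracle"))
        np.testing.assert_allclose(legacy, corrected, rtol=1e-6)

    def test_conductivity_term_identical(self, blood_model):
        w = 2 * math.pi * 1e3
        sigma_term = blood_model.sigma_dc / (w * blood_model.eps0)
        legacy = legacy_eps_imag(w, blood_model, 1e-30)  # dispersive part suppressed
        assert legacy == pytest.approx(sigma_term, rel=1e-10)

    def test_point_mass_is_debye_up_to_amplitude(self):
        tau = 3e-8
        model = make_model(ts=tau * 1e-3, tau_c=tau, delta_eps=1.0)
        w = 2 * math.pi * np.logspace(6, 8, 7)
        legacy = np.asarray(legacy_eps_imag(w, model, 1.0))
        debye_shape = w * tau / (1 + (w * tau) ** 2)
        ratio = legacy / debye_shape
        np.testing.assert_allclose(ratio, ratio[0], rtol=0.01)


class TestConvertAmplitude:
    def test_published_worked_example(self, blood_component):
        legacy = convert_amplitude(BLOOD["delta_eps"], blood_component)
        assert legacy == pytest.approx(BLOOD["legacy_delta_eps"], rel=1e-3)

    def test_tau_c_zero_reduces(self):
        ts = 4e-8
        comp = SpeciesComponent(params=MWParameters.from_spectroscopy(ts=ts, tau_c=0.0), weight=1.0)
        assert convert_amplitude(7.0, comp) == pytest.approx(
            7.0 * math.sqrt(2 * math.pi) / ts, rel=1e-13
        )

    def test_round_trip(self, blood_component):
        forward = convert_amplitude(123.4, blood_component)
        assert convert_amplitude_inverse(forward, blood_component) == pytest.approx(
            123.4, rel=1e-14
        )

    def test_zero_weight_rejected(self, blood_params):
        comp = SpeciesComponent(params=blood_params, weight=0.0)
        with pytest.raises(ParameterDomainError):
            convert_amplitude(1.0, comp)
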