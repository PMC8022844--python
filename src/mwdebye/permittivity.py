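"""Forward evaluation of complex permittivity for Modified-Weibull mixtures.

The model is a superposition of Debye relaxators whose relaxation times
follow a (mixture of) Modified-Weibull law(s):

    eps*(w) = eps_inf + delta_eps * int_0^inf f(tau) / (1 + j w tau) dtau
              - j * sigma_dc / (w * eps0)

After the substitution y = w*tau each species' contribution reduces to the
rational-kernel integrals I_1 / I_2 of :mod:`mwdebye.kernels` with arguments
``a = w*tau_c`` and ``b = sqrt(2)*w*Ts``:

    eps'(w)  = eps_inf + delta_eps * sum_k r_k * I_1(a_k, b_k) / (w^2 Ts_k^2 c_k)
    eps''(w) =           delta_eps * sum_k r_k * I_2(a_k, b_k) / (w^2 Ts_k^2 c_k)
               + sigma_dc / (w * eps0)

Three methods are exposed: ``oracle`` (adaptive quadrature of the tau-domain
integrand, sharing no code with the series route), ``series`` (Gauss-Laguerre
node sums with automatic order escalation), and, for the imaginary part only,
``approx`` (the closed erf form obtained by replacing y^2/(1+y^2) with the
order-3 exponential-sum surrogate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate, special

from . import kernels, mwdist
from .errors import ParameterDomainError, SpectrumValidationError
from .mwdist import MWParameters, SpeciesComponent, gaussian_labelled_norm

__all__ = [
    "EPS0_PAPER",
    "DielectricModel",
    "Spectrum",
    "ColeParameters",
    "eps_real",
    "eps_imag",
    "eps_complex",
    "eps_imag_ac",
    "cole_eps",
    "legacy_eps_imag",
    "convert_amplitude",
    "convert_amplitude_inverse",
]

#: Vacuum permittivity as printed in the worked blood example, F/m.
EPS0_PAPER = 8.854e-12

_SQRT2 = math.sqrt(2.0)
_SQRT_2PI = math.sqrt(2.0 * math.pi)

_METHODS_REAL = ("oracle", "series")
_METHODS_IMAG = ("oracle", "series", "approx")


@dataclass(frozen=True)
class DielectricModel:
    """Static dielectric parameters plus the mixture of relaxation-time laws."""

    eps_inf: float
    delta_eps: float
    sigma_dc: float
    components: tuple
    eps0: float = EPS0_PAPER

    def __post_init__(self) -> None:
        if not self.delta_eps > 0:
            raise ParameterDomainError(f"delta_eps must be positive, got {self.delta_eps!r}")
        if not self.eps_inf >= 1.0:
            raise ParameterDomainError(f"eps_inf must be >= 1, got {self.eps_inf!r}")
        if not self.sigma_dc >= 0.0:
            raise ParameterDomainError(f"sigma_dc must be >= 0, got {self.sigma_dc!r}")
        if not self.eps0 > 0.0:
            raise ParameterDomainError(f"eps0 must be positive, got {self.eps0!r}")
        object.__setattr__(self, "components", tuple(self.components))
        total = sum(comp.weight for comp in self.components)
        if not self.components or abs(total - 1.0) > mwdist.WEIGHT_SUM_TOL:
            raise ParameterDomainError(
                f"component weights must sum to 1 within {mwdist.WEIGHT_SUM_TOL}, got {total!r}"
            )

    @property
    def eps_dc(self) -> float:
        return self.eps_inf + self.delta_eps

    @classmethod
    def single_species(
        cls,
        eps_inf: float,
        delta_eps: float,
        sigma_dc: float,
        ts: float,
        tau_c: float,
        label: str = "RBC",
        eps0: float = EPS0_PAPER,
    ) -> "DielectricModel":
        comp = SpeciesComponent(
            params=MWParameters.from_spectroscopy(ts=ts, tau_c=tau_c), weight=1.0, label=label
        )
        return cls(eps_inf=eps_inf, delta_eps=delta_eps, sigma_dc=sigma_dc,
                   components=(comp,), eps0=eps0)


@dataclass(frozen=True)
class Spectrum:
    """A measured or simulated spectrum on a strictly increasing frequency grid."""

    frequency_hz: np.ndarray
    eps_real: np.ndarray
    eps_imag: np.ndarray
    eps_imag_ac: np.ndarray | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.frequency_hz, float)
        er = np.asarray(self.eps_real, float)
        ei = np.asarray(self.eps_imag, float)
        object.__setattr__(self, "frequency_hz", f)
        object.__setattr__(self, "eps_real", er)
        object.__setattr__(self, "eps_imag", ei)
        if f.ndim != 1 or er.shape != f.shape or ei.shape != f.shape:
            raise SpectrumValidationError("frequency/eps arrays must be 1-d of equal length")
        if not np.all(f > 0):
            raise SpectrumValidationError("frequencies must be strictly positive")
        if not np.all(np.diff(f) > 0):
            raise SpectrumValidationError("frequencies must be strictly increasing and unique")
        if self.eps_imag_ac is not None:
            ac = np.asarray(self.eps_imag_ac, float)
            object.__setattr__(self, "eps_imag_ac", ac)
            if ac.shape != f.shape:
                raise SpectrumValidationError("eps_imag_ac must match the frequency grid")
            if np.any(ac > ei + 1e-9 * np.maximum(np.abs(ei), 1.0)):
                raise SpectrumValidationError(
                    "eps_imag_ac must not exceed eps_imag (sigma_dc >= 0)"
                )

    def __len__(self) -> int:
        return self.frequency_hz.size

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies, rad/s."""
        return 2.0 * math.pi * self.frequency_hz


@dataclass(frozen=True)
class ColeParameters:
    """Cole-equation parameters; the Cole parameter itself is alpha_c = 1 - alpha."""

    eps_inf: float
    delta_eps: float
    tau: float
    alpha: float

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ParameterDomainError(f"alpha must lie in (0, 1], got {self.alpha!r}")
        if not self.tau > 0:
            raise ParameterDomainError(f"tau must be positive, got {self.tau!r}")

    @property
    def cole_parameter(self) -> float:
        return 1.0 - self.alpha


def _check_omega(w) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ParameterDomainError("angular frequency w must be strictly positive")
    return w


# ---------------------------------------------------------------------------
# Per-species normalised integrals
# ---------------------------------------------------------------------------

def _species_integral_oracle(p: int, w: float, params: MWParameters) -> float:
    """tau-domain quadrature of int q(tau) * (w tau)^(p-1) / (1 + w^2 tau^2) dtau.

    p=1 gives the eps' kernel, p=2 the eps'' kernel.  The support is truncated
    at gamma + 12*eta after checking the discarded tail mass is < 1e-14.
    """
    eta, gamma, c = params.eta, params.gamma, params.c
    hi = max(gamma, 0.0) + 12.0 * eta
    tail = 1.0 - mwdist.mw_cdf(hi, params)
    if tail > 1e-14:  # pragma: no cover - 12 eta leaves ~1e-60
        raise ParameterDomainError(f"truncated tail mass {tail!r} exceeds 1e-14")

    def integrand(tau: float) -> float:
        q = 2.0 / (eta * c) * (tau / eta) * math.exp(-(((tau - gamma) / eta) ** 2))
        return q * (w * tau) ** (p - 1) / (1.0 + (w * tau) ** 2)

    interior = [x for x in (gamma,) if 0.0 < x < hi]
    value, _ = integrate.quad(
        integrand, 0.0, hi, points=interior or None, limit=200, epsabs=1e-13, epsrel=1e-10
    )
    return value


def _species_integral_series(p: int, w: np.ndarray, params: MWParameters) -> np.ndarray:
    a = w * params.tau_c
    b = w * params.eta  # eta = sqrt(2) * Ts
    return kernels.i_p_series_auto_vec(p, a, b) / (w * w * params.ts**2 * params.c)


def _dispersive_sum(p: int, w: np.ndarray, model: DielectricModel, method: str) -> np.ndarray:
    out = np.zeros_like(w)
    for comp in model.components:
        if comp.weight == 0.0:
            continue
        if method == "oracle":
            vals = np.array([_species_integral_oracle(p, wi, comp.params) for wi in w.ravel()])
        else:
            vals = _species_integral_series(p, w.ravel(), comp.params)
        out += comp.weight * vals.reshape(w.shape)
    return out


def _imag_approx(w: np.ndarray, model: DielectricModel,
                 approx: kernels.ExpSumApprox) -> np.ndarray:
    """Closed erf form for the dispersive part of eps''.

    Obtained by substituting the exponential-sum surrogate for y^2/(1+y^2)
    into the y-domain integral and evaluating each Gaussian term exactly:

        I_2(a,b) ~ sum_l lambda_l * [G0(a, b)
                   - exp(-a^2 beta_l / (1 + beta_l b^2))
                     * G0 evaluated at the beta_l-damped location/scale]

    with G0(a,b) = (b sqrt(pi)/2) * (1 + erf(a/b)).  Fully vectorised in w.
    """
    lam = np.asarray(approx.lambdas, float)[:, None]
    bet = np.asarray(approx.betas, float)[:, None]
    wf = w.ravel()[None, :]
    out = np.zeros(wf.shape[1])
    for comp in model.components:
        if comp.weight == 0.0:
            continue
        ts, tau_c, c = comp.params.ts, comp.params.tau_c, comp.params.c
        a = wf * tau_c
        b = _SQRT2 * wf * ts
        g0 = b * math.sqrt(math.pi) / 2.0 * special.erfc(-a / b)
        d = 1.0 + bet * b * b
        sq = np.sqrt(d)
        damped = (
            np.exp(-a * a * bet / d)
            * b * math.sqrt(math.pi) / (2.0 * sq)
            * special.erfc(-a / (b * sq))
        )
        i2 = np.sum(lam * (g0 - damped), axis=0)
        out += comp.weight * i2 / (wf.ravel() ** 2 * ts * ts * c)
    return out.reshape(w.shape)


# ---------------------------------------------------------------------------
# Public evaluators
# ---------------------------------------------------------------------------

def eps_real(w, model: DielectricModel, method: str = "series"):
    """Real permittivity eps'(w); lies in [eps_inf, eps_dc] and decreases in w."""
    if method not in _METHODS_REAL:
        raise ParameterDomainError(
            f"method must be one of {_METHODS_REAL} for eps_real, got {method!r}"
        )
    w = _check_omega(w)
    out = model.eps_inf + model.delta_eps * _dispersive_sum(1, w, model, method)
    return out if out.ndim else float(out)


def eps_imag(w, model: DielectricModel, method: str = "series",
             approx: kernels.ExpSumApprox = kernels.M3_PRINTED):
    """Imaginary permittivity eps''(w), including the dc-conductivity term."""
    if method not in _METHODS_IMAG:
        raise ParameterDomainError(
            f"method must be one of {_METHODS_IMAG} for eps_imag, got {method!r}"
        )
    w = _check_omega(w)
    if method == "approx":
        disp = _imag_approx(w, model, approx)
    else:
        disp = _dispersive_sum(2, w, model, method)
    out = model.delta_eps * disp + model.sigma_dc / (w * model.eps0)
    return out if out.ndim else float(out)


def eps_imag_ac(w, model: DielectricModel, method: str = "series",
                approx: kernels.ExpSumApprox = kernels.M3_PRINTED):
    """eps'' with the dc-conductivity term removed; non-negative, vanishes at both ends."""
    w = _check_omega(w)
    out = np.asarray(eps_imag(w, model, method=method, approx=approx)) - model.sigma_dc / (
        w * model.eps0
    )
    return out if out.ndim else float(out)


def eps_complex(w, model: DielectricModel, method: str = "series"):
    """eps' - j * eps'', both parts evaluated with the same method."""
    w = _check_omega(w)
    out = np.asarray(eps_real(w, model, method=method)) - 1j * np.asarray(
        eps_imag(w, model, method=method)
    )
    return out if out.ndim else complex(out)


def cole_eps(w, params: ColeParameters):
    """The Cole equation eps_inf + delta_eps / (1 + (j w tau)^alpha), principal branch."""
    w = _check_omega(w)
    jwt = 1j * w * params.tau
    out = params.eps_inf + params.delta_eps / (1.0 + jwt**params.alpha)
    return out if out.ndim else complex(out)


def legacy_eps_imag(w, model: DielectricModel, legacy_delta_eps: float):
    """The earlier literature's mis-normalised eps'' (comparison only).

    Uses the unnormalised 'Gaussian-labelled' density tau/(Ts sqrt(2 pi)) *
    exp(-(tau-tau_c)^2/(2 Ts^2)) directly, without weights r_k or the
    normalising constants c_k, evaluated by adaptive quadrature.
    """
    w = _check_omega(w)

    def one(wi: float) -> float:
        total = 0.0
        for comp in model.components:
            ts, tau_c = comp.params.ts, comp.params.tau_c
            hi = max(tau_c, 0.0) + 12.0 * _SQRT2 * ts

            def integrand(tau: float) -> float:
                dens = tau / (ts * _SQRT_2PI) * math.exp(-((tau - tau_c) ** 2) / (2 * ts * ts))
                return wi * tau * dens / (1.0 + (wi * tau) ** 2)

            interior = [x for x in (tau_c,) if 0.0 < x < hi]
            total += integrate.quad(
                integrand, 0.0, hi, points=interior or None, limit=200,
                epsabs=1e-14, epsrel=1e-10,
            )[0]
        return legacy_delta_eps * total + model.sigma_dc / (wi * model.eps0)

    out = np.array([one(wi) for wi in w.ravel()]).reshape(w.shape)
    return out if out.ndim else float(out)


def convert_amplitude(delta_eps_new: float, component: SpeciesComponent) -> float:
    """Legacy amplitude equivalent to a corrected-model amplitude.

    delta_eps_legacy = delta_eps_new * r_k * sqrt(2 pi) / (Ts_k * c_k); with
    this conversion the legacy and corrected single-species eps'' curves agree
    pointwise.  The divisor is exactly the mass of the mislabelled density.
    """
    if component.weight == 0.0:
        raise ParameterDomainError("cannot convert amplitude for a zero-weight component")
    norm = gaussian_labelled_norm(component.params.ts, component.params.tau_c)
    return delta_eps_new * component.weight / norm


def convert_amplitude_inverse(delta_eps_legacy: float, component: SpeciesComponent) -> float:
    """Inverse of :func:`convert_amplitude` (exact algebraic round trip)."""
    if component.weight == 0.0:
        raise ParameterDomainError("cannot convert amplitude for a zero-weight component")
    norm = gaussian_labelled_norm(component.params.ts, component.params.tau_c)
    return delta_eps_legacy * norm / component.weight
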