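"""Modified-Weibull relaxation-time distribution.

The distribution has density

    q(u) = (2 / (eta * c)) * (u / eta) * exp(-((u - gamma) / eta)**2),  u >= 0

i.e. a Rayleigh-type (shape-2 Weibull) density whose location shift sits only
inside the exponential, renormalised by the constant

    c(gamma, eta) = exp(-(gamma/eta)**2)
                    + sqrt(pi) * (gamma/eta) * (1 + erf(gamma/eta)).

The spectroscopy literature parameterises the same law by ``Ts = eta/sqrt(2)``
and ``tau_c = gamma``; both parameterisations are exposed.  The missing
constant ``c`` is the central correction this package implements: the density
above had previously been mislabelled as Gaussian and used unnormalised.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special

from .errors import IdentifiabilityWarning, ParameterDomainError, PhysicalRegimeWarning

__all__ = [
    "MWParameters",
    "SpeciesComponent",
    "normalizing_constant",
    "mw_pdf",
    "mw_cdf",
    "mw_quantile",
    "mw_sample",
    "log_time_density",
    "mixture_pdf",
    "gaussian_labelled_norm",
]

_SQRT2 = math.sqrt(2.0)
_SQRT_PI = math.sqrt(math.pi)
_SQRT_2PI = math.sqrt(2.0 * math.pi)

#: Tolerance on mixture weights summing to one.
WEIGHT_SUM_TOL = 1e-12


def normalizing_constant(gamma: float, eta: float) -> float:
    """Normalising constant ``c(gamma, eta)`` of the Modified-Weibull density.

    Strictly positive, depends on the parameters only through ``gamma/eta``
    and is strictly increasing in that ratio.
    """
    if not eta > 0:
        raise ParameterDomainError(f"eta must be positive, got {eta!r}")
    r = gamma / eta
    # 1 + erf(r) written as erfc(-r) for accuracy at very negative r.
    return float(np.exp(-r * r) + _SQRT_PI * r * special.erfc(-r))


@dataclass(frozen=True)
class MWParameters:
    """Parameters of one species' relaxation-time law.

    ``eta`` is the scale and ``gamma`` the location (both in seconds).  The
    spectroscopy-facing aliases are ``ts = eta / sqrt(2)`` and
    ``tau_c = gamma``.
    """

    eta: float
    gamma: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.eta) and self.eta > 0):
            raise ParameterDomainError(f"eta must be positive and finite, got {self.eta!r}")
        if not np.isfinite(self.gamma):
            raise ParameterDomainError(f"gamma must be finite, got {self.gamma!r}")
        if self.gamma / self.eta < 1.0:
            warnings.warn(
                "gamma/eta < 1: the untruncated kernel has noticeable mass below "
                "tau = 0; the renormalised density remains valid on [0, inf).",
                PhysicalRegimeWarning,
                stacklevel=2,
            )

    @classmethod
    def from_spectroscopy(cls, ts: float, tau_c: float) -> "MWParameters":
        """Build from the (Ts, tau_c) parameterisation: eta = sqrt(2)*Ts, gamma = tau_c."""
        if not ts > 0:
            raise ParameterDomainError(f"ts must be positive, got {ts!r}")
        return cls(eta=_SQRT2 * ts, gamma=tau_c)

    @property
    def ts(self) -> float:
        return self.eta / _SQRT2

    @property
    def tau_c(self) -> float:
        return self.gamma

    @property
    def ratio(self) -> float:
        """Shape ratio gamma/eta, the only combination the constant c depends on."""
        return self.gamma / self.eta

    @property
    def c(self) -> float:
        return normalizing_constant(self.gamma, self.eta)


@dataclass(frozen=True)
class SpeciesComponent:
    """One mixture component: a Modified-Weibull law plus its weight r_k."""

    params: MWParameters
    weight: float = 1.0
    label: str = "RBC"

    def __post_init__(self) -> None:
        if not (0.0 <= self.weight <= 1.0):
            raise ParameterDomainError(f"weight must lie in [0, 1], got {self.weight!r}")


def _check_nonneg(u: np.ndarray) -> None:
    if np.any(u < 0):
        raise ParameterDomainError("relaxation times must be non-negative")


def mw_pdf(u, params: MWParameters):
    """Density of the Modified-Weibull law, in 1/seconds.  ``u >= 0``."""
    u = np.asarray(u, dtype=float)
    _check_nonneg(u)
    eta, gamma = params.eta, params.gamma
    out = (2.0 / (eta * params.c)) * (u / eta) * np.exp(-(((u - gamma) / eta) ** 2))
    return out if out.ndim else float(out)


def mw_cdf(u, params: MWParameters):
    """Distribution function, by the same integration by parts that yields c.

    F(u) = [ sqrt(pi)*r*(erf((u-gamma)/eta) + erf(r)) + exp(-r^2)
             - exp(-((u-gamma)/eta)^2) ] / c,   r = gamma/eta.
    """
    u = np.asarray(u, dtype=float)
    _check_nonneg(u)
    eta, gamma, c = params.eta, params.gamma, params.c
    r = gamma / eta
    s = (u - gamma) / eta
    val = (
        _SQRT_PI * r * (special.erf(s) + special.erf(r))
        + np.exp(-r * r)
        - np.exp(-s * s)
    ) / c
    val = np.clip(val, 0.0, 1.0)
    return val if val.ndim else float(val)


def mw_quantile(p, params: MWParameters):
    """Inverse of :func:`mw_cdf` by bracketed root finding (no closed form)."""
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ParameterDomainError("probabilities must lie in [0, 1]")
    hi0 = max(params.gamma, 0.0) + 8.0 * params.eta  # cdf(hi0) == 1 to double precision

    def _one(pi: float) -> float:
        if pi == 0.0:
            return 0.0
        if pi == 1.0:
            return math.inf
        hi = hi0
        while mw_cdf(hi, params) < pi:  # pragma: no cover - defensive
            hi *= 2.0
        return optimize.brentq(
            lambda x: mw_cdf(x, params) - pi, 0.0, hi, xtol=1e-300, rtol=1e-14
        )

    out = np.vectorize(_one, otypes=[float])(p_arr)
    return out if out.ndim else float(out)


def mw_sample(params: MWParameters, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` relaxation times by inverse-cdf sampling; reproducible per seed."""
    if n < 1:
        raise ParameterDomainError(f"n must be >= 1, got {n!r}")
    rng = np.random.default_rng(seed)
    return np.asarray(mw_quantile(rng.random(n), params))


def log_time_density(l, params: MWParameters):
    """Density of ln(tau): g(l) = exp(l) * q(exp(l)); integrates to 1 over the line."""
    l = np.asarray(l, dtype=float)
    u = np.exp(l)
    out = u * mw_pdf(u, params)
    return out if out.ndim else float(out)


def _check_weights(components: Sequence[SpeciesComponent]) -> None:
    if not components:
        raise ParameterDomainError("at least one mixture component is required")
    total = sum(comp.weight for comp in components)
    if abs(total - 1.0) > WEIGHT_SUM_TOL:
        raise ParameterDomainError(
            f"mixture weights must sum to 1 within {WEIGHT_SUM_TOL}, got {total!r}"
        )
    if len(components) > 1:
        warnings.warn(
            "identifiability of multi-component Modified-Weibull mixtures is an "
            "open question; fitted mixture parameters may not be unique",
            IdentifiabilityWarning,
            stacklevel=3,
        )


def mixture_pdf(u, components: Sequence[SpeciesComponent]):
    """Weighted mixture density sum_k r_k q_k(u); weights must sum to 1."""
    _check_weights(components)
    u = np.asarray(u, dtype=float)
    out = sum(comp.weight * np.asarray(mw_pdf(u, comp.params)) for comp in components)
    out = np.asarray(out)
    return out if out.ndim else float(out)


def gaussian_labelled_norm(ts: float, tau_c: float) -> float:
    """Total mass of the historically 'Gaussian-labelled' unnormalised density.

    This is the integral over [0, inf) of

        (tau / (Ts * sqrt(2*pi))) * exp(-(tau - tau_c)^2 / (2 Ts^2))

    which equals ``Ts * c(tau_c, sqrt(2) Ts) / sqrt(2*pi)`` and is 1 only in
    degenerate coincidences: the earlier literature treated it as a unit-mass
    pdf, which is the mis-specification corrected here.
    """
    if not ts > 0:
        raise ParameterDomainError(f"ts must be positive, got {ts!r}")
    return ts * normalizing_constant(tau_c, _SQRT2 * ts) / _SQRT_2PI
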