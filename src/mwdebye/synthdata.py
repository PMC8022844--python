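"""Synthetic dielectric spectra with controlled noise.

Emulates the whole-blood beta-relaxation regime (1-100 MHz, single RBC
species) so that fitting and validation are testable without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import permittivity
from .errors import ParameterDomainError
from .permittivity import DielectricModel, Spectrum

__all__ = ["NoiseSpec", "default_blood_model", "simulate_spectrum"]

_NOISE_KINDS = ("none", "relative_gaussian", "lognormal")


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative per-point noise: none, relative Gaussian, or lognormal."""

    kind: str = "none"
    level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _NOISE_KINDS:
            raise ParameterDomainError(f"noise kind must be one of {_NOISE_KINDS}, got {self.kind!r}")
        if self.level < 0:
            raise ParameterDomainError(f"noise level must be >= 0, got {self.level!r}")

    @classmethod
    def parse(cls, text: str, seed: int = 0) -> "NoiseSpec":
        """Parse 'kind' or 'kind:level', e.g. ``relative_gaussian:0.01``."""
        kind, _, level = text.partition(":")
        return cls(kind=kind, level=float(level) if level else 0.0, seed=seed)

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none" or self.level == 0.0:
            return values
        if self.kind == "relative_gaussian":
            return values * (1.0 + self.level * rng.standard_normal(values.shape))
        return values * np.exp(self.level * rng.standard_normal(values.shape))


def default_blood_model(eps_inf: float = 10.0) -> DielectricModel:
    """Single-RBC-species model at the published whole-blood beta-relaxation fit.

    delta_eps = 8.993e3, Ts = 1.139e-7 s, tau_c = 2.434e-8 s,
    sigma_dc = 0.3204 S/m.  No high-frequency permittivity was published for
    this fit; ``eps_inf`` is a configurable default and does not influence
    eps'' or eps''_AC.
    """
    return DielectricModel.single_species(
        eps_inf=eps_inf,
        delta_eps=8.993e3,
        sigma_dc=3.204e-1,
        ts=1.139e-7,
        tau_c=2.434e-8,
        label="RBC",
    )


def simulate_spectrum(
    model: DielectricModel,
    fmin: float = 1e5,
    fmax: float = 1e9,
    points: int = 60,
    spacing: str = "log",
    noise: NoiseSpec | None = None,
    method: str = "series",
) -> Spectrum:
    """Forward-simulate a spectrum, optionally with multiplicative noise.

    The clean curve is the forward model bit-for-bit; noise draws are
    reproducible per :attr:`NoiseSpec.seed`.  ``eps_imag_ac`` is derived from
    the (noisy) eps'' using the model's dc conductivity.
    """
    if not (0 < fmin < fmax):
        raise ParameterDomainError("need 0 < fmin < fmax")
    if points < 2:
        raise ParameterDomainError(f"points must be >= 2, got {points!r}")
    if spacing == "log":
        f = np.logspace(math.log10(fmin), math.log10(fmax), points)
    elif spacing == "linear":
        f = np.linspace(fmin, fmax, points)
    else:
        raise ParameterDomainError(f"spacing must be 'log' or 'linear', got {spacing!r}")
    w = 2.0 * math.pi * f
    er = np.asarray(permittivity.eps_real(w, model, method=method))
    ei = np.asarray(permittivity.eps_imag(w, model, method=method))
    if noise is not None and noise.kind != "none":
        rng = np.random.default_rng(noise.seed)
        er = noise.apply(er, rng)
        ei = noise.apply(ei, rng)
    ac = ei - model.sigma_dc / (w * model.eps0)
    return Spectrum(frequency_hz=f, eps_real=er, eps_imag=ei, eps_imag_ac=ac)
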