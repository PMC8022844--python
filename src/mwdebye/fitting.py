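"""Weighted nonlinear least-squares estimation from dielectric spectra.

Positive parameters (delta_eps, Ts, tau_c, sigma_dc) are fitted in log10
space so unconstrained trust-region steps respect their physical domains;
mixture weights, when freed, use a softmax (logit) parameterisation with the
last component as reference.  The default target is the imaginary part on a
log10 scale, since the beta-relaxation spans several decades in both axes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from . import permittivity
from .errors import (
    BoundaryWarning,
    FittingError,
    IdentifiabilityWarning,
    ParameterDomainError,
    PhysicalRegimeWarning,
    SpectrumValidationError,
)
from .mwdist import MWParameters, SpeciesComponent
from .permittivity import DielectricModel, Spectrum

__all__ = ["FitOptions", "FitResult", "ProfileResult", "fit_spectrum", "profile_parameter"]

_LN10 = math.log(10.0)

_DEFAULT_BOUNDS = {
    "delta_eps": (1e-6, 1e12),
    "sigma_dc": (1e-12, 1e4),
    "eps_inf": (1.0, 1e6),
    "ts": (1e-13, 1e-2),
    "tau_c": (1e-13, 1e-2),
    "logit": (-30.0, 30.0),
}

#: Distance (log10 units / logit units) below which a parameter counts as
#: pinned.  Bounds span ~10 decades, so landing within one decade of a bound
#: means the data do not resolve the parameter, only its smallness.
_BOUNDARY_TOL = 1.0


@dataclass(frozen=True)
class FitOptions:
    """Knobs for :func:`fit_spectrum`.

    ``targets`` is ``imag`` or ``joint`` (eps' and eps'' together);
    ``loss_space`` is ``log10`` or ``linear``; ``method`` selects the forward
    permittivity evaluator; ``model_kind`` is ``corrected`` (normalised
    Modified-Weibull) or ``legacy`` (the historical mis-normalised form, for
    comparison studies).
    """

    targets: str = "imag"
    loss_space: str = "log10"
    method: str = "series"
    model_kind: str = "corrected"
    multi_start: int = 1
    seed: int = 0
    fit_eps_inf: bool = False
    fit_weights: bool = False
    max_nfev: int = 1000
    bounds: Mapping[str, tuple] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.targets not in ("imag", "joint"):
            raise ParameterDomainError(f"targets must be 'imag' or 'joint', got {self.targets!r}")
        if self.loss_space not in ("log10", "linear"):
            raise ParameterDomainError(
                f"loss_space must be 'log10' or 'linear', got {self.loss_space!r}"
            )
        if self.model_kind not in ("corrected", "legacy"):
            raise ParameterDomainError(
                f"model_kind must be 'corrected' or 'legacy', got {self.model_kind!r}"
            )
        if self.model_kind == "legacy" and self.targets != "imag":
            raise ParameterDomainError("the legacy model only defines eps''; use targets='imag'")
        if self.multi_start < 1:
            raise ParameterDomainError("multi_start must be >= 1")

    def bound(self, name: str) -> tuple:
        base = name.rsplit("_", 1)[0] if name[-1].isdigit() else name
        if name in self.bounds:
            return tuple(self.bounds[name])
        if base in self.bounds:
            return tuple(self.bounds[base])
        return _DEFAULT_BOUNDS[base]


@dataclass
class FitResult:
    """Outcome of a fit; ``params`` maps parameter names to linear-scale values."""

    model: DielectricModel
    params: dict
    stderr: dict
    residual: np.ndarray
    loss: float
    success: bool
    warnings: list
    starts: list
    fixed: dict
    options: FitOptions
    spectrum: Spectrum
    template: DielectricModel


@dataclass(frozen=True)
class ProfileResult:
    """Profiled loss over a grid of one parameter (others re-optimised)."""

    name: str
    grid: np.ndarray
    loss: np.ndarray
    flat: bool


# ---------------------------------------------------------------------------
# Parameter vector plumbing
# ---------------------------------------------------------------------------

def _param_names(n_comp: int, options: FitOptions) -> list:
    names = ["delta_eps", "sigma_dc"]
    if options.fit_eps_inf:
        names.append("eps_inf")
    for k in range(n_comp):
        names += [f"ts_{k}", f"tau_c_{k}"]
    if options.fit_weights and n_comp > 1:
        names += [f"logit_{k}" for k in range(n_comp - 1)]
    return names


def _is_log(name: str) -> bool:
    return not name.startswith("logit")


def _to_x(name: str, value: float) -> float:
    return math.log10(value) if _is_log(name) else value


def _from_x(name: str, x: float) -> float:
    return 10.0**x if _is_log(name) else x


def _weights_from_logits(logits: Sequence[float], n_comp: int) -> np.ndarray:
    z = np.concatenate([np.asarray(logits, float), [0.0]])
    e = np.exp(z - z.max())
    return e / e.sum()


def _build_model(params: Mapping[str, float], template: DielectricModel,
                 options: FitOptions) -> DielectricModel:
    n_comp = len(template.components)
    if options.fit_weights and n_comp > 1:
        logits = [params[f"logit_{k}"] for k in range(n_comp - 1)]
        weights = _weights_from_logits(logits, n_comp)
    else:
        weights = [comp.weight for comp in template.components]
    comps = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PhysicalRegimeWarning)
        for k, comp in enumerate(template.components):
            comps.append(
                SpeciesComponent(
                    params=MWParameters.from_spectroscopy(
                        ts=params[f"ts_{k}"], tau_c=params[f"tau_c_{k}"]
                    ),
                    weight=float(weights[k]),
                    label=comp.label,
                )
            )
        return DielectricModel(
            eps_inf=params.get("eps_inf", template.eps_inf),
            delta_eps=params["delta_eps"],
            sigma_dc=params["sigma_dc"],
            components=tuple(comps),
            eps0=template.eps0,
        )


def _predict(w: np.ndarray, params: Mapping[str, float], template: DielectricModel,
             options: FitOptions):
    model = _build_model(params, template, options)
    if options.model_kind == "legacy":
        # "delta_eps" plays the role of the legacy amplitude here
        ei = np.asarray(permittivity.legacy_eps_imag(w, model, params["delta_eps"]))
        return None, ei
    ei = np.asarray(permittivity.eps_imag(w, model, method=options.method))
    er = None
    if options.targets == "joint":
        er = np.asarray(permittivity.eps_real(w, model, method=options.method))
    return er, ei


# ---------------------------------------------------------------------------
# Initial values from the data
# ---------------------------------------------------------------------------

def _initial_guess(spectrum: Spectrum, template: DielectricModel,
                   options: FitOptions) -> dict:
    w = spectrum.omega
    ei = spectrum.eps_imag
    sigma0 = max(float(ei[0] * w[0] * template.eps0), 1e-10)
    ac = ei - sigma0 / (w * template.eps0)
    ac = np.where(ac > 0, ac, 0.0)
    if np.all(ac == 0):  # conductivity-dominated everywhere; fall back to mid-grid
        peak_idx = len(w) // 2
        peak_val = float(np.max(ei))
    else:
        peak_idx = int(np.argmax(ac))
        peak_val = float(ac[peak_idx])
    tau0 = 1.0 / float(w[peak_idx])
    init = {
        "delta_eps": max(2.0 * peak_val, 1e-3),
        "sigma_dc": sigma0,
    }
    if options.fit_eps_inf:
        init["eps_inf"] = max(float(spectrum.eps_real[-1]), 1.0)
    for k in range(len(template.components)):
        spread = 2.0**k  # separate identical multi-component starts
        init[f"ts_{k}"] = tau0 * spread
        init[f"tau_c_{k}"] = tau0 * spread
    if options.fit_weights and len(template.components) > 1:
        for k in range(len(template.components) - 1):
            init[f"logit_{k}"] = 0.0
    return init


# ---------------------------------------------------------------------------
# Core solver
# ---------------------------------------------------------------------------

def _fit_core(
    spectrum: Spectrum,
    template: DielectricModel,
    options: FitOptions,
    fixed: Mapping[str, float] | None = None,
    init: Mapping[str, float] | None = None,
) -> FitResult:
    fixed = dict(fixed or {})
    names = _param_names(len(template.components), options)
    free = [n for n in names if n not in fixed]
    n_free = len(free)

    if len(spectrum) < n_free + 4:
        raise SpectrumValidationError(
            f"need at least {n_free + 4} points for {n_free} free parameters, "
            f"got {len(spectrum)}"
        )
    fspan = spectrum.frequency_hz[-1] / spectrum.frequency_hz[0]
    if fspan < 10.0:
        raise SpectrumValidationError(
            f"frequency span must cover at least one decade, got x{fspan:.2f}"
        )

    if len(template.components) > 1:
        warnings.warn(
            "multi-component Modified-Weibull fits may not be identifiable; "
            "interpret the estimates with caution",
            IdentifiabilityWarning,
            stacklevel=3,
        )

    w = spectrum.omega
    data_imag = spectrum.eps_imag
    data_real = spectrum.eps_real
    if options.loss_space == "log10" and (
        np.any(data_imag <= 0) or (options.targets == "joint" and np.any(data_real <= 0))
    ):
        raise FittingError("log10 loss requires strictly positive data; use loss_space='linear'")

    base_init = _initial_guess(spectrum, template, options)
    if init:
        base_init.update({k: v for k, v in init.items() if k in base_init})

    lo = np.array([_to_x(n, options.bound(n)[0]) for n in free])
    hi = np.array([_to_x(n, options.bound(n)[1]) for n in free])

    def residuals(x: np.ndarray) -> np.ndarray:
        params = dict(fixed)
        params.update({n: _from_x(n, xi) for n, xi in zip(free, x)})
        er, ei = _predict(w, params, template, options)
        if options.loss_space == "log10":
            res = np.log10(np.maximum(ei, 1e-300)) - np.log10(data_imag)
            if er is not None:
                res = np.concatenate([res, np.log10(np.maximum(er, 1e-300)) - np.log10(data_real)])
        else:
            res = ei - data_imag
            if er is not None:
                res = np.concatenate([res, er - data_real])
        return res

    rng = np.random.default_rng(options.seed)
    x0_base = np.clip(np.array([_to_x(n, base_init[n]) for n in free]), lo, hi)
    starts_log, best, best_x = [], None, None
    for start in range(options.multi_start):
        x0 = x0_base if start == 0 else np.clip(
            x0_base + rng.uniform(-0.5, 0.5, size=n_free), lo, hi
        )
        try:
            sol = optimize.least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=options.max_nfev,
            )
            starts_log.append(
                {"start": start, "loss": 2.0 * sol.cost, "success": bool(sol.success)}
            )
            # a solve stopped by the evaluation budget is still a usable
            # candidate (success stays False); only raising solves are dropped
            if np.isfinite(sol.cost) and (best is None or sol.cost < best.cost):
                best, best_x = sol, sol.x
        except Exception as exc:
            starts_log.append({"start": start, "loss": math.inf, "error": str(exc)})
    if best is None:
        raise FittingError(f"all {options.multi_start} fitting starts failed: {starts_log!r}")

    params = dict(fixed)
    params.update({n: _from_x(n, xi) for n, xi in zip(free, best_x)})

    fit_warnings = []
    for n, xi, l, h in zip(free, best_x, lo, hi):
        if xi - l < _BOUNDARY_TOL or h - xi < _BOUNDARY_TOL:
            msg = f"parameter {n} is pinned near a bound (value {_from_x(n, xi):.6g})"
            fit_warnings.append(msg)
            warnings.warn(msg, BoundaryWarning, stacklevel=3)
    if len(template.components) > 1:
        fit_warnings.append("multi-component mixture: identifiability not guaranteed")

    m = best.fun.size
    stderr = {}
    if m > n_free:
        try:
            jtj = best.jac.T @ best.jac
            cov = np.linalg.pinv(jtj) * (2.0 * best.cost / (m - n_free))
            se_x = np.sqrt(np.maximum(np.diag(cov), 0.0))
            for n, xi, se in zip(free, best_x, se_x):
                stderr[n] = _LN10 * _from_x(n, xi) * se if _is_log(n) else se
        except np.linalg.LinAlgError:  # pragma: no cover
            stderr = {n: math.inf for n in free}

    model = _build_model(params, template, options)
    return FitResult(
        model=model,
        params=params,
        stderr=stderr,
        residual=best.fun,
        loss=2.0 * best.cost,
        success=bool(best.success),
        warnings=fit_warnings,
        starts=starts_log,
        fixed=dict(fixed),
        options=options,
        spectrum=spectrum,
        template=template,
    )


def fit_spectrum(
    spectrum: Spectrum,
    template: DielectricModel,
    options: FitOptions | None = None,
) -> FitResult:
    """Estimate model parameters from a spectrum.

    ``template`` supplies the model structure (component count, labels, fixed
    weights, eps_inf when not fitted, eps0); initial values are derived from
    the data (sigma_dc from the low-frequency eps'' limb, tau_c from the
    eps''_AC peak) and perturbed log-uniformly across multi-starts.
    """
    return _fit_core(spectrum, template, options or FitOptions())


def profile_parameter(result: FitResult, name: str, grid) -> ProfileResult:
    """Profile likelihood: re-optimise all other parameters over a grid of ``name``.

    A flat profile (relative loss variation below 1e-4) triggers an
    identifiability warning, the practical symptom of the open mixture
    identifiability question.
    """
    names = _param_names(len(result.template.components), result.options)
    if name not in names:
        raise ParameterDomainError(f"unknown parameter {name!r}; known: {names}")
    if not result.success:
        # an unconverged fit is often precisely the one worth profiling
        warnings.warn(
            "profiling an unconverged fit; the profile may reflect the "
            "optimiser budget rather than the loss surface",
            IdentifiabilityWarning,
            stacklevel=2,
        )
    grid = np.asarray(grid, dtype=float)
    losses = np.empty(grid.shape)
    for i, value in enumerate(grid):
        sub = _fit_core(
            result.spectrum,
            result.template,
            result.options,
            fixed={**result.fixed, name: float(value)},
            init=result.params,
        )
        losses[i] = sub.loss
    span = float(np.max(losses) - np.min(losses))
    # floor: a loss span below (1e-6 rms per residual)^2 is indistinguishable
    # from a perfect fit at double precision
    floor = result.residual.size * 1e-12
    flat = span <= max(1e-4 * float(np.min(losses)), floor)
    if flat:
        warnings.warn(
            f"loss profile for {name!r} is flat: the parameter is not identified "
            "by these data",
            IdentifiabilityWarning,
            stacklevel=2,
        )
    return ProfileResult(name=name, grid=grid, loss=losses, flat=flat)
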