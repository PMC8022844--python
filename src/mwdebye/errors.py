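"""Exception and warning types shared across the package."""


class ParameterDomainError(ValueError):
    """A parameter lies outside its mathematical or physical domain."""


class SpectrumValidationError(ValueError):
    """A spectrum (or spectrum file) violates its structural invariants."""


class NumericalConvergenceError(RuntimeError):
    """A quadrature or series evaluation failed to reach its tolerance."""


class FittingError(RuntimeError):
    """All optimisation starts failed, or the data cannot support a fit."""


class PhysicalRegimeWarning(UserWarning):
    """Parameters are admissible but outside the physically comfortable regime.

    Emitted e.g. when gamma/eta < 1, where the untruncated Gaussian kernel
    carries non-negligible mass below tau = 0 before renormalisation.
    """


class IdentifiabilityWarning(UserWarning):
    """Multi-component mixtures of Modified-Weibull laws may not be identifiable."""


class BoundaryWarning(UserWarning):
    """A fitted parameter is pinned at (or numerically touching) a bound."""
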