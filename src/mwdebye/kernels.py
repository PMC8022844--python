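"""Integral building blocks for the permittivity evaluators.

Everything here reduces, one way or another, to the rational-kernel integral

    I_p(a, b) = int_0^inf  y^p / (1 + y^2) * exp(-((y - a)/b)^2)  dy,

with p in {0, 1, 2}.  Three evaluation routes are provided:

* :func:`i_p_oracle` - adaptive quadrature in y.  Ground truth for everything
  else; deliberately shares no code with the series routes.
* :func:`i1_series` / :func:`i2_series` - the explicit Gauss-Laguerre node
  sums obtained by expanding 1/(1+y^2) = int_0^inf exp(-t(1+y^2)) dt and
  evaluating the inner Gaussian integral in closed (erf/exp) form.
* :func:`i_p_series_auto` - order escalation over Laguerre rules with a
  segmented evaluation of the same closed-form t-integrand as fallback for
  the large-(a, b) regimes where plain Gauss-Laguerre nodes cannot resolve
  the 1/(a^2 + b^2) scale at any feasible order.

The exponential-sum surrogate of y^2/(1+y^2) used by the fast imaginary-part
approximation also lives here, together with its validator and refitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import integrate, optimize, special

from .errors import FittingError, NumericalConvergenceError, ParameterDomainError

__all__ = [
    "QuadratureRule",
    "ExpSumApprox",
    "M3_PRINTED",
    "gauss_power_integral",
    "i_p_oracle",
    "i1_series",
    "i2_series",
    "i_p_series_auto",
    "i_p_segmented",
    "expsum_value",
    "validate_expsum",
    "fit_expsum",
]

_SQRT_PI = math.sqrt(math.pi)

#: Escalation ladder for the plain Gauss-Laguerre series.
AUTO_ORDERS = (16, 32, 64, 128, 256)


@dataclass(frozen=True)
class QuadratureRule:
    """Gauss-Laguerre rule: nodes are roots of the order-n Laguerre polynomial."""

    order: int
    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        x, q = np.asarray(self.nodes, float), np.asarray(self.weights, float)
        if x.shape != (self.order,) or q.shape != (self.order,):
            raise ParameterDomainError("nodes/weights must have length `order`")
        if not (np.all(x > 0) and np.all(np.diff(x) > 0)):
            raise ParameterDomainError("nodes must be strictly positive and increasing")
        # weights are mathematically positive; the extreme-node ones underflow
        # to exactly 0.0 in double precision at high order, which is accepted
        if not (np.all(q >= 0) and q.max() > 0):
            raise ParameterDomainError("weights must be non-negative with positive mass")
        if abs(q.sum() - 1.0) > 1e-10:
            raise ParameterDomainError("weights must sum to 1 (integral of exp(-t))")

    @classmethod
    def gauss_laguerre(cls, order: int) -> "QuadratureRule":
        return _laguerre_rule(order)


@lru_cache(maxsize=32)
def _laguerre_rule(order: int) -> QuadratureRule:
    if not 1 <= order <= 700:
        # scipy's weight recurrence overflows somewhere above ~700 nodes.
        raise ParameterDomainError(f"order must lie in [1, 700], got {order!r}")
    x, q = special.roots_laguerre(order)
    return QuadratureRule(order=order, nodes=x, weights=q)


# ---------------------------------------------------------------------------
# Gaussian power integral (Theorem-level building block)
# ---------------------------------------------------------------------------

def _gauss_power_explicit(alpha1: int, alpha2: float, alpha3: float):
    """int_0^inf y^alpha1 exp(-((y-alpha2)/alpha3)^2) dy for alpha1 in {0,1,2}."""
    z = alpha2 / alpha3
    erfc_neg = special.erfc(-z)  # = 1 + erf(z)
    ez2 = np.exp(-z * z)
    if alpha1 == 0:
        return alpha3 * _SQRT_PI / 2.0 * erfc_neg
    if alpha1 == 1:
        return alpha3**2 / 2.0 * (ez2 + _SQRT_PI * z * erfc_neg)
    return alpha3**3 * (_SQRT_PI / 4.0 * (1.0 + 2.0 * z * z) * erfc_neg + z / 2.0 * ez2)


def _gauss_power_hyp1f1(alpha1: float, alpha2: float, alpha3: float) -> float:
    """General-exponent route via Kummer's confluent hypergeometric function."""
    z = alpha2 / alpha3
    pref = _SQRT_PI * special.gamma(alpha1 + 1.0) / 2.0 ** (alpha1 + 1.0)
    term1 = special.hyp1f1(-alpha1 / 2.0, 0.5, -z * z) / special.gamma(1.0 + alpha1 / 2.0)
    term2 = (
        2.0
        * z
        * special.hyp1f1((1.0 - alpha1) / 2.0, 1.5, -z * z)
        / special.gamma((1.0 + alpha1) / 2.0)
    )
    return float(pref * alpha3 ** (alpha1 + 1.0) * (term1 + term2))


def gauss_power_integral(alpha1: float, alpha2: float, alpha3: float, method: str = "auto") -> float:
    """``int_0^inf y^alpha1 * exp(-((y - alpha2)/alpha3)^2) dy``.

    Uses explicit erf/exp reductions for integer ``alpha1`` in {0, 1, 2} and a
    confluent-hypergeometric representation otherwise.  Finite and positive on
    its domain ``alpha1 > -1``, ``alpha3 > 0``.
    """
    if not alpha1 > -1.0:
        raise ParameterDomainError(f"alpha1 must exceed -1, got {alpha1!r}")
    if not alpha3 > 0.0:
        raise ParameterDomainError(f"alpha3 must be positive, got {alpha3!r}")
    is_small_int = alpha1 in (0.0, 1.0, 2.0)
    if method == "explicit" or (method == "auto" and is_small_int):
        if not is_small_int:
            raise ParameterDomainError("explicit route only covers alpha1 in {0, 1, 2}")
        return float(_gauss_power_explicit(int(alpha1), alpha2, alpha3))
    if method in ("auto", "hyp1f1"):
        return _gauss_power_hyp1f1(alpha1, alpha2, alpha3)
    raise ParameterDomainError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Oracle
# ---------------------------------------------------------------------------

def i_p_oracle(p: int, a: float, b: float, epsabs: float = 1e-13, epsrel: float = 1e-11) -> float:
    """Adaptive quadrature of I_p(a, b); the ground-truth route.

    The Gaussian factor confines the integrand to ``[a - 15 b, a + 15 b]``
    (intersected with the half-line), where the discarded tail is below
    1e-97 of the kernel mass.
    """
    if p not in (0, 1, 2):
        raise ParameterDomainError(f"p must be in {{0, 1, 2}}, got {p!r}")
    if not b > 0:
        raise ParameterDomainError(f"b must be positive, got {b!r}")

    def integrand(y: float) -> float:
        return y**p / (1.0 + y * y) * math.exp(-(((y - a) / b) ** 2))

    hi = a + 15.0 * b
    interior = [x for x in (max(a - 15.0 * b, 0.0), a) if 0.0 < x < hi]
    value, err = integrate.quad(
        integrand, 0.0, hi, points=interior or None, limit=400, epsabs=epsabs, epsrel=epsrel
    )
    if not np.isfinite(value) or (value != 0.0 and err > 1e-6 * abs(value) + 1e-12):
        raise NumericalConvergenceError(
            f"I_{p}({a!r}, {b!r}) quadrature did not converge: value={value!r}, err={err!r}"
        )
    return value


# ---------------------------------------------------------------------------
# Series (Gauss-Laguerre node sums with closed-form inner integrals)
# ---------------------------------------------------------------------------

def _inner_gaussian(p: int, t, a: float, b: float):
    """Closed form of int_0^inf y^p exp(-((y-a)/b)^2 - t y^2) dy, vectorised in t.

    Completing the square maps this onto the pure Gaussian power integral with
    location a/(1+t b^2) and scale b/sqrt(1+t b^2), times exp(-a^2 t/(1+t b^2)).
    The published node-sum brackets are this expression with the removable
    1/a factor left unsimplified; the factored form below is regular at a = 0.
    """
    t = np.asarray(t, dtype=float)
    d = 1.0 + t * b * b
    sq = np.sqrt(d)
    z = a / (b * sq)
    damp = np.exp(-a * a * t / d)
    erfc_neg = special.erfc(-z)
    if p == 0:
        return damp * (b * _SQRT_PI / 2.0) / sq * erfc_neg
    if p == 1:
        return damp * b * b / (2.0 * d) * (np.exp(-z * z) + _SQRT_PI * z * erfc_neg)
    return damp * b**3 / d**1.5 * (
        _SQRT_PI / 4.0 * (1.0 + 2.0 * z * z) * erfc_neg + z / 2.0 * np.exp(-z * z)
    )


def _series(p: int, a: float, b: float, rule: QuadratureRule) -> float:
    if not b > 0:
        raise ParameterDomainError(f"b must be positive, got {b!r}")
    return float(np.sum(rule.weights * _inner_gaussian(p, rule.nodes, a, b)))


def i1_series(a: float, b: float, rule: QuadratureRule) -> float:
    """Gauss-Laguerre node sum for I_1(a, b); converges to the oracle as order grows."""
    return _series(1, a, b, rule)


def i2_series(a: float, b: float, rule: QuadratureRule) -> float:
    """Gauss-Laguerre node sum for I_2(a, b); converges to the oracle as order grows."""
    return _series(2, a, b, rule)


_LEG_X, _LEG_W = np.polynomial.legendre.leggauss(40)
_T_CUTOFF = 45.0  # exp(-45) ~ 3e-20: negligible tail of the exponential weight


def i_p_segmented(p: int, a: float, b: float) -> float:
    """Evaluate int_0^inf exp(-t) * F_p(t; a, b) dt over geometric t-segments.

    Same closed-form integrand as the Laguerre node sums, but integrated over
    decade segments starting at the short scale 1/(1 + a^2 + b^2) so that both
    that scale and the O(1) exponential cutoff are resolved.  Used when plain
    node escalation cannot converge (large a or b).
    """
    if p not in (0, 1, 2):
        raise ParameterDomainError(f"p must be in {{0, 1, 2}}, got {p!r}")
    if not b > 0:
        raise ParameterDomainError(f"b must be positive, got {b!r}")
    scale = 1.0 / (1.0 + a * a + b * b)
    breaks = [0.0, scale]
    while breaks[-1] < _T_CUTOFF:
        breaks.append(min(breaks[-1] * 10.0, _T_CUTOFF))
    total = 0.0
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        t = 0.5 * (hi - lo) * _LEG_X + 0.5 * (hi + lo)
        total += 0.5 * (hi - lo) * float(
            np.sum(_LEG_W * np.exp(-t) * _inner_gaussian(p, t, a, b))
        )
    return total


def i_p_series_auto(
    p: int,
    a: float,
    b: float,
    rtol: float = 1e-6,
    orders: Sequence[int] = AUTO_ORDERS,
    allow_fallback: bool = True,
) -> float:
    """Series value with automatic order escalation.

    Successive Laguerre orders are compared until they agree to ``rtol``.  When
    1 + a^2 + b^2 is large the plain node sums cannot converge at any feasible
    order (the nodes never resolve the short t-scale); the segmented evaluation
    of the same integrand is used instead.  With ``allow_fallback=False`` that
    regime raises :class:`NumericalConvergenceError` naming (a, b).
    """
    if p not in (0, 1, 2):
        raise ParameterDomainError(f"p must be in {{0, 1, 2}}, got {p!r}")
    hard_regime = (1.0 + a * a + b * b) > 100.0
    if not hard_regime:
        prev = None
        for order in orders:
            val = _series(p, a, b, _laguerre_rule(order))
            if prev is not None and abs(val - prev) <= rtol * max(abs(val), 1e-300):
                return val
            prev = val
    if allow_fallback:
        return i_p_segmented(p, a, b)
    raise NumericalConvergenceError(
        f"Gauss-Laguerre series for I_{p} did not converge at orders {tuple(orders)} "
        f"in the regime a={a!r}, b={b!r}; use the oracle or segmented evaluation"
    )


def i_p_series_auto_vec(
    p: int,
    a: np.ndarray,
    b: np.ndarray,
    rtol: float = 1e-6,
    orders: Sequence[int] = AUTO_ORDERS,
) -> np.ndarray:
    """Vectorised :func:`i_p_series_auto` over parallel arrays of (a, b).

    Escalates all not-yet-converged entries together at each Laguerre order,
    then finishes the hard-regime entries with the segmented evaluation.
    """
    a = np.atleast_1d(np.asarray(a, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterDomainError("a and b must be 1-d arrays of equal length")
    if np.any(b <= 0):
        raise ParameterDomainError("b must be positive")
    out = np.full(a.shape, np.nan)
    done = (1.0 + a * a + b * b) > 100.0  # hard regime: go straight to segments
    prev = np.full(a.shape, np.nan)
    for order in orders:
        idx = np.where(~done)[0]
        if idx.size == 0:
            break
        rule = _laguerre_rule(order)
        f = _inner_gaussian(p, rule.nodes[None, :], a[idx, None], b[idx, None])
        vals = np.sum(rule.weights[None, :] * f, axis=1)
        conv = np.abs(vals - prev[idx]) <= rtol * np.maximum(np.abs(vals), 1e-300)
        out[idx[conv]] = vals[conv]
        done[idx[conv]] = True
        prev[idx] = vals
    for i in np.where(np.isnan(out))[0]:
        out[i] = i_p_segmented(p, float(a[i]), float(b[i]))
    return out


# ---------------------------------------------------------------------------
# Exponential-sum surrogate of y^2 / (1 + y^2)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpSumApprox:
    """Coefficients of  y^2/(1+y^2) ~ sum_l lambda_l * (1 - exp(-beta_l y^2)).

    ``max_abs_error``/``argmax_y`` are populated by :func:`validate_expsum`;
    the supremum of the surrogate as y -> inf is ``sum(lambdas)``.
    """

    lambdas: tuple
    betas: tuple
    max_abs_error: float | None = None
    argmax_y: float | None = None

    def __post_init__(self) -> None:
        if len(self.lambdas) != len(self.betas) or not self.lambdas:
            raise ParameterDomainError("lambdas and betas must be non-empty, equal length")
        if any(beta <= 0 for beta in self.betas):
            raise ParameterDomainError("all betas must be positive")

    @property
    def order(self) -> int:
        return len(self.lambdas)


#: Published order-3 coefficients (max abs error ~0.0185 near y = 0.546).
M3_PRINTED = ExpSumApprox(
    lambdas=(0.58974, 0.313759, 0.0870197),
    betas=(1.28188, 0.253207, 0.0438525),
)


def expsum_value(y, approx: ExpSumApprox):
    """Value of the exponential-sum surrogate; exactly 0 at y = 0."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ParameterDomainError("y must be non-negative")
    lam = np.asarray(approx.lambdas, float)
    bet = np.asarray(approx.betas, float)
    flat = y.ravel()
    val = np.sum(lam[:, None] * (1.0 - np.exp(-bet[:, None] * flat * flat)), axis=0)
    val = val.reshape(y.shape)
    return val if val.ndim else float(val)


def _expsum_abs_err(y: np.ndarray, approx: ExpSumApprox) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    target = y * y / (1.0 + y * y)
    return np.abs(target - np.asarray(expsum_value(y, approx)))


def validate_expsum(
    approx: ExpSumApprox,
    num_points: int = 100_001,
    y_min: float = 1e-4,
    y_max: float = 1e4,
) -> ExpSumApprox:
    """Scan the absolute error of the surrogate and refine its maximiser.

    Dense log-grid scan over ``[y_min, y_max]``, golden-section refinement
    around the grid argmax, plus the analytic y -> inf limit ``|1 - sum(lambda)|``
    (reported with ``argmax_y = inf`` if the tail dominates).  Returns a copy
    of ``approx`` with ``max_abs_error`` and ``argmax_y`` populated.
    """
    if num_points < 3:
        raise ParameterDomainError("num_points must be at least 3")
    grid = np.logspace(math.log10(y_min), math.log10(y_max), num_points)
    err = _expsum_abs_err(grid, approx)
    idx = int(np.argmax(err))
    lo = grid[max(idx - 1, 0)]
    hi = grid[min(idx + 1, num_points - 1)]
    res = optimize.minimize_scalar(
        lambda y: -float(_expsum_abs_err(np.asarray([y]), approx)[0]),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    max_err, arg = -float(res.fun), float(res.x)
    if float(err[idx]) > max_err:  # refinement should never lose to the scan
        max_err, arg = float(err[idx]), float(grid[idx])
    tail = abs(1.0 - float(np.sum(approx.lambdas)))
    if tail > max_err:
        max_err, arg = tail, math.inf
    return replace(approx, max_abs_error=max_err, argmax_y=arg)


def fit_expsum(
    M: int,
    num_points: int = 600,
    y_min: float = 1e-3,
    y_max: float = 1e3,
    multi_start: int = 1,
    seed: int = 0,
) -> ExpSumApprox:
    """Least-squares fit of the order-M exponential-sum surrogate.

    Residuals are taken on a log-spaced y grid; betas are parameterised in
    log space to enforce positivity.  A soft-minimax polish (high-order p-norm
    of the residuals) follows the sum-of-squares stage, since the published
    coefficients were obtained with an unspecified objective.  The returned
    object carries its validated maximum error.
    """
    if M < 1:
        raise ParameterDomainError(f"M must be >= 1, got {M!r}")
    grid = np.logspace(math.log10(y_min), math.log10(y_max), num_points)
    target = grid * grid / (1.0 + grid * grid)
    rng = np.random.default_rng(seed)

    def unpack(x: np.ndarray):
        return x[:M], np.exp(x[M:])

    def residuals(x: np.ndarray) -> np.ndarray:
        lam, bet = unpack(x)
        model = np.sum(lam[:, None] * (1.0 - np.exp(-bet[:, None] * grid**2)), axis=0)
        return model - target

    def softmax_residuals(x: np.ndarray) -> np.ndarray:
        # p-norm emphasis on the worst residuals approximates a minimax fit
        r = residuals(x)
        return np.sign(r) * np.abs(r) ** 4

    base_lam = np.full(M, 1.0 / M)
    base_logbet = np.log(np.logspace(-1.5, 0.5, M)[::-1]) if M > 1 else np.array([0.0])
    best = None
    failures = []
    for start in range(max(multi_start, 1)):
        x0 = np.concatenate([base_lam, base_logbet])
        if start > 0:
            x0 = x0 + rng.uniform(-0.5, 0.5, size=x0.size)
        try:
            sol = optimize.least_squares(residuals, x0, method="lm", max_nfev=20_000)
            sol = optimize.least_squares(softmax_residuals, sol.x, method="lm", max_nfev=20_000)
        except Exception as exc:  # pragma: no cover - solver pathologies
            failures.append(f"start {start}: {exc}")
            continue
        lam, bet = unpack(sol.x)
        candidate = validate_expsum(ExpSumApprox(lambdas=tuple(lam), betas=tuple(bet)))
        if best is None or candidate.max_abs_error < best.max_abs_error:
            best = candidate
    if best is None:
        raise FittingError("all exponential-sum fitting starts failed: " + "; ".join(failures))
    return best
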