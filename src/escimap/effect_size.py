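"""Standardized effect sizes for t-tests and their exact confidence intervals.

This module holds the scalar mathematics behind the whole package: the
d-family of standardized mean differences, the small-sample bias correction
that turns Cohen's :math:`d_p` into Hedges' :math:`g`, and exact confidence
intervals obtained by inverting the noncentral t-distribution.

The central facts used throughout:

* a t-statistic converts to a standardized effect via a design-dependent
  scale factor, ``d_p = t * scale`` (``scale = sqrt(1/n1 + 1/n2)`` for the
  two-sample t-test, ``sqrt(1/n)`` for the one-sample t-test, and
  ``sqrt(c'(X'X)^- c)`` for a general GLM contrast);
* the observed t estimates the noncentrality parameter Delta of a
  noncentral t-distribution with the analysis degrees of freedom, so a CI
  for Delta — found by root-finding on the noncentral-t CDF — maps
  monotonically onto a CI for the effect size via the same scale factor;
* the CI limits are *not* bias-corrected: only the point estimate is
  multiplied by the correction factor J.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special
from scipy import stats as sps

__all__ = [
    "CDF_TOL",
    "EffectSizeEstimate",
    "NcpInterval",
    "TTestEffectSize",
    "ci_g",
    "correction_factor_j",
    "dp_from_t",
    "equivalence_test",
    "hedges_g",
    "inferiority_test",
    "ncp_ci",
    "ncp_ci_array",
    "one_sample_scale",
    "pooled_sd",
    "se_g_approx",
    "two_sample_scale",
]

#: maximum tolerated residual |F(t; dof, Delta) - target| at a returned CI limit
CDF_TOL = 1e-6


def _check_group_size(n: int, name: str = "n") -> int:
    n = int(n)
    if n < 2:
        raise ValueError(f"{name} must be >= 2, got {n}")
    return n


def _check_dof(dof: int) -> int:
    dof = int(dof)
    if dof < 1:
        raise ValueError(f"dof must be >= 1, got {dof}")
    return dof


def pooled_sd(n1: int, s1: float, n2: int, s2: float) -> float:
    """Pooled standard deviation of two groups.

    ``sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2))``
    """
    n1 = _check_group_size(n1, "n1")
    n2 = _check_group_size(n2, "n2")
    if not (s1 > 0 and s2 > 0):
        raise ValueError("standard deviations must be positive")
    return math.sqrt(((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / (n1 + n2 - 2))


def two_sample_scale(n1: int, n2: int) -> float:
    """Contrast scale ``sqrt(1/n1 + 1/n2)`` of the two-sample t-test."""
    n1 = _check_group_size(n1, "n1")
    n2 = _check_group_size(n2, "n2")
    return math.sqrt(1.0 / n1 + 1.0 / n2)


def one_sample_scale(n: int) -> float:
    """Contrast scale ``sqrt(1/n)`` of the one-sample t-test."""
    return math.sqrt(1.0 / _check_group_size(n))


def dp_from_t(t: float, scale: float) -> float:
    """Uncorrected standardized effect ``d_p = t * scale``.

    ``scale`` is the design-dependent factor (see :func:`two_sample_scale`,
    :func:`one_sample_scale`, and :func:`escimap.design.contrast_variance_scale`).
    The scalar API rejects non-finite t; at the map level non-finite voxels
    propagate as missing values instead.
    """
    if not scale > 0:
        raise ValueError("scale must be positive")
    if not math.isfinite(t):
        raise ValueError("t must be finite")
    return t * scale


def correction_factor_j(dof: int, exact: bool = False) -> float:
    """Small-sample bias correction factor J.

    By default the standard approximation ``J = 1 - 3/(4 dof - 1)`` is used.
    With ``exact=True`` the gamma-function form
    ``J = Gamma(dof/2) / (sqrt(dof/2) * Gamma((dof-1)/2))`` is returned.
    """
    dof = _check_dof(dof)
    if exact:
        if dof == 1:
            return 0.0
        return math.exp(
            special.gammaln(dof / 2.0) - special.gammaln((dof - 1) / 2.0)
        ) / math.sqrt(dof / 2.0)
    return 1.0 - 3.0 / (4.0 * dof - 1.0)


def hedges_g(d_p: float, dof: int, exact_j: bool = False) -> float:
    """Hedges' g: the bias-corrected standardized effect ``d_p * J(dof)``."""
    return d_p * correction_factor_j(dof, exact=exact_j)


def se_g_approx(g: float, n1: int, n2: int) -> float:
    """Approximate standard error of g for a two-sample design.

    ``sqrt((n1+n2)/(n1 n2) + g^2 / (2 (n1+n2-2)))``.  This feeds a
    normal-approximation interval ``g +/- z * se``; it is offered only as a
    clearly approximate alternative to the exact noncentral-t interval that
    the rest of the package uses.
    """
    n1 = _check_group_size(n1, "n1")
    n2 = _check_group_size(n2, "n2")
    return math.sqrt((n1 + n2) / (n1 * n2) + g ** 2 / (2.0 * (n1 + n2 - 2)))


@dataclass(frozen=True)
class NcpInterval:
    """Two-sided confidence interval for the noncentrality parameter Delta."""

    delta_lower: float
    delta_upper: float
    confidence: float

    def __post_init__(self) -> None:
        if not self.delta_lower <= self.delta_upper:
            raise ValueError("delta_lower must not exceed delta_upper")


def _check_confidence(confidence: float) -> float:
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must lie in (0, 1), got {confidence}")
    return float(confidence)


def _nct_cdf(t, dof, delta):
    """Noncentral-t CDF, robust in the far tails.

    scipy's implementation can return NaN deep in the lower tail; there we
    fall back on the reflection identity F(t; dof, d) = SF(-t; dof, -d) and,
    failing that, clamp to the limiting 0/1 value.
    """
    t = np.asarray(t, dtype=float)
    delta = np.asarray(delta, dtype=float)
    with np.errstate(all="ignore"):
        c = np.asarray(sps.nct.cdf(t, dof, delta))
        bad = ~np.isfinite(c) & np.isfinite(t) & np.isfinite(delta)
        if bad.any():
            c = np.where(bad, sps.nct.sf(-t, dof, -delta), c)
            still = ~np.isfinite(c) & np.isfinite(t) & np.isfinite(delta)
            if still.any():
                c = np.where(still, (t >= delta).astype(float), c)
    if c.ndim == 0:
        return float(c)
    return c


def _ncp_root_scalar(t: float, dof: int, target: float, tol: float) -> float:
    """Solve F(t; dof, Delta) = target for Delta (F is decreasing in Delta).

    Brent's method on an expanding bracket [t - k sqrt(dof), t + k sqrt(dof)]
    with k doubled until the target is straddled.
    """

    def f(delta: float) -> float:
        return _nct_cdf(t, dof, delta) - target

    k = 1.0
    lo = t - k * math.sqrt(dof)
    hi = t + k * math.sqrt(dof)
    for _ in range(64):
        if f(lo) > 0.0 and f(hi) < 0.0:
            break
        k *= 2.0
        lo = t - k * math.sqrt(dof)
        hi = t + k * math.sqrt(dof)
    else:
        raise ArithmeticError(
            f"could not bracket the noncentrality root (t={t}, dof={dof}, "
            f"target={target})"
        )
    root = optimize.brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)
    resid = abs(f(root))
    if resid > tol:
        raise ArithmeticError(
            f"noncentrality root residual {resid:.3g} exceeds tolerance {tol:.3g}"
        )
    return float(root)


def ncp_ci(t: float, dof: int, confidence: float = 0.90,
           tol: float = CDF_TOL) -> NcpInterval:
    """Exact two-sided CI for the noncentrality parameter Delta.

    ``delta_lower`` solves ``F(t; dof, Delta) = 1 - alpha/2`` and
    ``delta_upper`` solves ``F(t; dof, Delta) = alpha/2`` with
    ``alpha = 1 - confidence``; F is the noncentral-t CDF.
    """
    dof = _check_dof(dof)
    confidence = _check_confidence(confidence)
    if not math.isfinite(t):
        raise ValueError("t must be finite")
    alpha = 1.0 - confidence
    lower = _ncp_root_scalar(t, dof, 1.0 - alpha / 2.0, tol)
    upper = _ncp_root_scalar(t, dof, alpha / 2.0, tol)
    return NcpInterval(delta_lower=lower, delta_upper=upper, confidence=confidence)


def ncp_ci_array(t, dof: int, confidence: float = 0.90, iterations: int = 48):
    """Vectorized noncentrality-parameter CI limits.

    Same defining equations as :func:`ncp_ci`, solved by per-element bracket
    expansion followed by a fixed number of bisection steps on the
    noncentral-t CDF (all array-valued).  Non-finite entries of ``t``
    propagate as NaN in both outputs.

    Returns ``(delta_lower, delta_upper)`` arrays of the shape of ``t``.
    """
    dof = _check_dof(dof)
    confidence = _check_confidence(confidence)
    alpha = 1.0 - confidence
    t = np.asarray(t, dtype=float)
    lower = np.full(t.shape, np.nan)
    upper = np.full(t.shape, np.nan)
    finite = np.isfinite(t)
    tv = t[finite]
    if tv.size:
        lower[finite] = _ncp_root_array(tv, dof, 1.0 - alpha / 2.0, iterations)
        upper[finite] = _ncp_root_array(tv, dof, alpha / 2.0, iterations)
    if t.ndim == 0:
        return float(lower), float(upper)
    return lower, upper


def _ncp_root_array(tv, dof, target, iterations):
    sqrt_dof = math.sqrt(dof)
    k_lo = np.full(tv.shape, sqrt_dof)
    k_hi = np.full(tv.shape, sqrt_dof)
    lo = tv - k_lo
    hi = tv + k_hi
    for _ in range(64):
        bad_lo = _nct_cdf(tv, dof, lo) < target
        bad_hi = _nct_cdf(tv, dof, hi) > target
        if not (bad_lo.any() or bad_hi.any()):
            break
        k_lo[bad_lo] *= 2.0
        k_hi[bad_hi] *= 2.0
        lo = tv - k_lo
        hi = tv + k_hi
    else:  # pragma: no cover - would need pathological inputs
        raise ArithmeticError("could not bracket noncentrality roots")
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        go_right = _nct_cdf(tv, dof, mid) > target  # root lies above mid
        lo = np.where(go_right, mid, lo)
        hi = np.where(go_right, hi, mid)
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class EffectSizeEstimate:
    """Standardized effect size with its exact confidence interval.

    Attributes
    ----------
    d_p : float
        Uncorrected standardized effect (Cohen's d, pooled-SD flavour).
    g : float
        Bias-corrected effect, ``d_p * J(dof)`` (Hedges' g).
    ci_lower, ci_upper : float
        Limits of the exact noncentral-t CI.  Note these bracket ``d_p``
        (the CI limits are not bias-corrected).
    confidence : float
        Two-sided confidence level, e.g. 0.90.
    dof : int
        Degrees of freedom of the underlying t-test.
    scale : float
        Design scale factor ``sqrt(c'(X'X)^- c)`` used in the conversion.
    """

    d_p: float
    g: float
    ci_lower: float
    ci_upper: float
    confidence: float
    dof: int
    scale: float

    def __post_init__(self) -> None:
        if not self.ci_lower <= self.ci_upper:
            raise ValueError("ci_lower must not exceed ci_upper")
        if not self.scale > 0:
            raise ValueError("scale must be positive")

    @property
    def ci(self) -> tuple[float, float]:
        return (self.ci_lower, self.ci_upper)

    def summary(self) -> str:
        pct = 100.0 * self.confidence
        lines = [
            "Standardized effect size (exact noncentral-t CI)",
            "=" * 48,
            f"d_p (uncorrected)   {self.d_p: .6f}",
            f"g (Hedges)          {self.g: .6f}",
            f"{pct:.1f}% CI          [{self.ci_lower: .6f}, {self.ci_upper: .6f}]",
            f"dof                 {self.dof}",
            f"scale sqrt(c'(X'X)^-c)  {self.scale: .6f}",
        ]
        return "\n".join(lines)


def ci_g(t: float, dof: int, scale: float, confidence: float = 0.90,
         exact_j: bool = False) -> EffectSizeEstimate:
    """Effect size g and its exact CI from a t-statistic.

    The noncentrality CI is scaled by the design factor; the point estimate
    additionally receives the bias correction J, the limits do not.
    """
    d_p = dp_from_t(t, scale)
    interval = ncp_ci(t, dof, confidence)
    return EffectSizeEstimate(
        d_p=d_p,
        g=hedges_g(d_p, dof, exact_j=exact_j),
        ci_lower=interval.delta_lower * scale,
        ci_upper=interval.delta_upper * scale,
        confidence=confidence,
        dof=dof,
        scale=scale,
    )


def inferiority_test(estimate: EffectSizeEstimate, bound: float) -> bool:
    """True iff the effect is statistically smaller than ``bound``.

    Declared when the CI upper limit lies strictly below the bound; an upper
    limit including or exceeding the bound counts as not inferior.
    """
    return estimate.ci_upper < bound


def equivalence_test(estimate: EffectSizeEstimate, lower_bound: float,
                     upper_bound: float) -> bool:
    """True iff the CI lies strictly inside (lower_bound, upper_bound).

    This is the CI formulation of the two-one-sided-tests (TOST) procedure:
    with a two-sided (1 - 2*alpha) interval it corresponds to both one-sided
    tests at level alpha being significant.
    """
    if not lower_bound < upper_bound:
        raise ValueError("equivalence bounds must satisfy lower < upper")
    return lower_bound < estimate.ci_lower and estimate.ci_upper < upper_bound


class TTestEffectSize:
    """Scalar model: one t-statistic plus its design, fitted to an effect size.

    Parameters
    ----------
    t : float
        Observed t-statistic.
    dof : int
        Degrees of freedom.  May be omitted when ``n``/``n1, n2`` are given
        (then the conventional ``n - 1`` / ``n1 + n2 - 2`` is used).
    scale : float, optional
        Design scale ``sqrt(c'(X'X)^- c)``.  Alternatively pass ``n`` for a
        one-sample design or ``n1`` and ``n2`` for a two-sample design.

    ``fit(confidence)`` returns an :class:`EffectSizeEstimate`.
    """

    def __init__(self, t: float, dof: int | None = None, *,
                 scale: float | None = None, n: int | None = None,
                 n1: int | None = None, n2: int | None = None) -> None:
        given = sum(x is not None for x in (scale, n, n1))
        if given != 1 or (n1 is None) != (n2 is None):
            raise ValueError("specify exactly one of scale=, n=, or n1=/n2=")
        if scale is not None:
            if dof is None:
                raise ValueError("dof is required when scale is given directly")
            self.scale = float(scale)
        elif n is not None:
            self.scale = one_sample_scale(n)
            dof = (n - 1) if dof is None else dof
        else:
            self.scale = two_sample_scale(n1, n2)
            dof = (n1 + n2 - 2) if dof is None else dof
        self.t = float(t)
        self.dof = _check_dof(dof)

    def fit(self, confidence: float = 0.90,
            exact_j: bool = False) -> EffectSizeEstimate:
        return ci_g(self.t, self.dof, self.scale, confidence=confidence,
                    exact_j=exact_j)
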