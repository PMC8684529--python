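"""Loss functions and the numerical posterior-risk machinery.

Six loss families for estimating a positive parameter beta by beta_hat
(Delta = beta_hat - beta throughout):

* ``SELF``  — squared error, Delta^2.
* ``LLF``   — LINEX, exp(c Delta) - c Delta - 1, asymmetric, c != 0.
* ``ASLF``  — asymmetric ratio loss, beta/beta_hat + beta_hat/beta - 2.
* ``ENLF``  — entropy loss, r - ln r - 1 with r = beta_hat/beta.
* ``CLLF``  — composite LINEX, exp(-c Delta) + exp(c Delta) - 2, symmetric, c > 0.
* ``WCLLF`` — weighted composite LINEX, exp(-omega beta) * CLLF; the weight
  discounts errors made at large beta and reduces to CLLF at omega = 0.

Besides evaluating losses, this module integrates the posterior risk
``E[L(beta_hat, beta) | data]`` under a gamma posterior by adaptive
quadrature and minimizes it numerically.  The numerical minimizer is the
package's independent check on every closed-form Bayes estimator: the two
routes share no algebra.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize
from scipy import stats as _sps

from .bayes import PosteriorGamma

__all__ = ["LossFamily", "LossSpec", "loss", "posterior_risk", "argmin_risk"]


class LossFamily(str, enum.Enum):
    SELF = "SELF"
    LLF = "LLF"
    ASLF = "ASLF"
    ENLF = "ENLF"
    CLLF = "CLLF"
    WCLLF = "WCLLF"


@dataclass(frozen=True)
class LossSpec:
    """A loss family plus its constants.

    ``c`` is the LINEX asymmetry/curvature constant (nonzero for LLF,
    strictly positive for CLLF/WCLLF, unused otherwise); ``omega`` is the
    exponential weight-decay rate of WCLLF (>= 0, and must be 0 for every
    other family).
    """

    family: LossFamily
    c: float | None = None
    omega: float = 0.0

    def __post_init__(self) -> None:
        fam = LossFamily(self.family)
        object.__setattr__(self, "family", fam)
        if fam is LossFamily.LLF:
            if self.c is None or self.c == 0:
                raise ValueError("LLF requires a nonzero constant c")
        elif fam in (LossFamily.CLLF, LossFamily.WCLLF):
            if self.c is None or not self.c > 0:
                raise ValueError(f"{fam.value} requires c > 0, got {self.c!r}")
        elif self.c is not None:
            raise ValueError(f"{fam.value} takes no constant c")
        if self.omega < 0:
            raise ValueError(f"omega must be >= 0, got {self.omega!r}")
        if fam is not LossFamily.WCLLF and self.omega != 0:
            raise ValueError(f"omega applies only to WCLLF, not {fam.value}")


def loss(spec: LossSpec, estimate, parameter):
    """Evaluate the loss at ``estimate`` for true value ``parameter``.

    Broadcasts over arrays.  Every family is >= 0 with a unique zero at
    ``estimate == parameter``.
    """
    est = np.asarray(estimate, dtype=float)
    par = np.asarray(parameter, dtype=float)
    fam = spec.family
    if fam in (LossFamily.ASLF, LossFamily.ENLF):
        if np.any(par <= 0) or np.any(est <= 0):
            raise ValueError(f"{fam.value} requires estimate > 0 and parameter > 0")
    delta = est - par
    if fam is LossFamily.SELF:
        out = delta**2
    elif fam is LossFamily.LLF:
        cd = spec.c * delta
        out = np.expm1(cd) - cd
    elif fam is LossFamily.ASLF:
        out = par / est + est / par - 2.0
    elif fam is LossFamily.ENLF:
        r = est / par
        out = r - np.log(r) - 1.0
    elif fam is LossFamily.CLLF:
        out = 2.0 * (np.cosh(spec.c * delta) - 1.0)
    elif fam is LossFamily.WCLLF:
        out = np.exp(-spec.omega * par) * 2.0 * (np.cosh(spec.c * delta) - 1.0)
    else:  # pragma: no cover
        raise AssertionError(fam)
    return out if out.ndim else float(out)


def _check_integrable(spec: LossSpec, post: PosteriorGamma) -> None:
    """Reject posteriors whose exponential tilt makes the risk integral diverge."""
    rate = float(post.rate)
    shape = float(post.shape)
    fam = spec.family
    if fam is LossFamily.LLF and rate + spec.c <= 0:
        raise ValueError(f"LINEX risk diverges: needs posterior rate + c > 0 (rate={rate}, c={spec.c})")
    if fam is LossFamily.CLLF and rate <= spec.c:
        raise ValueError(f"composite-LINEX risk diverges: needs posterior rate > c (rate={rate}, c={spec.c})")
    if fam is LossFamily.WCLLF and rate + spec.omega <= spec.c:
        raise ValueError(
            "weighted composite-LINEX risk diverges: needs posterior rate + omega > c "
            f"(rate={rate}, omega={spec.omega}, c={spec.c})"
        )
    if fam in (LossFamily.ASLF, LossFamily.ENLF) and shape <= 1:
        raise ValueError(f"{fam.value} risk needs posterior shape > 1 so that E[1/beta] exists")


def _tilt(spec: LossSpec) -> float:
    """Largest positive exponential-growth rate the loss contributes in beta."""
    fam = spec.family
    if fam is LossFamily.LLF:
        return max(-spec.c, 0.0)
    if fam is LossFamily.CLLF:
        return spec.c
    if fam is LossFamily.WCLLF:
        return spec.c - spec.omega
    return 0.0


def _quad_posterior(post: PosteriorGamma, integrand, tilt: float) -> float:
    """Integrate integrand(beta) * h(beta | data) over (0, inf).

    The interval is split at the posterior mean and at the mean of the
    exponentially tilted posterior (rate reduced by ``tilt``), since the
    tilt moves the effective mode, and truncated ~40 tilted standard
    deviations into the tail (beyond which the integrand underflows and
    would otherwise produce 0*inf artifacts); absolute tolerance ~1e-12
    on the well-scaled posteriors used here.
    """
    rate = float(post.rate)
    shape = float(post.shape)
    dens = _sps.gamma(a=shape, scale=1.0 / rate)

    def f(b):
        return integrand(b) * dens.pdf(b)

    eff_rate = rate - max(tilt, 0.0)
    breaks = {shape / rate}
    if tilt > 0:
        breaks.add(shape / eff_rate)
    hi = (shape + 40.0 * math.sqrt(shape) + 40.0) / eff_rate
    total = 0.0
    lo = 0.0
    for b in sorted(breaks) + [hi]:
        part, _ = integrate.quad(f, lo, b, epsabs=1e-13, epsrel=1e-11, limit=200)
        total += part
        lo = b
    return total


def posterior_risk(spec: LossSpec, estimate: float, post: PosteriorGamma) -> float:
    """Posterior expected loss at ``estimate`` by adaptive quadrature."""
    if estimate <= 0 and spec.family in (LossFamily.ASLF, LossFamily.ENLF):
        raise ValueError(f"{spec.family.value} requires estimate > 0")
    _check_integrable(spec, post)
    return _quad_posterior(post, lambda b: loss(spec, estimate, b), _tilt(spec))


def _risk_derivative(spec: LossSpec, estimate: float, post: PosteriorGamma) -> float:
    """d/d(estimate) of the posterior risk, differentiating under the integral."""
    fam = spec.family
    c = spec.c

    if fam is LossFamily.SELF:
        def d(b):
            return 2.0 * (estimate - b)
    elif fam is LossFamily.LLF:
        def d(b):
            return c * np.expm1(c * (estimate - b))
    elif fam is LossFamily.ASLF:
        def d(b):
            return 1.0 / b - b / estimate**2
    elif fam is LossFamily.ENLF:
        def d(b):
            return 1.0 / b - 1.0 / estimate
    elif fam is LossFamily.CLLF:
        def d(b):
            return 2.0 * c * np.sinh(c * (estimate - b))
    elif fam is LossFamily.WCLLF:
        def d(b):
            return np.exp(-spec.omega * b) * 2.0 * c * np.sinh(c * (estimate - b))
    else:  # pragma: no cover
        raise AssertionError(fam)

    return _quad_posterior(post, d, _tilt(spec))


def argmin_risk(spec: LossSpec, post: PosteriorGamma) -> float:
    """Numerically minimize the posterior risk over estimates in (0, inf).

    Finds the root of the quadrature-evaluated risk derivative (the risk is
    convex in the estimate for every supported family on the posteriors
    used here), bracketed around the posterior mean and refined by Brent's
    method to ~1e-12 relative.  Serves as the independent oracle for the
    closed-form estimators.
    """
    _check_integrable(spec, post)
    mean = float(post.mean)
    lo, hi = mean / 2.0, mean * 2.0

    def g(est):
        return _risk_derivative(spec, est, post)

    for _ in range(60):
        if g(lo) <= 0:
            break
        lo /= 2.0
        if lo < mean * 1e-9:
            raise RuntimeError(f"risk-derivative bracketing failed at the lower end (mean={mean})")
    for _ in range(60):
        if g(hi) >= 0:
            break
        hi *= 2.0
        if hi > mean * 1e4:
            raise RuntimeError(f"risk-derivative bracketing failed at the upper end (mean={mean})")
    root = optimize.brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    return float(root)
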