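"""The von Bertalanffy scaling law for nodule growth.

The model is the power-law ODE

    dV/dt = alpha * V**beta

whose closed-form solution is ``V(t)**(1-beta) = V0**(1-beta) + (1-beta)*alpha*t``
for beta != 1 and ``V(t) = V0 * exp(alpha*t)`` for beta = 1. The dimensionless
exponent beta indexes the growth pattern: decelerated, linear, subexponential,
exponential or accelerated (faster than exponential, with a finite blow-up
time t* = V0**(1-beta) / ((beta-1)*alpha) when beta > 1 and alpha > 0).

Fitting a three-scan series (V0, V1, V2) reduces, in the variable c = 1 - beta,
to a one-dimensional root-find on

    f(c) = expm1(c*a1) / expm1(c*a2) = (t1 - t0) / (t2 - t0),

where a_i = ln(V_i / V0). For strictly increasing volumes (0 < a1 < a2) f is
strictly decreasing from 1 (c -> -inf) to 0 (c -> +inf), so the root — and
hence beta — is unique. Longer series are fitted by least squares on
log-volumes, initialised from the exact three-point solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

from .cohort import ScanObservation
from .errors import BlowUpError, DomainError, FitConvergenceError, ParameterError

#: below this |1 - beta| the exponential (beta = 1) closed form is used
_BETA_ONE_TOL = 1e-8


class GrowthCategory(str, Enum):
    DECELERATED = "decelerated"
    LINEAR = "linear"
    SUBEXPONENTIAL = "subexponential"
    EXPONENTIAL = "exponential"
    ACCELERATED = "accelerated"


def classify_growth(beta: float) -> GrowthCategory:
    """Bin a growth exponent into its category.

    Boundaries are upper-inclusive: decelerated beta <= -0.1; linear
    -0.1 < beta <= 0.1; subexponential 0.1 < beta <= 0.9; exponential
    0.9 < beta <= 1.1; accelerated beta > 1.1.
    """
    if not math.isfinite(beta):
        raise DomainError(f"growth exponent must be finite, got {beta}")
    if beta <= -0.1:
        return GrowthCategory.DECELERATED
    if beta <= 0.1:
        return GrowthCategory.LINEAR
    if beta <= 0.9:
        return GrowthCategory.SUBEXPONENTIAL
    if beta <= 1.1:
        return GrowthCategory.EXPONENTIAL
    return GrowthCategory.ACCELERATED


@dataclass(frozen=True)
class VBFit:
    """A fitted von Bertalanffy law for one nodule.

    ``alpha`` has units mm^{3(1-beta)} / month; ``beta`` is dimensionless.
    ``residual`` is the RMS of log-volume residuals (numerically zero for the
    exact three-point fit).
    """

    alpha: float
    beta: float
    method: str  # "exact3" | "least_squares"
    residual: float
    category: GrowthCategory
    converged: bool
    nodule_id: str | None = None

    def to_record(self) -> dict:
        return {
            "nodule_id": self.nodule_id,
            "alpha": self.alpha,
            "beta": self.beta,
            "method": self.method,
            "residual": self.residual,
            "category": self.category.value,
            "converged": self.converged,
        }


def blow_up_time(v0: float, alpha: float, beta: float) -> float:
    """Finite blow-up time t* for beta > 1 and alpha > 0; inf otherwise."""
    if beta > 1 and alpha > 0:
        return v0 ** (1.0 - beta) / ((beta - 1.0) * alpha)
    return math.inf


def vb_solve_forward(
    v0: float, alpha: float, beta: float, times: Sequence[float]
) -> np.ndarray:
    """Evaluate the closed-form solution V(t) at the requested times.

    Raises :class:`BlowUpError` if a time at or beyond t* is requested
    (beta > 1), and :class:`DomainError` if the solution leaves the positive
    domain (possible for beta < 1 with alpha < 0).
    """
    if v0 <= 0 or not math.isfinite(v0):
        raise DomainError(f"v0 must be positive and finite, got {v0}")
    t = np.asarray(times, dtype=float)
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise DomainError("times must be finite and >= 0")
    if abs(1.0 - beta) < _BETA_ONE_TOL:
        return v0 * np.exp(alpha * t)
    c = 1.0 - beta
    t_star = blow_up_time(v0, alpha, beta)
    if np.any(t >= t_star):
        raise BlowUpError(t_star)
    base = v0**c + c * alpha * t
    if np.any(base <= 0):
        raise DomainError(
            "solution leaves the positive domain: V0^(1-beta) + (1-beta)*alpha*t <= 0"
        )
    out = base ** (1.0 / c)
    out[t == 0] = v0  # exact at baseline, no roundoff through the power
    return out


def _f_ratio(c: float, a1: float, a2: float) -> float:
    """expm1(c*a1)/expm1(c*a2), continuous at c = 0 where it equals a1/a2."""
    if c == 0.0:
        return a1 / a2
    x1, x2 = c * a1, c * a2
    if x2 > 700.0:  # avoid overflow; ratio -> exp(c*(a1-a2))
        return math.exp(x1 - x2)
    return math.expm1(x1) / math.expm1(x2)


def _as_tv(obs: Sequence[ScanObservation]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([o.time_months for o in obs], dtype=float)
    v = np.array([o.volume_mm3 for o in obs], dtype=float)
    return t, v


def _log_residuals(t, v, v0, alpha, beta) -> np.ndarray:
    if abs(1.0 - beta) < _BETA_ONE_TOL:
        pred = math.log(v0) + alpha * t
    else:
        c = 1.0 - beta
        base = v0**c + c * alpha * t
        if np.any(base <= 0):
            return np.full(len(t), np.inf)
        pred = np.log(base) / c
    return pred - np.log(v)


def vb_fit_exact3(
    obs: Sequence[ScanObservation],
    beta_range: tuple[float, float] = (-10.0, 10.0),
    nodule_id: str | None = None,
) -> VBFit:
    """Fit (alpha, beta) exactly through three strictly increasing volumes.

    The fit passes through all three points by construction; the exponent is
    the unique root of the one-dimensional consistency equation (see module
    docstring). A root outside ``beta_range`` raises
    :class:`FitConvergenceError` rather than clamping.
    """
    if len(obs) != 3:
        raise ParameterError(f"exact three-point fit needs exactly 3 observations, got {len(obs)}")
    t, v = _as_tv(obs)
    if np.any(np.diff(v) <= 0):
        raise DomainError("volumes must be strictly increasing for the exact fit")
    t = t - t[0]
    a1 = math.log(v[1] / v[0])
    a2 = math.log(v[2] / v[0])
    r = t[1] / t[2]

    lo, hi = 1.0 - beta_range[1], 1.0 - beta_range[0]  # bracket in c = 1 - beta
    f = lambda c: _f_ratio(c, a1, a2) - r
    f_lo, f_hi = f(lo), f(hi)
    if f_lo * f_hi > 0:
        raise FitConvergenceError(
            f"growth exponent root not bracketed in beta range {beta_range}"
        )
    c = brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)

    if abs(c) < _BETA_ONE_TOL:
        beta = 1.0
        alpha = a1 / t[1]
    else:
        beta = 1.0 - c
        alpha = v[0] ** c * math.expm1(c * a1) / (c * t[1])
    resid = float(np.sqrt(np.mean(_log_residuals(t, v, v[0], alpha, beta) ** 2)))
    return VBFit(
        alpha=alpha,
        beta=beta,
        method="exact3",
        residual=resid,
        category=classify_growth(beta),
        converged=True,
        nodule_id=nodule_id,
    )


def vb_fit_ls(
    obs: Sequence[ScanObservation],
    beta_range: tuple[float, float] = (-10.0, 10.0),
    nodule_id: str | None = None,
) -> VBFit:
    """Least-squares fit of (alpha, beta) on log-volumes for series of >= 3 scans.

    The baseline volume is fixed at the first observed volume (the model's V0).
    Initialised from the exact three-point fit on the (first, middle, last)
    observations; for exactly three scans this returns the exact fit.
    Non-convergence is reported via ``converged=False``, never silently.
    """
    if len(obs) < 3:
        raise ParameterError(f"least-squares fit needs >= 3 observations, got {len(obs)}")
    if len(obs) == 3:
        fit = vb_fit_exact3(obs, beta_range, nodule_id)
        return fit

    t, v = _as_tv(obs)
    t = t - t[0]
    v0 = v[0]
    mid = len(obs) // 2
    try:
        init = vb_fit_exact3([obs[0], obs[mid], obs[-1]], beta_range)
        x0 = np.array([init.alpha, init.beta])
    except (DomainError, FitConvergenceError):
        lam = (math.log(v[-1]) - math.log(v0)) / t[-1]
        x0 = np.array([lam, 1.0])

    def resid(x):
        alpha, beta = x
        r = _log_residuals(t, v, v0, alpha, beta)
        bad = ~np.isfinite(r)
        if bad.any():  # soft penalty keeps the optimizer inside the domain
            c = 1.0 - beta
            base = v0**c + c * alpha * t
            r = np.where(np.isfinite(r), r, 0.0) + np.where(bad, 1e3 * (1.0 - base), 0.0)
        return r

    res = least_squares(resid, x0, method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    alpha, beta = res.x
    r = _log_residuals(t, v, v0, alpha, beta)
    converged = bool(res.success and np.all(np.isfinite(r)))
    rms = float(np.sqrt(np.mean(r**2))) if np.all(np.isfinite(r)) else math.inf
    return VBFit(
        alpha=float(alpha),
        beta=float(beta),
        method="least_squares",
        residual=rms,
        category=classify_growth(beta) if math.isfinite(beta) else GrowthCategory.LINEAR,
        converged=converged,
        nodule_id=nodule_id,
    )
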