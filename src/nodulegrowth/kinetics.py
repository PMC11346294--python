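"""Growth rates, volume doubling times and baseline features.

Candidate discriminators between benign and malignant nodules, computed from
the first three scans (V0, V1, V2):

* linear rate  nu_if  = (V_f - V_i) / dt            [mm³/month]
* exponential rate  lambda_if = (ln V_f - ln V_i) / dt   [1/month]
* Schwartz doubling time  VDT_exp = ln2 / lambda_01      [months]
* scaling-law doubling time
  VDT_beta = ((2 V0)^(1-beta) - V0^(1-beta)) / ((1-beta) alpha)
* baseline volume V0, baseline attenuation HU0 and the "mass" product V0*HU0.

"log" is the natural logarithm throughout, so VDT = ln2/lambda is exact for
pure exponential growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np

from .cohort import NoduleSeries, ScanObservation
from .errors import DomainError, ParameterError
from .growth import VBFit, vb_fit_exact3

LN2 = math.log(2.0)


def linear_rate(v_i: float, v_f: float, dt: float) -> float:
    """Linear growth rate nu = (v_f - v_i) / dt in mm³/month."""
    if dt <= 0:
        raise DomainError(f"dt must be positive, got {dt}")
    return (v_f - v_i) / dt


def exp_rate(v_i: float, v_f: float, dt: float) -> float:
    """Exponential growth rate lambda = (ln v_f - ln v_i) / dt in 1/month."""
    if dt <= 0:
        raise DomainError(f"dt must be positive, got {dt}")
    if v_i <= 0 or v_f <= 0:
        raise DomainError("volumes must be positive for the exponential rate")
    return (math.log(v_f) - math.log(v_i)) / dt


def ls_rates(obs: Sequence[ScanObservation]) -> tuple[float, float]:
    """OLS slopes of volume vs time (nu_ls) and ln volume vs time (lambda_ls)."""
    if len(obs) < 3:
        raise ParameterError(f"least-squares rates need >= 3 observations, got {len(obs)}")
    t = np.array([o.time_months for o in obs], dtype=float)
    v = np.array([o.volume_mm3 for o in obs], dtype=float)
    nu = float(np.polyfit(t, v, 1)[0])
    lam = float(np.polyfit(t, np.log(v), 1)[0])
    return nu, lam


def vdt_schwartz(lam: float) -> float:
    """Modified Schwartz doubling time ln2/lambda (months).

    lambda = 0 yields +inf (no growth: doubling never happens); negative
    lambda passes through as a negative VDT signalling shrinkage.
    """
    if lam == 0.0:
        return math.inf
    return LN2 / lam


def vdt_beta(v0: float, alpha: float, beta: float) -> float:
    """Doubling time under the fitted scaling law.

    VDT_beta = ((2 V0)^(1-beta) - V0^(1-beta)) / ((1-beta) alpha), with the
    exponential limit ln2/alpha at beta -> 1. alpha = 0 yields +inf; a
    shrinking law (alpha < 0) never doubles and raises :class:`DomainError`.
    """
    if v0 <= 0:
        raise DomainError(f"v0 must be positive, got {v0}")
    if alpha == 0.0:
        return math.inf
    if alpha < 0.0:
        raise DomainError("doubling is unreachable for alpha < 0 (shrinking nodule)")
    # singular-branch window +/-1e-6: inside it the exponential limit is used;
    # the induced error, |1-beta|*|ln v0 + ln2/2|, is far below the beta
    # resolution of any realistic fit
    if abs(1.0 - beta) <= 1.05e-6:  # padded so beta = 1 +/- 1e-6 falls inside
        return LN2 / alpha
    c = 1.0 - beta
    return v0**c * (2.0**c - 1.0) / (c * alpha)


def lesion_mass(volume: float, hu: float) -> float:
    """Lesion "mass": the product volume x mean attenuation (mm³·HU).

    Typically negative for lung nodules, whose mean HU is below zero.
    """
    if volume <= 0:
        raise DomainError(f"volume must be positive, got {volume}")
    return volume * hu


@dataclass(frozen=True)
class KineticsFeatures:
    """Per-nodule kinetic features from the first three scans.

    Missing attenuation leaves hu0/mass0 as NaN (missing), never zero.
    """

    nodule_id: str
    nu_01: float
    nu_02: float
    nu_12: float
    nu_ls: float
    lambda_01: float
    lambda_02: float
    lambda_12: float
    lambda_ls: float
    vdt_exp_01: float
    vdt_exp_ls: float
    vdt_beta: float
    v0: float
    hu0: float
    mass0: float

    def to_record(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_features(series: NoduleSeries, fit: VBFit | None = None) -> KineticsFeatures:
    """All pairwise and least-squares rates, both VDT estimators and baseline
    features for one (inclusion-filtered) nodule.

    The scaling-law VDT uses ``fit`` when given, otherwise the exact
    three-point fit on the first three scans.
    """
    if len(series) < 3:
        raise ParameterError(f"{series.nodule_id}: need >= 3 scans for kinetic features")
    obs3 = series.observations[:3]
    t = [o.time_months for o in obs3]
    v = [o.volume_mm3 for o in obs3]
    try:
        nu_01 = linear_rate(v[0], v[1], t[1] - t[0])
        nu_02 = linear_rate(v[0], v[2], t[2] - t[0])
        nu_12 = linear_rate(v[1], v[2], t[2] - t[1])
        lam_01 = exp_rate(v[0], v[1], t[1] - t[0])
        lam_02 = exp_rate(v[0], v[2], t[2] - t[0])
        lam_12 = exp_rate(v[1], v[2], t[2] - t[1])
        nu_ls, lam_ls = ls_rates(obs3)
    except DomainError as err:
        raise DomainError(f"{series.nodule_id}: {err}") from err

    if fit is None:
        fit = vb_fit_exact3(obs3, nodule_id=series.nodule_id)
    try:
        vdt_b = vdt_beta(v[0], fit.alpha, fit.beta)
    except DomainError:
        vdt_b = math.nan

    hu0 = obs3[0].attenuation_hu
    hu0 = math.nan if hu0 is None else hu0
    mass0 = math.nan if math.isnan(hu0) else lesion_mass(v[0], hu0)
    return KineticsFeatures(
        nodule_id=series.nodule_id,
        nu_01=nu_01,
        nu_02=nu_02,
        nu_12=nu_12,
        nu_ls=nu_ls,
        lambda_01=lam_01,
        lambda_02=lam_02,
        lambda_12=lam_12,
        lambda_ls=lam_ls,
        vdt_exp_01=vdt_schwartz(lam_01),
        vdt_exp_ls=vdt_schwartz(lam_ls),
        vdt_beta=vdt_b,
        v0=v[0],
        hu0=hu0,
        mass0=mass0,
    )
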