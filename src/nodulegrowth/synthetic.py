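"""Synthetic screening cohorts with the statistical structure of the study
population: 140 malignant and 40 benign nodules followed over three annual
CT scans, with reference growth-pattern mixtures, baseline-volume quartiles,
scan-interval quartiles, attenuation trajectories and morphology mix.

Each nodule is generated forward through the scaling law itself: a growth
category (hence an exponent beta) is assigned by count, a baseline volume V0
is drawn from a log-normal calibrated to the group's reference median/IQR, scan
times (0, t1, t2) come from triangular distributions fitted to the reference
interval quartiles, and a 24-month-scale target fold-change FC fixes the rate
coefficient analytically:

    alpha = (FC**(1-beta) - 1) * V0**(1-beta) / ((1-beta) * t2)   (beta != 1)
    alpha = ln(FC) / t2                                           (beta == 1)

so V(t2) = FC * V0 exactly, trajectories are strictly increasing and a
beta > 1 nodule can never reach its blow-up time within follow-up. With zero
volumetry noise the drawn (alpha, beta) are exactly recoverable by the
three-point fit, which makes the generator a ground-truth oracle for the
whole pipeline.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import norm

from .cohort import Cohort, Malignancy, Morphology, NoduleSeries, ScanObservation
from .errors import ParameterError
from .growth import GrowthCategory, vb_solve_forward

CATEGORY_ORDER = (
    GrowthCategory.DECELERATED,
    GrowthCategory.LINEAR,
    GrowthCategory.SUBEXPONENTIAL,
    GrowthCategory.EXPONENTIAL,
    GrowthCategory.ACCELERATED,
)

_Z75 = norm.ppf(0.75)  # 0.6744897...


def lognormal_from_quartiles(q25: float, q50: float, q75: float) -> tuple[float, float]:
    """Least-squares (mu, sigma) of a log-normal matching three quantiles.

    The LS solution in log space is mu = mean of the three log-quantiles and
    sigma = (ln q75 - ln q25) / (2 z_0.75); only two parameters are available
    for three target quantiles, so the match is exact only for a log-
    symmetric triple.
    """
    logs = np.log([q25, q50, q75])
    return float(logs.mean()), float((logs[2] - logs[0]) / (2 * _Z75))


def triangular_from_quartiles(
    q25: float, q50: float, q75: float, lower: float = 0.5
) -> tuple[float, float, float]:
    """(left, mode, right) of a triangular distribution least-squares fitted to
    the target quartiles, with the left endpoint bounded below by ``lower``
    (scan intervals must stay positive). An exact triangular match to these
    asymmetric quartiles does not exist, hence the LS fit."""

    def ppf(p, a, m, b):
        fm = (m - a) / (b - a)
        return np.where(
            p < fm,
            a + np.sqrt(np.clip(p * (b - a) * (m - a), 0, None)),
            b - np.sqrt(np.clip((1 - p) * (b - a) * (b - m), 0, None)),
        )

    def resid(x):
        a = lower + x[0] ** 2
        m = a + x[1] ** 2
        b = m + x[2] ** 2
        return ppf(np.array([0.25, 0.5, 0.75]), a, m, b) - np.array([q25, q50, q75])

    x0 = np.sqrt(
        [
            max(q25 - (q50 - q25) - lower, 0.1),
            max(q50 - max(q25 - (q50 - q25), lower), 0.1),
            max(2 * (q75 - q50), 0.1),
        ]
    )
    res = least_squares(resid, x0, xtol=1e-12, ftol=1e-12)
    a = lower + res.x[0] ** 2
    m = a + res.x[1] ** 2
    b = m + res.x[2] ** 2
    return float(a), float(m), float(b)


@dataclass
class CohortSpec:
    """Free parameters of the generator, defaulting to the reference screening cohort.

    ``category_mix_*`` are exact counts per growth category in the order
    (decelerated, linear, subexponential, exponential, accelerated);
    ``fold_change_24mo`` gives per-category (lo, hi) uniform ranges for the
    target fold-change at the third scan; ``v0_quartiles_*`` are the reference
    baseline-volume (q25, median, q75) in mm³; schedules are (q25, median,
    q75) of the first->second and first->third scan intervals in months.
    """

    n_benign: int = 40
    n_malignant: int = 140
    category_mix_benign: tuple[int, ...] = (20, 0, 8, 1, 11)
    category_mix_malignant: tuple[int, ...] = (37, 1, 13, 6, 83)
    beta_ranges: dict = field(
        default_factory=lambda: {
            GrowthCategory.DECELERATED: (-2.0, -0.1),
            GrowthCategory.LINEAR: (-0.1, 0.1),
            GrowthCategory.SUBEXPONENTIAL: (0.1, 0.9),
            GrowthCategory.EXPONENTIAL: (0.9, 1.1),
            GrowthCategory.ACCELERATED: (1.1, 2.5),
        }
    )
    v0_quartiles_benign: tuple[float, float, float] = (49.5, 103.5, 414.3)
    v0_quartiles_malignant: tuple[float, float, float] = (64.3, 179.3, 527.2)
    fold_change_24mo: dict = field(
        default_factory=lambda: {
            "benign": {
                GrowthCategory.DECELERATED: (1.2, 1.9),
                GrowthCategory.LINEAR: (1.3, 2.1),
                GrowthCategory.SUBEXPONENTIAL: (1.4, 2.4),
                GrowthCategory.EXPONENTIAL: (1.6, 2.8),
                GrowthCategory.ACCELERATED: (1.8, 3.4),
            },
            "malignant": {
                GrowthCategory.DECELERATED: (1.5, 2.6),
                GrowthCategory.LINEAR: (1.7, 2.9),
                GrowthCategory.SUBEXPONENTIAL: (2.0, 3.6),
                GrowthCategory.EXPONENTIAL: (2.3, 4.2),
                GrowthCategory.ACCELERATED: (2.4, 5.2),
            },
        }
    )
    t1_quartiles: tuple[float, float, float] = (6.2, 12.2, 13.9)
    t2_quartiles: tuple[float, float, float] = (14.37, 24.3, 30.8)
    min_scan_gap: float = 1.0
    hu_trajectory_benign: tuple[float, float, float] = (-146.0, -156.0, -131.0)
    hu_trajectory_malignant: tuple[float, float, float] = (-314.0, -291.0, -233.0)
    hu_between_sd: float = 120.0
    hu_within_sd: float = 15.0
    morphology_mix_malignant: tuple[int, int, int] = (81, 28, 31)  # solid/part/non
    morphology_mix_benign: tuple[int, int, int] = (40, 0, 0)
    stage_mix_malignant: tuple[int, int, int, int] = (112, 12, 15, 1)  # I-IV
    volumetry_noise: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if sum(self.category_mix_benign) != self.n_benign:
            raise ParameterError("category_mix_benign must sum to n_benign")
        if sum(self.category_mix_malignant) != self.n_malignant:
            raise ParameterError("category_mix_malignant must sum to n_malignant")
        if sum(self.morphology_mix_benign) != self.n_benign:
            raise ParameterError("morphology_mix_benign must sum to n_benign")
        if sum(self.morphology_mix_malignant) != self.n_malignant:
            raise ParameterError("morphology_mix_malignant must sum to n_malignant")
        if sum(self.stage_mix_malignant) != self.n_malignant:
            raise ParameterError("stage_mix_malignant must sum to n_malignant")
        if not 0 <= self.volumetry_noise < 1:
            raise ParameterError("volumetry_noise must be in [0, 1)")
        for group in ("benign", "malignant"):
            if group not in self.fold_change_24mo:
                raise ParameterError(f"fold_change_24mo missing group {group!r}")
            for cat, (lo, hi) in self.fold_change_24mo[group].items():
                if lo <= 1.0 or hi < lo:
                    raise ParameterError(
                        f"fold_change_24mo[{group}][{cat}] must satisfy 1 < lo <= hi"
                    )

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["beta_ranges"] = {k.value: list(v) for k, v in self.beta_ranges.items()}
        d["fold_change_24mo"] = {
            g: {k.value: list(v) for k, v in sub.items()}
            for g, sub in self.fold_change_24mo.items()
        }
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSpec":
        d = json.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown CohortSpec field(s): {sorted(unknown)}")
        if "beta_ranges" in d:
            d["beta_ranges"] = {GrowthCategory(k): tuple(v) for k, v in d["beta_ranges"].items()}
        if "fold_change_24mo" in d:
            d["fold_change_24mo"] = {
                g: {GrowthCategory(k): tuple(v) for k, v in sub.items()}
                for g, sub in d["fold_change_24mo"].items()
            }
        for key, val in list(d.items()):
            if isinstance(val, list):
                d[key] = tuple(val)
        spec = cls(**d)
        spec.validate()
        return spec


def default_cohort_spec() -> CohortSpec:
    """The generator defaults: the reference screening-cohort characteristics
    (group sizes, growth-pattern mixtures, baseline-volume and scan-interval
    quartiles, attenuation trajectories, morphology mix)."""
    spec = CohortSpec()
    spec.validate()
    return spec


def _alpha_for_fold_change(v0: float, beta: float, fc: float, t2: float) -> float:
    if abs(1.0 - beta) < 1e-12:
        return math.log(fc) / t2
    c = 1.0 - beta
    return v0**c * (fc**c - 1.0) / (c * t2)


def _draw_triangular(rng, params, n=None):
    a, m, b = params
    return rng.triangular(a, m, b, size=n)


def generate_cohort(
    spec: CohortSpec, seed: int | None = None, return_truth: bool = False
):
    """Generate a cohort under ``spec``; deterministic for a given seed.

    With ``return_truth`` also returns a DataFrame of the drawn per-nodule
    ground truth (category, beta, alpha, v0, fold-change, scan times).
    """
    import pandas as pd

    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    t1_params = triangular_from_quartiles(*spec.t1_quartiles)
    t2_params = triangular_from_quartiles(*spec.t2_quartiles)

    series: list[NoduleSeries] = []
    truth_rows: list[dict] = []
    for group, n, mix, v0q, morph_mix, hu_traj in (
        ("benign", spec.n_benign, spec.category_mix_benign, spec.v0_quartiles_benign,
         spec.morphology_mix_benign, spec.hu_trajectory_benign),
        ("malignant", spec.n_malignant, spec.category_mix_malignant,
         spec.v0_quartiles_malignant, spec.morphology_mix_malignant,
         spec.hu_trajectory_malignant),
    ):
        mu, sigma = lognormal_from_quartiles(*v0q)
        categories = [c for c, k in zip(CATEGORY_ORDER, mix) for _ in range(k)]
        morphologies = [
            m
            for m, k in zip((Morphology.SOLID, Morphology.PART_SOLID, Morphology.NON_SOLID), morph_mix)
            for _ in range(k)
        ]
        rng.shuffle(morphologies)
        if group == "malignant":
            stages = [s for s, k in zip(("I", "II", "III", "IV"), spec.stage_mix_malignant) for _ in range(k)]
            rng.shuffle(stages)
        else:
            stages = [None] * n

        for i, cat in enumerate(categories):
            nodule_id = f"{group[0].upper()}{i + 1:03d}"
            lo, hi = spec.beta_ranges[cat]
            beta = rng.uniform(lo, hi)
            v0 = float(np.exp(rng.normal(mu, sigma)))
            t1 = float(_draw_triangular(rng, t1_params))
            t2 = float(_draw_triangular(rng, t2_params))
            for _ in range(100):
                if t2 > t1 + spec.min_scan_gap:
                    break
                t2 = float(_draw_triangular(rng, t2_params))
            else:
                t2 = t1 + spec.min_scan_gap + 1.0
            fc_lo, fc_hi = spec.fold_change_24mo[group][cat]
            fc = rng.uniform(fc_lo, fc_hi)
            alpha = _alpha_for_fold_change(v0, beta, fc, t2)
            times = np.array([0.0, t1, t2])
            volumes = vb_solve_forward(v0, alpha, beta, times)
            if spec.volumetry_noise > 0:
                volumes = volumes * (1.0 + rng.uniform(-spec.volumetry_noise, spec.volumetry_noise, 3))
            hu_offset = rng.normal(0.0, spec.hu_between_sd)
            hu = np.asarray(hu_traj) + hu_offset + rng.normal(0.0, spec.hu_within_sd, 3)
            obs = tuple(
                ScanObservation(t, v, h) for t, v, h in zip(times, volumes, hu)
            )
            series.append(
                NoduleSeries(
                    nodule_id=nodule_id,
                    malignancy=Malignancy(group),
                    observations=obs,
                    morphology=morphologies[i],
                    stage=stages[i],
                )
            )
            truth_rows.append(
                {
                    "nodule_id": nodule_id,
                    "malignancy": group,
                    "category": cat.value,
                    "beta": beta,
                    "alpha": alpha,
                    "v0": v0,
                    "fold_change": fc,
                    "t1": t1,
                    "t2": t2,
                }
            )

    cohort = Cohort(series=tuple(series), provenance=f"synthetic(seed={seed if seed is not None else spec.seed})")
    if return_truth:
        return cohort, pd.DataFrame(truth_rows)
    return cohort


def generate_fixture(name: str, seed: int = 0):
    """Named regenerable fixtures.

    tiny
        six nodules: one per growth category (forward-solved, noiseless) plus
        one non-increasing series that fails the inclusion filter.
    default
        the full cohort under :func:`default_cohort_spec` (noiseless).
    degenerate
        edge cases: near-flat growth, an exact beta = 1 exponential series,
        and a beta = 2 nodule observed close to its blow-up time.
    """
    if name == "default":
        return generate_cohort(default_cohort_spec(), seed=seed)
    if name == "tiny":
        series = []
        params = [
            ("T001", GrowthCategory.DECELERATED, -1.0),
            ("T002", GrowthCategory.LINEAR, 0.0),
            ("T003", GrowthCategory.SUBEXPONENTIAL, 0.5),
            ("T004", GrowthCategory.EXPONENTIAL, 1.0),
            ("T005", GrowthCategory.ACCELERATED, 1.4),
        ]
        for i, (nid, cat, beta) in enumerate(params):
            v0 = 100.0 + 10 * i
            alpha = _alpha_for_fold_change(v0, beta, 3.0, 24.0)
            vols = vb_solve_forward(v0, alpha, beta, [0.0, 12.0, 24.0])
            obs = tuple(
                ScanObservation(t, v, -200.0 + 5 * t) for t, v in zip([0.0, 12.0, 24.0], vols)
            )
            series.append(
                NoduleSeries(nid, Malignancy.MALIGNANT if beta > 0.9 else Malignancy.BENIGN,
                             obs, Morphology.SOLID)
            )
        series.append(
            NoduleSeries(
                "T006",
                Malignancy.BENIGN,
                tuple(
                    ScanObservation(t, v, -150.0)
                    for t, v in zip([0.0, 12.0, 24.0], [100.0, 95.0, 120.0])
                ),
                Morphology.SOLID,
            )
        )
        return Cohort(tuple(series), provenance="fixture:tiny")
    if name == "degenerate":
        series = [
            NoduleSeries(
                "D001", Malignancy.BENIGN,
                tuple(ScanObservation(t, v, -150.0) for t, v in zip([0.0, 12.0, 24.0], [100.0, 101.0, 102.0])),
                Morphology.SOLID,
            ),
            NoduleSeries(
                "D002", Malignancy.MALIGNANT,
                tuple(
                    ScanObservation(t, v, -250.0)
                    for t, v in zip([0.0, 12.0, 24.0], vb_solve_forward(100.0, 0.05, 1.0, [0.0, 12.0, 24.0]))
                ),
                Morphology.SOLID,
            ),
            NoduleSeries(
                "D003", Malignancy.MALIGNANT,
                tuple(
                    ScanObservation(t, v, -300.0)
                    for t, v in zip(
                        [0.0, 12.0, 24.0],
                        vb_solve_forward(100.0, _alpha_for_fold_change(100.0, 2.0, 50.0, 24.0), 2.0, [0.0, 12.0, 24.0]),
                    )
                ),
                Morphology.SOLID,
            ),
        ]
        return Cohort(tuple(series), provenance="fixture:degenerate")
    raise ParameterError(f"unknown fixture {name!r} (use tiny, default or degenerate)")
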