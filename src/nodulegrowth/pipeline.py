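"""End-to-end orchestration: fit a cohort, assemble the feature matrix,
summarise growth categories, run the perturbation protocol per nodule and
build the evaluation report. The CLI is a thin wrapper over these functions.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, ExclusionLog, inclusion_filter
from .discrimination import (
    FEATURE_COLUMNS,
    ClassifierEval,
    evaluate_all_features,
    multivariable_score,
)
from .errors import EvaluationError, ParameterError
from .growth import GrowthCategory, VBFit, vb_fit_exact3, vb_fit_ls
from .kinetics import compute_features
from .sensitivity import SensitivityOutcome, sensitivity_analysis

CATEGORY_ORDER = (
    GrowthCategory.DECELERATED,
    GrowthCategory.LINEAR,
    GrowthCategory.SUBEXPONENTIAL,
    GrowthCategory.EXPONENTIAL,
    GrowthCategory.ACCELERATED,
)


def fit_cohort(cohort: Cohort, method: str = "exact3") -> dict[str, VBFit]:
    """Fit the growth law for every series in an (already filtered) cohort.

    ``method="exact3"`` fits the first three scans exactly (the default,
    mirroring the three-measurement protocol); ``"least_squares"`` uses all
    scans.
    """
    if method not in ("exact3", "least_squares"):
        raise ParameterError(f"unknown fit method {method!r}")
    fits = {}
    for s in cohort:
        if method == "exact3":
            fits[s.nodule_id] = vb_fit_exact3(s.observations[:3], nodule_id=s.nodule_id)
        else:
            fits[s.nodule_id] = vb_fit_ls(s.observations, nodule_id=s.nodule_id)
    return fits


def feature_table(cohort: Cohort, method: str = "exact3") -> pd.DataFrame:
    """Feature matrix: one row per nodule, the 16 candidate discriminators
    plus labels. Undefined entries (e.g. missing attenuation) are NaN."""
    fits = fit_cohort(cohort, method)
    rows = []
    for s in cohort:
        fit = fits[s.nodule_id]
        feats = compute_features(s, fit=fit)
        row = {"nodule_id": s.nodule_id, "beta": fit.beta, "alpha": fit.alpha}
        row.update(feats.to_record())
        row["malignancy"] = s.malignancy.value
        row["morphology"] = s.morphology.value
        row["category"] = fit.category.value
        rows.append(row)
    df = pd.DataFrame(rows).set_index("nodule_id")
    return df[list(FEATURE_COLUMNS) + ["malignancy", "morphology", "category"]]


def category_count_table(fits: dict[str, VBFit], cohort: Cohort) -> pd.DataFrame:
    """Growth-category counts by malignancy group (rows: categories)."""
    counts = pd.DataFrame(
        0, index=[c.value for c in CATEGORY_ORDER], columns=["benign", "malignant"]
    )
    for s in cohort:
        counts.loc[fits[s.nodule_id].category.value, s.malignancy.value] += 1
    return counts


def sensitivity_report(
    cohort: Cohort,
    n_reps: int = 200,
    epsilon: float = 0.05,
    threshold: float = 0.5,
    seed: int = 0,
) -> tuple[list[SensitivityOutcome], float]:
    """Run the perturbation protocol on every nodule; per-nodule seeds are
    spawned deterministically from ``seed``. Returns the outcomes and the
    fraction of nodules meeting the robustness criterion."""
    child_seeds = np.random.SeedSequence(seed).generate_state(len(cohort))
    outcomes = [
        sensitivity_analysis(s, n_reps=n_reps, epsilon=epsilon, threshold=threshold, seed=int(cs))
        for s, cs in zip(cohort, child_seeds)
    ]
    frac = float(np.mean([o.robust for o in outcomes])) if outcomes else math.nan
    return outcomes, frac


def evaluation_table(evals: list[ClassifierEval]) -> pd.DataFrame:
    """Flat report table: one row per feature with AUC / sensitivity /
    specificity at the Youden operating point."""
    return pd.DataFrame([e.to_record() for e in evals]).set_index("feature_name")


def _round_floats(obj, ndigits: int | None):
    if ndigits is None:
        return obj
    if isinstance(obj, float):
        return float(f"{obj:.{ndigits}g}") if math.isfinite(obj) else obj
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


@dataclass
class RunReport:
    """Everything one end-to-end run produced, JSON-serializable."""

    config: dict
    n_benign: int
    n_malignant: int
    exclusions: dict
    category_counts: dict
    feature_evals: list[dict]
    sensitivity_fraction_robust: float | None = None
    multivariable: dict | None = None

    def to_json(self, path: str | Path, ndigits: int | None = 6) -> None:
        payload = {
            "version": __version__,
            "config_hash": config_hash(self.config),
            "config": self.config,
            "cohort": {"n_benign": self.n_benign, "n_malignant": self.n_malignant},
            "exclusions": self.exclusions,
            "category_counts": self.category_counts,
            "feature_evals": self.feature_evals,
            "sensitivity_fraction_robust": self.sensitivity_fraction_robust,
            "multivariable": self.multivariable,
        }
        Path(path).write_text(json.dumps(_round_floats(payload, ndigits), indent=2))


def run_pipeline(
    cohort: Cohort,
    min_scans: int = 3,
    fit_method: str = "exact3",
    sensitivity_seed: int = 0,
    n_reps: int = 200,
    epsilon: float = 0.05,
    threshold: float = 0.5,
    run_sensitivity: bool = True,
    multivariable_candidates: list[str] | None = None,
) -> tuple[RunReport, pd.DataFrame]:
    """Filter, fit, featurise, (optionally) perturb and evaluate a cohort."""
    filtered, log = inclusion_filter(cohort, min_scans=min_scans)
    if len(filtered) == 0:
        raise EvaluationError("no nodules remain after the inclusion filter")
    fits = fit_cohort(filtered, fit_method)
    features = feature_table(filtered, fit_method)
    counts = category_count_table(fits, filtered)
    labels = features["malignancy"]
    if labels.nunique() < 2:
        raise EvaluationError("cohort has a single class; evaluation is undefined")
    evals = evaluate_all_features(features)

    frac_robust = None
    if run_sensitivity:
        _, frac_robust = sensitivity_report(
            filtered, n_reps=n_reps, epsilon=epsilon, threshold=threshold, seed=sensitivity_seed
        )

    mv = None
    if multivariable_candidates:
        model = multivariable_score(features, multivariable_candidates)
        mv = {
            "included_features": list(model.included_features),
            "coefficients": model.coefficients,
            "eliminated": list(model.eliminated),
            "penalized": model.penalized,
            "degenerate": model.degenerate,
            "eval": model.eval.to_record(),
        }

    config = {
        "min_scans": min_scans,
        "fit_method": fit_method,
        "n_reps": n_reps,
        "epsilon": epsilon,
        "threshold": threshold,
        "sensitivity_seed": sensitivity_seed,
        "multivariable_candidates": multivariable_candidates,
    }
    report = RunReport(
        config=config,
        n_benign=int((labels == "benign").sum()),
        n_malignant=int((labels == "malignant").sum()),
        exclusions={k: v.value for k, v in log.excluded.items()},
        category_counts={c: counts[c].to_dict() for c in counts.columns},
        feature_evals=[e.to_record() for e in evals],
        sensitivity_fraction_robust=frac_robust,
        multivariable=mv,
    )
    return report, features
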