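"""Benign-vs-malignant evaluation: ROC/AUC, operating points, group tests and
a multivariable growth-rate x morphology score.

AUC here is the tie-aware concordance probability
P(score_mal > score_ben) + 0.5 * P(equal); the ROC curve is built by sweeping
every distinct threshold (no intermediate-point dropping), and the trapezoid
under it equals the pair-counting definition. Each feature's direction is
chosen so the reported AUC is >= 0.5, with the orientation recorded (e.g.
doubling times are lower-is-malignant).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import EvaluationError, ParameterError

#: canonical evaluation order — one row per candidate discriminator
FEATURE_COLUMNS = (
    "beta",
    "alpha",
    "vdt_beta",
    "nu_01",
    "nu_02",
    "nu_12",
    "nu_ls",
    "lambda_01",
    "lambda_02",
    "lambda_12",
    "lambda_ls",
    "vdt_exp_01",
    "vdt_exp_ls",
    "v0",
    "hu0",
    "mass0",
)


@dataclass(frozen=True)
class ClassifierEval:
    """ROC evaluation of one scalar feature as a malignancy classifier."""

    feature_name: str
    auc: float
    direction: str  # "higher_is_malignant" | "lower_is_malignant"
    threshold: float
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int
    roc_points: tuple[tuple[float, float], ...]  # (fpr, tpr)
    n_missing: int = 0

    def to_record(self, include_roc: bool = False) -> dict:
        rec = {
            "feature_name": self.feature_name,
            "auc": self.auc,
            "direction": self.direction,
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "n_missing": self.n_missing,
        }
        if include_roc:
            rec["roc_points"] = [list(p) for p in self.roc_points]
        return rec


def _as_binary_labels(labels) -> np.ndarray:
    y = np.asarray(
        [1 if str(getattr(l, "value", l)) == "malignant" else 0 for l in labels]
    )
    return y


def auc_mann_whitney(scores, labels) -> float:
    """Unfolded (higher-is-malignant) tie-aware AUC via the rank statistic."""
    y = _as_binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("both classes must be present to compute an AUC")
    ranks = stats.rankdata(s)
    return (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def roc_auc(scores, labels) -> tuple[float, np.ndarray, str, np.ndarray]:
    """Threshold-sweep ROC and AUC with automatic orientation.

    Returns ``(auc, roc_points, direction, thresholds)`` where roc_points is an
    (k, 2) array of (fpr, tpr) from (0,0) to (1,1) and thresholds are in
    oriented-score units aligned with roc_points. Non-finite scores must be
    excluded by the caller.
    """
    y = _as_binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise EvaluationError("scores must be finite (exclude missing values first)")
    if y.sum() == 0 or (1 - y).sum() == 0:
        raise EvaluationError("both classes must be present to compute an AUC")

    direction = "higher_is_malignant"
    if auc_mann_whitney(s, labels) < 0.5:
        s = -s
        direction = "lower_is_malignant"
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, np.column_stack([fpr, tpr]), direction, thr


def youden_operating_point(scores, labels) -> tuple[float, float, float, str]:
    """Operating point maximising Youden's J = sensitivity + specificity - 1.

    Ties in J are broken toward higher specificity. The returned threshold is
    in original feature units; the decision rule is "feature >= threshold is
    malignant" for direction higher_is_malignant and "<= threshold" otherwise.
    Returns (threshold, sensitivity, specificity, direction).
    """
    _, points, direction, thr = roc_auc(scores, labels)
    fpr, tpr = points[:, 0], points[:, 1]
    j = tpr - fpr
    best = np.flatnonzero(j >= j.max() - 1e-12)  # tolerance: 1/3 vs 1-2/3 ties
    best = best[np.argmin(fpr[best])]  # higher specificity on ties
    threshold = float(thr[best])
    if direction == "lower_is_malignant":
        threshold = -threshold
    return threshold, float(tpr[best]), float(1.0 - fpr[best]), direction


def evaluate_feature(values, labels, name: str) -> ClassifierEval:
    """ROC evaluation of one feature column, excluding non-finite values."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=object)
    keep = np.isfinite(v)
    n_missing = int((~keep).sum())
    v, y = v[keep], y[keep]
    auc, points, direction, _ = roc_auc(v, y)
    threshold, sens, spec, _ = youden_operating_point(v, y)
    n_pos = int(_as_binary_labels(y).sum())
    return ClassifierEval(
        feature_name=name,
        auc=auc,
        direction=direction,
        threshold=threshold,
        sensitivity=sens,
        specificity=spec,
        n_pos=n_pos,
        n_neg=len(y) - n_pos,
        roc_points=tuple(map(tuple, points)),
        n_missing=n_missing,
    )


def evaluate_all_features(
    features: pd.DataFrame,
    label_col: str = "malignancy",
    feature_cols: tuple[str, ...] = FEATURE_COLUMNS,
) -> list[ClassifierEval]:
    """One :class:`ClassifierEval` per candidate feature, in canonical order."""
    missing = [c for c in feature_cols if c not in features.columns]
    if missing:
        raise EvaluationError(f"feature column(s) missing from the matrix: {missing}")
    if label_col not in features.columns:
        raise EvaluationError(f"label column {label_col!r} missing from the matrix")
    labels = features[label_col].to_numpy()
    return [evaluate_feature(features[c].to_numpy(), labels, c) for c in feature_cols]


@dataclass(frozen=True)
class GroupComparison:
    """Rank-based omnibus comparison with optional adjusted post-hoc pairs."""

    groups: tuple[str, ...]
    statistic: float
    p_value: float
    pairwise: dict[tuple[str, str], float] | None = None
    pairwise_unadjusted: dict[tuple[str, str], float] | None = None


def compare_groups(values, groups) -> GroupComparison:
    """Kruskal-Wallis omnibus test; Holm-adjusted pairwise Mann-Whitney U
    post-hocs when more than two groups are compared."""
    v = np.asarray(values, dtype=float)
    g = np.asarray([str(x) for x in groups])
    names = tuple(sorted(set(g)))
    if len(names) < 2:
        raise ParameterError("need at least two groups to compare")
    samples = [v[g == name] for name in names]
    for name, s in zip(names, samples):
        if len(s) < 2:
            warnings.warn(f"group {name!r} has fewer than 2 observations", stacklevel=2)
    stat, p = stats.kruskal(*samples)
    pairwise = pairwise_raw = None
    if len(names) > 2:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
        raw = [
            stats.mannwhitneyu(v[g == a], v[g == b], alternative="two-sided").pvalue
            for a, b in pairs
        ]
        adj = multipletests(raw, method="holm")[1]
        pairwise = dict(zip(pairs, map(float, adj)))
        pairwise_raw = dict(zip(pairs, map(float, raw)))
    return GroupComparison(
        groups=names,
        statistic=float(stat),
        p_value=float(p),
        pairwise=pairwise,
        pairwise_unadjusted=pairwise_raw,
    )


def ks_normality_screen(values) -> tuple[float, float]:
    """Kolmogorov-Smirnov screen against a fitted normal (reporting only —
    the pipeline's comparisons are rank-based regardless of the outcome)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    stat, p = stats.kstest(v, "norm", args=(v.mean(), v.std(ddof=1)))
    return float(stat), float(p)


@dataclass(frozen=True)
class MultivariableModel:
    """Backward-eliminated logistic score combining candidate features."""

    included_features: tuple[str, ...]
    coefficients: dict[str, float]
    scores: np.ndarray
    eval: ClassifierEval
    penalized: bool = False
    eliminated: tuple[str, ...] = ()
    degenerate: bool = False


MORPHOLOGY_DUMMIES = ("morphology_part_solid", "morphology_non_solid")


def _design_matrix(features: pd.DataFrame, candidates: list[str]) -> pd.DataFrame:
    cols = {}
    for name in candidates:
        if name == "morphology":
            morph = features["morphology"].astype(str)
            cols["morphology_part_solid"] = (morph == "part_solid").astype(float)
            cols["morphology_non_solid"] = (morph == "non_solid").astype(float)
        else:
            cols[name] = pd.to_numeric(features[name], errors="coerce")
    return pd.DataFrame(cols, index=features.index)


def multivariable_score(
    features: pd.DataFrame,
    candidate_set: list[str],
    label_col: str = "malignancy",
    p_stay: float = 0.05,
) -> MultivariableModel:
    """Stepwise (backward Wald) logistic model of malignancy.

    ``candidate_set`` names numeric feature columns and may include
    "morphology", encoded as two indicators (part-solid, non-solid; solid is
    the reference). Terms are removed one at a time — highest Wald p first —
    until every remaining term has p <= ``p_stay``. Scores are the linear
    predictor; the evaluation is in-sample. Perfect separation falls back to
    an L2-penalized fit (flagged, no elimination).
    """
    X_full = _design_matrix(features, list(candidate_set))
    y_all = pd.Series(_as_binary_labels(features[label_col].to_numpy()), index=features.index)
    complete = X_full.notna().all(axis=1) & np.isfinite(X_full).all(axis=1)
    X_full, y = X_full[complete], y_all[complete]
    if y.nunique() < 2:
        raise EvaluationError("both classes must be present to fit the model")

    terms = list(X_full.columns)
    eliminated: list[str] = []
    penalized = False
    params: pd.Series | None = None
    while terms:
        X = sm.add_constant(X_full[terms], has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(res.bse)) or np.any(res.bse > 1e4):
                raise PerfectSeparationError("unstable standard errors")
        except (PerfectSeparationError, np.linalg.LinAlgError):
            clf = LogisticRegression(C=1.0, max_iter=2000)
            clf.fit(X_full[terms].to_numpy(), y.to_numpy())
            params = pd.Series(
                np.concatenate([[clf.intercept_[0]], clf.coef_[0]]), index=["const"] + terms
            )
            penalized = True
            break
        pvals = res.pvalues.drop("const")
        worst = pvals.idxmax()
        if pvals[worst] > p_stay:
            terms.remove(worst)
            eliminated.append(worst)
            continue
        params = res.params
        break

    if not terms or params is None:
        # every candidate eliminated: degenerate intercept-only model
        scores = np.zeros(int(complete.sum()))
        ev = ClassifierEval(
            feature_name="multivariable",
            auc=0.5,
            direction="higher_is_malignant",
            threshold=0.0,
            sensitivity=1.0,
            specificity=0.0,
            n_pos=int(y.sum()),
            n_neg=int((1 - y).sum()),
            roc_points=((0.0, 0.0), (1.0, 1.0)),
        )
        return MultivariableModel((), {}, scores, ev, penalized, tuple(eliminated), True)

    lin = params["const"] + X_full[terms].to_numpy() @ params[terms].to_numpy()
    ev = evaluate_feature(lin, y.map({1: "malignant", 0: "benign"}).to_numpy(), "multivariable")
    return MultivariableModel(
        included_features=tuple(terms),
        coefficients={k: float(v) for k, v in params.items()},
        scores=np.asarray(lin, dtype=float),
        eval=ev,
        penalized=penalized,
        eliminated=tuple(eliminated),
        degenerate=False,
    )
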