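"""ROC/AUC, operating points, group tests and the multivariable score."""

import numpy as np
import pandas as pd
import pytest

from nodulegrowth import (
    FEATURE_COLUMNS,
    compare_groups,
    evaluate_all_features,
    evaluate_feature,
    multivariable_score,
    roc_auc,
    youden_operating_point,
)
from nodulegrowth.discrimination import auc_mann_whitney, ks_normality_screen
from nodulegrowth.errors import EvaluationError, ParameterError


def brute_force_auc(scores, labels):
    """Independent oracle: tie-aware concordant-pair counting."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == "malignant"]
    neg = s[y == "benign"]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def labelled(benign, malignant):
    scores = np.concatenate([benign, malignant])
    labels = np.array(["benign"] * len(benign) + ["malignant"] * len(malignant))
    return scores, labels


class TestAUC:
    def test_perfect_separation(self):
        auc, points, direction, _ = roc_auc(*labelled([1, 2], [3, 4]))
        assert auc == 1.0 and direction == "higher_is_malignant"
        assert tuple(points[0]) == (0.0, 0.0) and tuple(points[-1]) == (1.0, 1.0)

    def test_identical_distributions(self):
        auc, _, _, _ = roc_auc(*labelled([1, 2, 3], [1, 2, 3]))
        assert auc == pytest.approx(0.5)

    def test_tied_example_seven_ninths(self):
        scores, labels = labelled([1, 2, 3], [2, 3, 4])
        auc, _, _, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(7 / 9, abs=1e-12)
        assert brute_force_auc(scores, labels) == pytest.approx(7 / 9, abs=1e-15)

    def test_sweep_equals_pair_counting_on_random_instances(self, rng):
        """1000 random small instances with heavy ties: trapezoid ROC area
        equals the tie-aware pair count to 1e-12."""
        for _ in range(1000):
            n_pos = rng.integers(1, 16)
            n_neg = rng.integers(1, 16)
            scores = rng.integers(0, 6, n_pos + n_neg).astype(float)
            labels = np.array(["malignant"] * n_pos + ["benign"] * n_neg)
            auc, _, direction, _ = roc_auc(scores, labels)
            bf = brute_force_auc(scores, labels)
            expected = bf if direction == "higher_is_malignant" else 1.0 - bf
            assert abs(auc - expected) < 1e-12

    def test_monotone_invariance(self):
        scores, labels = labelled([0.1, 0.4, 0.7, 0.9], [0.3, 0.8, 1.2, 2.0])
        base, _, _, _ = roc_auc(scores, labels)
        for f in (np.exp, lambda x: 3 * x + 1, np.arctan, lambda x: x**3):
            auc, _, _, _ = roc_auc(f(scores), labels)
            assert auc == pytest.approx(base, abs=1e-12)

    def test_direction_bookkeeping(self):
        scores, labels = labelled([5, 6, 7], [1, 2, 3])
        auc, _, direction, _ = roc_auc(scores, labels)
        assert direction == "lower_is_malignant" and auc == 1.0
        flipped = np.where(labels == "benign", "malignant", "benign")
        auc2, _, direction2, _ = roc_auc(scores, flipped)
        assert direction2 == "higher_is_malignant" and auc2 == auc

    def test_single_class_raises(self):
        with pytest.raises(EvaluationError):
            roc_auc([1, 2, 3], ["benign"] * 3)
        with pytest.raises(EvaluationError):
            roc_auc([1, np.nan], ["benign", "malignant"])


class TestYouden:
    def test_perfect(self):
        _, sens, spec, _ = youden_operating_point(*labelled([1, 2], [3, 4]))
        assert sens == 1.0 and spec == 1.0

    def test_identical_distributions_trivial_point(self):
        scores, labels = labelled([1, 2, 3], [1, 2, 3])
        _, sens, spec, _ = youden_operating_point(scores, labels)
        assert sens + spec - 1 == pytest.approx(0.0, abs=1e-12)

    def test_tie_broken_toward_specificity(self):
        # J = 1/3 at three cut-points; report the high-specificity one
        thr, sens, spec, direction = youden_operating_point(*labelled([1, 2, 3], [2, 3, 4]))
        assert direction == "higher_is_malignant"
        assert (sens, spec) == (pytest.approx(1 / 3), pytest.approx(1.0))
        assert 3 < thr <= 4


class TestEvaluateAll:
    def test_constructed_dominance(self, rng):
        n = 60
        df = pd.DataFrame({c: rng.normal(size=2 * n) for c in FEATURE_COLUMNS})
        df["malignancy"] = ["benign"] * n + ["malignant"] * n
        df.loc[df.malignancy == "malignant", "nu_02"] += 3.0
        evals = {e.feature_name: e for e in evaluate_all_features(df)}
        assert evals["nu_02"].auc > 0.9
        assert evals["nu_02"].direction == "higher_is_malignant"
        assert [e.feature_name for e in evaluate_all_features(df)] == list(FEATURE_COLUMNS)

    def test_missing_column_named(self):
        df = pd.DataFrame({"beta": [1.0, 2.0], "malignancy": ["benign", "malignant"]})
        with pytest.raises(EvaluationError, match="alpha"):
            evaluate_all_features(df)

    def test_missing_values_excluded_and_counted(self):
        vals = np.array([1.0, np.nan, 2.0, 3.0, np.inf, 4.0])
        labels = np.array(["benign", "benign", "benign", "malignant", "malignant", "malignant"])
        ev = evaluate_feature(vals, labels, "x")
        assert ev.n_missing == 2 and ev.n_pos == 2 and ev.n_neg == 2


class TestMultivariable:
    def test_single_candidate_matches_raw_feature(self, rng):
        n = 80
        x = np.concatenate([rng.normal(0, 1, n), rng.normal(1.5, 1, n)])
        labels = ["benign"] * n + ["malignant"] * n
        df = pd.DataFrame({"x": x, "malignancy": labels})
        model = multivariable_score(df, ["x"])
        raw = evaluate_feature(x, np.array(labels), "x")
        assert model.eval.auc == pytest.approx(raw.auc, abs=1e-12)
        assert model.included_features == ("x",)

    def test_noise_candidate_eliminated(self, rng):
        n = 90
        informative = np.concatenate([rng.normal(0, 1, n), rng.normal(2.0, 1, n)])
        noise = rng.normal(size=2 * n)
        labels = ["benign"] * n + ["malignant"] * n
        df = pd.DataFrame({"nu": informative, "junk": noise, "malignancy": labels})
        model = multivariable_score(df, ["nu", "junk"])
        assert model.included_features == ("nu",)
        assert "junk" in model.eliminated

    def test_separable_falls_back_penalized(self):
        df = pd.DataFrame(
            {"x": [0.0, 1.0, 2.0, 10.0, 11.0, 12.0],
             "malignancy": ["benign"] * 3 + ["malignant"] * 3}
        )
        model = multivariable_score(df, ["x"])
        assert model.penalized and model.eval.auc == 1.0

    def test_morphology_indicators(self, rng):
        n = 40
        df = pd.DataFrame(
            {
                "nu": np.concatenate([rng.normal(0, 1, n), rng.normal(2, 1, n)]),
                "morphology": ["solid"] * n + ["part_solid", "non_solid"] * (n // 2),
                "malignancy": ["benign"] * n + ["malignant"] * n,
            }
        )
        model = multivariable_score(df, ["nu", "morphology"])
        assert set(model.coefficients) >= {"const", "nu"}
        assert len(model.scores) == 2 * n


class TestGroupComparison:
    def test_identical_groups(self):
        res = compare_groups([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.p_value == pytest.approx(1.0, abs=0.05)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_full_rank_separation(self):
        res = compare_groups([1, 2, 3, 101, 102, 103], ["a"] * 3 + ["b"] * 3)
        assert res.p_value < 0.1  # maximal separation at n=3+3
        assert res.pairwise is None  # only two groups: no post-hocs

    def test_holm_adjustment_monotone(self, rng):
        vals = rng.normal(size=30)
        groups = np.repeat(["a", "b", "c"], 10)
        res = compare_groups(vals, groups)
        for pair, adj in res.pairwise.items():
            assert adj >= res.pairwise_unadjusted[pair] - 1e-15

    def test_single_group_raises_and_small_group_warns(self):
        with pytest.raises(ParameterError):
            compare_groups([1, 2], ["a", "a"])
        with pytest.warns(UserWarning):
            compare_groups([1, 2, 3, 4], ["a", "b", "b", "b"])

    def test_ks_screen_reports(self, rng):
        stat, p = ks_normality_screen(rng.normal(size=200))
        assert 0 <= stat <= 1 and 0 <= p <= 1


def test_mann_whitney_auc_unfolded():
    scores, labels = labelled([5, 6, 7], [1, 2, 3])
    assert auc_mann_whitney(scores, labels) == 0.0  # unfolded, not clipped at 0.5
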