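from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirmeth import (
    AnalysisError,
    ConfusionTable,
    RunConfig,
    ValidationError,
    build_expression_matrix,
    confusion_from_calls,
    evaluate_panel,
    metrics_from_confusion,
    optimize_threshold,
    score_cohort,
)
from mirmeth.diagnostics import round_percent


def series(values, prefix="S"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])


def brute_force_best_ca(values, truth):
    """Independent oracle: exhaustively try every achievable threshold rule
    (positive iff value <= t) including the two constant classifiers, and
    return the maximum number of correct assignments."""
    values = np.asarray(values, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    cutpoints = set(values) | {-np.inf}
    best = -1
    for c in cutpoints:
        pred = values <= c
        best = max(best, int((pred == truth).sum()))
    return best


class TestConfusion:
    def test_perfect_prediction(self):
        truth = series([True] * 9 + [False] * 7)
        c = confusion_from_calls(truth, truth)
        assert (c.tp, c.fp, c.tn, c.fn) == (9, 0, 7, 0)

    def test_all_positive_degenerate(self):
        truth = series([True] * 9 + [False] * 7)
        pred = series([True] * 16)
        c = confusion_from_calls(pred, truth)
        assert (c.tp, c.fp, c.tn, c.fn) == (9, 7, 0, 0)

    def test_reported_low_normal_counts(self):
        # 9/9 hypermethylators called low; 4/7 non-hypermethylators normal
        truth = series([True] * 9 + [False] * 7)
        pred = series([True] * 9 + [True] * 3 + [False] * 4)
        c = confusion_from_calls(pred, truth)
        assert (c.tp, c.fn, c.tn, c.fp) == (9, 0, 4, 3)

    def test_disjoint_sample_sets_rejected(self):
        with pytest.raises(ValidationError):
            confusion_from_calls(series([True], "A"), series([True], "B"))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            ConfusionTable(tp=-1, fp=0, tn=0, fn=0)


class TestMetrics:
    def test_counts_9_0_4_3(self):
        m = metrics_from_confusion(ConfusionTable(tp=9, fn=0, tn=4, fp=3))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv, m.ca) == (
            100, 57, 75, 100, 81
        )

    def test_counts_9_0_3_4(self):
        m = metrics_from_confusion(ConfusionTable(tp=9, fn=0, tn=3, fp=4))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv, m.ca) == (
            100, 43, 69, 100, 75
        )

    def test_zero_denominator_is_na(self):
        m = metrics_from_confusion(ConfusionTable(tp=0, fp=0, tn=4, fn=3))
        assert m.ppv is None
        assert m.specificity == 100
        assert m.npv is not None

    @pytest.mark.parametrize("num,den,expected", [(10, 16, 63), (11, 16, 69)])
    def test_half_up_rounding(self, num, den, expected):
        assert round_percent(num / den) == expected

    def test_half_up_vs_banker_differ_at_half(self):
        assert round_percent(0.125, "half_up") == 13
        assert round_percent(0.125, "banker") == 12

    @given(
        tp=st.integers(0, 30), fp=st.integers(0, 30),
        tn=st.integers(0, 30), fn=st.integers(0, 30),
    )
    @settings(max_examples=300, deadline=None)
    def test_bayes_consistency_exact(self, tp, fp, tn, fn):
        """PPV = sens*pi / (sens*pi + (1-spec)(1-pi)) as exact rationals."""
        c = ConfusionTable(tp=tp, fp=fp, tn=tn, fn=fn)
        if c.n == 0 or c.n_positive == 0 or c.n_negative == 0:
            return
        if tp + fp == 0:
            assert metrics_from_confusion(c).ppv is None
            return
        sens = Fraction(tp, tp + fn)
        spec = Fraction(tn, tn + fp)
        pi = Fraction(c.n_positive, c.n)
        rhs = sens * pi / (sens * pi + (1 - spec) * (1 - pi))
        assert Fraction(tp, tp + fp) == rhs
        ppv_float = metrics_from_confusion(c).fractions["ppv"]
        assert ppv_float == pytest.approx(float(rhs), rel=1e-12)


class TestOptimizeThreshold:
    def test_separable(self):
        expr = series([0.2, 0.3, 0.4, 1.1, 1.5, 2.0])
        truth = series([True, True, True, False, False, False])
        r = optimize_threshold(expr, truth)
        assert r.metrics.ca == 100
        assert 0.4 < r.threshold < 1.1

    def test_all_identical_values(self):
        expr = series([1.0] * 10)
        truth = series([True] * 3 + [False] * 7)
        r = optimize_threshold(expr, truth)
        # only the two constant classifiers exist; CA = max(pi, 1-pi)
        assert r.metrics.fractions["ca"] == 0.7
        assert r.tie_set_size >= 1

    def test_one_class_truth_errors(self):
        with pytest.raises(AnalysisError):
            optimize_threshold(series([1.0, 2.0]), series([True, True]))

    def test_too_few_samples_errors(self):
        with pytest.raises(AnalysisError):
            optimize_threshold(series([1.0]), series([True]))

    @given(st.data())
    @settings(max_examples=400, deadline=None)
    def test_matches_brute_force_oracle(self, data):
        n = data.draw(st.integers(2, 12))
        values = data.draw(
            st.lists(
                st.floats(0.01, 100.0, allow_nan=False),
                min_size=n, max_size=n,
            )
        )
        truth = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda t: any(t) and not all(t)
            )
        )
        r = optimize_threshold(series(values), series(truth))
        best = brute_force_best_ca(values, truth)
        assert r.confusion.tp + r.confusion.tn == best

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_rank_invariance_under_monotone_transform(self, data):
        n = data.draw(st.integers(3, 10))
        # well-separated values: adjacent floats would collapse under log
        grid = data.draw(
            st.lists(st.integers(1, 5000), min_size=n, max_size=n, unique=True)
        )
        values = [g / 7.0 for g in grid]
        truth = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda t: any(t) and not all(t)
            )
        )
        r1 = optimize_threshold(series(values), series(truth))
        transformed = [np.log(v) * 3 + 7 for v in values]
        r2 = optimize_threshold(series(transformed), series(truth))
        assert r1.confusion == r2.confusion
        assert r1.tie_set_size == r2.tie_set_size

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_ca_at_least_constant_classifier(self, data):
        n = data.draw(st.integers(2, 15))
        values = data.draw(
            st.lists(st.floats(0.01, 10.0), min_size=n, max_size=n)
        )
        truth = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda t: any(t) and not all(t)
            )
        )
        r = optimize_threshold(series(values), series(truth))
        pi = sum(truth) / n
        assert r.metrics.fractions["ca"] >= max(pi, 1 - pi) - 1e-12

    def test_threshold_between_observations_and_tiebreak(self):
        # two CA-maximizing candidates; tie broken toward higher sensitivity
        expr = series([1.0, 2.0, 3.0, 4.0])
        truth = series([True, True, False, False])
        r = optimize_threshold(expr, truth)
        assert r.threshold == pytest.approx(2.5)
        assert r.metrics.sensitivity == 100


class TestEvaluatePanel:
    def test_default_cohort(self, default_cohort, config):
        from mirmeth import build_expression_matrix, score_cohort

        ct_table, meta, _ = default_cohort
        matrix = build_expression_matrix(ct_table, meta, config)
        scores = score_cohort(matrix, meta, config)
        results = evaluate_panel(matrix, scores, config)
        assert [r.assay_id for r in results] == list(config.mir_panel)
        for r in results:
            truth = scores.loc[
                scores["subtype"] == "basal_like", "hypermethylator"
            ]
            pi = truth.mean()
            assert r.metrics.fractions["ca"] >= max(pi, 1 - pi) - 1e-12
            assert r.confusion.n_positive == truth.sum()

    def test_one_class_subset_errors(self, default_cohort, config):
        ct_table, meta, _ = default_cohort
        matrix = build_expression_matrix(ct_table, meta, config)
        scores = score_cohort(matrix, meta, config)
        scores = scores.copy()
        scores["hypermethylator"] = False
        with pytest.raises(AnalysisError):
            evaluate_panel(matrix, scores, config)

    def test_empty_subset_errors(self, default_cohort, config):
        ct_table, meta, _ = default_cohort
        matrix = build_expression_matrix(ct_table, meta, config)
        scores = score_cohort(matrix, meta, config)
        with pytest.raises(AnalysisError):
            evaluate_panel(matrix, scores, config, subset=[])
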