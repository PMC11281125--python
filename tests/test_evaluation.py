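"""Confusion counts, sensitivity/precision/F1, ROC and AUC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fundustruct.evaluation import (ConfusionCounts, confusion_from_predictions,
                                    metrics, report_from_predictions, roc_curve)

G, N = "glaucoma", "normal"


def concordance_auc(labels, scores, positive=G):
    """Independent AUC oracle: Mann-Whitney pairwise concordance with
    ties counted one half."""
    pos = [s for l, s in zip(labels, scores) if l == positive]
    neg = [s for l, s in zip(labels, scores) if l != positive]
    wins = sum(1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_hand_counted_example(self):
        c = confusion_from_predictions([G, G, N, N], [G, N, N, N], positive=G)
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 0, 2)

    def test_perfect_predictions(self):
        c = confusion_from_predictions([G, N, G], [G, N, G], positive=G)
        assert c.fp == 0 and c.fn == 0
        assert c.total == 3

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            confusion_from_predictions([], [], positive=G)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_from_predictions([G], [G, N], positive=G)

    def test_swapping_positive_class_swaps_roles(self):
        labels = [G, G, N, N, N]
        preds = [G, N, G, N, N]
        a = confusion_from_predictions(labels, preds, positive=G)
        b = confusion_from_predictions(labels, preds, positive=N)
        assert a.tp == b.tn and a.tn == b.tp and a.fp == b.fn and a.fn == b.fp

    def test_permutation_invariance(self, rng):
        labels = [G if x else N for x in rng.integers(0, 2, 30)]
        preds = [G if x else N for x in rng.integers(0, 2, 30)]
        perm = rng.permutation(30)
        a = confusion_from_predictions(labels, preds, positive=G)
        b = confusion_from_predictions([labels[i] for i in perm],
                                       [preds[i] for i in perm], positive=G)
        assert (a.tp, a.fp, a.fn, a.tn) == (b.tp, b.fp, b.fn, b.tn)


class TestMetrics:
    def test_hand_arithmetic(self):
        sens, prec, f1 = metrics(ConfusionCounts(tp=9, fn=1, fp=1, tn=9))
        assert sens == pytest.approx(0.9)
        assert prec == pytest.approx(0.9)
        assert f1 == pytest.approx(0.9)

    def test_perfect_counts(self):
        sens, prec, f1 = metrics(ConfusionCounts(tp=5, fn=0, fp=0, tn=5))
        assert (sens, prec, f1) == (1.0, 1.0, 1.0)

    def test_undefined_precision_reported_as_nan(self):
        with pytest.warns(UserWarning, match="precision undefined"):
            sens, prec, f1 = metrics(ConfusionCounts(tp=0, fn=3, fp=0, tn=2))
        assert sens == 0.0
        assert np.isnan(prec) and np.isnan(f1)

    def test_f1_is_harmonic_mean(self, rng):
        for _ in range(20):
            tp, fn, fp, tn = rng.integers(1, 50, 4)
            sens, prec, f1 = metrics(ConfusionCounts(int(tp), int(fp), int(fn), int(tn)))
            assert f1 == pytest.approx(2 * prec * sens / (prec + sens))


class TestRoc:
    def test_perfect_separation(self):
        _, auc = roc_curve([G, G, N, N], [0.9, 0.8, 0.2, 0.1])
        assert auc == pytest.approx(1.0)

    def test_all_tied_scores(self):
        _, auc = roc_curve([G, N, G, N], [0.5, 0.5, 0.5, 0.5])
        assert auc == pytest.approx(0.5)

    def test_four_sample_toy(self):
        """3 concordant pairs of 4 -> AUC 0.75, against the pairwise oracle."""
        labels = [G, N, G, N]
        scores = [0.9, 0.8, 0.4, 0.3]
        _, auc = roc_curve(labels, scores)
        assert auc == pytest.approx(0.75)
        assert auc == pytest.approx(concordance_auc(labels, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([G, G], [0.4, 0.6])

    def test_curve_endpoints_and_monotonicity(self, rng):
        labels = [G if x else N for x in rng.integers(0, 2, 40)]
        labels[0], labels[1] = G, N
        scores = rng.random(40).tolist()
        points, _ = roc_curve(labels, scores)
        fpr = [p[0] for p in points]
        tpr = [p[1] for p in points]
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)
        assert all(a <= b for a, b in zip(fpr, fpr[1:]))
        assert all(a <= b for a, b in zip(tpr, tpr[1:]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.booleans(),
                              st.floats(0, 1, allow_nan=False, width=16)),
                    min_size=4, max_size=60))
    def test_trapezoid_equals_concordance(self, pairs):
        """Trapezoidal AUC equals the Mann-Whitney estimator."""
        labels = [G if b else N for b, _ in pairs]
        scores = [s for _, s in pairs]
        if len(set(labels)) < 2:
            labels[0], labels[1] = G, N
        _, auc = roc_curve(labels, scores)
        assert auc == pytest.approx(concordance_auc(labels, scores), abs=1e-9)


class TestReports:
    def test_constant_classifier_degenerates_gracefully(self):
        """A model that always answers glaucoma: sensitivity 1, precision
        equal to prevalence, AUC 0.5 from tied scores."""
        labels = [G, G, N, N, N]
        preds = [G] * 5
        with pytest.warns(UserWarning):
            report = report_from_predictions(labels, preds, scores=[0.7] * 5)
        assert report.per_class[G]["sensitivity"] == 1.0
        assert report.per_class[G]["precision"] == pytest.approx(2 / 5)
        assert report.auc == pytest.approx(0.5)

    def test_model_report_fields(self, attention_run):
        report = attention_run["report"]
        for cls in (G, N):
            row = report.per_class[cls]
            s, p, f = row["sensitivity"], row["precision"], row["f1"]
            if not (np.isnan(s) or np.isnan(p)):
                assert f == pytest.approx(2 * p * s / (p + s))
        assert 0.0 <= report.auc <= 1.0
        assert report.extra["n_samples"] == 16
        assert report.to_json()
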