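"""ROC / AUC / DeLong: brute-force oracles and rank invariances."""

import subprocess
import sys
import textwrap

import numpy as np
import pytest

from abratio.classification import (
    auc,
    classification_stats,
    delong_paired_test,
    roc_curve,
)


def brute_force_auc(pos, neg):
    """Pairwise comparison count: wins + half-ties over all pos x neg pairs."""
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def labelled(pos, neg):
    scores = np.concatenate([pos, neg])
    labels = np.array(["positive"] * len(pos) + ["negative"] * len(neg))
    return scores, labels


class TestAUC:
    def test_perfect_separation_lower_positive(self):
        scores, labels = labelled([0.03, 0.04], [0.08, 0.09])
        assert auc(scores, labels) == 1.0

    def test_enumerated_four_pair_example(self):
        scores, labels = labelled([1, 3], [2, 4])
        assert auc(scores, labels, orientation="higher_is_positive") == 0.25

    def test_all_ties_give_half(self):
        scores, labels = labelled([5.0, 5.0, 5.0], [5.0, 5.0])
        assert auc(scores, labels) == 0.5

    @pytest.mark.parametrize("n_pos,n_neg", [(3, 4), (10, 10), (25, 25), (50, 37)])
    def test_rank_identity_equals_brute_force(self, rng, n_pos, n_neg):
        pos = np.round(rng.normal(1, 1, n_pos), 1)  # rounding induces ties
        neg = np.round(rng.normal(0, 1, n_neg), 1)
        scores, labels = labelled(pos, neg)
        assert auc(scores, labels, orientation="higher_is_positive") == pytest.approx(
            brute_force_auc(pos, neg), abs=1e-12
        )

    def test_invariance_under_monotone_transform(self, rng):
        pos, neg = rng.normal(-1, 1, 20), rng.normal(0, 1, 25)
        scores, labels = labelled(pos, neg)
        ref = auc(scores, labels)
        assert auc(np.exp(scores), labels) == pytest.approx(ref)
        assert auc(scores**3, labels) == pytest.approx(ref)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc(np.array([1.0, 2.0]), np.array(["positive", "positive"]))


class TestROCCurve:
    def test_trapezoid_area_equals_rank_auc_on_random_data(self, rng):
        pos = np.round(rng.normal(0.06, 0.01, 30), 3)
        neg = np.round(rng.normal(0.08, 0.01, 35), 3)
        scores, labels = labelled(pos, neg)
        roc = roc_curve(scores, labels)  # internal assertion checks the identity
        assert 0 <= roc.auc <= 1

    def test_perfect_marker_reaches_the_corner(self):
        scores, labels = labelled([0.03, 0.04], [0.08, 0.09])
        roc = roc_curve(scores, labels)
        corner = roc.curve[(roc.curve.sensitivity == 1) & (roc.curve.specificity == 1)]
        assert len(corner) == 1

    def test_single_distinct_score_is_diagonal(self):
        scores, labels = labelled([2.0, 2.0], [2.0])
        roc = roc_curve(scores, labels)
        assert roc.auc == 0.5
        assert len(roc.curve) == 2


class TestDeLong:
    def test_identical_markers_give_p_one(self, rng):
        pos, neg = rng.normal(0.06, 0.01, 20), rng.normal(0.08, 0.01, 25)
        scores, labels = labelled(pos, neg)
        res = delong_paired_test(scores, scores, labels)
        assert res.delta_auc == 0.0
        assert res.p == 1.0
        assert res.degenerate

    def test_monotone_transform_gives_zero_delta(self, rng):
        pos, neg = rng.normal(0.06, 0.01, 20), rng.normal(0.08, 0.01, 25)
        scores, labels = labelled(pos, neg)
        res = delong_paired_test(scores, np.log(scores), labels)
        assert res.delta_auc == pytest.approx(0.0, abs=1e-12)
        assert res.degenerate  # identical placements -> zero variance

    def test_null_p_values_are_uniform(self, rng):
        """Two equally informative markers sharing a latent: p ~ U(0,1)."""
        from scipy import stats

        ps = []
        for _ in range(500):
            latent = np.concatenate([rng.normal(1.0, 1, 25), rng.normal(0.0, 1, 25)])
            labels = np.array(["positive"] * 25 + ["negative"] * 25)
            a = latent + rng.normal(0, 1, 50)
            b = latent + rng.normal(0, 1, 50)
            res = delong_paired_test(a, b, labels, orientation="higher_is_positive")
            ps.append(res.p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_matches_r_proc_reference(self, tmp_path):
        """Cross-check z and p against the pROC implementation."""
        rng = np.random.default_rng(2024)
        n = 40
        labels_int = np.repeat([1, 0], [18, 22])
        latent = np.where(labels_int == 1, 1.2, 0.0) + rng.normal(0, 1, n)
        a = np.round(latent + rng.normal(0, 0.8, n), 6)
        b = np.round(latent + rng.normal(0, 0.8, n), 6)
        labels = np.where(labels_int == 1, "positive", "negative")
        ours = delong_paired_test(a, b, labels, orientation="higher_is_positive")
        script = textwrap.dedent(
            f"""
            suppressMessages(library(pROC))
            y <- c({", ".join(map(str, labels_int))})
            a <- c({", ".join(map(str, a))})
            b <- c({", ".join(map(str, b))})
            ra <- roc(y, a, direction="<", quiet=TRUE)
            rb <- roc(y, b, direction="<", quiet=TRUE)
            t <- roc.test(ra, rb, method="delong", paired=TRUE)
            cat(sprintf("%.10f %.10f %.10f", auc(ra), auc(rb), t$p.value))
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        auc_a_r, auc_b_r, p_r = map(float, out.stdout.split())
        assert ours.auc_a == pytest.approx(auc_a_r, abs=1e-9)
        assert ours.auc_b == pytest.approx(auc_b_r, abs=1e-9)
        assert ours.p == pytest.approx(p_r, abs=1e-6)


class TestClassificationStats:
    def test_perfect_separation(self):
        scores, labels = labelled([0.03, 0.04], [0.08, 0.09])
        stats_ = classification_stats(scores, labels)
        assert stats_.sensitivity == 1.0
        assert stats_.specificity == 1.0
        assert stats_.youden_j == 1.0

    def test_uninformative_scores_have_zero_j(self):
        scores, labels = labelled([5.0, 5.0], [5.0, 5.0, 5.0])
        stats_ = classification_stats(scores, labels)
        assert stats_.youden_j == pytest.approx(0.0)

    def test_hand_counted_contingency_table(self):
        # threshold 0.06, lower-is-positive: calls pos <= 0.06
        pos = [0.03, 0.05, 0.06, 0.09]       # tp=3, fn=1
        neg = [0.04, 0.07, 0.08, 0.09, 0.10] # fp=1, tn=4
        scores, labels = labelled(pos, neg)
        stats_ = classification_stats(scores, labels, threshold=0.06)
        assert stats_.sensitivity == pytest.approx(3 / 4)
        assert stats_.specificity == pytest.approx(4 / 5)
        assert stats_.ppv == pytest.approx(3 / 4)
        assert stats_.npv == pytest.approx(4 / 5)
        assert stats_.accuracy == pytest.approx(7 / 9)

    def test_youden_rule_beats_any_fixed_threshold(self, rng):
        pos = rng.normal(0.06, 0.012, 30)
        neg = rng.normal(0.08, 0.012, 30)
        scores, labels = labelled(pos, neg)
        best = classification_stats(scores, labels)
        for t in np.quantile(scores, [0.1, 0.3, 0.5, 0.7, 0.9]):
            fixed = classification_stats(scores, labels, threshold=float(t))
            assert best.youden_j >= fixed.youden_j - 1e-12
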