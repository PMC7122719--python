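import itertools

import numpy as np
import pytest

from psychembed.evaluate import (
    align_clusters,
    bootstrap_evaluate,
    classification_metrics,
    contrast_labels,
    fit_gmm_binary,
    permutation_test_means,
    tsne_project,
)


def brute_force_auc(probs, labels):
    """AUC by enumeration over all (positive, negative) pairs, ties 0.5."""
    pos = [p for p, y in zip(probs, labels) if y == 1]
    neg = [p for p, y in zip(probs, labels) if y == 0]
    total = 0.0
    for a, b in itertools.product(pos, neg):
        total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestContrasts:
    def test_case_vs_rest(self):
        groups = ["case", "control", "supercontrol"]
        np.testing.assert_array_equal(contrast_labels(groups, "C_vs_CS"), [1, 0, 0])
        np.testing.assert_array_equal(contrast_labels(groups, "CC_vs_S"), [1, 1, 0])

    def test_unknown_group_or_contrast(self):
        with pytest.raises(ValueError, match="contrast"):
            contrast_labels(["case"], "bogus")
        with pytest.raises(ValueError, match="group"):
            contrast_labels(["patient"], "C_vs_CS")


class TestGmm:
    def test_separated_gaussians_recovered(self):
        rng = np.random.default_rng(0)
        X = np.vstack(
            [rng.standard_normal((100, 3)) - 5, rng.standard_normal((100, 3)) + 5]
        )
        truth = np.repeat([0, 1], 100)
        post = fit_gmm_binary(X, seed=0)
        hard = (post[:, 1] > 0.5).astype(int)
        agreement = max(np.mean(hard == truth), np.mean(hard != truth))
        assert agreement >= 0.99

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(1)
        post = fit_gmm_binary(rng.standard_normal((50, 4)), seed=0)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_degenerate_duplicated_cluster_warns(self, caplog):
        X = np.tile([[1.0, 2.0]], (40, 1)) + 1e-9 * np.random.default_rng(2).standard_normal((40, 2))
        with caplog.at_level("WARNING"):
            fit_gmm_binary(X, seed=0, on_nonconvergence="warn")
        assert "unstable" in caplog.text


class TestAlignClusters:
    def test_anti_aligned_posteriors_flipped(self):
        labels = np.array([1, 1, 0, 0])
        post = np.array([0.1, 0.2, 0.9, 0.8])
        out = align_clusters(post, labels)
        np.testing.assert_allclose(out, 1 - post)
        assert classification_metrics(out, labels)["AUC"] == 1.0

    def test_exact_half_auc_unchanged(self):
        labels = np.array([1, 0])
        post = np.array([0.5, 0.5])
        np.testing.assert_array_equal(align_clusters(post, labels), post)

    def test_oriented_auc_lower_bound_with_saturated_posteriors(self):
        # mixture posteriors saturate toward 0/1; orientation must still
        # guarantee AUC >= 0.5 even when labels are pure noise
        rng = np.random.default_rng(3)
        for i in range(20):
            X = rng.standard_normal((150, 5))
            y = (rng.random(150) < 0.5).astype(int)
            post = fit_gmm_binary(X, seed=i)
            auc = classification_metrics(align_clusters(post, y), y)["AUC"]
            assert auc >= 0.5

    def test_random_labels_oriented_auc_near_half(self):
        rng = np.random.default_rng(4)
        aucs = []
        for i in range(10):
            X = rng.standard_normal((400, 3))
            y = (rng.random(400) < 0.5).astype(int)
            prob = align_clusters(
                fit_gmm_binary(X, seed=i, on_nonconvergence="warn"), y
            )
            aucs.append(classification_metrics(prob, y)["AUC"])
        assert 0.5 <= np.mean(aucs) <= 0.6


class TestClassificationMetrics:
    def test_perfect_probabilities(self):
        m = classification_metrics(np.array([1.0, 1, 0, 0]), np.array([1, 1, 0, 0]))
        assert m == {"ACC": 1.0, "AUC": 1.0, "FPR": 0.0, "FNR": 0.0}

    def test_uninformative_probabilities_tie_averaged(self):
        m = classification_metrics(np.full(6, 0.5), np.array([1, 0, 1, 0, 1, 0]))
        assert m["AUC"] == 0.5

    def test_printed_toy_case(self):
        probs = np.array([0.9, 0.8, 0.3, 0.1])
        labels = np.array([1, 0, 1, 0])
        m = classification_metrics(probs, labels)
        assert m["AUC"] == pytest.approx(brute_force_auc(probs, labels)) == 0.75
        assert m["ACC"] == 0.5 and m["FPR"] == 0.5 and m["FNR"] == 0.5

    def test_rank_auc_equals_brute_force_with_ties(self):
        rng = np.random.default_rng(5)
        for n in (8, 20, 50):
            probs = rng.integers(0, 5, size=n) / 4  # heavy ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            m = classification_metrics(probs, labels)
            assert m["AUC"] == pytest.approx(brute_force_auc(probs, labels), abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="one class"):
            classification_metrics(np.array([0.2, 0.6]), np.array([1, 1]))

    def test_accuracy_identity_with_rates(self):
        rng = np.random.default_rng(6)
        probs = rng.random(60)
        labels = rng.integers(0, 2, size=60)
        m = classification_metrics(probs, labels)
        n_pos, n_neg = labels.sum(), (1 - labels).sum()
        assert m["ACC"] == pytest.approx(
            1 - (m["FPR"] * n_neg + m["FNR"] * n_pos) / 60, abs=1e-12
        )


class TestBootstrapEvaluate:
    groups = ["case"] * 40 + ["control"] * 15 + ["supercontrol"] * 25

    def test_null_features_auc_near_half(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((80, 4))
        rep = bootstrap_evaluate(X, self.groups, "C_vs_CS", method="logistic", B=30, seed=0)
        mean, lo, hi = rep.summary["AUC"]
        assert 0.35 <= mean <= 0.65
        assert lo <= 0.5 <= hi

    def test_separated_cohort_logistic_auc_high(self):
        rng = np.random.default_rng(1)
        y = contrast_labels(self.groups, "C_vs_CS")
        X = rng.standard_normal((80, 4)) + 4 * y[:, None]
        rep = bootstrap_evaluate(X, self.groups, "C_vs_CS", method="logistic", B=20, seed=0)
        assert rep.summary["AUC"][0] >= 0.9

    def test_ci_ordering_everywhere(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((80, 3))
        for method in ("logistic", "gmm"):
            rep = bootstrap_evaluate(X, self.groups, "CC_vs_S", method=method, B=10, seed=0)
            for mean, lo, hi in rep.summary.values():
                assert lo <= mean <= hi
                assert 0 <= lo and hi <= 1

    def test_patient_order_permutation_invariance_of_oof_metrics(self):
        # fold assignment is canonical in (label, features), so permuting
        # patients with the same fold seed leaves pooled metrics unchanged
        from psychembed.evaluate import _logistic_oof_probs

        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 3))
        y = contrast_labels(self.groups[:60], "C_vs_CS")
        m1 = classification_metrics(_logistic_oof_probs(X, y, seed=9), y)
        perm = rng.permutation(60)
        m2 = classification_metrics(_logistic_oof_probs(X[perm], y[perm], seed=9), y[perm])
        for k in m1:
            assert m1[k] == pytest.approx(m2[k], abs=1e-12)

    def test_report_tidy_frame(self):
        rng = np.random.default_rng(4)
        rep = bootstrap_evaluate(
            rng.standard_normal((80, 2)), self.groups, "C_vs_CS", B=5, seed=0,
            feature_set="2PC",
        )
        df = rep.to_frame()
        assert set(df["metric"]) == {"ACC", "AUC", "FPR", "FNR"}
        assert (df["feature_set"] == "2PC").all()


class TestPermutationTest:
    def test_identical_samples_p_one(self):
        a = np.arange(10.0)
        assert permutation_test_means(a, a.copy(), n_perm=999, seed=0) == 1.0

    def test_disjoint_samples_minimum_p(self):
        a = np.full(50, 1.0) + np.arange(50) * 1e-3
        b = np.zeros(50)
        p = permutation_test_means(a, b, n_perm=999, seed=0)
        assert p <= 0.002

    def test_too_few_values_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            permutation_test_means(np.array([1.0]), np.array([1.0, 2.0]))


class TestTsne:
    def test_shape_and_determinism(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 8))
        a = tsne_project(X, seed=0, perplexity=10)
        b = tsne_project(X, seed=0, perplexity=10)
        assert a.shape == (60, 2)
        np.testing.assert_array_equal(a, b)

    def test_separated_clusters_stay_separated(self):
        rng = np.random.default_rng(1)
        X = np.vstack(
            [rng.standard_normal((40, 6)) - 6, rng.standard_normal((40, 6)) + 6]
        )
        Y = tsne_project(X, seed=0, perplexity=15)
        intra = np.mean(
            [np.linalg.norm(Y[i] - Y[j]) for i in range(40) for j in range(i + 1, 40)]
        )
        inter = np.mean(
            [np.linalg.norm(Y[i] - Y[j]) for i in range(40) for j in range(40, 80)]
        )
        assert inter > intra

    def test_perplexity_too_large_raises(self):
        with pytest.raises(ValueError, match="perplexity"):
            tsne_project(np.zeros((10, 3)), perplexity=5)
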