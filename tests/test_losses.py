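"""Contrastive and multitask losses against hand values and loop oracles."""

import numpy as np
import pytest

from flimcontrast.losses import (MALIGNANT, HEALTHY, BENIGN,
                                 adaptive_alpha, adaptive_beta,
                                 balanced_class_weights, build_anchors,
                                 clustering_loss, consistency_loss,
                                 consistency_loss_and_grad,
                                 contrastive_loss_and_grad, contrastive_total,
                                 cross_entropy, multitask_loss,
                                 separation_loss, static_beta)
from oracles import (naive_adaptive_beta, naive_clustering_loss,
                     naive_separation_loss, random_anchor_batch)


class TestAnchors:
    def test_single_patient_mean_equals_anchor(self):
        a = build_anchors(np.array([[0., 0.], [2., 0.]]), [0, 0], [1, 1])
        np.testing.assert_allclose(a.anchors[0], [1.0, 0.0])
        assert len(a.groups) == 1
        np.testing.assert_allclose(a.groups[0].mean, [1.0, 0.0])

    def test_two_patients_one_class(self):
        a = build_anchors(np.array([[0., 0.], [2., 0.]]), [0, 0], [1, 2])
        np.testing.assert_allclose(a.anchors[0], [1.0, 0.0])
        means = sorted(tuple(g.mean) for g in a.groups)
        assert means == [(0.0, 0.0), (2.0, 0.0)]
        assert a.n_pos_patients(0) == 2

    def test_patient_roles_across_classes(self):
        emb = np.array([[0., 0.], [1., 0.], [5., 0.], [6., 0.]])
        a = build_anchors(emb, [0, 0, 1, 1], [1, 2, 3, 4])
        # each patient mean is a positive for its class, negative for the
        # other
        assert a.n_pos_patients(0) == 2 and a.n_neg_patients(0) == 2
        assert a.n_pos_patients(1) == 2 and a.n_neg_patients(1) == 2

    def test_anchor_is_pixel_weighted_mean_of_patients(self, rng):
        emb, labels, pids = random_anchor_batch(rng)
        a = build_anchors(emb, labels, pids)
        for c in a.classes:
            total = sum(g.n_pixels for g in a.groups_of(int(c)))
            weighted = sum(g.n_pixels * g.mean for g in a.groups_of(int(c)))
            np.testing.assert_allclose(a.anchors[int(c)], weighted / total,
                                       atol=1e-12)


class TestClusteringLoss:
    def test_identical_embeddings_zero(self):
        a = build_anchors(np.ones((6, 3)), [0, 0, 0, 1, 1, 1],
                          [0, 0, 1, 2, 2, 3])
        assert clustering_loss(a, 1.0) == 0.0

    def test_hand_value(self):
        a = build_anchors(np.array([[0., 0.], [2., 0.]]), [0, 0], [1, 2])
        assert clustering_loss(a, 1.0) == pytest.approx(2.0)

    def test_linear_in_alpha(self, rng):
        emb, labels, pids = random_anchor_batch(rng)
        a = build_anchors(emb, labels, pids)
        assert clustering_loss(a, 3.0) == pytest.approx(
            3.0 * clustering_loss(a, 1.0))


class TestSeparationLoss:
    def test_hand_value(self):
        a = build_anchors(np.array([[0., 0.], [3., 0.]]), [0, 1], [1, 2])
        beta = {(0, 1): 1.0, (1, 0): 1.0}
        assert separation_loss(a, beta) == pytest.approx(18.0)

    def test_coincident_classes_zero(self):
        a = build_anchors(np.ones((4, 2)), [0, 0, 1, 1], [0, 1, 2, 3])
        assert separation_loss(a, static_beta(a)) == 0.0

    def test_squared_distance_homogeneity(self):
        emb = np.array([[0., 0.], [3., 1.]])
        beta = {(0, 1): 1.0, (1, 0): 1.0}
        l1 = separation_loss(build_anchors(emb, [0, 1], [1, 2]), beta)
        l2 = separation_loss(build_anchors(2 * emb, [0, 1], [1, 2]), beta)
        assert l2 == pytest.approx(4 * l1)

    def test_single_class_batch_returns_zero(self):
        a = build_anchors(np.ones((2, 2)), [0, 0], [0, 1])
        assert separation_loss(a, {}) == 0.0


class TestAdaptiveWeights:
    def test_beta_hand_example(self):
        # class means (0,0), (1,0), (3,0); first class: squared distances
        # 1 and 9 -> raw (1, 1/9) -> normalized (0.9, 0.1)
        a = build_anchors(np.array([[0., 0.], [1., 0.], [3., 0.]]),
                          [0, 1, 2], [0, 1, 2])
        beta = adaptive_beta(a)
        assert beta[(0, 1)] == pytest.approx(0.9)
        assert beta[(0, 2)] == pytest.approx(0.1)

    def test_beta_singleton_pair(self):
        a = build_anchors(np.array([[0., 0.], [5., 0.]]), [0, 1], [0, 1])
        beta = adaptive_beta(a)
        assert beta[(0, 1)] == pytest.approx(1.0)
        assert beta[(1, 0)] == pytest.approx(1.0)

    def test_beta_equidistant_classes_equal(self):
        emb = np.array([[0., 0.], [2., 0.], [1., np.sqrt(3)]])
        a = build_anchors(emb, [0, 1, 2], [0, 1, 2])
        beta = adaptive_beta(a)
        assert beta[(0, 1)] == pytest.approx(0.5)
        assert beta[(0, 2)] == pytest.approx(0.5)

    def test_beta_normalized_within_anchor_class(self, rng):
        for _ in range(10):
            emb, labels, pids = random_anchor_batch(rng)
            a = build_anchors(emb, labels, pids)
            beta = adaptive_beta(a)
            for c in a.classes:
                total = sum(b for (ca, _), b in beta.items() if ca == c)
                assert total == pytest.approx(1.0, abs=1e-9)

    def test_beta_larger_for_poorly_separated_pair(self):
        emb = np.array([[0., 0.], [0.5, 0.], [10., 0.]])
        a = build_anchors(emb, [0, 1, 2], [0, 1, 2])
        beta = adaptive_beta(a)
        assert beta[(0, 1)] > beta[(0, 2)]

    @pytest.mark.parametrize("s,expected", [(0.0, 1.0), (1.0, 0.0),
                                            (0.5, 0.5), (-0.3, 1.0),
                                            (1.4, 0.0)])
    def test_alpha_schedule(self, s, expected):
        assert adaptive_alpha(s, 1.0) == pytest.approx(expected)

    def test_alpha_monotone_nonincreasing(self, rng):
        s = np.sort(rng.uniform(-1, 1, 20))
        alphas = [adaptive_alpha(v, 2.0) for v in s]
        assert all(a >= b for a, b in zip(alphas, alphas[1:]))


class TestContrastiveTotal:
    def test_hand_arithmetic(self):
        report = contrastive_total(2.0, 18.0)
        assert report.l_contr == -16.0

    def test_zero_separation(self):
        assert contrastive_total(2.5, 0.0).l_contr == 2.5

    def test_identity_holds_on_random_batches(self, rng):
        for _ in range(10):
            emb, labels, pids = random_anchor_batch(rng)
            report, _ = contrastive_loss_and_grad(emb, labels, pids, 0.7)
            assert report.l_contr == report.l_clust - report.l_sep


class TestOracleEquivalence:
    def test_losses_match_naive_loops(self, rng):
        # 50 randomized batches varying classes, patients and pixel counts
        for _ in range(50):
            emb, labels, pids = random_anchor_batch(rng)
            alpha = float(rng.uniform(0.1, 2.0))
            a = build_anchors(emb, labels, pids)
            beta = adaptive_beta(a)
            assert clustering_loss(a, alpha) == pytest.approx(
                naive_clustering_loss(emb, labels, pids, alpha), abs=1e-6)
            assert separation_loss(a, beta) == pytest.approx(
                naive_separation_loss(emb, labels, pids,
                                      naive_adaptive_beta(emb, labels)),
                abs=1e-6)
            for key, value in beta.items():
                assert value == pytest.approx(
                    naive_adaptive_beta(emb, labels)[key], abs=1e-6)


class TestContrastiveGradient:
    def test_matches_finite_differences(self, rng):
        for _ in range(5):
            emb, labels, pids = random_anchor_batch(rng)
            beta = adaptive_beta(build_anchors(emb, labels, pids))
            _, grad = contrastive_loss_and_grad(emb, labels, pids, 0.7,
                                                beta=beta)
            eps = 1e-6
            for _ in range(10):
                i = rng.integers(len(emb))
                j = rng.integers(emb.shape[1])
                ep, em = emb.copy(), emb.copy()
                ep[i, j] += eps
                em[i, j] -= eps
                rp, _ = contrastive_loss_and_grad(ep, labels, pids, 0.7,
                                                  beta=beta)
                rm, _ = contrastive_loss_and_grad(em, labels, pids, 0.7,
                                                  beta=beta)
                num = (rp.l_contr - rm.l_contr) / (2 * eps)
                assert grad[i, j] == pytest.approx(num, abs=1e-5)

    def test_gradient_step_improves_both_objectives(self):
        # 2 classes x 2 patients with unequal pixel counts: a small step
        # along -grad of the combined loss tightens classes and pushes the
        # class anchors apart; the single-term steps move their own
        # objective in the right direction as well
        labels = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1])
        pids = np.array([0, 0, 0, 1, 1, 2, 2, 2, 2, 3, 3])
        emb = np.random.default_rng(0).normal(size=(11, 2))

        def stats(e):
            a = build_anchors(e, labels, pids)
            within = sum(np.sum((a.anchors[g.class_label] - g.mean) ** 2)
                         for g in a.groups)
            between = np.sum((a.anchors[0] - a.anchors[1]) ** 2)
            return within, between

        w0, b0 = stats(emb)
        _, grad = contrastive_loss_and_grad(emb, labels, pids, alpha=1.0)
        w1, b1 = stats(emb - 0.001 * grad)
        assert w1 < w0
        assert b1 > b0

        _, g_clust = contrastive_loss_and_grad(emb, labels, pids, alpha=1.0,
                                               use_separation=False)
        assert stats(emb - 0.001 * g_clust)[0] < w0
        _, g_sep = contrastive_loss_and_grad(emb, labels, pids, alpha=1.0,
                                             use_clustering=False)
        assert stats(emb - 0.001 * g_sep)[1] > b0


class TestClassWeights:
    def test_imbalanced_example(self):
        w = balanced_class_weights([0, 0, 0, 1])
        assert w[0] == pytest.approx(4 / 6)
        assert w[1] == pytest.approx(2.0)

    def test_balanced_labels_unit_weights(self):
        w = balanced_class_weights([0, 1, 0, 1])
        assert w[0] == pytest.approx(1.0) and w[1] == pytest.approx(1.0)

    def test_weighted_mean_is_one(self, rng):
        labels = rng.integers(0, 3, 60)
        w = balanced_class_weights(labels)
        per_sample = np.array([w[int(y)] for y in labels])
        assert per_sample.mean() == pytest.approx(1.0)

    def test_empty_labels_rejected(self):
        with pytest.raises(ValueError):
            balanced_class_weights([])


def _confident(n, cls, lo=-12.0, hi=12.0):
    logits = np.full((n, 2), lo)
    logits[:, cls] = hi
    return logits


class TestConsistencyLoss:
    def test_consistent_confident_heads_near_zero(self):
        labels = np.array([MALIGNANT, MALIGNANT, HEALTHY])
        diag = _confident(3, 1)
        diag[2] = _confident(1, 0)
        delin = np.vstack([_confident(2, 1), _confident(1, 0)])
        assert consistency_loss(diag, delin, labels) < 1e-3

    def test_contradiction_contributes_cross_entropy(self):
        # malignant sample: diagnosis says malignant with certainty,
        # delineation gives the lesion class probability p
        labels = np.array([MALIGNANT])
        diag = _confident(1, 1, lo=-30, hi=30)
        delin = np.array([[0.7, -0.2]])
        p = np.exp(-0.2) / (np.exp(0.7) + np.exp(-0.2))
        loss = consistency_loss(diag, delin, labels)
        assert loss == pytest.approx(-np.log(p), rel=1e-6)

    def test_healthy_contradiction_pushes_diagnosis(self):
        labels = np.array([HEALTHY])
        delin = _confident(1, 0)          # delineation: healthy
        diag = np.array([[-1.0, 1.0]])    # diagnosis: malignant (wrong)
        loss, grad_diag, grad_delin = consistency_loss_and_grad(
            diag, delin, labels)
        assert loss > 0
        assert np.any(grad_diag != 0)
        assert np.all(grad_delin == 0)  # selection does not backpropagate

    def test_no_contributors_gives_zero(self):
        labels = np.array([BENIGN, BENIGN])
        diag = _confident(2, 0)
        delin = _confident(2, 1)
        assert consistency_loss(diag, delin, labels) == 0.0


class TestMultitaskLoss:
    def test_uniform_predictions_give_ln2_terms(self):
        n = 6
        logits = np.zeros((n, 2))
        labels = np.full(n, 0)
        contr = np.full(n, BENIGN)  # no consistency triggers
        report, _, _ = multitask_loss(logits, logits.copy(), labels, labels,
                                      contr)
        assert report.ce_diag == pytest.approx(np.log(2), rel=1e-6)
        assert report.ce_delin == pytest.approx(np.log(2), rel=1e-6)
        assert report.l_mt == pytest.approx(2 * np.log(2), rel=1e-6)

    def test_perfect_consistent_predictions_near_zero(self):
        labels = np.array([1, 1, 0])
        contr = np.array([MALIGNANT, MALIGNANT, HEALTHY])
        diag = _confident(3, 1)
        diag[2] = _confident(1, 0)
        delin = np.vstack([_confident(2, 1), _confident(1, 0)])
        report, _, _ = multitask_loss(diag, delin, labels, labels, contr)
        assert report.l_mt < 1e-3

    def test_additive_identity(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 20))
            diag = rng.normal(size=(n, 2))
            delin = rng.normal(size=(n, 2))
            y = rng.integers(0, 2, n)
            contr = rng.integers(0, 3, n)
            report, _, _ = multitask_loss(diag, delin, y, y, contr)
            assert report.l_mt == report.ce_diag + report.ce_delin + report.l_reg

    def test_cross_entropy_gradient_matches_finite_differences(self, rng):
        logits = rng.normal(size=(5, 2))
        y = rng.integers(0, 2, 5)
        w = rng.uniform(0.5, 2.0, 5)
        loss, grad = cross_entropy(logits, y, w)
        eps = 1e-6
        for i in range(5):
            for j in range(2):
                lp, lm = logits.copy(), logits.copy()
                lp[i, j] += eps
                lm[i, j] -= eps
                num = (cross_entropy(lp, y, w)[0]
                       - cross_entropy(lm, y, w)[0]) / (2 * eps)
                assert grad[i, j] == pytest.approx(num, abs=1e-6)
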