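"""Encoder/decoder layers and every loss term, against hand or brute-force oracles."""

import numpy as np
import pytest

from sgae import nn
from sgae.autograd import Tensor

from test_autograd import check_grad


class TestEncoderLayer:
    def test_zero_parameters_give_zero_output(self, rng):
        h = rng.normal(size=(4, 3))
        out = nn.encoder_layer(h, np.eye(4), np.zeros((3, 2)), np.zeros((3, 2)),
                               np.zeros(2), "relu")
        assert np.all(out.data == 0)

    def test_identity_passthrough(self, rng):
        h = rng.normal(size=(4, 3))
        out = nn.encoder_layer(h, np.eye(4), np.eye(3), np.zeros((3, 3)),
                               np.zeros(3), "identity")
        assert np.allclose(out.data, h)

    def test_matches_naive_triple_loop(self, rng):
        n, m, mp = 4, 3, 2
        h, a = rng.normal(size=(n, m)), rng.normal(size=(n, n))
        w1, w2 = rng.normal(size=(m, mp)), rng.normal(size=(m, mp))
        b = rng.normal(size=mp)
        out = nn.encoder_layer(h, a, w1, w2, b, "relu").data
        expect = np.zeros((n, mp))
        for i in range(n):
            for j in range(mp):
                g = sum(a[i, k] * h[k, :] @ w1[:, j] for k in range(n))
                r = h[i, :] @ w2[:, j] + b[j]
                expect[i, j] = max(g, 0.0) + max(r, 0.0)
        assert np.abs(out - expect).max() < 1e-6

    def test_encode_composes_layers(self, rng):
        params = nn.EncoderParams.init([3, 4, 2], rng)
        a = np.eye(5)
        x = rng.normal(size=(5, 3))
        full = nn.encode(x, a, params).data
        step1 = nn.encoder_layer(x, a, params.w1[0], params.w2[0], params.b[0],
                                 "relu")
        step2 = nn.encoder_layer(step1, a, params.w1[1], params.w2[1],
                                 params.b[1], "identity")
        assert np.abs(full - step2.data).max() < 1e-7

    def test_encode_single_linear_layer_collapses(self, rng):
        w1 = rng.normal(size=(3, 2))
        params = nn.EncoderParams(w1=[Tensor(w1)],
                                  w2=[Tensor(np.zeros((3, 2)))],
                                  b=[Tensor(np.zeros(2))])
        x = rng.normal(size=(4, 3))
        assert np.allclose(nn.encode(x, np.eye(4), params).data, x @ w1)

    def test_encode_rejects_nan(self, rng):
        params = nn.EncoderParams.init([3, 2], rng)
        x = rng.normal(size=(4, 3))
        x[1, 1] = np.nan
        with pytest.raises(ValueError, match="finite"):
            nn.encode(x, np.eye(4), params)


class TestFuseAndDecoders:
    def test_fuse_rules(self, rng):
        h2 = rng.normal(size=(4, 3))
        assert np.allclose(nn.fuse(h2, h2, 0.3).data, h2)
        assert np.allclose(nn.fuse(h2, 2 * h2, 1.0).data, h2)
        assert np.allclose(nn.fuse(2 * h2, h2, 0.5).data, 1.5 * h2)
        with pytest.raises(ValueError):
            nn.fuse(h2, h2[:2], 0.5)

    def test_decode_features_identity_layer(self, rng):
        h = rng.normal(size=(4, 3))
        params = nn.DecoderParams(w=[Tensor(np.eye(3))])
        assert np.allclose(nn.decode_features(h, np.eye(4), params).data, h)

    def test_decode_features_matches_naive(self, rng):
        h, a = rng.normal(size=(4, 2)), rng.normal(size=(4, 4))
        w = rng.normal(size=(2, 3))
        params = nn.DecoderParams(w=[Tensor(w)])
        # single (final) layer is linear
        assert np.abs(nn.decode_features(h, a, params).data - a @ h @ w).max() < 1e-6

    def test_decode_adjacency(self, rng):
        assert np.allclose(nn.decode_adjacency(np.zeros((3, 2))).data, 0.5)
        q = np.linalg.qr(rng.normal(size=(4, 4)))[0]
        assert np.allclose(nn.decode_adjacency(q, squash=False).data, np.eye(4),
                           atol=1e-12)
        out = nn.decode_adjacency(rng.normal(size=(5, 2))).data
        assert np.array_equal(out, out.T)


class TestReconstructionLosses:
    def test_rec_f_zero_at_perfect_reconstruction(self, rng):
        a = rng.normal(size=(3, 3))
        x = rng.normal(size=(3, 2))
        assert nn.loss_rec_f(a, x, a @ x).item() == 0.0

    def test_rec_f_scalar_case(self):
        assert nn.loss_rec_f(np.array([[1.0]]), np.array([[2.0]]),
                             Tensor(np.array([[0.0]]))).item() == pytest.approx(2.0)

    def test_rec_f_quadratic_scaling(self, rng):
        a, x = rng.normal(size=(3, 3)), rng.normal(size=(3, 2))
        resid = rng.normal(size=(3, 2))
        l1 = nn.loss_rec_f(a, x, a @ x + resid).item()
        l2 = nn.loss_rec_f(a, x, a @ x + 2 * resid).item()
        assert l2 == pytest.approx(4 * l1)

    def test_rec_a_example(self):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        rec = np.full((2, 2), 0.5)
        assert nn.loss_rec_a(a, rec).item() == pytest.approx(0.25)
        assert nn.loss_rec_a(a, a).item() == 0.0

    def test_rec_a_symmetric_in_arguments(self, rng):
        a, b = rng.random((3, 3)), rng.random((3, 3))
        assert nn.loss_rec_a(a, b).item() == pytest.approx(nn.loss_rec_a(b, a).item())


class TestRedundancyReduction:
    def test_sample_corr_self_orthogonal_rows(self):
        h = np.eye(3) * np.array([[2.0], [3.0], [4.0]])
        assert np.allclose(nn.cross_view_sample_corr(h, h).data, np.eye(3))

    def test_sample_corr_antiparallel_diagonal(self, rng):
        h = rng.normal(size=(4, 3))
        s = nn.cross_view_sample_corr(h, -h).data
        assert np.allclose(np.diag(s), -1.0)

    def test_corr_matches_bruteforce_cosine(self, rng):
        h1, h2 = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        s_n = nn.cross_view_sample_corr(h1, h2).data
        for i in range(4):
            for j in range(4):
                cos = h1[i] @ h2[j] / (np.linalg.norm(h1[i]) * np.linalg.norm(h2[j]))
                assert abs(s_n[i, j] - cos) < 1e-7
        s_f = nn.cross_view_feature_corr(h1, h2).data
        for a in range(3):
            for b in range(3):
                cos = h1[:, a] @ h2[:, b] / (
                    np.linalg.norm(h1[:, a]) * np.linalg.norm(h2[:, b]))
                assert abs(s_f[a, b] - cos) < 1e-7

    def test_feature_corr_scalar_case(self, rng):
        h1, h2 = rng.normal(size=(5, 1)), rng.normal(size=(5, 1))
        s = nn.cross_view_feature_corr(h1, h2).data
        assert s.shape == (1, 1)

    def test_loss_rr_examples(self):
        assert nn.loss_rr(np.eye(3), np.eye(2)).item() == 0.0
        assert nn.loss_rr(np.ones((2, 2)), np.eye(2)).item() == pytest.approx(0.5)

    def test_identical_views_diagonal_ones(self, rng):
        h = rng.normal(size=(5, 3))
        s = nn.cross_view_sample_corr(h, h).data
        assert np.allclose(np.diag(s), 1.0, atol=1e-9)


class TestClusteringGuidance:
    def test_soft_assignment_rows_sum_to_one(self, rng):
        q = nn.soft_assignment(rng.normal(size=(6, 3)),
                               rng.normal(size=(3, 3))).data
        assert np.abs(q.sum(axis=1) - 1).max() < 1e-9

    def test_equidistant_point_splits_mass(self):
        h = np.array([[0.0, 0.0]])
        centers = np.array([[1.0, 0.0], [-1.0, 0.0]])
        assert np.allclose(nn.soft_assignment(h, centers).data, 0.5)

    def test_student_t_kernel_hand_value(self):
        h = np.array([[0.0]])
        centers = np.array([[0.0], [1.0]])
        q = nn.soft_assignment(h, centers, nu=1.0).data
        assert np.allclose(q, [2 / 3, 1 / 3], atol=1e-9)

    def test_translation_invariance(self, rng):
        h, c = rng.normal(size=(5, 2)), rng.normal(size=(3, 2))
        shift = rng.normal(size=2)
        q1 = nn.soft_assignment(h, c).data
        q2 = nn.soft_assignment(h + shift, c + shift).data
        assert np.abs(q1 - q2).max() < 1e-9

    def test_target_distribution_examples(self, rng):
        q = np.abs(rng.random((6, 3))) + 0.01
        q /= q.sum(axis=1, keepdims=True)
        p = nn.target_distribution(q)
        assert np.abs(p.sum(axis=1) - 1).max() < 1e-9
        onehot = np.repeat(np.eye(3), 2, axis=0)
        assert np.allclose(nn.target_distribution(onehot), onehot)
        single = np.array([[0.8, 0.2]])
        assert np.allclose(nn.target_distribution(single), single)

    def test_kl_examples(self, rng):
        q = np.abs(rng.random((5, 3))) + 0.01
        q /= q.sum(axis=1, keepdims=True)
        assert nn.loss_clustering(q, q).item() == pytest.approx(0.0, abs=1e-9)
        p = np.array([[1.0, 0.0]])
        q2 = np.array([[0.5, 0.5]])
        assert nn.loss_clustering(p, q2).item() == pytest.approx(np.log(2), rel=1e-6)
        p3 = nn.target_distribution(q)
        assert nn.loss_clustering(p3, q).item() >= 0.0

    def test_total_loss(self):
        parts = {"rec_f": 1.0, "rec_a": 2.0, "rr": 3.0, "clustering": 4.0}
        assert nn.total_loss(parts).item() == pytest.approx(10.0)
        w = {"rec_f": 0, "rec_a": 0, "rr": 0, "clustering": 1}
        assert nn.total_loss(parts, w).item() == pytest.approx(4.0)
        assert nn.total_loss({k: 0.0 for k in parts}).item() == 0.0


class TestParameterSharing:
    def test_both_views_respond_to_one_weight(self, rng):
        params = nn.EncoderParams.init([3, 4, 2], rng)
        x1, x2 = rng.random((5, 3)) + 0.5, rng.random((5, 3)) + 0.5
        a1, a2 = np.eye(5), np.full((5, 5), 0.2)
        h1a, h2a = nn.encode(x1, a1, params).data, nn.encode(x2, a2, params).data
        params.w1[0].data[0, 0] += 5.0  # large enough to flip ReLU gates
        h1b, h2b = nn.encode(x1, a1, params).data, nn.encode(x2, a2, params).data
        assert not np.allclose(h1a, h1b)
        assert not np.allclose(h2a, h2b)


class TestLossGradients:
    """Analytic gradients of every loss term vs central finite differences."""

    def test_rec_f_gradient(self, rng):
        a, x = rng.normal(size=(5, 5)), rng.normal(size=(5, 3))
        check_grad(lambda h: nn.loss_rec_f(a, x, h), rng.normal(size=(5, 3)),
                   tol=1e-4)

    def test_rec_a_gradient(self, rng):
        a = (rng.random((5, 5)) < 0.4).astype(float)
        a = np.triu(a, 1) + np.triu(a, 1).T
        check_grad(lambda r: nn.loss_rec_a(a, r), rng.random((5, 5)), tol=1e-4)

    def test_rr_gradient(self, rng):
        check_grad(lambda h1, h2: nn.loss_rr(nn.cross_view_sample_corr(h1, h2),
                                             nn.cross_view_feature_corr(h1, h2)),
                   rng.normal(size=(5, 3)), rng.normal(size=(5, 3)), tol=1e-4)

    def test_clustering_gradient(self, rng):
        q0 = np.abs(rng.random((5, 3))) + 0.1
        p = nn.target_distribution(q0 / q0.sum(axis=1, keepdims=True))
        check_grad(lambda h, c: nn.loss_clustering(p, nn.soft_assignment(h, c)),
                   rng.normal(size=(5, 2)), rng.normal(size=(3, 2)), tol=1e-4)

    def test_full_network_gradient(self, rng):
        params = nn.EncoderParams.init([3, 4, 2], rng)
        dec = nn.DecoderParams.init([2, 4, 3], rng)
        x = rng.normal(size=(5, 3))
        a = np.full((5, 5), 0.2)

        def loss(w1_0):
            saved = params.w1[0]
            params.w1[0] = w1_0
            h = nn.encode(x, a, params)
            out = nn.loss_rec_f(a, x, nn.decode_features(h, a, dec))
            params.w1[0] = saved
            return out

        check_grad(loss, params.w1[0].data.copy(), tol=1e-4)
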