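"""Encoder blocks, inner-product decoder, and the cascade classifier."""

import numpy as np
import pytest

from mirlink import nn
from mirlink.autodiff import tensor
from mirlink.views import normalize_adjacency

LN2 = float(np.log(2.0))


def make_block(d_in, d_out, seed=0):
    return nn.GCNMLPBlock(d_in, d_out, np.random.default_rng(seed))


class TestGCNMLPBlock:
    def test_zero_weights_give_zero_output(self):
        block = make_block(4, 3)
        for p in block.parameters():
            p.data[...] = 0.0
        out = block(np.eye(5), np.random.default_rng(0).normal(size=(5, 4)))
        np.testing.assert_array_equal(out.data, np.zeros((5, 3)))

    def test_identity_propagation(self):
        block = make_block(4, 4)
        block.W_gcn.data = np.eye(4)
        block.W_mlp.data[...] = 0.0
        block.b.data[...] = 0.0
        H = np.abs(np.random.default_rng(1).normal(size=(6, 4)))
        np.testing.assert_allclose(block(np.eye(6), H).data, H, atol=1e-12)

    def test_matches_dense_oracle_on_random_graph(self):
        """Independently coded matrix arithmetic on a 5-node graph."""
        rng = np.random.default_rng(7)
        A = (rng.random((5, 5)) < 0.5).astype(float)
        A = np.triu(A, 1); A = A + A.T
        norm = normalize_adjacency(A)
        H = rng.normal(size=(5, 4))
        block = make_block(4, 3, seed=7)
        expected = np.maximum(
            norm @ H @ block.W_gcn.data + H @ block.W_mlp.data + block.b.data,
            0.0,
        )
        np.testing.assert_allclose(block(norm, H).data, expected, atol=1e-10)

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError, match="width"):
            make_block(4, 3)(np.eye(5), np.zeros((5, 6)))


class TestViewEncoder:
    def test_zero_weights_give_zero_embedding(self):
        enc = nn.ViewEncoder(6, 8, np.random.default_rng(0))
        for p in enc.parameters():
            p.data[...] = 0.0
        Z = enc(np.eye(4), np.random.default_rng(0).normal(size=(4, 6)))
        np.testing.assert_array_equal(Z.data, np.zeros((4, 8)))

    def test_latent_shape_default_width(self):
        enc = nn.ViewEncoder(10, 128, np.random.default_rng(0))
        Z = enc(np.eye(10), np.eye(10))
        assert Z.shape == (10, 128)

    def test_deterministic(self):
        rng_in = np.random.default_rng(3)
        X = rng_in.normal(size=(5, 4))
        a = nn.ViewEncoder(4, 8, np.random.default_rng(5))(np.eye(5), X)
        b = nn.ViewEncoder(4, 8, np.random.default_rng(5))(np.eye(5), X)
        np.testing.assert_array_equal(a.data, b.data)


class TestDecoder:
    def test_zero_embedding_gives_half(self):
        out = nn.decode_inner_product(np.zeros((4, 3)))
        np.testing.assert_allclose(out.data, np.full((4, 4), 0.5))

    def test_orthonormal_rows(self):
        out = nn.decode_inner_product(np.eye(3)).data
        sig1 = 1 / (1 + np.exp(-1.0))
        np.testing.assert_allclose(np.diag(out), sig1, atol=1e-12)
        off = out[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.5, atol=1e-12)

    def test_symmetric_open_interval(self):
        Z = np.random.default_rng(0).normal(size=(6, 4))
        out = nn.decode_inner_product(Z).data
        np.testing.assert_allclose(out, out.T, atol=1e-12)
        assert ((out > 0) & (out < 1)).all()


class TestReconstructionLoss:
    def test_half_probabilities_give_ln2(self):
        target = np.array([[1, 0], [0, 1]], dtype=float)
        loss = nn.reconstruction_loss(target, tensor(np.full((2, 2), 0.5)))
        assert loss.item() == pytest.approx(LN2, rel=1e-10)

    def test_perfect_reconstruction_limit(self):
        target = np.array([[1.0, 0.0]])
        eps = 1e-9
        loss = nn.reconstruction_loss(target, tensor([[1 - eps, eps]]))
        assert loss.item() < 1e-8

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(2)
        target = rng.integers(0, 2, size=(4, 4)).astype(float)
        p = rng.uniform(0.01, 0.99, size=(4, 4))
        expected = -np.mean(target * np.log(p) + (1 - target) * np.log(1 - p))
        loss = nn.reconstruction_loss(target, tensor(p))
        assert loss.item() == pytest.approx(expected, abs=1e-10)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="shape"):
            nn.reconstruction_loss(np.zeros((2, 2)), tensor(np.full((3, 3), 0.5)))


class TestAssemblePairFeatures:
    def test_zero_embeddings_width(self):
        d = 5
        F = nn.assemble_pair_features(
            np.zeros((7, d)), np.zeros((7, d)), np.zeros((4, d)),
            np.zeros((3, d)), [(0, 0), (3, 2)],
        )
        assert F.shape == (2, 4 * d)
        np.testing.assert_array_equal(F.data, 0.0)

    def test_default_width_512(self):
        d = 128
        F = nn.assemble_pair_features(
            np.zeros((5, d)), np.zeros((5, d)), np.zeros((3, d)),
            np.zeros((2, d)), [(0, 0)],
        )
        assert F.shape == (1, 512)

    def test_local_global_sum_commutes(self):
        rng = np.random.default_rng(0)
        zl = rng.normal(size=(6, 3))
        zg = rng.normal(size=(6, 3))
        zm = rng.normal(size=(4, 3))
        zd = rng.normal(size=(2, 3))
        pairs = [(1, 0), (3, 1)]
        a = nn.assemble_pair_features(zl, zg, zm, zd, pairs)
        b = nn.assemble_pair_features(zg, zl, zm, zd, pairs)
        np.testing.assert_allclose(a.data, b.data, atol=1e-12)

    def test_blocks_placed_correctly(self):
        d = 2
        zm = np.arange(8, dtype=float).reshape(4, d)
        zd = 100 + np.arange(6, dtype=float).reshape(3, d)
        zl = np.zeros((7, d))
        zg = np.zeros((7, d))
        F = nn.assemble_pair_features(zl, zg, zm, zd, [(2, 1)]).data[0]
        np.testing.assert_array_equal(F[:2], zm[2])
        np.testing.assert_array_equal(F[-2:], zd[1])

    def test_view_ablation_drops_blocks(self):
        d = 3
        F = nn.assemble_pair_features(
            np.ones((5, d)), None, None, None, [(0, 1)], m=3)
        assert F.shape == (1, 2 * d)

    def test_out_of_range_index_errors(self):
        with pytest.raises(IndexError):
            nn.assemble_pair_features(
                np.zeros((3, 2)), None, np.zeros((2, 2)), np.zeros((1, 2)),
                [(0, 5)],
            ).data


def make_classifier(use_attention=True, d_in=16, seed=0):
    return nn.CascadeClassifier(
        d_in, np.random.default_rng(seed), hidden_widths=(12, 8, 6), d_h=6,
        attn_rank=3, use_attention=use_attention,
    )


class TestCascadeClassifier:
    def test_zero_weights_give_zero_hierarchy(self):
        clf = make_classifier()
        for p in clf.parameters():
            p.data[...] = 0.0
        h0, h1, h2 = clf.hierarchical_projections(np.ones((3, 16)))
        for h in (h0, h1, h2):
            np.testing.assert_array_equal(h.data, np.zeros((3, 6)))

    def test_projection_widths_stackable(self):
        clf = make_classifier()
        hs = clf.hierarchical_projections(np.random.default_rng(0).normal(size=(4, 16)))
        assert all(h.shape == (4, 6) for h in hs)

    def test_hierarchy_matches_affine_oracle(self):
        """Hand-coded affine+ReLU chain on a random 1x8 input."""
        clf = make_classifier(d_in=8, seed=3)
        x = np.random.default_rng(4).normal(size=(1, 8))
        H = x
        expected = []
        for Wh, bh, Wp, bp in zip(clf.W_hier, clf.b_hier, clf.W_proj, clf.b_proj):
            H = np.maximum(H @ Wh.data + bh.data, 0)
            expected.append(np.maximum(H @ Wp.data + bp.data, 0))
        got = clf.hierarchical_projections(x)
        for e, g in zip(expected, got):
            np.testing.assert_allclose(g.data, e, atol=1e-10)

    def test_zero_win_gives_uniform_layer_attention(self):
        clf = make_classifier()
        clf.W_in.data[...] = 0.0
        h = np.random.default_rng(0).normal(size=(2, 6))
        from mirlink.autodiff import stack, tensor

        s = stack([tensor(h), tensor(h), tensor(h)], axis=-2)
        attn = (s @ clf.W_in).softmax(axis=-1)
        np.testing.assert_allclose(attn.data, 1.0 / 3.0, atol=1e-12)

    def test_zero_h_fuses_to_zero(self):
        clf = make_classifier()
        z = np.zeros((3, 6))
        fused = clf.layer_attention_fuse(z, z, z)
        np.testing.assert_array_equal(fused.data, np.zeros((3, 6)))

    def test_feature_attention_zero_input(self):
        clf = make_classifier()
        out = clf.feature_attention_refine(np.zeros((2, 6)))
        np.testing.assert_array_equal(out.data, np.zeros((2, 6)))

    def test_feature_attention_uniform_case(self):
        """W1 = W2 = 0 makes attention uniform: out = h + mean-mixed h."""
        clf = make_classifier()
        clf.W1.data[...] = 0.0
        clf.W2.data[...] = 0.0
        h = np.random.default_rng(5).normal(size=(3, 6))
        out = clf.feature_attention_refine(h)
        expected = h + np.full_like(h, h.mean(axis=1, keepdims=True))
        np.testing.assert_allclose(out.data, expected, atol=1e-10)

    def test_attention_rows_sum_to_one(self):
        clf = make_classifier()
        h = np.random.default_rng(6).normal(size=(4, 6))
        col = tensor(h).reshape(4, 6, 1)
        scores = (col @ clf.W1) @ (col @ clf.W2).T
        attn = scores.softmax(axis=-1)
        np.testing.assert_allclose(attn.data.sum(axis=-1), 1.0, atol=1e-12)

    def test_zero_head_gives_half_probability(self):
        clf = make_classifier()
        clf.W_head.data[...] = 0.0
        clf.b_head.data[...] = 0.0
        p = clf.predict_proba(np.random.default_rng(0).normal(size=(5, 16)))
        np.testing.assert_allclose(p.data, 0.5, atol=1e-12)

    def test_probabilities_in_open_interval(self):
        for use_attn in (True, False):
            clf = make_classifier(use_attention=use_attn, seed=9)
            p = clf.predict_proba(np.random.default_rng(1).normal(size=(8, 16)))
            assert ((p.data > 0) & (p.data < 1)).all()

    def test_monotone_in_head_bias(self):
        clf = make_classifier()
        x = np.random.default_rng(2).normal(size=(3, 16))
        p0 = clf.predict_proba(x).data.copy()
        clf.b_head.data[...] += 1.0
        p1 = clf.predict_proba(x).data
        assert (p1 > p0).all()

    def test_permutation_consistency(self):
        """Identical pair features yield identical probabilities."""
        clf = make_classifier()
        x = np.random.default_rng(3).normal(size=(1, 16))
        batch = np.vstack([x, x, x])
        p = clf.predict_proba(batch).data
        assert p[0] == pytest.approx(p[1]) == pytest.approx(p[2])

    def test_forward_deterministic(self):
        clf = make_classifier(seed=11)
        x = np.random.default_rng(4).normal(size=(6, 16))
        np.testing.assert_array_equal(
            clf.predict_proba(x).data, clf.predict_proba(x).data)
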