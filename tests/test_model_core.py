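import numpy as np
import pytest

from ecotree.knowledge_graph import KnowledgeGraph, gcn_embed
from ecotree.model_core import (
    AttentionConfig,
    CoOccurrencePrior,
    FusionParams,
    ModelError,
    RegionFeature,
    TinyBackbone,
    conditional_fuse,
    cooccurrence_bias,
    hierarchical_fusion,
    kv_guided_attention,
    query_offset,
    roi_align,
    roi_features,
)
from ecotree.taxonomy import LabelPath


class TestKvGuidedAttention:
    def test_singleton_returns_value(self, rng):
        q = rng.normal(size=5)
        K = rng.normal(size=(1, 4))
        W_k = rng.normal(size=(5, 4))
        W_v = rng.normal(size=(6, 4))
        out = kv_guided_attention(q, K, W_k, W_v)
        np.testing.assert_allclose(out, W_v @ K[0])

    def test_identical_keys_give_mean_value(self, rng):
        q = rng.normal(size=5)
        base = rng.normal(size=4)
        K = np.stack([base, base, base])
        W_k = rng.normal(size=(5, 4))
        W_v = rng.normal(size=(6, 4))
        # same keys, but perturb values via different K? keys identical => use
        # identical K rows: softmax uniform, output is the (identical) value
        out = kv_guided_attention(q, K, W_k, W_v)
        np.testing.assert_allclose(out, (K @ W_v.T).mean(axis=0))

    def test_brute_force_softmax_oracle(self, rng):
        for _ in range(50):
            N, dk, dq = 4, 3, 5
            q = rng.normal(size=dq)
            K = rng.normal(size=(N, dk))
            W_k = rng.normal(size=(dq, dk))
            W_v = rng.normal(size=(dq, dk))
            out = kv_guided_attention(q, K, W_k, W_v)
            # two-loop reference; the softmax scale is the projected key dim
            keys = [W_k @ K[j] for j in range(N)]
            values = [W_v @ K[j] for j in range(N)]
            exps = [np.exp(q @ k / np.sqrt(len(k))) for k in keys]
            Z = sum(exps)
            ref = sum((e / Z) * v for e, v in zip(exps, values))
            np.testing.assert_allclose(out, ref, atol=1e-6)

    def test_weights_sum_to_one_indirectly(self, rng):
        # constant values => output equals that constant whatever the weights
        q = rng.normal(size=4)
        K = np.stack([np.ones(3) * c for c in (1.0, 1.0, 1.0)])
        W_k = rng.normal(size=(4, 3))
        out = kv_guided_attention(q, K, W_k, np.eye(3))
        np.testing.assert_allclose(out, np.ones(3) * np.ones(3).sum() / 3 * 3 / 3, atol=1e-9)

    def test_empty_knowledge_set_rejected(self, rng):
        with pytest.raises(ModelError, match="empty"):
            kv_guided_attention(rng.normal(size=3), np.empty((0, 4)), np.eye(4), np.eye(4))


class TestHierarchicalFusion:
    def test_zero_value_path_is_identity(self, rng):
        x = rng.normal(size=(3, 3, 6))
        K = rng.normal(size=(4, 5))
        out = hierarchical_fusion(x, K, W_q=rng.normal(size=(2, 6)), W_k=rng.normal(size=(2, 5)), W_v=np.zeros((6, 5)))
        np.testing.assert_allclose(out, x)

    def test_single_knowledge_vector_broadcast(self, rng):
        x = rng.normal(size=(2, 6))
        K = rng.normal(size=(1, 5))
        W_v = rng.normal(size=(6, 5))
        out = hierarchical_fusion(x, K, W_q=rng.normal(size=(2, 6)), W_k=rng.normal(size=(2, 5)), W_v=W_v)
        np.testing.assert_allclose(out, x + W_v @ K[0])

    def test_missing_embeddings_identity_fallback(self, rng):
        x = rng.normal(size=(4, 6))
        out = hierarchical_fusion(x, None, np.eye(6), np.eye(6), np.eye(6))
        np.testing.assert_allclose(out, x)

    def test_composition_with_attention_oracle(self, rng):
        x = rng.normal(size=(2, 2, 6))
        K = rng.normal(size=(5, 4))
        W_q = rng.normal(size=(3, 6))
        W_k = rng.normal(size=(3, 4))
        W_v = rng.normal(size=(6, 4))
        out = hierarchical_fusion(x, K, W_q, W_k, W_v)
        assert out.shape == x.shape
        for i in range(2):
            for j in range(2):
                ref = kv_guided_attention(W_q @ x[i, j], K, W_k, W_v) + x[i, j]
                np.testing.assert_allclose(out[i, j], ref, atol=1e-6)


class TestQueryOffset:
    def test_mu_zero_identity(self, rng):
        q = rng.normal(size=7)
        out = query_offset(q, rng.normal(size=4), 0.0, rng.normal(size=(7, 4)))
        np.testing.assert_allclose(out, q)

    def test_offset_bounded_by_mu(self, rng):
        for _ in range(20):
            q = rng.normal(size=7)
            mu = float(rng.uniform(-2, 2))
            out = query_offset(q, rng.normal(size=4), mu, rng.normal(size=(7, 4)))
            assert np.max(np.abs(out - q)) <= abs(mu) + 1e-12

    def test_constructed_cancellation(self, rng):
        offset = rng.uniform(-0.9, 0.9, size=5)
        q = -offset
        # phi_W = 0, phi_b = arctanh(offset) makes the shift exactly `offset`
        out = query_offset(q, np.zeros(3), 1.0, np.zeros((5, 3)), np.arctanh(offset))
        np.testing.assert_allclose(out, np.zeros(5), atol=1e-12)


class TestCooccurrenceBias:
    def prior(self):
        return CoOccurrencePrior({("a", "b"): np.e - 1.0, ("b", "a"): np.e - 1.0})

    def test_eta_zero_identity(self, rng):
        logits = rng.normal(size=(3, 3))
        out = cooccurrence_bias(logits, self.prior(), {0: "a", 1: "b"}, eta=0.0)
        np.testing.assert_allclose(out, logits)

    def test_zero_prior_identity(self, rng):
        logits = rng.normal(size=(3, 3))
        out = cooccurrence_bias(logits, CoOccurrencePrior({}), {0: "a", 1: "b"}, eta=2.0)
        np.testing.assert_allclose(out, logits)

    def test_unit_boost_at_w_e_minus_one(self, rng):
        logits = np.zeros((2, 2))
        out = cooccurrence_bias(logits, self.prior(), {0: "a", 1: "b"}, eta=1.5)
        assert out[0, 1] == pytest.approx(1.5)  # log(1 + (e-1)) = 1
        assert out[0, 0] == 0.0

    def test_rows_still_softmax_normalize(self, rng):
        logits = rng.normal(size=(4, 4))
        out = cooccurrence_bias(logits, self.prior(), {0: "a", 1: "b", 2: "a"}, eta=0.7)
        p = np.exp(out)
        p /= p.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(p.sum(axis=1), np.ones(4), atol=1e-6)

    def test_unmapped_region_no_bias(self, rng):
        logits = rng.normal(size=(3, 3))
        out = cooccurrence_bias(logits, self.prior(), {}, eta=1.0)
        np.testing.assert_allclose(out, logits)


class TestConditionalFuse:
    def setup_method(self):
        self.graph = KnowledgeGraph()
        self.graph.add_triple("s1", "predation", "s2")
        self.graph.add_triple("s1", "cohabitation", "s3")
        self.graph.add_triple("s1", "competition", "s4")
        self.embedding = gcn_embed(self.graph, d_k=4, seed=0)
        self.params = FusionParams.init(d_model=6, d_k=4, mu=0.3, seed=1)
        self.x = RegionFeature(np.arange(6, dtype=float), (0, 0, 1, 1))

    def test_no_path_identity(self):
        out = conditional_fuse(self.x, None, self.graph, self.embedding, self.params)
        np.testing.assert_allclose(out, self.x.vector)

    def test_unknown_species_identity(self):
        path = LabelPath(("o", "f", "not_in_kg"))
        out = conditional_fuse(self.x, path, self.graph, self.embedding, self.params)
        np.testing.assert_allclose(out, self.x.vector)

    def test_empty_neighborhood_offset_only(self):
        g = KnowledgeGraph()
        g.add_triple("s1", "predation", "s2")
        emb = gcn_embed(g, d_k=4, seed=0)
        # isolated entity with an embedding but no triples
        from ecotree.knowledge_graph import Entity

        g2 = KnowledgeGraph()
        g2.add_entity(Entity("s9", "s9"))
        emb.entity_vectors["s9"] = np.ones(4)
        path = LabelPath(("o", "f", "s9"))
        out = conditional_fuse(self.x, path, g2, emb, self.params)
        ref = query_offset(
            self.x.vector, np.ones(4), self.params.mu, self.params.phi_W, self.params.phi_b
        )
        np.testing.assert_allclose(out, ref)

    def test_composition_oracle_three_neighbors(self):
        path = LabelPath(("o", "f", "s1"))
        out = conditional_fuse(self.x, path, self.graph, self.embedding, self.params)
        K_i = self.embedding.entity_vectors["s1"]
        q = query_offset(self.x.vector, K_i, self.params.mu, self.params.phi_W, self.params.phi_b)
        nbrs = [other for (_r, other, _c) in self.graph.neighbors("s1")]
        K_n = np.stack([self.embedding.entity_vectors[n] for n in nbrs])
        ref = q + kv_guided_attention(q, K_n, self.params.W_k, self.params.W_v)
        np.testing.assert_allclose(out, ref, atol=1e-9)


class TestTinyBackbone:
    def test_stage_geometry_at_224(self):
        pyramid = TinyBackbone().forward(np.zeros((224, 224, 3), dtype=np.uint8))
        assert [p.shape[:2] for p in pyramid] == [(56, 56), (28, 28), (14, 14), (7, 7)]

    def test_zero_input_zero_features(self):
        pyramid = TinyBackbone().forward(np.zeros((96, 96, 3), dtype=np.uint8))
        for p in pyramid:
            np.testing.assert_allclose(p, 0.0, atol=1e-12)

    def test_deterministic_under_fixed_seed(self, rng):
        img = rng.integers(0, 256, size=(96, 96, 3), dtype=np.uint8)
        p1 = TinyBackbone(AttentionConfig(seed=4)).forward(img)
        p2 = TinyBackbone(AttentionConfig(seed=4)).forward(img)
        for a, b in zip(p1, p2):
            assert a.tobytes() == b.tobytes()

    def test_indivisible_side_rejected(self):
        with pytest.raises(ModelError, match="divisible"):
            TinyBackbone().forward(np.zeros((100, 100, 3)))

    def test_channel_doubling(self):
        cfg = AttentionConfig(base_channels=8)
        pyramid = TinyBackbone(cfg).forward(np.zeros((64, 64, 3)))
        assert [p.shape[2] for p in pyramid] == [8, 16, 32, 64]

    def test_finite_gradient_smoke(self, rng):
        """Numerical input-gradients of the first stage are finite."""
        bb = TinyBackbone(AttentionConfig(base_channels=4, blocks_per_stage=1))
        img = rng.uniform(0, 255, size=(32, 32, 3))
        base = bb.forward(img)[0].sum()
        eps = 1e-4
        for _ in range(5):
            i, j, c = rng.integers(32), rng.integers(32), rng.integers(3)
            pert = img.copy()
            pert[i, j, c] += eps
            g = (bb.forward(pert)[0].sum() - base) / eps
            assert np.isfinite(g)


class TestRoIFeatures:
    def test_constant_region_gives_constant_vector(self):
        feat = np.full((12, 12, 5), 3.25)
        pyramid = [feat, feat, feat, feat]
        out = roi_features(pyramid, [(8.0, 8.0, 24.0, 24.0)], stage=1, strides=(4, 4, 8, 16))
        np.testing.assert_allclose(out[0].vector, 3.25)

    def test_identical_boxes_identical_vectors(self, rng):
        feat = rng.normal(size=(12, 12, 5))
        pyramid = [feat] * 4
        box = (4.0, 6.0, 20.0, 18.0)
        out = roi_features(pyramid, [box, box], stage=1, strides=(4, 4, 8, 16))
        np.testing.assert_allclose(out[0].vector, out[1].vector)
        assert out[0].box == out[1].box == box

    def test_degenerate_box_rejected(self, rng):
        feat = rng.normal(size=(12, 12, 5))
        with pytest.raises(ModelError, match="degenerate"):
            roi_features([feat] * 4, [(4.0, 4.0, 4.0, 10.0)], stage=1)

    def test_unit_grid_bilinear_oracle(self, rng):
        """1x1 grid with one sample per bin equals one hand-computed bilinear
        lookup at the box center."""
        feat = rng.normal(size=(8, 8, 2))
        box = (2.0, 3.0, 6.0, 7.0)  # stride 1: center at (4.0, 5.0) -> (3.5, 4.5)
        out = roi_align(feat, box, stride=1, grid=1, samples=1)
        cy, cx = 4.5, 3.5  # y, x after the half-pixel alignment shift
        y0, x0 = int(np.floor(cy)), int(np.floor(cx))
        fy, fx = cy - y0, cx - x0
        ref = (
            feat[y0, x0] * (1 - fy) * (1 - fx)
            + feat[y0, x0 + 1] * (1 - fy) * fx
            + feat[y0 + 1, x0] * fy * (1 - fx)
            + feat[y0 + 1, x0 + 1] * fy * fx
        )
        np.testing.assert_allclose(out[0, 0], ref, atol=1e-9)

    def test_box_order_preserved(self, rng):
        feat = rng.normal(size=(12, 12, 3))
        boxes = [(0.0, 0.0, 8.0, 8.0), (8.0, 8.0, 24.0, 24.0)]
        out = roi_features([feat] * 4, boxes, stage=0, strides=(2, 4, 8, 16))
        assert [f.box for f in out] == boxes
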