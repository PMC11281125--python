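"""Branch CNN, attention fusion, and classifier training."""

import numpy as np
import pytest

from fundustruct import nn
from fundustruct.classifier import (CLASSES, BranchSpec, ClassifierTrainConfig,
                                    FusionMode, HeadSpec, attention_fuse,
                                    build_branch, build_glaucoma_model, predict,
                                    train_classifier)

from conftest import SMOKE_BRANCH, SMOKE_HEAD


class TestBranch:
    def test_default_branch_shape_trace(self):
        """64x64x1 in -> 16x16 spatial with 512 channels out."""
        branch = build_branch(seed=0)
        branch.eval()
        out = branch(nn.Tensor(np.zeros((1, 1, 64, 64), dtype=np.float32)))
        assert out.shape == (1, 512, 16, 16)

    def test_introspection_matches_paper_layout(self):
        desc = build_branch().describe()
        assert desc["n_conv_layers"] == 4
        assert desc["conv_filters"] == [64, 128, 256, 512]
        assert desc["kernel"] == 3
        assert desc["n_norm_pool_stages"] == 2

    def test_zero_input_finite_output(self):
        branch = build_branch(SMOKE_BRANCH, seed=2)
        branch.eval()
        out = branch(nn.Tensor(np.zeros((2, 1, 64, 64), dtype=np.float32)))
        assert np.all(np.isfinite(out.data))

    def test_bad_spec_rejected(self):
        with pytest.raises(ValueError):
            BranchSpec(conv_filters=(64, 128))


def brute_force_attention(q, k, v):
    """Independent oracle: per-query softmax over key dot products."""
    n, p, c = q.shape
    out = np.zeros_like(v)
    weights = np.zeros((n, p, p))
    for b in range(n):
        for i in range(p):
            logits = np.array([q[b, i] @ k[b, j] / np.sqrt(c) for j in range(p)])
            e = np.exp(logits - logits.max())
            w = e / e.sum()
            weights[b, i] = w
            out[b, i] = sum(w[j] * v[b, j] for j in range(p))
    return out, weights


class TestAttentionFuse:
    def _maps(self, q_flat, kv_flat):
        # (N, P, C) -> (N, C, H, W) with H*W == P
        def to_map(flat):
            n, p, c = flat.shape
            h = int(np.sqrt(p))
            return nn.Tensor(flat.transpose(0, 2, 1).reshape(n, c, h, p // h))
        return to_map(q_flat), to_map(kv_flat)

    def test_identical_keys_give_uniform_weights(self, rng):
        q = rng.standard_normal((1, 4, 3)).astype(np.float32)
        kv = np.tile(rng.standard_normal((1, 1, 3)).astype(np.float32), (1, 4, 1))
        qm, km = self._maps(q, kv)
        attended, weights = attention_fuse(qm, km)
        np.testing.assert_allclose(weights.data, 0.25, atol=1e-6)
        np.testing.assert_allclose(attended.data, km.data, atol=1e-6)

    def test_two_position_hand_computed_softmax(self):
        """d=2 toy where the softmax weights are computed by hand."""
        q = np.array([[[1.0, 0.0], [0.0, 1.0]]], dtype=np.float32)   # (1, 2, 2)
        k = np.array([[[2.0, 0.0], [0.0, 4.0]]], dtype=np.float32)
        qm, km = self._maps(q, k)
        _, weights = attention_fuse(qm, km)
        # query 0: logits (2/sqrt2, 0) -> softmax([sqrt2, 0])
        e = np.exp([np.sqrt(2.0), 0.0])
        np.testing.assert_allclose(weights.data[0, 0], e / e.sum(), atol=1e-5)
        e1 = np.exp([0.0, 4.0 / np.sqrt(2.0)])
        np.testing.assert_allclose(weights.data[0, 1], e1 / e1.sum(), atol=1e-5)

    def test_single_position_passthrough(self, rng):
        q = rng.standard_normal((2, 1, 5)).astype(np.float32)
        kv = rng.standard_normal((2, 1, 5)).astype(np.float32)
        qm = nn.Tensor(q.transpose(0, 2, 1).reshape(2, 5, 1, 1))
        km = nn.Tensor(kv.transpose(0, 2, 1).reshape(2, 5, 1, 1))
        attended, weights = attention_fuse(qm, km)
        np.testing.assert_allclose(weights.data, 1.0, atol=1e-7)
        np.testing.assert_allclose(attended.data, km.data, atol=1e-7)

    def test_matches_brute_force_oracle(self, rng):
        """3-position toy vs the independent double-loop softmax oracle."""
        q = rng.standard_normal((2, 9, 4)).astype(np.float32)
        kv = rng.standard_normal((2, 9, 4)).astype(np.float32)
        qm, km = self._maps(q, kv)
        attended, weights = attention_fuse(qm, km)
        oracle_out, oracle_w = brute_force_attention(q, kv, kv)
        np.testing.assert_allclose(weights.data, oracle_w, atol=1e-5)
        flat = attended.data.reshape(2, 4, 9).transpose(0, 2, 1)
        np.testing.assert_allclose(flat, oracle_out, atol=1e-5)

    def test_weights_rows_sum_to_one(self, rng):
        qm = nn.Tensor(rng.standard_normal((3, 8, 4, 4)).astype(np.float32) * 5)
        km = nn.Tensor(rng.standard_normal((3, 8, 4, 4)).astype(np.float32) * 5)
        _, weights = attention_fuse(qm, km)
        assert weights.data.min() >= 0
        np.testing.assert_allclose(weights.data.sum(axis=-1), 1.0, atol=1e-5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            attention_fuse(nn.Tensor(np.zeros((1, 2, 4, 4), dtype=np.float32)),
                           nn.Tensor(np.zeros((1, 3, 4, 4), dtype=np.float32)))


class TestGlaucomaModel:
    def test_softmax_output_contract(self):
        model = build_glaucoma_model(SMOKE_BRANCH, SMOKE_HEAD, FusionMode("attention"), seed=3)
        x = np.random.default_rng(0).random((2, 64, 64), dtype=np.float32)
        probs = model.predict_proba(x, x, x)
        assert probs.shape == (2, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_fusion_channel_arithmetic(self):
        att = build_glaucoma_model(fusion=FusionMode("attention"))
        abl = build_glaucoma_model(fusion=FusionMode("concat-ablation"))
        assert att.pre_head_channels == 2 * 512
        assert abl.pre_head_channels == 3 * 512

    def test_head_introspection(self):
        desc = build_glaucoma_model(fusion=FusionMode("attention")).describe()
        assert desc["head"]["conv_filters"] == [2048, 4096, 4096]
        assert desc["head"]["final_kernel"] == 1
        assert desc["branch"]["conv_filters"] == [64, 128, 256, 512]
        assert desc["n_branches"] == 3

    def test_invalid_fusion_rejected(self):
        with pytest.raises(ValueError):
            FusionMode("self-attention")


def tiny_triples(rng, n=4):
    out = []
    for i in range(n):
        label = "glaucoma" if i % 2 == 0 else "normal"
        t = tuple(rng.random((64, 64), dtype=np.float32) for _ in range(3))
        out.append((t, label))
    return out


class TestTraining:
    def test_single_class_rejected(self, rng):
        data = [(t, "glaucoma") for t, _ in tiny_triples(rng)]
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(data, ClassifierTrainConfig(epochs=1),
                             branch_spec=SMOKE_BRANCH, head_spec=SMOKE_HEAD)

    def test_same_seed_identical_history(self, rng):
        data = tiny_triples(rng)
        cfg = ClassifierTrainConfig(epochs=2, seed=5)
        _, h1 = train_classifier(data, cfg, FusionMode("attention"),
                                 branch_spec=SMOKE_BRANCH, head_spec=SMOKE_HEAD)
        _, h2 = train_classifier(data, cfg, FusionMode("attention"),
                                 branch_spec=SMOKE_BRANCH, head_spec=SMOKE_HEAD)
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["train_accuracy"] == h2["train_accuracy"]

    def test_learns_phantom_signal(self, attention_run):
        """The attention model separates the cup-to-disc classes on
        held-out phantoms."""
        assert max(attention_run["history"]["val_accuracy"]) >= 0.9

    def test_attention_weights_recorded(self, attention_run, study_triples):
        model = attention_run["model"]
        (img, ves, dsc), _ = study_triples["val"][0]
        model.predict_proba(img, ves, dsc)
        wv, wd = model.last_attention
        np.testing.assert_allclose(wv.sum(axis=-1), 1.0, atol=1e-4)
        np.testing.assert_allclose(wd.sum(axis=-1), 1.0, atol=1e-4)


class TestPredict:
    def test_probability_contract_and_determinism(self, attention_run, study_triples):
        model = attention_run["model"]
        triple, _ = study_triples["val"][0]
        label1, p1 = predict(model, triple)
        label2, p2 = predict(model, triple)
        assert label1 == label2 and label1 in CLASSES
        np.testing.assert_array_equal(p1, p2)
        assert abs(p1.sum() - 1.0) < 1e-5

    def test_batch_equals_per_item(self, attention_run, study_triples):
        model = attention_run["model"]
        triples = [t for t, _ in study_triples["val"][:3]]
        imgs = np.stack([t[0] for t in triples])
        vess = np.stack([t[1] for t in triples])
        dscs = np.stack([t[2] for t in triples])
        batch = model.predict_proba(imgs, vess, dscs)
        singles = np.stack([model.predict_proba(t[0], t[1], t[2])[0] for t in triples])
        np.testing.assert_allclose(batch, singles, atol=1e-4)
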