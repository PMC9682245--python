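"""Encoder model: attention masking, heads, padding invariance, persistence."""

import numpy as np
import pytest

from ehrformer.model import (AcuityTransformer, ModelConfig, MultiHeadAttention,
                             attention_bias, sliding_global_attention)
from ehrformer.nn import Tensor
from ehrformer.sequence import pad_and_batch


def dense_attention_oracle(x, attn: MultiHeadAttention, allowed: np.ndarray):
    """Independent full attention with an explicit per-pair boolean mask."""
    W = {k: getattr(attn, k).weight.data for k in ("q", "k", "v", "out")}
    b = {k: getattr(attn, k).bias.data for k in ("q", "k", "v", "out")}
    B, L, d = x.shape
    h, dh = attn.heads, attn.head_dim
    out = np.zeros_like(x)
    for bi in range(B):
        q = x[bi] @ W["q"] + b["q"]
        k = x[bi] @ W["k"] + b["k"]
        v = x[bi] @ W["v"] + b["v"]
        ctx = np.zeros((L, d))
        for head in range(h):
            sl = slice(head * dh, (head + 1) * dh)
            scores = q[:, sl] @ k[:, sl].T / np.sqrt(dh)
            probs = np.zeros_like(scores)
            for i in range(L):
                mask = allowed[bi, i]
                if mask.any():
                    row = scores[i, mask]
                    e = np.exp(row - row.max())
                    probs[i, mask] = e / e.sum()
                else:
                    probs[i] = 1.0 / L  # degenerate all-masked row
            ctx[:, sl] = probs @ v[:, sl]
        out[bi] = ctx @ W["out"] + b["out"]
    return out


def allowed_from_masks(window, global_mask, pad_mask):
    B, L = pad_mask.shape
    idx = np.arange(L)
    band = np.abs(idx[:, None] - idx[None, :]) <= window // 2
    allowed = np.broadcast_to(band, (B, L, L)).copy()
    allowed |= global_mask[:, :, None]
    allowed |= global_mask[:, None, :]
    allowed &= pad_mask[:, None, :] & pad_mask[:, :, None]
    return allowed


def make_attention(d=16, heads=4, seed=0):
    rng = np.random.default_rng(seed)
    return MultiHeadAttention(d, heads, 0.0, rng, rng, np.float64)


class TestSlidingGlobalAttention:
    def test_wide_window_equals_full_attention(self):
        rng = np.random.default_rng(0)
        attn = make_attention()
        x = rng.normal(size=(2, 12, 16))
        pad = np.ones((2, 12), dtype=bool)
        glob = np.zeros((2, 12), dtype=bool)
        out = sliding_global_attention(attn, Tensor(x), 64, glob, pad)
        ref = dense_attention_oracle(x, attn, allowed_from_masks(64, glob, pad))
        np.testing.assert_allclose(out.data, ref, atol=1e-10)

    def test_sequence_length_one(self):
        attn = make_attention()
        x = np.random.default_rng(1).normal(size=(1, 1, 16))
        pad = np.ones((1, 1), dtype=bool)
        glob = np.zeros((1, 1), dtype=bool)
        out = sliding_global_attention(attn, Tensor(x), 4, glob, pad).data
        # softmax over a single logit is 1: output = out-proj of value path
        v = x[0] @ attn.v.weight.data + attn.v.bias.data
        ref = v @ attn.out.weight.data + attn.out.bias.data
        np.testing.assert_allclose(out[0], ref, atol=1e-10)

    def test_window_one_with_global_token_mask_structure(self):
        pad = np.ones((1, 6), dtype=bool)
        glob = np.zeros((1, 6), dtype=bool)
        glob[0, 0] = True
        allowed = allowed_from_masks(1, glob, pad)[0]
        assert allowed[0].all()          # global row sees everything
        assert allowed[:, 0].all()       # everyone sees the global token
        assert not allowed[1, 5]         # distant non-global pair is masked
        assert not allowed[5, 1]
        bias = attention_bias(1, glob, pad, np.float64)[0, 0]
        np.testing.assert_array_equal(bias == 0.0, allowed)

    def test_random_configurations_match_oracle(self):
        rng = np.random.default_rng(7)
        attn = make_attention()
        for _ in range(25):
            L = int(rng.integers(2, 24))
            window = int(rng.integers(1, 9))
            x = rng.normal(size=(1, L, 16))
            pad = np.ones((1, L), dtype=bool)
            pad[0, L - int(rng.integers(0, L // 2 + 1)):] = False
            glob = np.zeros((1, L), dtype=bool)
            for g in rng.choice(L, size=int(rng.integers(0, 4)), replace=False):
                glob[0, g] = True
            glob &= pad
            out = sliding_global_attention(attn, Tensor(x), window, glob, pad)
            ref = dense_attention_oracle(x, attn,
                                         allowed_from_masks(window, glob, pad))
            real = pad[0]
            np.testing.assert_allclose(out.data[0][real], ref[0][real], atol=1e-9)


@pytest.fixture(scope="module")
def tiny_model_and_batches(small_prepared):
    config = ModelConfig(layers=2, hidden=16, feedforward=32, heads=4,
                         window=16, dropout=0.1, n_tasks=7,
                         vocab_size=small_prepared.vocab.size,
                         static_width=small_prepared.static_width,
                         static_hidden=[16], seed=0)
    model = AcuityTransformer(config).eval()
    return model, small_prepared.train.batches


class TestForward:
    def test_logit_shape_and_head_width(self, tiny_model_and_batches):
        model, batches = tiny_model_and_batches
        logits = model.forward(batches[0])
        assert logits.shape == (batches[0].size, 7)
        # per-task head consumes layers x hidden concatenation
        assert model.heads[0].weight.data.shape[0] == 2 * 16
        full_scale = ModelConfig(vocab_size=50, static_width=4)
        assert full_scale.layers * full_scale.hidden == 1024

    def test_padding_invariance(self, small_prepared):
        config = ModelConfig(layers=2, hidden=16, feedforward=32, heads=4,
                             window=16, n_tasks=7,
                             vocab_size=small_prepared.vocab.size,
                             static_width=small_prepared.static_width,
                             static_hidden=[16], seed=1, dtype="float64")
        model = AcuityTransformer(config).eval()
        seqs = sorted([s for b in small_prepared.train.batches
                       for s in _unbatch(b)], key=lambda s: s["length"])
        short, long_ = seqs[0], seqs[-1]
        alone = model.forward(_rebatch([short])).data[0]
        padded = model.forward(_rebatch([short, long_])).data[0]
        np.testing.assert_allclose(alone, padded, atol=1e-5)

    def test_each_head_gets_gradient_from_its_task(self, small_prepared):
        config = ModelConfig(layers=1, hidden=16, feedforward=32, heads=2,
                             window=8, n_tasks=7, dropout=0.0,
                             vocab_size=small_prepared.vocab.size,
                             static_width=small_prepared.static_width,
                             static_hidden=[8], seed=3)
        model = AcuityTransformer(config)
        batch = small_prepared.train.batches[0]
        for task in range(7):
            for p in model.parameters():
                p.grad = None
            logits = model.forward(batch)
            logits[:, task].bce_with_logits(batch.labels[:, task]).mean().backward()
            g = model.heads[task].weight.grad
            assert g is not None and np.abs(g).sum() > 0
            for other in range(7):
                if other != task:
                    g_other = model.heads[other].weight.grad
                    assert g_other is None or np.abs(g_other).sum() == 0

    def test_discrete_only_has_fewer_parameters(self, small_prepared):
        kw = dict(layers=1, hidden=16, feedforward=32, heads=2, window=8,
                  n_tasks=7, vocab_size=small_prepared.vocab.size,
                  static_width=small_prepared.static_width, static_hidden=[8])
        full = AcuityTransformer(ModelConfig(**kw))
        disc = AcuityTransformer(ModelConfig(**kw, discrete_only=True))
        assert disc.num_parameters() < full.num_parameters()

    def test_checkpoint_round_trip(self, tiny_model_and_batches, tmp_path):
        model, batches = tiny_model_and_batches
        model.save(tmp_path / "ckpt")
        restored = AcuityTransformer.load(str(tmp_path / "ckpt")).eval()
        a = model.forward(batches[0]).data
        b = restored.forward(batches[0]).data
        np.testing.assert_array_equal(a, b)


def _unbatch(batch):
    out = []
    for i in range(batch.size):
        n = int(batch.lengths[i])
        out.append({"tokens": batch.tokens[i, :n], "global": batch.global_mask[i, :n],
                    "special": batch.special_mask[i, :n], "static": batch.static[i],
                    "labels": batch.labels[i], "length": n,
                    "stay_id": batch.stay_ids[i]})
    return out


def _rebatch(items):
    from ehrformer.sequence import AssembledSequence
    seqs = [AssembledSequence(tokens=i["tokens"], global_mask=i["global"],
                              special_mask=i["special"], static_vector=i["static"],
                              labels=i["labels"], los_hours=0.0,
                              stay_id=i["stay_id"]) for i in items]
    return pad_and_batch(seqs)
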