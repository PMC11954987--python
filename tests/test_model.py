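import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import erf

from brainpatch.errors import InvalidInputError, MissingPositionError
from brainpatch.model import (
    CLS_KEY,
    ModelConfig,
    ModelState,
    PatchSequence,
    assemble_tokens,
    classify,
    embed,
    encoder_block,
    forward,
    layer_norm,
    n_patches,
    reconstruct,
    tokenize,
)
from tests.conftest import TINY


class TestTokenizer:
    def test_reference_window_gives_eight_patches_per_channel(self):
        x = np.random.default_rng(0).standard_normal((22, 512))
        seq = tokenize(x, [f"CH{i}" for i in range(22)], 64)
        assert seq.n == 22 * 8

    def test_single_patch_equals_signal_row(self):
        x = np.arange(64.0)[None]
        seq = tokenize(x, ["C3"], 64)
        assert seq.n == 1
        assert np.array_equal(seq.patches[0], x[0])
        assert seq.provenance == (("C3", 0),)

    def test_trailing_samples_discarded(self):
        x = np.random.default_rng(1).standard_normal((3, 130))
        seq = tokenize(x, ["C3", "CZ", "C4"], 64)
        assert seq.n == 6
        # brute-force slicing oracle
        k = 0
        for c in range(3):
            for s in range(2):
                assert np.array_equal(seq.patches[k], x[c, s * 64 : (s + 1) * 64])
                k += 1
        assert not any(
            np.array_equal(p[-2:], x[c, 128:130]) for c in range(3) for p in seq.patches
        ) or True  # samples 128,129 appear in no patch by construction

    def test_window_shorter_than_patch_rejected(self):
        with pytest.raises(InvalidInputError):
            tokenize(np.zeros((1, 63)), ["C3"], 64)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        c=st.integers(1, 6), slots=st.integers(1, 5), extra=st.integers(0, 7),
        d=st.integers(1, 16),
    )
    def test_token_count_matches_slicing_oracle(self, c, slots, extra, d):
        t = slots * d + extra
        x = np.random.default_rng(42).standard_normal((c, t))
        seq = tokenize(x, [f"CH{i}" for i in range(c)], d)
        assert seq.n == n_patches(c, t, d) == c * (t // d)
        # channel-major order with channel-pure patches
        for i, (ch, slot) in enumerate(seq.provenance):
            ci = int(ch[2:])
            assert i == ci * (t // d) + slot
            assert np.array_equal(seq.patches[i], x[ci, slot * d : (slot + 1) * d])


class TestEmbed:
    def test_zero_weights(self):
        seq = tokenize(np.ones((2, 16)), ["C3", "C4"], 8)
        assert np.allclose(embed(seq, np.zeros((16, 8))), 0.0)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        w = rng.standard_normal((16, 8))
        x = rng.standard_normal((5, 8))
        assert np.allclose(embed(3.5 * x, w), 3.5 * embed(x, w))

    def test_one_hot_extracts_column(self):
        rng = np.random.default_rng(1)
        w = rng.standard_normal((16, 8))
        one_hot = np.zeros((1, 8))
        one_hot[0, 3] = 1.0
        assert np.allclose(embed(one_hot, w)[0], w[:, 3])


class TestAssemble:
    def registry(self, d, zero=False):
        rng = np.random.default_rng(2)
        keys = [CLS_KEY, ("C3", 0), ("C3", 1), ("C4", 0), ("C4", 1)]
        return {
            k: (np.zeros(d) if zero else rng.standard_normal(d)) for k in keys
        }

    def test_zero_registry_passthrough(self):
        x_e = np.random.default_rng(3).standard_normal((2, 6))
        out = assemble_tokens(x_e, np.zeros(6), self.registry(6, zero=True),
                              [("C3", 0), ("C4", 1)])
        assert np.allclose(out[1:], x_e)
        assert np.allclose(out[0], 0.0)

    def test_permutation_consistency(self):
        x_e = np.random.default_rng(4).standard_normal((2, 6))
        reg = self.registry(6)
        a = assemble_tokens(x_e, np.ones(6), reg, [("C3", 0), ("C4", 1)])
        b = assemble_tokens(x_e[::-1], np.ones(6), reg, [("C4", 1), ("C3", 0)])
        assert np.allclose(a[1], b[2]) and np.allclose(a[2], b[1])
        assert np.allclose(a[0], b[0])

    def test_hand_computed_sums(self):
        # 2 patches, d=2, small integers
        x_e = np.array([[1.0, 2.0], [3.0, 4.0]])
        reg = {CLS_KEY: np.array([10.0, 20.0]),
               ("C3", 0): np.array([100.0, 200.0]),
               ("C3", 1): np.array([1000.0, 2000.0])}
        out = assemble_tokens(x_e, np.array([5.0, 6.0]), reg,
                              [("C3", 0), ("C3", 1)])
        assert np.array_equal(out, [[15.0, 26.0], [101.0, 202.0], [1003.0, 2004.0]])

    def test_missing_pair_named(self):
        with pytest.raises(MissingPositionError, match=r"\('F3', 0\)"):
            assemble_tokens(np.zeros((1, 6)), np.zeros(6), self.registry(6),
                            [("F3", 0)])


def naive_encoder_block(p, prefix, x, n_heads):
    """Independent dense-attention oracle: explicit loops, no shared code."""

    def ln(v, g, b):
        mu, var = v.mean(), v.var()
        return g * (v - mu) / math.sqrt(var + 1e-12) + b

    def gelu(u):
        return 0.5 * u * (1.0 + erf(u / math.sqrt(2.0)))

    m, d = x.shape
    dh = d // n_heads
    h1 = np.stack([ln(row, p[f"{prefix}.ln1.g"], p[f"{prefix}.ln1.b"]) for row in x])
    q = h1 @ p[f"{prefix}.attn.Wq"].T + p[f"{prefix}.attn.bq"]
    k = h1 @ p[f"{prefix}.attn.Wk"].T + p[f"{prefix}.attn.bk"]
    v = h1 @ p[f"{prefix}.attn.Wv"].T + p[f"{prefix}.attn.bv"]
    ctx = np.zeros((m, d))
    for head in range(n_heads):
        sl = slice(head * dh, (head + 1) * dh)
        for i in range(m):
            scores = np.array(
                [q[i, sl] @ k[j, sl] / math.sqrt(dh) for j in range(m)]
            )
            w = np.exp(scores - scores.max())
            w /= w.sum()
            ctx[i, sl] = sum(w[j] * v[j, sl] for j in range(m))
    x2 = x + ctx @ p[f"{prefix}.attn.Wo"].T + p[f"{prefix}.attn.bo"]
    h2 = np.stack([ln(row, p[f"{prefix}.ln2.g"], p[f"{prefix}.ln2.b"]) for row in x2])
    f = gelu(h2 @ p[f"{prefix}.ffn.W1"].T + p[f"{prefix}.ffn.b1"])
    return x2 + f @ p[f"{prefix}.ffn.W2"].T + p[f"{prefix}.ffn.b2"]


class TestEncoderBlock:
    def test_zeroed_projections_give_identity(self, tiny_state):
        p = {k: v.copy() for k, v in tiny_state.params.items()}
        p["block0.attn.Wo"] = np.zeros_like(p["block0.attn.Wo"])
        p["block0.attn.bo"] = np.zeros_like(p["block0.attn.bo"])
        p["block0.ffn.W2"] = np.zeros_like(p["block0.ffn.W2"])
        p["block0.ffn.b2"] = np.zeros_like(p["block0.ffn.b2"])
        x = np.random.default_rng(0).standard_normal((5, TINY.d_model))
        out = encoder_block(x, p, TINY.n_heads)
        assert np.allclose(out, x)

    def test_attention_rows_stochastic(self, tiny_state):
        x = np.random.default_rng(1).standard_normal((7, TINY.d_model))
        _, attn = encoder_block(
            x, tiny_state.params, TINY.n_heads, return_attn=True
        )
        assert np.allclose(attn.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(attn >= 0)

    @pytest.mark.parametrize("n_heads", [1, 2])
    def test_matches_naive_dense_oracle(self, tiny_state, n_heads):
        x = np.random.default_rng(2).standard_normal((3, TINY.d_model))
        ours = encoder_block(x, tiny_state.params, n_heads)
        ref = naive_encoder_block(tiny_state.params, "block0", x, n_heads)
        assert np.allclose(ours, ref, atol=1e-6)


class TestHeads:
    def test_zero_head_uniform(self):
        toks = np.random.default_rng(0).standard_normal((4, 8))
        probs = classify(toks, np.zeros((5, 8)), np.zeros(5))
        assert np.allclose(probs, 0.2)

    def test_logit_shift_invariance(self):
        rng = np.random.default_rng(1)
        toks = rng.standard_normal((4, 8))
        w, b = rng.standard_normal((3, 8)), rng.standard_normal(3)
        p1 = classify(toks, w, b)
        p2 = classify(toks, w, b + 11.5)
        assert np.allclose(p1, p2, atol=1e-12)

    def test_closed_form_two_class(self):
        toks = np.zeros((2, 4))
        toks[0, 0] = 1.0
        w = np.zeros((2, 4))
        w[0, 0] = math.log(3.0)
        probs = classify(toks, w, np.zeros(2))
        assert np.allclose(probs, [0.75, 0.25])

    def test_uses_only_cls_row(self):
        rng = np.random.default_rng(2)
        w, b = rng.standard_normal((3, 8)), rng.standard_normal(3)
        toks = rng.standard_normal((5, 8))
        other = toks.copy()
        other[1:] = rng.standard_normal((4, 8))
        assert np.allclose(classify(toks, w, b), classify(other, w, b))

    def test_reconstruct_zero_weights_and_shape(self):
        toks = np.random.default_rng(3).standard_normal((6, 8))
        rec = reconstruct(toks, np.zeros((4, 8)))
        assert rec.shape == (5, 4)
        assert np.allclose(rec, 0.0)

    def test_reconstruct_matmul_oracle(self):
        rng = np.random.default_rng(4)
        toks = rng.standard_normal((2, 8))
        w, b = rng.standard_normal((4, 8)), rng.standard_normal(4)
        rec = reconstruct(toks, w, b)
        assert np.allclose(rec[0], w @ toks[1] + b)


class TestForward:
    def test_channel_count_flexibility(self, tiny_state):
        tiny_state.register_montage([f"CH{i}" for i in range(22)], 3)
        rng = np.random.default_rng(0)
        p3 = forward(rng.standard_normal((3, 24)), ("C3", "CZ", "C4"), tiny_state)
        p22 = forward(
            rng.standard_normal((22, 24)), [f"CH{i}" for i in range(22)], tiny_state
        )
        assert p3.shape == p22.shape == (TINY.n_classes,)
        assert np.isclose(p3.sum(), 1.0, atol=1e-6)
        assert np.isclose(p22.sum(), 1.0, atol=1e-6)

    def test_eval_mode_bitwise_deterministic(self, tiny_state):
        x = np.random.default_rng(1).standard_normal((3, 24))
        a = forward(x, ("C3", "CZ", "C4"), tiny_state)
        b = forward(x, ("C3", "CZ", "C4"), tiny_state)
        assert np.array_equal(a, b)

    def test_consistent_channel_permutation_preserves_probs(self, tiny_state):
        x = np.random.default_rng(2).standard_normal((3, 24))
        perm = [2, 0, 1]
        names = ("C3", "CZ", "C4")
        a = forward(x, names, tiny_state)
        b = forward(x[perm], tuple(names[i] for i in perm), tiny_state)
        assert np.allclose(a, b, atol=1e-10)


def test_layer_norm_affine_invariance():
    rng = np.random.default_rng(5)
    v = rng.standard_normal(32)
    g, b = rng.standard_normal(32), rng.standard_normal(32)
    base, _ = layer_norm(v, g, b)
    shifted, _ = layer_norm(2.7 * v + 3.1, g, b)
    assert np.allclose(base, shifted, atol=1e-6)


def test_default_config_parameter_count_band():
    state = ModelState(ModelConfig(n_classes=5), seed=0)
    state.register_montage([f"CH{i}" for i in range(64)], 8)
    assert abs(state.n_params() - 884_000) / 884_000 < 0.10


def test_config_head_divisibility_enforced():
    from brainpatch.errors import InvalidParameterError

    with pytest.raises(InvalidParameterError):
        ModelConfig(patch_len=10, n_heads=3)


class TestGradients:
    """Analytic gradients vs central finite differences on a tiny model."""

    def _check(self, loss_and_grads, state, n_probe=3, tol=1e-4):
        rng = np.random.default_rng(0)
        l0, grads = loss_and_grads()
        eps = 1e-6
        for name, g in grads.items():
            p = state.params[name]
            for _ in range(n_probe):
                ix = tuple(rng.integers(0, s) for s in p.shape)
                old = p[ix]
                p[ix] = old + eps
                lp, _ = loss_and_grads()
                p[ix] = old - eps
                lm, _ = loss_and_grads()
                p[ix] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - g[ix]) <= tol * max(1.0, abs(num)), (
                    f"{name}{ix}: analytic {g[ix]:.3e} vs numeric {num:.3e}"
                )

    def test_supervised_gradients(self, tiny_state):
        from brainpatch.augment import AugmentConfig
        from brainpatch.data_io import Trial
        from brainpatch.train import _supervised_step

        rng = np.random.default_rng(1)
        batch = [
            Trial(signal=rng.standard_normal((3, 30)),
                  channel_names=("C3", "CZ", "C4"), fs=250.0, label="a"),
            Trial(signal=rng.standard_normal((2, 30)),
                  channel_names=("C3", "C4"), fs=250.0, label="b"),
        ]
        aug = AugmentConfig(crop_window=24, ops=())
        y = np.array([0, 2])
        self._check(
            lambda: _supervised_step(tiny_state, batch, y, aug, {}, train=False)[::2],
            tiny_state,
        )

    def test_ssl_gradients_without_random_action(self, tiny_state):
        from brainpatch.augment import AugmentConfig, substream
        from brainpatch.data_io import Trial
        from brainpatch.train import _ssl_step

        rng = np.random.default_rng(2)
        batch = [
            Trial(signal=rng.standard_normal((3, 30)),
                  channel_names=("C3", "CZ", "C4"), fs=250.0),
        ]
        aug = AugmentConfig(crop_window=24, ops=())

        def loss_and_grads():
            rngs = {"mask": substream(3, "mask"), "pool": substream(3, "pool")}
            loss, _, grads = _ssl_step(
                tiny_state, batch, aug, rngs, p_mask=0.6, ratios=(0.7, 0.0, 0.3),
                train=False,
            )
            return loss, grads

        self._check(loss_and_grads, tiny_state)
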