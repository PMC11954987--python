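"""Forward and backward passes of the patch Transformer, in NumPy.

The encoder is a pre-LN Transformer: each block computes

    X  <- X + MHSA(LN(X))
    X  <- X + FFN(LN(X))

with multi-head self-attention, a GELU feed-forward, dropout on the
attention weights and the FFN output (training only), and a final layer
normalization before the heads.  Classification reads only the cls token
(row 0); reconstruction projects every patch token back to signal space.

Every operation has a hand-derived vector-Jacobian product so the model
trains without an autodiff framework; the gradients are validated
against finite differences in the test suite.  Batched tensors are
(B, M, d_model) with M = N + 1 tokens; an optional boolean key mask marks
padded positions, which are excluded from attention normalization and
(by the losses) from every gradient.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
from scipy.special import erf

from ..errors import InvalidInputError, MissingPositionError
from .config import ModelConfig
from .state import CLS_KEY, ModelState
from .tokenizer import PatchSequence, tokenize

__all__ = [
    "embed",
    "assemble_tokens",
    "encoder_block",
    "classify",
    "reconstruct",
    "forward",
    "layer_norm",
    "encoder_forward",
    "encoder_backward",
]

LN_EPS = 1e-12  # float64 throughout; small enough that LN is exactly
# scale/shift-invariant to ~1e-9, large enough to guard degenerate tokens
MASK_NEG = -1e30
SQRT2 = math.sqrt(2.0)
INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


# ---------------------------------------------------------------- primitives


def layer_norm(x: np.ndarray, g: np.ndarray, b: np.ndarray):
    """LN over the last axis; returns (y, cache) with cache = (xhat, inv_std)."""
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + LN_EPS)
    xhat = (x - mu) * inv_std
    return g * xhat + b, (xhat, inv_std)


def _layer_norm_vjp(dy: np.ndarray, g: np.ndarray, cache):
    xhat, inv_std = cache
    dyg = dy * g
    m1 = dyg.mean(axis=-1, keepdims=True)
    m2 = (dyg * xhat).mean(axis=-1, keepdims=True)
    dx = inv_std * (dyg - m1 - xhat * m2)
    axes = tuple(range(dy.ndim - 1))
    return dx, (dy * xhat).sum(axis=axes), dy.sum(axis=axes)


def _gelu(u: np.ndarray) -> np.ndarray:
    return 0.5 * u * (1.0 + erf(u / SQRT2))


def _gelu_grad(u: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(u / SQRT2)) + u * INV_SQRT_2PI * np.exp(-0.5 * u * u)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _dropout_mask(rng: np.random.Generator, shape, p: float) -> np.ndarray:
    return (rng.random(shape) >= p) / (1.0 - p)


# ----------------------------------------------------------- spec operations


def embed(patches: PatchSequence | np.ndarray, w_e: np.ndarray) -> np.ndarray:
    """Linear patch embedding X_E = X_P W_E^T (no bias)."""
    x_p = patches.patches if isinstance(patches, PatchSequence) else np.asarray(patches)
    return x_p @ w_e.T


def assemble_tokens(
    x_e: np.ndarray,
    cls_vec: np.ndarray,
    pos_registry: Mapping[tuple[str, int], np.ndarray],
    provenance: Sequence[tuple[str, int]],
) -> np.ndarray:
    """Prepend the cls token and add positional vectors looked up by provenance.

    Row 0 is cls + its positional row; row i is X_E[i-1] plus the
    registry vector for provenance[i-1].  Unknown (channel, slot) pairs
    raise MissingPositionError; growing the registry is the caller's
    decision (see weight transfer in the training module).
    """
    n, d = x_e.shape
    if len(provenance) != n:
        raise InvalidInputError("provenance length must equal embedded patch count")
    out = np.empty((n + 1, d))
    if CLS_KEY not in pos_registry:
        raise MissingPositionError(f"no positional embedding for (channel, slot) = {CLS_KEY}")
    out[0] = cls_vec + pos_registry[CLS_KEY]
    for i, key in enumerate(provenance):
        if key not in pos_registry:
            raise MissingPositionError(
                f"no positional embedding for (channel, slot) = {key}"
            )
        out[i + 1] = x_e[i] + pos_registry[key]
    return out


def classify(tokens: np.ndarray, w_class: np.ndarray, b_class: np.ndarray) -> np.ndarray:
    """Softmax class probabilities from the cls token (row 0) only."""
    logits = tokens[..., 0, :] @ w_class.T + b_class
    return softmax(logits, axis=-1)


def reconstruct(tokens: np.ndarray, w_recon: np.ndarray, b_recon: np.ndarray = None) -> np.ndarray:
    """Per-patch signal reconstructions from token rows 1..N (cls excluded)."""
    if b_recon is None:
        b_recon = np.zeros(w_recon.shape[0])
    return tokens[..., 1:, :] @ w_recon.T + b_recon


# ------------------------------------------------------------ encoder blocks


def _split_heads(x: np.ndarray, n_heads: int) -> np.ndarray:
    b, m, d = x.shape
    return x.reshape(b, m, n_heads, d // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x: np.ndarray) -> np.ndarray:
    b, h, m, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(b, m, h * dh)


def _block_forward(p, prefix, x, key_mask, n_heads, p_drop, train, rng):
    """One pre-LN block on (B, M, d); returns (out, cache, head_attention)."""
    cache: dict = {"x": x}
    h1, c1 = layer_norm(x, p[f"{prefix}.ln1.g"], p[f"{prefix}.ln1.b"])
    q = h1 @ p[f"{prefix}.attn.Wq"].T + p[f"{prefix}.attn.bq"]
    k = h1 @ p[f"{prefix}.attn.Wk"].T + p[f"{prefix}.attn.bk"]
    v = h1 @ p[f"{prefix}.attn.Wv"].T + p[f"{prefix}.attn.bv"]
    qs, ks, vs = (_split_heads(t, n_heads) for t in (q, k, v))
    dh = qs.shape[-1]
    scores = qs @ ks.transpose(0, 1, 3, 2) / math.sqrt(dh)
    if key_mask is not None:
        scores = scores + np.where(key_mask[:, None, None, :], 0.0, MASK_NEG)
    attn = softmax(scores, axis=-1)
    drop_a = None
    if train and p_drop > 0:
        drop_a = _dropout_mask(rng, attn.shape, p_drop)
        attn_used = attn * drop_a
    else:
        attn_used = attn
    ctx = _merge_heads(attn_used @ vs)
    ao = ctx @ p[f"{prefix}.attn.Wo"].T + p[f"{prefix}.attn.bo"]
    x2 = x + ao
    h2, c2 = layer_norm(x2, p[f"{prefix}.ln2.g"], p[f"{prefix}.ln2.b"])
    u = h2 @ p[f"{prefix}.ffn.W1"].T + p[f"{prefix}.ffn.b1"]
    a = _gelu(u)
    o = a @ p[f"{prefix}.ffn.W2"].T + p[f"{prefix}.ffn.b2"]
    drop_f = None
    if train and p_drop > 0:
        drop_f = _dropout_mask(rng, o.shape, p_drop)
        o = o * drop_f
    out = x2 + o
    cache.update(
        h1=h1, c1=c1, ks=ks, qs=qs, vs=vs, attn=attn, drop_a=drop_a, ctx=ctx,
        x2=x2, h2=h2, c2=c2, u=u, a=a, drop_f=drop_f,
    )
    return out, cache, attn


def _flat_outer(dy: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Weight gradient for y = x @ W.T summed over batch and token axes."""
    return dy.reshape(-1, dy.shape[-1]).T @ x.reshape(-1, x.shape[-1])


def _block_backward(p, prefix, cache, d_out, n_heads):
    g: dict[str, np.ndarray] = {}
    axes = (0, 1)
    # FFN branch
    do = d_out if cache["drop_f"] is None else d_out * cache["drop_f"]
    g[f"{prefix}.ffn.b2"] = do.sum(axis=axes)
    g[f"{prefix}.ffn.W2"] = _flat_outer(do, cache["a"])
    da = do @ p[f"{prefix}.ffn.W2"]
    du = da * _gelu_grad(cache["u"])
    g[f"{prefix}.ffn.b1"] = du.sum(axis=axes)
    g[f"{prefix}.ffn.W1"] = _flat_outer(du, cache["h2"])
    dh2 = du @ p[f"{prefix}.ffn.W1"]
    dx2_ln, g[f"{prefix}.ln2.g"], g[f"{prefix}.ln2.b"] = _layer_norm_vjp(
        dh2, p[f"{prefix}.ln2.g"], cache["c2"]
    )
    dx2 = d_out + dx2_ln
    # attention branch
    dao = dx2
    g[f"{prefix}.attn.bo"] = dao.sum(axis=axes)
    g[f"{prefix}.attn.Wo"] = _flat_outer(dao, cache["ctx"])
    dctx = _split_heads(dao @ p[f"{prefix}.attn.Wo"], n_heads)
    attn, drop_a = cache["attn"], cache["drop_a"]
    attn_used = attn if drop_a is None else attn * drop_a
    d_attn_used = dctx @ cache["vs"].transpose(0, 1, 3, 2)
    dvs = attn_used.transpose(0, 1, 3, 2) @ dctx
    d_attn = d_attn_used if drop_a is None else d_attn_used * drop_a
    dscores = attn * (d_attn - (d_attn * attn).sum(axis=-1, keepdims=True))
    dh_scale = 1.0 / math.sqrt(cache["qs"].shape[-1])
    dqs = dscores @ cache["ks"] * dh_scale
    dks = dscores.transpose(0, 1, 3, 2) @ cache["qs"] * dh_scale
    dq, dk, dv = (_merge_heads(t) for t in (dqs, dks, dvs))
    h1 = cache["h1"]
    dh1 = np.zeros_like(h1)
    for name, dt in (("Wq", dq), ("Wk", dk), ("Wv", dv)):
        g[f"{prefix}.attn.{name}"] = _flat_outer(dt, h1)
        dh1 += dt @ p[f"{prefix}.attn.{name}"]
    g[f"{prefix}.attn.bq"] = dq.sum(axis=axes)
    g[f"{prefix}.attn.bk"] = dk.sum(axis=axes)
    g[f"{prefix}.attn.bv"] = dv.sum(axis=axes)
    dx_ln, g[f"{prefix}.ln1.g"], g[f"{prefix}.ln1.b"] = _layer_norm_vjp(
        dh1, p[f"{prefix}.ln1.g"], cache["c1"]
    )
    return dx2 + dx_ln, g


def encoder_block(
    x: np.ndarray,
    params: Mapping[str, np.ndarray],
    n_heads: int,
    p_drop: float = 0.0,
    train: bool = False,
    rng: np.random.Generator | None = None,
    prefix: str = "block0",
    return_attn: bool = False,
):
    """One encoder block on a single (M, d) token matrix."""
    if train and p_drop > 0 and rng is None:
        raise InvalidInputError("dropout in training mode requires an rng")
    out, _, attn = _block_forward(
        params, prefix, x[None], None, n_heads, p_drop, train, rng
    )
    return (out[0], attn[0]) if return_attn else out[0]


def encoder_forward(
    params: Mapping[str, np.ndarray],
    cfg: ModelConfig,
    x0: np.ndarray,
    key_mask: np.ndarray | None = None,
    train: bool = False,
    rng: np.random.Generator | None = None,
    collect_attn: bool = False,
):
    """Full encoder stack + final LN on (B, M, d); returns (Xf, cache, attns)."""
    if train and cfg.p_drop > 0 and rng is None:
        raise InvalidInputError("dropout in training mode requires an rng")
    x = x0
    caches, attns = [], []
    for i in range(cfg.n_blocks):
        x, c, attn = _block_forward(
            params, f"block{i}", x, key_mask, cfg.n_heads, cfg.p_drop, train, rng
        )
        caches.append(c)
        if collect_attn:
            attns.append(attn)
    xf, c_f = layer_norm(x, params["ln_f.g"], params["ln_f.b"])
    return xf, {"blocks": caches, "lnf": c_f}, attns


def encoder_backward(
    params: Mapping[str, np.ndarray],
    cfg: ModelConfig,
    cache,
    d_xf: np.ndarray,
):
    """VJP of encoder_forward; returns (dX0, grads by parameter name)."""
    grads: dict[str, np.ndarray] = {}
    dx, grads["ln_f.g"], grads["ln_f.b"] = _layer_norm_vjp(
        d_xf, params["ln_f.g"], cache["lnf"]
    )
    for i in reversed(range(cfg.n_blocks)):
        dx, g = _block_backward(params, f"block{i}", cache["blocks"][i], dx, cfg.n_heads)
        grads.update(g)
    return dx, grads


# ------------------------------------------------------------- whole network


def forward(
    x_window: np.ndarray,
    channel_names: Sequence[str],
    state: ModelState,
    mode: str = "classify",
    train: bool = False,
    rng: np.random.Generator | None = None,
    return_attn: bool = False,
):
    """Single-trial forward pass: tokenize -> embed -> assemble -> encode -> head.

    Works for any channel count whose (channel, slot) pairs are present
    in the positional registry; no encoder weight depends on the montage.
    """
    cfg, p = state.config, state.params
    seq = tokenize(x_window, channel_names, cfg.patch_len)
    x_e = embed(seq, p["embed.W"])
    x0 = assemble_tokens(x_e, p["cls"], state.pos_registry(), seq.provenance)
    xf, _, attns = encoder_forward(
        p, cfg, x0[None], train=train, rng=rng, collect_attn=return_attn
    )
    if mode == "classify":
        out = classify(xf, p["head.W"], p["head.b"])[0]
    elif mode == "reconstruct":
        out = reconstruct(xf, p["recon.W"], p["recon.b"])[0]
    else:
        raise InvalidInputError(f"unknown forward mode {mode!r}")
    if return_attn:
        return out, [a[0] for a in attns]
    return out
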