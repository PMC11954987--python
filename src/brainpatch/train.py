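"""Optimization policy and training loops.

Training uses AdamW with decoupled weight decay (0.01 on matrix weights;
none on biases, layer-norm parameters, the positional registry, the cls
and mask tokens, or — by default — the classification head, whose decay
is raised to 1.0 only for supervised pre-training), betas (0.9, 0.95),
global-norm gradient clipping at 1, and a learning rate that ramps
linearly from 0 to 3e-4 over the warm-up steps then follows a cosine
decay to 3e-5.  An epoch is one pass over all training trials.

Multi-dataset batches may mix trials with different channel counts;
shorter token sequences are padded and the padded positions are excluded
from attention normalization and from every loss, so they contribute
zero gradient.  All randomness flows from ``TrainPolicy.rng_seed``
through named substreams, making runs bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import numpy as np

from .augment import AugmentConfig, apply_ops, center_crop, subsample_channels, substream
from .data_io import Trial
from .errors import ConfigError, InvalidParameterError, LabelMappingError
from .model.config import ModelConfig
from .model.network import (
    classify,
    encoder_backward,
    encoder_forward,
    softmax,
)
from .model.state import CLS_KEY, ModelState
from .model.tokenizer import tokenize
from . import ssl as ssl_mod

__all__ = [
    "TrainPolicy",
    "LabelMap",
    "UNIFIED_CLASSES",
    "default_label_map",
    "amalgamate",
    "lr_schedule",
    "build_param_groups",
    "make_mixed_batches",
    "transfer_weights",
    "fit",
    "evaluate",
    "TrainingLog",
    "AdamW",
]

UNIFIED_CLASSES = ("LEFT_HAND", "RIGHT_HAND", "FEET", "REST", "BOTH_HANDS")


@dataclasses.dataclass(frozen=True)
class TrainPolicy:
    """Optimizer and schedule hyperparameters."""

    lr_max: float = 3e-4
    lr_min: float = 3e-5
    warmup_epochs: int = 10
    total_epochs: int = 60
    weight_decay: float = 0.01
    head_weight_decay: float = 0.0  # 1.0 during supervised pre-training
    betas: tuple[float, float] = (0.9, 0.95)
    grad_clip_norm: float = 1.0
    batch_size: int = 32
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.warmup_epochs <= self.total_epochs:
            raise InvalidParameterError("need 0 <= warmup_epochs <= total_epochs")
        if not 0 < self.lr_min <= self.lr_max:
            raise InvalidParameterError("need 0 < lr_min <= lr_max")
        if self.batch_size < 1:
            raise InvalidParameterError("batch_size must be >= 1")


# ------------------------------------------------------------ label mapping


@dataclasses.dataclass(frozen=True)
class LabelMap:
    """(dataset_id, native_label) -> unified motor-imagery class."""

    mapping: Mapping[tuple[str, str], str]


def default_label_map() -> LabelMap:
    """Amalgamation of the five public pre-training datasets' labels."""
    rows = {
        "AlexMI": {"right hand": "RIGHT_HAND", "feet": "FEET", "rest": "REST"},
        "BNCI2015004": {"right hand": "RIGHT_HAND", "feet": "FEET"},
        "Cho2017": {"left hand": "LEFT_HAND", "right hand": "RIGHT_HAND"},
        "Lee2019_MI": {"left hand": "LEFT_HAND", "right hand": "RIGHT_HAND"},
        "PhysionetMI": {
            "left hand": "LEFT_HAND",
            "right hand": "RIGHT_HAND",
            "feet": "FEET",
            "rest": "REST",
            "both hands": "BOTH_HANDS",
        },
    }
    mapping = {
        (ds, label): cls for ds, labels in rows.items() for label, cls in labels.items()
    }
    return LabelMap(mapping=mapping)


def amalgamate(label: str, dataset_id: str, label_map: LabelMap) -> str:
    """Map a dataset-native label to the unified five-class space."""
    key = (dataset_id, str(label).lower())
    try:
        return label_map.mapping[key]
    except KeyError:
        raise LabelMappingError(
            f"no unified class for label {label!r} of dataset {dataset_id!r}"
        ) from None


# ---------------------------------------------------------------- schedule


def lr_schedule(
    step: int, warmup_steps: int, total_steps: int, lr_max: float, lr_min: float
) -> float:
    """Linear warm-up from 0 to lr_max, then cosine decay to lr_min."""
    if step <= 0:
        return 0.0 if warmup_steps > 0 else lr_max
    if step < warmup_steps:
        return lr_max * step / warmup_steps
    if step >= total_steps:
        return lr_min
    frac = (step - warmup_steps) / max(total_steps - warmup_steps, 1)
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + math.cos(math.pi * frac))


# ------------------------------------------------------------ param groups

#: parameter-name suffixes that receive the standard weight decay
_DECAYED_SUFFIXES = (".Wq", ".Wk", ".Wv", ".Wo", ".W1", ".W2")


def _decay_for(name: str, policy: TrainPolicy) -> float:
    if name == "head.W":
        return policy.head_weight_decay
    if name == "embed.W" or name == "recon.W":
        return policy.weight_decay
    if any(name.endswith(s) for s in _DECAYED_SUFFIXES):
        return policy.weight_decay
    # biases, LN gains/biases, positional registry, cls and mask tokens
    return 0.0


def build_param_groups(state: ModelState, policy: TrainPolicy) -> list[dict]:
    """Partition all trainables into weight-decay groups (exhaustive, disjoint)."""
    groups: dict[float, list[str]] = {}
    for name in state.params:
        groups.setdefault(_decay_for(name, policy), []).append(name)
    return [
        {"weight_decay": wd, "names": sorted(names)}
        for wd, names in sorted(groups.items())
    ]


# ---------------------------------------------------------------- optimizer


class AdamW:
    """AdamW with decoupled decay and global-norm gradient clipping."""

    def __init__(self, params: Mapping[str, np.ndarray], betas=(0.9, 0.95), eps=1e-8):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0

    def step(
        self,
        params: dict[str, np.ndarray],
        grads: Mapping[str, np.ndarray],
        lr: float,
        wd_by_name: Mapping[str, float],
        clip_norm: float | None,
    ) -> float:
        """In-place update; returns the post-clipping global gradient norm."""
        gnorm = math.sqrt(sum(float((g * g).sum()) for g in grads.values()))
        scale = 1.0
        if clip_norm is not None and gnorm > clip_norm:
            scale = clip_norm / (gnorm + 1e-12)
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for name, g in grads.items():
            g = g * scale
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            update = (self.m[name] / c1) / (np.sqrt(self.v[name] / c2) + self.eps)
            params[name] -= lr * update + lr * wd_by_name.get(name, 0.0) * params[name]
        return gnorm * scale


# ----------------------------------------------------------------- batching


def make_mixed_batches(
    trials: Sequence[Trial],
    batch_size: int,
    rng: np.random.Generator,
    subsample_policy=None,
) -> Iterable[list[Trial]]:
    """One epoch of shuffled batches, possibly mixing datasets and montages.

    Every trial is visited exactly once per epoch.  When a channel
    subsampling policy is given, each trial independently keeps a random
    channel subset (order preserved).
    """
    order = rng.permutation(len(trials))
    for lo in range(0, len(trials), batch_size):
        batch = [trials[i] for i in order[lo : lo + batch_size]]
        if subsample_policy is not None:
            batch = [subsample_channels(t, rng, subsample_policy) for t in batch]
        yield batch


# ----------------------------------------------------------- weight transfer


def transfer_weights(
    pretrained: ModelState,
    target_montage: Sequence[str],
    n_slots: int,
    class_names: Sequence[str],
    seed: int = 0,
) -> ModelState:
    """Build a fine-tuning state from a pre-trained one.

    The linear projection, cls token, mask token, encoder blocks, final
    LN, and reconstruction head are copied.  Positional rows are copied
    for (channel, slot) keys seen in pre-training and freshly
    initialized for new sensors.  The classification head is always
    reinitialized for the target classes.
    """
    cfg = pretrained.config
    new_cfg = dataclasses.replace(cfg, n_classes=len(class_names))
    state = ModelState(new_cfg, seed=seed, class_names=tuple(class_names))
    for name, value in pretrained.params.items():
        if name.startswith(("head.",)) or name == "pos_table":
            continue
        state.params[name] = value.copy()
    state.register_montage(target_montage, n_slots)
    for key, row in pretrained.pos_index.items():
        if key in state.pos_index:
            state.params["pos_table"][state.pos_index[key]] = pretrained.params[
                "pos_table"
            ][row]
    return state


# ------------------------------------------------------------- training log


@dataclasses.dataclass
class TrainingLog:
    """Per-epoch metrics plus per-step post-clipping gradient norms."""

    epochs: list[dict] = dataclasses.field(default_factory=list)
    step_grad_norms: list[float] = dataclasses.field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.epochs)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ------------------------------------------------------------ batch kernels


def _class_indices(batch, class_to_idx, label_map):
    idx = []
    for t in batch:
        label = t.label
        if label_map is not None:
            label = amalgamate(label, t.dataset_id, label_map)
        if label not in class_to_idx:
            raise ConfigError(f"label {label!r} not among model classes")
        idx.append(class_to_idx[label])
    return np.array(idx)


def _prepare_tokens(state, batch, augment_cfg, rngs, train):
    """Crop/augment, tokenize, and pad one batch; no embedding yet."""
    d_patch = state.config.patch_len
    seqs = []
    for t in batch:
        x = apply_ops(t.signal, augment_cfg, rngs, train)
        seqs.append(tokenize(x, t.channel_names, d_patch))
    n_max = max(s.n for s in seqs)
    b = len(batch)
    patches = np.zeros((b, n_max, d_patch))
    valid = np.zeros((b, n_max), dtype=bool)
    pos_rows = np.zeros((b, n_max), dtype=np.intp)
    slots = np.full((b, n_max), -1, dtype=np.intp)
    for i, seq in enumerate(seqs):
        patches[i, : seq.n] = seq.patches
        valid[i, : seq.n] = True
        for j, key in enumerate(seq.provenance):
            pos_rows[i, j] = state.pos_index[key]
            slots[i, j] = key[1]
    key_mask = np.concatenate([np.ones((b, 1), dtype=bool), valid], axis=1)
    return patches, valid, pos_rows, slots, key_mask


def _assemble_batch(state, embedded, valid, pos_rows):
    """[cls; X_E] + positions, padded rows forced to zero; (B, N+1, d)."""
    p = state.params
    b, n_max, d = embedded.shape
    x0 = np.zeros((b, n_max + 1, d))
    x0[:, 0] = p["cls"] + p["pos_table"][state.pos_index[CLS_KEY]]
    gathered = p["pos_table"][pos_rows]
    x0[:, 1:] = (embedded + gathered) * valid[..., None]
    return x0


def _scatter_common_grads(state, grads, d_x0, valid, pos_rows, patches,
                          embed_passthrough):
    """Gradients for cls, positional table, and the linear projection."""
    d = state.config.d_model
    d_cls_rows = d_x0[:, 0]
    grads["cls"] = grads.get("cls", 0) + d_cls_rows.sum(axis=0)
    pos_g = np.zeros_like(state.params["pos_table"])
    pos_g[state.pos_index[CLS_KEY]] += d_cls_rows.sum(axis=0)
    d_tok = d_x0[:, 1:] * valid[..., None]
    np.add.at(pos_g, pos_rows[valid], d_tok[valid])
    grads["pos_table"] = grads.get("pos_table", 0) + pos_g
    thru = valid & embed_passthrough
    d_emb = d_tok[thru]  # (K, d)
    grads["embed.W"] = grads.get("embed.W", 0) + d_emb.T @ patches[thru]
    return d_tok


def _supervised_step(state, batch, y_idx, augment_cfg, rngs, train=True):
    """Forward + backward for one supervised batch; returns (loss, acc, grads)."""
    cfg, p = state.config, state.params
    patches, valid, pos_rows, _, key_mask = _prepare_tokens(
        state, batch, augment_cfg, rngs, train
    )
    embedded = patches @ p["embed.W"].T
    x0 = _assemble_batch(state, embedded, valid, pos_rows)
    xf, cache, _ = encoder_forward(
        p, cfg, x0, key_mask=key_mask, train=train, rng=rngs.get("dropout")
    )
    cls_out = xf[:, 0]
    logits = cls_out @ p["head.W"].T + p["head.b"]
    probs = softmax(logits, axis=-1)
    b = len(batch)
    loss = float(-np.mean(np.log(probs[np.arange(b), y_idx] + 1e-300)))
    acc = float(np.mean(probs.argmax(axis=1) == y_idx))
    # backward
    d_logits = probs.copy()
    d_logits[np.arange(b), y_idx] -= 1.0
    d_logits /= b
    grads = {
        "head.W": d_logits.T @ cls_out,
        "head.b": d_logits.sum(axis=0),
        "recon.W": np.zeros_like(p["recon.W"]),
        "recon.b": np.zeros_like(p["recon.b"]),
        "mask_token": np.zeros_like(p["mask_token"]),
    }
    d_xf = np.zeros_like(xf)
    d_xf[:, 0] = d_logits @ p["head.W"]
    d_x0, enc_grads = encoder_backward(p, cfg, cache, d_xf)
    grads.update(enc_grads)
    _scatter_common_grads(
        state, grads, d_x0, valid, pos_rows, patches,
        embed_passthrough=np.ones_like(valid),
    )
    return loss, acc, grads


def _ssl_step(state, batch, augment_cfg, rngs, p_mask, ratios, train=True):
    """Forward + backward for one masked-reconstruction batch."""
    cfg, p = state.config, state.params
    patches, valid, pos_rows, slots, key_mask = _prepare_tokens(
        state, batch, augment_cfg, rngs, train
    )
    b, n_max, d_patch = patches.shape
    n_slots = int(slots.max()) + 1
    embedded = patches @ p["embed.W"].T
    pool = embedded[valid]  # all real embedded patches in the batch
    corrupted = embedded.copy()
    manipulated = np.zeros((b, n_max), dtype=bool)
    # kind: 0 = embedding passthrough (unmanipulated or keep), 1 = mask, 2 = random
    kind = np.zeros((b, n_max), dtype=np.int8)
    rng_mask, rng_pool = rngs["mask"], rngs["pool"]
    for i in range(b):
        plan = ssl_mod.plan_mask(n_slots, p_mask=p_mask, ratios=ratios, rng=rng_mask)
        for j in range(n_max):
            if not valid[i, j]:
                continue
            act = plan.actions.get(int(slots[i, j]))
            if act is None:
                continue
            manipulated[i, j] = True
            if act == "mask":
                corrupted[i, j] = p["mask_token"]
                kind[i, j] = 1
            elif act == "random":
                corrupted[i, j] = pool[int(rng_pool.integers(0, pool.shape[0]))]
                kind[i, j] = 2
    x0 = _assemble_batch(state, corrupted, valid, pos_rows)
    xf, cache, _ = encoder_forward(
        p, cfg, x0, key_mask=key_mask, train=train, rng=rngs.get("dropout")
    )
    recons = xf[:, 1:] @ p["recon.W"].T + p["recon.b"]
    flat_mask = (manipulated & valid).reshape(-1)
    loss, d_r_flat = ssl_mod.recon_loss_grad(
        recons.reshape(-1, d_patch), patches.reshape(-1, d_patch), flat_mask
    )
    d_r = d_r_flat.reshape(recons.shape)
    grads = {
        "recon.W": _flatten2(d_r).T @ _flatten2(xf[:, 1:]),
        "recon.b": d_r.sum(axis=(0, 1)),
        "head.W": np.zeros_like(p["head.W"]),
        "head.b": np.zeros_like(p["head.b"]),
    }
    d_xf = np.zeros_like(xf)
    d_xf[:, 1:] = d_r @ p["recon.W"]
    d_x0, enc_grads = encoder_backward(p, cfg, cache, d_xf)
    grads.update(enc_grads)
    d_tok = _scatter_common_grads(
        state, grads, d_x0, valid, pos_rows, patches,
        embed_passthrough=(kind == 0),
    )
    # gradient for tokens replaced by the learned mask vector
    mask_rows = kind == 1
    grads["mask_token"] = (
        d_tok[mask_rows].sum(axis=0) if mask_rows.any() else np.zeros(cfg.d_model)
    )
    return loss, float("nan"), grads


def _flatten2(x: np.ndarray) -> np.ndarray:
    return x.reshape(-1, x.shape[-1])


# ------------------------------------------------------------------ fitting


def fit(
    trials: Sequence[Trial],
    state: ModelState,
    policy: TrainPolicy,
    objective: str = "supervised",
    eval_trials: Sequence[Trial] | None = None,
    augment: AugmentConfig | None = None,
    label_map: LabelMap | None = None,
    p_mask: float = ssl_mod.DEFAULT_P_MASK,
    ratios: tuple[float, float, float] = ssl_mod.DEFAULT_RATIOS,
) -> tuple[ModelState, TrainingLog]:
    """Train ``state`` in place; returns (state, log).

    ``objective`` is ``"supervised"`` (cross-entropy on the cls token)
    or ``"ssl"`` (masked-patch cosine reconstruction).  Fully
    reproducible given ``policy.rng_seed``.
    """
    if objective not in ("supervised", "ssl"):
        raise InvalidParameterError(f"unknown objective {objective!r}")
    if not trials:
        raise InvalidParameterError("fit requires at least one trial")
    augment = augment or AugmentConfig()
    n_slots = augment.crop_window // state.config.patch_len
    if n_slots < 1:
        raise ConfigError("crop_window shorter than one patch")
    # register every montage up-front so the optimizer sees the full table
    for t in trials:
        state.register_montage(t.channel_names, n_slots)
    if eval_trials:
        for t in eval_trials:
            state.register_montage(t.channel_names, n_slots)

    class_to_idx: dict[str, int] = {}
    if objective == "supervised":
        if label_map is not None:
            labels = sorted(
                {amalgamate(t.label, t.dataset_id, label_map) for t in trials}
            )
        else:
            labels = sorted({t.label for t in trials})
        if None in labels:
            raise ConfigError("supervised training requires labels on all trials")
        if state.class_names is None:
            if len(labels) != state.config.n_classes:
                raise ConfigError(
                    f"model has {state.config.n_classes} classes but data has "
                    f"{len(labels)}: {labels}"
                )
            state.class_names = tuple(labels)
        class_to_idx = {c: i for i, c in enumerate(state.class_names)}

    groups = build_param_groups(state, policy)
    wd_by_name = {n: g["weight_decay"] for g in groups for n in g["names"]}
    opt = AdamW(state.params, betas=policy.betas)
    seed = policy.rng_seed
    rngs = {name: substream(seed, name) for name in
            ("batches", "noise", "dc", "scale", "shift", "dropout", "mask",
             "pool", "subsample")}

    steps_per_epoch = math.ceil(len(trials) / policy.batch_size)
    warmup_steps = policy.warmup_epochs * steps_per_epoch
    total_steps = policy.total_epochs * steps_per_epoch
    log = TrainingLog()
    step = 0
    for epoch in range(policy.total_epochs):
        losses, accs = [], []
        for batch in make_mixed_batches(
            trials, policy.batch_size, rngs["batches"],
            subsample_policy=augment.channel_subsample,
        ):
            if objective == "supervised":
                y_idx = _class_indices(batch, class_to_idx, label_map)
                loss, acc, grads = _supervised_step(
                    state, batch, y_idx, augment, rngs
                )
                accs.append(acc)
            else:
                loss, _, grads = _ssl_step(
                    state, batch, augment, rngs, p_mask, ratios
                )
            step += 1
            lr = lr_schedule(step, warmup_steps, total_steps,
                             policy.lr_max, policy.lr_min)
            gnorm = opt.step(state.params, grads, lr, wd_by_name,
                             policy.grad_clip_norm)
            log.step_grad_norms.append(gnorm)
            losses.append(loss)
        row = {
            "epoch": epoch,
            "split": "train",
            "loss": float(np.mean(losses)),
            "accuracy": float(np.mean(accs)) if accs else float("nan"),
            "lr": lr,
        }
        log.epochs.append(row)
        if eval_trials is not None and objective == "supervised":
            acc = evaluate(state, eval_trials, augment.crop_window,
                           label_map=label_map)
            log.epochs.append(
                {"epoch": epoch, "split": "eval", "loss": float("nan"),
                 "accuracy": acc, "lr": lr}
            )
    return state, log


def evaluate(
    state: ModelState,
    trials: Sequence[Trial],
    crop_window: int,
    batch_size: int = 64,
    label_map: LabelMap | None = None,
) -> float:
    """Top-1 accuracy with the deterministic centered evaluation crop."""
    probs = predict_proba(state, trials, crop_window, batch_size)
    class_to_idx = {c: i for i, c in enumerate(state.class_names)}
    y = _class_indices(trials, class_to_idx, label_map)
    return float(np.mean(probs.argmax(axis=1) == y))


def predict_proba(
    state: ModelState,
    trials: Sequence[Trial],
    crop_window: int,
    batch_size: int = 64,
) -> np.ndarray:
    """Class probabilities for each trial (eval mode, centered crop)."""
    cfg, p = state.config, state.params
    n_slots = crop_window // cfg.patch_len
    for t in trials:
        state.register_montage(t.channel_names, n_slots)
    eval_cfg = AugmentConfig(crop_window=crop_window, ops=())
    out = []
    for lo in range(0, len(trials), batch_size):
        batch = list(trials[lo : lo + batch_size])
        patches, valid, pos_rows, _, key_mask = _prepare_tokens(
            state, batch, eval_cfg, {}, train=False
        )
        embedded = patches @ p["embed.W"].T
        x0 = _assemble_batch(state, embedded, valid, pos_rows)
        xf, _, _ = encoder_forward(p, cfg, x0, key_mask=key_mask, train=False)
        out.append(classify(xf, p["head.W"], p["head.b"]))
    return np.concatenate(out, axis=0)
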