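"""Model parameters, the positional-embedding registry, and checkpoints.

Positional embeddings are stored as a keyed registry mapping
(channel_name, time_slot) -> row of one growing table, plus one row for
the classification token.  Montages of any size therefore share rows for
common sensors, which is what makes the encoder weights reusable across
datasets with different channel counts.
"""

from __future__ import annotations

import json

import numpy as np

from ..errors import InvalidParameterError, MissingPositionError
from .config import ModelConfig

__all__ = ["ModelState", "CLS_KEY"]

#: registry key of the classification token's positional row
CLS_KEY = ("__CLS__", -1)

INIT_STD = 0.02
CHECKPOINT_FORMAT = "brainpatch-ckpt-1"


def _pos_key_str(key: tuple[str, int]) -> str:
    return f"{key[0]}|{key[1]}"


class ModelState:
    """All trainable tensors plus the positional registry and class names."""

    def __init__(
        self,
        config: ModelConfig,
        seed: int = 0,
        class_names: tuple[str, ...] | None = None,
    ):
        self.config = config
        rng = np.random.default_rng(seed)
        d, D, h = config.d_model, config.patch_len, config.ffn_hidden
        p: dict[str, np.ndarray] = {}
        p["embed.W"] = rng.normal(0.0, INIT_STD, (d, D))
        p["cls"] = rng.normal(0.0, INIT_STD, (d,))
        p["mask_token"] = rng.normal(0.0, INIT_STD, (d,))
        for i in range(config.n_blocks):
            b = f"block{i}"
            p[f"{b}.ln1.g"] = np.ones(d)
            p[f"{b}.ln1.b"] = np.zeros(d)
            for w in ("Wq", "Wk", "Wv", "Wo"):
                p[f"{b}.attn.{w}"] = rng.normal(0.0, INIT_STD, (d, d))
            for bias in ("bq", "bk", "bv", "bo"):
                p[f"{b}.attn.{bias}"] = np.zeros(d)
            p[f"{b}.ln2.g"] = np.ones(d)
            p[f"{b}.ln2.b"] = np.zeros(d)
            p[f"{b}.ffn.W1"] = rng.normal(0.0, INIT_STD, (h, d))
            p[f"{b}.ffn.b1"] = np.zeros(h)
            p[f"{b}.ffn.W2"] = rng.normal(0.0, INIT_STD, (d, h))
            p[f"{b}.ffn.b2"] = np.zeros(d)
        p["ln_f.g"] = np.ones(d)
        p["ln_f.b"] = np.zeros(d)
        p["head.W"] = rng.normal(0.0, INIT_STD, (config.n_classes, d))
        p["head.b"] = np.zeros(config.n_classes)
        p["recon.W"] = rng.normal(0.0, INIT_STD, (D, d))
        p["recon.b"] = np.zeros(D)
        # positional registry starts with only the cls row
        p["pos_table"] = rng.normal(0.0, INIT_STD, (1, d))
        self.params = p
        self.pos_index: dict[tuple[str, int], int] = {CLS_KEY: 0}
        self.class_names: tuple[str, ...] | None = class_names
        self._pos_rng = rng  # continues the init stream for registry growth

    # ---------------- positional registry ----------------

    def register_positions(self, keys) -> int:
        """Add registry rows for unseen (channel, slot) keys; return #added."""
        new = [k for k in keys if k not in self.pos_index]
        if not new:
            return 0
        d = self.config.d_model
        rows = self._pos_rng.normal(0.0, INIT_STD, (len(new), d))
        base = self.params["pos_table"].shape[0]
        self.params["pos_table"] = np.vstack([self.params["pos_table"], rows])
        for j, k in enumerate(new):
            self.pos_index[k] = base + j
        return len(new)

    def register_montage(self, channel_names, n_slots: int) -> int:
        keys = [
            (str(ch).upper(), s) for ch in channel_names for s in range(n_slots)
        ]
        return self.register_positions(keys)

    def pos_vector(self, key: tuple[str, int]) -> np.ndarray:
        try:
            return self.params["pos_table"][self.pos_index[key]]
        except KeyError:
            raise MissingPositionError(
                f"no positional embedding registered for (channel, slot) = {key}"
            ) from None

    def pos_registry(self) -> dict[tuple[str, int], np.ndarray]:
        """Read-only snapshot of the registry as a key -> vector mapping."""
        return {k: self.params["pos_table"][i] for k, i in self.pos_index.items()}

    # ---------------- bookkeeping ----------------

    def n_params(self) -> int:
        """Total trainable scalar count, including the current registry."""
        return int(sum(v.size for v in self.params.values()))

    def reinit_head(self, class_names: tuple[str, ...], seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        d = self.config.d_model
        self.params["head.W"] = rng.normal(0.0, INIT_STD, (len(class_names), d))
        self.params["head.b"] = np.zeros(len(class_names))
        self.config = ModelConfig(
            patch_len=self.config.patch_len,
            n_blocks=self.config.n_blocks,
            n_heads=self.config.n_heads,
            ffn_hidden=self.config.ffn_hidden,
            p_drop=self.config.p_drop,
            n_classes=len(class_names),
            d_model=self.config.d_model,
        )
        self.class_names = tuple(class_names)

    # ---------------- checkpoint I/O ----------------

    def save(self, path) -> None:
        meta = {
            "format": CHECKPOINT_FORMAT,
            "config": self.config.__dict__,
            "pos_keys": [_pos_key_str(k) for k, _ in sorted(
                self.pos_index.items(), key=lambda kv: kv[1]
            )],
            "class_names": list(self.class_names) if self.class_names else None,
        }
        np.savez(path, __meta__=np.bytes_(json.dumps(meta)), **self.params)

    @classmethod
    def load(cls, path) -> "ModelState":
        with np.load(path) as f:
            meta = json.loads(bytes(f["__meta__"]).decode())
            if meta.get("format") != CHECKPOINT_FORMAT:
                raise InvalidParameterError(
                    f"unrecognized checkpoint format tag {meta.get('format')!r}"
                )
            params = {k: f[k] for k in f.files if k != "__meta__"}
        state = cls.__new__(cls)
        state.config = ModelConfig(**meta["config"])
        state.params = params
        state.pos_index = {}
        for row, ks in enumerate(meta["pos_keys"]):
            ch, slot = ks.rsplit("|", 1)
            state.pos_index[(ch, int(slot))] = row
        cn = meta.get("class_names")
        state.class_names = tuple(cn) if cn else None
        state._pos_rng = np.random.default_rng(0)
        return state
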