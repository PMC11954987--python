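"""Interpretability operators.

Three views into a trained model: (1) the dominant frequency of each
learned embedding filter — rows of the linear projection act as temporal
filters, and at fs = 250 Hz with D = 64 samples per patch one spectral
bin step corresponds to fs / D = 3.90625 Hz, i.e. roughly "four times
the number of cycles per patch"; (2) cosine similarity between the
learned positional embeddings of sensors, which for motor-imagery models
reveals hemispheric structure over the motor cortex; (3) attention
rollout, the recursive product of residual-corrected attention matrices,
whose cls row attributes the classification to individual patches.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "RolloutMap",
    "filter_spectra",
    "pos_similarity",
    "attention_rollout",
    "render_maps",
]


@dataclasses.dataclass(frozen=True)
class RolloutMap:
    """Token-to-token attribution matrix; row 0 is the cls token."""

    matrix: np.ndarray  # (N+1, N+1), rows sum to 1

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InvalidInputError("rollout matrix must be square")

    def cls_importance(self, n_channels: int, n_slots: int) -> np.ndarray:
        """cls-row attribution over patches, reshaped to (channel, slot)."""
        row = self.matrix[0, 1:]
        if row.size != n_channels * n_slots:
            raise InvalidInputError(
                f"{row.size} patch attributions cannot form a "
                f"({n_channels}, {n_slots}) grid"
            )
        return row.reshape(n_channels, n_slots)


def filter_spectra(w_e: np.ndarray, fs: float, d: int | None = None) -> np.ndarray:
    """Dominant frequency (Hz) of each embedding-filter row of W_E.

    The dominant frequency is the argmax over nonzero bins of the
    magnitude spectrum, scaled by fs / D.  A constant (DC-only) row has
    no nonzero-bin peak and is reported as 0 Hz.
    """
    d = w_e.shape[1] if d is None else d
    mags = np.abs(np.fft.rfft(w_e, axis=1))
    ac = mags[:, 1:]  # nonzero bins
    peaks = np.argmax(ac, axis=1) + 1
    freqs = peaks * fs / d
    flat = ac.max(axis=1) <= 1e-12
    freqs = np.where(flat, 0.0, freqs)
    return freqs


def pos_similarity(
    pos_registry: Mapping[tuple[str, int], np.ndarray],
    montage: Sequence[str],
) -> np.ndarray:
    """Channel x channel cosine similarity of learned positional embeddings.

    Each sensor is summarized by the mean of its per-slot embedding rows;
    the matrix is symmetric with unit diagonal.
    """
    montage = [str(c).upper() for c in montage]
    vecs = []
    for ch in montage:
        rows = [v for (c, s), v in pos_registry.items() if c == ch and s >= 0]
        if not rows:
            raise InvalidInputError(f"no positional rows registered for channel {ch!r}")
        vecs.append(np.mean(rows, axis=0))
    v = np.asarray(vecs)
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise InvalidInputError("zero-norm positional vector")
    vn = v / norms
    sim = vn @ vn.T
    np.fill_diagonal(sim, 1.0)
    return sim


def _as_layer_matrices(layers, head_agg: str) -> list[np.ndarray]:
    out = []
    for a in layers:
        a = np.asarray(a)
        if a.ndim == 3:  # (heads, M, M)
            if head_agg != "mean":
                raise InvalidInputError(f"unknown head aggregation {head_agg!r}")
            a = a.mean(axis=0)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise InvalidInputError("attention matrices must be square")
        rowsum = a.sum(axis=1)
        if np.any(a < -1e-9) or not np.allclose(rowsum, 1.0, atol=1e-6):
            raise InvalidInputError("attention matrices must be row-stochastic")
        out.append(a)
    return out


def attention_rollout(attn_layers, head_agg: str = "mean") -> RolloutMap:
    """Recursive multiplication of residual-corrected attention matrices.

    Heads are averaged per layer; each layer matrix is corrected for the
    residual path as 0.5 (A + I) with rows renormalized; the rollout is
    the product from the first to the last layer.
    """
    mats = _as_layer_matrices(attn_layers, head_agg)
    if not mats:
        raise InvalidInputError("attention_rollout needs at least one layer")
    m = mats[0].shape[0]
    rollout = np.eye(m)
    for a in mats:
        a_tilde = 0.5 * (a + np.eye(m))
        a_tilde /= a_tilde.sum(axis=1, keepdims=True)
        rollout = a_tilde @ rollout
    return RolloutMap(matrix=rollout)


def render_maps(
    rollout: RolloutMap,
    trial,
    d: int,
    out_path,
) -> str:
    """Write a per-trial (channel x slot) importance heatmap with signal overlay."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    c = trial.n_channels
    n_slots = rollout.matrix.shape[0] - 1
    slots = n_slots // c
    grid = rollout.cls_importance(c, slots)
    window = trial.signal[:, : slots * d]
    fig, axes = plt.subplots(c, 1, figsize=(8, 1.4 * c), sharex=True, squeeze=False)
    vmax = grid.max() if grid.max() > 0 else 1.0
    for ci in range(c):
        ax = axes[ci, 0]
        ax.imshow(
            grid[ci : ci + 1],
            aspect="auto",
            extent=(0, slots * d, window[ci].min(), window[ci].max()),
            cmap="viridis",
            vmin=0.0,
            vmax=vmax,
        )
        ax.plot(np.arange(slots * d), window[ci], color="white", lw=0.6)
        ax.set_ylabel(trial.channel_names[ci], rotation=0, ha="right")
        ax.set_yticks([])
    axes[-1, 0].set_xlabel("sample")
    fig.suptitle(f"patch importance ({trial.label or 'unlabeled'})")
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return str(out_path)
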