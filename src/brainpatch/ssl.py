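"""Masked-patch self-supervised pre-training primitives.

Following the BERT recipe adapted to EEG: time slots (not individual
channel patches) are selected for manipulation with probability
``p_mask`` = 0.3, because a single masked sensor could be interpolated
from its spatial neighbors, making per-patch masking trivial.  A
selected slot's action applies to the patches of ALL channels at that
slot: replace by a learned mask token (80%), replace by a random
embedded patch from the current batch (10%), or keep unchanged (10%).
Keep-action patches still count as manipulated for the reconstruction
loss, which is the cosine distance 1 - cos(x, x_hat) averaged over
manipulated patches only.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .errors import DegeneratePatchError, InvalidParameterError

__all__ = [
    "MaskPlan",
    "plan_mask",
    "corrupt",
    "recon_loss",
    "batch_recon_loss",
    "ACTIONS",
]

ACTIONS = ("mask", "random", "keep")

DEFAULT_P_MASK = 0.3
DEFAULT_RATIOS = (0.8, 0.1, 0.1)


@dataclasses.dataclass(frozen=True)
class MaskPlan:
    """Which time slots are manipulated and how.

    ``actions`` maps selected slot index -> action name; unselected
    slots are absent.  ``p_mask`` records the selection probability the
    plan was drawn with.
    """

    n_time_slots: int
    actions: dict[int, str]
    p_mask: float

    @property
    def selected_slots(self) -> frozenset[int]:
        return frozenset(self.actions)

    def __post_init__(self) -> None:
        for slot, act in self.actions.items():
            if not 0 <= slot < self.n_time_slots:
                raise InvalidParameterError(f"slot {slot} outside [0, {self.n_time_slots})")
            if act not in ACTIONS:
                raise InvalidParameterError(f"unknown action {act!r}")


def plan_mask(
    n_time_slots: int,
    p_mask: float = DEFAULT_P_MASK,
    ratios: tuple[float, float, float] = DEFAULT_RATIOS,
    rng: np.random.Generator | None = None,
) -> MaskPlan:
    """Draw a manipulation plan over time slots.

    Each slot is selected independently with probability ``p_mask``;
    each selected slot receives one action drawn with the given
    (mask, random, keep) ratios.
    """
    if not 0.0 <= p_mask <= 1.0:
        raise InvalidParameterError(f"p_mask must be in [0, 1], got {p_mask}")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise InvalidParameterError(f"action ratios must sum to 1, got {ratios}")
    if rng is None:
        rng = np.random.default_rng()
    selected = np.flatnonzero(rng.random(n_time_slots) < p_mask)
    drawn = rng.choice(len(ACTIONS), size=selected.size, p=list(ratios))
    actions = {int(s): ACTIONS[a] for s, a in zip(selected, drawn)}
    return MaskPlan(n_time_slots=n_time_slots, actions=actions, p_mask=p_mask)


def corrupt(
    embedded_tokens: np.ndarray,
    provenance: Sequence[tuple[str, int]],
    plan: MaskPlan,
    mask_token: np.ndarray,
    rng: np.random.Generator,
    batch_pool: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a mask plan to one trial's embedded patches (cls not included).

    ``embedded_tokens`` is the (N, d_model) matrix of embedded patches
    BEFORE the cls token and positional embeddings are added; the slot
    of token i is provenance[i][1].  ``batch_pool`` is a (P, d_model)
    matrix of embedded patches from the current batch from which
    random-replacement tokens are drawn uniformly.

    Returns (corrupted_tokens, manipulated) where ``manipulated`` is a
    boolean (N,) vector marking every patch whose slot was selected —
    including keep-action patches, which enter the loss unchanged.
    """
    out = embedded_tokens.copy()
    n = out.shape[0]
    manipulated = np.zeros(n, dtype=bool)
    for i in range(n):
        act = plan.actions.get(provenance[i][1])
        if act is None:
            continue
        manipulated[i] = True
        if act == "mask":
            out[i] = mask_token
        elif act == "random":
            out[i] = batch_pool[int(rng.integers(0, batch_pool.shape[0]))]
    return out, manipulated


def recon_loss(x_hat: np.ndarray, x: np.ndarray) -> float:
    """Cosine reconstruction distance 1 - cos(x, x_hat), in [0, 2]."""
    nx, nh = np.linalg.norm(x), np.linalg.norm(x_hat)
    if nx == 0.0 or nh == 0.0:
        raise DegeneratePatchError("cosine loss undefined for a zero-norm patch")
    return float(1.0 - float(x @ x_hat) / (nx * nh))


def batch_recon_loss(
    recons: np.ndarray, originals: np.ndarray, manipulated: np.ndarray
) -> float:
    """Mean cosine distance over manipulated patches only."""
    idx = np.flatnonzero(manipulated)
    if idx.size == 0:
        return 0.0
    return float(
        np.mean([recon_loss(recons[i], originals[i]) for i in idx])
    )


def recon_loss_grad(
    recons: np.ndarray, originals: np.ndarray, manipulated: np.ndarray
) -> tuple[float, np.ndarray]:
    """Loss and its gradient w.r.t. the reconstructions (vectorized).

    d/dx_hat [1 - x.x_hat/(|x||x_hat|)] =
        -x/(|x||x_hat|) + (x.x_hat) x_hat / (|x| |x_hat|^3),
    averaged over the manipulated set.
    """
    idx = np.flatnonzero(manipulated)
    grad = np.zeros_like(recons)
    if idx.size == 0:
        return 0.0, grad
    xh = recons[idx]
    x = originals[idx]
    nx = np.linalg.norm(x, axis=1)
    nh = np.linalg.norm(xh, axis=1)
    if np.any(nx == 0.0) or np.any(nh == 0.0):
        raise DegeneratePatchError("cosine loss undefined for a zero-norm patch")
    dots = np.einsum("ij,ij->i", x, xh)
    cos = dots / (nx * nh)
    loss = float(np.mean(1.0 - cos))
    g = -x / (nx * nh)[:, None] + (dots / (nx * nh**3))[:, None] * xh
    grad[idx] = g / idx.size
    return loss, grad
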