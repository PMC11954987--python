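"""Channel-pure patch tokenization of a (C x T) EEG window.

Each channel is cut into floor(T / D) non-overlapping patches of D
samples; the trailing T mod D samples are discarded.  Tokens are ordered
channel-major (all time slots of channel 1, then channel 2, ...), and
every patch carries its (channel_name, time_slot) provenance so that
positional embeddings can be looked up per sensor and slot.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from ..errors import InvalidInputError

__all__ = ["PatchSequence", "tokenize", "n_patches"]


@dataclasses.dataclass(frozen=True)
class PatchSequence:
    """N channel-pure patches of length D plus per-patch provenance."""

    patches: np.ndarray  # (N, D)
    provenance: tuple[tuple[str, int], ...]  # ((channel_name, time_slot), ...)

    def __post_init__(self) -> None:
        if self.patches.shape[0] != len(self.provenance):
            raise InvalidInputError("provenance length must equal patch count")

    @property
    def n(self) -> int:
        return self.patches.shape[0]


def n_patches(c: int, t: int, d: int) -> int:
    """Token count N = C * floor(T / D)."""
    return c * (t // d)


def tokenize(x: np.ndarray, channel_names: Sequence[str], d: int) -> PatchSequence:
    """Cut a (C, T) window into a channel-major PatchSequence."""
    x = np.asarray(x)
    c, t = x.shape
    if t < d:
        raise InvalidInputError(
            f"window length {t} is shorter than the patch length {d}"
        )
    if len(channel_names) != c:
        raise InvalidInputError(
            f"{len(channel_names)} channel names for {c} signal rows"
        )
    slots = t // d
    # (C, slots, D) view, then channel-major flatten
    patches = x[:, : slots * d].reshape(c, slots, d).reshape(c * slots, d)
    prov = tuple(
        (str(ch).upper(), s) for ch in channel_names for s in range(slots)
    )
    return PatchSequence(patches=np.ascontiguousarray(patches), provenance=prov)
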