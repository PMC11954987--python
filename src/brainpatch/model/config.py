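"""Model hyperparameters."""

from __future__ import annotations

import dataclasses

from ..errors import InvalidParameterError


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters of the patch Transformer.

    ``patch_len`` (D) is the number of raw samples per channel-pure
    patch; the model width is tied to it as d_model = 2 D.  Defaults
    reproduce the reference configuration: D=64, d_model=128, 4 pre-LN
    encoder blocks with 4 heads and a 512-wide feed-forward, dropout 0.1.
    """

    patch_len: int = 64
    n_blocks: int = 4
    n_heads: int = 4
    ffn_hidden: int = 512
    p_drop: float = 0.1
    n_classes: int = 2
    d_model: int | None = None

    def __post_init__(self) -> None:
        if self.patch_len < 1:
            raise InvalidParameterError("patch_len must be >= 1")
        if self.d_model is None:
            object.__setattr__(self, "d_model", 2 * self.patch_len)
        if self.d_model % self.n_heads != 0:
            raise InvalidParameterError(
                f"d_model={self.d_model} not divisible by n_heads={self.n_heads}"
            )
        if self.n_classes < 2:
            raise InvalidParameterError("n_classes must be >= 2")
        if not 0.0 <= self.p_drop < 1.0:
            raise InvalidParameterError("p_drop must be in [0, 1)")

    @property
    def head_dim(self) -> int:
        return self.d_model // self.n_heads
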