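"""Per-trial EEG data augmentation and pre-training channel subsampling.

Four operators, each applied per trial after session z-scoring (so the
sigmas are in z-scored units): additive Gaussian noise, a constant DC
shift, multiplicative amplitude scaling, and a random time-shifted crop.
DC shifts and amplitude scales draw ONE scalar per trial applied to all
channels, so relative channel amplitudes — which carry the class signal —
are preserved.

During multi-dataset pre-training, channels are additionally subsampled
per trial (independent Bernoulli keep per channel, floor of one channel),
which both augments and teaches channel-count flexibility.
"""

from __future__ import annotations

import dataclasses
import zlib

import numpy as np

from .data_io import Trial
from .errors import InvalidParameterError

__all__ = [
    "AugmentConfig",
    "ChannelSubsamplePolicy",
    "add_gaussian_noise",
    "dc_shift",
    "amplitude_scale",
    "time_shift_crop",
    "center_crop",
    "subsample_channels",
    "substream",
]

#: operator names accepted by training regimes
AUGMENT_OPS = ("noise", "dc", "scale", "shift")


@dataclasses.dataclass(frozen=True)
class ChannelSubsamplePolicy:
    """Independent Bernoulli channel keep with a floor of ``min_channels``."""

    keep_prob: float = 1.0
    min_channels: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.keep_prob <= 1.0:
            raise InvalidParameterError(
                f"keep_prob must be in (0, 1], got {self.keep_prob}"
            )
        if self.min_channels < 1:
            raise InvalidParameterError("min_channels must be >= 1")


@dataclasses.dataclass(frozen=True)
class AugmentConfig:
    """Augmentation hyperparameters; sigmas are in z-scored signal units.

    ``ops`` names the operators active during training: any subset of
    ``("noise", "dc", "scale", "shift")``.  When "shift" is absent the
    training crop is the deterministic centered window, the same one
    always used at evaluation time.
    """

    noise_sigma: float = 0.1
    dc_sigma: float = 0.1
    scale_mu: float = 1.0
    scale_sigma: float = 0.1
    crop_window: int = 512
    ops: tuple[str, ...] = ("shift",)
    channel_subsample: ChannelSubsamplePolicy | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_sigma", "dc_sigma", "scale_sigma"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.crop_window <= 0:
            raise InvalidParameterError("crop_window must be positive")
        unknown = set(self.ops) - set(AUGMENT_OPS)
        if unknown:
            raise InvalidParameterError(f"unknown augmentation ops {sorted(unknown)}")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from one master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(name.encode()),))
    )


def add_gaussian_noise(x: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Element-wise independent N(0, sigma^2) noise."""
    if sigma < 0:
        raise InvalidParameterError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return x
    return x + sigma * rng.standard_normal(x.shape)


def dc_shift(x: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Add one N(0, sigma^2) scalar to every entry of the trial."""
    if sigma < 0:
        raise InvalidParameterError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return x
    return x + sigma * rng.standard_normal()


def amplitude_scale(
    x: np.ndarray, mu: float, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Multiply the trial by one N(mu, sigma^2) scalar."""
    if sigma < 0:
        raise InvalidParameterError(f"sigma must be >= 0, got {sigma}")
    a = mu if sigma == 0 else mu + sigma * rng.standard_normal()
    return a * x

def time_shift_crop(x: np.ndarray, window: int, rng: np.random.Generator) -> np.ndarray:
    """Crop a contiguous window at a uniformly random onset (a fresh draw per call)."""
    t = x.shape[-1]
    if window > t:
        raise InvalidParameterError(f"crop window {window} exceeds trial length {t}")
    start = int(rng.integers(0, t - window + 1))
    return x[..., start : start + window]


def center_crop(x: np.ndarray, window: int) -> np.ndarray:
    """Deterministic evaluation crop: the window centered in the trial."""
    t = x.shape[-1]
    if window > t:
        raise InvalidParameterError(f"crop window {window} exceeds trial length {t}")
    start = (t - window) // 2
    return x[..., start : start + window]


def subsample_channels(
    trial: Trial, rng: np.random.Generator, policy: ChannelSubsamplePolicy | None
) -> Trial:
    """Randomly drop channels (order preserved); identity for keep-all policy."""
    if policy is None or policy.keep_prob >= 1.0:
        return trial
    c = trial.n_channels
    keep = rng.random(c) < policy.keep_prob
    floor = min(policy.min_channels, c)
    if keep.sum() < floor:
        # force a random subset of size `floor` to stay
        forced = rng.choice(c, size=floor, replace=False)
        keep[forced] = True
    idx = np.flatnonzero(keep)
    return trial.replace(
        signal=trial.signal[idx],
        channel_names=tuple(trial.channel_names[i] for i in idx),
    )


def apply_ops(
    x: np.ndarray, cfg: AugmentConfig, rngs: dict[str, np.random.Generator], train: bool
) -> np.ndarray:
    """Apply the configured per-trial operators to one (C, T) signal.

    Cropping happens first (random onset in training when "shift" is
    active, centered otherwise); the value-perturbing operators follow.
    """
    if train and "shift" in cfg.ops:
        x = time_shift_crop(x, cfg.crop_window, rngs["shift"])
    else:
        x = center_crop(x, cfg.crop_window)
    if train:
        if "noise" in cfg.ops:
            x = add_gaussian_noise(x, cfg.noise_sigma, rngs["noise"])
        if "dc" in cfg.ops:
            x = dc_shift(x, cfg.dc_sigma, rngs["dc"])
        if "scale" in cfg.ops:
            x = amplitude_scale(x, cfg.scale_mu, cfg.scale_sigma, rngs["scale"])
    return x
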