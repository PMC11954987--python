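"""EEG trial containers, preprocessing, and the HDF5 session format.

A *trial* is one (channels x time) EEG segment with montage metadata.
Preprocessing follows standard motor-imagery practice: an 8-45 Hz
band-pass, optional resampling to a common rate (250 Hz for multi-dataset
training), and channel-wise z-scoring with statistics pooled over all
trials of one recording session.  Training and evaluation sessions are
normalized separately by the caller.

On disk, one HDF5 file holds one session: file-level attributes ``fs``
and ``channel_names``; one group ``/trials/<i>`` per trial with a
``signal`` dataset (C x T, float32) and attributes ``label``,
``subject_id``, ``session_id``, ``dataset_id``.
"""

from __future__ import annotations

import dataclasses
from fractions import Fraction
from typing import Sequence

import h5py
import numpy as np
from scipy import signal as sps

from .errors import DegenerateChannelError, InvalidParameterError, SessionFormatError

__all__ = [
    "Trial",
    "SessionStats",
    "bandpass_filter",
    "resample_trial",
    "session_zscore",
    "read_session",
    "write_session",
    "read_edf",
    "by_session",
]


@dataclasses.dataclass(frozen=True)
class Trial:
    """One EEG recording segment.

    Channel names are normalized to upper-case 10-20 labels on
    construction so that e.g. ``"Cz"`` and ``"CZ"`` refer to the same
    sensor throughout the package.
    """

    signal: np.ndarray  # (C, T)
    channel_names: tuple[str, ...]
    fs: float
    label: str | None = None
    subject_id: str = "S0"
    session_id: str = "sess0"
    dataset_id: str = "default"

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal)
        if sig.ndim != 2 or sig.shape[0] < 1 or sig.shape[1] < 1:
            raise SessionFormatError(
                f"signal must be a (C, T) matrix with C, T >= 1; got shape {sig.shape}"
            )
        names = tuple(str(n).upper() for n in self.channel_names)
        if len(names) != sig.shape[0]:
            raise SessionFormatError(
                f"{len(names)} channel names for {sig.shape[0]} signal rows"
            )
        if len(set(names)) != len(names):
            raise SessionFormatError(f"duplicate channel names in {names}")
        if not self.fs > 0:
            raise SessionFormatError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "signal", sig)
        object.__setattr__(self, "channel_names", names)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def replace(self, **kw) -> "Trial":
        return dataclasses.replace(self, **kw)


@dataclasses.dataclass(frozen=True)
class SessionStats:
    """Per-channel mean and population standard deviation of one session."""

    channel_names: tuple[str, ...]
    mean: np.ndarray  # (C,)
    std: np.ndarray  # (C,)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"channel": self.channel_names, "mean": self.mean, "std": self.std}
        ).to_csv(path, index=False)


def bandpass_filter(trial: Trial, low_hz: float = 8.0, high_hz: float = 45.0) -> Trial:
    """Zero-phase 4th-order Butterworth band-pass, applied per channel.

    The forward-backward (``sosfiltfilt``) application doubles the
    effective order and removes phase distortion, which matters for
    patch-level waveform interpretation.
    """
    nyq = trial.fs / 2.0
    if not 0 < low_hz:
        raise InvalidParameterError(f"low_hz must be positive, got {low_hz}")
    if not low_hz < high_hz:
        raise InvalidParameterError(
            f"high_hz must exceed low_hz, got high_hz={high_hz} <= low_hz={low_hz}"
        )
    if not high_hz < nyq:
        raise InvalidParameterError(
            f"high_hz must be below the Nyquist rate {nyq} Hz, got {high_hz}"
        )
    sos = sps.butter(4, [low_hz, high_hz], btype="bandpass", fs=trial.fs, output="sos")
    out = sps.sosfiltfilt(sos, trial.signal, axis=1)
    return trial.replace(signal=np.ascontiguousarray(out))


def bandpass_response_db(fs: float, freq_hz: float, low_hz: float = 8.0,
                         high_hz: float = 45.0) -> float:
    """Magnitude response (dB) of the zero-phase band-pass at one frequency."""
    sos = sps.butter(4, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=[freq_hz], fs=fs)
    # forward-backward application squares the magnitude response
    return 40.0 * np.log10(np.abs(h[0]) + 1e-300)


def resample_trial(trial: Trial, target_fs: float) -> Trial:
    """Polyphase resampling to ``target_fs``; T_out = round(T * target_fs / fs)."""
    if not target_fs > 0:
        raise InvalidParameterError(f"target_fs must be positive, got {target_fs}")
    if target_fs == trial.fs:
        return trial
    ratio = Fraction(target_fs).limit_denominator(10**6) / Fraction(
        trial.fs
    ).limit_denominator(10**6)
    out = sps.resample_poly(trial.signal, ratio.numerator, ratio.denominator, axis=1)
    t_out = int(round(trial.n_samples * target_fs / trial.fs))
    if out.shape[1] > t_out:
        out = out[:, :t_out]
    elif out.shape[1] < t_out:
        pad = np.repeat(out[:, -1:], t_out - out.shape[1], axis=1)
        out = np.concatenate([out, pad], axis=1)
    return trial.replace(signal=np.ascontiguousarray(out), fs=float(target_fs))


def session_zscore(trials: Sequence[Trial]) -> tuple[list[Trial], SessionStats]:
    """Channel-wise z-score with statistics pooled over the whole session.

    All trials must belong to one session and share the montage and
    sampling rate.  Uses the population (ddof=0) standard deviation: this
    is a normalization, not an estimate of a noise parameter.
    """
    if not trials:
        raise InvalidParameterError("session_zscore requires at least one trial")
    first = trials[0]
    for t in trials[1:]:
        if t.session_id != first.session_id:
            raise SessionFormatError(
                f"mixed sessions {first.session_id!r} and {t.session_id!r}"
            )
        if t.channel_names != first.channel_names:
            raise SessionFormatError("inconsistent channel_names within session")
        if t.fs != first.fs:
            raise SessionFormatError("inconsistent sampling rate within session")
    pooled = np.concatenate([t.signal for t in trials], axis=1)
    mean = pooled.mean(axis=1)
    std = pooled.std(axis=1, ddof=0)
    for c, s in zip(first.channel_names, std):
        if s == 0.0:
            raise DegenerateChannelError(
                f"channel {c!r} has zero variance over the session"
            )
    out = [
        t.replace(signal=(t.signal - mean[:, None]) / std[:, None]) for t in trials
    ]
    return out, SessionStats(first.channel_names, mean, std)


def write_session(trials: Sequence[Trial], path) -> None:
    """Write one session of trials to an HDF5 file (layout in module docstring)."""
    if not trials:
        raise InvalidParameterError("cannot write an empty session")
    first = trials[0]
    for t in trials:
        if t.channel_names != first.channel_names:
            raise SessionFormatError(
                "inconsistent channel_names across trials in one session file"
            )
        if t.fs != first.fs:
            raise SessionFormatError("inconsistent fs across trials in one session file")
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = float(first.fs)
        f.attrs["channel_names"] = list(first.channel_names)
        grp = f.create_group("trials")
        for i, t in enumerate(trials):
            g = grp.create_group(str(i))
            g.create_dataset("signal", data=t.signal.astype(np.float32))
            g.attrs["label"] = "" if t.label is None else str(t.label)
            g.attrs["subject_id"] = t.subject_id
            g.attrs["session_id"] = t.session_id
            g.attrs["dataset_id"] = t.dataset_id


def read_session(path) -> list[Trial]:
    """Read a session file written by :func:`write_session`."""
    trials: list[Trial] = []
    with h5py.File(path, "r") as f:
        if "fs" not in f.attrs:
            raise SessionFormatError(f"{path}: missing required file attribute 'fs'")
        if "channel_names" not in f.attrs:
            raise SessionFormatError(
                f"{path}: missing required file attribute 'channel_names'"
            )
        fs = float(f.attrs["fs"])
        names = tuple(str(n) for n in f.attrs["channel_names"])
        if "trials" not in f:
            raise SessionFormatError(f"{path}: missing group '/trials'")
        grp = f["trials"]
        for key in sorted(grp.keys(), key=int):
            g = grp[key]
            if "signal" not in g:
                raise SessionFormatError(
                    f"{path}: group '/trials/{key}' missing dataset 'signal'"
                )
            label = str(g.attrs.get("label", ""))
            trials.append(
                Trial(
                    signal=np.asarray(g["signal"], dtype=np.float32),
                    channel_names=names,
                    fs=fs,
                    label=label or None,
                    subject_id=str(g.attrs.get("subject_id", "S0")),
                    session_id=str(g.attrs.get("session_id", "sess0")),
                    dataset_id=str(g.attrs.get("dataset_id", "default")),
                )
            )
    return trials


def read_edf(path, dataset_id: str = "edf", label: str | None = None) -> Trial:
    """Optional EDF import adapter (requires ``mne``); returns one Trial."""
    import mne  # deferred: optional dependency

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Trial(
        signal=raw.get_data(),
        channel_names=tuple(raw.ch_names),
        fs=float(raw.info["sfreq"]),
        label=label,
        dataset_id=dataset_id,
    )


def by_session(trials: Sequence[Trial]) -> dict[str, list[Trial]]:
    """Group a flat trial list by session_id, preserving order."""
    out: dict[str, list[Trial]] = {}
    for t in trials:
        out.setdefault(t.session_id, []).append(t)
    return out
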