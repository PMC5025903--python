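"""EMG envelope preprocessing for gait-cycle synergy analysis.

Raw multi-channel surface EMG is turned into amplitude- and time-normalized
per-stride envelopes: band-pass filtering (3rd-order Butterworth, 40-400 Hz),
rectification, low-pass filtering (3rd-order Butterworth, 5 Hz), segmentation
at ipsilateral initial contacts, linear time normalization to 100 points per
stride, and amplitude normalization by the per-muscle median of per-stride
maxima. All filtering is zero-phase (forward-backward) so envelope peaks stay
aligned with the gait events the downstream timing metrics depend on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import (
    DegenerateChannelError,
    InsufficientEventsError,
    InsufficientStridesError,
    InvalidParameterError,
    OutOfRangeEventError,
    TooShortError,
)

N_CYCLE_POINTS = 100

__all__ = [
    "RawEmgRecording",
    "EnvelopeRecording",
    "EnvelopeStrideSet",
    "compute_envelope",
    "segment_strides",
    "time_normalize",
    "amplitude_normalize",
    "select_representative_strides",
    "preprocess_recording",
    "N_CYCLE_POINTS",
]


@dataclass
class RawEmgRecording:
    """Multi-channel raw EMG: ``data`` is muscles x samples."""

    muscle_names: list[str]
    sample_rate: float
    data: np.ndarray
    side: str = "dominant"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.sample_rate <= 0:
            raise InvalidParameterError("sample_rate must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.muscle_names):
            raise InvalidParameterError(
                f"data must be (n_muscles={len(self.muscle_names)}) x samples, "
                f"got shape {self.data.shape}"
            )
        if len(set(self.muscle_names)) != len(self.muscle_names):
            raise InvalidParameterError("muscle_names must be unique")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class EnvelopeRecording:
    """Nonnegative EMG envelopes, muscles x samples."""

    muscle_names: list[str]
    sample_rate: float
    data: np.ndarray
    side: str = "dominant"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if np.any(self.data < 0):
            raise InvalidParameterError("envelope data must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EnvelopeStrideSet:
    """Time- and amplitude-normalized stride envelopes.

    ``strides`` is n_strides x n_muscles x 100; ``normalization_constants``
    holds the per-muscle divisor (median over strides of the per-stride
    maximum) so the normalization can be inverted.
    """

    muscle_names: list[str]
    strides: np.ndarray
    normalization_constants: np.ndarray = field(default=None)  # type: ignore[assignment]
    side: str = "dominant"

    def __post_init__(self) -> None:
        self.strides = np.asarray(self.strides, dtype=float)
        if self.strides.ndim != 3 or self.strides.shape[2] != N_CYCLE_POINTS:
            raise InvalidParameterError(
                f"strides must be n_strides x n_muscles x {N_CYCLE_POINTS}, "
                f"got {self.strides.shape}"
            )
        if np.any(self.strides < 0):
            raise InvalidParameterError("stride envelopes must be nonnegative")
        if self.normalization_constants is None:
            self.normalization_constants = np.ones(self.strides.shape[1])
        self.normalization_constants = np.asarray(self.normalization_constants, dtype=float)

    @property
    def n_strides(self) -> int:
        return self.strides.shape[0]

    @property
    def n_muscles(self) -> int:
        return self.strides.shape[1]

    def concatenated(self) -> np.ndarray:
        """Muscles x (100 * n_strides) matrix with strides laid out in time order."""
        return np.concatenate(list(self.strides), axis=1)

    def mean_envelope(self) -> np.ndarray:
        """Across-stride mean envelope, muscles x 100."""
        return self.strides.mean(axis=0)


def _butter_sos(order: int, cut, fs: float, btype: str):
    nyq = fs / 2.0
    cuts = np.atleast_1d(cut).astype(float)
    if np.any(cuts <= 0) or np.any(cuts >= nyq):
        raise InvalidParameterError(
            f"cutoff frequencies {cuts} must lie strictly inside (0, {nyq}) Hz"
        )
    return signal.butter(order, cuts if len(cuts) > 1 else cuts[0], btype=btype, fs=fs, output="sos")


def compute_envelope(
    raw: RawEmgRecording,
    band_lo: float = 40.0,
    band_hi: float = 400.0,
    env_cut: float = 5.0,
    order: int = 3,
) -> EnvelopeRecording:
    """Band-pass filter, rectify and low-pass filter raw EMG into envelopes.

    Both filters are Butterworth of the given order, applied forward-backward
    (zero phase). Output is clipped at zero: sosfiltfilt of a rectified signal
    can undershoot by a few machine epsilons around sharp transients.
    """
    if not band_lo < band_hi:
        raise InvalidParameterError("band_lo must be below band_hi")
    fs = raw.sample_rate
    sos_band = _butter_sos(order, [band_lo, band_hi], fs, "bandpass")
    sos_env = _butter_sos(order, env_cut, fs, "lowpass")
    min_len = 3 * (order + 1)
    if raw.n_samples <= min_len:
        raise TooShortError(
            f"recording of {raw.n_samples} samples is shorter than the "
            f"filter warm-up of {min_len} samples"
        )
    banded = signal.sosfiltfilt(sos_band, raw.data, axis=1)
    rect = np.abs(banded)
    env = signal.sosfiltfilt(sos_env, rect, axis=1)
    env = np.clip(env, 0.0, None)
    return EnvelopeRecording(list(raw.muscle_names), fs, env, side=raw.side)


def segment_strides(env: EnvelopeRecording, ic_times: np.ndarray) -> list[np.ndarray]:
    """Cut envelopes at ipsilateral initial contacts: k ICs give k-1 strides.

    Stride *i* spans the half-open window ``[IC_i, IC_{i+1})`` in samples, so
    consecutive strides partition the recording between the first and last IC.
    """
    ic_times = np.asarray(ic_times, dtype=float)
    if ic_times.size < 2:
        raise InsufficientEventsError(
            f"need at least 2 initial contacts, got {ic_times.size}"
        )
    if np.any(np.diff(ic_times) <= 0):
        raise InvalidParameterError("ic_times must be strictly increasing")
    idx = np.round(ic_times * env.sample_rate).astype(int)
    if idx[0] < 0 or idx[-1] > env.n_samples:
        raise OutOfRangeEventError(
            f"events span samples [{idx[0]}, {idx[-1]}] outside recording "
            f"of {env.n_samples} samples"
        )
    return [env.data[:, a:b] for a, b in zip(idx[:-1], idx[1:])]


def time_normalize(stride: np.ndarray, n_points: int = N_CYCLE_POINTS) -> np.ndarray:
    """Linearly resample one stride (muscles x samples) onto ``n_points`` columns.

    The uniform output grid spans the stride exactly, so first and last samples
    are preserved; linear interpolation keeps nonnegative envelopes nonnegative
    and monotone segments monotone.
    """
    stride = np.asarray(stride, dtype=float)
    n = stride.shape[1]
    if n < 2:
        raise TooShortError(f"stride of {n} sample(s) cannot be time-normalized")
    x_old = np.arange(n, dtype=float)
    x_new = np.linspace(0.0, n - 1.0, n_points)
    return np.vstack([np.interp(x_new, x_old, row) for row in stride])


def amplitude_normalize(
    strides: np.ndarray | list[np.ndarray],
    muscle_names: list[str],
    side: str = "dominant",
    eps: float = 1e-12,
) -> EnvelopeStrideSet:
    """Divide each muscle by the median (over strides) of its per-stride maximum.

    With an even stride count the median is the mean of the two middle values
    (numpy convention). A muscle whose median maximum is at or below ``eps``
    is a flat channel and raises, naming the muscle.
    """
    arr = np.stack([np.asarray(s, dtype=float) for s in strides])
    maxima = arr.max(axis=2)  # n_strides x n_muscles
    divisors = np.median(maxima, axis=0)
    for name, d in zip(muscle_names, divisors):
        if d <= eps:
            raise DegenerateChannelError(
                f"muscle '{name}' has median per-stride maximum {d:.3g}; "
                "flat channels cannot be amplitude-normalized"
            )
    normed = arr / divisors[None, :, None]
    return EnvelopeStrideSet(list(muscle_names), normed, divisors, side=side)


def select_representative_strides(
    strideset: EnvelopeStrideSet,
    n_keep: int = 20,
    n_trim_start: int = 3,
    n_trim_end: int = 3,
) -> EnvelopeStrideSet:
    """Drop acceleration/deceleration strides, then keep ``n_keep`` consecutive
    strides centered in what remains."""
    n = strideset.n_strides
    remaining = n - n_trim_start - n_trim_end
    if remaining < n_keep:
        raise InsufficientStridesError(
            f"{n} strides minus trim {n_trim_start}+{n_trim_end} leaves "
            f"{remaining}, fewer than the {n_keep} requested"
        )
    start = n_trim_start + (remaining - n_keep) // 2
    return EnvelopeStrideSet(
        strideset.muscle_names,
        strideset.strides[start : start + n_keep],
        strideset.normalization_constants,
        side=strideset.side,
    )


def preprocess_recording(
    raw: RawEmgRecording,
    ic_times: np.ndarray,
    n_keep: int | None = 20,
    n_trim_start: int = 3,
    n_trim_end: int = 3,
    band_lo: float = 40.0,
    band_hi: float = 400.0,
    env_cut: float = 5.0,
    order: int = 3,
) -> EnvelopeStrideSet:
    """Full envelope chain: filter, rectify, segment, time- and amplitude-normalize.

    ``n_keep=None`` skips representative-stride selection and keeps every stride.
    """
    env = compute_envelope(raw, band_lo=band_lo, band_hi=band_hi, env_cut=env_cut, order=order)
    segments = segment_strides(env, ic_times)
    normalized = [time_normalize(s) for s in segments]
    strideset = amplitude_normalize(normalized, raw.muscle_names, side=raw.side)
    if n_keep is not None:
        strideset = select_representative_strides(strideset, n_keep, n_trim_start, n_trim_end)
    return strideset
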