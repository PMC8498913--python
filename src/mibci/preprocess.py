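"""Signal conditioning: decimation, Butterworth filtering, windowing, rescaling.

The chain mirrors what a streaming motor-imagery system does: decimate
500→250 Hz, apply a causal third-order Butterworth band-pass (4–33 Hz),
rescale the whole recording linearly so its global extrema map to [−1, 1],
then cut overlapped fixed-length windows from each annotated class segment,
discarding the first seconds after every class transition. Filters default to
forward-only (causal) so that offline cross-validation estimates the online
system; a zero-phase option exists for exploratory analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from mibci.simulate import CLASSES, Recording


class DegenerateInputError(ValueError):
    """Input has no usable dynamic range (e.g. constant signal)."""


@dataclass(frozen=True)
class WindowSpec:
    """Fixed-length analysis window with fractional overlap."""

    length_s: float = 4.0
    overlap_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.length_s <= 0:
            raise ValueError(f"length_s must be > 0, got {self.length_s}")
        if not 0.0 <= self.overlap_frac < 1.0:
            raise ValueError(
                f"overlap_frac must lie in [0, 1), got {self.overlap_frac}"
            )

    def length_samples(self, fs: float) -> int:
        return int(round(self.length_s * fs))

    def stride_samples(self, fs: float) -> int:
        stride = int(round(self.length_samples(fs) * (1.0 - self.overlap_frac)))
        return max(stride, 1)


@dataclass
class EpochSet:
    """Labeled fixed-length windows cut from one or more recordings.

    ``windows`` is (n, channels, samples); ``provenance`` records
    (subject_id, trial_id, start_s) per window.
    """

    windows: np.ndarray
    labels: np.ndarray  # class_id strings, one per window
    window_spec: WindowSpec
    fs: float
    provenance: list[tuple[int, int, float]] = field(default_factory=list)
    channel_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.windows.ndim != 3:
            raise ValueError(f"windows must be 3-D, got shape {self.windows.shape}")
        if len(self.labels) != len(self.windows):
            raise ValueError("labels and windows length mismatch")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def classes(self) -> tuple[str, ...]:
        present = set(self.labels.tolist())
        return tuple(c for c in CLASSES if c in present) + tuple(
            sorted(present - set(CLASSES))
        )

    def subset(self, mask: np.ndarray) -> "EpochSet":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return EpochSet(
            self.windows[idx],
            self.labels[idx],
            self.window_spec,
            self.fs,
            [self.provenance[i] for i in idx] if self.provenance else [],
            self.channel_labels,
        )

    @staticmethod
    def concatenate(parts: list["EpochSet"]) -> "EpochSet":
        if not parts:
            raise ValueError("nothing to concatenate")
        first = parts[0]
        for p in parts[1:]:
            if p.fs != first.fs or p.window_spec != first.window_spec:
                raise ValueError("incompatible EpochSets")
        return EpochSet(
            np.concatenate([p.windows for p in parts]),
            np.concatenate([p.labels for p in parts]),
            first.window_spec,
            first.fs,
            sum((p.provenance for p in parts), []),
            first.channel_labels,
        )


def resample_to(rec: Recording, target_fs: float) -> Recording:
    """Integer-factor decimation with a zero-phase anti-alias low-pass.

    Only integer ratios are supported (the pipeline's single conversion is
    500→250 Hz). The anti-alias filter is an order-8 Butterworth low-pass at
    0.34 × target_fs applied forward-backward, then every ``q``-th sample is
    kept. Annotations are in seconds and carry over unchanged.
    """
    ratio = rec.fs / target_fs
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError(
            f"target_fs={target_fs} must integer-divide fs={rec.fs}"
        )
    if q == 1:
        return rec.copy_with(rec.data.copy())
    sos = signal.butter(8, 0.34 * target_fs, btype="low", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(filtered[:, ::q], fs=target_fs)


def _butter_apply(
    rec: Recording, sos: np.ndarray, causal: bool
) -> Recording:
    if causal:
        out = signal.sosfilt(sos, rec.data, axis=1)
    else:
        out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(np.asarray(out))


def bandpass(
    rec: Recording,
    low: float = 4.0,
    high: float = 33.0,
    order: int = 3,
    causal: bool = True,
) -> Recording:
    """Butterworth band-pass per channel (default: third order, 4–33 Hz).

    ``causal=True`` (default) runs the filter forward only, as a streaming
    system must; ``causal=False`` uses zero-phase forward-backward filtering.
    """
    if not 0 < low < high < rec.fs / 2:
        raise ValueError(
            f"need 0 < low < high < fs/2, got ({low}, {high}) at fs={rec.fs}"
        )
    sos = signal.butter(order, (low, high), btype="bandpass", fs=rec.fs, output="sos")
    return _butter_apply(rec, sos, causal)


def highpass(
    rec: Recording, cutoff: float = 4.0, order: int = 3, causal: bool = True
) -> Recording:
    """Butterworth high-pass per channel (default: third order, 4 Hz)."""
    if not 0 < cutoff < rec.fs / 2:
        raise ValueError(f"cutoff must lie in (0, fs/2), got {cutoff}")
    sos = signal.butter(order, cutoff, btype="highpass", fs=rec.fs, output="sos")
    return _butter_apply(rec, sos, causal)


def butter_gain(
    fs: float,
    freq_hz: float,
    low: float | None = None,
    high: float | None = None,
    order: int = 3,
) -> float:
    """Analytic |H(f)| of the package's Butterworth designs (test oracle)."""
    if low is not None and high is not None:
        sos = signal.butter(order, (low, high), btype="bandpass", fs=fs, output="sos")
    elif low is not None:
        sos = signal.butter(order, low, btype="highpass", fs=fs, output="sos")
    else:
        sos = signal.butter(order, high, btype="lowpass", fs=fs, output="sos")
    _, h = signal.sosfreqz(sos, worN=[freq_hz], fs=fs)
    return float(np.abs(h[0]))


def segment_window_count(
    usable_s: float, spec: WindowSpec, fs: float
) -> int:
    """Closed-form window count: floor((usable − length)/stride) + 1."""
    length = spec.length_samples(fs)
    stride = spec.stride_samples(fs)
    usable = int(round(usable_s * fs))
    if usable < length:
        return 0
    return (usable - length) // stride + 1


def segment(
    rec: Recording, spec: WindowSpec, discard_s: float = 2.0
) -> EpochSet:
    """Cut overlapped windows from every annotated class segment.

    The first ``discard_s`` seconds of each segment are dropped (reaction
    time to the new cue). Windows start at the usable-segment start, advance
    by ``length × (1 − overlap)`` and never cross a segment boundary. Window
    start times are quantized to whole samples.
    """
    if not rec.annotations:
        raise ValueError("recording has no class annotations")
    length = spec.length_samples(rec.fs)
    stride = spec.stride_samples(rec.fs)
    windows, labels, provenance = [], [], []
    for start_s, end_s, cls in rec.annotations:
        i0 = int(round((start_s + discard_s) * rec.fs))
        i1 = min(int(round(end_s * rec.fs)), rec.n_samples)
        if i1 - i0 < length:
            warnings.warn(
                f"segment ({start_s:.1f}-{end_s:.1f}s, {cls}) shorter than one "
                f"{spec.length_s} s window after {discard_s} s discard; skipped",
                stacklevel=2,
            )
            continue
        for w0 in range(i0, i1 - length + 1, stride):
            windows.append(rec.data[:, w0 : w0 + length])
            labels.append(cls)
            provenance.append((rec.subject_id, rec.trial_id, w0 / rec.fs))
    if windows:
        arr = np.stack(windows)
    else:
        arr = np.empty((0, rec.n_channels, length))
    return EpochSet(
        arr,
        np.asarray(labels, dtype=object),
        spec,
        rec.fs,
        provenance,
        rec.montage.channel_labels,
    )


def rescale_bounds(x: Recording | EpochSet) -> tuple[float, float]:
    data = x.data if isinstance(x, Recording) else x.windows
    return float(np.min(data)), float(np.max(data))


def apply_rescale(
    x: Recording | EpochSet | np.ndarray, vmin: float, vmax: float
):
    """Affine map sending ``vmin → −1`` and ``vmax → +1``."""
    if vmax <= vmin:
        raise DegenerateInputError("max must exceed min for rescaling")

    def f(a: np.ndarray) -> np.ndarray:
        return 2.0 * (a - vmin) / (vmax - vmin) - 1.0

    if isinstance(x, Recording):
        return x.copy_with(f(x.data))
    if isinstance(x, EpochSet):
        return EpochSet(
            f(x.windows),
            x.labels.copy(),
            x.window_spec,
            x.fs,
            list(x.provenance),
            x.channel_labels,
        )
    return f(np.asarray(x))


def rescale(x: Recording | EpochSet):
    """Linear rescale of the whole object (all channels jointly) to [−1, 1].

    Applied per continuous recording before windowing, so inter-channel
    amplitude ratios survive — the spatial classifier exploits them.
    Idempotent: output extrema are exactly ±1, so a second pass is identity.
    """
    vmin, vmax = rescale_bounds(x)
    if vmax <= vmin:
        raise DegenerateInputError(
            "constant input cannot be rescaled to [-1, 1]"
        )
    return apply_rescale(x, vmin, vmax)
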