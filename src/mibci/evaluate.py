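"""Cross-validation, confusion matrices, Wolpaw ITR and alpha-rhythm SNR.

The information transfer rate follows Wolpaw's definition for an N-target
selection task with accuracy A and w seconds per command:

    ITR = [log2 N + A log2 A + (1 − A) log2((1 − A)/(N − 1))] × 60 / w

in bits per minute, with the 0·log0 limits at A ∈ {0, 1}.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from mibci import classify as _classify
from mibci.features import psda_features, welch_psd
from mibci.preprocess import (
    EpochSet,
    WindowSpec,
    bandpass,
    rescale,
    resample_to,
    segment,
)
from mibci.simulate import CLASSES, Recording


@dataclass
class ConfusionMatrix:
    """K×K count matrix, rows = true class, columns = predicted."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be ({k}, {k}), got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ValueError("class orders differ")
        return ConfusionMatrix(self.counts + other.counts, self.classes)


def confusion(
    y_true: np.ndarray, y_pred: np.ndarray, class_order: tuple[str, ...] = CLASSES
) -> ConfusionMatrix:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    index = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"label outside class order: {t!r}/{p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, tuple(class_order))


@dataclass
class CVResult:
    """Per-fold and pooled evaluation of a leave-one-recording-out CV."""

    folds: list[ConfusionMatrix]
    classes: tuple[str, ...]
    histories: list[list[float]] = field(default_factory=list)

    @property
    def pooled(self) -> ConfusionMatrix:
        out = self.folds[0]
        for f in self.folds[1:]:
            out = out + f
        return out

    @property
    def fold_accuracies(self) -> list[float]:
        return [f.accuracy for f in self.folds]

    @property
    def pooled_accuracy(self) -> float:
        return self.pooled.accuracy

    @property
    def mean_sem(self) -> tuple[float, float]:
        return summarize(self.fold_accuracies)


def summarize(values) -> tuple[float, float]:
    """Mean ± SEM (sample SD / √n); needs at least two values."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values for mean ± SEM")
    return float(v.mean()), float(v.std(ddof=1) / math.sqrt(v.size))


def itr(n_targets: int, accuracy: float, seconds_per_command: float) -> float:
    """Wolpaw information transfer rate in bits per minute.

    ``seconds_per_command`` is the combined time per selection including
    latencies. The raw formula value is returned — no clipping at zero.
    """
    if n_targets < 2:
        raise ValueError(f"need at least 2 targets, got {n_targets}")
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError(f"accuracy must lie in [0, 1], got {accuracy}")
    if seconds_per_command <= 0:
        raise ValueError(f"seconds_per_command must be > 0, got {seconds_per_command}")
    n, a = n_targets, accuracy
    bits = math.log2(n)
    if a > 0.0:
        bits += a * math.log2(a)
    if a < 1.0:
        bits += (1.0 - a) * math.log2((1.0 - a) / (n - 1))
    return bits * 60.0 / seconds_per_command + 0.0  # normalize -0.0


def preprocess_recording(
    rec: Recording,
    target_fs: float = 250.0,
    band: tuple[float, float] = (4.0, 33.0),
    order: int = 3,
    causal: bool = True,
    do_rescale: bool = True,
) -> Recording:
    """The standard conditioning chain: decimate, band-pass, rescale.

    ``do_rescale=False`` stops before the amplitude rescale — useful when the
    extrema must be frozen from training data (the streaming path).
    """
    out = resample_to(rec, target_fs) if rec.fs != target_fs else rec
    out = bandpass(out, band[0], band[1], order=order, causal=causal)
    return rescale(out) if do_rescale else out


def crossvalidate(
    recordings: list[Recording],
    family: str = "spatial_cnn",
    window_spec: WindowSpec = WindowSpec(4.0, 0.5),
    seed: int = 0,
    discard_s: float = 2.0,
    target_fs: float = 250.0,
    band: tuple[float, float] = (4.0, 33.0),
    order: int = 3,
    model_kwargs: dict | None = None,
    classifier_factory=None,
) -> CVResult:
    """Fivefold leave-one-recording-out cross-validation for one subject.

    Fold i holds out recording i for validation and trains on the remaining
    four. Each recording is conditioned (decimation, causal band-pass,
    per-recording rescale to [−1, 1]) and windowed; data-dependent fitting
    (SVM feature standardization, CNN weights) sees training folds only. For
    the CNNs the held-out recording also drives early stopping, mirroring
    the training protocol's use of the validation split.

    ``classifier_factory(train_epochs, val_epochs, seed) -> (labels_fn)`` can
    replace the built-in families in tests (e.g. oracle or constant
    classifiers).
    """
    if len(recordings) != 5:
        raise ValueError(f"expected exactly 5 recordings, got {len(recordings)}")
    model_kwargs = dict(model_kwargs or {})
    epoch_sets = [
        segment(
            preprocess_recording(r, target_fs, band, order), window_spec, discard_s
        )
        for r in recordings
    ]
    classes = tuple(
        c for c in CLASSES if any(c in es.labels for es in epoch_sets)
    )
    folds, histories = [], []
    for i in range(5):
        val = epoch_sets[i]
        train = EpochSet.concatenate([es for j, es in enumerate(epoch_sets) if j != i])
        if classifier_factory is not None:
            y_pred = classifier_factory(train, val, seed + i)
        elif family in ("spatial_cnn", "standard_cnn"):
            build = (
                _classify.build_spatial_cnn
                if family == "spatial_cnn"
                else _classify.build_standard_cnn
            )
            spec = build(
                channels=train.windows.shape[1],
                samples=train.windows.shape[2],
                n_classes=len(classes),
                **model_kwargs,
            )
            clf = _classify.train_cnn(spec, train, val, seed=seed + i)
            histories.append(clf.history)
            y_pred, _ = _classify.predict(clf, val)
        elif family == "psda_svm":
            f_train = psda_features(train, band=band)
            f_val = psda_features(val, band=band)
            clf = _classify.train_svm_psda(f_train, **model_kwargs)
            y_pred, _ = _classify.predict(clf, f_val)
        else:
            raise ValueError(f"unknown family {family!r}")
        folds.append(confusion(val.labels, y_pred, classes))
    return CVResult(folds, classes, histories)


@dataclass
class SnrResult:
    per_window_db: list[float]
    mean_db: float
    sd_db: float
    skipped: int = 0


def snr_alpha(
    rec: Recording,
    alpha_band: tuple[float, float] = (8.0, 13.0),
    window_s: float = 5.0,
    exclusion_hz: float = 2.0,
    noise_range: tuple[float, float] = (4.0, 40.0),
    nfft: int = 4096,
    taper_len: int | None = None,
    channel: int = 0,
) -> SnrResult:
    """Alpha-peak SNR in dB per 5 s window of an eyes-closed recording.

    Per window: Welch PSD (Hann taper over the full window by default,
    zero-padded to ``nfft``); the signal amplitude is the square root of the
    largest PSD value whose frequency is a spectral peak inside
    ``alpha_band``; the noise amplitude is the largest spectral amplitude in
    ``noise_range`` outside ±``exclusion_hz`` of that peak. SNR is
    ``10·log10((A_signal/A_noise)²)``. Windows without a detectable in-band
    peak are skipped with a warning. The recording should already be
    high-pass filtered (4 Hz).
    """
    x = rec.data[channel]
    n_win = int(round(window_s * rec.fs))
    if n_win > len(x):
        raise ValueError("recording shorter than one window")
    seg_len = n_win if taper_len is None else min(taper_len, n_win)
    values = []
    skipped = 0
    for start in range(0, len(x) - n_win + 1, n_win):
        w = x[start : start + n_win]
        psd = welch_psd(w, rec.fs, seg_len=seg_len, taper="hann", nfft=max(nfft, seg_len))
        amp = np.sqrt(psd.power[0])
        freqs = psd.freqs
        in_band = (freqs >= alpha_band[0]) & (freqs <= alpha_band[1])
        peaks, _ = sp_signal.find_peaks(amp)
        band_peaks = [p for p in peaks if in_band[p]]
        if not band_peaks:
            skipped += 1
            warnings.warn(
                f"no alpha peak detected in window starting at {start / rec.fs:.1f} s",
                stacklevel=2,
            )
            continue
        p_sig = max(band_peaks, key=lambda p: amp[p])
        a_signal = amp[p_sig]
        f_sig = freqs[p_sig]
        noise_mask = (
            (freqs >= noise_range[0])
            & (freqs <= noise_range[1])
            & (np.abs(freqs - f_sig) > exclusion_hz)
        )
        if not noise_mask.any():
            skipped += 1
            continue
        a_noise = amp[noise_mask].max()
        values.append(float(10.0 * np.log10((a_signal / a_noise) ** 2)))
    if values:
        mean = float(np.mean(values))
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    else:
        mean, sd = float("nan"), float("nan")
    return SnrResult(values, mean, sd, skipped)
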