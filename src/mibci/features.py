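"""Welch spectra, band power, PSDA feature vectors and ERD/ERS maps."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from mibci.preprocess import EpochSet
from mibci.simulate import BANDS


@dataclass
class PSDEstimate:
    """One-sided Welch power spectral density, channels × frequency bins."""

    freqs: np.ndarray  # Hz, uniform grid from 0 to fs/2
    power: np.ndarray  # (channels, n_freqs), µV²/Hz
    fs: float
    seg_len: int
    taper: str
    overlap_frac: float
    nfft: int

    @property
    def total_power(self) -> np.ndarray:
        """Integrated density per channel (≈ time-domain variance)."""
        return np.trapezoid(self.power, self.freqs, axis=-1)


def welch_psd(
    x: np.ndarray,
    fs: float,
    seg_len: int = 512,
    taper: str = "hann",
    overlap_frac: float = 0.5,
    nfft: int | None = None,
) -> PSDEstimate:
    """Averaged modified periodogram (Welch), one-sided density scaling.

    ``x`` is (n_samples,) or (channels, n_samples). A signal shorter than
    ``seg_len`` is an error; callers that want a fixed frequency grid for
    short windows should pass ``seg_len=min(512, n)`` with ``nfft=512``
    (zero-padding), as :func:`psda_features` does.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    n = x.shape[-1]
    if seg_len > n:
        raise ValueError(f"seg_len={seg_len} exceeds signal length {n}")
    if nfft is None:
        nfft = seg_len
    if nfft < seg_len:
        raise ValueError(f"nfft={nfft} must be >= seg_len={seg_len}")
    noverlap = int(round(seg_len * overlap_frac))
    freqs, power = signal.welch(
        x,
        fs=fs,
        window=taper,
        nperseg=seg_len,
        noverlap=noverlap,
        nfft=nfft,
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    return PSDEstimate(freqs, power, fs, seg_len, taper, overlap_frac, nfft)


def band_power(psd: PSDEstimate, band: tuple[float, float]) -> np.ndarray:
    """Trapezoidal integral of the PSD over ``band``, per channel (µV²)."""
    lo, hi = band
    if not 0 <= lo < hi <= psd.fs / 2 + 1e-9:
        raise ValueError(f"band {band} outside [0, fs/2]")
    mask = (psd.freqs >= lo) & (psd.freqs <= hi)
    if mask.sum() < 2:
        raise ValueError(f"band {band} covers fewer than two grid points")
    return np.trapezoid(psd.power[..., mask], psd.freqs[mask], axis=-1)


@dataclass
class FeatureMatrix:
    """PSDA features: per window, concatenated per-channel in-band PSD bins."""

    X: np.ndarray  # (n_windows, channels × bins)
    labels: np.ndarray
    freqs: np.ndarray  # in-band frequency grid (per channel block)
    channels: tuple[str, ...]
    fs: float
    window_length_s: float

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.labels):
            raise ValueError("labels and rows mismatch")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("features must be finite")

    def __len__(self) -> int:
        return self.X.shape[0]


def psda_features(
    epochs: EpochSet,
    band: tuple[float, float] = (4.0, 33.0),
    seg_len: int = 512,
    nfft: int = 512,
    overlap_frac: float = 0.5,
) -> FeatureMatrix:
    """Welch-PSD feature vectors for the SVM route.

    Each window's per-channel Welch PSD (512-point Hann grid; shorter windows
    are zero-padded to keep the grid identical across window sizes) is
    restricted to the analysis band and concatenated channel-wise.
    """
    n = epochs.windows.shape[-1]
    eff_seg = min(seg_len, n)
    flat = epochs.windows.reshape(-1, n)  # (n_windows × channels, samples)
    psd = welch_psd(flat, epochs.fs, eff_seg, "hann", overlap_frac, nfft)
    lo, hi = band
    mask = (psd.freqs >= lo) & (psd.freqs <= hi)
    n_win, n_ch = epochs.windows.shape[:2]
    X = psd.power[:, mask].reshape(n_win, n_ch * int(mask.sum()))
    channels = epochs.channel_labels or tuple(f"ch{i}" for i in range(n_ch))
    return FeatureMatrix(
        X=X,
        labels=epochs.labels.copy(),
        freqs=psd.freqs[mask],
        channels=channels,
        fs=epochs.fs,
        window_length_s=epochs.window_spec.length_s,
    )


@dataclass
class ErdErsMap:
    """Relative band-power change per (class, channel, band) vs a reference.

    Negative entries are event-related desynchronization, positive entries
    synchronization. Entries where the reference power is zero are NaN.
    """

    table: pd.DataFrame  # columns: class_id, channel, band, rel_change
    reference: str

    def value(self, class_id: str, channel: str, band: str) -> float:
        t = self.table
        row = t[
            (t["class_id"] == class_id)
            & (t["channel"] == channel)
            & (t["band"] == band)
        ]
        if row.empty:
            raise KeyError((class_id, channel, band))
        return float(row["rel_change"].iloc[0])


def _mean_band_powers(
    epochs: EpochSet, bands: dict[str, tuple[float, float]]
) -> dict[str, np.ndarray]:
    """Per class: mean over windows of per-channel band power, (ch, band)."""
    band_names = list(bands)
    out = {}
    n = epochs.windows.shape[-1]
    eff_seg = min(256, n)
    for cls in epochs.classes:
        sub = epochs.windows[epochs.labels == cls]
        flat = sub.reshape(-1, n)
        psd = welch_psd(flat, epochs.fs, eff_seg, "hann", 0.5, max(512, eff_seg))
        powers = np.stack(
            [band_power(psd, bands[b]) for b in band_names], axis=-1
        )  # (n_win × ch, bands)
        powers = powers.reshape(len(sub), epochs.windows.shape[1], len(band_names))
        out[cls] = powers.mean(axis=0)
    return out


def erd_ers_map(
    epochs: EpochSet,
    reference_class: str | None = None,
    bands: dict[str, tuple[float, float]] | None = None,
    channels: tuple[str, ...] | None = None,
) -> ErdErsMap:
    """ERD/ERS map: (mean class power − reference power) / reference power.

    With no explicit rest condition in the protocol, the default reference
    for each class is the pooled mean over the other classes.
    """
    bands = dict(bands or BANDS)
    if channels is None:
        channels = epochs.channel_labels or tuple(
            f"ch{i}" for i in range(epochs.windows.shape[1])
        )
    classes = epochs.classes
    if reference_class is not None and reference_class not in classes:
        raise ValueError(f"reference class {reference_class!r} not present")
    means = _mean_band_powers(epochs, bands)
    rows = []
    for cls in classes:
        if reference_class is not None:
            ref = means[reference_class]
        else:
            others = [means[c] for c in classes if c != cls]
            ref = np.mean(others, axis=0) if others else means[cls]
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = (means[cls] - ref) / ref
        rel = np.where(ref > 0, rel, np.nan)
        for ci, ch in enumerate(channels):
            for bi, b in enumerate(bands):
                rows.append(
                    {
                        "class_id": cls,
                        "channel": ch,
                        "band": b,
                        "rel_change": rel[ci, bi],
                    }
                )
    return ErdErsMap(
        pd.DataFrame(rows), reference_class or "pooled-others"
    )
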