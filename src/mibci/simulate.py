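"""Synthetic sensorimotor EEG with ERD/ERS class structure.

The generator emulates a low-channel-count motor-imagery session: six scalp
channels over frontal, central and parieto-occipital sites, a 1/f ("pink")
broadband background partly shared across channels (a crude stand-in for
volume conduction), and narrowband sensorimotor rhythms (mu, beta) plus a
posterior alpha rhythm. Each task class modulates the amplitude of specific
(channel, band) oscillations: event-related desynchronization (ERD) scales a
band's amplitude below baseline during the task, event-related
synchronization (ERS) scales it above. Sessions follow a block protocol of
one-minute single-task segments; the first two seconds of each segment are
meant to be discarded downstream while the subject reacts to the cue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

#: Canonical class order used throughout the package.
CLASSES: tuple[str, ...] = ("eyes_closed", "left_hand", "right_hand", "feet")

#: Frequency bands (Hz). mu/beta are sensorimotor; alpha is posterior.
BANDS: dict[str, tuple[float, float]] = {
    "mu": (8.0, 12.0),
    "beta": (18.0, 26.0),
    "alpha": (8.0, 13.0),
}

DEFAULT_CHANNELS: tuple[str, ...] = ("Fz", "C5", "C3", "C4", "C6", "POz")

#: Cross-channel source layout per band: channels in one group receive the
#: same underlying oscillatory source (volume conduction smears a cortical
#: source across neighbouring electrodes). Sensorimotor rhythms have one
#: source per hemisphere plus a midline source; the posterior alpha source
#: projects broadly onto all channels.
DEFAULT_SOURCE_GROUPS: dict[str, tuple[tuple[str, ...], ...]] = {
    "mu": (("C3", "C5"), ("C4", "C6"), ("Fz",), ("POz",)),
    "beta": (("C3", "C5"), ("C4", "C6"), ("Fz",), ("POz",)),
    "alpha": (DEFAULT_CHANNELS,),
}


class ConfigurationError(ValueError):
    """A simulation configuration is inconsistent or incomplete."""


@dataclass(frozen=True)
class MontageSpec:
    """Recording montage: six scalp channels, a reference and a ground."""

    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    reference_label: str = "Cz"
    ground_label: str = "mastoid"

    def __post_init__(self) -> None:
        if len(self.channel_labels) != 6:
            raise ConfigurationError(
                f"expected exactly 6 recording channels, got {len(self.channel_labels)}"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ConfigurationError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)


@dataclass(frozen=True)
class ClassProfile:
    """Amplitude modulation a task class applies to (channel, band) rhythms.

    ``band_modulation`` maps ``(channel, band)`` to a dimensionless amplitude
    multiplier; 1.0 is baseline, < 1 is ERD, > 1 is ERS.  Pairs not listed
    default to 1.0.  Oscillation *power* scales with the square of the
    multiplier.
    """

    class_id: str
    band_modulation: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (ch, band), mult in self.band_modulation.items():
            if mult <= 0:
                raise ConfigurationError(
                    f"multiplier for ({ch}, {band}) must be > 0, got {mult}"
                )
            if band not in BANDS:
                raise ConfigurationError(f"unknown band {band!r}")

    def multiplier(self, channel: str, band: str) -> float:
        return self.band_modulation.get((channel, band), 1.0)


def default_profiles(
    erd: float = 0.6, ers: float = 2.5, erd_mild: float = 0.8
) -> dict[str, ClassProfile]:
    """Standard somatotopic class→channel modulation map.

    Hand motor imagery desynchronizes mu/beta over the contralateral central
    channels; foot imagery desynchronizes midline-adjacent Fz with a mild
    bilateral component; eyes-closed synchronizes posterior alpha at POz.
    Fully overridable through :class:`SimConfig`.
    """
    beta_erd = math.sqrt(erd)  # beta ERD is typically shallower than mu ERD
    return {
        "left_hand": ClassProfile(
            "left_hand",
            {
                ("C4", "mu"): erd,
                ("C6", "mu"): erd,
                ("C4", "beta"): beta_erd,
                ("C6", "beta"): beta_erd,
            },
        ),
        "right_hand": ClassProfile(
            "right_hand",
            {
                ("C3", "mu"): erd,
                ("C5", "mu"): erd,
                ("C3", "beta"): beta_erd,
                ("C5", "beta"): beta_erd,
            },
        ),
        "feet": ClassProfile(
            "feet",
            {
                ("Fz", "mu"): erd,
                ("Fz", "beta"): beta_erd,
                ("C3", "mu"): erd_mild,
                ("C4", "mu"): erd_mild,
            },
        ),
        "eyes_closed": ClassProfile("eyes_closed", {("POz", "alpha"): ers}),
    }


@dataclass(frozen=True)
class Segment:
    """One single-task block within a trial (times in seconds, within-trial)."""

    trial: int
    class_id: str
    start: float
    duration: float

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class ProtocolSchedule:
    """Ordered single-task segments for a session of one or more trials."""

    segments: tuple[Segment, ...]
    discard_s: float = 2.0
    trials: int = 5
    subjects: int = 4

    @property
    def trial_duration(self) -> float:
        return max(s.end for s in self.segments if s.trial == 0)

    def trial_segments(self, trial: int) -> list[Segment]:
        return [s for s in self.segments if s.trial == trial]

    @property
    def class_ids(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(s.class_id for s in self.segments))


def make_protocol(
    trials: int = 5,
    class_order: tuple[str, ...] = CLASSES,
    segment_s: float = 60.0,
    discard_s: float = 2.0,
    subjects: int = 4,
) -> ProtocolSchedule:
    """Build the block protocol: one segment per class per trial.

    The default reproduces the session layout of a four-class recording
    protocol: eyes-closed first, then the motor-imagery tasks, 60 s each,
    4 min per trial, five trials per subject.
    """
    if trials < 1:
        raise ValueError(f"trials must be >= 1, got {trials}")
    if segment_s <= 0 or discard_s < 0 or segment_s <= discard_s:
        raise ValueError(
            f"need segment_s > discard_s >= 0, got segment_s={segment_s}, discard_s={discard_s}"
        )
    if not class_order:
        raise ValueError("class_order must be non-empty")
    segments = []
    for trial in range(trials):
        t = 0.0
        for cls in class_order:
            segments.append(Segment(trial, cls, t, segment_s))
            t += segment_s
    return ProtocolSchedule(tuple(segments), discard_s, trials, subjects)


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic-EEG generator.

    Amplitudes are µV RMS of the baseline oscillation per channel;
    ``noise_scale`` / ``common_noise_scale`` are µV RMS of the per-channel and
    channel-shared 1/f backgrounds. Defaults target a classification problem
    that is clearly learnable but not trivial at 4 s windows.
    """

    montage: MontageSpec = field(default_factory=MontageSpec)
    profiles: dict[str, ClassProfile] = field(default_factory=default_profiles)
    fs: float = 500.0
    background_exponent: float = 1.0
    oscillation_amplitudes: dict[str, float] = field(
        default_factory=lambda: {"mu": 4.5, "beta": 2.25, "alpha": 3.0}
    )
    noise_scale: float = 2.0
    common_noise_scale: float = 12.0
    source_groups: dict[str, tuple[tuple[str, ...], ...]] = field(
        default_factory=lambda: dict(DEFAULT_SOURCE_GROUPS)
    )
    source_coherence: float = 0.9
    line_noise_hz: float | None = None
    line_noise_amp: float = 0.0
    crossfade_s: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        nyq = self.fs / 2.0
        top = max(hi for _, hi in BANDS.values())
        if self.fs <= 2 * top:
            raise ConfigurationError(
                f"fs={self.fs} must exceed twice the highest simulated frequency ({top} Hz)"
            )
        if self.line_noise_hz is not None and self.line_noise_hz >= nyq:
            raise ConfigurationError("line_noise_hz above Nyquist")


@dataclass
class Recording:
    """Continuous multi-channel EEG in µV with class-interval annotations.

    ``annotations`` are half-open intervals ``(start_s, end_s, class_id)``.
    """

    data: np.ndarray  # (n_channels, n_samples), µV
    fs: float
    montage: MontageSpec
    annotations: list[tuple[float, float, str]]
    subject_id: int = 0
    trial_id: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data must be ({self.montage.n_channels}, n_samples), got {self.data.shape}"
            )
        dur = self.duration
        for start, end, cls in self.annotations:
            if not (0.0 <= start < end <= dur + 1e-9):
                raise ValueError(
                    f"annotation ({start}, {end}, {cls}) outside [0, {dur})"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs

    def copy_with(self, data: np.ndarray, fs: float | None = None) -> "Recording":
        return Recording(
            data=data,
            fs=self.fs if fs is None else fs,
            montage=self.montage,
            annotations=list(self.annotations),
            subject_id=self.subject_id,
            trial_id=self.trial_id,
        )


def pink_noise(
    duration: float,
    fs: float,
    exponent: float = 1.0,
    scale: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Gaussian noise with a power-law spectrum ``PSD ∝ f**-exponent``.

    Synthesized by spectral shaping: white Gaussian noise is transformed to
    the frequency domain, each positive-frequency bin scaled by
    ``f**(-exponent/2)``, and transformed back. The DC bin is zeroed. The
    result is normalized to the requested RMS ``scale``.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    if not 0.0 <= exponent <= 2.0:
        raise ValueError(f"exponent must lie in [0, 2], got {exponent}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs))
    white = rng.standard_normal(n)
    if exponent == 0.0:
        x = white
    else:
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        shaping = np.zeros_like(freqs)
        shaping[1:] = freqs[1:] ** (-exponent / 2.0)
        x = np.fft.irfft(spec * shaping, n=n)
    rms = np.sqrt(np.mean(x**2))
    if rms > 0:
        x = x * (scale / rms)
    return x


def _band_carrier(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS narrowband noise: band-filtered white noise.

    Band-filtered noise gives Welch peaks with realistic width, unlike pure
    sinusoids whose spectral lines are unrealistically sharp for ERD work.
    """
    white = rng.standard_normal(n)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _envelope(
    n: int,
    fs: float,
    segments: list[Segment],
    multipliers: list[float],
    crossfade_s: float,
) -> np.ndarray:
    """Piecewise-constant multiplier track with raised-cosine crossfades.

    Each internal boundary blends the left and right values over
    ``crossfade_s`` seconds centred on the boundary, so the modulated
    oscillation has no amplitude discontinuities.
    """
    env = np.empty(n)
    for seg, mult in zip(segments, multipliers):
        i0 = int(round(seg.start * fs))
        i1 = min(int(round(seg.end * fs)), n)
        env[i0:i1] = mult
    half = int(round(crossfade_s * fs / 2))
    if half > 0:
        for seg, left, right in zip(
            segments[1:], multipliers[:-1], multipliers[1:]
        ):
            b = int(round(seg.start * fs))
            i0, i1 = max(b - half, 0), min(b + half, n)
            if i1 <= i0:
                continue
            t = np.arange(i0 - (b - half), i1 - (b - half)) / (2 * half)
            blend = 0.5 - 0.5 * np.cos(np.pi * np.clip(t, 0, 1))
            env[i0:i1] = left + (right - left) * blend
    return env


def oscillation_component(
    config: SimConfig,
    protocol: ProtocolSchedule,
    subject_id: int = 0,
    trial_id: int = 0,
) -> np.ndarray:
    """Noise-free sum of the class-modulated narrowband oscillations.

    Useful as ground truth: band power of this component inside a segment is
    ``(amplitude × multiplier)²`` up to carrier estimation error.
    """
    return _synthesize(config, protocol, subject_id, trial_id, with_noise=False)


def _seed_for(config: SimConfig, subject_id: int, trial_id: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        entropy=config.seed, spawn_key=(subject_id, trial_id)
    )


def _synthesize(
    config: SimConfig,
    protocol: ProtocolSchedule,
    subject_id: int,
    trial_id: int,
    with_noise: bool,
) -> np.ndarray:
    segments = protocol.trial_segments(trial_id % protocol.trials)
    if not segments:
        segments = protocol.trial_segments(0)
    for seg in segments:
        if seg.class_id not in config.profiles:
            raise ConfigurationError(f"no ClassProfile for class {seg.class_id!r}")
    fs = config.fs
    dur = max(s.end for s in segments) - segments[0].start
    n = int(round(dur * fs))
    ss = _seed_for(config, subject_id, trial_id)
    # fixed spawn layout: common noise, shared band sources, then channels
    n_groups = sum(len(g) for g in config.source_groups.values())
    children = ss.spawn(1 + n_groups + config.montage.n_channels)
    out = np.zeros((config.montage.n_channels, n))
    t0 = segments[0].start
    shifted = [replace(s, start=s.start - t0) for s in segments]
    if with_noise and config.common_noise_scale > 0:
        common = pink_noise(
            dur, fs, config.background_exponent, config.common_noise_scale,
            np.random.default_rng(children[0]),
        )
        out += common[None, :]
    # shared source carriers: channels in one group oscillate coherently
    group_carriers: dict[str, dict[str, np.ndarray]] = {}
    gi = 1
    for band, groups in config.source_groups.items():
        group_carriers[band] = {}
        for group in groups:
            carrier = _band_carrier(
                n, fs, BANDS[band], np.random.default_rng(children[gi])
            )
            for ch in group:
                group_carriers[band][ch] = carrier
            gi += 1
    coh = math.sqrt(config.source_coherence)
    ind = math.sqrt(1.0 - config.source_coherence)
    for ci, ch in enumerate(config.montage.channel_labels):
        rng = np.random.default_rng(children[1 + n_groups + ci])
        acc = np.zeros(n)
        for band, amp in config.oscillation_amplitudes.items():
            own = _band_carrier(n, fs, BANDS[band], rng)
            shared = group_carriers.get(band, {}).get(ch)
            carrier = own if shared is None else coh * shared + ind * own
            mults = [
                amp * config.profiles[s.class_id].multiplier(ch, band)
                for s in shifted
            ]
            env = _envelope(n, fs, shifted, mults, config.crossfade_s)
            acc += env * carrier
        if with_noise:
            if config.noise_scale > 0:
                acc += pink_noise(
                    dur, fs, config.background_exponent, config.noise_scale, rng
                )
            if config.line_noise_hz is not None and config.line_noise_amp > 0:
                t = np.arange(n) / fs
                phase = rng.uniform(0, 2 * np.pi)
                acc += (
                    config.line_noise_amp
                    * np.sqrt(2)
                    * np.sin(2 * np.pi * config.line_noise_hz * t + phase)
                )
        out[ci] += acc
    return out


def simulate_recording(
    config: SimConfig,
    protocol: ProtocolSchedule,
    subject_id: int = 0,
    trial_id: int = 0,
) -> Recording:
    """Generate one trial's continuous recording.

    Each channel is the sum of a shared and a per-channel 1/f background and
    per-band narrowband oscillations whose amplitudes follow the active
    segment's class profile (raised-cosine crossfade at boundaries).
    Deterministic: the same config, protocol and ids give a byte-identical
    recording.
    """
    data = _synthesize(config, protocol, subject_id, trial_id, with_noise=True)
    segments = protocol.trial_segments(trial_id % protocol.trials)
    t0 = segments[0].start
    annotations = [(s.start - t0, s.end - t0, s.class_id) for s in segments]
    return Recording(
        data=data,
        fs=config.fs,
        montage=config.montage,
        annotations=annotations,
        subject_id=subject_id,
        trial_id=trial_id,
    )


def simulate_subject(
    config: SimConfig, protocol: ProtocolSchedule, subject_id: int = 0
) -> list[Recording]:
    """All trials of one subject (one Recording per trial)."""
    return [
        simulate_recording(config, protocol, subject_id, trial)
        for trial in range(protocol.trials)
    ]
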