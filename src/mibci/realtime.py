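"""Online control-scheme simulation: sliding windows, agreement, game scoring.

The streaming loop classifies a trailing fixed-length window at a fixed
cadence (default: 4 s windows every 0.16 s). Two consecutive agreeing
classifications form a confirmed instruction; agreement pairs do not overlap,
so sustained intent re-confirms every second tick. Confirmed commands are
scored against a cue schedule modeled on a rhythm game: a colored cube spawns
at a fixed interval, each color demanding one of the four classes, and a cue
scores a point when a matching confirmed command arrives in its response
window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from mibci.classify import TrainedClassifier, predict
from mibci.features import psda_features
from mibci.preprocess import EpochSet, WindowSpec, apply_rescale, bandpass, resample_to
from mibci.simulate import CLASSES, ProtocolSchedule, Recording, Segment


@dataclass(frozen=True)
class StreamConfig:
    window_s: float = 4.0
    tick_s: float = 0.16
    agreement_n: int = 2

    def __post_init__(self) -> None:
        if self.tick_s <= 0:
            raise ValueError(f"tick_s must be > 0, got {self.tick_s}")
        if self.agreement_n < 1:
            raise ValueError(f"agreement_n must be >= 1, got {self.agreement_n}")


#: positional correspondence of the printed color and action lists
COLOR_TO_CLASS: dict[str, str] = {
    "Blue": "feet",
    "Green": "left_hand",
    "Red": "right_hand",
    "Yellow": "eyes_closed",
}
CLASS_TO_COLOR = {v: k for k, v in COLOR_TO_CLASS.items()}


@dataclass(frozen=True)
class Cue:
    spawn_s: float
    color: str
    required_class: str


@dataclass(frozen=True)
class GameSchedule:
    """Cue spawn schedule: first cue after an initial delay, then periodic."""

    total_s: float = 240.0
    initial_delay_s: float = 1.0
    spawn_interval_s: float = 4.0
    cues: tuple[Cue, ...] = ()


@dataclass
class CueOutcome:
    cue: Cue
    outcome: str  # correct | wrong | missed
    latency_s: float | None  # first matching (or first) response − spawn


@dataclass
class GameScore:
    points: int
    outcomes: list[CueOutcome]

    @property
    def n_cues(self) -> int:
        return len(self.outcomes)

    @property
    def fraction_correct(self) -> float:
        return self.points / self.n_cues if self.n_cues else 0.0


def make_schedule(
    total_s: float = 240.0,
    initial_delay_s: float = 1.0,
    spawn_interval_s: float = 4.0,
    seed: int = 0,
) -> GameSchedule:
    """Cues at ``initial_delay + k·interval`` for k = 0, 1, … while < total.

    Colors (hence required classes) are drawn uniformly with the seed.
    """
    if total_s <= 0 or initial_delay_s < 0 or spawn_interval_s <= 0:
        raise ValueError("durations must be positive")
    rng = np.random.default_rng(seed)
    colors = list(COLOR_TO_CLASS)
    cues = []
    t = initial_delay_s
    while t < total_s:
        color = colors[rng.integers(len(colors))]
        cues.append(Cue(t, color, COLOR_TO_CLASS[color]))
        t += spawn_interval_s
    return GameSchedule(total_s, initial_delay_s, spawn_interval_s, tuple(cues))


def schedule_to_protocol(schedule: GameSchedule) -> ProtocolSchedule:
    """Single-trial protocol whose segments follow the cue schedule.

    Used to synthesize the EEG of a compliant subject: the required class is
    performed from each spawn until the next (the pre-game lead-in carries
    the first cue's class so the opening window is not unlabeled noise).
    """
    segs = []
    cues = schedule.cues
    for i, cue in enumerate(cues):
        start = 0.0 if i == 0 else cue.spawn_s
        end = cues[i + 1].spawn_s if i + 1 < len(cues) else schedule.total_s
        segs.append(Segment(0, cue.required_class, start, end - start))
    return ProtocolSchedule(tuple(segs), discard_s=0.0, trials=1, subjects=1)


def stream_classify(
    rec: Recording,
    clf: TrainedClassifier,
    cfg: StreamConfig = StreamConfig(),
    band: tuple[float, float] = (4.0, 33.0),
    order: int = 3,
    target_fs: float = 250.0,
    rescale_bounds: tuple[float, float] | None = None,
) -> list[tuple[float, str]]:
    """Raw classification stream: one (time, label) per tick.

    Preprocessing matches the offline chain but with no lookahead: the
    anti-alias decimation and causal band-pass run over the stream, and the
    amplitude rescale uses extrema frozen from training data
    (``rescale_bounds``); with ``None`` the band-passed stream's own extrema
    are used (training-free demo mode). Tick k classifies the trailing
    ``window_s`` seconds ending at ``window_s + k·tick_s``.
    """
    if rec.duration < cfg.window_s:
        warnings.warn("recording shorter than one window; empty stream", stacklevel=2)
        return []
    proc = resample_to(rec, target_fs) if rec.fs != target_fs else rec
    proc = bandpass(proc, band[0], band[1], order=order, causal=True)
    if rescale_bounds is None:
        rescale_bounds = (float(proc.data.min()), float(proc.data.max()))
    proc = apply_rescale(proc, *rescale_bounds)
    fs = proc.fs
    win = int(round(cfg.window_s * fs))
    times, windows = [], []
    t = cfg.window_s
    while t <= rec.duration + 1e-9:
        end = min(int(round(t * fs)), proc.n_samples)
        windows.append(proc.data[:, end - win : end])
        times.append(t)
        t += cfg.tick_s
    spec = WindowSpec(cfg.window_s, 0.0)
    epochs = EpochSet(
        np.stack(windows),
        np.asarray(["eyes_closed"] * len(windows), dtype=object),  # placeholder
        spec,
        fs,
        channel_labels=rec.montage.channel_labels,
    )
    if clf.family == "psda_svm":
        feats = psda_features(epochs, band=band)
        labels, _ = predict(clf, feats)
    else:
        labels, _ = predict(clf, epochs)
    return list(zip(times, labels.tolist()))


def confirm_commands(
    raw: list[tuple[float, str]], cfg: StreamConfig = StreamConfig()
) -> list[tuple[float, str]]:
    """Non-overlapping runs of ``agreement_n`` consecutive agreeing labels.

    A confirmation consumes its ticks: with the default n = 2, the stream
    [A, A, A] confirms once (ticks 1–2), and [A, A, A, A] twice.
    The confirmed time is the last tick of the agreeing run.
    """
    confirmed = []
    run = 0
    prev = None
    for t, label in raw:
        run = run + 1 if label == prev else 1
        prev = label
        if run == cfg.agreement_n:
            confirmed.append((t, label))
            run = 0
            prev = None if cfg.agreement_n > 1 else label
    return confirmed


def run_game(
    confirmed: list[tuple[float, str]],
    schedule: GameSchedule,
    resolve: str = "until_correct",
) -> GameScore:
    """Score confirmed commands against the cue schedule.

    Each cue's response window runs from its spawn to the next spawn (or the
    end of the game). With the default ``resolve="until_correct"`` a wrong
    command gives feedback but leaves the cue active, so a later matching
    command within the window still scores — wrong attempts do not clear the
    cube. ``resolve="first"`` instead freezes each cue's outcome at the first
    confirmed command in its window. One point per correct cue.
    """
    if resolve not in ("until_correct", "first"):
        raise ValueError(f"unknown resolve mode {resolve!r}")
    outcomes = []
    points = 0
    cues = schedule.cues
    for i, cue in enumerate(cues):
        w_end = cues[i + 1].spawn_s if i + 1 < len(cues) else schedule.total_s
        responses = [(t, c) for t, c in confirmed if cue.spawn_s <= t < w_end]
        if not responses:
            outcomes.append(CueOutcome(cue, "missed", None))
            continue
        if resolve == "first":
            t0, c0 = responses[0]
            ok = c0 == cue.required_class
        else:
            match = next(
                ((t, c) for t, c in responses if c == cue.required_class), None
            )
            ok = match is not None
            t0 = match[0] if ok else responses[0][0]
        points += int(ok)
        outcomes.append(
            CueOutcome(cue, "correct" if ok else "wrong", t0 - cue.spawn_s)
        )
    return GameScore(points, outcomes)
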