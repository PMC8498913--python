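"""End-to-end pipeline: simulate → preprocess → train → CV → stream → game.

A :class:`PipelineConfig` holds every stage's parameters and all seeds; a run
writes its artifacts plus a manifest (parameters, seeds, content hashes) so
that reruns are verifiable. Simulation and preprocessing artifacts reproduce
bit-exactly; classifier metrics reproduce within seed-fixed determinism.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from mibci import io as mio
from mibci.classify import (
    build_spatial_cnn,
    build_standard_cnn,
    predict,
    train_cnn,
    train_svm_psda,
)
from mibci.evaluate import crossvalidate, itr, preprocess_recording
from mibci.features import psda_features
from mibci.preprocess import EpochSet, WindowSpec, segment
from mibci.realtime import (
    StreamConfig,
    confirm_commands,
    make_schedule,
    run_game,
    schedule_to_protocol,
    stream_classify,
)
from mibci.simulate import (
    CLASSES,
    ProtocolSchedule,
    SimConfig,
    make_protocol,
    simulate_recording,
    simulate_subject,
)

log = logging.getLogger("mibci")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything one run needs; round-trips losslessly through YAML/JSON."""

    out_dir: str = "mibci_out"
    seed: int = 0
    subjects: int = 1
    trials: int = 5
    segment_s: float = 60.0
    discard_s: float = 2.0
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    window_s: float = 4.0
    overlap_frac: float = 0.5
    band: tuple[float, float] = (4.0, 33.0)
    filter_order: int = 3
    target_fs: float = 250.0
    family: str = "spatial_cnn"
    model: dict = field(default_factory=dict)  # hyperparameter overrides
    stream: dict = field(default_factory=dict)  # StreamConfig overrides
    game_total_s: float = 240.0
    game_initial_delay_s: float = 1.0
    game_spawn_interval_s: float = 4.0
    save_format: str = "csv"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "band" in d:
            d["band"] = tuple(d["band"])
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            yaml.safe_load(text)
            if path.suffix in (".yml", ".yaml")
            else json.loads(text)
        )
        if not isinstance(data, dict):
            raise PipelineError("config", f"{path} does not contain a mapping")
        try:
            return cls.from_dict(data)
        except TypeError as exc:
            raise PipelineError("config", str(exc)) from None

    def dump(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(d, sort_keys=False))
        else:
            path.write_text(json.dumps(d, indent=1))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the results bundle (also written out).

    Stages: synthetic session generation per subject, preprocessing and
    windowing, per-subject cross-validation, a final model fit, a streamed
    closed-loop game session, and ITR from the pooled CV accuracy.
    """
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "seeds": {},
        "artifacts": {},
    }
    window_spec = WindowSpec(config.window_s, config.overlap_frac)
    results: dict = {}

    # ---- simulate -----------------------------------------------------
    stage = "simulate"
    try:
        sim_cfg = SimConfig(seed=config.seed, **config.sim)
        protocol = make_protocol(
            trials=config.trials,
            segment_s=config.segment_s,
            discard_s=config.discard_s,
            subjects=config.subjects,
        )
        manifest["seeds"]["simulate"] = config.seed
        sessions = []
        for s in range(config.subjects):
            recs = simulate_subject(sim_cfg, protocol, s)
            sessions.append(recs)
            for rec in recs:
                name = f"subject{s}_trial{rec.trial_id}.{config.save_format}"
                p = mio.write_recording(rec, out / name, config.save_format)
                manifest["artifacts"][name] = _sha256(p)
            log.info("simulated subject %d: %d recordings", s, len(recs))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- preprocess + crossvalidate -----------------------------------
    stage = "crossvalidate"
    try:
        cv_results = {}
        for s, recs in enumerate(sessions):
            cv = crossvalidate(
                recs,
                family=config.family,
                window_spec=window_spec,
                seed=config.seed + 100 + s,
                discard_s=config.discard_s,
                target_fs=config.target_fs,
                band=config.band,
                order=config.filter_order,
                model_kwargs=config.model,
            )
            manifest["seeds"][f"crossvalidate_subject{s}"] = config.seed + 100 + s
            cv_results[s] = cv
            log.info(
                "subject %d CV: pooled=%.3f folds=%s",
                s,
                cv.pooled_accuracy,
                [round(a, 3) for a in cv.fold_accuracies],
            )
        pooled_acc = float(
            np.mean([cv.pooled_accuracy for cv in cv_results.values()])
        )
        results["cv"] = {
            s: {
                "fold_accuracies": cv.fold_accuracies,
                "pooled_accuracy": cv.pooled_accuracy,
                "confusion_pooled": cv.pooled.counts.tolist(),
                "classes": list(cv.classes),
            }
            for s, cv in cv_results.items()
        }
        results["pooled_accuracy"] = pooled_acc
        results["itr_bits_per_min"] = itr(
            len(CLASSES), pooled_acc, config.window_s
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- train final model on subject 0 -------------------------------
    stage = "train"
    try:
        recs = sessions[0]
        # unscaled conditioned recordings: their extrema are frozen for the
        # streaming stage; offline epochs rescale per recording
        from mibci.preprocess import rescale as _rescale

        proc_raw = [
            preprocess_recording(
                r, config.target_fs, config.band, config.filter_order,
                do_rescale=False,
            )
            for r in recs
        ]
        epoch_sets = [
            segment(_rescale(p), window_spec, config.discard_s) for p in proc_raw
        ]
        train_set = EpochSet.concatenate(epoch_sets[:-1])
        val_set = epoch_sets[-1]
        manifest["seeds"]["train"] = config.seed + 500
        if config.family in ("spatial_cnn", "standard_cnn"):
            build = (
                build_spatial_cnn
                if config.family == "spatial_cnn"
                else build_standard_cnn
            )
            spec = build(
                channels=train_set.windows.shape[1],
                samples=train_set.windows.shape[2],
                n_classes=len(set(train_set.labels.tolist())),
                **config.model,
            )
            clf = train_cnn(spec, train_set, val_set, seed=config.seed + 500)
        else:
            clf = train_svm_psda(psda_features(train_set, band=config.band))
        log.info("trained final %s model", config.family)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stream + game -------------------------------------------------
    stage = "stream"
    try:
        schedule = make_schedule(
            config.game_total_s,
            config.game_initial_delay_s,
            config.game_spawn_interval_s,
            seed=config.seed + 900,
        )
        manifest["seeds"]["game_schedule"] = config.seed + 900
        game_protocol = schedule_to_protocol(schedule)
        game_rec = simulate_recording(
            sim_cfg, game_protocol, subject_id=0, trial_id=0
        )
        stream_cfg = StreamConfig(
            window_s=config.window_s, **config.stream
        )
        # rescale extrema frozen from the training recordings (no lookahead)
        bounds = (
            float(min(p.data.min() for p in proc_raw[:-1])),
            float(max(p.data.max() for p in proc_raw[:-1])),
        )
        raw = stream_classify(
            game_rec,
            clf,
            stream_cfg,
            band=config.band,
            order=config.filter_order,
            target_fs=config.target_fs,
            rescale_bounds=bounds,
        )
        confirmed = confirm_commands(raw, stream_cfg)
        score = run_game(confirmed, schedule)
        results["game"] = {
            "points": score.points,
            "n_cues": score.n_cues,
            "fraction_correct": score.fraction_correct,
            "n_raw": len(raw),
            "n_confirmed": len(confirmed),
        }
        session_path = out / "session.jsonl"
        with open(session_path, "w") as fh:
            for t, c in raw:
                fh.write(json.dumps({"time": t, "type": "raw", "class": c}) + "\n")
            for t, c in confirmed:
                fh.write(
                    json.dumps({"time": t, "type": "confirmed", "class": c}) + "\n"
                )
            for oc in score.outcomes:
                fh.write(
                    json.dumps(
                        {
                            "time": oc.cue.spawn_s,
                            "type": "cue",
                            "class": oc.cue.required_class,
                            "outcome": oc.outcome,
                            "latency_s": oc.latency_s,
                        }
                    )
                    + "\n"
                )
        manifest["artifacts"]["session.jsonl"] = _sha256(session_path)
        log.info(
            "game: %d/%d cues correct", score.points, score.n_cues
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    results["runtime_s"] = time.time() - t_start
    (out / "results.json").write_text(json.dumps(results, indent=1))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return results
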