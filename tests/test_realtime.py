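"""Streaming cadence, agreement confirmation and game scoring."""

import numpy as np
import pytest

import mibci
from mibci.realtime import (
    COLOR_TO_CLASS,
    Cue,
    GameSchedule,
    StreamConfig,
    confirm_commands,
    make_schedule,
    run_game,
    schedule_to_protocol,
    stream_classify,
)


class TestConfirm:
    def test_simple_pair_confirms_once(self):
        raw = [(4.0, "A"), (4.16, "A")]
        assert confirm_commands(raw) == [(4.16, "A")]

    def test_alternating_stream_never_confirms(self):
        labels = ["A", "B", "A", "B", "A"]
        raw = [(4 + 0.16 * i, l) for i, l in enumerate(labels)]
        assert confirm_commands(raw) == []

    def test_non_overlapping_pairs(self):
        raw = [(4 + 0.16 * i, "A") for i in range(4)]
        confirmed = confirm_commands(raw)
        assert [c for _, c in confirmed] == ["A", "A"]
        assert [t for t, _ in confirmed] == [raw[1][0], raw[3][0]]

    def test_run_of_three_confirms_once(self):
        raw = [(4 + 0.16 * i, "A") for i in range(3)]
        assert len(confirm_commands(raw)) == 1

    def test_confirmation_matches_its_raw_pair(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(["A", "B", "C"], 200).tolist()
        raw = [(4 + 0.16 * i, l) for i, l in enumerate(labels)]
        for t, c in confirm_commands(raw):
            k = round((t - 4) / 0.16)
            assert labels[k] == c and labels[k - 1] == c

    def test_agreement_one_passes_everything(self):
        raw = [(4.0, "A"), (4.16, "B")]
        assert confirm_commands(raw, StreamConfig(agreement_n=1)) == raw


class TestSchedule:
    def test_default_schedule_has_sixty_cues(self):
        s = make_schedule(240.0, 1.0, 4.0, seed=0)
        assert len(s.cues) == 60
        assert s.cues[0].spawn_s == 1.0 and s.cues[-1].spawn_s == 237.0

    def test_short_game(self):
        s = make_schedule(9.0, 1.0, 4.0, seed=0)
        assert [c.spawn_s for c in s.cues] == [1.0, 5.0]

    def test_seeded_color_sequence_reproducible(self):
        a = make_schedule(seed=7)
        b = make_schedule(seed=7)
        assert [c.color for c in a.cues] == [c.color for c in b.cues]

    def test_color_class_mapping(self):
        assert COLOR_TO_CLASS == {
            "Blue": "feet",
            "Green": "left_hand",
            "Red": "right_hand",
            "Yellow": "eyes_closed",
        }

    def test_schedule_to_protocol_covers_game(self):
        s = make_schedule(240.0, 1.0, 4.0, seed=1)
        p = schedule_to_protocol(s)
        segs = p.trial_segments(0)
        assert segs[0].start == 0.0
        assert segs[-1].end == pytest.approx(240.0)
        for a, b in zip(segs, segs[1:]):
            assert b.start == pytest.approx(a.end)


def _schedule_from(classes, spawn=4.0, delay=1.0):
    cues = []
    t = delay
    inv = {v: k for k, v in COLOR_TO_CLASS.items()}
    for c in classes:
        cues.append(Cue(t, inv[c], c))
        t += spawn
    return GameSchedule(t - spawn + spawn, delay, spawn, tuple(cues))


class TestRunGame:
    def test_perfect_responder_scores_all(self):
        sched = _schedule_from(["feet", "left_hand", "right_hand"])
        confirmed = [(c.spawn_s + 1.0, c.required_class) for c in sched.cues]
        score = run_game(confirmed, sched)
        assert score.points == 3
        assert all(o.outcome == "correct" for o in score.outcomes)

    def test_no_commands_all_missed(self):
        sched = _schedule_from(["feet", "left_hand"])
        score = run_game([], sched)
        assert score.points == 0
        assert all(o.outcome == "missed" for o in score.outcomes)

    def test_wrong_then_correct_scores_by_default(self):
        """A wrong attempt leaves the cue active until a matching command."""
        sched = _schedule_from(["feet"])
        confirmed = [(1.5, "left_hand"), (3.0, "feet")]
        assert run_game(confirmed, sched).points == 1
        assert run_game(confirmed, sched, resolve="first").points == 0

    def test_commands_outside_window_ignored(self):
        sched = _schedule_from(["feet", "left_hand"])
        confirmed = [(5.5, "feet")]  # matches cue 1 but arrives in cue 2's window
        score = run_game(confirmed, sched)
        assert score.points == 0
        assert [o.outcome for o in score.outcomes] == ["missed", "wrong"]

    def test_points_match_brute_force_replay(self):
        rng = np.random.default_rng(3)
        classes = rng.choice(sorted(COLOR_TO_CLASS.values()), 30).tolist()
        sched = _schedule_from(classes)
        commands = [
            (float(rng.uniform(1.0, 121.0)), str(rng.choice(sorted(COLOR_TO_CLASS.values()))))
            for _ in range(200)
        ]
        commands.sort()
        score = run_game(commands, sched)
        # replay: a cue scores iff any command in [spawn, next spawn) matches
        expected = 0
        for i, cue in enumerate(sched.cues):
            end = sched.cues[i + 1].spawn_s if i + 1 < len(sched.cues) else sched.total_s
            if any(
                cue.spawn_s <= t < end and c == cue.required_class
                for t, c in commands
            ):
                expected += 1
        assert score.points == expected


class TestStreamClassify:
    def _quick_classifier(self, epochs):
        from mibci.classify import build_spatial_cnn, train_cnn

        spec = build_spatial_cnn(
            6, epochs.windows.shape[2], 4, max_epochs=2
        )
        return train_cnn(spec, epochs, epochs, seed=0)

    def test_tick_count_and_times(self, default_subject, conditioned_epochs):
        """10 s of signal, 4 s windows, 0.16 s ticks → 38 classifications."""
        from mibci.preprocess import WindowSpec
        from mibci.evaluate import preprocess_recording

        rec = default_subject[0]
        short = mibci.Recording(
            rec.data[:, : int(10 * rec.fs)], rec.fs, rec.montage,
            [(0.0, 10.0, "eyes_closed")],
        )
        epochs = mibci.segment(
            preprocess_recording(default_subject[1]), WindowSpec(4.0, 0.5), 2.0
        )
        clf = self._quick_classifier(epochs)
        raw = stream_classify(short, clf, StreamConfig())
        assert len(raw) == 38
        times = [t for t, _ in raw]
        np.testing.assert_allclose(times, 4.0 + 0.16 * np.arange(38), atol=1e-9)

    def test_too_short_recording_warns_empty(self, default_subject, conditioned_epochs):
        rec = default_subject[0]
        short = mibci.Recording(
            rec.data[:, : int(2 * rec.fs)], rec.fs, rec.montage,
            [(0.0, 2.0, "eyes_closed")],
        )
        clf = self._quick_classifier(
            conditioned_epochs.subset(np.arange(16))
        )
        with pytest.warns(UserWarning):
            assert stream_classify(short, clf, StreamConfig()) == []

    def test_confirmed_labels_follow_step_change_with_lag(self):
        """On a step change the confirmed label never flips before the step.

        The latency floor is a property of the trailing window plus the
        agreement rule, so the stream is decoded with an accurate analytic
        rule (POz alpha-to-beta power ratio, threshold calibrated on a
        separate labeled recording) rather than a trained network: before
        the change every window contains only the old class, so no
        confirmed command of the new class can precede it.
        """
        from mibci.classify import TrainedClassifier
        from mibci.features import band_power, welch_psd
        from mibci.simulate import default_profiles

        # constructed easy scenario: strong alpha ERS, light background, so
        # the analytic rule is unambiguous and only the machinery is tested
        cfg = mibci.SimConfig(seed=21, profiles=default_profiles(ers=8.0),
                              noise_scale=1.0, common_noise_scale=2.0)

        def alpha_beta_ratio(windows, fs):
            out = []
            for w in windows:
                psd = welch_psd(w[5], fs, seg_len=min(512, w.shape[-1]), nfft=512)
                out.append(
                    float(band_power(psd, (8, 13))[0] / band_power(psd, (18, 26))[0])
                )
            return np.asarray(out)

        # calibrate the threshold on a separate labeled recording
        calib_proto = mibci.make_protocol(
            trials=1, class_order=("eyes_closed", "left_hand"), segment_s=15.0
        )
        calib = mibci.simulate_recording(cfg, calib_proto, 0, 1)
        from mibci.evaluate import preprocess_recording

        calib_proc = preprocess_recording(calib, do_rescale=False)
        ep = mibci.segment(calib_proc, mibci.WindowSpec(4.0, 0.5), 2.0)
        r = alpha_beta_ratio(ep.windows, ep.fs)
        thr = np.sqrt(
            r[ep.labels == "eyes_closed"].mean() * r[ep.labels == "left_hand"].mean()
        )
        # the rule must be unambiguous on pure windows of either class
        assert r[ep.labels == "eyes_closed"].min() > thr
        assert r[ep.labels == "left_hand"].max() < thr

        class AlphaRatioRule:
            def predict_proba(self, windows):
                ratios = alpha_beta_ratio(windows, 250.0)
                probs = np.zeros((len(windows), 2))
                probs[ratios >= thr, 0] = 1.0
                probs[ratios < thr, 1] = 1.0
                return probs

        clf = TrainedClassifier(
            family="spatial_cnn",
            model=AlphaRatioRule(),
            spec=None,
            fingerprint={"fs": 250.0, "window_length_s": 4.0, "rescaled": True,
                         "band": (4.0, 33.0)},
            label_map=("eyes_closed", "left_hand"),
        )
        step_rec = mibci.simulate_recording(cfg, calib_proto, 0, 0)
        bounds = (float(calib_proc.data.min()), float(calib_proc.data.max()))
        raw = stream_classify(step_rec, clf, StreamConfig(), rescale_bounds=bounds)
        confirmed = confirm_commands(raw)
        assert confirmed  # the stream does produce commands
        first_flip = next((t for t, c in confirmed if c == "left_hand"), None)
        assert first_flip is not None and first_flip >= 15.0
        # and the change is detected within one window of the step
        assert first_flip <= 15.0 + 4.0 + 0.5
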