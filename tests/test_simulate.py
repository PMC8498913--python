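"""Protocol arithmetic, pink-noise spectra and ERD/ERS modulation."""

import numpy as np
import pytest
from scipy import signal

import mibci
from mibci.features import band_power, welch_psd
from mibci.simulate import (
    BANDS,
    ClassProfile,
    ConfigurationError,
    MontageSpec,
    oscillation_component,
)


class TestProtocol:
    @pytest.mark.parametrize(
        "trials,order,seg,discard,n_segments,trial_s",
        [
            (5, mibci.CLASSES, 60.0, 2.0, 20, 240.0),
            (1, ("eyes_closed",), 60.0, 0.0, 1, 60.0),
            (2, mibci.CLASSES, 10.0, 2.0, 8, 40.0),
        ],
    )
    def test_segment_bookkeeping(self, trials, order, seg, discard, n_segments, trial_s):
        p = mibci.make_protocol(trials, order, seg, discard)
        assert len(p.segments) == n_segments
        assert p.trial_duration == pytest.approx(trial_s)
        per_trial = p.trial_segments(0)
        assert [s.class_id for s in per_trial] == list(order)
        assert per_trial[-1].end == len(order) * seg

    def test_session_starts_eyes_closed(self):
        p = mibci.make_protocol()
        assert p.trial_segments(0)[0].class_id == "eyes_closed"

    def test_contiguous_non_overlapping(self):
        p = mibci.make_protocol(3, mibci.CLASSES, 15.0, 2.0)
        for t in range(3):
            segs = p.trial_segments(t)
            for a, b in zip(segs, segs[1:]):
                assert b.start == a.end

    @pytest.mark.parametrize("kwargs", [dict(trials=0), dict(segment_s=-1.0), dict(segment_s=1.0, discard_s=2.0)])
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            mibci.make_protocol(**kwargs)


class TestPinkNoise:
    def test_white_limit_is_flat(self):
        x = mibci.pink_noise(60, 250, exponent=0.0, scale=1.0, seed=0)
        f, p = signal.welch(x, fs=250, nperseg=1024)
        band = p[(f > 2) & (f < 100)]
        # flat within estimation error: no order-of-magnitude trend
        assert band.max() / band.min() < 10

    def test_deterministic(self):
        a = mibci.pink_noise(5, 500, 1.0, 2.0, seed=42)
        b = mibci.pink_noise(5, 500, 1.0, 2.0, seed=42)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, mibci.pink_noise(5, 500, 1.0, 2.0, seed=43))

    def test_one_over_f_slope(self):
        """Fitted log-log slope over 2-40 Hz ≈ −1 for exponent 1."""
        slopes = []
        for seed in range(50):
            x = mibci.pink_noise(60, 250, 1.0, 1.0, seed=seed)
            f, p = signal.welch(x, fs=250, nperseg=2048)
            m = (f >= 2) & (f <= 40)
            slopes.append(np.polyfit(np.log10(f[m]), np.log10(p[m]), 1)[0])
        assert -1.3 < np.mean(slopes) < -0.7

    def test_rms_scaling(self):
        x = mibci.pink_noise(10, 250, 1.0, scale=3.5, seed=1)
        assert np.sqrt(np.mean(x**2)) == pytest.approx(3.5, rel=1e-9)

    @pytest.mark.parametrize("kwargs", [dict(duration=0), dict(exponent=2.5)])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            mibci.pink_noise(duration=kwargs.get("duration", 1.0), fs=100,
                             exponent=kwargs.get("exponent", 1.0))


class TestSimulateRecording:
    def test_shape_fs_annotations(self, default_recording, short_protocol):
        rec = default_recording
        assert rec.data.shape == (6, int(48 * 500))
        assert rec.fs == 500.0
        total = sum(e - s for s, e, _ in rec.annotations)
        assert total == pytest.approx(rec.duration)

    def test_byte_identical_reproduction(self, short_protocol):
        cfg = mibci.SimConfig(seed=5)
        a = mibci.simulate_recording(cfg, short_protocol, 1, 2)
        b = mibci.simulate_recording(cfg, short_protocol, 1, 2)
        np.testing.assert_array_equal(a.data, b.data)

    def test_distinct_across_trials_and_subjects(self, short_protocol):
        cfg = mibci.SimConfig(seed=5)
        a = mibci.simulate_recording(cfg, short_protocol, 0, 0)
        b = mibci.simulate_recording(cfg, short_protocol, 0, 1)
        c = mibci.simulate_recording(cfg, short_protocol, 1, 0)
        assert not np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_missing_profile_is_configuration_error(self, short_protocol):
        cfg = mibci.SimConfig(seed=0, profiles={})
        with pytest.raises(ConfigurationError):
            mibci.simulate_recording(cfg, short_protocol, 0, 0)

    def test_null_modulation_equalizes_band_power(self):
        """All multipliers 1 → no class leaves a band-power signature."""
        profiles = {c: ClassProfile(c, {}) for c in mibci.CLASSES}
        cfg = mibci.SimConfig(seed=3, profiles=profiles)
        proto = mibci.make_protocol(trials=1, segment_s=12.0)
        rec = mibci.simulate_recording(cfg, proto, 0, 0)
        powers = []
        for start, end, _ in rec.annotations:
            seg = rec.data[:, int((start + 2) * 500) : int(end * 500)]
            psd = welch_psd(seg, 500, seg_len=1024)
            powers.append(band_power(psd, BANDS["mu"]))
        powers = np.asarray(powers)
        # across classes, per-channel mu power varies within estimation error
        assert (powers.max(axis=0) / powers.min(axis=0)).max() < 2.5

    def test_erd_multiplier_scales_component_power(self):
        """Oracle: noise-free oscillation power scales with multiplier²."""
        erd = 0.5
        profiles = {c: ClassProfile(c, {}) for c in mibci.CLASSES}
        profiles["left_hand"] = ClassProfile("left_hand", {("C4", "mu"): erd})
        amps = {"mu": 4.0}
        cfg = mibci.SimConfig(seed=9, profiles=profiles, oscillation_amplitudes=amps)
        proto = mibci.make_protocol(
            trials=1, class_order=("eyes_closed", "left_hand"), segment_s=20.0
        )
        comp = oscillation_component(cfg, proto, 0, 0)
        c4 = cfg.montage.channel_labels.index("C4")
        fs = cfg.fs
        # direct periodogram band power on interior samples (skip crossfade)
        def mu_power(sl):
            f, p = signal.periodogram(comp[c4, sl], fs=fs)
            m = (f >= BANDS["mu"][0]) & (f <= BANDS["mu"][1])
            return np.trapezoid(p[m], f[m])

        base = mu_power(slice(int(2 * fs), int(18 * fs)))
        mod = mu_power(slice(int(22 * fs), int(38 * fs)))
        assert mod / base == pytest.approx(erd**2, rel=0.25)

    def test_alpha_ers_dominates_eyes_closed(self):
        """POz alpha power is highest in the eyes-closed segment, every seed."""
        for seed in range(10):
            cfg = mibci.SimConfig(seed=seed)
            proto = mibci.make_protocol(trials=1, segment_s=12.0)
            rec = mibci.simulate_recording(cfg, proto, 0, 0)
            poz = rec.montage.channel_labels.index("POz")
            by_class = {}
            for start, end, cls in rec.annotations:
                seg = rec.data[poz, int((start + 2) * 500) : int(end * 500)]
                psd = welch_psd(seg, 500, seg_len=1024)
                by_class[cls] = float(band_power(psd, BANDS["alpha"])[0])
            assert max(by_class, key=by_class.get) == "eyes_closed"

    def test_power_linearity_in_amplitude(self):
        """Doubling a band amplitude quadruples the component's band power."""
        proto = mibci.make_protocol(trials=1, segment_s=10.0)
        powers = []
        for amp in (2.0, 4.0):
            cfg = mibci.SimConfig(seed=4, oscillation_amplitudes={"mu": amp})
            comp = oscillation_component(cfg, proto, 0, 0)
            f, p = signal.periodogram(comp[2], fs=500)
            m = (f >= 8) & (f <= 12)
            powers.append(np.trapezoid(p[m], f[m]))
        assert powers[1] / powers[0] == pytest.approx(4.0, rel=0.05)


class TestTypes:
    def test_montage_validation(self):
        with pytest.raises(ConfigurationError):
            MontageSpec(channel_labels=("Fz", "C3"))
        with pytest.raises(ConfigurationError):
            MontageSpec(channel_labels=("Fz",) * 6)

    def test_profile_validation(self):
        with pytest.raises(ConfigurationError):
            ClassProfile("left_hand", {("C4", "mu"): -1.0})
        with pytest.raises(ConfigurationError):
            ClassProfile("left_hand", {("C4", "gamma"): 1.2})
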