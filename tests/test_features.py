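import numpy as np
import pytest

from respemg import envelope as ev
from respemg import features as ft
from respemg import synthgen
from respemg.envelope import Envelope
from respemg.signal_core import Signal
from respemg.synthgen import BreathPattern


def make_env(samples, fs=1000, corrected=True, noise=0.1):
    return Envelope(
        np.asarray(samples, dtype=float), fs=fs, method="rms", window_ms=250,
        baseline_corrected=corrected, noise_floor=noise,
    )


def triangle_env(fs=1000):
    """Rises 0→1 µV over [0,1] s, falls 1→0 over [1,2] s."""
    up = np.linspace(0, 1, fs, endpoint=False)
    down = np.linspace(1, 0, fs + 1)
    return make_env(np.concatenate([up, down]), fs=fs)


class TestDetectOffset70:
    def test_triangle_closed_form(self):
        env = triangle_env()
        offset, crossed = ft.detect_offset_70(env, (0.0, 2.0))
        assert crossed
        assert offset == pytest.approx(1.3, abs=2e-3)

    def test_plateau_then_step(self):
        x = np.concatenate([np.zeros(100), np.full(300, 1.0), np.full(100, 0.5)])
        env = make_env(x, fs=1000)
        offset, crossed = ft.detect_offset_70(env, (0.0, 0.5))
        assert crossed
        # first sub-threshold sample is at index 400 (interpolated just before)
        assert 0.395 <= offset <= 0.401

    def test_never_reaches_falls_back_to_minimum(self):
        x = np.concatenate([np.linspace(0, 1, 200), np.full(300, 0.9)])
        env = make_env(x, fs=1000)
        offset, crossed = ft.detect_offset_70(env, (0.0, 0.5))
        assert not crossed

    def test_raised_cosine_closed_form(self):
        # decay (1 + cos(πu/td))/2 crosses 0.7 at u = td·acos(0.4)/π
        fs = 1000
        _, gt = synthgen.simulate_emg(BreathPattern(), 20.0, fs, seed=1)
        act = gt.activation
        env = make_env(act.samples, fs=fs)
        onset, peak, _ = gt.breaths[1]
        next_onset = gt.breaths[2][0]
        td = 0.25 * 4.0  # decay time on a 4 s cycle
        expected = peak + td * np.arccos(0.4) / np.pi
        offset, crossed = ft.detect_offset_70(env, (onset, next_onset))
        assert crossed
        assert abs(offset - expected) <= 0.030


class TestDetectBreaths:
    def test_flat_envelope(self):
        assert ft.detect_breaths(make_env(np.zeros(5000)), noise=0.1) == []

    def test_short_blip_rejected(self):
        x = np.zeros(5000)
        x[2000:2100] = 5.0  # 100 ms blip
        assert ft.detect_breaths(make_env(x), noise=0.1) == []

    def test_sustained_burst_detected(self):
        x = np.zeros(5000)
        x[2000:3000] = 5.0
        breaths = ft.detect_breaths(make_env(x), noise=0.1)
        assert len(breaths) == 1
        assert breaths[0].onset_s == pytest.approx(2.0, abs=0.002)

    def test_uncorrected_envelope_rejected(self):
        env = make_env(np.zeros(5000), corrected=False)
        with pytest.raises(ValueError, match="baseline-corrected"):
            ft.detect_breaths(env, noise=0.1)

    def test_nesting_of_thresholds(self, wavelet_result):
        env = wavelet_result.envelopes["emg"]
        noise = env.noise_floor
        loose = ft.detect_breaths(env, noise, onset_k=3)
        strict = ft.detect_breaths(env, noise, onset_k=5)
        # every strict breath overlaps a loose one
        for b in strict:
            assert any(
                a.onset_s <= b.peak_s <= a.offset_s or a.onset_s <= b.onset_s <= a.offset_s
                for a in loose
            )


class TestAmplitude:
    def test_plateau(self):
        env = make_env(np.full(2000, 5.0))
        b = ft.Breath(onset_s=0.1, peak_s=1.0, offset_s=1.9)
        assert ft.breath_amplitude(env, b, method="minmax") == pytest.approx(0.0)
        assert ft.breath_amplitude(env, b, method="minmax", include_baseline=True) == 5.0

    def test_percentile_robust_to_spike(self):
        x = np.full(2000, 5.0)
        x[1000] = 50.0
        env = make_env(x)
        b = ft.Breath(onset_s=0.1, peak_s=1.0, offset_s=1.9)
        assert ft.breath_amplitude(env, b, method="minmax", include_baseline=True) == 50.0
        assert ft.breath_amplitude(env, b, method="p95_p5", include_baseline=True) == pytest.approx(5.0, rel=0.01)

    def test_homogeneity(self, rng):
        x = np.abs(rng.normal(size=3000))
        b = ft.Breath(onset_s=0.5, peak_s=1.5, offset_s=2.5)
        a1 = ft.breath_amplitude(make_env(x), b)
        a2 = ft.breath_amplitude(make_env(2 * x), b)
        assert a2 == pytest.approx(2 * a1, rel=1e-9)


class TestNormalization:
    def test_recording_max(self):
        np.testing.assert_allclose(
            ft.normalize_amplitudes([2, 4, 8], mode="recording_max"), [0.25, 0.5, 1.0]
        )

    def test_max_maneuver(self):
        np.testing.assert_allclose(
            ft.normalize_amplitudes([2, 4, 8], mode="max_maneuver", reference=10),
            [0.2, 0.4, 0.8],
        )

    def test_all_equal(self):
        np.testing.assert_allclose(
            ft.normalize_amplitudes([3, 3, 3], mode="recording_max"), [1, 1, 1]
        )

    def test_bad_reference(self):
        with pytest.raises(ValueError):
            ft.normalize_amplitudes([1, 2], mode="max_maneuver", reference=0)


class TestEtp:
    def test_rectangle(self):
        x = np.zeros(3000)
        x[1000:2001] = 5.0
        env = make_env(x)
        b = ft.Breath(onset_s=1.0, peak_s=1.5, offset_s=2.0)
        assert ft.emg_time_product(env, b) == pytest.approx(5.0, rel=0.01)

    def test_triangle_area(self):
        env = triangle_env()
        b = ft.Breath(onset_s=0.0, peak_s=1.0, offset_s=2.0)
        assert ft.emg_time_product(env, b) == pytest.approx(1.0, rel=0.01)

    def test_baseline_additivity(self):
        x = np.zeros(3000)
        x[500:2501] = 1.0  # constant 1 µV over 2 s
        with_offset = make_env(x)
        without = make_env(np.zeros(3000))
        b = ft.Breath(onset_s=0.5, peak_s=1.5, offset_s=2.5)
        diff = ft.emg_time_product(with_offset, b) - ft.emg_time_product(without, b)
        assert diff == pytest.approx(2.0, rel=0.01)

    def test_uncorrected_rejected(self):
        env = make_env(np.ones(3000), corrected=False)
        b = ft.Breath(onset_s=0.5, peak_s=1.5, offset_s=2.5)
        with pytest.raises(ValueError):
            ft.emg_time_product(env, b)
        assert ft.emg_time_product(env, b, include_baseline=True) > 0

    def test_per_minute_binning(self):
        env = make_env(np.full(130_000, 1.0), fs=1000)
        breaths = [
            ft.Breath(onset_s=float(t), peak_s=t + 1.0, offset_s=t + 2.0)
            for t in (10, 30, 70, 100, 125)
        ]
        by_min = ft.etp_per_minute(env, breaths)
        assert set(by_min) == {0, 1, 2}
        assert by_min[0] == pytest.approx(4.0, rel=0.01)  # two 2 s breaths
        assert by_min[1] == pytest.approx(4.0, rel=0.01)
        assert by_min[2] == pytest.approx(2.0, rel=0.01)


class TestNme:
    def _paw(self, deflection=10.0):
        x = np.zeros(10_000)
        x[4000:6000] = -deflection * np.sin(np.linspace(0, np.pi, 2000))
        return Signal(x, fs=1000, kind="pressure")

    def _env(self, peak=5.0):
        x = np.zeros(10_000)
        x[4000:6000] = peak * np.sin(np.linspace(0, np.pi, 2000))
        return make_env(x)

    def test_arithmetic(self):
        est = ft.estimate_nme_occlusion(self._paw(10), self._env(5), (4.0, 6.0),
                                        correction=0.8)
        assert est.k == pytest.approx(1.6, rel=1e-6)

    def test_correction_linearity(self):
        e7 = ft.estimate_nme_occlusion(self._paw(), self._env(), (4.0, 6.0), correction=0.7)
        e8 = ft.estimate_nme_occlusion(self._paw(), self._env(), (4.0, 6.0), correction=0.8)
        assert e7.k / e8.k == pytest.approx(7 / 8, rel=1e-9)

    def test_no_deflection_error(self):
        with pytest.raises(ValueError, match="no occlusion effort"):
            ft.estimate_nme_occlusion(self._paw(0.1), self._env(), (4.0, 6.0))

    def test_recovery_from_synthetic_occlusions(self, default_scene, wavelet_result):
        mixed, gt = default_scene
        k_true = 2.0
        occl = (3, 7, 11)
        paw = synthgen.simulate_ventilator(
            gt.breaths, 1000, 60.0, occlusion_breath_indices=occl,
            k_true=k_true, activation=gt.activation,
        )
        env = wavelet_result.envelopes["emg"]
        ks = []
        for i in occl:
            onset, _, offset = gt.breaths[i]
            est = ft.estimate_nme_occlusion(paw, env, (onset - 0.2, offset + 0.3),
                                            correction=1.0)
            ks.append(est.k)
        assert abs(np.mean(ks) - k_true) <= 0.10 * k_true


class TestPmus:
    def test_arithmetic(self):
        env = make_env(np.full(100, 5.0))
        pmus = ft.pmus_waveform(env, 1.6)
        assert pmus.samples.max() == pytest.approx(8.0)
        assert pmus.kind == "pressure"

    def test_k_zero_rejected(self):
        with pytest.raises(ValueError):
            ft.pmus_waveform(make_env(np.ones(10)), 0.0)

    def test_end_to_end_peaks(self, default_scene, wavelet_result):
        _, gt = default_scene
        k_true = 2.0
        env = wavelet_result.envelopes["emg"]
        pmus = ft.pmus_waveform(env, k_true)
        for b in wavelet_result.breaths["emg"]:
            i = int(b.peak_s * 1000)
            expected = k_true * gt.activation.samples[i]
            assert abs(pmus.samples[i] - expected) <= 0.20 * expected


class TestTiming:
    def test_positive_delay(self):
        tc = ft.timing_compare(10.0, 10.25, 2.0)
        assert tc.delay_ms == pytest.approx(250)
        assert tc.phase_angle_deg == pytest.approx(45)

    def test_zero_delay(self):
        tc = ft.timing_compare(5.0, 5.0, 3.0)
        assert tc.delay_ms == 0
        assert tc.phase_angle_deg == 0

    def test_vent_precedes(self):
        tc = ft.timing_compare(8.0, 7.9, 4.0)
        assert tc.delay_ms == pytest.approx(-100)
        assert tc.phase_angle_deg == pytest.approx(-9)

    def test_invalid_cycle(self):
        with pytest.raises(ValueError):
            ft.timing_compare(0, 1, 0)


class TestTimeToPeak:
    def test_simple(self):
        b = ft.Breath(onset_s=10.0, peak_s=10.8, offset_s=11.5)
        assert ft.time_to_peak(b) == pytest.approx(0.8)

    def test_raised_cosine_duty(self):
        # duty 0.4 on a 4 s cycle: activation peaks 1.6 s after onset
        _, gt = synthgen.simulate_emg(BreathPattern(), 20.0, 1000, seed=2)
        onset, peak, _ = gt.breaths[1]
        assert peak - onset == pytest.approx(1.6, abs=0.05)

    def test_degenerate(self):
        with pytest.raises(ValueError):
            ft.Breath(onset_s=1.0, peak_s=1.0, offset_s=1.0)


class TestScalingInvariants:
    def test_amplitude_and_etp_homogeneous_timing_invariant(self, rng):
        x = np.abs(rng.normal(size=4000)) + 0.01
        b = ft.Breath(onset_s=0.5, peak_s=2.0, offset_s=3.5)
        e1, e2 = make_env(x), make_env(3 * x)
        assert ft.emg_time_product(e2, b) == pytest.approx(3 * ft.emg_time_product(e1, b))
        assert ft.breath_amplitude(e2, b) == pytest.approx(3 * ft.breath_amplitude(e1, b))


class TestStaircaseRecovery:
    def test_amplitude_tracks_activation(self):
        # three-level amplitude staircase 2/5/8 µV through the wavelet preset
        from respemg import pipelines as pl
        from respemg.signal_core import Recording

        rng = np.random.default_rng(42)
        segments, act_peaks = [], []
        for amp in (2.0, 5.0, 8.0):
            pat = BreathPattern(peak_rms_uv=amp)
            clean, g = synthgen.simulate_emg(pat, 20.0, 1000, seed=rng)
            m, g = synthgen.mix(clean, synthgen.ContaminationSpec(), seed=rng,
                                ground_truth=g)
            segments.append(m.samples)
            act_peaks += [amp] * len(g.breaths)
        sig = Signal(np.concatenate(segments), fs=1000, label="emg", kind="emg")
        res = pl.run_pipeline(Recording.from_signals([sig]),
                              pl.preset_config("wavelet", fs=1000.0))
        table = res.features
        assert table is not None and len(table) >= 10
        # per-breath amplitude vs the programmed staircase level
        levels = []
        for onset in table["onset_s"]:
            levels.append((2.0, 5.0, 8.0)[min(int(onset // 20), 2)])
        r = np.corrcoef(table["amplitude_uv"], levels)[0, 1]
        assert r >= 0.8


class TestVentMatching:
    def test_pairing_and_unmatched(self):
        breaths = [
            ft.Breath(onset_s=t, peak_s=t + 1, offset_s=t + 2) for t in (0.0, 4.0, 8.0)
        ]
        vent = np.array([0.2, 4.3])
        pairs, unmatched = ft.match_breaths_to_vent(breaths, vent, cycle_s=4.0)
        assert len(pairs) == 2
        assert unmatched == 1
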