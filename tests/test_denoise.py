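import numpy as np
import pytest

from respemg import denoise as dn
from respemg import synthgen
from respemg.signal_core import Signal
from respemg.synthgen import BreathPattern, ContaminationSpec


def _rms(x):
    return np.sqrt(np.mean(np.square(x)))


class TestHighpass:
    def test_dc_rejection(self):
        sig = Signal(np.full(5000, 5.0), fs=1000)
        out = dn.highpass(sig, 20)
        assert np.max(np.abs(out.samples)) < 0.05

    def test_passband_flat(self, make_sine):
        sig = make_sine(100, 1000, 5.0)
        out = dn.highpass(sig, 20)
        assert abs(_rms(out.samples) / _rms(sig.samples) - 1) < 0.01

    def test_high_cutoff_data_check_mode(self, make_sine):
        # 200 Hz cutoff is legitimate; a 1 Hz sine must drop > 60 dB
        sig = make_sine(1, 1000, 10.0)
        out = dn.highpass(sig, 200)
        assert _rms(out.samples) < 1e-3 * _rms(sig.samples)

    def test_cutoff_beyond_nyquist(self, make_sine):
        with pytest.raises(ValueError):
            dn.highpass(make_sine(10, 1000, 1.0), 600)


class TestNotch:
    def test_mains_suppressed(self, make_sine):
        # steady-state response: exclude the 0.5 s edge-transient regions
        sig = make_sine(50, 1000, 5.0)
        out = dn.notch_mains(sig, 50)
        assert _rms(out.samples[500:-500]) < 0.03 * _rms(sig.samples)

    def test_neighbors_untouched(self, make_sine):
        sig = make_sine(100, 1000, 5.0)
        out = dn.notch_mains(sig, 50)
        assert abs(_rms(out.samples) / _rms(sig.samples) - 1) < 0.02

    def test_invalid_frequency(self, make_sine):
        with pytest.raises(ValueError):
            dn.notch_mains(make_sine(10, 1000, 1.0), 70)


class TestRPeaks:
    def test_clean_ecg(self):
        ecg, truth = synthgen.simulate_ecg(60, 100.0, 1000, 30.0, seed=0)
        rp = dn.detect_r_peaks(ecg)
        assert abs(len(rp) - 30) <= 1
        for t in truth:
            assert np.min(np.abs(rp.times_s - t)) <= 0.010

    @pytest.mark.parametrize("hr", [50, 80, 120])
    def test_timing_error_across_rates(self, hr):
        clean, gt = synthgen.simulate_emg(BreathPattern(), 60.0, 1000, seed=hr)
        mixed, gt = synthgen.mix(
            clean, ContaminationSpec(heart_rate_bpm=hr, hr_jitter=0.03),
            seed=hr, ground_truth=gt,
        )
        rp = dn.detect_r_peaks(dn.highpass(mixed, 20))
        errs = [np.min(np.abs(rp.times_s - t)) for t in gt.rpeak_times]
        assert np.median(errs) < 0.010

    def test_flat_signal(self):
        rp = dn.detect_r_peaks(Signal(np.zeros(10_000), fs=1000))
        assert len(rp) == 0
        assert rp.warning is not None

    def test_too_short(self):
        with pytest.raises(ValueError, match="5 s"):
            dn.detect_r_peaks(Signal(np.random.default_rng(0).normal(size=1000), fs=1000))

    def test_rate_flagging(self):
        rp = dn.RPeakList(times_s=[1.0, 1.1, 1.2])  # 600 bpm implied
        assert rp.warning is not None


@pytest.fixture(scope="module")
def mixed_scene():
    return synthgen.default_scene(seed=21)


class TestGating:

    def test_locality(self, mixed_scene):
        mixed, gt = mixed_scene
        hp = dn.highpass(mixed, 20)
        rp = dn.RPeakList(gt.rpeak_times)
        gated, mask = dn.gate_ecg(hp, rp, fill="zeros", assume_highpassed=True)
        in_gate = np.zeros(hp.n, bool)
        for a, b in mask.intervals:
            in_gate[int(np.ceil(a * 1000 - 1e-9)) : int(np.ceil(b * 1000 - 1e-9))] = True
        np.testing.assert_array_equal(gated.samples[~in_gate], hp.samples[~in_gate])

    def test_gated_fraction(self):
        ecg, truth = synthgen.simulate_ecg(60, 100.0, 1000, 60.0, seed=1)
        hp = dn.highpass(ecg, 20)
        gated, mask = dn.gate_ecg(hp, dn.RPeakList(truth), window_ms=150,
                                  assume_highpassed=True)
        expected = len(truth) * 0.150 / 60.0
        assert abs(mask.gated_fraction(60.0) - expected) <= 0.150 / 60.0

    def test_zeros_fill_removes_power(self, mixed_scene):
        mixed, gt = mixed_scene
        hp = dn.highpass(mixed, 20)
        gated, _ = dn.gate_ecg(hp, dn.RPeakList(gt.rpeak_times), fill="zeros",
                               assume_highpassed=True)
        assert _rms(gated.samples) < _rms(hp.samples)

    @pytest.mark.parametrize("fill", ["zeros", "hold", "linear", "median"])
    def test_fill_methods_finite(self, mixed_scene, fill):
        mixed, gt = mixed_scene
        gated, _ = dn.gate_ecg(mixed, dn.RPeakList(gt.rpeak_times), fill=fill)
        assert np.all(np.isfinite(gated.samples))

    def test_tachycardia_regime_rejected(self):
        sig = Signal(np.random.default_rng(0).normal(size=10_000), fs=1000)
        fast = dn.RPeakList(np.arange(0.5, 9.5, 0.25))  # 240 bpm
        with pytest.raises(ValueError, match="tachycardia"):
            dn.gate_ecg(sig, fast, window_ms=300, assume_highpassed=True)

    def test_bad_fill(self):
        sig = Signal(np.zeros(5000), fs=1000)
        with pytest.raises(ValueError):
            dn.gate_ecg(sig, dn.RPeakList([1.0]), fill="cubic")


class TestWaveletLevels:
    @pytest.mark.parametrize("fs,expected", [(1000, 5), (500, 4), (2000, 6), (1400, 5)])
    def test_rule(self, fs, expected):
        assert dn.choose_wavelet_levels(fs) == expected

    def test_low_fs(self):
        with pytest.raises(ValueError):
            dn.choose_wavelet_levels(200)


class TestWaveletDenoise:
    def test_pure_emg_preserved(self):
        sig, _ = synthgen.simulate_emg(BreathPattern(), 30.0, 1000, seed=31)
        out = dn.wavelet_denoise(sig, dn.WaveletPlan())
        assert abs(_rms(out.samples) / _rms(sig.samples) - 1) < 0.10
        assert np.corrcoef(out.samples, sig.samples)[0, 1] >= 0.9

    def test_mad_option_still_suppresses_qrs(self, mixed_scene):
        mixed, gt = mixed_scene
        out = dn.wavelet_denoise(mixed, dn.WaveletPlan(sigma_estimator="mad"))
        near_r = np.zeros(mixed.n, bool)
        for r in gt.rpeak_times:
            near_r[max(int((r - 0.075) * 1000), 0) : int((r + 0.075) * 1000)] = True
        assert _rms(out.samples[near_r]) < 0.3 * _rms(mixed.samples[near_r])

    def test_infinite_multiplier_removes_only_approximation(self):
        rng = np.random.default_rng(0)
        sig = Signal(rng.normal(size=8192), fs=1000)
        plan = dn.WaveletPlan(threshold_multiplier=1e12)
        out = dn.wavelet_denoise(sig, plan)
        # residual = approximation band only: low-frequency, small for white noise
        residual = sig.samples - out.samples
        from scipy import signal as sps

        f, p = sps.welch(residual, fs=1000, nperseg=1024)
        in_band = np.trapezoid(p[f <= 1000 / 2**6], f[f <= 1000 / 2**6])
        assert in_band / np.trapezoid(p, f) > 0.9

    def test_idempotent_without_ecg(self):
        sig, _ = synthgen.simulate_emg(BreathPattern(), 30.0, 1000, seed=32)
        once = dn.wavelet_denoise(sig, dn.WaveletPlan())
        twice = dn.wavelet_denoise(once, dn.WaveletPlan())
        assert abs(_rms(twice.samples) - _rms(once.samples)) < 0.05 * _rms(once.samples)

    def test_too_many_levels(self):
        sig = Signal(np.random.default_rng(0).normal(size=64), fs=1000)
        with pytest.raises(ValueError, match="levels"):
            dn.wavelet_denoise(sig, dn.WaveletPlan(n_levels=10))

    @pytest.mark.parametrize("wavelet", ["db2", "db4"])
    def test_perfect_reconstruction(self, wavelet):
        rng = np.random.default_rng(1)
        x = rng.normal(size=4096)
        a, d = dn._swt_analyze(x, wavelet, 5)
        y = dn._swt_synthesize(a, d, wavelet)
        np.testing.assert_allclose(y, x, atol=1e-9)

    def test_plan_validation(self):
        with pytest.raises(ValueError):
            dn.WaveletPlan(wavelet="haar")
        with pytest.raises(ValueError):
            dn.WaveletPlan(threshold_multiplier=0)


class TestZeroPhase:
    """All filters must leave a band-limited burst's timing untouched."""

    @pytest.mark.parametrize(
        "op",
        [
            lambda s: dn.highpass(s, 20),
            lambda s: dn.notch_mains(s, 50),
        ],
    )
    def test_no_lag(self, op):
        fs = 1000
        t = np.arange(4000) / fs
        burst = np.sin(2 * np.pi * 80 * t) * np.exp(-0.5 * ((t - 2.0) / 0.2) ** 2)
        sig = Signal(burst, fs=fs)
        out = op(sig)
        lag = np.argmax(np.correlate(out.samples, sig.samples, "full")) - (sig.n - 1)
        assert lag == 0
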