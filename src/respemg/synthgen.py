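"""Synthetic respiratory sEMG generator with full ground truth.

Produces band-limited (25–250 Hz) amplitude-modulated EMG bursts at the
1–10 µV scale, optionally contaminated with a PQRST cardiac artifact,
sinusoidal baseline wander, mains interference and broadband noise, plus a
pneumatic ventilator-pressure channel.  Every generator returns the hidden
state (clean EMG, activation profile, R-peak times, breath landmarks, true
neuromechanical conversion factor) so downstream stages have an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signal_core import Signal

__all__ = [
    "BreathPattern",
    "ContaminationSpec",
    "GroundTruth",
    "simulate_emg",
    "simulate_ecg",
    "mix",
    "simulate_ventilator",
    "default_scene",
    "DEFAULT_BAND_HZ",
]

DEFAULT_BAND_HZ = (25.0, 250.0)

#: Fraction of the respiratory cycle over which activation decays after the
#: inspiratory peak (raised-cosine shape); the 70 %-of-peak offset has a
#: closed-form location on this decay.
DECAY_FRACTION = 0.25


@dataclass
class BreathPattern:
    """Respiratory activation pattern parameters."""

    respiratory_rate: float = 15.0  # breaths/min
    duty_cycle: float = 0.4  # inspiratory fraction of the cycle
    activation_shape: str = "raised_cosine"  # or "trapezoid"
    peak_rms_uv: float = 5.0  # target in-breath 250 ms RMS
    breath_jitter: float = 0.0  # CV of cycle duration

    def __post_init__(self) -> None:
        if not self.respiratory_rate > 0:
            raise ValueError("respiratory_rate must be positive")
        if not 0 < self.duty_cycle < 1:
            raise ValueError("duty_cycle must lie in (0, 1)")
        if self.peak_rms_uv < 0:
            raise ValueError("peak_rms_uv must be nonnegative")
        if self.activation_shape not in ("raised_cosine", "trapezoid"):
            raise ValueError(f"unknown activation_shape {self.activation_shape!r}")


@dataclass
class ContaminationSpec:
    """Amplitudes and rates of the contaminant components."""

    ecg_amplitude_uv: float = 100.0  # R-wave peak
    heart_rate_bpm: float = 70.0
    hr_jitter: float = 0.0  # CV of beat interval
    wander_amplitude_uv: float = 20.0
    wander_freq_hz: float = 0.3
    mains_freq_hz: float = 50.0
    mains_amplitude_uv: float = 5.0
    white_noise_sd_uv: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "ecg_amplitude_uv",
            "wander_amplitude_uv",
            "mains_amplitude_uv",
            "white_noise_sd_uv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.mains_freq_hz not in (50.0, 60.0, 50, 60):
            raise ValueError("mains_freq_hz must be 50 or 60")
        if self.wander_freq_hz > 0.5:
            raise ValueError("wander_freq_hz must be ≤ 0.5 Hz")


@dataclass
class GroundTruth:
    """Hidden generator state used as the downstream test oracle."""

    clean_emg: Signal | None = None
    activation: Signal | None = None  # modulating envelope, µV RMS scale
    rpeak_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    breaths: list[tuple[float, float, float]] = field(default_factory=list)
    k_true: float | None = None  # cmH2O/µV, when a ventilator channel exists
    noise_floor_sd_uv: float = 0.0

    def __post_init__(self) -> None:
        self.rpeak_times = np.asarray(self.rpeak_times, dtype=np.float64)
        if self.rpeak_times.size > 1 and not np.all(np.diff(self.rpeak_times) > 0):
            raise ValueError("rpeak_times must be strictly increasing")
        for onset, peak, offset in self.breaths:
            if not (onset < peak <= offset):
                raise ValueError(
                    f"breath landmarks must satisfy onset < peak ≤ offset, "
                    f"got ({onset}, {peak}, {offset})"
                )
        if self.activation is not None and np.any(self.activation.samples < -1e-12):
            raise ValueError("activation must be nonnegative")


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------


def _activation_profile(
    pattern: BreathPattern, duration_s: float, fs: float, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[float, float, float]]]:
    """Nonnegative activation profile (peak 1) and breath landmark triples."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    act = np.zeros(n)
    breaths: list[tuple[float, float, float]] = []

    mean_cycle = 60.0 / pattern.respiratory_rate
    start = 0.0
    while start < duration_s:
        cycle = mean_cycle
        if pattern.breath_jitter > 0:
            cycle = mean_cycle * max(
                0.2, 1.0 + pattern.breath_jitter * rng.standard_normal()
            )
        ti = pattern.duty_cycle * cycle  # inspiratory (rise) time
        td = DECAY_FRACTION * cycle  # decay time after peak
        peak_t = start + ti
        end_t = peak_t + td
        if peak_t >= duration_s:
            break

        seg = (t >= start) & (t < peak_t)
        if pattern.activation_shape == "raised_cosine":
            act[seg] = 0.5 * (1.0 - np.cos(np.pi * (t[seg] - start) / ti))
        else:  # trapezoid: linear rise over first 30 % of ti, then plateau
            rise = 0.3 * ti
            u = t[seg] - start
            act[seg] = np.minimum(u / rise, 1.0)
        seg = (t >= peak_t) & (t < end_t)
        if pattern.activation_shape == "raised_cosine":
            act[seg] = 0.5 * (1.0 + np.cos(np.pi * (t[seg] - peak_t) / td))
        else:
            act[seg] = 1.0 - (t[seg] - peak_t) / td

        breaths.append((start, peak_t, min(end_t, duration_s)))
        start += cycle

    return act, breaths


def simulate_emg(
    pattern: BreathPattern,
    duration_s: float,
    fs: float,
    seed: int | np.random.Generator = 0,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
) -> tuple[Signal, GroundTruth]:
    """Band-limited Gaussian noise modulated by a respiratory activation profile.

    The carrier is white Gaussian noise band-passed to ``band_hz`` with a
    4th-order zero-phase Butterworth and normalized to unit RMS, so the
    activation profile *is* the local RMS: in-breath 250 ms RMS peaks at
    ``pattern.peak_rms_uv`` in expectation.
    """
    if fs < 500:
        raise ValueError(
            f"fs must be at least 500 Hz for respiratory sEMG (25–250 Hz "
            f"spectral content); got {fs}"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(duration_s * fs))

    noise = rng.standard_normal(n)
    lo, hi = band_hz
    hi = min(hi, 0.49 * fs)
    sos = sps.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    carrier = sps.sosfiltfilt(sos, noise)
    carrier /= np.std(carrier)

    act, breaths = _activation_profile(pattern, duration_s, fs, rng)
    act = act * pattern.peak_rms_uv
    emg = carrier * act

    sig = Signal(emg, fs=fs, label="emg", kind="emg")
    gt = GroundTruth(
        clean_emg=sig,
        activation=Signal(act, fs=fs, label="activation", kind="other"),
        breaths=breaths,
    )
    return sig, gt


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------

# Gaussian PQRST template: (latency_s relative to R, amplitude relative to R,
# full width at half maximum in s).  Only the R amplitude, rate and jitter
# are user-facing.
_PQRST = (
    (-0.170, 0.15, 0.040),  # P
    (-0.030, -0.12, 0.025),  # Q
    (0.000, 1.00, 0.025),  # R
    (0.030, -0.25, 0.025),  # S
    (0.250, 0.35, 0.070),  # T
)


def simulate_ecg(
    heart_rate_bpm: float,
    amplitude_uv: float,
    fs: float,
    duration_s: float,
    seed: int | np.random.Generator = 0,
    hr_jitter: float = 0.0,
) -> tuple[Signal, np.ndarray]:
    """Gaussian-deflection PQRST train; returns the signal and exact R apexes."""
    if not 30 <= heart_rate_bpm <= 220:
        raise ValueError(
            f"heart_rate_bpm must lie in [30, 220], got {heart_rate_bpm}"
        )
    if amplitude_uv < 0:
        raise ValueError("amplitude_uv must be nonnegative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    ecg = np.zeros(n)

    mean_rr = 60.0 / heart_rate_bpm
    rpeaks = []
    beat = 0.5 * mean_rr  # first beat clear of the edge
    while beat < duration_s - 0.3:
        rpeaks.append(beat)
        rr = mean_rr
        if hr_jitter > 0:
            rr = mean_rr * max(0.3, 1.0 + hr_jitter * rng.standard_normal())
        beat += rr
    rpeaks = np.asarray(rpeaks)

    for r in rpeaks:
        for lat, rel_amp, fwhm in _PQRST:
            sigma = fwhm / 2.3548  # FWHM → Gaussian σ
            center = r + lat
            lo = max(int((center - 5 * sigma) * fs), 0)
            hi = min(int((center + 5 * sigma) * fs) + 1, n)
            ecg[lo:hi] += (
                amplitude_uv
                * rel_amp
                * np.exp(-0.5 * ((t[lo:hi] - center) / sigma) ** 2)
            )

    return Signal(ecg, fs=fs, label="ecg", kind="emg"), rpeaks


# ---------------------------------------------------------------------------
# Mixing and ventilator
# ---------------------------------------------------------------------------


def mix(
    emg: Signal,
    contamination: ContaminationSpec,
    seed: int | np.random.Generator = 0,
    ground_truth: GroundTruth | None = None,
) -> tuple[Signal, GroundTruth]:
    """Clean EMG + ECG + baseline wander + mains + white noise.

    Components are generated independently, so sample variances add.  The
    returned ground truth carries the R-peak times and the white-noise SD.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    c = contamination
    n = emg.n
    fs = emg.fs
    t = np.arange(n) / fs
    duration = n / fs

    total = emg.samples.copy()
    rpeaks = np.empty(0)
    if c.ecg_amplitude_uv > 0:
        ecg, rpeaks = simulate_ecg(
            c.heart_rate_bpm, c.ecg_amplitude_uv, fs, duration, rng, c.hr_jitter
        )
        total += ecg.samples
    if c.wander_amplitude_uv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        total += c.wander_amplitude_uv * np.sin(2 * np.pi * c.wander_freq_hz * t + phase)
    if c.mains_amplitude_uv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        total += c.mains_amplitude_uv * np.sin(2 * np.pi * c.mains_freq_hz * t + phase)
    if c.white_noise_sd_uv > 0:
        total += c.white_noise_sd_uv * rng.standard_normal(n)

    gt = ground_truth if ground_truth is not None else GroundTruth(clean_emg=emg)
    gt.rpeak_times = rpeaks
    gt.noise_floor_sd_uv = c.white_noise_sd_uv
    return Signal(total, fs=fs, label=emg.label or "emg", kind="emg"), gt


def simulate_ventilator(
    breaths: list[tuple[float, float, float]],
    fs: float,
    duration_s: float,
    trigger_delay_ms: float = 100.0,
    cycle_delay_ms: float = 100.0,
    occlusion_breath_indices: tuple[int, ...] = (),
    k_true: float | None = None,
    activation: Signal | None = None,
    support_cmh2o: float = 10.0,
) -> Signal:
    """Airway-pressure channel tracking the breath landmarks.

    Normal breaths get a square-ish pressurization ramp from
    ``onset + trigger_delay`` to ``offset + cycle_delay`` (50 ms rise/fall).
    Occlusion breaths instead show a negative deflection equal to
    ``−k_true × activation`` — an end-expiratory occlusion maneuver.
    """
    if not np.isfinite(trigger_delay_ms) or not np.isfinite(cycle_delay_ms):
        raise ValueError("delays must be finite")
    for idx in occlusion_breath_indices:
        if not 0 <= idx < len(breaths):
            raise ValueError(
                f"occlusion breath index {idx} out of range for {len(breaths)} breaths"
            )
    if occlusion_breath_indices and (k_true is None or k_true <= 0):
        raise ValueError("occlusion breaths require k_true > 0")
    if occlusion_breath_indices and activation is None:
        raise ValueError("occlusion breaths require the activation profile")

    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    paw = np.zeros(n)
    ramp_s = 0.05
    occluded = set(occlusion_breath_indices)

    for i, (onset, _peak, offset) in enumerate(breaths):
        if i in occluded:
            lo = max(int(onset * fs), 0)
            hi = min(int((offset + 0.2) * fs), n)
            paw[lo:hi] -= k_true * activation.samples[lo:hi]
            continue
        start = onset + trigger_delay_ms / 1000.0
        end = offset + cycle_delay_ms / 1000.0
        if start >= duration_s:
            continue
        seg = (t > start) & (t < end)
        shape = np.ones(np.count_nonzero(seg))
        u = t[seg]
        rise = np.clip((u - start) / ramp_s, 0.0, 1.0)
        fall = np.clip((end - u) / ramp_s, 0.0, 1.0)
        paw[seg] = support_cmh2o * shape * np.minimum(rise, fall)

    return Signal(paw, fs=fs, label="paw", kind="pressure")


def default_scene(
    seed: int = 0,
    duration_s: float = 60.0,
    fs: float = 1000.0,
    pattern: BreathPattern | None = None,
    contamination: ContaminationSpec | None = None,
) -> tuple[Signal, GroundTruth]:
    """The reference synthetic scene: 15 breaths/min, duty 0.4, EMG 5 µV,
    ECG R-wave 100 µV, wander 20 µV @ 0.3 Hz, mains 5 µV @ 50 Hz, white
    noise 0.5 µV, at 1000 Hz."""
    rng = np.random.default_rng(seed)
    pattern = pattern or BreathPattern()
    contamination = contamination or ContaminationSpec()
    clean, gt = simulate_emg(pattern, duration_s, fs, rng)
    return mix(clean, contamination, rng, ground_truth=gt)
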