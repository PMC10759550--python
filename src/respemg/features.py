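"""Breath-level parameter extraction.

Breath segmentation on the baseline-corrected envelope, the 70 %-of-peak
offset rule, per-breath magnitude parameters (amplitude, normalization,
EMG-time product), neuromechanical conversion to Pmus via occlusion-derived
efficiency, and patient–ventilator timing metrics (absolute delay, phase
angle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .envelope import Envelope
from .signal_core import Signal

__all__ = [
    "Breath",
    "BreathFeatures",
    "NmeEstimate",
    "TimingComparison",
    "detect_breaths",
    "detect_offset_70",
    "breath_amplitude",
    "normalize_amplitudes",
    "emg_time_product",
    "etp_per_minute",
    "estimate_nme_occlusion",
    "pmus_waveform",
    "timing_compare",
    "time_to_peak",
    "breath_feature_table",
    "detect_pressurization_onsets",
    "match_breaths_to_vent",
]


@dataclass
class Breath:
    """One respiratory cycle's landmark times (seconds, reference clock)."""

    onset_s: float
    peak_s: float
    offset_s: float
    source: str = "envelope"
    peak_value: float = 0.0
    offset_is_70pct: bool = True  # False: fell back to the inter-breath minimum

    def __post_init__(self) -> None:
        if not (self.onset_s < self.peak_s <= self.offset_s):
            raise ValueError(
                f"breath landmarks must satisfy onset < peak ≤ offset, got "
                f"({self.onset_s}, {self.peak_s}, {self.offset_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class BreathFeatures:
    amplitude_uv: float
    etp_uvs: float
    time_to_peak_s: float
    duration_s: float
    amplitude_normalized: float | None = None

    def __post_init__(self) -> None:
        for name in ("amplitude_uv", "etp_uvs", "time_to_peak_s", "duration_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class NmeEstimate:
    """Occlusion-derived neuromechanical efficiency (cmH2O per µV)."""

    k: float
    correction: float
    occlusion_window: tuple[float, float]
    paw_deflection: float
    emg_peak: float

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError("k must be positive")


@dataclass
class TimingComparison:
    """EMG-vs-ventilator event timing.  Positive delay: the ventilator event
    follows the EMG event (EMG precedes)."""

    delay_ms: float
    phase_angle_deg: float
    reference_cycle_s: float
    convention: str = "positive = ventilator event follows EMG event"


# ---------------------------------------------------------------------------
# Segmentation and timing
# ---------------------------------------------------------------------------


def detect_breaths(
    env: Envelope,
    noise: float,
    min_duration_ms: float = 300.0,
    onset_k: float = 3.0,
) -> list[Breath]:
    """Threshold-crossing breath segmentation on a corrected envelope.

    A breath starts where the envelope exceeds ``onset_k × noise`` and stays
    above it for at least ``min_duration_ms``; its peak is the envelope
    maximum of that run and its offset comes from the 70 %-of-peak rule
    (searched up to the next onset).
    """
    if not env.baseline_corrected:
        raise ValueError("detect_breaths requires a baseline-corrected envelope")
    x = env.samples
    thr = onset_k * noise
    if thr <= 0:
        thr = 1e-3 * (x.max() if x.max() > 0 else 1.0)

    above = x > thr
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [x.size]))

    min_run = int(round(min_duration_ms / 1000.0 * env.fs))
    keep = (ends - starts) >= min_run
    starts, ends = starts[keep], ends[keep]

    breaths: list[Breath] = []
    for i, (s, e) in enumerate(zip(starts, ends)):
        onset_t = env.t0 + s / env.fs
        # middle of the maximal run, so a plateau peak lands strictly inside
        maxima = np.flatnonzero(x[s:e] == x[s:e].max())
        peak_i = s + int(maxima[maxima.size // 2])
        if peak_i == s:
            peak_i += 1
        peak_t = env.t0 + peak_i / env.fs
        next_onset = (
            env.t0 + starts[i + 1] / env.fs if i + 1 < starts.size else env.t0 + env.duration
        )
        offset_t, crossed = detect_offset_70(env, (onset_t, next_onset))
        if offset_t <= peak_t:
            offset_t = peak_t
        breaths.append(
            Breath(
                onset_s=onset_t,
                peak_s=peak_t,
                offset_s=offset_t,
                peak_value=float(x[peak_i]),
                offset_is_70pct=crossed,
            )
        )
    return breaths


def detect_offset_70(
    env: Envelope, breath_window: tuple[float, float]
) -> tuple[float, bool]:
    """First time after the in-window peak at which the envelope drops to
    70 % of the peak value, by linear interpolation between samples.

    Returns ``(offset_s, crossed)``; when the envelope never reaches 70 %
    before the window ends, the time of the minimum envelope value in
    between is returned with ``crossed=False``.
    """
    a, b = breath_window
    i0 = env.index_at(a)
    i1 = max(env.index_at(b), i0 + 1)
    x = env.samples[i0 : i1 + 1]
    peak_rel = int(np.argmax(x))
    peak_val = x[peak_rel]
    target = 0.7 * peak_val

    after = x[peak_rel:]
    below = np.flatnonzero(after <= target)
    if below.size == 0:
        j = peak_rel + int(np.argmin(after))
        return env.t0 + (i0 + j) / env.fs, False
    j = int(below[0])
    if j == 0:  # plateau exactly at/below target (degenerate)
        return env.t0 + (i0 + peak_rel) / env.fs, True
    y0, y1 = after[j - 1], after[j]
    frac = 0.0 if y0 == y1 else (y0 - target) / (y0 - y1)
    t = (i0 + peak_rel + j - 1 + frac) / env.fs
    return env.t0 + t, True


def time_to_peak(breath: Breath) -> float:
    """Seconds from onset to envelope peak."""
    return breath.peak_s - breath.onset_s


# ---------------------------------------------------------------------------
# Magnitude parameters
# ---------------------------------------------------------------------------


def _breath_slice(env: Envelope, breath: Breath) -> np.ndarray:
    i0 = env.index_at(breath.onset_s)
    i1 = env.index_at(breath.offset_s) + 1
    x = env.samples[i0:i1]
    if x.size == 0:
        raise ValueError("breath window contains no envelope samples")
    return x


def breath_amplitude(
    env: Envelope,
    breath: Breath,
    method: str = "p95_p5",
    include_baseline: bool = False,
) -> float:
    """Per-breath amplitude, as max − min or the more robust p95 − p5.

    With ``include_baseline`` the minimum (or 5th percentile) is not
    subtracted — on a corrected envelope the baseline is zero, so this
    returns the peak level itself.
    """
    x = _breath_slice(env, breath)
    if method == "minmax":
        return float(x.max()) if include_baseline else float(x.max() - x.min())
    if method == "p95_p5":
        hi = np.percentile(x, 95)
        return float(hi) if include_baseline else float(hi - np.percentile(x, 5))
    raise ValueError(f"unknown amplitude method {method!r}")


def normalize_amplitudes(
    values, mode: str = "recording_max", reference: float | None = None
) -> np.ndarray:
    """Normalize per-breath amplitudes to a maximal maneuver or recording max."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty amplitude series")
    if mode == "max_maneuver":
        if reference is None or reference <= 0:
            raise ValueError("max_maneuver normalization requires a positive reference")
        return values / reference
    if mode == "recording_max":
        peak = values.max()
        if peak <= 0:
            raise ValueError("recording maximum is not positive")
        return values / peak
    raise ValueError(f"unknown normalization mode {mode!r}")


def emg_time_product(
    env: Envelope, breath: Breath, include_baseline: bool = False
) -> float:
    """Trapezoidal area under the envelope over [onset, offset], in µV·s."""
    if not env.baseline_corrected and not include_baseline:
        raise ValueError(
            "emg_time_product requires a baseline-corrected envelope "
            "(or include_baseline=True)"
        )
    x = _breath_slice(env, breath)
    return float(np.trapezoid(x, dx=1.0 / env.fs))


def etp_per_minute(
    env: Envelope, breaths: list[Breath], include_baseline: bool = False
) -> dict[int, float]:
    """Per-time-unit EMG-time product: per-breath ETPs summed over fixed,
    non-overlapping one-minute bins (keyed by minute index of the onset)."""
    out: dict[int, float] = {}
    for b in breaths:
        minute = int((b.onset_s - env.t0) // 60)
        out[minute] = out.get(minute, 0.0) + emg_time_product(env, b, include_baseline)
    return out


# ---------------------------------------------------------------------------
# Neuromechanical conversion
# ---------------------------------------------------------------------------


def estimate_nme_occlusion(
    paw: Signal,
    env: Envelope,
    occlusion_window: tuple[float, float],
    correction: float = 0.8,
    min_deflection_cmh2o: float = 0.5,
) -> NmeEstimate:
    """Neuromechanical efficiency from an end-expiratory occlusion.

    k = correction × |paw nadir − pre-occlusion baseline| / envelope peak,
    with the correction factor (0.7 or 0.8) accounting for the diaphragm's
    higher efficiency during isometric contraction than tidal breathing.
    """
    if not 0 < correction <= 1:
        raise ValueError("correction factor must lie in (0, 1]")
    a, b = occlusion_window
    seg = paw.slice(a, b)

    # baseline from the 0.5 s preceding the window (or its first decile)
    pre = paw.slice(max(a - 0.5, paw.t0), a)
    baseline = (
        float(np.median(pre.samples))
        if pre.duration > 0.05
        else float(np.median(seg.samples[: max(seg.n // 10, 1)]))
    )
    nadir = float(seg.samples.min())
    deflection = baseline - nadir
    if deflection < min_deflection_cmh2o:
        raise ValueError(
            f"no occlusion effort detected: airway-pressure deflection "
            f"{deflection:.2f} cmH2O < {min_deflection_cmh2o} cmH2O"
        )

    i0, i1 = env.index_at(a), env.index_at(b) + 1
    emg_peak = float(env.samples[i0:i1].max())
    if emg_peak <= 0:
        raise ValueError("no envelope activity inside the occlusion window")

    return NmeEstimate(
        k=correction * deflection / emg_peak,
        correction=correction,
        occlusion_window=(a, b),
        paw_deflection=deflection,
        emg_peak=emg_peak,
    )


def pmus_waveform(env: Envelope, k: float) -> Signal:
    """Pointwise respiratory-muscle pressure: Pmus(t) = k × envelope(t)."""
    if not k > 0:
        raise ValueError("conversion factor k must be positive")
    if not env.baseline_corrected:
        raise ValueError("pmus_waveform requires a baseline-corrected envelope")
    return Signal(k * env.samples, fs=env.fs, label="pmus", kind="pressure", t0=env.t0)


# ---------------------------------------------------------------------------
# Patient–ventilator timing
# ---------------------------------------------------------------------------


def timing_compare(
    emg_event_s: float, vent_event_s: float, reference_cycle_s: float
) -> TimingComparison:
    """Absolute delay and phase angle between an EMG and a ventilator event."""
    if not reference_cycle_s > 0:
        raise ValueError("reference_cycle_s must be positive")
    delay_s = vent_event_s - emg_event_s
    return TimingComparison(
        delay_ms=1000.0 * delay_s,
        phase_angle_deg=360.0 * delay_s / reference_cycle_s,
        reference_cycle_s=reference_cycle_s,
    )


def detect_pressurization_onsets(
    paw: Signal, threshold_cmh2o: float | None = None
) -> np.ndarray:
    """Start times of ventilator pressurizations (upward threshold crossings)."""
    thr = threshold_cmh2o if threshold_cmh2o is not None else 0.05 * paw.samples.max()
    above = paw.samples > thr
    starts = np.flatnonzero(np.diff(above.astype(np.int8)) == 1) + 1
    if above.size and above[0]:
        starts = np.concatenate(([0], starts))
    return paw.t0 + starts / paw.fs


def match_breaths_to_vent(
    breaths: list[Breath], vent_onsets: np.ndarray, cycle_s: float
) -> tuple[list[tuple[Breath, float]], int]:
    """Pair each EMG breath with the nearest ventilator onset within half a
    cycle.  Returns the pairs and the count of unpaired EMG breaths
    (candidate ineffective efforts)."""
    pairs: list[tuple[Breath, float]] = []
    unmatched = 0
    vent = np.asarray(vent_onsets, dtype=np.float64)
    for br in breaths:
        if vent.size == 0:
            unmatched += 1
            continue
        j = int(np.argmin(np.abs(vent - br.onset_s)))
        if abs(vent[j] - br.onset_s) <= cycle_s / 2:
            pairs.append((br, float(vent[j])))
        else:
            unmatched += 1
    return pairs, unmatched


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------


def breath_feature_table(
    env: Envelope,
    breaths: list[Breath],
    amplitude_method: str = "p95_p5",
    normalization: str = "recording_max",
    reference: float | None = None,
) -> pd.DataFrame:
    """One row per breath: landmarks plus all magnitude/timing features."""
    if not breaths:
        return pd.DataFrame(
            columns=[
                "onset_s", "peak_s", "offset_s", "duration_s", "time_to_peak_s",
                "amplitude_uv", "amplitude_normalized", "etp_uvs",
            ]
        )
    amps = np.array([breath_amplitude(env, b, method=amplitude_method) for b in breaths])
    try:
        norm = normalize_amplitudes(amps, mode=normalization, reference=reference)
    except ValueError:
        norm = np.full(amps.shape, np.nan)
    rows = {
        "onset_s": [b.onset_s for b in breaths],
        "peak_s": [b.peak_s for b in breaths],
        "offset_s": [b.offset_s for b in breaths],
        "duration_s": [b.duration_s for b in breaths],
        "time_to_peak_s": [time_to_peak(b) for b in breaths],
        "amplitude_uv": amps,
        "amplitude_normalized": norm,
        "etp_uvs": [emg_time_product(env, b) for b in breaths],
    }
    return pd.DataFrame(rows)
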