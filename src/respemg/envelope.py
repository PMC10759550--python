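"""Envelope extraction (RMS, ARV, rectified median, fixed sample entropy)
and baseline correction.

All window estimators default to a centered 250 ms window with a 1-sample
step; edges use the available partial window so the envelope stays
time-aligned and equal in length to the signal.  fSampEn defaults to a
50 ms step with linear interpolation back to the signal rate, because a
1-sample step is computationally expensive for the entropy estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .signal_core import Signal

__all__ = [
    "Envelope",
    "FsampenParams",
    "moving_rms",
    "moving_arv",
    "moving_median_rect",
    "fsampen_envelope",
    "estimate_noise_floor",
    "correct_baseline",
]


@dataclass
class Envelope:
    """Demodulated activity waveform with estimator provenance."""

    samples: np.ndarray
    fs: float
    method: str  # rms | arv | median_rect | fsampen
    window_ms: float
    causality: str = "centered"  # or "causal"
    step_ms: float = 0.0  # 0 ⇒ one sample
    t0: float = 0.0
    baseline_corrected: bool = False
    noise_floor: float | None = None
    flags: list = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.window_ms <= 0:
            raise ValueError("window_ms must be positive")
        if self.causality not in ("centered", "causal"):
            raise ValueError("causality must be 'centered' or 'causal'")
        if self.flags is None:
            self.flags = []

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def index_at(self, t: float) -> int:
        i = int(round((t - self.t0) * self.fs))
        return min(max(i, 0), self.n - 1)

    def value_at(self, t: float) -> float:
        return float(np.interp(t, self.times(), self.samples))

    def to_signal(self, kind: str = "other") -> Signal:
        return Signal(self.samples, fs=self.fs, label=self.method, kind=kind, t0=self.t0)


@dataclass
class FsampenParams:
    """Fixed-tolerance sample-entropy parameters (m = 1, r = 0.2–0.3 × SD)."""

    m: int = 1
    r_mult: float = 0.25  # × whole-signal SD, fixed once for the recording
    window_ms: float = 250.0
    step_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be ≥ 1")
        if not self.r_mult > 0:
            raise ValueError("r_mult must be positive")


# ---------------------------------------------------------------------------
# Moving-window estimators
# ---------------------------------------------------------------------------


def _window_samples(sig: Signal, window_ms: float, minimum: int = 3) -> int:
    w = int(round(window_ms / 1000.0 * sig.fs))
    if w < minimum:
        raise ValueError(
            f"window of {window_ms} ms is {w} samples at fs={sig.fs}; "
            f"at least {minimum} required"
        )
    return w


def _window_bounds(n: int, w: int, causality: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample half-open window bounds, clipped to the signal (partial
    windows at the edges)."""
    i = np.arange(n)
    if causality == "centered":
        lo = i - (w - 1) // 2
        hi = i + w // 2 + 1
    else:  # causal: trailing window [i-w+1, i]
        lo = i - w + 1
        hi = i + 1
    return np.clip(lo, 0, n), np.clip(hi, 0, n)


def _moving_mean(x: np.ndarray, w: int, causality: str) -> np.ndarray:
    lo, hi = _window_bounds(x.size, w, causality)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    return (csum[hi] - csum[lo]) / (hi - lo)


def _apply_step(env: np.ndarray, sig: Signal, step_ms: float | None) -> tuple[np.ndarray, float, float]:
    """Subsample the per-sample envelope to the requested step."""
    if not step_ms:
        return env, sig.fs, 1000.0 / sig.fs
    step = max(int(round(step_ms / 1000.0 * sig.fs)), 1)
    return env[::step], sig.fs / step, step * 1000.0 / sig.fs


def moving_rms(
    sig: Signal,
    window_ms: float = 250.0,
    causality: str = "centered",
    step_ms: float | None = None,
) -> Envelope:
    """Moving root-mean-square envelope."""
    w = _window_samples(sig, window_ms)
    env = np.sqrt(_moving_mean(sig.samples**2, w, causality))
    env, fs, step = _apply_step(env, sig, step_ms)
    return Envelope(env, fs=fs, method="rms", window_ms=window_ms,
                    causality=causality, step_ms=step, t0=sig.t0)


def moving_arv(
    sig: Signal,
    window_ms: float = 250.0,
    causality: str = "centered",
    step_ms: float | None = None,
) -> Envelope:
    """Moving average-rectified-value envelope (mean of |x|)."""
    w = _window_samples(sig, window_ms)
    env = _moving_mean(np.abs(sig.samples), w, causality)
    env, fs, step = _apply_step(env, sig, step_ms)
    return Envelope(env, fs=fs, method="arv", window_ms=window_ms,
                    causality=causality, step_ms=step, t0=sig.t0)


def moving_median_rect(
    sig: Signal,
    window_ms: float = 250.0,
    causality: str = "centered",
    step_ms: float | None = None,
) -> Envelope:
    """Moving median of the rectified signal — immune to isolated spikes."""
    w = _window_samples(sig, window_ms)
    x = np.abs(sig.samples)
    n = x.size
    lo, hi = _window_bounds(n, w, causality)
    env = np.empty(n)

    # interior samples share a full window: vectorize via a strided view,
    # in chunks to bound the sort working set
    full = np.flatnonzero(hi - lo == w)
    if full.size:
        view = np.lib.stride_tricks.sliding_window_view(x, w)
        rows = lo[full]
        for s in range(0, full.size, 4096):
            sel = slice(s, s + 4096)
            env[full[sel]] = np.median(view[rows[sel]], axis=1)
    for i in np.flatnonzero(hi - lo != w):
        env[i] = np.median(x[lo[i] : hi[i]])

    env, fs, step = _apply_step(env, sig, step_ms)
    return Envelope(env, fs=fs, method="median_rect", window_ms=window_ms,
                    causality=causality, step_ms=step, t0=sig.t0)


# ---------------------------------------------------------------------------
# Fixed sample entropy
# ---------------------------------------------------------------------------


def sample_entropy(x: np.ndarray, m: int, r: float) -> float:
    """Sample entropy −ln(A/B) with Chebyshev distance and a given tolerance.

    B counts ordered pairs (i < j) of length-``m`` templates within ``r``;
    A counts the same for length ``m + 1``.  Self-matches are excluded by
    construction.  Returns ``nan`` when either count is zero.
    """
    n = x.size
    if m >= n:
        raise ValueError(f"embedding dimension m={m} must be < window length {n}")
    # pairwise Chebyshev match matrix for length-1 templates
    d = np.abs(x[:, None] - x[None, :]) <= r

    def _count(length: int) -> int:
        nt = n - length + 1
        match = d[:nt, :nt]
        for k in range(1, length):
            match = match & d[k : k + nt, k : k + nt]
        iu = np.triu_indices(nt, k=1)
        return int(np.count_nonzero(match[iu]))

    b = _count(m)
    a = _count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return -float(np.log(a / b))


def fsampen_envelope(sig: Signal, params: FsampenParams | None = None) -> Envelope:
    """Fixed-tolerance sample-entropy envelope.

    The tolerance ``r`` is computed once from the whole signal's SD (that is
    the "fixed" part): large-amplitude windows then produce fewer template
    matches and higher entropy, so the entropy tracks muscle activity while
    staying robust to isolated spikes.  Windows where the entropy is
    undefined (zero matches) take the maximum finite value attained
    elsewhere and are flagged.
    """
    params = params or FsampenParams()
    w = _window_samples(sig, params.window_ms, minimum=100)
    if params.m >= w:
        raise ValueError("embedding dimension must be smaller than the window")
    r = params.r_mult * float(np.std(sig.samples))
    x = sig.samples
    n = x.size
    step = max(int(round(params.step_ms / 1000.0 * sig.fs)), 1)

    centers = np.arange(0, n, step)
    half_lo = (w - 1) // 2
    half_hi = w // 2 + 1
    values = np.empty(centers.size)
    for k, c in enumerate(centers):
        lo = max(c - half_lo, 0)
        hi = min(c + half_hi, n)
        if r == 0:
            values[k] = 0.0  # constant signal: every template matches
            continue
        values[k] = sample_entropy(x[lo:hi], params.m, r)

    flags = []
    bad = ~np.isfinite(values)
    if bad.any():
        finite = values[~bad]
        ceiling = float(finite.max()) if finite.size else 0.0
        values[bad] = ceiling
        flags.append(f"{int(bad.sum())} undefined-entropy windows set to max {ceiling:.3g}")

    # interpolate back to the signal rate so the envelope aligns sample-wise
    env = np.interp(np.arange(n), centers, values)
    return Envelope(env, fs=sig.fs, method="fsampen", window_ms=params.window_ms,
                    causality="centered", step_ms=step * 1000.0 / sig.fs,
                    t0=sig.t0, flags=flags)


# ---------------------------------------------------------------------------
# Baseline correction
# ---------------------------------------------------------------------------


def estimate_noise_floor(env: Envelope, percentile: float = 5.0) -> float:
    """Between-breath noise level: a low percentile of the envelope."""
    return float(np.percentile(env.samples, percentile))


def correct_baseline(env: Envelope, noise: float) -> Envelope:
    """Subtract the baseline noise level from an envelope.

    RMS envelopes subtract the noise *variance* (out = √max(env² − noise², 0)),
    not the standard deviation; ARV/median/entropy envelopes subtract the
    level directly, clipped at zero.
    """
    if env.baseline_corrected:
        raise ValueError("envelope is already baseline-corrected")
    if noise < 0:
        raise ValueError("noise level must be nonnegative")
    if env.method == "rms":
        out = np.sqrt(np.maximum(env.samples**2 - noise**2, 0.0))
    else:
        out = np.maximum(env.samples - noise, 0.0)
    return replace(env, samples=out, baseline_corrected=True, noise_floor=noise,
                   flags=list(env.flags))
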