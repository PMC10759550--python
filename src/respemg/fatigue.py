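"""Spectral indices proposed for fatigue monitoring.

Mean/median frequency, the high/low-frequency power ratio (H = 150–350 Hz,
L = 20–46.7 Hz), the spectral-moments ratio of order five (M(−1)/M(5), the
Dimitrov-style index), and their per-breath trends.  No cutoff values are
applied: none exist for respiratory sEMG.

Spectral features are computed on the denoised *raw* signal within each
breath, never on the envelope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .features import Breath
from .signal_core import Signal

__all__ = [
    "SpectralFeatures",
    "psd_segment",
    "mean_median_frequency",
    "hl_ratio",
    "smr5",
    "spectral_features",
    "fatigue_trend",
]

H_BAND_HZ = (150.0, 350.0)
L_BAND_HZ = (20.0, 46.7)
SMR_SUPPORT_HZ = (20.0, 350.0)


@dataclass
class SpectralFeatures:
    mnf_hz: float
    mdf_hz: float
    hl_ratio: float
    smr5: float
    band_truncated: bool = False


def psd_segment(
    sig: Signal, segment_window: tuple[float, float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD (Hann window, 50 % overlap, 256-sample segments).

    Normalized as a density: the integral over frequency equals the segment
    variance (Parseval, within estimator error).
    """
    seg = sig if segment_window is None else sig.slice(*segment_window)
    if seg.n < 256:
        raise ValueError(
            f"segment of {seg.n} samples too short for a PSD (≥ 256 required)"
        )
    nperseg = min(256, seg.n)
    f, p = sps.welch(
        seg.samples, fs=seg.fs, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, detrend="constant", scaling="density",
    )
    return f, p


def mean_median_frequency(
    f: np.ndarray, p: np.ndarray
) -> tuple[float, float]:
    """MNF = Σ f·P / Σ P; MDF = half-total-power frequency (interpolated)."""
    f = np.asarray(f, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    total = p.sum()
    if not total > 0:
        raise ValueError("zero total power: MNF/MDF undefined")
    mnf = float((f * p).sum() / total)

    csum = np.cumsum(p)
    half = 0.5 * total
    j = int(np.searchsorted(csum, half))
    if j == 0:
        mdf = float(f[0])
    else:
        prev = csum[j - 1]
        frac = (half - prev) / (csum[j] - prev) if csum[j] > prev else 0.0
        mdf = float(f[j - 1] + frac * (f[j] - f[j - 1]))
    return mnf, mdf


def _band_power(f: np.ndarray, p: np.ndarray, band: tuple[float, float]) -> float:
    lo, hi = band
    mask = (f >= lo) & (f <= hi)
    if mask.sum() < 2:
        sel = p[mask]
        return float(sel.sum() * (f[1] - f[0])) if sel.size else 0.0
    return float(np.trapezoid(p[mask], f[mask]))


def hl_ratio(
    f: np.ndarray,
    p: np.ndarray,
    h_band: tuple[float, float] = H_BAND_HZ,
    l_band: tuple[float, float] = L_BAND_HZ,
) -> tuple[float, bool]:
    """High/low frequency power ratio.

    If the Nyquist limit falls below the upper H edge, the H band is
    integrated up to Nyquist and the truncation flagged (fs = 500 Hz is
    legitimate but cannot reach 350 Hz).
    """
    nyq = float(f[-1])
    truncated = nyq < h_band[1]
    h_hi = min(h_band[1], nyq)
    low = _band_power(f, p, l_band)
    if not low > 0:
        raise ValueError("zero power in the low band: H/L ratio undefined")
    high = _band_power(f, p, (h_band[0], h_hi))
    return high / low, truncated


def smr5(
    f: np.ndarray, p: np.ndarray, support: tuple[float, float] = SMR_SUPPORT_HZ
) -> float:
    """Spectral-moments ratio of order five: M(−1)/M(5) over 20–350 Hz.

    M(k) = Σ f^k · P(f) · Δf on the support (truncated at Nyquist).
    Spectral compression toward low frequencies raises this index.
    """
    lo, hi = support
    mask = (f >= max(lo, 1e-9)) & (f <= hi)
    fsel, psel = f[mask], p[mask]
    if not psel.sum() > 0:
        raise ValueError("zero power in the SMR support band")
    m_neg1 = float(np.trapezoid(psel / fsel, fsel))
    m_5 = float(np.trapezoid(psel * fsel**5, fsel))
    return m_neg1 / m_5


def spectral_features(sig: Signal, window: tuple[float, float] | None = None) -> SpectralFeatures:
    f, p = psd_segment(sig, window)
    mnf, mdf = mean_median_frequency(f, p)
    hl, truncated = hl_ratio(f, p)
    return SpectralFeatures(
        mnf_hz=mnf, mdf_hz=mdf, hl_ratio=hl, smr5=smr5(f, p),
        band_truncated=truncated,
    )


def fatigue_trend(
    sig: Signal, breaths: list[Breath]
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-breath spectral features on the denoised raw signal plus a
    least-squares slope per index over breath number.

    Breaths whose inspiratory segment is shorter than 256 samples are
    skipped (flagged in the table); fewer than 3 usable breaths is an error.
    """
    rows = []
    for i, br in enumerate(breaths):
        n_seg = int((br.offset_s - br.onset_s) * sig.fs)
        if n_seg < 256:
            rows.append({"breath": i, "skipped": True})
            continue
        feats = spectral_features(sig, (br.onset_s, br.offset_s))
        rows.append(
            {
                "breath": i,
                "skipped": False,
                "mnf_hz": feats.mnf_hz,
                "mdf_hz": feats.mdf_hz,
                "hl_ratio": feats.hl_ratio,
                "smr5": feats.smr5,
                "band_truncated": feats.band_truncated,
            }
        )
    table = pd.DataFrame(rows)
    usable = table[~table["skipped"]] if "skipped" in table else table
    if len(usable) < 3:
        raise ValueError(
            f"fatigue trend requires ≥ 3 usable breaths, got {len(usable)}"
        )

    slopes = {}
    x = usable["breath"].to_numpy(dtype=np.float64)
    for col in ("mnf_hz", "mdf_hz", "hl_ratio", "smr5"):
        slopes[f"{col}_slope"] = float(np.polyfit(x, usable[col].to_numpy(), 1)[0])
    return table, slopes
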