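"""Core data model for uniformly sampled physiological channels.

A :class:`Signal` is the universal currency of the toolkit: a 1-D array of
amplitudes (µV for EMG, cmH2O for pressure, L/s for flow) with a sampling
rate and a start-time offset.  A :class:`Recording` is a set of time-aligned
signals sharing one reference clock.  This module also provides file I/O
(EDF and delimited text with a JSON sidecar), resampling with antialiasing,
and acquisition-validity checks.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping

import numpy as np
from scipy import signal as sps

from . import _edf

__all__ = [
    "Signal",
    "Recording",
    "AcquisitionReport",
    "read_recording",
    "write_recording",
    "resample",
    "check_acquisition",
]

KINDS = ("emg", "pressure", "flow", "other")

#: Conventional amplitude unit per channel kind.
KIND_UNITS = {"emg": "uV", "pressure": "cmH2O", "flow": "L/s", "other": ""}


@dataclass
class Signal:
    """A uniformly sampled channel.

    Sample ``i`` occurs at time ``t0 + i / fs`` (0-based); all event times
    in the toolkit are reported in seconds on this reference clock.
    """

    samples: np.ndarray
    fs: float
    label: str = ""
    kind: str = "other"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 1:
            raise ValueError("signal must contain at least one sample")
        if not np.isfinite(self.samples).all():
            raise ValueError("signal contains non-finite samples")
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")

    # -- basic geometry ----------------------------------------------------

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal span in seconds (n / fs)."""
        return self.n / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def index_at(self, t: float) -> int:
        """Nearest sample index for time ``t`` (clipped to valid range)."""
        i = int(round((t - self.t0) * self.fs))
        return min(max(i, 0), self.n - 1)

    def slice(self, start_s: float, end_s: float) -> "Signal":
        """Samples with times in ``[start_s, end_s)``."""
        i0 = int(np.ceil((start_s - self.t0) * self.fs - 1e-9))
        i1 = int(np.ceil((end_s - self.t0) * self.fs - 1e-9))
        i0 = max(i0, 0)
        i1 = min(max(i1, i0 + 1), self.n)
        return replace(self, samples=self.samples[i0:i1], t0=self.t0 + i0 / self.fs)

    def with_samples(self, samples: np.ndarray) -> "Signal":
        return replace(self, samples=np.asarray(samples, dtype=np.float64))

    @property
    def unit(self) -> str:
        return KIND_UNITS[self.kind]


@dataclass
class Recording:
    """Named, time-aligned collection of signals on one reference clock."""

    signals: dict[str, Signal] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, sig in self.signals.items():
            if sig.label and sig.label != label:
                raise ValueError(
                    f"signal label {sig.label!r} disagrees with key {label!r}"
                )
            sig.label = label

    @classmethod
    def from_signals(cls, signals: Iterable[Signal]) -> "Recording":
        out: dict[str, Signal] = {}
        dupes: list[str] = []
        for s in signals:
            if s.label in out:
                dupes.append(s.label)
            else:
                out[s.label] = s
        if dupes:
            raise ValueError(f"duplicate channel labels: {sorted(set(dupes))}")
        return cls(signals=out)

    def __getitem__(self, label: str) -> Signal:
        return self.signals[label]

    def __contains__(self, label: str) -> bool:
        return label in self.signals

    def __len__(self) -> int:
        return len(self.signals)

    @property
    def labels(self) -> list[str]:
        return list(self.signals)

    def channels(self, kind: str | None = None) -> list[Signal]:
        sigs = list(self.signals.values())
        if kind is not None:
            sigs = [s for s in sigs if s.kind == kind]
        return sigs


@dataclass
class AcquisitionReport:
    """Acquisition validity flags for one channel.

    ``fs_ok`` requires at least 500 Hz, ``fs_ideal`` at least 1000 Hz.
    """

    fs_ok: bool
    fs_ideal: bool
    clipping_fraction: float
    flatline_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.clipping_fraction <= 1.0):
            raise ValueError("clipping_fraction outside [0, 1]")
        if not (0.0 <= self.flatline_fraction <= 1.0):
            raise ValueError("flatline_fraction outside [0, 1]")

    @property
    def ok(self) -> bool:
        return self.fs_ok and self.clipping_fraction < 0.01 and self.flatline_fraction < 0.01


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _sidecar_path(path: str) -> str:
    return path + ".json"


def read_recording(
    path: str,
    format: str | None = None,
    fs: float | None = None,
    kinds: Mapping[str, str] | None = None,
) -> Recording:
    """Read a recording from an EDF or delimited-text file.

    For text input the sampling rate must come from the JSON sidecar written
    by :func:`write_recording` or the ``fs`` argument; there is no silent
    default.  Channel kinds are taken from the sidecar when present,
    otherwise from ``kinds``, defaulting to ``emg`` (amplitudes in µV).
    """
    fmt = format or _guess_format(path)
    if not os.path.exists(path):
        raise IOError(f"cannot read recording: no such file {path!r}")

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if os.path.exists(sidecar):
        with open(sidecar, encoding="utf-8") as fh:
            meta = json.load(fh)
    chan_meta = meta.get("channels", {})

    def _kind(label: str) -> str:
        if label in chan_meta and "kind" in chan_meta[label]:
            return chan_meta[label]["kind"]
        if kinds and label in kinds:
            return kinds[label]
        return "emg"

    if fmt == "edf":
        channels = _edf.read_edf(path)
        labels = [c.label for c in channels]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate channel labels in {path!r}: {dupes}")
        sigs = []
        for ch in channels:
            n_true = chan_meta.get(ch.label, {}).get("n_samples")
            samples = ch.samples[:n_true] if n_true else ch.samples
            sigs.append(Signal(samples, fs=ch.fs, label=ch.label, kind=_kind(ch.label)))
        return Recording.from_signals(sigs)

    if fmt == "csv":
        import pandas as pd

        df = pd.read_csv(path)
        labels = [str(c) for c in df.columns]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate channel labels in {path!r}: {dupes}")
        file_fs = meta.get("fs", fs)
        if file_fs is None:
            raise ValueError(
                f"no sampling rate for text recording {path!r}: "
                "provide fs= or a JSON sidecar"
            )
        sigs = [
            Signal(df[c].to_numpy(dtype=np.float64), fs=float(file_fs), label=c, kind=_kind(c))
            for c in labels
        ]
        return Recording.from_signals(sigs)

    raise ValueError(f"unknown recording format {fmt!r} (expected 'edf' or 'csv')")


def write_recording(
    rec: Recording,
    path: str,
    format: str | None = None,
    provenance: Mapping | None = None,
) -> None:
    """Write a recording to EDF or CSV, with a JSON sidecar.

    The sidecar stores per-channel metadata (kind, true sample count) and
    any provenance mapping — the resolved parameters of whatever produced
    the data — so that files are self-describing.
    """
    fmt = format or _guess_format(path)
    if len(rec) == 0:
        raise ValueError("cannot write an empty recording")

    if fmt == "edf":
        channels = [
            _edf.EdfChannel(
                label=s.label, samples=s.samples, fs=s.fs, unit=s.unit or "uV"
            )
            for s in rec.channels()
        ]
        _edf.write_edf(path, channels)
    elif fmt == "csv":
        import pandas as pd

        fss = {s.fs for s in rec.channels()}
        if len(fss) != 1:
            raise ValueError(
                "CSV output requires a common sampling rate across channels; "
                f"got {sorted(fss)} — resample explicitly first"
            )
        ns = {s.n for s in rec.channels()}
        if len(ns) != 1:
            raise ValueError("CSV output requires equal-length channels")
        pd.DataFrame({s.label: s.samples for s in rec.channels()}).to_csv(
            path, index=False
        )
    else:
        raise ValueError(f"unknown recording format {fmt!r} (expected 'edf' or 'csv')")

    meta = {
        "format": fmt,
        "fs": rec.channels()[0].fs if len({s.fs for s in rec.channels()}) == 1 else None,
        "channels": {
            s.label: {"kind": s.kind, "fs": s.fs, "n_samples": s.n}
            for s in rec.channels()
        },
    }
    if provenance:
        meta["provenance"] = dict(provenance)
    with open(_sidecar_path(path), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)


def _guess_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext == ".edf":
        return "edf"
    if ext in (".csv", ".txt", ".tsv"):
        return "csv"
    raise ValueError(f"cannot infer recording format from {path!r}")


# ---------------------------------------------------------------------------
# Resampling and acquisition checks
# ---------------------------------------------------------------------------


def resample(sig: Signal, target_fs: float) -> Signal:
    """Resample to ``target_fs`` with antialiasing on downsampling.

    When downsampling, a zero-phase 8th-order Butterworth low-pass at
    0.45 × target_fs is applied before rational-rate polyphase resampling,
    so content below 0.4 × target_fs survives with < 1% amplitude error.
    """
    if not (target_fs > 0):
        raise ValueError(f"target_fs must be positive, got {target_fs}")
    if target_fs == sig.fs:
        return replace(sig, samples=sig.samples.copy())

    x = sig.samples
    if target_fs < sig.fs:
        sos = sps.butter(8, 0.45 * target_fs, btype="low", fs=sig.fs, output="sos")
        x = sps.sosfiltfilt(sos, x)
    frac = Fraction(target_fs / sig.fs).limit_denominator(10_000)
    y = sps.resample_poly(x, frac.numerator, frac.denominator, padtype="line")
    return replace(sig, samples=y, fs=target_fs)


def check_acquisition(sig: Signal, flatline_min_s: float = 1.0) -> AcquisitionReport:
    """Sampling-rate, clipping, and flatline checks on a raw channel."""
    x = sig.samples
    n = x.size

    # Clipping: samples saturated at the global rails, counted only when the
    # rail value repeats (a clean extremum touched once is not clipping).
    clipped = 0
    if np.ptp(x) > 0:
        for rail in (x.min(), x.max()):
            cnt = int(np.sum(x == rail))
            if cnt > 1:
                clipped += cnt

    # Flatline: runs of identical consecutive samples longer than 1 s.
    flat = 0
    if n > 1:
        change = np.flatnonzero(np.diff(x) != 0)
        bounds = np.concatenate(([-1], change, [n - 1]))
        run_lengths = np.diff(bounds)
        min_run = int(np.ceil(flatline_min_s * sig.fs))
        flat = int(run_lengths[run_lengths > min_run].sum())
    elif n == 1:
        flat = 0

    return AcquisitionReport(
        fs_ok=sig.fs >= 500.0,
        fs_ideal=sig.fs >= 1000.0,
        clipping_fraction=min(clipped / n, 1.0),
        flatline_fraction=min(flat / n, 1.0),
    )
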