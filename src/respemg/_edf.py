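"""Minimal EDF (European Data Format) reader/writer.

Implements the plain EDF subset needed here: a fixed 256-byte ASCII header,
256 bytes per signal of channel headers, and data records of little-endian
16-bit integers with per-channel linear physical scaling.  Channels may have
different sampling rates (different samples-per-record).  Record duration is
fixed at 1 s on write; the final record is zero-padded (true sample counts
travel in the recording's JSON sidecar).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

HEADER_SIZE = 256
CHANNEL_HEADER_SIZE = 256
DIG_MIN, DIG_MAX = -32768, 32767


@dataclass
class EdfChannel:
    label: str
    samples: np.ndarray
    fs: float
    unit: str = "uV"


def _field(value: str, width: int) -> bytes:
    b = value.encode("ascii", "replace")[:width]
    return b.ljust(width)


def _num(value: float, width: int) -> bytes:
    s = f"{value:.10g}"[:width]
    return _field(s, width)


def write_edf(path: str, channels: list[EdfChannel]) -> None:
    if not channels:
        raise ValueError("no channels to write")
    for ch in channels:
        if abs(ch.fs - round(ch.fs)) > 1e-9:
            raise ValueError(
                f"EDF output requires integer sampling rates (1 s records); "
                f"channel {ch.label!r} has fs={ch.fs}"
            )

    spr = [int(round(ch.fs)) for ch in channels]  # samples per 1 s record
    n_records = max(int(np.ceil(ch.samples.size / s)) for ch, s in zip(channels, spr))

    phys_min, phys_max, scaled = [], [], []
    for ch in channels:
        lo, hi = float(np.min(ch.samples)), float(np.max(ch.samples))
        if hi <= lo:
            hi = lo + 1.0
        # widen marginally so extremes stay strictly inside the digital range
        span = hi - lo
        lo -= 1e-6 * span
        hi += 1e-6 * span
        gain = (DIG_MAX - DIG_MIN) / (hi - lo)
        dig = np.round((ch.samples - lo) * gain + DIG_MIN).astype("<i2")
        phys_min.append(lo)
        phys_max.append(hi)
        scaled.append(dig)

    ns = len(channels)
    header = b"".join(
        [
            _field("0", 8),  # version
            _field("X X X X", 80),  # patient id
            _field("Startdate X X X X", 80),  # recording id
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _num(HEADER_SIZE + ns * CHANNEL_HEADER_SIZE, 8),
            _field("", 44),  # reserved
            _num(n_records, 8),
            _num(1, 8),  # record duration (s)
            _num(ns, 4),
        ]
    )
    header += b"".join(_field(ch.label, 16) for ch in channels)
    header += b"".join(_field("sEMG electrode", 80) for _ in channels)
    header += b"".join(_field(ch.unit, 8) for ch in channels)
    header += b"".join(_num(phys_min[i], 8) for i in range(ns))
    header += b"".join(_num(phys_max[i], 8) for i in range(ns))
    header += b"".join(_num(DIG_MIN, 8) for _ in channels)
    header += b"".join(_num(DIG_MAX, 8) for _ in channels)
    header += b"".join(_field("", 80) for _ in channels)  # prefiltering
    header += b"".join(_num(s, 8) for s in spr)
    header += b"".join(_field("", 32) for _ in channels)  # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for dig, s in zip(scaled, spr):
                chunk = dig[r * s : (r + 1) * s]
                if chunk.size < s:
                    chunk = np.concatenate(
                        [chunk, np.zeros(s - chunk.size, dtype="<i2")]
                    )
                fh.write(chunk.tobytes())


def read_edf(path: str) -> list[EdfChannel]:
    with open(path, "rb") as fh:
        head = fh.read(HEADER_SIZE)
        if len(head) < HEADER_SIZE:
            raise IOError(f"truncated EDF header in {path!r}")
        n_records = int(head[236:244].decode("ascii").strip())
        record_dur = float(head[244:252].decode("ascii").strip())
        ns = int(head[252:256].decode("ascii").strip())

        sub = fh.read(ns * CHANNEL_HEADER_SIZE)

        def col(offset: int, width: int) -> list[str]:
            start = offset * ns
            return [
                sub[start + i * width : start + (i + 1) * width]
                .decode("ascii")
                .strip()
                for i in range(ns)
            ]

        # channel-header layout: labels(16) transducer(80) unit(8)
        # phys_min(8) phys_max(8) dig_min(8) dig_max(8) prefilter(80) spr(8)
        labels = col(0, 16)
        units = col(16 + 80, 8)
        phys_min = [float(v) for v in col(16 + 80 + 8, 8)]
        phys_max = [float(v) for v in col(16 + 80 + 16, 8)]
        dig_min = [int(float(v)) for v in col(16 + 80 + 24, 8)]
        dig_max = [int(float(v)) for v in col(16 + 80 + 32, 8)]
        spr = [int(v) for v in col(16 + 80 + 40 + 80, 8)]

        raw = np.frombuffer(fh.read(), dtype="<i2")

    per_record = sum(spr)
    if raw.size < n_records * per_record:
        raise IOError(f"truncated EDF data in {path!r}")
    raw = raw[: n_records * per_record].reshape(n_records, per_record)

    channels = []
    pos = 0
    for i in range(ns):
        dig = raw[:, pos : pos + spr[i]].reshape(-1).astype(np.float64)
        pos += spr[i]
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        phys = (dig - dig_min[i]) * gain + phys_min[i]
        channels.append(
            EdfChannel(
                label=labels[i], samples=phys, fs=spr[i] / record_dur, unit=units[i]
            )
        )
    return channels
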