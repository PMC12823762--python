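"""Minimal plain-EDF (European Data Format) reader and writer.

Implements the classic EDF layout only: ASCII header, fixed 1-second
data records, 16-bit little-endian samples with linear physical/digital
scaling.  No EDF+ annotations, no discontinuous records.  Sufficient to
round-trip the four polygraphy channels this package works with; the
16-bit quantisation introduces an error of at most half a digital step
of the declared physical range.
"""

from __future__ import annotations

from datetime import datetime
from pathlib import Path

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(text: str, width: int) -> bytes:
    b = str(text)[:width].encode("ascii")
    return b + b" " * (width - len(b))


def _num(x: float, width: int) -> bytes:
    s = f"{x:.10g}"[:width]
    return _field(s, width)


def write_edf(path, labels, signals, rates, units=None,
              physical_ranges=None, start: datetime | None = None) -> Path:
    """Write signals to a plain EDF file with 1-second data records.

    Each rate must be a positive integer (samples per 1 s record).
    ``physical_ranges`` gives (min, max) per signal; defaults to the
    observed range padded by 1 unit.
    """
    path = Path(path)
    ns = len(labels)
    if not (len(signals) == len(rates) == ns):
        raise ValueError("labels, signals and rates must have equal length")
    units = units or [""] * ns
    rates = [int(r) for r in rates]
    if any(r < 1 for r in rates):
        raise ValueError("EDF writer requires integer rates >= 1 Hz")
    signals = [np.asarray(s, dtype=float) for s in signals]
    if physical_ranges is None:
        physical_ranges = []
        for s in signals:
            lo, hi = float(np.min(s)), float(np.max(s))
            if lo == hi:
                lo, hi = lo - 1.0, hi + 1.0
            physical_ranges.append((lo - 1.0, hi + 1.0))
    n_records = min(s.size // r for s, r in zip(signals, rates))
    if n_records < 1:
        raise ValueError("signals shorter than one data record")
    start = start or datetime(2000, 1, 1, 22, 0, 0)

    header = b"".join([
        _field("0", 8),
        _field("X X X X", 80),
        _field("Startdate X X X X", 80),
        _field(start.strftime("%d.%m.%y"), 8),
        _field(start.strftime("%H.%M.%S"), 8),
        _field(str(256 * (ns + 1)), 8),
        _field("", 44),
        _field(str(n_records), 8),
        _field("1", 8),
        _field(str(ns), 4),
    ])
    header += b"".join(_field(lab, 16) for lab in labels)
    header += b"".join(_field("", 80) for _ in range(ns))
    header += b"".join(_field(u, 8) for u in units)
    header += b"".join(_num(pr[0], 8) for pr in physical_ranges)
    header += b"".join(_num(pr[1], 8) for pr in physical_ranges)
    header += b"".join(_field(str(_DIG_MIN), 8) for _ in range(ns))
    header += b"".join(_field(str(_DIG_MAX), 8) for _ in range(ns))
    header += b"".join(_field("", 80) for _ in range(ns))
    header += b"".join(_field(str(r), 8) for r in rates)
    header += b"".join(_field("", 32) for _ in range(ns))
    assert len(header) == 256 * (ns + 1)

    digital = []
    for s, r, (pmin, pmax) in zip(signals, rates, physical_ranges):
        scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
        d = np.rint((np.clip(s, pmin, pmax) - pmin) * scale + _DIG_MIN)
        digital.append(d[: n_records * r].astype("<i2").reshape(n_records, r))

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            for d in digital:
                fh.write(d[rec].tobytes())
    return path


def read_edf(path):
    """Read a plain EDF file; returns (labels, rates_hz, signals).

    Signals are returned in physical units as float arrays.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise ValueError(f"{path}: not an EDF file (truncated header)")

    def fld(off, width):
        return raw[off:off + width].decode("ascii", errors="replace").strip()

    n_records = int(fld(236, 8))
    record_dur = float(fld(244, 8))
    ns = int(fld(252, 4))
    off = 256

    def sig_fields(width):
        nonlocal off
        out = [fld(off + i * width, width) for i in range(ns)]
        off += ns * width
        return out

    labels = sig_fields(16)
    sig_fields(80)  # transducer
    sig_fields(8)   # physical dimension
    pmins = [float(x) for x in sig_fields(8)]
    pmaxs = [float(x) for x in sig_fields(8)]
    dmins = [float(x) for x in sig_fields(8)]
    dmaxs = [float(x) for x in sig_fields(8)]
    sig_fields(80)  # prefiltering
    nsamp = [int(x) for x in sig_fields(8)]
    sig_fields(32)  # reserved

    data_off = 256 * (ns + 1)
    rec_len = sum(nsamp)
    body = np.frombuffer(raw, dtype="<i2", offset=data_off)
    if n_records < 0:  # length-unknown convention
        n_records = body.size // rec_len
    body = body[: n_records * rec_len].reshape(n_records, rec_len)

    signals, rates = [], []
    col = 0
    for i in range(ns):
        d = body[:, col:col + nsamp[i]].reshape(-1).astype(float)
        col += nsamp[i]
        gain = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        signals.append((d - dmins[i]) * gain + pmins[i])
        rates.append(nsamp[i] / record_dur)
    return labels, rates, signals
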