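"""Minimal EDF/EDF+ reading and writing.

Only the signal payload of the format is needed here: fixed-width ASCII
headers followed by interleaved little-endian 16-bit records.  Per-signal
sampling rates are preserved exactly as stored, which matters because
polysomnographs routinely mix rates (e.g. 256 Hz EEG next to 100 Hz EOG)
and the preprocessing pipeline needs the native rate of every channel.

Values round-trip to the 16-bit quantization implied by each signal's
physical range; labels and rates round-trip exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["EdfSignal", "read_edf_file", "write_edf_file", "EdfFormatError"]


class EdfFormatError(ValueError):
    """Raised when a file cannot be parsed as EDF/EDF+."""


@dataclass
class EdfSignal:
    label: str
    rate: float  # Hz
    samples: np.ndarray  # float64, physical units
    physical_dimension: str = "uV"


def _field(raw: bytes, start: int, width: int) -> str:
    return raw[start : start + width].decode("ascii", errors="replace").strip()


def read_edf_file(path) -> list[EdfSignal]:
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 256:
        raise EdfFormatError(f"{path}: file shorter than an EDF header")
    try:
        header_bytes = int(_field(raw, 184, 8))
        n_records = int(_field(raw, 236, 8))
        record_duration = float(_field(raw, 244, 8))
        n_signals = int(_field(raw, 252, 4))
    except ValueError as exc:  # non-numeric header fields
        raise EdfFormatError(f"{path}: malformed EDF header") from exc
    if n_signals <= 0:
        raise EdfFormatError(f"{path}: EDF file declares zero signals")
    if len(raw) < header_bytes:
        raise EdfFormatError(f"{path}: truncated EDF header")

    sig = raw[256:header_bytes]

    def sig_field(width: int, offset: int, k: int) -> str:
        start = offset * n_signals + k * width
        return sig[start : start + width].decode("ascii", errors="replace").strip()

    # Per-signal header arrays are stored field-major.
    labels, phys_min, phys_max, dig_min, dig_max, spr, dims = [], [], [], [], [], [], []
    offset = 0
    for width, store, conv in (
        (16, labels, str),      # label
        (80, None, None),       # transducer
        (8, dims, str),         # physical dimension
        (8, phys_min, float),
        (8, phys_max, float),
        (8, dig_min, float),
        (8, dig_max, float),
        (80, None, None),       # prefiltering
        (8, spr, int),          # samples per record
    ):
        for k in range(n_signals):
            start = offset + k * width
            text = sig[start : start + width].decode("ascii", errors="replace").strip()
            if store is not None:
                try:
                    store.append(conv(text))
                except ValueError as exc:
                    raise EdfFormatError(f"{path}: bad signal header field {text!r}") from exc
        offset += width * n_signals

    data = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    samples_per_record = sum(spr)
    if n_records < 0:  # EDF+ allows -1 ("unknown"); infer from file size
        n_records = len(data) // samples_per_record
    data = data[: n_records * samples_per_record].reshape(n_records, samples_per_record)

    signals: list[EdfSignal] = []
    col = 0
    for k in range(n_signals):
        block = data[:, col : col + spr[k]].reshape(-1).astype(np.float64)
        col += spr[k]
        drange = dig_max[k] - dig_min[k]
        gain = (phys_max[k] - phys_min[k]) / drange if drange != 0 else 1.0
        phys = phys_min[k] + (block - dig_min[k]) * gain
        rate = spr[k] / record_duration
        signals.append(EdfSignal(labels[k], rate, phys, dims[k]))
    return signals


def _pack(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def _num(value, width: int) -> bytes:
    text = f"{value:.{max(0, width - 2)}g}" if isinstance(value, float) else str(value)
    if len(text) > width:
        text = f"{float(value):.{width - 6}e}"
    return _pack(text, width)


def write_edf_file(path, signals: list[EdfSignal], *, patient: str = "X", recording: str = "X") -> None:
    """Write signals as EDF with 1-s data records.

    Each signal's rate must be a positive integer number of samples per
    second (the common case for PSG hardware); signals are truncated or
    zero-padded to a whole number of records.
    """
    if not signals:
        raise EdfFormatError("cannot write an EDF file with zero signals")
    rates = []
    for s in signals:
        r = s.rate
        if r <= 0 or abs(r - round(r)) > 1e-9:
            raise EdfFormatError(f"signal {s.label!r}: rate {r} Hz is not a whole number")
        rates.append(int(round(r)))
    n_records = max(int(math.ceil(len(s.samples) / r)) for s, r in zip(signals, rates))

    dig_min, dig_max = -32768, 32767
    headers = {"phys_min": [], "phys_max": [], "digital": []}
    for s, r in zip(signals, rates):
        x = np.zeros(n_records * r)
        x[: len(s.samples)] = s.samples
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            lo, hi = lo - 1.0, lo + 1.0
        # A touch of head-room keeps extreme samples off the digital rails.
        span = hi - lo
        lo, hi = lo - 1e-3 * span, hi + 1e-3 * span
        gain = (hi - lo) / (dig_max - dig_min)
        dig = np.round((x - lo) / gain + dig_min).astype("<i2")
        headers["phys_min"].append(lo)
        headers["phys_max"].append(hi)
        headers["digital"].append(dig.reshape(n_records, r))

    n_signals = len(signals)
    header_bytes = 256 * (1 + n_signals)
    head = b"".join(
        [
            _pack("0", 8),
            _pack(patient, 80),
            _pack(recording, 80),
            _pack("01.01.00", 8),
            _pack("00.00.00", 8),
            _num(header_bytes, 8),
            _pack("", 44),
            _num(n_records, 8),
            _num(1, 8),
            _num(n_signals, 4),
        ]
    )
    fields = [
        b"".join(_pack(s.label, 16) for s in signals),
        b"".join(_pack("", 80) for _ in signals),
        b"".join(_pack(s.physical_dimension, 8) for s in signals),
        b"".join(_num(float(v), 8) for v in headers["phys_min"]),
        b"".join(_num(float(v), 8) for v in headers["phys_max"]),
        b"".join(_num(dig_min, 8) for _ in signals),
        b"".join(_num(dig_max, 8) for _ in signals),
        b"".join(_pack("", 80) for _ in signals),
        b"".join(_num(r, 8) for r in rates),
        b"".join(_pack("", 32) for _ in signals),
    ]
    with open(path, "wb") as fh:
        fh.write(head)
        for f in fields:
            fh.write(f)
        for rec in range(n_records):
            for dig in headers["digital"]:
                fh.write(dig[rec].tobytes())
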