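"""Minimal EDF (European Data Format) export for continuous recordings.

Writes standard 16-bit EDF with one-second data records and symmetric
per-channel physical ranges; the record is zero-padded to a whole number of
seconds. Reading goes through :func:`mne.io.read_raw_edf` (see
:func:`read_edf`), which also serves as the independent round-trip check in
the test suite. Quantisation error is bounded by (physical range)/65534.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np

from .containers import ContinuousEEG
from .exceptions import ConfigurationError

_DIG_MAX = 32767
_DIG_MIN = -32767


def _field(value, width: int) -> bytes:
    text = str(value)[:width]
    return text.ljust(width).encode("ascii")


def _num(value: float, width: int) -> bytes:
    text = f"{value:.6g}"
    if len(text) > width:
        text = f"{value:.3g}"
    if len(text) > width:
        raise ConfigurationError(f"cannot encode {value} in {width} chars")
    return text.ljust(width).encode("ascii")


def write_edf(path, eeg: ContinuousEEG,
              start: _dt.datetime | None = None) -> None:
    """Write a ContinuousEEG to ``path`` as 16-bit EDF."""
    rate = eeg.sampling_rate_hz
    if abs(rate - round(rate)) > 1e-9:
        raise ConfigurationError("EDF export needs an integer sampling rate")
    spr = int(round(rate))                      # samples per 1 s record
    n_ch = eeg.n_channels
    n_records = int(np.ceil(eeg.n_samples / spr))
    padded = np.zeros((n_ch, n_records * spr))
    padded[:, :eeg.n_samples] = eeg.data

    pmax = np.maximum(np.abs(padded).max(axis=1) * 1.0001, 1e-3)
    scale = _DIG_MAX / pmax
    digital = np.round(padded * scale[:, None]).astype("<i2")

    start = start or _dt.datetime(2000, 1, 1)
    header = b"".join([
        _field("0", 8),
        _field("X X X X", 80),
        _field(f"Startdate X X X ref:{eeg.reference}", 80),
        _field(start.strftime("%d.%m.%y"), 8),
        _field(start.strftime("%H.%M.%S"), 8),
        _field(256 * (1 + n_ch), 8),
        _field("", 44),
        _field(n_records, 8),
        _field(1, 8),
        _field(n_ch, 4),
    ])
    per_signal = b"".join([
        b"".join(_field(lab, 16) for lab in eeg.channel_labels),
        b"".join(_field("AgAgCl electrode", 80) for _ in range(n_ch)),
        b"".join(_field("uV", 8) for _ in range(n_ch)),
        b"".join(_num(-p, 8) for p in pmax),
        b"".join(_num(p, 8) for p in pmax),
        b"".join(_field(_DIG_MIN, 8) for _ in range(n_ch)),
        b"".join(_field(_DIG_MAX, 8) for _ in range(n_ch)),
        b"".join(_field("", 80) for _ in range(n_ch)),
        b"".join(_field(spr, 8) for _ in range(n_ch)),
        b"".join(_field("", 32) for _ in range(n_ch)),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        # record-major, signal-contiguous within each record
        for r in range(n_records):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())


def read_edf(path, reference: str = "Cz") -> ContinuousEEG:
    """Read an EDF file into a ContinuousEEG (μV) via mne."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6
    return ContinuousEEG(
        data=data_uv,
        sampling_rate_hz=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        reference=reference,
    )
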