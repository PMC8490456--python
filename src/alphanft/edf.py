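"""Minimal EDF (European Data Format) export/import for synthetic recordings.

Writing uses a small self-contained EDF writer (fixed-format ASCII header +
16-bit little-endian samples, 1-s data records, physical unit microvolts).
Reading goes through :func:`mne.io.read_raw_edf`, which also serves as an
independent check of the writer in the test suite.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .spectral import MultiChannelSignal

__all__ = ["write_edf", "read_edf"]

_HEADER_DATE = "01.01.00"
_HEADER_TIME = "00.00.00"


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(signal: MultiChannelSignal, path) -> Path:
    """Write a multi-channel signal to an EDF file (physical unit uV).

    The sampling rate must be an integer (one data record per second).  The
    signal is zero-padded to a whole number of records.
    """
    fs = signal.sampling_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    path = Path(path)
    x = signal.samples
    n_rec = int(np.ceil(x.shape[0] / fs))
    padded = np.zeros((n_rec * fs, x.shape[1]))
    padded[: x.shape[0]] = x
    ns = x.shape[1]

    phys_max = float(np.max(np.abs(padded)))
    phys_max = max(np.ceil(phys_max * 1.05), 1.0)
    dig_min, dig_max = -32768, 32767
    scale = dig_max / phys_max
    digital = np.clip(np.round(padded * scale), dig_min, dig_max).astype("<i2")

    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad(f"Startdate X X X X kind={signal.segment_kind}", 80),
        _pad(_HEADER_DATE, 8),
        _pad(_HEADER_TIME, 8),
        _pad(str(256 * (1 + ns)), 8),
        _pad("", 44),
        _pad(str(n_rec), 8),
        _pad("1", 8),
        _pad(str(ns), 4),
    ])
    fields = [
        (signal.channel_labels, 16),
        (["" for _ in range(ns)], 80),            # transducer
        (["uV" for _ in range(ns)], 8),           # physical dimension
        ([f"{-phys_max:g}" for _ in range(ns)], 8),
        ([f"{phys_max:g}" for _ in range(ns)], 8),
        ([str(dig_min) for _ in range(ns)], 8),
        ([str(dig_max) for _ in range(ns)], 8),
        (["" for _ in range(ns)], 80),            # prefiltering
        ([str(fs) for _ in range(ns)], 8),
        (["" for _ in range(ns)], 32),
    ]
    sig_header = b"".join(
        b"".join(_pad(str(v), width) for v in values)
        for values, width in fields
    )
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_rec):
            block = digital[r * fs:(r + 1) * fs]  # (fs, ns)
            fh.write(block.T.tobytes())           # per-signal contiguous
    return path


def read_edf(path, segment_kind: str = "trial",
             expected_sampling_rate_hz: float | None = None,
             ) -> MultiChannelSignal:
    """Read an EDF recording into a :class:`MultiChannelSignal` (uV).

    Labels are accepted case-insensitively.  If
    ``expected_sampling_rate_hz`` is given and does not match the file, a
    ``ValueError`` is raised (guards config/recording mismatches).
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    if expected_sampling_rate_hz is not None and \
            abs(fs - expected_sampling_rate_hz) > 1e-6:
        raise ValueError(
            f"sampling rate mismatch: file {fs} Hz, "
            f"expected {expected_sampling_rate_hz} Hz")
    data = raw.get_data() * 1e6  # Volts -> microvolts
    labels = tuple(raw.ch_names)
    return MultiChannelSignal(data.T, fs, labels, segment_kind)
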