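"""EDF input/output and label tables.

Reading goes through :func:`mne.io.read_raw_edf`. Writing uses a minimal
EDF writer implemented here (16-bit samples, one data record per second),
sufficient for round-tripping synthetic recordings; the mne reader serves
as its independent cross-check in the test suite.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import EegRecording
from .errors import ParameterError

_HEADER_FIELDS = 256  # bytes of the fixed EDF header


def _ascii(value: str, width: int) -> bytes:
    s = value[:width].ljust(width)
    return s.encode("ascii")


def write_edf(rec: EegRecording, path: str | os.PathLike) -> None:
    """Write a recording as a 16-bit EDF file.

    The signal is split into 1-second data records; a trailing partial
    second is zero-padded. Per-channel physical ranges are symmetric
    around zero and chosen from the data.
    """
    fs = rec.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ParameterError("EDF writer requires an integer sampling rate")
    data = np.asarray(rec.data, dtype=np.float64)
    nch, nsamp = data.shape
    n_records = int(np.ceil(nsamp / spr)) if nsamp else 0
    padded = np.zeros((nch, n_records * spr))
    padded[:, :nsamp] = data

    phys_max = np.maximum(np.abs(padded).max(axis=1), 1e-6)
    # keep the printed 8-char field exact: round up to 6 significant digits
    phys_max = np.array([float(f"{v:.6g}") * 1.000001 + 1e-9 for v in phys_max])
    dig_max, dig_min = 32767, -32768

    header = b""
    header += _ascii("0", 8)
    header += _ascii(f"X X X {rec.subject_id}", 80)
    header += _ascii("Startdate 01-JAN-2000 X X X", 80)
    header += _ascii("01.01.00", 8)
    header += _ascii("00.00.00", 8)
    header += _ascii(str(_HEADER_FIELDS * (1 + nch)), 8)
    header += _ascii("", 44)
    header += _ascii(str(n_records), 8)
    header += _ascii("1", 8)
    header += _ascii(str(nch), 4)

    def field(values: Iterable[str], width: int) -> bytes:
        return b"".join(_ascii(v, width) for v in values)

    names = [str(n) for n in rec.channel_names]
    header += field((f"EEG {n}" for n in names), 16)
    header += field(("" for _ in names), 80)          # transducer
    header += field(("uV" for _ in names), 8)         # physical dimension
    header += field((f"{-m:.6g}" for m in phys_max), 8)
    header += field((f"{m:.6g}" for m in phys_max), 8)
    header += field((str(dig_min) for _ in names), 8)
    header += field((str(dig_max) for _ in names), 8)
    header += field(("" for _ in names), 80)          # prefiltering
    header += field((str(spr) for _ in names), 8)
    header += field(("" for _ in names), 32)

    scale = (dig_max - dig_min) / (2 * phys_max)      # digital units per uV
    digital = np.clip(np.round(padded * scale[:, None]), dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())


def read_edf(path: str | os.PathLike, label: int | None = None) -> EegRecording:
    """Read an EDF file into an :class:`EegRecording` (microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # Volts -> microvolts
    names = [n.removeprefix("EEG ").strip() for n in raw.ch_names]
    return EegRecording(
        data=data,
        channel_names=names,
        fs=float(raw.info["sfreq"]),
        subject_id=Path(path).stem,
        label=label,
    )


def write_labels_csv(path: str | os.PathLike,
                     subject_ids: Sequence[str],
                     labels: Sequence[int]) -> None:
    """Write the (subject_id, label) table; label 1 = stroke, 0 = control."""
    pd.DataFrame({"subject_id": subject_ids, "label": labels}).to_csv(path, index=False)


def read_labels_csv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"subject_id", "label"} - set(df.columns)
    if missing:
        raise ParameterError(f"labels table missing columns: {sorted(missing)}")
    return df
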