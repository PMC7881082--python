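"""Reading and writing EEG records and seizure annotations.

Two on-disk record formats are supported:

* **EDF** (European Data Format), the distribution format of public scalp
  EEG databases. Reading is delegated to :mod:`mne` after an in-package
  header validation pass that enforces this package's contract (at least one
  signal, one common sampling rate). A minimal 16-bit EDF writer is included
  so synthetic records can round-trip; amplitudes are stored at the 16-bit
  resolution typical of clinical recorders, so round-trip accuracy is set by
  the stored physical/digital scale factor.
* **CSV record dialect**: header row of channel labels, one row per time
  sample, values in microvolts; the sampling rate is supplied by the caller.

Seizure annotations travel in a sidecar CSV with columns
``record_id,start_s,end_s`` (0-based, half-open second intervals).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import RecordFormatError
from .records import EEGRecord, SeizureAnnotation

__all__ = [
    "read_edf",
    "write_edf",
    "read_csv_record",
    "write_csv_record",
    "read_annotations",
    "write_annotations",
]

_EDF_HEADER_LEN = 256
_EDF_SIGNAL_HEADER_LEN = 256
_DIG_MAX = 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(record: EEGRecord, path) -> None:
    """Write a record as a minimal single-data-record EDF file.

    Each channel is scaled to signed 16-bit integers against a symmetric
    physical range, as EDF prescribes; the quantization step (physical range
    / 2^16) bounds the round-trip error. The whole signal is stored as one
    data record, so no divisibility constraint is placed on the duration.
    """
    path = Path(path)
    n_sig, n_samp = record.signal.shape
    duration = n_samp / record.fs
    dur_str = f"{duration:.6g}"
    if len(dur_str) > 8:
        raise ValueError(f"record duration {duration} not representable in EDF header")

    # symmetric physical range per channel, re-parsed from its 8-char header
    # representation so the stored scale factor is exactly what we used
    phys_max, scales = [], []
    for c in range(n_sig):
        pm = float(np.max(np.abs(record.signal[c])))
        pm = pm * 1.0001 + 1.0  # headroom; avoids zero range on flat channels
        pm_str = f"{pm:.6g}"[:8]
        pm = float(pm_str)
        phys_max.append(pm_str)
        scales.append(pm / _DIG_MAX)

    with open(path, "wb") as fh:
        header_bytes = _EDF_HEADER_LEN + n_sig * _EDF_SIGNAL_HEADER_LEN
        fh.write(_ascii(0, 8))
        fh.write(_ascii(record.record_id[:80], 80))
        fh.write(_ascii("seizurekit", 80))
        fh.write(_ascii("01.01.00", 8))
        fh.write(_ascii("00.00.00", 8))
        fh.write(_ascii(header_bytes, 8))
        fh.write(_ascii("", 44))
        fh.write(_ascii(1, 8))  # one data record
        fh.write(_ascii(dur_str, 8))
        fh.write(_ascii(n_sig, 4))
        fields = [
            [_ascii(lbl[:16], 16) for lbl in record.channel_labels],
            [_ascii("", 80)] * n_sig,
            [_ascii("uV", 8)] * n_sig,
            [_ascii("-" + phys_max[c], 8) for c in range(n_sig)],
            [_ascii(phys_max[c], 8) for c in range(n_sig)],
            [_ascii(-_DIG_MAX, 8)] * n_sig,
            [_ascii(_DIG_MAX, 8)] * n_sig,
            [_ascii("", 80)] * n_sig,
            [_ascii(n_samp, 8)] * n_sig,
            [_ascii("", 32)] * n_sig,
        ]
        for block in fields:
            fh.write(b"".join(block))
        for c in range(n_sig):
            dig = np.round(record.signal[c] / scales[c]).astype("<i2")
            fh.write(dig.tobytes())


def _validate_edf_header(path: Path) -> None:
    """Enforce the package's EDF contract before handing the file to mne."""
    with open(path, "rb") as fh:
        head = fh.read(_EDF_HEADER_LEN)
        if len(head) < _EDF_HEADER_LEN:
            raise RecordFormatError(f"{path}: truncated EDF header (< 256 bytes)")
        try:
            n_sig = int(head[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise RecordFormatError(
                f"{path}: unreadable 'number of signals' header field"
            ) from exc
        if n_sig < 1:
            raise RecordFormatError(
                f"{path}: EDF declares {n_sig} signals; at least 1 required"
            )
        sig_head = fh.read(n_sig * _EDF_SIGNAL_HEADER_LEN)
        if len(sig_head) < n_sig * _EDF_SIGNAL_HEADER_LEN:
            raise RecordFormatError(f"{path}: truncated EDF signal headers")
        # samples-per-record block sits after 8 fixed-width per-signal blocks
        off = n_sig * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
        spr = []
        for c in range(n_sig):
            raw = sig_head[off + 8 * c : off + 8 * (c + 1)].decode("ascii").strip()
            try:
                spr.append(int(raw))
            except ValueError as exc:
                raise RecordFormatError(
                    f"{path}: bad 'samples per record' field for signal {c}: {raw!r}"
                ) from exc
        if len(set(spr)) > 1:
            raise RecordFormatError(
                f"{path}: channels carry differing sampling rates "
                f"(samples per record {sorted(set(spr))}); unsupported"
            )


def read_edf(path, annotations_path=None) -> EEGRecord:
    """Read an EDF file into an :class:`EEGRecord` (microvolts).

    Annotations are empty unless a sidecar annotation CSV is supplied via
    ``annotations_path``.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_edf_header(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - mne message varies
        raise RecordFormatError(f"{path}: unreadable EDF file ({exc})") from exc
    signal = raw.get_data(units="uV")
    record_id = path.stem
    annotations = []
    if annotations_path is not None:
        annotations = read_annotations(annotations_path, record_id=record_id)
    return EEGRecord(
        signal=signal,
        fs=float(raw.info["sfreq"]),
        channel_labels=[str(ch) for ch in raw.ch_names],
        annotations=annotations,
        record_id=record_id,
    )


def write_csv_record(record: EEGRecord, path) -> None:
    """Write the record in the CSV dialect (one column per channel)."""
    df = pd.DataFrame(record.signal.T, columns=record.channel_labels)
    df.to_csv(path, index=False)


def read_csv_record(path, fs: float, annotations_path=None, record_id=None) -> EEGRecord:
    """Read the CSV record dialect: header of channel labels, rows = samples."""
    path = Path(path)
    try:
        df = pd.read_csv(path, engine="python")
    except pd.errors.ParserError as exc:
        raise RecordFormatError(f"{path}: ragged CSV record ({exc})") from exc
    if df.shape[0] == 0:
        raise RecordFormatError(f"{path}: header-only CSV record (no sample rows)")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise RecordFormatError(
                f"{path}: non-numeric cell in column {col!r} at row {row}"
            )
        df[col] = coerced
    if df.isna().any().any():
        row = int(np.flatnonzero(df.isna().any(axis=1).to_numpy())[0]) + 2
        raise RecordFormatError(f"{path}: missing value at row {row}")
    record_id = record_id or path.stem
    annotations = []
    if annotations_path is not None:
        annotations = read_annotations(annotations_path, record_id=record_id)
    return EEGRecord(
        signal=df.to_numpy().T,
        fs=float(fs),
        channel_labels=[str(c) for c in df.columns],
        annotations=annotations,
        record_id=record_id,
    )


def write_annotations(records: list[EEGRecord], path) -> None:
    """Write all records' annotations to a sidecar CSV."""
    rows = [
        {"record_id": rec.record_id, "start_s": ann.start_s, "end_s": ann.end_s}
        for rec in records
        for ann in rec.annotations
    ]
    pd.DataFrame(rows, columns=["record_id", "start_s", "end_s"]).to_csv(
        path, index=False
    )


def read_annotations(path, record_id: str | None = None) -> list[SeizureAnnotation]:
    """Read a sidecar annotation CSV, optionally filtered to one record."""
    df = pd.read_csv(path)
    required = {"record_id", "start_s", "end_s"}
    if not required.issubset(df.columns):
        raise RecordFormatError(
            f"{path}: annotation CSV must carry columns {sorted(required)}"
        )
    if record_id is not None:
        df = df[df["record_id"].astype(str) == str(record_id)]
    return [
        SeizureAnnotation(float(r.start_s), float(r.end_s)) for r in df.itertuples()
    ]
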