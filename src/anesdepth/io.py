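"""Reading/writing EEG records and cutting them into labelled epochs.

Two signal formats are supported:

* CSV — header ``time_s,amplitude_uV``, one sample per row;
* EDF — single-channel European Data Format, physical dimension µV
  (read through :mod:`mne`; written by a minimal built-in writer).

Segment labels travel in a sidecar CSV with header ``start_s,end_s,label``.
"""

from __future__ import annotations

import csv
import logging
import math
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AnesthesiaState, EEGRecord, Epoch, Segment

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# label sidecar


def read_labels(path: str | Path) -> list[Segment]:
    df = pd.read_csv(path)
    required = {"start_s", "end_s", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"label file must have columns {sorted(required)}")
    return [
        Segment(float(r.start_s), float(r.end_s), AnesthesiaState.from_string(r.label))
        for r in df.itertuples()
    ]


def write_labels(segments: list[Segment], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["start_s", "end_s", "label"])
        for seg in segments:
            w.writerow([f"{seg.start_s:.6f}", f"{seg.end_s:.6f}", seg.label.name])


# ---------------------------------------------------------------------------
# CSV signal format


def _read_csv_signal(path: Path) -> tuple[np.ndarray, float]:
    df = pd.read_csv(path)
    if not {"time_s", "amplitude_uV"}.issubset(df.columns):
        raise ValueError("signal CSV must have columns time_s,amplitude_uV")
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise ValueError("signal CSV must contain at least two samples")
    dt = float(np.median(np.diff(t)))
    if dt <= 0:
        raise ValueError("non-increasing time column")
    return df["amplitude_uV"].to_numpy(float), 1.0 / dt


def _write_csv_signal(rec: EEGRecord, path: Path) -> None:
    t = np.arange(len(rec.samples)) / rec.fs_hz
    # %.10g keeps the sample interval exact for power-of-two rates
    pd.DataFrame({"time_s": t, "amplitude_uV": rec.samples}).to_csv(
        path, index=False, float_format="%.10g"
    )


# ---------------------------------------------------------------------------
# EDF: minimal single-channel writer + mne-based reader

_EDF_DIG_MAX = 32767


def _edf_field(value: str, width: int) -> bytes:
    s = value[:width].ljust(width)
    return s.encode("ascii")


def _write_edf(rec: EEGRecord, path: Path) -> None:
    """Write a single-channel EDF file (16-bit, 1 s data records).

    The physical range is symmetric around zero at the signal's absolute
    maximum, so amplitude resolution is |x|max / 32767 µV. A trailing
    partial second is zero-padded.
    """
    fs = rec.fs_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1 s record
    n_rec = math.ceil(len(rec.samples) / spr)
    x = np.zeros(n_rec * spr)
    x[: len(rec.samples)] = rec.samples

    phys_max = max(float(np.max(np.abs(x))), 1e-6)
    scale = _EDF_DIG_MAX / phys_max
    digital = np.clip(np.round(x * scale), -_EDF_DIG_MAX, _EDF_DIG_MAX).astype("<i2")

    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),
            _edf_field("Startdate X X X X", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(str(256 + 256), 8),
            _edf_field("", 44),
            _edf_field(str(n_rec), 8),
            _edf_field("1", 8),
            _edf_field("1", 4),
            # per-signal fields
            _edf_field(f"EEG {rec.channel}"[:16], 16),
            _edf_field("AgAgCl electrode", 80),
            _edf_field("uV", 8),
            _edf_field(f"{-phys_max:.6g}"[:8], 8),
            _edf_field(f"{phys_max:.6g}"[:8], 8),
            _edf_field(str(-_EDF_DIG_MAX), 8),
            _edf_field(str(_EDF_DIG_MAX), 8),
            _edf_field("", 80),
            _edf_field(str(spr), 8),
            _edf_field("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(struct.pack(f"<{len(digital)}h", *digital.tolist()))


def _read_edf(path: Path) -> tuple[np.ndarray, float, str]:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if len(raw.ch_names) > 1:
        log.warning(
            "EDF file %s has %d channels; using the first (%s)",
            path,
            len(raw.ch_names),
            raw.ch_names[0],
        )
    data = raw.get_data(picks=[0])[0]
    # mne returns EEG channels in volts
    return data * 1e6, float(raw.info["sfreq"]), raw.ch_names[0]


# ---------------------------------------------------------------------------
# public record I/O


def read_record(path: str | Path, label_path: str | Path | None = None) -> EEGRecord:
    """Read a signal file (EDF or CSV) plus an optional label sidecar.

    Amplitudes are returned in µV; segments are validated against the
    record duration.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    channel = "unknown"
    if suffix == ".edf":
        samples, fs, channel = _read_edf(path)
    elif suffix == ".csv":
        samples, fs = _read_csv_signal(path)
    else:
        raise ValueError(f"unknown signal file extension {suffix!r} (use .edf or .csv)")
    segments = read_labels(label_path) if label_path is not None else []
    return EEGRecord(samples=samples, fs_hz=fs, segments=segments, channel=channel)


def write_record(
    rec: EEGRecord, path: str | Path, label_path: str | Path | None = None
) -> None:
    """Write a record as EDF or CSV (by extension) plus its label sidecar."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".edf":
        _write_edf(rec, path)
    elif suffix == ".csv":
        _write_csv_signal(rec, path)
    else:
        raise ValueError(f"unknown signal file extension {suffix!r} (use .edf or .csv)")
    if label_path is not None:
        write_labels(rec.segments, label_path)


# ---------------------------------------------------------------------------
# epoching


def epochize(
    rec: EEGRecord, epoch_s: float = 2.0, overlap: float = 0.5
) -> list[Epoch]:
    """Cut a labelled record into fixed-length epochs.

    Windows advance by ``epoch_s * (1 - overlap)``; every epoch lies fully
    inside one labelled segment (windows straddling a segment boundary are
    dropped) and inherits that segment's label.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    n_epoch = int(round(epoch_s * rec.fs_hz))
    if abs(n_epoch - epoch_s * rec.fs_hz) > 1e-6:
        raise ValueError("epoch_s * fs_hz must be an integer number of samples")
    step = max(1, int(round(n_epoch * (1 - overlap))))

    epochs: list[Epoch] = []
    for seg in rec.segments:
        i0 = int(round(seg.start_s * rec.fs_hz))
        i1 = int(round(seg.end_s * rec.fs_hz))
        if i1 - i0 < n_epoch:
            raise ValueError(
                f"epoch_s={epoch_s} exceeds segment {seg.label.name} "
                f"({seg.duration_s:.3f} s)"
            )
        for start in range(i0, i1 - n_epoch + 1, step):
            epochs.append(
                Epoch(
                    samples=rec.samples[start : start + n_epoch],
                    fs_hz=rec.fs_hz,
                    label=seg.label,
                    source_offset_s=start / rec.fs_hz,
                )
            )
    return epochs


def reject_artifacts(
    epochs: list[Epoch], amp_limit_uV: float = 500.0
) -> list[Epoch]:
    """Drop epochs containing any sample beyond ±``amp_limit_uV``.

    A simple amplitude guardrail against gross (e.g. movement or
    electrode-pop) artifacts; the number of rejected epochs is logged.
    """
    if amp_limit_uV <= 0:
        raise ValueError("amp_limit_uV must be positive")
    kept = [e for e in epochs if np.max(np.abs(e.samples)) <= amp_limit_uV]
    n_rej = len(epochs) - len(kept)
    if n_rej:
        log.info("rejected %d/%d epochs above %.0f uV", n_rej, len(epochs), amp_limit_uV)
    return kept
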