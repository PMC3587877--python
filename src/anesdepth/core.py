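"""Core containers: anesthesia states, labelled records and analysis epochs.

The analysis unit throughout the package is the :class:`Epoch` — a
fixed-length, single-channel slice of EEG carrying its anesthesia-state
label. A full recording session is an :class:`EEGRecord`: one amplitude
series in microvolts plus a list of labelled, non-overlapping segments.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np


class AnesthesiaState(enum.IntEnum):
    """The four reference anesthesia classes, ordered by depth.

    The integer order (AWAKE < LIGHT < DEEP < ISOELECTRIC) is also the
    fixed tie-break order used by the classifier.
    """

    AWAKE = 0
    LIGHT = 1
    DEEP = 2
    ISOELECTRIC = 3

    @classmethod
    def from_string(cls, name: str) -> "AnesthesiaState":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            valid = ", ".join(s.name for s in cls)
            raise ValueError(
                f"unknown anesthesia class {name!r}; valid classes: {valid}"
            ) from None


@dataclass(frozen=True)
class Segment:
    """Half-open labelled interval [start_s, end_s) of a record."""

    start_s: float
    end_s: float
    label: AnesthesiaState

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class EEGRecord:
    """Single-channel EEG with sampling rate and state-labelled segments.

    Parameters
    ----------
    samples : ndarray
        Amplitude series in microvolts.
    fs_hz : float
        Sampling rate in Hz.
    segments : list of Segment
        Non-overlapping labelled intervals, within the record duration.
    channel : str
        Montage / channel description.
    """

    samples: np.ndarray
    fs_hz: float
    segments: list[Segment] = field(default_factory=list)
    channel: str = "FPz"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        self.validate_segments()

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz

    def validate_segments(self) -> None:
        tol = 0.5 / self.fs_hz  # half a sample of slack at the record edge
        prev_end = 0.0
        for seg in sorted(self.segments, key=lambda s: s.start_s):
            if seg.end_s <= seg.start_s:
                raise ValueError(f"segment {seg} has non-positive duration")
            if seg.start_s < prev_end - tol:
                raise ValueError(f"segment {seg} overlaps the previous one")
            if seg.end_s > self.duration_s + tol:
                raise ValueError(
                    f"segment {seg} extends past record end ({self.duration_s:.3f} s)"
                )
            prev_end = seg.end_s


@dataclass
class Epoch:
    """Fixed-length windowed slice of a record with its true class label."""

    samples: np.ndarray
    fs_hz: float
    label: AnesthesiaState
    source_offset_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz

    def __len__(self) -> int:
        return len(self.samples)
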