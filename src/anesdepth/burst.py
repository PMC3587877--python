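"""Burst-suppression detection and the burst-suppression ratio (BS%).

A sample is suppressed when it lies inside a run where the rectified
amplitude stays at or below a threshold (default ±5 µV) for at least a
minimum duration (default 0.5 s) — the standard operationalization of
burst suppression in depth-of-anesthesia monitors. BS% is the percentage
of suppressed samples in an epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Epoch

DEFAULT_THRESHOLD_UV = 5.0
DEFAULT_MIN_MS = 500.0


@dataclass
class SuppressionMask:
    """Per-sample suppression flags with the criteria that produced them."""

    flags: np.ndarray
    fs_hz: float
    threshold_uV: float
    min_suppression_ms: float

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, bool)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True values."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_suppression(
    epoch: Epoch,
    threshold_uV: float = DEFAULT_THRESHOLD_UV,
    min_ms: float = DEFAULT_MIN_MS,
) -> SuppressionMask:
    """Flag samples lying in sub-threshold runs of at least ``min_ms``."""
    if threshold_uV <= 0:
        raise ValueError("threshold_uV must be positive")
    quiet = np.abs(epoch.samples) <= threshold_uV
    min_len = int(np.ceil(min_ms / 1000.0 * epoch.fs_hz))
    flags = np.zeros_like(quiet)
    for start, stop in _runs(quiet):
        if stop - start >= min_len:
            flags[start:stop] = True
    return SuppressionMask(
        flags=flags,
        fs_hz=epoch.fs_hz,
        threshold_uV=threshold_uV,
        min_suppression_ms=min_ms,
    )


def bsr(mask: SuppressionMask) -> float:
    """Burst-suppression ratio in percent: 100 × suppressed / total samples."""
    if mask.flags.size == 0:
        raise ValueError("empty suppression mask")
    return 100.0 * float(np.mean(mask.flags))


def burst_suppression_ratio(
    epoch: Epoch,
    threshold_uV: float = DEFAULT_THRESHOLD_UV,
    min_ms: float = DEFAULT_MIN_MS,
) -> float:
    """Convenience wrapper: detect suppression and return BS% for one epoch."""
    return bsr(detect_suppression(epoch, threshold_uV=threshold_uV, min_ms=min_ms))
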