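"""Bispectrum estimation and the SynchFastSlow characteristic.

The bispectrum B(f1, f2) = E[X(f1) X(f2) X*(f1+f2)] captures quadratic
phase coupling between frequency triples; it vanishes for Gaussian
signals. The direct (FFT-based) estimator averages the triple product over
Hann-windowed segments and reports the magnitude surface on the principal
bifrequency domain f1 ≥ f2 ≥ 0, f1 + f2 ≤ analysis ceiling.

SynchFastSlow is the log ratio of summed bispectral magnitude over the
broad 0.5–47 Hz region to the fast 40–47 Hz region (regions defined by the
bifrequency sum f1 + f2), the convention of the BIS monitor literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Epoch

#: Region definitions (Hz, applied to f1 + f2).
BROAD_REGION_HZ = (0.5, 47.0)
FAST_REGION_HZ = (40.0, 47.0)

SENTINEL = float("nan")


@dataclass(frozen=True)
class BispectrumConfig:
    """Segmenting for the direct estimator.

    The default 0.25 s segment gives a 4 Hz bifrequency grid and 15
    averaged segments on a 2 s epoch — coarse but stable enough for the
    region-sum SynchFastSlow feature.
    """

    seg_s: float = 0.25
    overlap: float = 0.5
    window: str = "hann"
    min_segments: int = 8


@dataclass
class BispectrumEstimate:
    """Magnitude surface over the principal bifrequency domain."""

    f1_hz: np.ndarray  # flat arrays, one entry per (f1, f2) grid point
    f2_hz: np.ndarray
    magnitude: np.ndarray
    n_segments: int

    @property
    def fsum_hz(self) -> np.ndarray:
        return self.f1_hz + self.f2_hz

    def region_sum(self, lo_hz: float, hi_hz: float) -> float:
        """Summed magnitude over points with f1 + f2 in [lo, hi]."""
        m = (self.fsum_hz >= lo_hz) & (self.fsum_hz <= hi_hz)
        return float(self.magnitude[m].sum())


def _segments(epochs: list[Epoch], nperseg: int, step: int) -> np.ndarray:
    chunks = []
    for ep in epochs:
        x = ep.samples
        for start in range(0, len(x) - nperseg + 1, step):
            chunks.append(x[start : start + nperseg])
    if not chunks:
        return np.empty((0, nperseg))
    return np.asarray(chunks)


def bispectrum(
    epochs: list[Epoch] | Epoch, cfg: BispectrumConfig | None = None
) -> BispectrumEstimate:
    """Direct bispectrum estimate averaged over windowed segments.

    All epochs must share a sampling rate; segments are demeaned and
    Hann-windowed before the FFT. Raises if fewer than
    ``cfg.min_segments`` segments are available for averaging.
    """
    cfg = cfg or BispectrumConfig()
    if isinstance(epochs, Epoch):
        epochs = [epochs]
    if not epochs:
        raise ValueError("no epochs given")
    fs = epochs[0].fs_hz
    if any(ep.fs_hz != fs for ep in epochs):
        raise ValueError("epochs must share one sampling rate")

    nperseg = int(round(cfg.seg_s * fs))
    step = max(1, int(round(nperseg * (1 - cfg.overlap))))
    segs = _segments(epochs, nperseg, step)
    if len(segs) < cfg.min_segments:
        raise ValueError(
            f"only {len(segs)} segments available; need >= {cfg.min_segments}"
        )

    window = np.hanning(nperseg)
    segs = (segs - segs.mean(axis=1, keepdims=True)) * window
    spectra = np.fft.rfft(segs, axis=1)  # (n_seg, nperseg//2 + 1)

    n_half = spectra.shape[1] - 1
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    ceiling_bin = min(n_half, int(np.floor(BROAD_REGION_HZ[1] / (fs / nperseg))))

    i1_list, i2_list = [], []
    for i1 in range(ceiling_bin + 1):
        for i2 in range(i1 + 1):
            if i1 + i2 <= ceiling_bin:
                i1_list.append(i1)
                i2_list.append(i2)
    i1_arr = np.asarray(i1_list)
    i2_arr = np.asarray(i2_list)

    triple = (
        spectra[:, i1_arr] * spectra[:, i2_arr] * np.conj(spectra[:, i1_arr + i2_arr])
    )
    mag = np.abs(triple.mean(axis=0))
    return BispectrumEstimate(
        f1_hz=freqs[i1_arr],
        f2_hz=freqs[i2_arr],
        magnitude=mag,
        n_segments=len(segs),
    )


def synch_fast_slow(bs: BispectrumEstimate) -> float:
    """log10 of broad-band (0.5–47 Hz) over fast-band (40–47 Hz) bispectral sums.

    NaN sentinel when the fast-band sum is zero (e.g. a strictly
    low-frequency or zero signal).
    """
    num = bs.region_sum(*BROAD_REGION_HZ)
    den = bs.region_sum(*FAST_REGION_HZ)
    if den <= 0 or num <= 0:
        return SENTINEL
    return float(np.log10(num / den))
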