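"""Frequency-domain EEG characteristics.

Welch power spectral density, spectral edge frequency (SEF95), median
frequency, absolute and relative band powers for the classical qEEG bands,
and the BIS-style log beta ratio. All quantile and band features are
computed over the 0.5–47 Hz analysis range used throughout the
depth-of-anesthesia literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import Epoch

#: Analysis range in Hz: high-pass at 0.5 Hz, ceiling at 47 Hz.
ANALYSIS_RANGE_HZ: tuple[float, float] = (0.5, 47.0)

#: Conventional qEEG band edges (the paper-era monitors name the bands but
#: edges vary by vendor; these are the textbook values).
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
}

#: Sub-bands of the BIS beta ratio: log10(P[30-47] / P[11-20]).
BETA_RATIO_BANDS: tuple[tuple[float, float], tuple[float, float]] = (
    (30.0, 47.0),
    (11.0, 20.0),
)

SENTINEL = float("nan")


@dataclass(frozen=True)
class SpectralConfig:
    """Welch estimator settings: 1 s Hann segments, 50 % overlap."""

    seg_s: float = 1.0
    overlap: float = 0.5
    window: str = "hann"


@dataclass
class PSDEstimate:
    """One-sided PSD on a regular frequency grid (µV²/Hz)."""

    freqs_hz: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, float)
        self.power = np.asarray(self.power, float)

    @property
    def df(self) -> float:
        return float(self.freqs_hz[1] - self.freqs_hz[0])

    def band_mask(self, lo_hz: float, hi_hz: float) -> np.ndarray:
        return (self.freqs_hz >= lo_hz) & (self.freqs_hz <= hi_hz)

    def band_power(self, lo_hz: float, hi_hz: float) -> float:
        """Integrated power in [lo, hi] (µV²)."""
        return float(np.sum(self.power[self.band_mask(lo_hz, hi_hz)]) * self.df)

    @property
    def total_power(self) -> float:
        """Integrated power over the analysis range (µV²)."""
        return self.band_power(*ANALYSIS_RANGE_HZ)


def welch_psd(epoch: Epoch, cfg: SpectralConfig | None = None) -> PSDEstimate:
    """Welch PSD of one epoch.

    Satisfies Parseval consistency: the integral of the PSD over [0, fs/2]
    approximates the (mean-removed) signal variance.
    """
    cfg = cfg or SpectralConfig()
    nperseg = int(round(cfg.seg_s * epoch.fs_hz))
    if len(epoch.samples) < nperseg:
        raise ValueError(
            f"epoch of {len(epoch.samples)} samples shorter than one "
            f"{nperseg}-sample FFT segment"
        )
    freqs, power = signal.welch(
        epoch.samples,
        fs=epoch.fs_hz,
        window=cfg.window,
        nperseg=nperseg,
        noverlap=int(round(nperseg * cfg.overlap)),
        detrend="constant",
    )
    return PSDEstimate(freqs_hz=freqs, power=power)


def _power_quantile_freq(psd: PSDEstimate, quantile: float) -> float:
    """Smallest grid frequency whose cumulative power reaches the quantile.

    Computed over the analysis range; ties resolved toward the first bin
    reaching the threshold. Returns NaN for a zero-power spectrum.
    """
    mask = psd.band_mask(*ANALYSIS_RANGE_HZ)
    freqs = psd.freqs_hz[mask]
    power = psd.power[mask]
    total = float(power.sum())
    if total <= 0 or freqs.size == 0:
        return SENTINEL
    cum = np.cumsum(power)
    idx = int(np.searchsorted(cum, quantile * total - 1e-12))
    idx = min(idx, len(freqs) - 1)
    return float(freqs[idx])


def spectral_edge_frequency(psd: PSDEstimate, quantile: float = 0.95) -> float:
    """SEF: frequency below which ``quantile`` of the spectral power lies."""
    return _power_quantile_freq(psd, quantile)


def median_frequency(psd: PSDEstimate) -> float:
    """Frequency splitting the analysis-range power in half (SEF at 0.5)."""
    return _power_quantile_freq(psd, 0.5)


def band_powers(
    psd: PSDEstimate, bands: dict[str, tuple[float, float]] | None = None
) -> tuple[dict[str, float], dict[str, float]]:
    """Absolute band powers (µV²) and ratios relative to total 0.5–47 Hz power.

    Returns ``(absolute, relative)`` keyed by band name; relative ratios
    are NaN sentinels when total power is zero.
    """
    bands = bands or DEFAULT_BANDS
    total = psd.total_power
    absolute = {name: psd.band_power(lo, hi) for name, (lo, hi) in bands.items()}
    if total <= 0:
        relative = {name: SENTINEL for name in bands}
    else:
        relative = {name: absolute[name] / total for name in bands}
    return absolute, relative


def beta_ratio_bis(psd: PSDEstimate) -> float:
    """BIS-style relative beta ratio: log10(P[30–47 Hz] / P[11–20 Hz])."""
    (hi_lo, hi_hi), (lo_lo, lo_hi) = BETA_RATIO_BANDS
    p_fast = psd.band_power(hi_lo, hi_hi)
    p_slow = psd.band_power(lo_lo, lo_hi)
    if p_fast <= 0 or p_slow <= 0:
        return SENTINEL
    return float(np.log10(p_fast / p_slow))
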