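"""Entropy and complexity characteristics of EEG epochs.

Seven information-theoretic measures — Shannon, spectral, Rényi (orders −1
and 3), singular-value-decomposition, approximate entropy and Lempel–Ziv
complexity — plus a wavelet-energy entropy. These quantify the loss of
signal irregularity as anesthesia deepens: awake EEG is broadband and
unpredictable, deep-anesthesia EEG slow and regular, isoelectric EEG
nearly flat.

Histogram-based entropies (Shannon, Rényi) discretize the amplitude
distribution into ``hist_bins`` equal-width bins spanning a fixed
``hist_range_uV`` dynamic range (default ±200 µV, a typical EEG recording
range). Binning against the instrument range rather than the epoch's own
min–max makes these entropies sensitive to amplitude structure as well as
distribution shape: a 40 µV deep-anesthesia trace spreads over many more
bins than a near-isoelectric one, which is precisely what makes them
informative about anesthetic depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .core import Epoch
from .spectral import ANALYSIS_RANGE_HZ, PSDEstimate

SENTINEL = float("nan")


@dataclass(frozen=True)
class EntropyConfig:
    hist_bins: int = 64
    hist_range_uV: float = 200.0  # histogram spans ±hist_range_uV
    apen_m: int = 2
    apen_r_frac: float = 0.2
    svd_dim: int = 10
    svd_delay: int = 1
    lz_threshold: str = "median"  # or "mean"
    wavelet: str = "db4"
    wavelet_levels: int = 4
    renyi_eps: float = 1e-12

    def __post_init__(self) -> None:
        if self.hist_bins < 8:
            raise ValueError("hist_bins must be >= 8")
        if self.hist_range_uV <= 0:
            raise ValueError("hist_range_uV must be positive")
        if self.apen_m < 1:
            raise ValueError("apen_m must be >= 1")
        if not 0 < self.apen_r_frac < 1:
            raise ValueError("apen_r_frac must be in (0, 1)")
        if self.renyi_eps <= 0:
            raise ValueError("renyi_eps must be positive")
        if self.lz_threshold not in ("median", "mean"):
            raise ValueError("lz_threshold must be 'median' or 'mean'")


DEFAULT_CONFIG = EntropyConfig()


def _amplitude_probs(
    x: np.ndarray, bins: int, range_uV: float | None = None
) -> np.ndarray:
    """Occupied-bin probabilities of the amplitude histogram.

    With ``range_uV`` the bins span the fixed interval ±range_uV (samples
    beyond it are clipped into the edge bins); without it the epoch's own
    min–max range is used.
    """
    if np.ptp(x) == 0 and range_uV is None:
        return np.array([1.0])
    if range_uV is not None:
        x = np.clip(x, -range_uV, range_uV)
        counts, _ = np.histogram(x, bins=bins, range=(-range_uV, range_uV))
    else:
        counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / len(x)
    return p


def shannon_entropy(epoch: Epoch, cfg: EntropyConfig = DEFAULT_CONFIG) -> float:
    """Shannon entropy (bits) of the amplitude histogram; 0 for a constant."""
    p = _amplitude_probs(epoch.samples, cfg.hist_bins, cfg.hist_range_uV)
    return float(-np.sum(p * np.log2(p)))


def spectral_entropy(psd: PSDEstimate) -> float:
    """Normalized Shannon entropy of the PSD over the analysis range.

    0 for a single spectral line, 1 for a flat (white) spectrum; NaN
    sentinel for zero total power.
    """
    mask = psd.band_mask(*ANALYSIS_RANGE_HZ)
    power = psd.power[mask]
    total = power.sum()
    if total <= 0 or power.size < 2:
        return SENTINEL
    q = power[power > 0] / total
    return float(-np.sum(q * np.log(q)) / np.log(power.size))


def renyi_entropy(
    epoch: Epoch, order: float, cfg: EntropyConfig = DEFAULT_CONFIG
) -> float:
    """Rényi entropy of order α ≠ 1 (bits) on the amplitude histogram.

    H_α = (1 / (1 − α)) log2 Σ p^α over occupied bins. Zero-count bins are
    excluded before exponentiation — essential for negative orders, where
    p^α diverges as p → 0 — and probabilities are floored at
    ``renyi_eps``. Collapses to log2(k) on k equiprobable bins for any α.
    """
    if order == 1:
        raise ValueError("Renyi order must differ from 1 (use shannon_entropy)")
    p = _amplitude_probs(epoch.samples, cfg.hist_bins, cfg.hist_range_uV)
    if p.size < 2:
        return 0.0
    p = np.maximum(p, cfg.renyi_eps)
    return float(np.log2(np.sum(p**order)) / (1.0 - order))


def svd_entropy(epoch: Epoch, cfg: EntropyConfig = DEFAULT_CONFIG) -> float:
    """Entropy of the normalized singular-value spectrum of a delay embedding.

    The epoch is embedded into a (n − (d−1)τ) × d trajectory matrix with
    dimension d = ``svd_dim`` and lag τ = ``svd_delay``; the Shannon
    entropy of the normalized singular values, divided by log d, indexes
    the effective dimensionality: ≈0 for a rank-deficient (e.g. sinusoidal)
    signal, →1 for broadband noise.
    """
    x = epoch.samples
    d, tau = cfg.svd_dim, cfg.svd_delay
    span = (d - 1) * tau
    if len(x) <= span:
        raise ValueError(f"epoch of {len(x)} samples too short for embedding {d}x{tau}")
    rows = len(x) - span
    idx = np.arange(rows)[:, None] + tau * np.arange(d)[None, :]
    matrix = x[idx]
    sv = np.linalg.svd(matrix, compute_uv=False)
    total = sv.sum()
    if total <= 0:
        return 0.0
    s = sv[sv > 0] / total
    return float(-np.sum(s * np.log(s)) / np.log(d))


# ---------------------------------------------------------------------------
# approximate entropy


def _phi(x: np.ndarray, m: int, r: float) -> float:
    """Φ_m(r): mean log of normalized template self-match counts."""
    n = len(x)
    n_templates = n - m + 1
    templates = np.lib.stride_tricks.sliding_window_view(x, m)
    # Chebyshev distance between all template pairs, vectorized
    dist = np.abs(templates[:, None, :] - templates[None, :, :]).max(axis=2)
    counts = (dist <= r).sum(axis=1)  # self-matches included (Pincus)
    return float(np.mean(np.log(counts / n_templates)))


def approximate_entropy(epoch: Epoch, cfg: EntropyConfig = DEFAULT_CONFIG) -> float:
    """ApEn(m, r) with r = ``apen_r_frac`` × SD of the epoch.

    ApEn = Φ_m(r) − Φ_{m+1}(r), self-matches included. Returns 0 for a
    constant (zero-SD) epoch. Low values indicate regularity; i.i.d. noise
    scores high.
    """
    x = np.asarray(epoch.samples, float)
    if len(x) < 50:
        raise ValueError("approximate entropy needs at least 50 samples")
    sd = float(np.std(x))
    if sd == 0:
        return 0.0
    r = cfg.apen_r_frac * sd
    m = cfg.apen_m
    return _phi(x, m, r) - _phi(x, m + 1, r)


def approximate_entropy_bruteforce(
    x: np.ndarray, m: int, r: float
) -> float:
    """Literal double-loop ApEn for cross-checking the vectorized version.

    Direct transcription of the definition: for each template of length m
    count templates within Chebyshev distance r (including itself), average
    the logs of the normalized counts, and subtract the same at m + 1.
    """
    x = np.asarray(x, float)

    def phi(m_: int) -> float:
        n_t = len(x) - m_ + 1
        logs = []
        for i in range(n_t):
            count = 0
            for j in range(n_t):
                if max(abs(x[i + k] - x[j + k]) for k in range(m_)) <= r:
                    count += 1
            logs.append(np.log(count / n_t))
        return float(np.mean(logs))

    return phi(m) - phi(m + 1)


# ---------------------------------------------------------------------------
# Lempel–Ziv complexity


def lz76_phrase_count(bits: np.ndarray) -> int:
    """Number of phrases in the LZ76 exhaustive-history parse.

    Each phrase is the shortest word starting at the current position that
    has not yet occurred as a substring of the text preceding its last
    symbol (so a phrase may overlap its own start). The final, possibly
    incomplete, phrase counts as one.
    """
    s = "".join("1" if b else "0" for b in np.asarray(bits).astype(bool))
    n = len(s)
    c = 0
    i = 0
    while i < n:
        k = 1
        while i + k <= n and s[i : i + k] in s[0 : i + k - 1]:
            k += 1
        c += 1
        i += k
    return c


def lempel_ziv_complexity(epoch: Epoch, cfg: EntropyConfig = DEFAULT_CONFIG) -> float:
    """Normalized LZ76 complexity of the binarized epoch.

    The signal is binarized against its median (or mean) and parsed into
    LZ76 phrases; the count c(n) is normalized by its random-sequence
    asymptote n / log2(n), so periodic signals score near 0 and random
    ones near 1.
    """
    x = np.asarray(epoch.samples, float)
    n = len(x)
    if n < 32:
        raise ValueError("Lempel-Ziv complexity needs at least 32 samples")
    thresh = np.median(x) if cfg.lz_threshold == "median" else np.mean(x)
    bits = x > thresh
    c = lz76_phrase_count(bits)
    return float(c * np.log2(n) / n)


# ---------------------------------------------------------------------------
# wavelet-based characteristic


def wavelet_characteristic(epoch: Epoch, cfg: EntropyConfig = DEFAULT_CONFIG) -> float:
    """Wavelet-energy entropy (bits).

    Shannon entropy of the relative energy distribution across the
    approximation and detail sub-bands of a ``wavelet_levels``-level
    discrete wavelet decomposition (default db4 × 4). Near 0 when energy
    is confined to one sub-band, near log2(levels + 1) for broadband
    signals; 0 for a zero-energy epoch.
    """
    x = np.asarray(epoch.samples, float)
    if len(x) < 2**cfg.wavelet_levels:
        raise ValueError("epoch too short for the wavelet decomposition depth")
    coeffs = pywt.wavedec(x, cfg.wavelet, level=cfg.wavelet_levels)
    energies = np.array([float(np.sum(c**2)) for c in coeffs])
    total = energies.sum()
    if total <= 0:
        return 0.0
    rel = energies[energies > 0] / total
    return float(-np.sum(rel * np.log2(rel)))
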