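"""Feature extraction: epochs → named feature matrix.

The 19 canonical characteristics plus the BIS-style log beta ratio are
registered under their conventional abbreviations:

========  =====================================
SEF       spectral edge frequency (95 %)
MF        median frequency
DBP/TBP/ABP/BBP   absolute delta/theta/alpha/beta band power
ARF/BRF/TRF       alpha/beta/theta relative band power
BSFSR     bispectral SynchFastSlow ratio
BS%       burst suppression percentage
ShE       Shannon entropy
SE        spectral entropy
RE(-1), RE(3)     Rényi entropies of order −1 and 3
SVDE      singular-value-decomposition entropy
AE        approximate entropy
L-Z V     Lempel–Ziv complexity
WBC       wavelet-energy entropy
BetaRatioBIS      log10 beta power ratio (30–47 / 11–20 Hz)
========  =====================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bispectral, burst, entropy, spectral
from .core import AnesthesiaState, Epoch

log = logging.getLogger(__name__)

#: Canonical feature order; the first 19 are the classical characteristics.
FEATURE_NAMES: tuple[str, ...] = (
    "SEF",
    "MF",
    "DBP",
    "TBP",
    "ABP",
    "BBP",
    "ARF",
    "BRF",
    "TRF",
    "BSFSR",
    "BS%",
    "ShE",
    "SE",
    "RE(-1)",
    "RE(3)",
    "SVDE",
    "AE",
    "L-Z V",
    "WBC",
    "BetaRatioBIS",
)

#: The 19 characteristics of the classical qEEG battery (no BetaRatioBIS).
CLASSIC_FEATURES: tuple[str, ...] = FEATURE_NAMES[:19]

ENTROPY_FEATURES: tuple[str, ...] = (
    "ShE",
    "SE",
    "RE(-1)",
    "RE(3)",
    "SVDE",
    "AE",
    "L-Z V",
)

FREQUENCY_FEATURES: tuple[str, ...] = (
    "SEF",
    "MF",
    "DBP",
    "TBP",
    "ABP",
    "BBP",
    "ARF",
    "BRF",
    "TRF",
)


@dataclass(frozen=True)
class FeatureConfig:
    spectral: spectral.SpectralConfig = field(default_factory=spectral.SpectralConfig)
    bispectral: bispectral.BispectrumConfig = field(
        default_factory=bispectral.BispectrumConfig
    )
    entropy: entropy.EntropyConfig = field(default_factory=entropy.EntropyConfig)
    bsr_threshold_uV: float = burst.DEFAULT_THRESHOLD_UV
    bsr_min_ms: float = burst.DEFAULT_MIN_MS


@dataclass
class FeatureMatrix:
    """Epochs × named-features table with per-row class labels."""

    data: pd.DataFrame
    labels: np.ndarray  # AnesthesiaState integer codes, one per row

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.labels) != len(self.data):
            raise ValueError("labels and data must have equal length")
        if self.data.columns.duplicated().any():
            raise ValueError("feature names must be unique")

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)

    def select(self, subset: list[str]) -> "FeatureMatrix":
        unknown = [s for s in subset if s not in self.data.columns]
        if unknown:
            raise KeyError(
                f"unknown features {unknown}; valid names: {self.feature_names}"
            )
        return FeatureMatrix(self.data[list(subset)].copy(), self.labels.copy())

    def drop_incomplete(self) -> "FeatureMatrix":
        """Remove rows containing sentinel (NaN) values, logging the count."""
        ok = ~self.data.isna().any(axis=1).to_numpy()
        n_bad = int((~ok).sum())
        if n_bad:
            log.info("excluding %d/%d sentinel-valued rows", n_bad, len(self.data))
        return FeatureMatrix(self.data.loc[ok].reset_index(drop=True), self.labels[ok])

    def class_counts(self) -> dict[str, int]:
        return {
            s.name: int(np.sum(self.labels == s.value)) for s in AnesthesiaState
        }


def extract_epoch_features(
    ep: Epoch, cfg: FeatureConfig | None = None
) -> dict[str, float]:
    """All registered characteristics of one epoch."""
    cfg = cfg or FeatureConfig()
    psd = spectral.welch_psd(ep, cfg.spectral)
    absolute, relative = spectral.band_powers(psd)

    try:
        bsp = bispectral.bispectrum(ep, cfg.bispectral)
        bsfsr = bispectral.synch_fast_slow(bsp)
    except ValueError:
        bsfsr = float("nan")

    return {
        "SEF": spectral.spectral_edge_frequency(psd),
        "MF": spectral.median_frequency(psd),
        "DBP": absolute["delta"],
        "TBP": absolute["theta"],
        "ABP": absolute["alpha"],
        "BBP": absolute["beta"],
        "ARF": relative["alpha"],
        "BRF": relative["beta"],
        "TRF": relative["theta"],
        "BSFSR": bsfsr,
        "BS%": burst.burst_suppression_ratio(
            ep, threshold_uV=cfg.bsr_threshold_uV, min_ms=cfg.bsr_min_ms
        ),
        "ShE": entropy.shannon_entropy(ep, cfg.entropy),
        "SE": entropy.spectral_entropy(psd),
        "RE(-1)": entropy.renyi_entropy(ep, -1.0, cfg.entropy),
        "RE(3)": entropy.renyi_entropy(ep, 3.0, cfg.entropy),
        "SVDE": entropy.svd_entropy(ep, cfg.entropy),
        "AE": entropy.approximate_entropy(ep, cfg.entropy),
        "L-Z V": entropy.lempel_ziv_complexity(ep, cfg.entropy),
        "WBC": entropy.wavelet_characteristic(ep, cfg.entropy),
        "BetaRatioBIS": spectral.beta_ratio_bis(psd),
    }


def extract_features(
    epochs: list[Epoch], cfg: FeatureConfig | None = None
) -> FeatureMatrix:
    """Extract the full characteristic battery for a list of epochs."""
    cfg = cfg or FeatureConfig()
    rows = [extract_epoch_features(ep, cfg) for ep in epochs]
    data = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    labels = np.array([int(ep.label) for ep in epochs])
    return FeatureMatrix(data=data, labels=labels)
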