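"""Synthetic anesthesia-EEG generator for the four reference classes.

Real depth-of-anesthesia reference data (awake volunteers, anesthetized
patients, isoelectric brain-death recordings) cannot be redistributed, so
the package ships a transparent generator that emulates the salient
properties of each state:

* AWAKE — low-amplitude, beta-dominant, irregular activity;
* LIGHT — moderate amplitude, alpha/theta-weighted;
* DEEP — high-amplitude delta-dominant activity with a moderate amount of
  burst suppression;
* ISOELECTRIC — near-flat signal at the instrument noise floor with rare,
  tiny residual bursts.

Each class is a mixture of band-pass-filtered white noise, one filter per
classical qEEG band (delta/theta/alpha/beta), weighted by per-band gains
and scaled to the class RMS amplitude. Burst suppression is modelled as a
multiplicative envelope: cycles with exponential lengths alternate a burst
interval and a suppression interval whose share of the cycle equals the
state's ``suppression_fraction``; inside suppression the shaped signal is
attenuated to the noise-floor RMS, emulating residual low-amplitude
cortical activity rather than pure instrument noise. A small white
instrument-noise component is added throughout and the trace is rounded
to the digitizer resolution (``adc_lsb_uV``), as any recorded signal is.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .core import AnesthesiaState, EEGRecord, Segment

#: Generator band edges in Hz. Besides the four classical qEEG bands the
#: generator can place power in a fast 30–47 Hz band ("gamma"): awake EEG
#: carries beta/gamma and frontalis-EMG energy up to the analysis ceiling,
#: and that fast content is what makes awake traces maximally irregular.
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 47.0),
}

#: Fraction of the noise floor RMS contributed by broadband instrument noise.
#: Kept small so that suppressed EEG is dominated by slow residual cortical
#: activity rather than white amplifier noise, as in a well-shielded,
#: band-limited recording chain.
_INSTRUMENT_NOISE_FRAC = 0.01

#: Suppression/burst cycle lengths are exponential, clipped to this range (s).
_CYCLE_CLIP_S = (1.0, 8.0)

#: A suppression interval shorter than this is stretched to it (detectability).
_MIN_SUPPRESSION_S = 0.5


@dataclass(frozen=True)
class StateSpec:
    """Generative description of one anesthesia class.

    Parameters
    ----------
    label : AnesthesiaState
    band_gains : dict
        Relative per-band power weights for delta/theta/alpha/beta
        (dimensionless, non-negative, not all zero).
    amplitude_uV : float
        Target RMS amplitude of the non-suppressed (burst) signal, in µV.
    suppression_fraction : float
        Fraction of time spent in suppression, in [0, 1].
    burst_rate_hz : float
        Burst onsets per second; sets the mean suppression/burst cycle
        length (only meaningful when ``suppression_fraction`` ∈ (0, 1)).
    """

    label: AnesthesiaState
    band_gains: dict[str, float] = field(
        default_factory=lambda: {b: 1.0 for b in BAND_EDGES}
    )
    amplitude_uV: float = 10.0
    suppression_fraction: float = 0.0
    burst_rate_hz: float = 0.0

    def __post_init__(self) -> None:
        gains = {b: float(self.band_gains.get(b, 0.0)) for b in BAND_EDGES}
        if any(g < 0 for g in gains.values()):
            raise ValueError("band_gains must be non-negative")
        if not any(g > 0 for g in gains.values()):
            raise ValueError("band_gains must not all be zero")
        object.__setattr__(self, "band_gains", gains)
        if not 0.0 <= self.suppression_fraction <= 1.0:
            raise ValueError("suppression_fraction must be in [0, 1]")
        if self.amplitude_uV <= 0:
            raise ValueError("amplitude_uV must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters shared across classes.

    ``fs_hz`` defaults to 128 Hz, comfortably above twice the 47 Hz
    analysis ceiling used by the spectral features. ``duration_s_per_class``
    defaults to 60 s — the study-replica scale used throughout the test
    suite; pass 900 for a full 15-minute-per-class session.
    """

    fs_hz: float = 128.0
    duration_s_per_class: float = 60.0
    seed: int = 0
    noise_floor_uV: float = 0.5
    adc_lsb_uV: float = 0.01

    def __post_init__(self) -> None:
        if self.fs_hz < 100:
            raise ValueError("fs_hz must be >= 100 (Nyquist above 47 Hz ceiling)")
        if self.duration_s_per_class <= 0:
            raise ValueError("duration_s_per_class must be positive")
        if self.noise_floor_uV < 0:
            raise ValueError("noise_floor_uV must be non-negative")
        if self.adc_lsb_uV < 0:
            raise ValueError("adc_lsb_uV must be non-negative")


def default_state_specs() -> dict[AnesthesiaState, StateSpec]:
    """Default generative specs for the four reference classes.

    The band weights encode the classical low-frequency shift of the EEG
    under deepening anesthesia: beta/gamma-dominant awake activity gives
    way to alpha/theta, then high-amplitude delta with occasional brief
    burst suppression, and finally a fully suppressed isoelectric trace
    whose only content is a slow sub-noise-floor drift. Amplitudes
    (10/20/60/2 µV RMS) follow the qualitative amplitude increase with
    depth; they are simulator defaults, not clinical claims.
    """
    return {
        AnesthesiaState.AWAKE: StateSpec(
            label=AnesthesiaState.AWAKE,
            band_gains={
                "delta": 0.02, "theta": 0.05, "alpha": 0.1, "beta": 1.0, "gamma": 0.8,
            },
            amplitude_uV=10.0,
            suppression_fraction=0.0,
            burst_rate_hz=0.0,
        ),
        AnesthesiaState.LIGHT: StateSpec(
            label=AnesthesiaState.LIGHT,
            band_gains={
                "delta": 0.2, "theta": 0.5, "alpha": 1.0, "beta": 0.05, "gamma": 0.0,
            },
            amplitude_uV=20.0,
            suppression_fraction=0.0,
            burst_rate_hz=0.0,
        ),
        AnesthesiaState.DEEP: StateSpec(
            label=AnesthesiaState.DEEP,
            band_gains={
                "delta": 1.0, "theta": 0.1, "alpha": 0.01, "beta": 0.002, "gamma": 0.0,
            },
            amplitude_uV=60.0,
            suppression_fraction=0.05,
            burst_rate_hz=0.05,
        ),
        AnesthesiaState.ISOELECTRIC: StateSpec(
            label=AnesthesiaState.ISOELECTRIC,
            band_gains={
                "delta": 1.0, "theta": 0.0, "alpha": 0.0, "beta": 0.0, "gamma": 0.0,
            },
            amplitude_uV=2.0,
            suppression_fraction=1.0,
            burst_rate_hz=0.0,
        ),
    }


def _shaped_noise(
    n: int, fs_hz: float, band_gains: dict[str, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS mixture of band-pass-filtered white noise."""
    out = np.zeros(n)
    for band, (lo, hi) in BAND_EDGES.items():
        gain = band_gains.get(band, 0.0)
        if gain <= 0:
            continue
        white = rng.standard_normal(n)
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs_hz, output="sos")
        comp = signal.sosfiltfilt(sos, white)
        rms = np.sqrt(np.mean(comp**2))
        if rms > 0:
            # gains weight band *power*
            out += np.sqrt(gain) * comp / rms
    total_rms = np.sqrt(np.mean(out**2))
    if total_rms > 0:
        out /= total_rms
    return out


def _suppression_envelope(
    n: int,
    fs_hz: float,
    fraction: float,
    burst_rate_hz: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean mask, True where the signal is suppressed.

    Cycle lengths are exponential with mean ``1 / burst_rate_hz`` (clipped
    to a physiological range); within each cycle the leading
    ``fraction``-share is suppressed, so the realized suppression fraction
    tracks the requested one closely even on short records. The per-cycle
    split also bounds single suppression intervals by the cycle length,
    which keeps moderate burst suppression from producing implausibly long
    flat stretches.
    """
    mask = np.zeros(n, dtype=bool)
    if fraction <= 0:
        return mask
    if fraction >= 1:
        return np.ones(n, dtype=bool)
    rate = burst_rate_hz if burst_rate_hz > 0 else 0.25
    t = 0.0
    total_s = n / fs_hz
    while t < total_s:
        cycle = float(np.clip(rng.exponential(1.0 / rate), *_CYCLE_CLIP_S))
        supp = max(fraction * cycle, _MIN_SUPPRESSION_S)
        supp = min(supp, cycle)
        i0 = int(round(t * fs_hz))
        i1 = int(round((t + supp) * fs_hz))
        mask[i0 : min(i1, n)] = True
        t += cycle
    return mask


def simulate_class(
    spec: StateSpec, cfg: SimConfig, seed: int | None = None
) -> EEGRecord:
    """Generate one labelled record for a single anesthesia class.

    Deterministic: identical (spec, cfg, seed) produce bit-identical
    samples. ``seed`` defaults to ``cfg.seed``.
    """
    n = int(round(cfg.fs_hz * cfg.duration_s_per_class))
    if n < 2:
        raise ValueError("duration too short for even one epoch")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    shaped = spec.amplitude_uV * _shaped_noise(n, cfg.fs_hz, spec.band_gains, rng)
    mask = _suppression_envelope(
        n, cfg.fs_hz, spec.suppression_fraction, spec.burst_rate_hz, rng
    )
    gain = np.ones(n)
    if spec.amplitude_uV > 0:
        gain[mask] = cfg.noise_floor_uV / spec.amplitude_uV
    x = shaped * gain
    x += _INSTRUMENT_NOISE_FRAC * cfg.noise_floor_uV * rng.standard_normal(n)
    if cfg.adc_lsb_uV > 0:
        # digitizer resolution: near-isoelectric stretches collapse onto a
        # few discrete codes, as in real flat recordings
        x = np.round(x / cfg.adc_lsb_uV) * cfg.adc_lsb_uV

    seg = Segment(0.0, n / cfg.fs_hz, spec.label)
    return EEGRecord(samples=x, fs_hz=cfg.fs_hz, segments=[seg])


def simulate_study(
    cfg: SimConfig,
    specs: dict[AnesthesiaState, StateSpec] | None = None,
) -> EEGRecord:
    """Concatenate one labelled segment per class into a full study record.

    All four classes must be present; segments appear in depth order
    (AWAKE, LIGHT, DEEP, ISOELECTRIC). Per-class sub-streams are seeded
    independently from ``cfg.seed`` so records are reproducible and class
    signals do not share noise.
    """
    if specs is None:
        specs = default_state_specs()
    for state in AnesthesiaState:
        if state not in specs:
            raise ValueError(f"missing class in specs: {state.name}")

    pieces: list[np.ndarray] = []
    segments: list[Segment] = []
    offset = 0.0
    ss = np.random.SeedSequence(cfg.seed)
    child_seeds = ss.spawn(len(AnesthesiaState))
    for state, child in zip(AnesthesiaState, child_seeds):
        seed = int(child.generate_state(1)[0] % (2**31))
        rec = simulate_class(specs[state], cfg, seed=seed)
        pieces.append(rec.samples)
        segments.append(Segment(offset, offset + rec.duration_s, state))
        offset += rec.duration_s
    return EEGRecord(
        samples=np.concatenate(pieces), fs_hz=cfg.fs_hz, segments=segments
    )


def with_suppression(spec: StateSpec, fraction: float) -> StateSpec:
    """Copy of ``spec`` with a different suppression fraction."""
    return replace(spec, suppression_fraction=fraction)
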