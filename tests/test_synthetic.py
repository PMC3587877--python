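import numpy as np
import pytest

from anesdepth import synthetic
from anesdepth.burst import burst_suppression_ratio
from anesdepth.core import AnesthesiaState, Epoch
from anesdepth.spectral import welch_psd
from anesdepth.synthetic import SimConfig, StateSpec, default_state_specs


class TestDefaultSpecs:
    def test_deep_is_delta_dominant(self):
        specs = default_state_specs()
        deep = specs[AnesthesiaState.DEEP]
        assert deep.band_gains["delta"] > deep.band_gains["beta"]

    def test_suppression_increases_with_depth(self):
        specs = default_state_specs()
        assert (
            specs[AnesthesiaState.ISOELECTRIC].suppression_fraction
            > specs[AnesthesiaState.DEEP].suppression_fraction
        )
        assert specs[AnesthesiaState.AWAKE].suppression_fraction == 0.0

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="band_gains"):
            StateSpec(AnesthesiaState.AWAKE, band_gains={"delta": -1.0})
        with pytest.raises(ValueError, match="band_gains"):
            StateSpec(AnesthesiaState.AWAKE, band_gains={"delta": 0.0})
        with pytest.raises(ValueError, match="suppression_fraction"):
            StateSpec(AnesthesiaState.AWAKE, suppression_fraction=1.5)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="fs_hz"):
            SimConfig(fs_hz=50.0)
        with pytest.raises(ValueError, match="duration"):
            SimConfig(duration_s_per_class=0.0)


class TestSimulateClass:
    def test_deterministic(self):
        spec = default_state_specs()[AnesthesiaState.LIGHT]
        cfg = SimConfig(seed=7, duration_s_per_class=10.0)
        a = synthetic.simulate_class(spec, cfg)
        b = synthetic.simulate_class(spec, cfg)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_fully_suppressed_silent_limit(self):
        spec = StateSpec(
            AnesthesiaState.ISOELECTRIC,
            band_gains={"delta": 1.0},
            amplitude_uV=2.0,
            suppression_fraction=1.0,
        )
        cfg = SimConfig(seed=0, duration_s_per_class=10.0, noise_floor_uV=0.0)
        rec = synthetic.simulate_class(spec, cfg)
        assert np.sqrt(np.mean(rec.samples**2)) < 1e-9

    def test_deep_psd_peaks_in_delta(self):
        spec = default_state_specs()[AnesthesiaState.DEEP]
        cfg = SimConfig(seed=3, duration_s_per_class=30.0)
        rec = synthetic.simulate_class(spec, cfg)
        psd = welch_psd(Epoch(rec.samples, rec.fs_hz, AnesthesiaState.DEEP))
        mask = (psd.freqs_hz >= 0.5) & (psd.freqs_hz <= 47.0)
        peak = psd.freqs_hz[mask][np.argmax(psd.power[mask])]
        assert 0.5 <= peak <= 4.0

    def test_amplitude_scaling(self):
        spec = default_state_specs()[AnesthesiaState.LIGHT]
        cfg = SimConfig(seed=5, duration_s_per_class=30.0)
        rec = synthetic.simulate_class(spec, cfg)
        rms = np.sqrt(np.mean(rec.samples**2))
        assert rms == pytest.approx(spec.amplitude_uV, rel=0.15)

    def test_rejects_too_short_duration(self):
        spec = default_state_specs()[AnesthesiaState.AWAKE]
        with pytest.raises(ValueError):
            synthetic.simulate_class(spec, SimConfig(duration_s_per_class=1e-3))


class TestSimulateStudy:
    def test_structure(self):
        cfg = SimConfig(seed=1, duration_s_per_class=20.0)
        rec = synthetic.simulate_study(cfg)
        assert rec.duration_s == pytest.approx(80.0)
        assert [seg.label for seg in rec.segments] == list(AnesthesiaState)
        assert all(seg.duration_s == pytest.approx(20.0) for seg in rec.segments)

    def test_missing_class_raises(self):
        specs = default_state_specs()
        del specs[AnesthesiaState.DEEP]
        with pytest.raises(ValueError, match="DEEP"):
            synthetic.simulate_study(SimConfig(duration_s_per_class=20.0), specs)

    def test_seed_changes_samples_not_structure(self):
        cfg_a = SimConfig(seed=1, duration_s_per_class=20.0)
        cfg_b = SimConfig(seed=2, duration_s_per_class=20.0)
        a = synthetic.simulate_study(cfg_a)
        b = synthetic.simulate_study(cfg_b)
        assert not np.array_equal(a.samples, b.samples)
        assert [s.label for s in a.segments] == [s.label for s in b.segments]
        assert len(a.samples) == len(b.samples)


class TestSuppressionRealism:
    def test_realized_suppression_tracks_spec(self):
        """Detector-measured suppression of a burst-suppressed record stays
        within 0.05 of the generative fraction."""
        spec = StateSpec(
            AnesthesiaState.ISOELECTRIC,
            band_gains={"delta": 1.0},
            amplitude_uV=30.0,
            suppression_fraction=0.9,
            burst_rate_hz=0.2,
        )
        cfg = SimConfig(seed=11, duration_s_per_class=60.0)
        rec = synthetic.simulate_class(spec, cfg)
        measured = burst_suppression_ratio(
            Epoch(rec.samples, rec.fs_hz, spec.label)
        )
        assert abs(measured / 100.0 - 0.9) <= 0.05

    def test_bsr_monotone_in_suppression_fraction(self):
        base = StateSpec(
            AnesthesiaState.DEEP,
            band_gains={"delta": 1.0, "theta": 0.1},
            amplitude_uV=40.0,
            suppression_fraction=0.0,
            burst_rate_hz=0.2,
        )
        cfg = SimConfig(seed=4, duration_s_per_class=60.0)
        values = []
        for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
            rec = synthetic.simulate_class(
                synthetic.with_suppression(base, frac), cfg
            )
            values.append(
                burst_suppression_ratio(Epoch(rec.samples, rec.fs_hz, base.label))
            )
        assert all(a <= b for a, b in zip(values, values[1:]))
        assert values[0] == 0.0
        assert values[-1] == 100.0
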