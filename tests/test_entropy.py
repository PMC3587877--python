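import numpy as np
import pytest

from anesdepth.entropy import (
    EntropyConfig,
    approximate_entropy,
    approximate_entropy_bruteforce,
    lempel_ziv_complexity,
    lz76_phrase_count,
    renyi_entropy,
    shannon_entropy,
    spectral_entropy,
    svd_entropy,
    wavelet_characteristic,
)
from anesdepth.spectral import welch_psd

from conftest import make_epoch, noise_epoch, tone_epoch


class TestShannon:
    def test_constant_signal_zero(self):
        assert shannon_entropy(make_epoch(np.full(256, 3.0))) == 0.0

    def test_uniform_noise_fills_bins(self, rng):
        cfg = EntropyConfig(hist_bins=64, hist_range_uV=200.0)
        x = rng.uniform(-200, 200, size=200_000)
        value = shannon_entropy(make_epoch(x), cfg)
        assert value == pytest.approx(np.log2(64), abs=0.02)

    def test_bounded_by_log_bins(self, rng):
        cfg = EntropyConfig(hist_bins=64)
        for _ in range(10):
            v = shannon_entropy(noise_epoch(rng), cfg)
            assert 0.0 <= v <= np.log2(64)


class TestSpectralEntropy:
    def test_tone_near_zero(self):
        assert spectral_entropy(welch_psd(tone_epoch(10.0))) < 0.4

    def test_white_noise_near_one(self, rng):
        assert spectral_entropy(welch_psd(noise_epoch(rng, duration_s=60.0))) >= 0.9

    def test_bounded(self, rng):
        for _ in range(10):
            v = spectral_entropy(welch_psd(noise_epoch(rng)))
            assert 0.0 <= v <= 1.0

    def test_zero_power_sentinel(self):
        assert np.isnan(spectral_entropy(welch_psd(make_epoch(np.zeros(256)))))


class TestRenyi:
    def _two_level_epoch(self):
        # exactly two occupied bins with p = (1/2, 1/2)
        x = np.concatenate([np.full(128, -50.0), np.full(128, 50.0)])
        return make_epoch(x)

    def test_half_half_order3_is_one_bit(self):
        assert renyi_entropy(self._two_level_epoch(), 3.0) == pytest.approx(1.0)

    def test_half_half_order_minus1_is_one_bit(self):
        assert renyi_entropy(self._two_level_epoch(), -1.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("order", [-1.0, 0.5, 2.0, 3.0])
    def test_equiprobable_bins_collapse_to_log_k(self, order):
        # four equally occupied bins -> log2(4) = 2 bits for every order
        levels = np.array([-150.0, -50.0, 50.0, 150.0])
        x = np.repeat(levels, 64)
        assert renyi_entropy(make_epoch(x), order) == pytest.approx(2.0)

    def test_order_one_limit_approaches_shannon(self, rng):
        ep = noise_epoch(rng, amplitude=60.0)
        she = shannon_entropy(ep)
        lo = renyi_entropy(ep, 0.99)
        hi = renyi_entropy(ep, 1.01)
        assert she == pytest.approx(lo, abs=0.05)
        assert she == pytest.approx(hi, abs=0.05)
        assert hi <= she <= lo  # Renyi entropy decreases in the order

    def test_order_one_rejected(self):
        with pytest.raises(ValueError):
            renyi_entropy(make_epoch(np.zeros(64)), 1.0)

    def test_single_bin_zero(self):
        assert renyi_entropy(make_epoch(np.full(256, 1.0)), 3.0) == 0.0


class TestSVDEntropy:
    def test_sinusoid_below_noise(self, rng):
        assert svd_entropy(tone_epoch(10.0)) < svd_entropy(noise_epoch(rng))

    def test_bounded(self, rng):
        for _ in range(5):
            assert 0.0 <= svd_entropy(noise_epoch(rng)) <= 1.0

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            svd_entropy(make_epoch(np.zeros(5)))


class TestApproximateEntropy:
    def test_constant_zero(self):
        assert approximate_entropy(make_epoch(np.full(256, 2.0))) == 0.0

    def test_sinusoid_below_noise(self, rng):
        assert approximate_entropy(tone_epoch(10.0)) < approximate_entropy(
            noise_epoch(rng)
        )

    def test_matches_bruteforce_oracle(self, rng):
        """Vectorized ApEn equals the literal double-loop definition."""
        cfg = EntropyConfig()
        for _ in range(20):
            x = rng.standard_normal(200)
            fast = approximate_entropy(make_epoch(x), cfg)
            slow = approximate_entropy_bruteforce(
                x, cfg.apen_m, cfg.apen_r_frac * np.std(x)
            )
            assert fast == pytest.approx(slow, abs=1e-10)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            approximate_entropy(make_epoch(np.zeros(10)))


class TestLempelZiv:
    def test_classic_parse(self):
        # hand parse 0 . 001 . 10 . 100 . 1000 . 101 -> 6 phrases
        bits = np.array([int(c) for c in "0001101001000101"])
        assert lz76_phrase_count(bits) == 6

    def test_alternating_sequence_low_complexity(self):
        x = np.tile([0.0, 10.0], 2048)
        assert lempel_ziv_complexity(make_epoch(x)) < 0.1

    def test_random_bits_high_complexity(self, rng):
        x = rng.standard_normal(4096)
        assert lempel_ziv_complexity(make_epoch(x)) > 0.7

    def test_single_symbol_minimal(self):
        assert lz76_phrase_count(np.zeros(64, dtype=int)) == 2

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            lempel_ziv_complexity(make_epoch(np.zeros(8)))


class TestWaveletCharacteristic:
    def test_band_limited_tone_low(self, rng):
        # a slow tone concentrates energy in the deepest approximation band
        assert wavelet_characteristic(tone_epoch(1.0, duration_s=8.0)) < 1.0

    def test_broadband_noise_high(self, rng):
        v = wavelet_characteristic(noise_epoch(rng, duration_s=8.0))
        levels = EntropyConfig().wavelet_levels
        assert 1.5 < v <= np.log2(levels + 1)

    def test_zero_energy_zero(self):
        assert wavelet_characteristic(make_epoch(np.zeros(256))) == 0.0
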