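import math
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import entrofuse as ef
from entrofuse.entropy import ARSpec, EntropyParams
from oracle_utils import ae_brute, fe_brute, se_brute


def random_series(rng, n):
    return rng.standard_normal(n)


class TestSpectralEntropy:
    def test_bounded_and_low_for_pure_tone(self):
        t = np.arange(1000) / 1000.0
        x = np.sin(2 * np.pi * 10 * t)
        h = ef.spectral_entropy(x, 1000.0)
        assert 0 <= h <= 1
        assert h < 0.3  # power concentrated in one bin

    def test_two_equal_bins_give_log2_over_logn(self):
        # on-bin tones at 10 and 20 Hz: exactly two spectral lines, no leakage
        t = np.arange(1000) / 1000.0
        x = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 20 * t)
        n_bins = int(np.sum((np.fft.rfftfreq(1000, 1 / 1000.0) >= 0.15)
                            & (np.fft.rfftfreq(1000, 1 / 1000.0) <= 45.0)))
        assert ef.spectral_entropy(x, 1000.0) == pytest.approx(
            math.log(2) / math.log(n_bins), abs=1e-9
        )

    def test_white_noise_is_nearly_flat(self):
        rng = np.random.default_rng(0)
        vals = [ef.spectral_entropy(rng.standard_normal(1000), 1000.0) for _ in range(100)]
        assert np.mean(vals) > 0.85

    def test_constant_series_is_zero(self):
        assert ef.spectral_entropy(np.full(512, 3.7), 256.0) == 0.0

    def test_nan_input_raises(self):
        with pytest.raises(ValueError):
            ef.spectral_entropy(np.array([1.0, np.nan, 2.0, 0.0]), 4.0)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_amplitude_scaling_invariance(self, scale):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(256)
        a = ef.spectral_entropy(x, 128.0)
        b = ef.spectral_entropy(scale * x, 128.0)
        assert abs(a - b) < 1e-9


class TestEmbeddingEntropiesAgainstBruteForce:
    """SE, FE and AE must match independent O(N^2) enumeration to 1e-10."""

    def test_oracle_agreement_on_random_series(self):
        rng = np.random.default_rng(42)
        params = EntropyParams()
        worst = {"AE": 0.0, "SE": 0.0, "FE": 0.0}
        for _ in range(200):
            n = int(rng.integers(15, 51))
            x = rng.standard_normal(n)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                worst["AE"] = max(worst["AE"], abs(ef.approximate_entropy(x, params) - ae_brute(x)))
                worst["SE"] = max(worst["SE"], abs(ef.sample_entropy(x, params) - se_brute(x)))
                worst["FE"] = max(worst["FE"], abs(ef.fuzzy_entropy(x, params) - fe_brute(x)))
        assert max(worst.values()) < 1e-10, worst

    def test_periodic_series_matches_oracle(self):
        x = np.tile([1.0, 2.0, 3.0], 10)
        params = EntropyParams(m=2, r_factor=0.5 / np.std(x))  # r = 0.5 absolute
        assert ef.approximate_entropy(x, params) == pytest.approx(ae_brute(x, 2, params.r_factor), abs=1e-12)


class TestEmbeddingEntropyProperties:
    @pytest.mark.parametrize("fn", [ef.approximate_entropy, ef.sample_entropy, ef.fuzzy_entropy])
    def test_zero_on_constant_series(self, fn):
        assert fn(np.full(40, 2.5)) == 0.0

    @pytest.mark.parametrize("fn", [ef.approximate_entropy, ef.sample_entropy, ef.fuzzy_entropy])
    def test_nonnegative_on_random_series(self, fn, rng):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vals = [fn(rng.standard_normal(60)) for _ in range(20)]
        assert min(vals) >= 0.0

    @pytest.mark.parametrize("fn", [ef.approximate_entropy, ef.sample_entropy, ef.fuzzy_entropy])
    @given(offset=st.floats(-50, 50), scale=st.floats(0.1, 10))
    def test_offset_and_scale_invariance(self, fn, offset, scale):
        """r = r_factor*SD makes the measures affine-invariant."""
        rng = np.random.default_rng(11)
        x = rng.standard_normal(80)
        base = fn(x)
        assert fn(x + offset) == pytest.approx(base, abs=1e-9)
        assert fn(scale * x) == pytest.approx(base, abs=1e-9)

    @pytest.mark.parametrize("fn", [ef.approximate_entropy, ef.fuzzy_entropy])
    def test_noise_more_irregular_than_sinusoid(self, fn):
        t = np.arange(150) / 100.0
        diffs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            noise = rng.standard_normal(150)
            tone = np.sqrt(2.0) * np.sin(2 * np.pi * 7 * t + rng.uniform(0, 2 * np.pi))
            diffs.append(fn(noise) - fn(tone))
        assert np.mean(diffs) > 0

    def test_sample_entropy_monotone_in_added_noise(self):
        t = np.arange(150) / 100.0
        tone = np.sin(2 * np.pi * 7 * t)
        means = []
        for amp in (0.1, 0.5, 1.0):
            vals = []
            for seed in range(50):
                rng = np.random.default_rng(seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    vals.append(ef.sample_entropy(tone + amp * rng.standard_normal(150)))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_too_short_series_raises(self):
        for fn in (ef.approximate_entropy, ef.sample_entropy, ef.fuzzy_entropy):
            with pytest.raises(ValueError):
                fn(np.array([1.0, 2.0, 3.0]))


class TestARCoefficients:
    def test_white_noise_coefficients_near_zero(self):
        rng = np.random.default_rng(1)
        coefs = ef.ar_coefficients(rng.standard_normal(5000), ARSpec(order=2))
        assert np.all(np.abs(coefs) < 0.05)

    def test_recovers_planted_ar2(self):
        rng = np.random.default_rng(2)
        x = np.zeros(5000)
        e = rng.standard_normal(5000)
        for t in range(2, 5000):
            x[t] = 0.5 * x[t - 1] - 0.3 * x[t - 2] + e[t]
        coefs = ef.ar_coefficients(x, ARSpec(order=2))
        assert coefs == pytest.approx([0.5, -0.3], abs=0.05)

    def test_constant_series_gives_zero_vector_with_warning(self):
        with pytest.warns(UserWarning):
            coefs = ef.ar_coefficients(np.full(100, 1.0), ARSpec(order=3))
        assert np.array_equal(coefs, np.zeros(3))

    def test_order_must_be_below_length(self):
        with pytest.raises(ValueError):
            ef.ar_coefficients(np.arange(5.0), ARSpec(order=10))
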