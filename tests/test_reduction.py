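import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dayfactor import (
    DegenerateInputError,
    MeanSpectrumSeries,
    ValidationError,
    WeightScheme,
    df_series,
    pca_first_component,
    per_channel_df,
    raw_day_factor,
)


def loop_day_factor(magnitudes, frequencies, log=math.log):
    """Independent scalar-loop oracle for the weighted |log Z| sum."""
    total = 0.0
    for z, f in zip(magnitudes, frequencies):
        total += (1.0 / f) * abs(log(z))
    return total


def spectra(days, mags):
    mags = np.asarray(mags, dtype=float)
    freqs = np.geomspace(1.0, 1e4, mags.shape[1])
    return MeanSpectrumSeries(days=days, frequencies=freqs, mean_magnitude=mags), freqs


class TestRawDayFactor:
    def test_single_point_ln_e_is_one(self):
        assert raw_day_factor([math.e], [1.0]) == pytest.approx(1.0, abs=1e-15)

    def test_two_point_hand_value(self):
        # w = [1, 0.1], |ln Z| = [1, 10] -> 1*1 + 0.1*10 = 2
        value = raw_day_factor([math.e, math.e**10], [1.0, 10.0])
        assert value == pytest.approx(2.0, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scalar_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        freqs = np.sort(rng.uniform(0.1, 2e6, size=20))
        mags = 10 ** rng.uniform(2, 7, size=20)
        got = raw_day_factor(mags, freqs)
        assert got == pytest.approx(loop_day_factor(mags, freqs), rel=1e-12)

    def test_base10_log(self):
        value = raw_day_factor([100.0], [1.0], WeightScheme(log_base="base10"))
        assert value == pytest.approx(2.0, rel=1e-14)

    def test_custom_weights(self):
        scheme = WeightScheme(kind="custom", weights=[2.0, 3.0])
        value = raw_day_factor([math.e, math.e], [1.0, 10.0], scheme)
        assert value == pytest.approx(5.0, rel=1e-14)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            raw_day_factor([1e5, 1e5], [1.0])

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValidationError):
            raw_day_factor([-1.0], [1.0])


class TestDFSeries:
    def test_first_day_exactly_one(self, rng):
        mags = 10 ** rng.uniform(3, 7, size=(6, 8))
        series, _ = spectra(np.arange(1, 7), mags)
        assert df_series(series).normalized[0] == 1.0

    def test_identical_spectra_give_flat_unity(self):
        row = np.array([1e6, 2e5, 5e4])
        series, _ = spectra([1, 2, 3], np.tile(row, (3, 1)))
        np.testing.assert_array_equal(df_series(series).normalized, 1.0)

    def test_hand_computed_scaled_day(self):
        # day 2 = day 1 x 10 on a 3-frequency grid; evaluate the formula by hand
        freqs = np.array([1.0, 10.0, 100.0])
        day1 = np.array([1e4, 1e5, 1e6])
        series = MeanSpectrumSeries(days=[1, 2], frequencies=freqs,
                                    mean_magnitude=np.stack([day1, day1 * 10]))
        out = df_series(series)
        raw1 = sum((1 / f) * abs(math.log(z)) for f, z in zip(freqs, day1))
        raw2 = sum((1 / f) * abs(math.log(10 * z)) for f, z in zip(freqs, day1))
        assert out.normalized[1] > 1
        assert out.normalized[1] == pytest.approx(raw2 / raw1, rel=1e-12)

    def test_locality_of_single_frequency_perturbation(self):
        freqs = np.array([1.0, 10.0, 100.0])
        day = np.array([1e4, 1e5, 1e6])
        base = raw_day_factor(day, freqs)
        bumped = day.copy()
        bumped[1] *= 1.7
        delta = abs(math.log(bumped[1])) - abs(math.log(day[1]))
        assert raw_day_factor(bumped, freqs) - base == pytest.approx(
            (1 / freqs[1]) * delta, rel=1e-12)

    def test_uniform_scaling_raises_normalized_df(self, rng):
        mags = 10 ** rng.uniform(3, 6, size=(3, 5))   # all Z > 1 ohm
        series, freqs = spectra([1, 2, 3], mags)
        scaled = mags.copy()
        scaled[2] *= 3.0
        out = df_series(series)
        out_scaled = df_series(
            MeanSpectrumSeries(days=[1, 2, 3], frequencies=freqs, mean_magnitude=scaled))
        assert out_scaled.normalized[2] > out.normalized[2]

    def test_low_frequency_moves_df_more_than_high(self):
        # same relative magnitude change, applied at the lowest vs highest frequency
        freqs = np.array([1.0, 10.0, 1000.0])
        day = np.array([1e5, 1e5, 1e5])
        base = raw_day_factor(day, freqs)
        low, high = day.copy(), day.copy()
        low[0] *= 2.0
        high[-1] *= 2.0
        assert (raw_day_factor(low, freqs) - base) > (raw_day_factor(high, freqs) - base)

    def test_per_channel_convenience_matches_df_series(self, rng):
        mag = 10 ** rng.uniform(3, 6, size=(4, 5, 3))
        days = np.arange(1, 5)
        freqs = np.geomspace(1, 1e4, 5)
        per_chan = per_channel_df(mag, days, freqs)
        assert len(per_chan) == 3
        single = df_series(MeanSpectrumSeries(days=days, frequencies=freqs,
                                              mean_magnitude=mag[:, :, 1]))
        np.testing.assert_allclose(per_chan[1].normalized, single.normalized, rtol=1e-14)


def eig_first_component(matrix):
    """Brute-force covariance eigen-decomposition oracle (days as variables)."""
    centered = matrix - matrix.mean(axis=0, keepdims=True)
    cov = centered.T @ centered
    eigvals, eigvecs = np.linalg.eigh(cov)
    return eigvecs[:, np.argmax(eigvals)]


class TestPCA:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_covariance_eigen_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_days, n_freqs = rng.integers(2, 11, size=2)
        mags = 10 ** rng.uniform(3, 6, size=(n_days, n_freqs))
        series = MeanSpectrumSeries(days=np.arange(1, n_days + 1),
                                    frequencies=np.geomspace(1, 1e4, n_freqs),
                                    mean_magnitude=mags)
        got = pca_first_component(series)
        oracle = eig_first_component(mags.T.astype(float))
        oracle = oracle if oracle[0] >= 0 else -oracle
        np.testing.assert_allclose(np.abs(got.coefficients), np.abs(oracle), atol=1e-10)
        np.testing.assert_allclose(got.normalized_coefficients,
                                   oracle / oracle[0], atol=1e-10)

    def test_agrees_with_sklearn_cross_check(self, rng):
        from sklearn.decomposition import PCA

        mags = 10 ** rng.uniform(3, 6, size=(5, 8))
        series = MeanSpectrumSeries(days=np.arange(1, 6),
                                    frequencies=np.geomspace(1, 1e4, 8),
                                    mean_magnitude=mags)
        got = pca_first_component(series)
        ref = PCA(n_components=1, svd_solver="full").fit(mags.T).components_[0]
        np.testing.assert_allclose(got.normalized_coefficients, ref / ref[0], atol=1e-10)

    def test_rank_one_scaled_profile(self):
        # columns are v * s_d: after centering, loadings follow the centered scales
        v = np.array([1.0, 2.0, 3.0, 4.0])
        scales = np.array([1.0, 1.5, 2.5])
        mags = (np.outer(v, scales)).T          # (days, freqs)
        series = MeanSpectrumSeries(days=[1, 2, 3], frequencies=[1, 10, 100, 1000],
                                    mean_magnitude=mags)
        got = pca_first_component(series)
        oracle = eig_first_component(mags.T)
        oracle = oracle if oracle[0] >= 0 else -oracle
        np.testing.assert_allclose(got.normalized_coefficients, oracle / oracle[0],
                                   atol=1e-10)
        assert np.linalg.norm(got.coefficients) == pytest.approx(1.0, abs=1e-12)

    def test_identical_day_columns_give_constant_loading(self):
        v = np.array([1e5, 2e5, 4e5, 8e5])
        mags = np.tile(v, (3, 1))               # every day identical
        series = MeanSpectrumSeries(days=[1, 2, 3], frequencies=[1, 10, 100, 1000],
                                    mean_magnitude=mags)
        got = pca_first_component(series)
        np.testing.assert_allclose(got.normalized_coefficients, 1.0, atol=1e-10)

    def test_sign_flip_immaterial_after_normalization(self, rng):
        mags = 10 ** rng.uniform(3, 6, size=(4, 6))
        series = MeanSpectrumSeries(days=np.arange(1, 5),
                                    frequencies=np.geomspace(1, 1e4, 6),
                                    mean_magnitude=mags)
        got = pca_first_component(series)
        flipped = -got.coefficients
        np.testing.assert_allclose(flipped / flipped[0], got.normalized_coefficients,
                                   rtol=1e-12)

    def test_zero_variance_after_centering_is_degenerate(self):
        series = MeanSpectrumSeries(days=[1, 2, 3], frequencies=[1, 10, 100, 1000],
                                    mean_magnitude=np.full((3, 4), 1e5))
        with pytest.raises(DegenerateInputError):
            pca_first_component(series)


class TestWeightScheme:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError):
            WeightScheme(kind="bogus")

    def test_custom_requires_weights_of_grid_length(self):
        with pytest.raises(ValidationError):
            WeightScheme(kind="custom")
        scheme = WeightScheme(kind="custom", weights=[1.0, 2.0])
        with pytest.raises(ValidationError):
            scheme.weights_for(np.array([1.0, 2.0, 3.0]))

    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "scheme.yaml"
        path.write_text("kind: custom\nweights: [1.0, 0.5]\nlog_base: base10\n")
        scheme = WeightScheme.from_yaml(path)
        assert scheme.log_base == "base10"
        np.testing.assert_array_equal(scheme.weights_for(np.array([1.0, 2.0])), [1.0, 0.5])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_first_day_unity_for_any_dataset_and_scheme(self, seed):
        rng = np.random.default_rng(seed)
        n_days, n_freqs = int(rng.integers(1, 8)), int(rng.integers(1, 12))
        mags = 10 ** rng.uniform(1, 7, size=(n_days, n_freqs))
        series = MeanSpectrumSeries(days=np.arange(1, n_days + 1),
                                    frequencies=np.sort(rng.uniform(0.1, 1e6, n_freqs)),
                                    mean_magnitude=mags)
        scheme = WeightScheme(kind="custom", weights=rng.uniform(0.1, 2.0, n_freqs),
                              log_base=("natural", "base10")[seed % 2])
        assert df_series(series, scheme).normalized[0] == 1.0
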