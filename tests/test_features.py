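import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import signal as sps

from stressfs import (
    DEFAULT_BANDS,
    FeatureTable,
    extract_features,
    fused_dimension,
    zscore_normalize,
)
from stressfs.errors import ConstantColumnError, ConstantSignalError, TooShortSignalError
from stressfs.features import (
    hjorth_parameters,
    katz_fd,
    line_length,
    peak_to_peak,
    phase_locking_value,
    relative_band_powers,
    skewness_kurtosis,
    spectral_entropy,
)

FS = 256.0
T = np.arange(0, 10, 1 / FS)
TONE10 = np.sin(2 * np.pi * 10 * T)


class TestHjorth:
    def test_constant_signal_raises(self):
        with pytest.raises(ConstantSignalError):
            hjorth_parameters(np.array([2.0, 2, 2, 2]))

    def test_sine_mobility_matches_first_difference_closed_form(self):
        # first difference of a sampled tone scales SD by 2 sin(pi f / fs)
        _, mobility, _ = hjorth_parameters(TONE10)
        assert mobility == pytest.approx(2 * np.sin(np.pi * 10 / FS), rel=1e-3)

    def test_sine_complexity_near_one(self):
        _, _, complexity = hjorth_parameters(TONE10)
        assert complexity == pytest.approx(1.0, rel=0.01)

    def test_activity_is_population_variance(self, rng):
        x = rng.standard_normal(100)
        activity, _, _ = hjorth_parameters(x)
        assert activity == pytest.approx(np.var(x))


class TestTimeDomain:
    def test_peak_to_peak(self):
        assert peak_to_peak(np.array([0.0, 3, -2, 1])) == 5.0
        assert peak_to_peak(np.array([7.0, 7, 7])) == 0.0

    @given(st.floats(-100, 100))
    def test_peak_to_peak_shift_invariant(self, c):
        x = np.array([0.0, 3, -2, 1])
        assert peak_to_peak(x + c) == pytest.approx(peak_to_peak(x), abs=1e-9)

    def test_line_length(self):
        assert line_length(np.array([0.0, 1, 0, 1])) == 3.0
        assert line_length(np.array([0.0, 1, 2, 3])) == 3.0

    def test_line_length_reversal_symmetric(self, rng):
        x = rng.standard_normal(50)
        assert line_length(x) == pytest.approx(line_length(x[::-1]))

    def test_too_short_inputs(self):
        with pytest.raises(TooShortSignalError):
            peak_to_peak(np.array([]))
        with pytest.raises(TooShortSignalError):
            line_length(np.array([1.0]))


class TestMoments:
    def test_symmetric_sample_zero_skew(self):
        skew, _ = skewness_kurtosis(np.array([-1.0, 0, 1]))
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_two_point_sample_kurtosis_one(self):
        # all |x - mu| equal -> fourth moment / sigma^4 = 1 (minimum possible)
        _, kurt = skewness_kurtosis(np.array([-1.0, 1, -1, 1]))
        assert kurt == pytest.approx(1.0)

    def test_gaussian_kurtosis_three(self, rng):
        _, kurt = skewness_kurtosis(rng.standard_normal(200_000))
        assert kurt == pytest.approx(3.0, abs=0.05)

    def test_zero_variance_raises(self):
        with pytest.raises(ConstantSignalError):
            skewness_kurtosis(np.ones(10))


class TestBandPowers:
    def test_pure_tone_concentrates_in_alpha(self, rng):
        x = TONE10 + 1e-3 * rng.standard_normal(TONE10.size)
        rp = relative_band_powers(x, FS)
        assert rp[1] >= 95.0  # alpha = [8, 12)

    def test_relative_powers_sum_to_100(self, rng):
        rp = relative_band_powers(rng.standard_normal(2048), FS)
        assert rp.sum() == pytest.approx(100.0, abs=1e-6)
        assert np.all((rp >= 0) & (rp <= 100))

    def test_band_limited_noise_lands_in_its_band(self, rng):
        # construct 20-30 Hz noise by FFT masking (independent construction)
        white = rng.standard_normal(4096)
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(white.size, 1 / FS)
        spec[(f < 20) | (f >= 30)] = 0.0
        x = np.fft.irfft(spec, n=white.size)
        rp = relative_band_powers(x, FS)
        assert rp[4] >= 90.0  # high beta


class TestSpectralEntropy:
    def _log_k(self, n):
        f, _ = sps.welch(np.zeros(n), fs=FS, nperseg=min(int(4 * FS), n))
        return np.log(((f >= 4) & (f <= 35)).sum())

    def test_tone_entropy_far_below_noise(self, rng):
        log_k = self._log_k(TONE10.size)
        se_tone = spectral_entropy(TONE10, FS)
        se_noise = spectral_entropy(rng.standard_normal(TONE10.size), FS)
        # Hamming-windowed Welch spreads a tone over its main lobe, so the
        # degenerate-spectrum limit is ~0.2 log K rather than 0.
        assert se_tone <= 0.2 * log_k
        assert se_noise >= 0.9 * log_k

    def test_amplitude_invariant(self, rng):
        x = rng.standard_normal(2048)
        assert spectral_entropy(x, FS) == pytest.approx(
            spectral_entropy(100.0 * x, FS), rel=1e-9
        )


class TestKatz:
    def test_ramp_is_a_line(self):
        assert katz_fd(np.array([0.0, 1, 2, 3, 4])) == pytest.approx(1.0)

    def test_alternating_signal_direct_formula(self):
        # planar curve: L = 4 sqrt(2), d = 4 (last point), n = 4
        x = np.array([0.0, 1, 0, 1, 0])
        expected = np.log10(4) / (np.log10(4 / (4 * np.sqrt(2))) + np.log10(4))
        assert expected > 1
        assert katz_fd(x) == pytest.approx(expected)

    def test_time_reversal_invariant_for_symmetric_waveform(self):
        x = np.sin(2 * np.pi * np.arange(101) / 100)  # odd-symmetric full cycle
        assert katz_fd(x) == pytest.approx(katz_fd(x[::-1]), rel=1e-9)

    @given(st.integers(0, 1000))
    def test_dimension_at_least_one(self, seed):
        x = np.random.default_rng(seed).standard_normal(64)
        assert katz_fd(x) >= 1.0


class TestPLV:
    def test_identical_channels(self):
        plv = phase_locking_value(np.vstack([TONE10, TONE10]))
        assert plv[0, 1] == pytest.approx(1.0)

    def test_constant_phase_lag(self):
        lagged = np.sin(2 * np.pi * 10 * T + np.pi / 3)
        plv = phase_locking_value(np.vstack([TONE10, lagged]))
        assert plv[0, 1] == pytest.approx(1.0, abs=1e-3)

    def test_matrix_properties(self, rng):
        plv = phase_locking_value(rng.standard_normal((4, 512)))
        assert np.allclose(plv, plv.T)
        assert np.allclose(np.diag(plv), 1.0)
        assert np.all((plv >= 0) & (plv <= 1))

    def test_independent_phases_follow_random_walk_law(self, rng):
        # |mean of N unit phasors with iid uniform phases| -> sqrt(pi)/(2 sqrt(N))
        n = 1000
        vals = [
            np.abs(np.exp(1j * rng.uniform(0, 2 * np.pi, n)).mean())
            for _ in range(200)
        ]
        theory = np.sqrt(np.pi) / (2 * np.sqrt(n))
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - theory) < 3 * se

    def test_independent_noise_plv_near_zero(self, rng):
        vals = [
            phase_locking_value(rng.standard_normal((2, 1000)))[0, 1]
            for _ in range(10)
        ]
        assert np.mean(vals) < 0.1

    def test_permutation_equivariance(self, rng):
        epoch = rng.standard_normal((4, 512))
        perm = np.array([2, 0, 3, 1])
        plv = phase_locking_value(epoch)
        plv_p = phase_locking_value(epoch[perm])
        assert np.allclose(plv_p, plv[np.ix_(perm, perm)], atol=1e-12)


class TestExtraction:
    @pytest.mark.parametrize("n_channels,expected", [(7, 161), (8, 188), (4, 86)])
    def test_fused_dimension_formula(self, n_channels, expected):
        assert fused_dimension(n_channels) == expected

    def test_full_roster_column_count_and_order(self, small_epochs):
        table = extract_features(small_epochs)
        assert table.n_features == fused_dimension(4) == 86
        assert table.n_rows == small_epochs.n_epochs
        assert list(table.y) == list(small_epochs.labels)
        # per-channel blocks first, connectivity last
        assert table.feature_names[0].startswith("ch00|time|")
        assert table.feature_names[-1].endswith("|connectivity|plv")
        assert len(set(table.feature_names)) == table.n_features

    def test_literal_roster_count(self, small_epochs):
        table = extract_features(small_epochs, roster="literal")
        assert table.n_features == 14 * 4 + 6

    def test_plv_only_roster_two_channels(self, small_epochs):
        from stressfs import EpochSet

        two = EpochSet(
            small_epochs.epochs[:, :2],
            small_epochs.fs,
            small_epochs.window_s,
            small_epochs.labels,
            small_epochs.channel_names[:2],
        )
        table = extract_features(two, roster="plv")
        assert table.n_features == 1

    def test_all_values_finite(self, small_epochs):
        table = extract_features(small_epochs)
        assert np.all(np.isfinite(table.X))

    def test_flat_epoch_dropped_with_warning(self, small_epochs):
        from stressfs import EpochSet

        epochs = small_epochs.epochs.copy()
        epochs[0] = 0.0
        es = EpochSet(
            epochs,
            small_epochs.fs,
            small_epochs.window_s,
            small_epochs.labels,
            small_epochs.channel_names,
        )
        with pytest.warns(UserWarning, match="dropped 1 epoch"):
            table = extract_features(es)
        assert table.n_rows == small_epochs.n_epochs - 1


class TestZscore:
    def test_closed_form_column(self):
        t = FeatureTable(np.array([[1.0], [2.0], [3.0]]), ["a"])
        out, _ = zscore_normalize(t)
        assert np.allclose(out.X[:, 0], [-1.2247448, 0, 1.2247448], atol=1e-6)

    def test_idempotent_and_train_stats_reused(self, rng):
        t = FeatureTable(rng.standard_normal((50, 3)), ["a", "b", "c"])
        out, std = zscore_normalize(t)
        assert np.allclose(out.X.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(out.X.std(axis=0), 1, atol=1e-9)
        again, _ = zscore_normalize(out)
        assert np.allclose(again.X, out.X, atol=1e-9)
        # held-out rows transformed with *training* statistics
        held = FeatureTable(rng.standard_normal((10, 3)) + 5.0, ["a", "b", "c"])
        held_n = std.transform(held)
        assert np.allclose(held_n.X, (held.X - t.X.mean(0)) / t.X.std(0))

    def test_constant_column_named_in_error(self):
        t = FeatureTable(np.c_[np.ones(5), np.arange(5.0)], ["flat", "ok"])
        with pytest.raises(ConstantColumnError, match="flat"):
            zscore_normalize(t)


def test_feature_table_csv_roundtrip(tmp_path, rng):
    t = FeatureTable(
        rng.standard_normal((6, 4)), ["a", "b", "c", "d"], np.array([0, 1, 0, 1, 0, 1])
    )
    path = tmp_path / "t.csv"
    t.to_csv(path)
    back = FeatureTable.from_csv(path)
    assert np.allclose(back.X, t.X, rtol=0, atol=0)
    assert back.feature_names == t.feature_names
    assert np.array_equal(back.y, t.y)
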