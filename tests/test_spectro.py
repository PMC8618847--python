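import numpy as np
import pytest

from bsound.audio_io import Recording
from bsound import spectro
from bsound.spectro import (
    FrameTensor,
    StftParams,
    WindowSpec,
    compute_norm_stats,
    default_params,
    frame_tensor,
    standardize,
    stft,
    to_db_spectrogram,
    window_weights,
)


def brute_force_stft(x, w, hop):
    """Direct double-summation of the windowed DFT (independent oracle)."""
    L = w.shape[0]
    M = (x.shape[0] - L) // hop + 1
    out = np.empty((M, L), dtype=complex)
    n = np.arange(L)
    for m in range(M):
        seg = w * x[m * hop : m * hop + L]
        for k in range(L):
            out[m, k] = np.sum(seg * np.exp(-2j * np.pi * k * n / L))
    return out


class TestWindows:
    def test_hann_endpoint_zero(self):
        w = window_weights(WindowSpec("hann", 8))
        assert w[0] == 0.0 and w[-1] == pytest.approx(0.0, abs=1e-15)

    def test_hamming_endpoint(self):
        w = window_weights(WindowSpec("hamming", 8))
        assert w[0] == pytest.approx(0.08)

    @pytest.mark.parametrize("kind", ["hann", "hamming"])
    def test_symmetry_and_midpoint(self, kind):
        w = window_weights(WindowSpec(kind, 9))  # N = 8 even
        assert w[4] == pytest.approx(1.0)
        assert np.allclose(w, w[::-1])
        assert np.all(w >= 0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(spectro.ConfigError):
            WindowSpec("blackman", 8)


class TestStft:
    def test_dc_concentrates_in_bin_zero(self):
        rec = Recording(samples=np.full(300, 0.3), sample_rate=1000)
        params = StftParams(window=WindowSpec("hann", 64), hop=16,
                            sample_rate=1000, max_freq=500)
        coeffs = stft(rec, params)
        w = window_weights(params.window)
        assert np.allclose(coeffs[:, 0], 0.3 * w.sum())
        # bins away from DC hold only window leakage, orders below the peak
        assert np.max(np.abs(coeffs[:, 10:54])) < 1e-2 * np.abs(coeffs[0, 0])

    def test_matches_brute_force_oracle(self, rng):
        x = rng.normal(size=1000)
        params = StftParams(window=WindowSpec("hann", 64), hop=16,
                            sample_rate=1000, max_freq=500)
        got = stft(Recording(samples=x, sample_rate=1000), params)
        want = brute_force_stft(x, window_weights(params.window), 16)
        assert np.max(np.abs(got - want)) / np.max(np.abs(want)) < 1e-9

    def test_sine_1500hz_lands_in_bin_15(self):
        t = np.arange(44_100) / 44_100
        rec = Recording(samples=np.sin(2 * np.pi * 1500 * t), sample_rate=44_100)
        coeffs = stft(rec, default_params())
        assert np.argmax(np.abs(coeffs).mean(axis=0)[:221]) == 15

    def test_short_signal_rejected(self):
        with pytest.raises(spectro.EmptyInputError):
            stft(Recording(samples=np.zeros(100), sample_rate=44100), default_params())

    def test_column_count(self, rng):
        x = rng.normal(size=88_200)
        coeffs = stft(Recording(samples=x, sample_rate=44_100), default_params())
        assert coeffs.shape[0] == (88_200 - 441) // 110 + 1 == 798


class TestDbSpectrogram:
    def test_db_mapping_and_floor(self):
        params = default_params()
        coeffs = np.zeros((3, 441), dtype=complex)
        coeffs[:, 1] = 1.0  # |X| = 1 -> 0 dB
        sp = to_db_spectrogram(coeffs, params)
        assert sp.values[0, 0] == pytest.approx(0.0)
        assert sp.values[0, 1] == pytest.approx(-100.0)  # |X| = 0 clamps to floor

    def test_default_crop_keeps_15_bins_excluding_dc(self):
        params = default_params()
        coeffs = np.ones((2, 441), dtype=complex)
        sp = to_db_spectrogram(coeffs, params)
        assert sp.n_bins == 15
        assert np.allclose(sp.freq_axis, 100.0 * np.arange(1, 16))


class TestNormalization:
    def test_constant_input(self):
        params = default_params()
        sp = to_db_spectrogram(np.full((4, 441), 0.01, dtype=complex), params)
        mean, std = compute_norm_stats([sp])
        assert mean == pytest.approx(-40.0)
        assert std == pytest.approx(0.0)

    def test_simple_mean(self):
        params = default_params()
        base = spectro.Spectrogram(
            values=np.array([[-10.0, -20.0], [-30.0, -40.0]]),
            freq_axis=np.array([100.0, 200.0]), time_axis=np.zeros(2),
            params=params, n_samples=441)
        mean, _ = compute_norm_stats([base])
        assert mean == pytest.approx(-25.0)

    def test_matches_two_pass_oracle(self, rng):
        params = default_params()
        specs = [spectro.Spectrogram(values=rng.normal(-40, 7, (50, 15)),
                                     freq_axis=np.arange(1, 16) * 100.0,
                                     time_axis=np.zeros(50), params=params,
                                     n_samples=441)
                 for _ in range(7)]
        mean, std = compute_norm_stats(specs)
        allv = np.concatenate([s.values.ravel() for s in specs])
        assert mean == pytest.approx(allv.mean(), abs=1e-12)
        assert std == pytest.approx(allv.std(), abs=1e-12)

    def test_standardize_with_own_stats_gives_unit_stats(self, rng):
        params = default_params()
        sp = spectro.Spectrogram(values=rng.normal(-40, 7, (60, 15)),
                                 freq_axis=np.arange(1, 16) * 100.0,
                                 time_axis=np.zeros(60), params=params,
                                 n_samples=441)
        mean, std = compute_norm_stats([sp])
        out = standardize(sp, mean, std)
        assert out.standardized
        assert out.values.mean() == pytest.approx(0.0, abs=1e-9)
        assert out.values.std() == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_std_rejected(self):
        params = default_params()
        sp = to_db_spectrogram(np.ones((2, 441), dtype=complex), params)
        with pytest.raises(ValueError):
            standardize(sp, 0.0, 0.0)


class TestFrameTensor:
    @pytest.fixture()
    def fragment_spec(self, rng):
        params = default_params()
        rec = Recording(samples=rng.normal(0, 0.01, 88_200), sample_rate=44_100)
        return to_db_spectrogram(stft(rec, params), params, n_samples=88_200)

    def test_default_shape_200x15x4(self, fragment_spec):
        ft = frame_tensor(fragment_spec)
        assert ft.blocks.shape == (200, 15, 4)

    def test_frame_column_alignment(self, fragment_spec):
        ft = frame_tensor(fragment_spec)
        v = fragment_spec.values
        assert np.array_equal(ft.blocks[0], v[0:4].T)       # c_0 = 0
        assert np.array_equal(ft.blocks[1], v[4:8].T)       # c_1 = floor(441/110) = 4
        assert np.array_equal(ft.blocks[2], v[8:12].T)

    def test_blocks_are_untouched_slices_with_zero_padding(self, fragment_spec):
        """Regrouping never alters a value; right edge pads with zeros."""
        ft = frame_tensor(fragment_spec)
        v = fragment_spec.values
        hop = fragment_spec.params.hop
        F = 441.0
        for m in (0, 57, 123, 199):
            c = int(np.floor(m * F / hop))
            avail = max(0, min(4, v.shape[0] - c))
            assert np.array_equal(ft.blocks[m][:, :avail], v[c : c + avail].T)
            assert np.all(ft.blocks[m][:, avail:] == 0.0)

    def test_invalid_cols_rejected(self, fragment_spec):
        with pytest.raises(spectro.ConfigError):
            frame_tensor(fragment_spec, cols_per_frame=0)
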