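"""Acoustic index correctness: closed forms, oracles, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from resound import (
    AudioClip,
    BandOccupancy,
    IndexConfig,
    ParameterError,
    SilentClipError,
    acoustic_entropy,
    adi,
    aei,
    band_occupancy,
    bioacoustic_index,
    compute_all_indices,
    compute_spectrogram,
)


def _tone(freq, dur=2.0, sr=44100, amp=0.5):
    t = np.arange(int(dur * sr)) / sr
    return AudioClip(amp * np.sin(2 * np.pi * freq * t), sr)


def _occ(p):
    p = np.asarray(p, dtype=float)
    edges = np.arange(len(p) + 1) * 1000.0
    return BandOccupancy(proportions=p, band_edges_hz=edges, threshold_db=-50.0)


class TestSpectrogram:
    def test_sine_peak_bin_and_zero_db_max(self):
        spec = compute_spectrogram(_tone(1000.0))
        peak_bin = np.argmax(spec.db.max(axis=1))
        assert abs(spec.freq_hz[peak_bin] - 1000.0) <= spec.bin_width_hz
        assert spec.db.max() == pytest.approx(0.0, abs=1e-12)

    def test_single_window_clip_gives_one_frame(self):
        clip = AudioClip(np.random.default_rng(0).normal(size=512), 44100)
        spec = compute_spectrogram(clip, window_samples=512, overlap=0.0)
        assert spec.n_frames == 1

    def test_frame_count_formula_with_overlap(self):
        clip = AudioClip(np.random.default_rng(0).normal(size=4096), 44100)
        spec = compute_spectrogram(clip, window_samples=512, overlap=0.5)
        assert spec.n_frames == (4096 - 512) // 256 + 1

    def test_silent_clip_signals(self):
        with pytest.raises(SilentClipError):
            compute_spectrogram(AudioClip(np.zeros(44100), 44100))

    def test_all_values_nonpositive(self):
        spec = compute_spectrogram(_tone(3000.0, dur=0.5))
        assert (spec.db <= 0).all()


class TestBandOccupancy:
    def test_pure_tone_occupies_its_band_only(self):
        spec = compute_spectrogram(_tone(500.0))
        occ = band_occupancy(spec)
        assert occ.proportions[0] > 0
        assert np.all(occ.proportions[1:] == 0)

    def test_white_noise_occupies_every_band(self):
        x = np.random.default_rng(1).normal(0, 0.3, 5 * 44100)
        occ = band_occupancy(compute_spectrogram(AudioClip(x, 44100)), threshold_db=-50)
        assert (occ.proportions > 0).all()

    def test_extreme_threshold_fills_all_cells(self):
        occ = band_occupancy(compute_spectrogram(_tone(500.0)), threshold_db=-1e9)
        assert np.allclose(occ.proportions, 1.0)

    def test_band_count_is_floor_of_ratio(self):
        spec = compute_spectrogram(_tone(500.0))
        assert band_occupancy(spec, 1000.0, 10000.0).n_bands == 10
        assert band_occupancy(spec, 3000.0, 10000.0).n_bands == 3

    def test_max_freq_beyond_nyquist_rejected(self):
        spec = compute_spectrogram(_tone(500.0, sr=8000))
        with pytest.raises(ParameterError):
            band_occupancy(spec, max_freq_hz=10000.0)


class TestADI:
    def test_uniform_occupancy_gives_log_n(self):
        assert adi(_occ([0.3] * 10)) == pytest.approx(math.log(10), abs=1e-9)

    def test_point_mass_gives_zero(self):
        assert adi(_occ([0, 0, 0.7, 0, 0, 0, 0, 0, 0, 0])) == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_bands_give_log_2(self):
        assert adi(_occ([0.4, 0.4] + [0] * 8)) == pytest.approx(math.log(2), abs=1e-9)

    def test_empty_occupancy_degenerate_zero(self):
        assert adi(_occ([0.0] * 10)) == 0.0


class TestAEI:
    def test_even_occupancy_gives_zero(self):
        assert aei(_occ([0.25] * 10)) == pytest.approx(0.0, abs=1e-12)

    def test_point_mass_gives_one_minus_inverse_n(self):
        assert aei(_occ([1.0] + [0.0] * 9)) == pytest.approx(0.9, abs=1e-9)

    @given(
        p=arrays(np.float64, 10, elements=st.floats(0.001, 1.0)),
        c=st.floats(0.01, 100.0),
    )
    def test_scale_invariance(self, p, c):
        assert aei(_occ(c * p)) == pytest.approx(aei(_occ(p)), abs=1e-9)

    @given(p=arrays(np.float64, 10, elements=st.floats(0.0, 1.0)))
    def test_range_and_adi_bound(self, p):
        assert 0.0 <= aei(_occ(p)) <= 1.0
        assert 0.0 <= adi(_occ(p)) <= math.log(10) + 1e-12


class TestOracleEquivalence:
    """ADI/AEI recomputed from the raw dB cell matrix by brute force."""

    @staticmethod
    def _brute_force(db, freq, threshold=-50.0, band_w=1000.0, max_f=10000.0):
        n_bands = int(max_f // band_w)
        props = []
        for k in range(n_bands):
            cells = []
            for i, f in enumerate(freq):
                if k * band_w <= f < (k + 1) * band_w:
                    cells.extend(db[i])
            props.append(
                sum(1 for v in cells if v > threshold) / len(cells) if cells else 0.0
            )
        tot = sum(props)
        a = 0.0
        if tot > 0:
            for p in props:
                if p > 0:
                    a -= (p / tot) * math.log(p / tot)
        # Gini via the sorted cumulative-share formula (independent route)
        n = len(props)
        srt = sorted(props)
        mean = sum(srt) / n
        if mean == 0:
            g = 0.0
        else:
            g = (2 * sum((i + 1) * v for i, v in enumerate(srt)) / (n * sum(srt))) - (n + 1) / n
        return a, g

    def test_random_clips_match_brute_force(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            kind = rng.integers(3)
            n = int(0.6 * 44100)
            if kind == 0:
                x = rng.normal(0, 0.2, n)
            elif kind == 1:
                f = rng.uniform(300, 9000)
                x = 0.4 * np.sin(2 * np.pi * f * np.arange(n) / 44100)
                x += rng.normal(0, 0.01, n)
            else:
                x = rng.laplace(0, 0.1, n) * (rng.uniform(size=n) > 0.5)
                if np.max(np.abs(x)) == 0:
                    x[0] = 0.1
            spec = compute_spectrogram(AudioClip(x, 44100))
            occ = band_occupancy(spec)
            a_ref, g_ref = self._brute_force(spec.db, spec.freq_hz)
            assert adi(occ) == pytest.approx(a_ref, abs=1e-9)
            assert aei(occ) == pytest.approx(g_ref, abs=1e-9)


class TestBioacousticIndex:
    def test_flat_mean_spectrum_gives_zero(self):
        spec = compute_spectrogram(_tone(500.0))
        spec.mean_power_db[:] = -20.0  # constant mean spectrum
        assert bioacoustic_index(spec) == pytest.approx(0.0, abs=1e-12)
        spec.mean_power_db = None  # definitional path from the cell matrix
        spec.db[:] = -20.0
        assert bioacoustic_index(spec) == pytest.approx(0.0, abs=1e-12)

    def test_tone_below_range_contributes_nothing(self):
        # tones ride on a -60 dB noise floor, as any field recording does;
        # a tone below min_freq then leaves the in-range spectrum nearly flat
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 5e-4, 2 * 44100)
        t = np.arange(2 * 44100) / 44100
        low_clip = AudioClip(0.5 * np.sin(2 * np.pi * 1000 * t) + noise, 44100)
        high_clip = AudioClip(0.5 * np.sin(2 * np.pi * 5000 * t) + noise, 44100)
        low = bioacoustic_index(compute_spectrogram(low_clip), 2000.0, 22050.0)
        high = bioacoustic_index(compute_spectrogram(high_clip), 2000.0, 22050.0)
        floor = bioacoustic_index(
            compute_spectrogram(AudioClip(noise, 44100)), 2000.0, 22050.0
        )
        # the out-of-range tone adds almost nothing beyond the noise floor's
        # own fluctuation area; the in-range tone adds a large area
        assert high > low
        assert abs(low - floor) < 0.25 * (high - floor)

    def test_empty_range_rejected(self):
        spec = compute_spectrogram(_tone(500.0))
        with pytest.raises(ParameterError):
            bioacoustic_index(spec, 5000.0, 4000.0)

    def test_adding_disjoint_song_never_decreases_bi(self, rng):
        t = np.arange(4 * 44100) / 44100
        base = 0.3 * np.sin(2 * np.pi * 3000 * t)
        for _ in range(5):
            extra = 0.3 * np.sin(2 * np.pi * rng.uniform(6000, 9000) * t + rng.uniform(0, 6))
            bi0 = bioacoustic_index(compute_spectrogram(AudioClip(base, 44100)))
            bi1 = bioacoustic_index(compute_spectrogram(AudioClip(base + extra, 44100)))
            assert bi1 >= bi0 - 1e-9


class TestAcousticEntropy:
    def test_white_noise_saturates_entropies(self):
        x = np.random.default_rng(2).normal(0, 0.2, 30 * 44100)
        h, ht, hf = acoustic_entropy(AudioClip(x, 44100))
        assert ht >= 0.95 and hf >= 0.95 and h >= 0.90

    def test_single_click_has_low_temporal_entropy(self):
        x = np.zeros(60 * 44100)
        x[1000:1044] = 0.8  # 1 ms click
        h, ht, hf = acoustic_entropy(AudioClip(x, 44100))
        assert ht < 0.5

    def test_product_identity_and_silence(self):
        x = np.random.default_rng(3).normal(0, 0.1, 44100)
        h, ht, hf = acoustic_entropy(AudioClip(x, 44100))
        assert h == ht * hf
        assert acoustic_entropy(AudioClip(np.zeros(44100), 44100)) == (0.0, 0.0, 0.0)


class TestComputeAllIndices:
    def test_agrees_with_individual_operations(self):
        x = np.random.default_rng(4).normal(0, 0.2, 3 * 44100)
        clip = AudioClip(x, 44100)
        all_idx = compute_all_indices(clip)
        spec = compute_spectrogram(clip)
        occ = band_occupancy(spec)
        h, ht, hf = acoustic_entropy(clip)
        assert all_idx.adi == pytest.approx(adi(occ), abs=1e-12)
        assert all_idx.aei == pytest.approx(aei(occ), abs=1e-12)
        assert all_idx.bi == pytest.approx(bioacoustic_index(spec), abs=1e-12)
        assert (all_idx.h, all_idx.ht, all_idx.hf) == (h, ht, hf)

    def test_silent_canvas_degenerate(self):
        idx = compute_all_indices(AudioClip(np.zeros(44100), 44100))
        assert idx.degenerate
        assert (idx.adi, idx.aei, idx.bi, idx.h) == (0.0, 0.0, 0.0, 0.0)

    def test_deterministic(self):
        x = np.random.default_rng(5).normal(0, 0.2, 44100)
        a = compute_all_indices(AudioClip(x, 44100))
        b = compute_all_indices(AudioClip(x.copy(), 44100))
        assert a == b

    @pytest.mark.parametrize("c", [0.1, 3.0, 17.5])
    def test_amplitude_scale_invariance(self, c):
        x = np.random.default_rng(6).normal(0, 0.05, 2 * 44100)
        a = compute_all_indices(AudioClip(x, 44100))
        b = compute_all_indices(AudioClip(c * x, 44100))
        assert a.adi == pytest.approx(b.adi, abs=1e-9)
        assert a.aei == pytest.approx(b.aei, abs=1e-9)
        assert a.h == pytest.approx(b.h, abs=1e-9)
        assert a.ht == pytest.approx(b.ht, abs=1e-9)
        assert a.hf == pytest.approx(b.hf, abs=1e-9)
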