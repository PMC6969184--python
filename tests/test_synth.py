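"""Synthetic soundscape generator: sweeps, confounders, noise, scenes."""

import numpy as np
import pytest
from scipy.signal import spectrogram

from upsweep.errors import SceneConfigError
from upsweep.synth import (
    ANALYSIS_BAND_HZ,
    CallParams,
    SceneConfig,
    gen_confounder,
    gen_noise,
    gen_upcall,
    render_scene,
)


def ridge_hz(wave, rate=2000.0):
    """Per-frame peak frequency of an STFT (the sweep-tracking oracle)."""
    f, t, s = spectrogram(wave, fs=rate, nperseg=128, noverlap=96)
    sxx = s[:, s.sum(axis=0) > 1e-12 * s.sum()]
    return f[np.argmax(sxx, axis=0)]


class TestUpcall:
    def test_linear_sweep_hits_midpoint_frequency(self):
        wave = gen_upcall(CallParams(start_hz=100, bandwidth_hz=100, duration_s=1.0))
        ridge = ridge_hz(wave)
        mid = ridge[len(ridge) // 2]
        assert abs(mid - 150.0) <= 2000.0 / 128  # within one STFT bin

    def test_ridge_rises_monotonically(self):
        wave = gen_upcall(CallParams(start_hz=80, bandwidth_hz=120, duration_s=1.5))
        ridge = ridge_hz(wave)
        interior = ridge[2:-2]  # envelope edges have little energy
        assert np.all(np.diff(interior) >= -2000.0 / 128)
        assert interior[-1] > interior[0] + 60

    def test_zero_bandwidth_limit_is_pure_tone(self):
        wave = gen_upcall(CallParams(start_hz=120, bandwidth_hz=1e-9, duration_s=1.0))
        ridge = ridge_hz(wave)
        assert np.all(np.abs(ridge[1:-1] - 120.0) <= 2000.0 / 128)

    def test_amplitude_linearity(self):
        p1 = CallParams(amplitude=1.0)
        p2 = CallParams(amplitude=2.0)
        np.testing.assert_allclose(gen_upcall(p2), 2.0 * gen_upcall(p1), atol=1e-12)

    def test_nyquist_guard(self):
        with pytest.raises(SceneConfigError):
            gen_upcall(CallParams(start_hz=900, bandwidth_hz=200))


class TestConfounders:
    def test_downsweep_ridge_decreases(self):
        wave, lo, hi = gen_confounder("downsweep", np.random.default_rng(0))
        ridge = ridge_hz(wave)[2:-2]
        assert ridge[-1] < ridge[0] - 40
        assert hi > lo

    def test_flat_tonal_ridge_is_flat(self):
        wave, *_ = gen_confounder("flat_tonal", np.random.default_rng(1))
        ridge = ridge_hz(wave)[1:-1]
        assert np.std(ridge) < 2000.0 / 128

    def test_broadband_pulse_is_short(self):
        wave, lo, hi = gen_confounder("broadband_pulse", np.random.default_rng(2))
        assert len(wave) <= 0.2 * 2000 + 1
        assert (lo, hi) == (10.0, 800.0)

    def test_near_miss_outside_call_envelope(self):
        for seed in range(6):
            wave, lo, _ = gen_confounder("near_miss_upsweep", np.random.default_rng(seed))
            dur = len(wave) / 2000.0
            assert lo > 200.0 or dur < 0.4

    def test_unknown_type(self):
        with pytest.raises(SceneConfigError, match="downsweep"):
            gen_confounder("song", np.random.default_rng(0))


class TestNoise:
    def test_flat_slope_spectrum_within_3db(self):
        rng = np.random.default_rng(0)
        # average many periodograms for a stable spectral estimate
        f, psd = None, 0.0
        from scipy.signal import welch

        wave = gen_noise(120.0, 2000.0, slope=0.0, rng=rng)
        f, psd = welch(wave, fs=2000.0, nperseg=1024)
        band = (f >= 20) & (f <= 780)
        db = 10 * np.log10(psd[band] / psd[band].mean())
        assert np.all(np.abs(db) < 3.0)

    def test_out_of_band_power_below_one_percent(self):
        wave = gen_noise(60.0, 2000.0, slope=1.0, band_hz=(10, 800), rng=np.random.default_rng(1))
        spec = np.abs(np.fft.rfft(wave)) ** 2
        f = np.fft.rfftfreq(len(wave), 1 / 2000.0)
        out = spec[(f < 10) | (f > 800)].sum()
        assert out < 0.01 * spec.sum()

    def test_unit_rms(self):
        wave = gen_noise(30.0, 2000.0, slope=1.0, rng=np.random.default_rng(2))
        assert np.sqrt(np.mean(wave**2)) == pytest.approx(1.0, rel=1e-9)

    def test_reproducible(self):
        a = gen_noise(5.0, 2000.0, rng=np.random.default_rng(3))
        b = gen_noise(5.0, 2000.0, rng=np.random.default_rng(3))
        assert np.array_equal(a, b)


class TestRenderScene:
    def test_zero_rates_give_pure_noise(self):
        scene = render_scene(
            SceneConfig(duration_s=30, call_rate_per_hour=0, confounder_rate_per_hour=0)
        )
        assert scene.annotations == []
        assert scene.confounder_log == []
        assert scene.stream.n_samples == 60000

    def test_poisson_call_counts(self):
        # lambda = 10 per scene; the mean over 100 seeds must sit within
        # 3 standard errors of 10
        counts = [
            len(
                render_scene(
                    SceneConfig(
                        duration_s=120,
                        call_rate_per_hour=300,
                        confounder_rate_per_hour=0,
                        rng_seed=seed,
                    )
                ).annotations
            )
            for seed in range(100)
        ]
        lam = 10.0
        se = np.sqrt(lam / 100)
        assert abs(np.mean(counts) - lam) <= 3 * se

    def test_bit_reproducible(self):
        cfg = SceneConfig(duration_s=60, call_rate_per_hour=120, rng_seed=9)
        a, b = render_scene(cfg), render_scene(cfg)
        assert np.array_equal(a.stream.samples, b.stream.samples)
        assert a.annotations == b.annotations

    def test_calls_do_not_overlap_each_other(self, small_scene):
        anns = small_scene.annotations
        for x, y in zip(anns, anns[1:]):
            assert y.begin_time_s >= x.end_time_s

    def test_measured_snr_within_one_db(self):
        # oracle: rendering the same seed with zero rates reproduces the
        # identical noise floor, so scene - noise isolates the calls
        target = 10.0
        measured = []
        seed = 0
        while len(measured) < 50:
            cfg = SceneConfig(
                duration_s=240,
                call_rate_per_hour=180,
                confounder_rate_per_hour=0,
                snr_db=target,
                rng_seed=seed,
            )
            scene = render_scene(cfg)
            noise_only = render_scene(
                SceneConfig(
                    duration_s=240,
                    call_rate_per_hour=0,
                    confounder_rate_per_hour=0,
                    snr_db=target,
                    rng_seed=seed,
                )
            )
            calls = scene.stream.samples - noise_only.stream.samples
            from scipy.signal import butter, sosfiltfilt

            sos = butter(4, ANALYSIS_BAND_HZ, btype="bandpass", fs=2000, output="sos")
            calls_f = sosfiltfilt(sos, calls)
            noise_f = sosfiltfilt(sos, noise_only.stream.samples)
            for ann in scene.annotations:
                i0 = int(ann.begin_time_s * 2000)
                i1 = int(ann.end_time_s * 2000)
                snr = 10 * np.log10(
                    np.mean(calls_f[i0:i1] ** 2) / np.mean(noise_f[i0:i1] ** 2)
                )
                measured.append(snr)
            seed += 1
        assert np.all(np.abs(np.array(measured[:50]) - target) <= 1.0)

    def test_annotations_have_inbox_energy_above_floor(self, small_scene):
        # every annotated call leaves visible energy in its box (SNR 12 here)
        from upsweep.dataset import extract_positive, sample_negatives

        neg = sample_negatives(
            small_scene.stream, small_scene.annotations, n=10, rng_seed=2
        )
        floor = np.median([n.patch.values.mean() for n in neg])
        params = neg[0].patch.params
        for ann in small_scene.annotations:
            ex = extract_positive(small_scene.stream, ann)
            lo = max(0, int((ann.low_freq_hz - params.freq_origin_hz) / params.bin_width_hz))
            hi = int((ann.high_freq_hz - params.freq_origin_hz) / params.bin_width_hz) + 1
            assert ex.patch.values[lo:hi].mean() > floor

    def test_impossible_rate_raises(self):
        with pytest.raises(SceneConfigError):
            render_scene(
                SceneConfig(duration_s=20, call_rate_per_hour=20000, rng_seed=0)
            )
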