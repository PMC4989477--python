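"""Spectra, resting-alpha estimation, alpha ratios, entrainment rules."""

import numpy as np
import pandas as pd
import pytest

from photodrive.preproc import AveragedBlock
from photodrive.recording import Recording
from photodrive.spectra import (
    AlphaPeakNotFound,
    alpha_peak_ratio,
    classify_entrainment,
    cohort_max_amplitude,
    compute_spectrum,
    estimate_resting_alpha,
    spectrum_of_array,
)
from photodrive.spectra import test_ratios as ratio_tests


def make_block(data, sfreq=1000.0, layout=None, period=100):
    n_flash = 40
    onsets = 500 + period * np.arange(n_flash)
    return AveragedBlock(
        multiplier=1.0,
        stim_freq_hz=sfreq / period,
        data=data,
        sfreq_hz=sfreq,
        flash_onset_samples=onsets,
        stim_end_sample=int(onsets[-1] + period),
        n_trains_averaged=30,
        layout=layout,
    )


class TestSpectrum:
    def test_unit_sine_gives_unit_peak_in_its_bin(self):
        t = np.arange(8192) / 1000.0
        x = np.sin(2 * np.pi * 10 * t)  # 10 Hz, integer cycles in 4096+ window
        spec = spectrum_of_array(x[None, :4000], 1000.0, (0, 4000))
        f_pk, a_pk = spec.peak_in_band(5, 15)
        assert f_pk == pytest.approx(10.0, abs=spec.native_resolution_hz)
        assert a_pk == pytest.approx(1.0, rel=0.05)

    def test_subset_average_is_mean_of_channel_amplitudes(self):
        t = np.arange(4000) / 1000.0
        x = np.vstack([np.sin(2 * np.pi * 10 * t), 3 * np.sin(2 * np.pi * 10 * t)])
        spec = spectrum_of_array(x, 1000.0, (0, 4000))
        _, a_pk = spec.peak_in_band(9, 11)
        assert a_pk == pytest.approx(2.0, rel=0.05)

    def test_white_noise_spectrum_is_flat(self):
        rng = np.random.default_rng(0)
        amps = []
        for _ in range(20):
            x = rng.standard_normal((8, 4000))
            spec = spectrum_of_array(x, 1000.0, (0, 4000))
            band = (spec.freqs > 5) & (spec.freqs < 450)
            amps.append(spec.amplitude[band])
        mean_amp = np.mean(amps, axis=0)
        assert mean_amp.std() / mean_amp.mean() < 0.1

    def test_power_is_amplitude_squared(self):
        rng = np.random.default_rng(1)
        spec = spectrum_of_array(rng.standard_normal((2, 1000)), 1000.0, (0, 1000))
        np.testing.assert_allclose(spec.power, spec.amplitude**2)

    def test_parseval_consistency(self):
        # sum of |X_k|^2 over the two-sided padded spectrum equals N_pad
        # times the windowed energy (numpy convention); our amplitude
        # convention rescales by (2/N)^2, asserted here once.
        rng = np.random.default_rng(2)
        x = rng.standard_normal(1024)
        spec = spectrum_of_array(x[None, :], 1000.0, (0, 1024))
        n = 1024
        X = np.fft.rfft(x, n=n)
        two_sided = np.abs(X) ** 2
        two_sided[1:-1] *= 2
        assert two_sided.sum() / n == pytest.approx((x**2).sum(), rel=1e-10)
        np.testing.assert_allclose(spec.amplitude, 2 * np.abs(X) / n, atol=1e-12)

    def test_mixed_channel_types_rejected(self, tiny_layout):
        data = np.zeros((tiny_layout.n_channels, 5000))
        blk = make_block(data, layout=tiny_layout)
        with pytest.raises(ValueError):
            compute_spectrum(blk, list(tiny_layout.names))  # mags + grads


class TestRestingAlpha:
    def _rest_recording(self, layout, signal):
        data = np.tile(signal, (layout.n_channels, 1))
        return Recording(
            data=data, sfreq_hz=1000.0,
            events=np.empty((0, 2)), layout=layout,
        )

    def test_oscillator_frequency_recovered(self, tiny_layout):
        t = np.arange(20000) / 1000.0
        rec = self._rest_recording(tiny_layout, np.sin(2 * np.pi * 10.58 * t))
        grads = tiny_layout.channel_names(types="grad")
        est = estimate_resting_alpha(rec, subset=grads)
        assert est == pytest.approx(10.58, abs=0.06)

    def test_pure_noise_flagged(self, tiny_layout):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((tiny_layout.n_channels, 20000))
        rec = Recording(data=data, sfreq_hz=1000.0, events=np.empty((0, 2)),
                        layout=tiny_layout)
        with pytest.raises(AlphaPeakNotFound):
            estimate_resting_alpha(rec, subset=tiny_layout.channel_names(types="grad"))

    def test_larger_of_two_peaks_wins(self, tiny_layout):
        t = np.arange(20000) / 1000.0
        sig = np.sin(2 * np.pi * 8 * t) + 2 * np.sin(2 * np.pi * 11 * t)
        rec = self._rest_recording(tiny_layout, sig)
        est = estimate_resting_alpha(rec, subset=tiny_layout.channel_names(types="grad"))
        assert est == pytest.approx(11.0, abs=0.06)

    def test_short_rest_rejected(self, tiny_layout):
        rec = self._rest_recording(tiny_layout, np.zeros(5000))
        with pytest.raises(ValueError):
            estimate_resting_alpha(rec)


class TestAlphaPeakRatio:
    def _spec(self, amp_at_10):
        t = np.arange(4000) / 1000.0
        x = amp_at_10 * np.sin(2 * np.pi * 10 * t)
        return spectrum_of_array(x[None, :], 1000.0, (0, 4000))

    def test_identical_spectra_give_unity(self):
        s = self._spec(1.0)
        assert alpha_peak_ratio(s, s, 10.0).ratio == pytest.approx(1.0)

    def test_doubled_stimulation_spectrum_gives_two(self):
        assert alpha_peak_ratio(self._spec(2.0), self._spec(1.0), 10.0).ratio == (
            pytest.approx(2.0, rel=1e-6)
        )

    def test_zero_resting_peak_rejected(self):
        zero = spectrum_of_array(np.zeros((1, 4000)), 1000.0, (0, 4000))
        with pytest.raises(ValueError):
            alpha_peak_ratio(self._spec(1.0), zero, 10.0)

    def test_mismatched_resolution_rejected(self):
        a = self._spec(1.0)
        b = spectrum_of_array(np.zeros((1, 2000)), 1000.0, (0, 2000))
        with pytest.raises(ValueError):
            alpha_peak_ratio(a, b, 10.0)


class TestEntrainmentClassifier:
    def _spectrum_with_peak(self, f_peak, amp, n=4000):
        t = np.arange(n) / 1000.0
        x = amp * np.sin(2 * np.pi * f_peak * t)
        return spectrum_of_array(x[None, :], 1000.0, (0, n))

    def test_peak_at_stim_freq_above_threshold_is_entrained(self):
        spec = self._spectrum_with_peak(10.0, 0.5)
        res = classify_entrainment(spec, 10.0, cohort_max_amp=1.0)
        assert res.entrained
        assert res.rule_trace["concurrence"] and res.rule_trace["amplitude_ok"]

    def test_subthreshold_peak_is_not_entrained(self):
        spec = self._spectrum_with_peak(10.0, 0.1)
        res = classify_entrainment(spec, 10.0, cohort_max_amp=1.0)
        assert not res.entrained
        assert res.rule_trace["concurrence"] and not res.rule_trace["amplitude_ok"]

    def test_response_at_alpha_instead_of_stim_freq_is_not_entrained(self):
        # stimulating at 0.95*alpha while the spectrum peaks at alpha only
        alpha, stim = 10.0, 9.5
        spec = self._spectrum_with_peak(alpha, 0.8)
        res = classify_entrainment(spec, stim, cohort_max_amp=1.0)
        assert res.response_freq_hz == pytest.approx(alpha, abs=0.3)
        assert not res.rule_trace["concurrence"]
        assert not res.entrained

    def test_search_range_outside_spectrum_rejected(self):
        spec = self._spectrum_with_peak(10.0, 1.0)
        with pytest.raises(ValueError):
            classify_entrainment(spec, 1.0, cohort_max_amp=1.0)

    def test_cohort_max_is_max_over_spectra(self):
        specs = [self._spectrum_with_peak(f, a) for f, a in ((10, 1.0), (12, 2.5))]
        assert cohort_max_amplitude(specs) == pytest.approx(2.5, rel=0.05)


class TestRatioStatistics:
    def test_unity_ratios_give_zero_t(self):
        ratios = pd.DataFrame({1.0: [1.0] * 4, 2.0: [1.0] * 4})
        out = ratio_tests(ratios)
        row = out["per_multiplier"].set_index("multiplier").loc[1.0]
        assert row["degenerate"] or row["t"] == 0.0

    def test_elevated_ratios_significant_above_one(self):
        rng = np.random.default_rng(0)
        ratios = pd.DataFrame({1.0: 2.0 + 0.01 * rng.standard_normal(6)})
        out = ratio_tests(ratios)
        row = out["per_multiplier"].iloc[0]
        assert row["p_greater"] < 1e-4
        assert row["p_less"] > 0.999

    def test_t_statistic_matches_hand_formula(self):
        x = np.array([1.2, 0.8, 1.5, 1.1, 0.9])
        out = ratio_tests(pd.DataFrame({1.0: x, 2.0: x * 0.5}))
        t_hand = (x.mean() - 1) / (x.std(ddof=1) / np.sqrt(len(x)))
        row = out["per_multiplier"].set_index("multiplier").loc[1.0]
        assert row["t"] == pytest.approx(t_hand, rel=1e-10)

    def test_pairwise_holm_correction_present(self):
        rng = np.random.default_rng(1)
        ratios = pd.DataFrame(
            {m: 1.0 + 0.1 * rng.standard_normal(5) for m in (0.5, 1.0, 2.0)}
        )
        out = ratio_tests(ratios)
        assert {"t", "p", "p_holm"} <= set(out["pairwise"].columns)
        assert (out["pairwise"]["p_holm"] >= out["pairwise"]["p"] - 1e-12).all()

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            ratio_tests(pd.DataFrame({1.0: [1.0]}))
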