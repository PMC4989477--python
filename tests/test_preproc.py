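"""Filtering closed forms, detrending, and train averaging."""

import numpy as np
import pytest

from photodrive.layout import default_layout
from photodrive.preproc import (
    bandpass,
    bandpass_array,
    detrend_baseline,
    epoch_and_average,
)
from photodrive.protocol import StimProtocol
from photodrive.recording import CODE_FLASH, CODE_TRAIN_START, Recording
from photodrive.synth import ResponseModelParams, simulate_session


def butter_bandpass_gain_sq(f, low=2.0, high=30.0, order=4, sfreq=None):
    """Analytic squared magnitude of the order-n Butterworth bandpass.

    |H(f)|^2 = 1 / (1 + ((f^2 - f1 f2) / (f (f2 - f1)))^(2n)); the
    forward-backward (zero-phase) filter applies it twice, so the measured
    amplitude ratio of a sinusoid is |H|^2.  With ``sfreq`` given, the
    formula is evaluated on the bilinear-transform (prewarped) frequency
    axis, which the digital realization follows exactly; without it the
    analog axis is used (accurate for f << Nyquist).
    """
    if sfreq is not None:
        warp = lambda x: sfreq / np.pi * np.tan(np.pi * x / sfreq)
        f, low, high = warp(f), warp(low), warp(high)
    w = (f**2 - low * high) / (f * (high - low))
    return 1.0 / (1.0 + w ** (2 * order))


def measured_sine_gain(f, sfreq=1000.0, dur=30.0):
    t = np.arange(int(dur * sfreq)) / sfreq
    x = np.sin(2 * np.pi * f * t)
    y = bandpass_array(x[None, :], sfreq)[0]
    interior = slice(int(5 * sfreq), int(25 * sfreq))
    return np.abs(y[interior]).max()


class TestBandpass:
    @pytest.mark.parametrize("f", [1.0, 10.0, 30.0, 50.0])
    def test_zero_phase_magnitude_matches_analytic_form(self, f):
        measured = measured_sine_gain(f)
        # Exact closed form on the prewarped (bilinear) frequency axis.
        assert measured == pytest.approx(
            butter_bandpass_gain_sq(f, sfreq=1000.0), rel=0.02
        )
        if f <= 30.0:
            # Far below Nyquist the analog-axis form holds as well.
            assert measured == pytest.approx(butter_bandpass_gain_sq(f), rel=0.02)

    def test_passband_sine_nearly_unattenuated(self):
        assert 0.98 <= measured_sine_gain(10.0) <= 1.0

    def test_stopband_sine_strongly_attenuated(self):
        assert measured_sine_gain(1.0) < 0.1

    def test_symmetric_input_gives_symmetric_output(self):
        n = 2001
        t = np.arange(n) - n // 2
        x = np.exp(-(t / 150.0) ** 2) * np.cos(2 * np.pi * 0.01 * t)
        y = bandpass_array(x[None, :], 1000.0)[0]
        np.testing.assert_allclose(y, y[::-1], atol=1e-6 * np.abs(y).max())

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 3000))
        lhs = bandpass_array((2.0 * x + 3.0 * y)[None, :], 1000.0)
        rhs = 2.0 * bandpass_array(x[None, :], 1000.0) + 3.0 * bandpass_array(
            y[None, :], 1000.0
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_cutoff_above_nyquist_rejected(self):
        rec = Recording(
            data=np.zeros((1, 100)),
            sfreq_hz=100.0,
            events=np.empty((0, 2)),
            layout=default_layout().subset(["MEG0001"]),
        )
        with pytest.raises(ValueError):
            bandpass(rec, 2.0, 60.0)


class TestDetrendBaseline:
    def test_pure_line_removed_entirely(self):
        t = np.arange(1000, dtype=float)
        x = 3.0 + 0.5 * t
        out = detrend_baseline(x[None, :], (0, 100))
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_offset_sine_keeps_sine_and_zeroes_baseline(self):
        t = np.arange(4000) / 1000.0
        x = np.sin(2 * np.pi * 10 * t) + 5.0
        out = detrend_baseline(x[None, :], (0, 500))[0]
        assert abs(out[:500].mean()) < 1e-10
        # oscillation preserved
        assert np.abs(out).max() == pytest.approx(1.0, abs=0.05)

    def test_baseline_mean_is_machine_zero_for_random_input(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((3, 2000)) * 50
        out = detrend_baseline(x, (100, 600))
        scale = np.abs(x).max()
        assert np.abs(out[:, 100:600].mean(axis=1)).max() < 1e-10 * scale

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            detrend_baseline(np.zeros((1, 100)), (50, 50))


class TestEpochAndAverage:
    def test_averaged_block_structure(self, small_session, small_protocol):
        rec = small_session.block(0)
        m = small_protocol.multipliers[0]
        blk = epoch_and_average(rec, small_protocol, m)
        assert blk.n_trains_averaged == small_protocol.trains_per_block
        assert len(blk.flash_onset_samples) == small_protocol.flashes_per_train
        assert blk.onset_sample == int(round(0.5 * small_protocol.sfreq_hz))

    def test_default_protocol_exposes_forty_flash_onsets(self, tiny_layout):
        protocol = StimProtocol(alpha_hz=10.0, multipliers=(1.0,), trains_per_block=2)
        session = simulate_session(
            protocol, tiny_layout, ResponseModelParams(snr=None, seed=0)
        )
        blk = epoch_and_average(session.block(0), protocol, 1.0)
        assert len(blk.flash_onset_samples) == 40

    def test_identical_trains_average_to_one_train(self, tiny_layout):
        # Build a synthetic recording with identical trains by hand.
        fs, n_trains, n_flash, period = 1000.0, 5, 8, 100
        stride = n_flash * period + 4000
        n = 1000 + n_trains * stride + 4000
        data = np.zeros((tiny_layout.n_channels, n))
        events = []
        rng = np.random.default_rng(0)
        train_shape = rng.standard_normal((tiny_layout.n_channels, stride))
        # First flash 600 samples into each copy, so the 500 ms pre-window
        # stays inside the copied segment.
        for i in range(n_trains):
            start = 1000 + i * stride
            data[:, start : start + stride] = train_shape
            events.append((start + 600, CODE_TRAIN_START))
            for k in range(n_flash):
                events.append((start + 600 + k * period, CODE_FLASH))
        rec = Recording(data=data, sfreq_hz=fs, events=np.array(events),
                        layout=tiny_layout)
        protocol = StimProtocol(
            alpha_hz=10.0, multipliers=(1.0,), trains_per_block=n_trains,
            flashes_per_train=n_flash,
        )
        blk = epoch_and_average(rec, protocol, 1.0)
        start = 1600 - blk.onset_sample
        single = data[:, start : start + blk.n_samples]
        np.testing.assert_allclose(blk.data, single, atol=1e-12)

    def test_averaging_shrinks_independent_noise_by_sqrt_n(self, tiny_layout):
        fs, n_trains, n_flash, period = 1000.0, 30, 4, 100
        stride = n_flash * period + 4000
        n = 1000 + n_trains * stride + 4000
        protocol = StimProtocol(
            alpha_hz=10.0, multipliers=(1.0,), trains_per_block=n_trains,
            flashes_per_train=n_flash,
        )
        ratios = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            data = rng.standard_normal((2, n))
            events = []
            for i in range(n_trains):
                start = 1000 + i * stride
                events.append((start, CODE_TRAIN_START))
                for k in range(n_flash):
                    events.append((start + k * period, CODE_FLASH))
            layout = tiny_layout.subset(list(tiny_layout.names[:2]))
            rec = Recording(data=data, sfreq_hz=fs, events=np.array(events),
                            layout=layout)
            blk = epoch_and_average(rec, protocol, 1.0)
            ratios.append(blk.data.std())
        assert np.mean(ratios) == pytest.approx(1 / np.sqrt(n_trains), rel=0.1)

    def test_missing_events_rejected(self, tiny_layout):
        rec = Recording(
            data=np.zeros((tiny_layout.n_channels, 1000)),
            sfreq_hz=1000.0,
            events=np.empty((0, 2)),
            layout=tiny_layout,
        )
        protocol = StimProtocol(alpha_hz=10.0, multipliers=(1.0,))
        with pytest.raises(ValueError):
            epoch_and_average(rec, protocol, 1.0)
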