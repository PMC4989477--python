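"""Preprocessing: bandpass filtering, detrending/baseline, train averaging.

The continuous recording of each stimulation block is zero-phase bandpass
filtered (2-30 Hz Butterworth of order 4 by default), then cut into trains
anchored at the flash event markers and averaged sample-by-sample across
the 30 trains.  Filtering precedes epoching so that filter edge transients
never touch the analysis windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .protocol import StimProtocol
from .recording import CODE_FLASH, CODE_TRAIN_START, Recording

__all__ = ["AveragedBlock", "bandpass", "detrend_baseline", "epoch_and_average"]

PRE_ONSET_S = 0.5   # epoch starts 500 ms before the first flash
POST_END_S = 3.0    # and ends 3 s after the end of the last period


@dataclass
class AveragedBlock:
    """Train-averaged channels x time data for one stimulation frequency.

    The time axis spans from ``PRE_ONSET_S`` before the first flash to
    ``POST_END_S`` after the end of the last stimulation period.
    ``flash_onset_samples`` are indices into this axis; ``stim_end_sample``
    marks the end of the last period (last flash onset + one period).
    """

    multiplier: float
    stim_freq_hz: float
    data: np.ndarray
    sfreq_hz: float
    flash_onset_samples: np.ndarray
    stim_end_sample: int
    n_trains_averaged: int
    layout: object = None
    meta: dict = None

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def onset_sample(self) -> int:
        return int(self.flash_onset_samples[0])

    @property
    def period_samples(self) -> int:
        return int(round(self.sfreq_hz / self.stim_freq_hz))


def bandpass(
    recording: Recording,
    low_hz: float = 2.0,
    high_hz: float = 30.0,
    order: int = 4,
) -> Recording:
    """Zero-phase Butterworth bandpass of the continuous recording.

    Forward-backward application (odd-symmetric edge padding) gives zero
    phase distortion; the effective magnitude response is the squared
    single-pass Butterworth magnitude.
    """
    nyq = recording.sfreq_hz / 2
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"require 0 < low ({low_hz}) < high ({high_hz}) < Nyquist ({nyq})"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", output="sos", fs=recording.sfreq_hz)
    filtered = signal.sosfiltfilt(sos, recording.data, axis=-1)
    return recording.copy_with(filtered)


def bandpass_array(
    data: np.ndarray, sfreq_hz: float, low_hz: float = 2.0, high_hz: float = 30.0, order: int = 4
) -> np.ndarray:
    """Array-level variant of :func:`bandpass` (last axis is time)."""
    nyq = sfreq_hz / 2
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError("cutoffs must satisfy 0 < low < high < Nyquist")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", output="sos", fs=sfreq_hz)
    return signal.sosfiltfilt(sos, data, axis=-1)


def detrend_baseline(
    data: np.ndarray, baseline: tuple[int, int]
) -> np.ndarray:
    """Remove the per-channel linear trend, then the baseline-window mean.

    Parameters
    ----------
    data
        channels x samples array (an averaged block).
    baseline
        (start, stop) sample window whose mean is subtracted; must be
        non-empty and lie inside the data extent.

    Returns
    -------
    Array of the same shape whose baseline-window mean is exactly zero per
    channel.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    start, stop = baseline
    if not (0 <= start < stop <= data.shape[1]):
        raise ValueError(f"baseline window {baseline} empty or outside data extent")
    out = signal.detrend(data, axis=-1, type="linear")
    out = out - out[:, start:stop].mean(axis=1, keepdims=True)
    return out


def epoch_and_average(
    recording: Recording,
    protocol: StimProtocol,
    multiplier: float,
    *,
    pre_onset_s: float = PRE_ONSET_S,
    post_end_s: float = POST_END_S,
) -> AveragedBlock:
    """Cut the block into per-train epochs and average them.

    Each epoch runs from ``PRE_ONSET_S`` before its first flash to
    ``POST_END_S`` after the end of its last period.  Epochs are anchored
    at the flash event markers, so non-divisor stimulation frequencies do
    not accumulate fractional-sample drift.  All trains must contain the
    expected number of flashes and produce equal-length epochs.
    """
    fs = recording.sfreq_hz
    f_stim = protocol.stim_freq(multiplier)
    period = int(round(fs / f_stim))
    n_flash = protocol.flashes_per_train

    train_starts = recording.event_samples(CODE_TRAIN_START)
    flashes = recording.event_samples(CODE_FLASH)
    if len(train_starts) == 0 or len(flashes) == 0:
        raise ValueError("recording lacks train/flash event markers")
    if len(flashes) != len(train_starts) * n_flash:
        raise ValueError(
            f"expected {len(train_starts) * n_flash} flash markers, found {len(flashes)}"
        )
    flashes = flashes.reshape(len(train_starts), n_flash)

    pre = int(round(pre_onset_s * fs))
    post = int(round(post_end_s * fs))
    # Per-train epoch extent relative to the first flash.
    rel_end = flashes[:, -1] - flashes[:, 0] + period + post
    if not np.all(rel_end == rel_end[0]):
        raise ValueError("trains have unequal epoch lengths; inconsistent events")
    length = int(rel_end[0]) + pre

    epochs = []
    for first, last in zip(flashes[:, 0], flashes[:, -1]):
        start = first - pre
        stop = start + length
        if start < 0 or stop > recording.n_samples:
            raise ValueError("epoch window exceeds the recording extent")
        epochs.append(recording.data[:, start:stop])
    avg = np.mean(epochs, axis=0)

    rel_flashes = (flashes[0] - flashes[0, 0] + pre).astype(np.int64)
    return AveragedBlock(
        multiplier=multiplier,
        stim_freq_hz=f_stim,
        data=avg,
        sfreq_hz=fs,
        flash_onset_samples=rel_flashes,
        stim_end_sample=int(rel_flashes[-1] + period),
        n_trains_averaged=len(train_starts),
        layout=recording.layout,
        meta=dict(recording.meta),
    )


def preprocess_block(
    recording: Recording,
    protocol: StimProtocol,
    multiplier: float,
    *,
    low_hz: float = 2.0,
    high_hz: float = 30.0,
    order: int = 4,
    pre_onset_s: float = PRE_ONSET_S,
    post_end_s: float = POST_END_S,
) -> AveragedBlock:
    """Filter, epoch/average, then detrend + baseline-correct one block."""
    filtered = bandpass(recording, low_hz, high_hz, order)
    block = epoch_and_average(
        filtered, protocol, multiplier, pre_onset_s=pre_onset_s, post_end_s=post_end_s
    )
    baseline = (0, block.onset_sample)
    block.data = detrend_baseline(block.data, baseline)
    return block
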