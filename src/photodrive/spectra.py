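"""Frequency-domain analysis of photic-driving responses.

Amplitude spectra of the train-averaged blocks are computed with a plain
(rectangular-window) FFT over the interval from the first flash to the end
of the 40th stimulation period, averaged over the 24 occipital gradiometer
channels.  Two quantities drive the downstream statistics:

* the *alpha peak ratio*: peak amplitude at the individual alpha frequency
  during stimulation divided by the resting-state alpha peak amplitude;
* the *response frequency*: location of the highest spectral peak within
  +-2 Hz of the stimulation frequency.

Frequency entrainment is classified by two conjunctive rules: the response
frequency must coincide with the stimulation frequency (or a harmonic)
within one non-padded frequency bin, and the response amplitude must exceed
20% of the maximum spectral peak found across the whole cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .preproc import AveragedBlock
from .recording import Recording

__all__ = [
    "Spectrum",
    "EntrainmentResult",
    "AlphaPeakRatio",
    "AlphaPeakNotFound",
    "compute_spectrum",
    "spectrum_of_array",
    "estimate_resting_alpha",
    "alpha_peak_ratio",
    "classify_entrainment",
    "cohort_max_amplitude",
    "test_ratios",
]

SEARCH_HALF_WIDTH_HZ = 2.0     # response-frequency search range around f_stim
AMP_THRESHOLD_FRACTION = 0.2   # of the cohort-wide maximum peak
HARMONICS = (1, 2, 3)


class AlphaPeakNotFound(RuntimeError):
    """No credible spectral peak in the alpha search band."""


@dataclass
class Spectrum:
    """Amplitude spectrum averaged over a channel subset.

    ``amplitude`` uses the single-sided peak-amplitude convention
    ``2*|X_k|/N`` (a unit sinusoid on an integer number of cycles gives an
    amplitude of 1 in its bin).  The FFT is zero-padded to the next power
    of two; ``native_resolution_hz`` is the pre-padding bin width used for
    the entrainment concurrence rule.
    """

    freqs: np.ndarray
    amplitude: np.ndarray
    window: tuple[int, int]
    channel_subset: list[str]
    native_resolution_hz: float

    @property
    def power(self) -> np.ndarray:
        return self.amplitude**2

    def peak_in_band(self, lo: float, hi: float) -> tuple[float, float]:
        """(frequency, amplitude) of the maximum within [lo, hi]."""
        m = (self.freqs >= lo) & (self.freqs <= hi)
        if not m.any():
            raise ValueError(f"band [{lo}, {hi}] Hz outside the spectrum range")
        i = np.argmax(self.amplitude[m])
        return float(self.freqs[m][i]), float(self.amplitude[m][i])


@dataclass
class EntrainmentResult:
    """Two-rule entrainment verdict for one block."""

    multiplier: float
    stim_freq_hz: float
    response_freq_hz: float
    response_amp: float
    threshold_amp: float
    entrained: bool
    rule_trace: dict


@dataclass
class AlphaPeakRatio:
    """Stimulation-to-rest ratio of alpha-band peak amplitudes."""

    multiplier: float
    ratio: float
    stim_peak: float
    rest_peak: float


def spectrum_of_array(
    data: np.ndarray,
    sfreq_hz: float,
    window: tuple[int, int],
    channel_names: list[str] | None = None,
) -> Spectrum:
    """Per-channel FFT amplitude over ``window``, averaged across channels."""
    data = np.atleast_2d(data)
    start, stop = window
    if not (0 <= start < stop <= data.shape[1]):
        raise ValueError(f"window {window} outside data extent")
    seg = data[:, start:stop]
    n = seg.shape[1]
    n_pad = 1 << (n - 1).bit_length()
    amps = 2.0 * np.abs(np.fft.rfft(seg, n=n_pad, axis=1)) / n
    freqs = np.fft.rfftfreq(n_pad, d=1.0 / sfreq_hz)
    return Spectrum(
        freqs=freqs,
        amplitude=amps.mean(axis=0),
        window=(start, stop),
        channel_subset=list(channel_names) if channel_names is not None else [],
        native_resolution_hz=sfreq_hz / n,
    )


def compute_spectrum(block: AveragedBlock, subset: list[str]) -> Spectrum:
    """Amplitude spectrum of an averaged block over a channel subset.

    The window runs from the first flash to the end of the 40th period.
    The subset must not mix magnetometers and gradiometers (their units,
    fT vs fT/cm, cannot be averaged).
    """
    if not subset:
        raise ValueError("channel subset must be nonempty")
    if block.layout is not None:
        idx = block.layout.index_of(subset)
        types = set(block.layout.types[idx])
        if len(types) > 1:
            raise ValueError(
                "channel subset mixes magnetometers and gradiometers; "
                "their units are incompatible"
            )
        data = block.data[idx]
    else:
        data = block.data
    window = (block.onset_sample, block.stim_end_sample)
    return spectrum_of_array(data, block.sfreq_hz, window, channel_names=subset)


def estimate_resting_alpha(
    recording: Recording,
    search_band: tuple[float, float] = (7.0, 13.0),
    subset: list[str] | None = None,
    min_peak_prominence_ratio: float = 2.0,
) -> float:
    """Individual alpha frequency from the resting-state amplitude spectrum.

    The estimate is the frequency of the maximal local peak of the
    subset-averaged amplitude spectrum within ``search_band``.  The peak
    must exceed ``min_peak_prominence_ratio`` times the in-band median
    amplitude; otherwise :class:`AlphaPeakNotFound` is raised rather than
    silently returning a noise bin.
    """
    if recording.duration_s < 10.0:
        raise ValueError("resting segment must be at least 10 s long")
    if subset is None:
        subset = recording.layout.occipital_gradiometers()
        if not subset:
            subset = list(recording.layout.names)
    idx = recording.layout.index_of(subset)
    spec = spectrum_of_array(
        recording.data[idx], recording.sfreq_hz, (0, recording.n_samples), subset
    )
    band = (spec.freqs >= search_band[0]) & (spec.freqs <= search_band[1])
    amp = spec.amplitude[band]
    freqs = spec.freqs[band]
    peaks, _ = sps.find_peaks(amp)
    if len(peaks) == 0:
        raise AlphaPeakNotFound(f"no local maximum in {search_band} Hz")
    best = peaks[np.argmax(amp[peaks])]
    if amp[best] < min_peak_prominence_ratio * np.median(amp):
        raise AlphaPeakNotFound(
            "alpha-band maximum does not stand out from the spectral floor"
        )
    return float(freqs[best])


def alpha_peak_ratio(
    stim_spectrum: Spectrum,
    rest_spectrum: Spectrum,
    alpha_hz: float,
    multiplier: float = np.nan,
    half_width_hz: float = 1.0,
) -> AlphaPeakRatio:
    """Ratio of alpha-band peak amplitudes: stimulation over rest.

    Both spectra must share their frequency resolution (the resting
    spectrum is computed over a window of the same length as the
    1.00*alpha stimulation window).
    """
    if abs(stim_spectrum.native_resolution_hz - rest_spectrum.native_resolution_hz) > 1e-9:
        raise ValueError("stimulation and rest spectra must share their resolution")
    band = (alpha_hz - half_width_hz, alpha_hz + half_width_hz)
    _, stim_peak = stim_spectrum.peak_in_band(*band)
    _, rest_peak = rest_spectrum.peak_in_band(*band)
    if rest_peak <= 0:
        raise ValueError("resting alpha peak amplitude is zero")
    return AlphaPeakRatio(
        multiplier=multiplier,
        ratio=stim_peak / rest_peak,
        stim_peak=stim_peak,
        rest_peak=rest_peak,
    )


def cohort_max_amplitude(spectra, band: tuple[float, float] = (2.0, 30.0)) -> float:
    """Maximum spectral peak over all spectra of a cohort (within ``band``)."""
    peak = 0.0
    for spec in spectra:
        m = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
        peak = max(peak, float(spec.amplitude[m].max()))
    if peak <= 0:
        raise ValueError("cohort spectra contain no positive amplitudes")
    return peak


def classify_entrainment(
    spectrum: Spectrum,
    stim_freq_hz: float,
    cohort_max_amp: float,
    multiplier: float = np.nan,
    *,
    search_half_width_hz: float = SEARCH_HALF_WIDTH_HZ,
    amp_threshold_fraction: float = AMP_THRESHOLD_FRACTION,
) -> EntrainmentResult:
    """Apply the two-rule entrainment classifier to one block spectrum.

    Rule 1 (concurrence): the response frequency — the maximal peak within
    +-2 Hz of the stimulation frequency — lies within one non-padded
    frequency bin of the stimulation frequency or one of its harmonics.
    Rule 2 (amplitude): the response amplitude exceeds 20% of the maximal
    peak found across the whole cohort.  Both must hold.
    """
    lo = stim_freq_hz - search_half_width_hz
    hi = stim_freq_hz + search_half_width_hz
    if lo < spectrum.freqs[0] or hi > spectrum.freqs[-1]:
        raise ValueError(
            f"search range [{lo:.2f}, {hi:.2f}] Hz outside the spectrum range"
        )
    m = (spectrum.freqs >= lo) & (spectrum.freqs <= hi)
    freqs = spectrum.freqs[m]
    amp = spectrum.amplitude[m]
    peaks, _ = sps.find_peaks(amp)
    if len(peaks) == 0:
        # No interior local maximum: fall back to the in-range maximum.
        peaks = np.array([int(np.argmax(amp))])
    # Maximal peak; ties broken toward the frequency nearest f_stim.
    best_amp = amp[peaks].max()
    cand = peaks[amp[peaks] >= best_amp * (1 - 1e-12)]
    best = cand[np.argmin(np.abs(freqs[cand] - stim_freq_hz))]
    f_resp, a_resp = float(freqs[best]), float(amp[best])

    tol = spectrum.native_resolution_hz
    dist = min(abs(f_resp - k * stim_freq_hz) for k in HARMONICS)
    concurrence = dist <= tol
    threshold = amp_threshold_fraction * cohort_max_amp
    amplitude_ok = a_resp > threshold
    return EntrainmentResult(
        multiplier=multiplier,
        stim_freq_hz=stim_freq_hz,
        response_freq_hz=f_resp,
        response_amp=a_resp,
        threshold_amp=threshold,
        entrained=bool(concurrence and amplitude_ok),
        rule_trace={
            "concurrence": bool(concurrence),
            "harmonic_distance_hz": float(dist),
            "amplitude_ok": bool(amplitude_ok),
        },
    )


def test_ratios(ratios: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Statistics on cohort alpha peak ratios.

    Parameters
    ----------
    ratios
        DataFrame indexed by subject with one column per multiplier,
        holding the alpha peak ratios.

    Returns
    -------
    dict with two tables:

    ``per_multiplier``
        One-sample t-statistics against a mean of 1 (no change of alpha
        activity under stimulation), with both one-sided p-values.
    ``pairwise``
        Paired t-tests between multipliers, Holm-corrected.
    """
    from statsmodels.stats.multitest import multipletests

    if ratios.shape[0] < 2:
        raise ValueError("need at least 2 subjects per multiplier")
    rows = []
    for mult in ratios.columns:
        x = ratios[mult].dropna().to_numpy()
        if np.std(x, ddof=1) == 0:
            rows.append(
                {"multiplier": mult, "n": len(x), "mean": x.mean(), "t": 0.0,
                 "p_greater": np.nan, "p_less": np.nan, "degenerate": True}
            )
            continue
        t_g = stats.ttest_1samp(x, popmean=1.0, alternative="greater")
        t_l = stats.ttest_1samp(x, popmean=1.0, alternative="less")
        rows.append(
            {"multiplier": mult, "n": len(x), "mean": x.mean(),
             "t": float(t_g.statistic), "p_greater": float(t_g.pvalue),
             "p_less": float(t_l.pvalue), "degenerate": False}
        )
    per_mult = pd.DataFrame(rows)

    pair_rows = []
    cols = list(ratios.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            a = ratios[cols[i]].to_numpy()
            b = ratios[cols[j]].to_numpy()
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 2 or np.std(a[ok] - b[ok], ddof=1) == 0:
                t_val, p_val = np.nan, np.nan
            else:
                res = stats.ttest_rel(a[ok], b[ok])
                t_val, p_val = float(res.statistic), float(res.pvalue)
            pair_rows.append(
                {"mult_a": cols[i], "mult_b": cols[j], "t": t_val, "p": p_val}
            )
    pairwise = pd.DataFrame(pair_rows, columns=["mult_a", "mult_b", "t", "p"])
    finite = pairwise["p"].notna()
    pairwise["p_holm"] = np.nan
    if finite.any():
        pairwise.loc[finite, "p_holm"] = multipletests(
            pairwise.loc[finite, "p"], method="holm"
        )[1]
    return {"per_multiplier": per_mult, "pairwise": pairwise}
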