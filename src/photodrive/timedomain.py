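"""Time-domain analysis: MGFP, Hilbert envelope, on/off-response detection.

When the flicker-fusion threshold of rod perception is exceeded the
stimulus is perceived as steady light; the evoked field then shows a
transient *on-response* shortly after the onset of the train and an
*off-response* after its end instead of a sustained oscillation.  Both are
read from the channel-mean Hilbert envelope of the train-averaged block
over a window from 500 ms before the stimulation onset until 3 s after
the end of the last period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import find_peaks, hilbert

from .layout import GRAD, MAG
from .preproc import AveragedBlock

__all__ = [
    "TransientResponse",
    "mgfp",
    "envelope",
    "detect_on_off",
    "test_off_occurrence",
]

PEAK_SD_FACTOR = 3.0   # peak must exceed baseline mean + this many baseline SDs
EDGE_EXCLUDE_MS = 100  # analytic-signal edge region excluded from peak search


@dataclass
class TransientResponse:
    """One detected (or absent) on- or off-response.

    Latency is measured from the first flash onset (on) or from the end of
    the last stimulation period (off) to the envelope peak.
    """

    kind: str                 # "on" | "off"
    detected: bool
    latency_ms: float = np.nan
    amplitude: float = np.nan


def mgfp(block: AveragedBlock, channel_type: str = MAG) -> np.ndarray:
    """Square root of mean global field power over one channel type.

    At each sample: sqrt of the mean over channels of the squared field.
    Channel types are never mixed (fT vs fT/cm).
    """
    if channel_type not in (MAG, GRAD):
        raise ValueError(f"unknown channel type {channel_type!r}")
    mask = block.layout.mask(types=channel_type)
    if not mask.any():
        raise ValueError(f"no channels of type {channel_type!r} in the block")
    return np.sqrt(np.mean(block.data[mask] ** 2, axis=0))


def envelope(
    block: AveragedBlock,
    window: tuple[int, int] | None = None,
    standardize: str | bool = "auto",
) -> np.ndarray:
    """Channel-mean magnitude of the analytic signal over ``window``.

    ``window`` defaults to 500 ms before the first flash until 3 s after
    the end of the last period (the full averaged-block extent).  Because
    fT and fT/cm cannot be averaged raw, mixed channel types are combined
    after per-type standardization: each channel's envelope is divided by
    the median envelope of its type (``standardize="auto"`` standardizes
    only when both types are present).
    """
    if window is None:
        window = (0, block.n_samples)
    start, stop = window
    if not (0 <= start < stop <= block.n_samples):
        raise ValueError(f"window {window} exceeds the block extent")
    data = block.data[:, start:stop]
    env = np.abs(hilbert(data, axis=1))

    types = block.layout.types if block.layout is not None else None
    do_std = standardize is True or (
        standardize == "auto" and types is not None and len(set(types)) > 1
    )
    if do_std:
        for t in set(types):
            m = types == t
            med = np.median(env[m])
            if med > 0:
                env[m] = env[m] / med
    return env.mean(axis=0)


def detect_on_off(
    env: np.ndarray,
    sfreq_hz: float,
    onset_sample: int,
    end_sample: int,
    *,
    sd_factor: float = PEAK_SD_FACTOR,
    edge_ms: float = EDGE_EXCLUDE_MS,
) -> tuple[TransientResponse, TransientResponse]:
    """First qualifying envelope peaks after stimulation onset and end.

    A peak qualifies when it exceeds the baseline mean plus ``sd_factor``
    baseline standard deviations, the baseline being the pre-onset segment
    of the envelope.  The first ``edge_ms`` of the envelope and its last
    ``edge_ms`` are excluded from the search (analytic-signal edge
    effects).  The on-response is searched between onset and end of the
    stimulation, the off-response after the end.
    """
    env = np.asarray(env, dtype=float)
    edge = int(round(edge_ms / 1000 * sfreq_hz))
    if onset_sample <= edge:
        raise ValueError("envelope must cover a pre-onset baseline segment")
    baseline = env[edge:onset_sample]
    thr = baseline.mean() + sd_factor * baseline.std()
    # "Outstanding" peak: prominence must also clear the baseline spread,
    # so ripple on a decaying post-stimulation plateau does not qualify.
    prominence = sd_factor * baseline.std()

    def first_peak(lo: int, hi: int, ref: int, kind: str) -> TransientResponse:
        seg = env[lo:hi]
        peaks, _ = find_peaks(seg, height=thr, prominence=prominence)
        if len(peaks) == 0:
            return TransientResponse(kind=kind, detected=False)
        p = int(peaks[0]) + lo
        return TransientResponse(
            kind=kind,
            detected=True,
            latency_ms=(p - ref) / sfreq_hz * 1000.0,
            amplitude=float(env[p]),
        )

    on = first_peak(onset_sample + 1, end_sample, onset_sample, "on")
    off = first_peak(end_sample + 1, len(env) - edge, end_sample, "off")
    return on, off


def test_off_occurrence(
    responses: pd.DataFrame,
    *,
    low_max: float = 1.10,
    high_min: float = 1.30,
    alpha: float = 0.05,
) -> dict:
    """Group statistics of transient responses across the cohort.

    Parameters
    ----------
    responses
        One row per (subject, multiplier) with columns ``subject``,
        ``multiplier``, ``off_detected`` (bool) and, optionally,
        ``on_latency_ms`` / ``on_amplitude``.

    Returns
    -------
    dict with the paired one-sided t-test of per-subject off-response
    occurrence proportions — high-frequency group (multiplier >=
    ``high_min``) vs low-frequency group (<= ``low_max``) — plus one-way
    ANOVAs of on-response latency and amplitude across multipliers.
    Subjects missing either group are excluded (with a count reported).
    """
    props = []
    excluded = 0
    for subj, grp in responses.groupby("subject"):
        low = grp[grp["multiplier"] <= low_max]
        high = grp[grp["multiplier"] >= high_min]
        if len(low) == 0 or len(high) == 0:
            excluded += 1
            continue
        props.append(
            {"subject": subj,
             "low": float(low["off_detected"].mean()),
             "high": float(high["off_detected"].mean())}
        )
    prop_df = pd.DataFrame(props)
    out: dict = {"n_subjects": len(prop_df), "n_excluded": excluded,
                 "proportions": prop_df}
    if len(prop_df) < 2:
        out.update({"t": np.nan, "p": np.nan, "reject": False, "degenerate": True})
        return out
    diff = prop_df["high"] - prop_df["low"]
    if np.std(diff, ddof=1) == 0:
        t_val = 0.0 if diff.mean() == 0 else np.inf * np.sign(diff.mean())
        p_val = np.nan if diff.mean() == 0 else (0.0 if diff.mean() > 0 else 1.0)
        out.update({"t": float(t_val) if np.isfinite(t_val) else t_val,
                    "p": p_val, "degenerate": True})
    else:
        res = stats.ttest_rel(prop_df["high"], prop_df["low"], alternative="greater")
        out.update({"t": float(res.statistic), "p": float(res.pvalue),
                    "degenerate": False})
    out["reject"] = bool(out["p"] is not None and np.isfinite(out["p"]) and out["p"] < alpha)

    for col, key in (("on_latency_ms", "anova_on_latency"), ("on_amplitude", "anova_on_amplitude")):
        if col not in responses.columns:
            continue
        groups = [
            g[col].dropna().to_numpy()
            for _, g in responses.groupby("multiplier")
        ]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) >= 2 and any(np.std(g, ddof=1) > 0 for g in groups):
            f, p = stats.f_oneway(*groups)
            out[key] = {"F": float(f), "p": float(p)}
        else:
            out[key] = {"F": np.nan, "p": np.nan}
    return out
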