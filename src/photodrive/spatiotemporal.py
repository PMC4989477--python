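"""Phase segmentation of correlation sequences and response classification.

A correlation-coefficient sequence of a driven block exposes three phases:
a rise while the neural network synchronizes with the stimulus
(*engagement*, phase I, complete by stimulus 5-10), a stable plateau
(phase II), and a decrease shortly after the end of the stimulation
(*disengagement*, phase III) following a short preservation of the driven
state.  The segmentation is operationalized as a three-segment
(linear rise / constant plateau / linear fall) least-squares fit with
exhaustive breakpoint search; phases count as detected when the fitted
rise and fall amplitudes each exceed a configured fraction of the plateau
level, the rise completes early enough, and the fit explains the sequence.

Responses are classified as *good* (phases present, plateau variance below
the 0.004 threshold), *moderate* (phases present, variance at or above the
threshold) or *weak* (no phases).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tmp import CorrSeq, TMPAtom

__all__ = [
    "PhaseSegmentation",
    "ResponseClass",
    "detect_phases",
    "classify_response",
    "compare_phase_variances",
    "VARIANCE_THRESHOLD",
]

VARIANCE_THRESHOLD = 0.004   # plateau variance separating good from moderate
MAX_PHASE1_END = 15          # engagement must complete by this stimulus
MIN_AMP_FRACTION = 0.10      # rise/fall amplitude as a fraction of the plateau
MIN_R_SQUARED = 0.5          # fit quality required to call phases present
N_STIM_PERIODS = 40


@dataclass
class PhaseSegmentation:
    """Breakpoints and plateau statistics of a three-phase sequence.

    ``phase1_end`` is the period at which the rise reaches the plateau
    (1-based); ``phase3_start`` the first period of the decrease (within
    the 10 post-stimulation periods, i.e. > 40).
    """

    phase1_end: int
    phase3_start: int
    plateau_level: float
    plateau_variance: float
    rise_amplitude: float
    fall_amplitude: float
    r_squared: float

    @property
    def preservation_periods(self) -> int:
        """Post-stimulation periods before the decay starts."""
        return int(np.clip(self.phase3_start - (N_STIM_PERIODS + 1) + 1, 0, 10))


@dataclass
class ResponseClass:
    """good / moderate / weak verdict for one (subject, frequency) cell."""

    label: str
    variance_used: float
    phases_detected: bool
    segmentation: PhaseSegmentation | None = None


def _piecewise_fit(seq: np.ndarray, b1: int, b2: int):
    """LSQ fit of rise(1..b1) -> plateau(b1..b2-1) -> fall(b2..n).

    Linear in (start level a, plateau p, end level e); returns the
    coefficient triple and the residual sum of squares.
    """
    n = len(seq)
    X = np.zeros((n, 3))
    i = np.arange(1, n + 1)
    rise = i <= b1
    w = (i[rise] - 1) / max(b1 - 1, 1)
    X[rise, 0] = 1 - w
    X[rise, 1] = w
    plateau = (i > b1) & (i < b2)
    X[plateau, 1] = 1.0
    fall = i >= b2
    v = (i[fall] - b2 + 1) / (n - b2 + 1)
    X[fall, 1] = 1 - v
    X[fall, 2] = v
    coef, _, _, _ = np.linalg.lstsq(X, seq, rcond=None)
    resid = seq - X @ coef
    return coef, float(resid @ resid)


def detect_phases(
    seq: np.ndarray | CorrSeq,
    *,
    max_phase1_end: int = MAX_PHASE1_END,
    min_amp_fraction: float = MIN_AMP_FRACTION,
    min_r_squared: float = MIN_R_SQUARED,
    n_stim: int = N_STIM_PERIODS,
) -> PhaseSegmentation | None:
    """Segment a sequence into rise / plateau / fall, or report absence.

    The breakpoint pair minimizing the squared error of the three-segment
    fit is found by exhaustive search (phase1_end in 2..``max_phase1_end``,
    phase3_start in ``n_stim``+1..n).  ``None`` is returned when the best
    fit fails any detection criterion — absence of phases is a valid
    outcome, not an error.
    """
    if isinstance(seq, CorrSeq):
        seq = seq.mean_sequence()
    seq = np.asarray(seq, dtype=float)
    n = len(seq)
    if n <= n_stim:
        raise ValueError(f"sequence must extend beyond the {n_stim} stimulus periods")

    best = None
    for b1 in range(2, max_phase1_end + 1):
        for b2 in range(n_stim + 1, n + 1):
            coef, sse = _piecewise_fit(seq, b1, b2)
            if best is None or sse < best[0]:
                best = (sse, b1, b2, coef)
    sse, b1, b2, (a, p, e) = best
    sst = float(((seq - seq.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    rise_amp = p - a
    fall_amp = p - e
    plateau_vals = seq[b1 - 1 : b2 - 1]
    plateau_var = float(np.var(plateau_vals, ddof=1)) if len(plateau_vals) > 1 else 0.0

    detected = (
        p > 0
        and rise_amp >= min_amp_fraction * p
        and fall_amp >= min_amp_fraction * p
        and r2 >= min_r_squared
    )
    if not detected:
        return None
    return PhaseSegmentation(
        phase1_end=b1,
        phase3_start=b2,
        plateau_level=float(p),
        plateau_variance=plateau_var,
        rise_amplitude=float(rise_amp),
        fall_amplitude=float(fall_amp),
        r_squared=float(r2),
    )


def classify_response(
    seq: np.ndarray | CorrSeq,
    threshold: float = VARIANCE_THRESHOLD,
    **detect_kwargs,
) -> ResponseClass:
    """Assign good / moderate / weak based on the phase segmentation.

    good: phases detected and plateau variance < ``threshold``;
    moderate: phases detected, variance >= ``threshold``;
    weak: phases not detected.
    """
    seg = detect_phases(seq, **detect_kwargs)
    if seg is None:
        return ResponseClass(label="weak", variance_used=np.nan, phases_detected=False)
    label = "good" if seg.plateau_variance < threshold else "moderate"
    return ResponseClass(
        label=label,
        variance_used=seg.plateau_variance,
        phases_detected=True,
        segmentation=seg,
    )


def phase_frequency_variances(
    atoms: list[TMPAtom],
    segmentation: PhaseSegmentation,
    sfreq_hz: float,
    ddof: int = 1,
) -> dict[str, float]:
    """Variance of the atoms' frequency parameter within each phase (Hz^2)."""
    freqs = np.array([a.freq_hz(sfreq_hz) for a in atoms])
    b1, b2 = segmentation.phase1_end, segmentation.phase3_start
    out = {}
    for name, vals in (
        ("I", freqs[:b1]),
        ("II", freqs[b1 : b2 - 1]),
        ("III", freqs[b2 - 1 :]),
    ):
        out[name] = float(np.var(vals, ddof=ddof)) if len(vals) > ddof else np.nan
    return out


def compare_phase_variances(
    cohort: list[tuple[list[TMPAtom], PhaseSegmentation]],
    sfreq_hz: float,
    ddof: int = 1,
) -> pd.DataFrame:
    """Paired comparison of per-phase frequency-parameter variances.

    For each subject, the variance of the atoms' modulation frequency is
    computed within phases I, II and III; phases I and III are then each
    compared against phase II with a paired t-test (alternative: larger
    variance in the transition phases).
    """
    if len(cohort) < 2:
        raise ValueError("need at least 2 subjects")
    table = []
    for atoms, seg in cohort:
        table.append(phase_frequency_variances(atoms, seg, sfreq_hz, ddof=ddof))
    var_df = pd.DataFrame(table)

    rows = []
    for phase in ("I", "III"):
        a = var_df[phase].to_numpy()
        b = var_df["II"].to_numpy()
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 2 or np.std(a[ok] - b[ok], ddof=1) == 0:
            rows.append(
                {"comparison": f"{phase} vs II", "n": int(ok.sum()),
                 "mean_var_phase": float(np.nanmean(a)),
                 "mean_var_II": float(np.nanmean(b)),
                 "t": np.nan, "p": np.nan, "degenerate": True}
            )
            continue
        res = stats.ttest_rel(a[ok], b[ok], alternative="greater")
        rows.append(
            {"comparison": f"{phase} vs II", "n": int(ok.sum()),
             "mean_var_phase": float(a[ok].mean()),
             "mean_var_II": float(b[ok].mean()),
             "t": float(res.statistic), "p": float(res.pvalue),
             "degenerate": False}
        )
    return pd.DataFrame(rows)
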