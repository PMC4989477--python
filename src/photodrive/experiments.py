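"""Recovery and calibration experiments on synthetic cohorts.

Each function runs a self-contained study against the generator's ground
truth: entrainment-classifier agreement, TMP parameter recovery, phase /
response-class recovery on planted correlation sequences, transient-latency
recovery, and type-I error control of the off-occurrence group test.  They
are used by the test suite and by the acceptance script; problem sizes are
arguments so studies can be scaled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import spatiotemporal, timedomain, tmp
from .layout import default_layout
from .pipeline import run_pipeline
from .preproc import preprocess_block
from .protocol import StimProtocol
from .synth import ResponseModelParams, simulate_session

__all__ = [
    "entrainment_agreement",
    "planted_atom_recovery",
    "planted_sequence",
    "phase_class_accuracy",
    "noise_weak_rate",
    "latency_recovery",
    "off_occurrence_type1_rate",
]


def entrainment_agreement(
    n_subjects: int,
    seed: int,
    snr: float | None = None,
    protocol_overrides: dict | None = None,
) -> dict:
    """Fraction of (subject, block) cells whose entrainment verdict matches
    the generator label, over a fresh synthetic cohort."""
    cfg = {
        "cohort": {"n_subjects": n_subjects},
        "seed": seed,
        "model": {"snr": snr},
        "protocol": protocol_overrides or {},
        "stages": ["spectra"],
    }
    report = run_pipeline(cfg)
    ok = report.cells[~report.cells["failed"]]
    return {
        "agreement": float((ok["entrained"] == ok["entrained_true"]).mean()),
        "n_cells": int(len(ok)),
        "report": report,
    }


def planted_atom_recovery(
    n_trials: int,
    snr: float,
    seed: int,
    *,
    window_len: int = 128,
    sfreq_hz: float = 1000.0,
    n_channels: int = 8,
) -> dict:
    """Recover the modulation of planted dictionary atoms under white noise.

    Per trial, a random dictionary atom with random per-channel amplitudes
    and phases is embedded at the requested SNR (atom RMS over noise SD);
    recovery counts when the fitted modulation lies within one grid step.
    Planted atoms carry at least one full carrier cycle under their
    envelope (``xi * s >= 2 pi``); below that the modulation of a Gabor is
    not identifiable from its shape.
    """
    rng = np.random.default_rng(seed)
    dictionary = tmp.build_dictionary(window_len, sfreq_hz)
    eligible = np.flatnonzero(
        dictionary.params[:, 2] * dictionary.params[:, 0] >= 2 * np.pi
    )
    hits = 0
    for _ in range(n_trials):
        i = int(rng.choice(eligible))
        s, u, xi = dictionary.params[i]
        amps = rng.uniform(0.5, 2.0, size=n_channels)
        phases = rng.uniform(-np.pi, np.pi, size=n_channels)
        atom = tmp.TMPAtom(
            s=s, u=u, xi=xi, amps=amps, phases=phases, window_len=window_len
        )
        clean = tmp.reconstruct(atom)
        noise_sd = np.sqrt((clean**2).mean()) / snr
        x = clean + noise_sd * rng.standard_normal(clean.shape)
        fit = tmp.fit_atom(x, dictionary)
        if abs(fit.xi - xi) <= dictionary.mod_step * (1 + 1e-9):
            hits += 1
    return {"rate": hits / n_trials, "n_trials": n_trials}


def planted_sequence(
    rng: np.random.Generator,
    *,
    plateau: float = 0.9,
    start: float = 0.3,
    end: float = 0.35,
    b1: int = 8,
    b2: int = 43,
    n: int = 50,
    plateau_jitter_sd: float = 0.0,
) -> np.ndarray:
    """Three-phase correlation sequence with planted breakpoints."""
    i = np.arange(1, n + 1, dtype=float)
    seq = np.full(n, plateau)
    rise = i <= b1
    seq[rise] = start + (plateau - start) * (i[rise] - 1) / (b1 - 1)
    fall = i >= b2
    seq[fall] = plateau + (end - plateau) * (i[fall] - b2 + 1) / (n - b2 + 1)
    if plateau_jitter_sd > 0:
        mid = (i > b1) & (i < b2)
        seq[mid] += rng.normal(0, plateau_jitter_sd, size=mid.sum())
    return np.clip(seq, 0.0, 1.0)


def phase_class_accuracy(
    n_trials: int,
    seed: int,
    *,
    plateau_jitter_sd: float,
    expected_label: str,
) -> dict:
    """Label accuracy on planted three-phase sequences with plateau jitter."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_trials):
        b1 = int(rng.integers(5, 11))
        b2 = int(rng.integers(41, 48))
        seq = planted_sequence(
            rng, b1=b1, b2=b2, plateau_jitter_sd=plateau_jitter_sd
        )
        rc = spatiotemporal.classify_response(seq)
        if rc.label == expected_label:
            hits += 1
    return {"rate": hits / n_trials, "n_trials": n_trials}


def noise_weak_rate(n_trials: int, seed: int) -> dict:
    """Fraction of pure-noise sequences labeled weak (no phases)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_trials):
        seq = rng.uniform(0, 1, size=50)
        if spatiotemporal.classify_response(seq).label == "weak":
            hits += 1
    return {"rate": hits / n_trials, "n_trials": n_trials}


def _occipital_layout(n_triplets: int | None = None):
    layout = default_layout()
    layout = layout.subset(layout.mask(region="occipital"))
    if n_triplets is not None:
        keep = np.isin(layout.triplet, np.unique(layout.triplet)[:n_triplets])
        layout = layout.subset(keep)
    return layout


def latency_recovery(
    n_trials: int,
    snr: float,
    seed: int,
    *,
    trains_per_block: int = 8,
    flashes_per_train: int = 15,
    tolerance_ms: float = 5.0,
) -> dict:
    """Recovery of planted on-response latencies from fused blocks.

    Each trial simulates one block above the fusion threshold with a
    planted on-latency drawn from 150-250 ms, runs the preprocessing and
    envelope detector, and scores recovery within ``tolerance_ms``.
    """
    rng = np.random.default_rng(seed)
    layout = _occipital_layout()
    hits = 0
    errors = []
    for trial in range(n_trials):
        alpha = float(rng.uniform(9.0, 11.5))
        lat = float(rng.uniform(150.0, 250.0))
        protocol = StimProtocol(
            alpha_hz=alpha,
            multipliers=(2.0,),
            trains_per_block=trains_per_block,
            flashes_per_train=flashes_per_train,
        )
        params = ResponseModelParams(
            snr=snr,
            on_latency_ms=lat,
            latency_jitter_sd_ms=0.0,
            seed=int(rng.integers(2**31 - 1)),
        )
        session = simulate_session(protocol, layout, params)
        blk = preprocess_block(session.block(0), protocol, 2.0)
        env = timedomain.envelope(blk)
        on, _ = timedomain.detect_on_off(
            env, blk.sfreq_hz, blk.onset_sample, blk.stim_end_sample
        )
        if on.detected:
            err = abs(on.latency_ms - lat)
            errors.append(err)
            if err <= tolerance_ms:
                hits += 1
    return {
        "rate": hits / n_trials,
        "n_trials": n_trials,
        "median_error_ms": float(np.median(errors)) if errors else np.nan,
    }


def off_occurrence_type1_rate(
    n_cohorts: int,
    seed: int,
    *,
    n_subjects: int = 6,
    trains_per_block: int = 3,
    flashes_per_train: int = 10,
    snr: float = 2.0,
    alpha_level: float = 0.05,
) -> dict:
    """Type-I error of the off-occurrence group test with fusion disabled.

    With the generator's fusion mechanism switched off no block carries a
    transient, so any off-response detections are noise-driven and equally
    likely in the low- and high-frequency groups; a valid paired test then
    rejects at close to the nominal level.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    p_values = []
    for _ in range(n_cohorts):
        cfg = {
            "cohort": {"n_subjects": n_subjects},
            "seed": int(rng.integers(2**31 - 1)),
            "protocol": {
                "trains_per_block": trains_per_block,
                "flashes_per_train": flashes_per_train,
                "resting_duration_s": 12.0,
            },
            "model": {"snr": snr, "fusion_threshold_mult": np.inf},
            "stages": ["transients"],
            "channels": "occipital:2",
        }
        report = run_pipeline(cfg)
        p = report.off_test.get("p", np.nan)
        p_values.append(p)
        if np.isfinite(p) and p < alpha_level:
            rejections += 1
    return {
        "rate": rejections / n_cohorts,
        "n_cohorts": n_cohorts,
        "p_values": p_values,
    }
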