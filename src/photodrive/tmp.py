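"""Topographic Matching Pursuit (TMP) with Gabor atoms.

TMP summarizes a multichannel window by a single Gabor atom — a scaled,
translated, modulated Gaussian — whose time-frequency parameters
(scale ``s``, translation ``u``, modulation ``xi``) are shared across all
channels while amplitude and phase adapt per channel.  The shared triple is
chosen to maximize the total signal energy captured over all channels
(one Matching Pursuit iteration with a multichannel criterion), which makes
the selected atom carry topographic information.

One atom is fitted per stimulation period (40 atoms) plus ten more for the
periods following the end of the stimulation.  A per-subject *reference
atom* — the average of the 40 atoms from stimulation at the individual
alpha frequency — serves as the template against which all atoms are
compared, yielding per-channel *correlation coefficient sequences* of
40 + 10 normalized coefficients whose rise/plateau/fall structure encodes
topographic engagement and disengagement.

Per-channel amplitude and phase are obtained by exact least-squares
projection of the channel signal onto the two-dimensional real span of the
complex atom (cosine and sine parts), so a window built from a dictionary
atom is recovered exactly.  The per-channel amplitude is the l2 norm of
the projected component, which makes the captured energies obey the
Bessel-type bound sum_c amp_c^2 <= sum_c ||x_c||^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .preproc import AveragedBlock

__all__ = [
    "GaborDictionary",
    "TMPAtom",
    "CorrSeq",
    "build_dictionary",
    "fit_atom",
    "atom_sequence",
    "reference_atom",
    "correlation_sequence",
    "reconstruct",
    "atoms_to_frame",
]

N_POST_PERIODS = 10
MIN_SCALE = 8                 # samples; shorter envelopes are above the band
MOD_STEP_HZ = 0.5
MOD_RANGE_HZ = (2.0, 30.0)


@dataclass
class TMPAtom:
    """One multichannel Gabor atom.

    ``s`` (scale, samples), ``u`` (translation, samples) and ``xi``
    (modulation, rad/sample) are shared across channels; ``amps`` and
    ``phases`` adapt the atom per channel.  Phases are measured at the
    envelope center ``u`` and wrapped to (-pi, pi].
    """

    s: float
    u: float
    xi: float
    amps: np.ndarray
    phases: np.ndarray
    window_len: int
    criterion: float = 0.0
    degenerate: bool = False

    @property
    def n_channels(self) -> int:
        return len(self.amps)

    def freq_hz(self, sfreq_hz: float) -> float:
        return self.xi * sfreq_hz / (2 * np.pi)


@dataclass
class CorrSeq:
    """Per-channel correlation-coefficient sequences (40 + 10 values).

    ``coefficients`` is channels x periods with all values in [0, 1]:
    the maximum over lag of the absolute normalized cross-correlation
    between each atom's waveform and the reference atom's waveform.
    """

    coefficients: np.ndarray
    multiplier: float = np.nan
    subject: str = ""
    channel_names: list = field(default_factory=list)

    @property
    def n_periods(self) -> int:
        return self.coefficients.shape[1]

    def mean_sequence(self) -> np.ndarray:
        """Channel-mean sequence used for phase detection/classification."""
        return self.coefficients.mean(axis=0)


@dataclass
class GaborDictionary:
    """Discretized Gabor family over a fixed window length.

    Atoms are ordered by (xi, s, u) so that exact ties in the selection
    criterion resolve to the lowest modulation, then the smallest scale,
    then the earliest translation.
    """

    window_len: int
    sfreq_hz: float
    params: np.ndarray        # (n_atoms, 3): s, u, xi
    cos_part: np.ndarray      # (n_atoms, N) real part of the unit-norm atom
    sin_part: np.ndarray      # (n_atoms, N) imaginary part
    gram_inv: np.ndarray      # (n_atoms, 3): inverse Gram entries a11,a12,a22
    scales: np.ndarray
    modulations: np.ndarray   # rad/sample grid

    @property
    def n_atoms(self) -> int:
        return len(self.params)

    @property
    def mod_step(self) -> float:
        return float(self.modulations[1] - self.modulations[0])


def build_dictionary(
    window_len: int,
    sfreq_hz: float,
    *,
    min_scale: int = MIN_SCALE,
    mod_step_hz: float = MOD_STEP_HZ,
    mod_range_hz: tuple[float, float] = MOD_RANGE_HZ,
) -> GaborDictionary:
    """Build the Gabor dictionary for a window.

    Scales form a dyadic ladder from ``min_scale`` up to the window length;
    translations sit on a quarter-scale lattice per scale; modulations are
    linearly spaced over ``mod_range_hz`` with step ``mod_step_hz``.
    """
    if window_len < 8:
        raise ValueError("window must be at least 8 samples")
    if min_scale > window_len:
        raise ValueError(
            f"window of {window_len} samples too short for min_scale={min_scale}"
        )
    scales = []
    s = min_scale
    while s <= window_len:
        scales.append(s)
        s *= 2
    mods_hz = np.arange(mod_range_hz[0], mod_range_hz[1] + 1e-9, mod_step_hz)
    mods = 2 * np.pi * mods_hz / sfreq_hz

    n = np.arange(window_len, dtype=float)
    # Unit-norm envelopes per (s, u), shared across modulations.
    su_pairs = []
    envs = []
    for s in scales:
        step = max(1, s // 4)
        for u in range(0, window_len, step):
            env = np.exp(-np.pi * ((n - u) / s) ** 2)
            env /= np.sqrt((env**2).sum())
            su_pairs.append((float(s), float(u)))
            envs.append(env)
    envs = np.array(envs)                     # (n_su, N)
    su = np.array(su_pairs)

    n_su, n_mod = len(su), len(mods)
    params = np.empty((n_mod * n_su, 3))
    cos_part = np.empty((n_mod * n_su, window_len))
    sin_part = np.empty((n_mod * n_su, window_len))
    for j, xi in enumerate(mods):             # ordered: xi outer, then (s, u)
        sl = slice(j * n_su, (j + 1) * n_su)
        params[sl, 0:2] = su
        params[sl, 2] = xi
        ph = xi * (n[None, :] - su[:, 1][:, None])
        cos_part[sl] = envs * np.cos(ph)
        sin_part[sl] = envs * np.sin(ph)

    grr = np.einsum("ij,ij->i", cos_part, cos_part)
    gii = np.einsum("ij,ij->i", sin_part, sin_part)
    gri = np.einsum("ij,ij->i", cos_part, sin_part)
    det = grr * gii - gri**2
    gram_inv = np.empty((len(params), 3))
    # Near-degenerate pairs (vanishing sine part): keep the cosine only.
    bad = det < 1e-12 * np.maximum(grr * gii, 1e-300)
    good = ~bad
    gram_inv[good, 0] = gii[good] / det[good]
    gram_inv[good, 1] = -gri[good] / det[good]
    gram_inv[good, 2] = grr[good] / det[good]
    gram_inv[bad, 0] = 1.0 / grr[bad]
    gram_inv[bad, 1] = 0.0
    gram_inv[bad, 2] = 0.0
    return GaborDictionary(
        window_len=window_len,
        sfreq_hz=sfreq_hz,
        params=params,
        cos_part=cos_part,
        sin_part=sin_part,
        gram_inv=gram_inv,
        scales=np.array(scales, dtype=float),
        modulations=mods,
    )


def fit_atom(window: np.ndarray, dictionary: GaborDictionary) -> TMPAtom:
    """Single multichannel Matching Pursuit iteration over the dictionary.

    Selects the (s, u, xi) maximizing the total captured energy
    ``sum_c ||P_gamma x_c||^2`` (projection onto the atom's real span),
    then records per-channel amplitude (l2 norm of the projection) and
    phase (at the envelope center).
    """
    x = np.atleast_2d(np.asarray(window, dtype=float))
    if x.shape[1] != dictionary.window_len:
        raise ValueError(
            f"window has {x.shape[1]} samples, dictionary expects "
            f"{dictionary.window_len}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains non-finite values")

    cr = x @ dictionary.cos_part.T        # (C, A)
    ci = x @ dictionary.sin_part.T
    # Criterion: energy captured by the phase-optimal real atom, i.e. the
    # exact projection onto span{cos part, sin part} per channel, summed
    # over channels.  A window lying in an atom's own span captures its
    # full energy, so planted atoms are always recovered.
    a11 = dictionary.gram_inv[:, 0]
    a12 = dictionary.gram_inv[:, 1]
    a22 = dictionary.gram_inv[:, 2]
    energy = a11 * cr**2 + 2 * a12 * cr * ci + a22 * ci**2
    crit = energy.sum(axis=0)
    best = int(np.argmax(crit))           # ties -> lowest xi, then s, then u

    s, u, xi = dictionary.params[best]
    a = a11[best] * cr[:, best] + a12[best] * ci[:, best]
    b = a12[best] * cr[:, best] + a22[best] * ci[:, best]
    amps = np.sqrt(np.maximum(energy[:, best], 0.0))
    # w = a*cos + b*sin = A*env*cos(xi(n-u) + phase) with phase = -atan2(b, a)
    phases = -np.arctan2(b, a)
    phases[amps == 0] = 0.0
    phases = np.where(phases <= -np.pi, phases + 2 * np.pi, phases)
    total = float(crit[best])
    return TMPAtom(
        s=float(s),
        u=float(u),
        xi=float(xi),
        amps=amps,
        phases=phases,
        window_len=dictionary.window_len,
        criterion=total,
        degenerate=bool(total <= 0.0),
    )


def reconstruct(atom: TMPAtom, channel: int | None = None) -> np.ndarray:
    """Real waveform(s) of an atom over its window.

    Returns channels x samples (or one row when ``channel`` is given):
    the unit-l2-norm phase-shifted Gabor waveform scaled by the channel
    amplitude, so a reconstruction's energy equals ``amp**2`` and fitting
    a reconstruction recovers the amplitude exactly.
    """
    n = np.arange(atom.window_len, dtype=float)
    env = np.exp(-np.pi * ((n - atom.u) / atom.s) ** 2)
    if channel is not None:
        wav = env * np.cos(atom.xi * (n - atom.u) + atom.phases[channel])
        norm = np.sqrt((wav**2).sum())
        return atom.amps[channel] * (wav / norm if norm > 0 else wav)
    wav = env[None, :] * np.cos(atom.xi * (n - atom.u)[None, :] + atom.phases[:, None])
    norms = np.sqrt((wav**2).sum(axis=1, keepdims=True))
    norms[norms == 0] = 1.0
    return atom.amps[:, None] * wav / norms


def atom_sequence(
    block: AveragedBlock,
    dictionary: GaborDictionary | None = None,
    n_post: int = N_POST_PERIODS,
) -> list[TMPAtom]:
    """One TMP atom per stimulation period plus ``n_post`` post periods.

    Windows are one period long, anchored at the flash onsets; the post
    windows continue at nominal period multiples after the last flash.
    """
    period = block.period_samples
    if dictionary is None:
        # One atom summarizes one period: envelopes narrower than half the
        # window act as bump-matchers for a single oscillation cycle and
        # bias the modulation estimate low, so the period dictionary uses
        # the {window/2, window} scales.
        dictionary = build_dictionary(
            period, block.sfreq_hz, min_scale=max(period // 2, 8)
        )
    onsets = list(block.flash_onset_samples)
    last = onsets[-1]
    exact_period = block.sfreq_hz / block.stim_freq_hz
    post_onsets = [int(round(last + k * exact_period)) for k in range(1, n_post + 1)]
    if post_onsets[-1] + period > block.n_samples:
        raise ValueError(
            f"block too short for {n_post} post-stimulation periods"
        )
    atoms = []
    for start in onsets + post_onsets:
        atoms.append(fit_atom(block.data[:, start : start + period], dictionary))
    return atoms


def _circular_mean(phases: np.ndarray, axis: int = 0) -> np.ndarray:
    """Resultant-vector circular mean, wrapped to (-pi, pi]."""
    res = np.exp(1j * phases).mean(axis=axis)
    ang = np.angle(res)
    ang = np.where(np.abs(res) < 1e-12, 0.0, ang)
    return np.where(ang <= -np.pi, ang + 2 * np.pi, ang)


def reference_atom(atoms: list[TMPAtom]) -> TMPAtom:
    """Parameter-wise average of the 40 stimulus-period atoms at 1.00*alpha.

    Scale, translation and modulation are averaged arithmetically;
    per-channel amplitudes arithmetically; per-channel phases circularly.
    """
    if not atoms:
        raise ValueError("cannot average an empty atom list")
    amps = np.stack([a.amps for a in atoms])
    phases = np.stack([a.phases for a in atoms])
    return TMPAtom(
        s=float(np.mean([a.s for a in atoms])),
        u=float(np.mean([a.u for a in atoms])),
        xi=float(np.mean([a.xi for a in atoms])),
        amps=amps.mean(axis=0),
        phases=_circular_mean(phases, axis=0),
        window_len=atoms[0].window_len,
        criterion=float(np.mean([a.criterion for a in atoms])),
    )


def correlation_sequence(
    reference: TMPAtom,
    atoms: list[TMPAtom],
    window_len: int | None = None,
    *,
    max_lag: int | None = None,
    multiplier: float = np.nan,
    subject: str = "",
    channel_names: list | None = None,
) -> CorrSeq:
    """Normalized correlation coefficients of every atom with the reference.

    Both atoms' real waveforms are reconstructed over a common window and,
    per channel, the maximum over lag of the absolute normalized
    cross-correlation is taken, giving values in [0, 1].  The lag search
    is bounded (default: 1/24 of the window) so that small temporal
    misalignments are absorbed while a genuine phase reversal or frequency
    change is not — an unbounded search would rate any two same-frequency
    atoms as identical.  A zero-energy waveform on a channel yields a
    coefficient of 0.
    """
    if any(a.n_channels != reference.n_channels for a in atoms):
        raise ValueError("reference and atoms must share their channel count")
    n = window_len or max(reference.window_len, max(a.window_len for a in atoms))
    if max_lag is None:
        max_lag = max(n // 24, 2)
    max_lag = min(max_lag, n - 1)
    ref_full = _pad_to(reconstruct(reference), n)
    ref_norm = np.linalg.norm(ref_full, axis=1)
    coeffs = np.zeros((reference.n_channels, len(atoms)))
    center = n - 1
    for j, atom in enumerate(atoms):
        wav = _pad_to(reconstruct(atom), n)
        wav_norm = np.linalg.norm(wav, axis=1)
        ok = (ref_norm > 0) & (wav_norm > 0)
        if not ok.any():
            continue
        xc = fftconvolve(ref_full[ok], wav[ok, ::-1], mode="full", axes=1)
        xc = xc[:, center - max_lag : center + max_lag + 1]
        coeffs[ok, j] = np.abs(xc).max(axis=1) / (ref_norm[ok] * wav_norm[ok])
    coeffs = np.clip(coeffs, 0.0, 1.0)
    return CorrSeq(
        coefficients=coeffs,
        multiplier=multiplier,
        subject=subject,
        channel_names=list(channel_names) if channel_names is not None else [],
    )


def _pad_to(w: np.ndarray, n: int) -> np.ndarray:
    if w.shape[1] == n:
        return w
    if w.shape[1] > n:
        return w[:, :n]
    out = np.zeros((w.shape[0], n))
    out[:, : w.shape[1]] = w
    return out


def atoms_to_frame(
    atoms: list[TMPAtom],
    sfreq_hz: float,
    channel_names: list,
    *,
    subject: str = "",
    multiplier: float = np.nan,
) -> pd.DataFrame:
    """Tabular serialization: one row per atom, per-channel amp/phase columns."""
    rows = []
    for i, a in enumerate(atoms):
        row = {
            "subject": subject,
            "multiplier": multiplier,
            "period": i + 1,
            "s": a.s,
            "u": a.u,
            "xi": a.xi,
            "freq_hz": a.freq_hz(sfreq_hz),
            "criterion": a.criterion,
        }
        for c, name in enumerate(channel_names):
            row[f"amp_{name}"] = a.amps[c]
            row[f"phase_{name}"] = a.phases[c]
        rows.append(row)
    return pd.DataFrame(rows)
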