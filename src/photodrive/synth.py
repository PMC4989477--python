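"""Synthetic MEG sessions emulating rod-driven photic driving.

The generator reproduces, with known ground truth, the phenomenology of
low-intensity (scotopic, rod-dominated) intermittent photic stimulation:

* stimulation inside the entrainment band (0.40-1.10 times the individual
  alpha frequency) locks the posterior alpha oscillator to the stimulation
  frequency, with resonance amplitude gains peaking at 1.00*alpha and
  0.50*alpha, and the driven rhythm persists for a few periods after the
  last flash before decaying;
* stimulation at or above the flicker-fusion multiplier (1.30) produces no
  sustained oscillation at the stimulation frequency — the flicker is
  perceived as steady light — but evokes an on-transient ~200 ms after
  train onset, a smaller off-transient after train end, and a partial
  suppression of the background alpha rhythm;
* the source projects to the sensors through a fixed dipolar occipital
  topography (magnetometers carry the field pattern in fT, planar
  gradiometers its tangential derivatives in fT/cm), with independent
  Gaussian sensor noise.

The oscillator is a hard-locking phase oscillator: inside the entrainment
band its instantaneous frequency equals the stimulation frequency with an
engagement ramp of a few periods; outside the band it free-runs at the
alpha frequency.  This is the simplest mechanism that reproduces the
entrainment, resonance, preservation and fusion effects the downstream
classifiers are built to detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .layout import GRAD, MAG, SensorLayout
from .protocol import StimProtocol
from .recording import (
    CODE_BLOCK_END,
    CODE_BLOCK_START,
    CODE_FLASH,
    CODE_TRAIN_END,
    CODE_TRAIN_START,
    Recording,
)

__all__ = [
    "ResponseModelParams",
    "BlockTruth",
    "SourceBlock",
    "Session",
    "simulate_source",
    "simulate_session",
    "dipolar_patterns",
]

#: Reference sensor amplitudes of a unit-amplitude source (resting alpha).
MAG_SCALE_FT = 200.0       # fT at the strongest magnetometer
GRAD_SCALE_FT_CM = 100.0   # fT/cm at the strongest gradiometer

#: Pole positions (x, y, sign) of the dipolar source patterns on the unit
#: disk: the driven occipital response and the topographically distinct
#: free-running background-alpha generators.
RESPONSE_POLES = ((0.25, -0.75, 1.0), (-0.25, -0.75, -1.0))
BACKGROUND_POLES = (
    ((0.45, -0.55, 1.0), (-0.05, -0.95, -1.0)),
    ((-0.40, -0.60, 1.0), (0.10, -0.90, -1.0)),
    ((0.15, -0.45, 1.0), (-0.20, -1.00, -1.0)),
    ((0.55, -0.80, 1.0), (-0.30, -0.45, -1.0)),
    ((-0.55, -0.75, 1.0), (0.30, -0.50, -1.0)),
    ((0.05, -0.65, 1.0), (-0.50, -0.95, -1.0)),
)


@dataclass(frozen=True)
class ResponseModelParams:
    """Tunable parameters of the rod-driven response model.

    Attributes
    ----------
    entrainment_band
        Multiplier interval (inclusive) in which the alpha oscillator locks
        to the stimulation frequency.
    fusion_threshold_mult
        Multiplier at and above which the flicker fuses: no oscillatory
        driving, on/off transients instead.
    resonance_gains
        Optional explicit multiplier -> amplitude-gain mapping.  When a
        multiplier is absent the double-Gaussian resonance profile below is
        used (peaks at 1.00 and 0.50 times alpha).
    gain_base, gain_alpha_peak, gain_half_peak, gain_width_alpha, gain_width_half
        Parameters of the default resonance profile
        ``g(m) = base + a*exp(-((m-1)/w1)^2) + b*exp(-((m-0.5)/w0.5)^2)``.
    subharmonic_gain, subharmonic_width
        Amplitude profile of the second-harmonic component evoked by
        stimulation near half the alpha frequency: driving at 0.50*alpha
        resonates the alpha rhythm itself, so the locked response carries a
        component at twice the stimulation frequency with amplitude
        ``subharmonic_gain * exp(-((m-0.5)/subharmonic_width)^2)``.
    alpha_amp
        Source amplitude of the resting alpha rhythm (arbitrary source
        units; the sensor scale is set by the projection).
    alpha_phase_diffusion
        Phase-diffusion rate of the free-running alpha oscillator in
        rad^2/s (random-walk phase).  The resting alpha rhythm is only
        coherent over a few hundred milliseconds; 5 rad^2/s gives a
        realistic spectral linewidth of just under 1 Hz.  Because the
        unlocked rhythm carries a random phase in every train, it largely
        cancels under train averaging while the stimulus-locked response
        survives — the effect that makes engagement visible.  Set to 0 for
        a fully coherent (pure sinusoid) background.
    background_split
        Fraction of the background-alpha energy carried by additional
        free-running generators with their own dipolar topographies,
        independent phase diffusion, and small frequency detunes
        (``background_detune_sd_hz``).  The driven response and the
        free-running rhythm do not share their generators; with several
        incoherent background sources the sensor topography genuinely
        destabilizes when the drive ends.  Set to 0 to project everything
        through the single response pattern.
    background_detune_sd_hz
        Standard deviation of the per-generator frequency offset from the
        nominal alpha frequency (the alpha band has finite width).
    alpha_suppression_locked
        Fraction of the background alpha removed while the oscillator is
        locked to the stimulus.
    alpha_suppression_fused
        Fraction of the background alpha removed during fused (>= fusion
        threshold) stimulation — event-related desynchronization.
    engage_periods
        Time constant of the engagement ramp, in stimulation periods.
    train_phase_jitter
        Half-width of the uniform random phase offset (rad) the oscillator
        carries at each train onset.  The free-running rhythm has an
        arbitrary phase when a train starts (the inter-train rest far
        exceeds the alpha coherence time), and the offset decays with the
        engagement time constant as the oscillator pulls into lock; across
        the 30 averaged trains this renders the early driven response
        incoherent, so engagement is visible in the train average.  Set to
        0 for a response locked from the first flash.
    alpha_recovery_tau_s
        Recovery time constant (s) of the suppressed background alpha
        after the driving ends (event-related desynchronization outlasts
        the stimulus by about a second).
    preservation_periods
        Number of periods the driven rhythm persists after the last flash
        before decaying back to the resting alpha.
    on_latency_ms, off_latency_ms
        Transient latencies after train onset / end of the last period.
    latency_jitter_sd_ms
        Per-subject (per-session) jitter of both latencies.
    transient_width_ms
        FWHM of the Gaussian transient bump.
    transient_gain, off_transient_scale
        On-bump amplitude in units of ``alpha_amp``; the off bump is the
        on bump scaled by ``off_transient_scale``.
    snr
        Sensor signal-to-noise ratio: the per-channel-type peak alpha
        amplitude divided by the noise standard deviation.  ``None`` or
        ``inf`` disables noise.
    pre_pad_s, post_pad_s
        Silence (background alpha only) before the first train and after
        the last inter-train rest of each block.
    seed
        Master seed; the same seed yields a bit-identical session.
    """

    entrainment_band: tuple[float, float] = (0.40, 1.10)
    fusion_threshold_mult: float = 1.30
    resonance_gains: dict | None = None
    gain_base: float = 1.2
    gain_alpha_peak: float = 1.8
    gain_half_peak: float = 0.8
    gain_width_alpha: float = 0.12
    gain_width_half: float = 0.08
    subharmonic_gain: float = 1.5
    subharmonic_width: float = 0.05
    alpha_amp: float = 1.0
    alpha_phase_diffusion: float = 5.0
    background_split: float = 0.85
    background_detune_sd_hz: float = 0.3
    alpha_suppression_locked: float = 0.9
    alpha_suppression_fused: float = 0.5
    engage_periods: float = 10.0
    train_phase_jitter: float = float(np.pi)
    alpha_recovery_tau_s: float = 1.0
    preservation_periods: int = 2
    on_latency_ms: float = 200.0
    off_latency_ms: float = 150.0
    latency_jitter_sd_ms: float = 18.0
    transient_width_ms: float = 50.0
    transient_gain: float = 2.0
    off_transient_scale: float = 0.6
    snr: float | None = 2.0
    pre_pad_s: float = 2.0
    post_pad_s: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.preservation_periods <= 3):
            raise ValueError("preservation_periods must lie in [1, 3]")

    def gain_for(self, multiplier: float) -> float:
        """Resonance amplitude gain at a multiplier (entrained blocks)."""
        if self.resonance_gains and multiplier in self.resonance_gains:
            return float(self.resonance_gains[multiplier])
        return (
            self.gain_base
            + self.gain_alpha_peak
            * math.exp(-(((multiplier - 1.0) / self.gain_width_alpha) ** 2))
            + self.gain_half_peak
            * math.exp(-(((multiplier - 0.5) / self.gain_width_half) ** 2))
        )

    def is_entrained(self, multiplier: float) -> bool:
        lo, hi = self.entrainment_band
        return lo <= multiplier <= hi and multiplier < self.fusion_threshold_mult

    def is_fused(self, multiplier: float) -> bool:
        return multiplier >= self.fusion_threshold_mult

    def with_(self, **kwargs) -> "ResponseModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class BlockTruth:
    """Generator ground truth for one stimulation block."""

    block_index: int
    multiplier: float
    stim_freq_hz: float
    entrained: bool
    fused: bool
    gain: float
    preservation_periods: int
    on_latency_ms: float | None   # effective (jittered); None when no transient
    off_latency_ms: float | None

    def as_dict(self) -> dict:
        return {
            "block_index": self.block_index,
            "multiplier": self.multiplier,
            "stim_freq_hz": self.stim_freq_hz,
            "entrained": self.entrained,
            "fused": self.fused,
            "gain": self.gain,
            "preservation_periods": self.preservation_periods,
            "on_latency_ms": self.on_latency_ms,
            "off_latency_ms": self.off_latency_ms,
        }


@dataclass
class SourceBlock:
    """Noiseless 1-D source time course for one stimulation block."""

    source: np.ndarray            # (n_samples,)
    sfreq_hz: float
    flash_samples: np.ndarray     # (n_trains, flashes_per_train)
    train_start_samples: np.ndarray
    train_end_samples: np.ndarray  # end of the last stimulation period
    truth: BlockTruth
    alpha_weight: np.ndarray | None = None  # background-alpha gate over time

    @property
    def n_samples(self) -> int:
        return len(self.source)


def _block_timing(protocol: StimProtocol, multiplier: float, params: ResponseModelParams):
    """Sample-accurate train/flash timing for one block.

    Train onsets sit on integer samples; flash onsets are rounded per flash
    from the exact continuous times, so fractional-sample drift of
    non-divisor frequencies never accumulates across a train.
    """
    fs = protocol.sfreq_hz
    f = protocol.stim_freq(multiplier)
    pre = int(round(params.pre_pad_s * fs))
    stride = int(round((protocol.train_duration_s(multiplier) + protocol.inter_train_rest_s) * fs))
    train_starts = pre + stride * np.arange(protocol.trains_per_block)
    k = np.arange(protocol.flashes_per_train)
    flash_offsets = np.round(k * fs / f).astype(np.int64)
    flash_samples = train_starts[:, None] + flash_offsets[None, :]
    train_ends = train_starts + int(round(protocol.flashes_per_train * fs / f))
    n_samples = int(train_starts[-1] + stride + round(params.post_pad_s * fs))
    return train_starts.astype(np.int64), train_ends.astype(np.int64), flash_samples, n_samples


def _raised_cosine_edge(t: np.ndarray, t0: float, width: float) -> np.ndarray:
    """Smooth 0 -> 1 step at t0 over `width` seconds."""
    x = np.clip((t - t0) / width, 0.0, 1.0)
    return 0.5 * (1 - np.cos(np.pi * x))


def simulate_source(
    multiplier: float,
    protocol: StimProtocol,
    params: ResponseModelParams,
    *,
    block_index: int = 0,
    on_latency_ms: float | None = None,
    off_latency_ms: float | None = None,
    rng: np.random.Generator | None = None,
) -> SourceBlock:
    """Noiseless source time course of one stimulation block.

    Inside the entrainment band the source oscillates at the stimulation
    frequency with the resonance gain, ramping up over a few periods
    (engagement) and persisting ``preservation_periods`` after the last
    flash.  At or above the fusion threshold there is no driven
    oscillation; instead Gaussian on/off transients are added and the
    background alpha is partially suppressed.  Background alpha is present
    throughout the rest intervals.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    fs = protocol.sfreq_hz
    f = protocol.stim_freq(multiplier)
    alpha = protocol.alpha_hz
    train_starts, train_ends, flash_samples, n_samples = _block_timing(
        protocol, multiplier, params
    )
    t = np.arange(n_samples) / fs

    entrained = params.is_entrained(multiplier)
    fused = params.is_fused(multiplier)
    gain = params.gain_for(multiplier) if entrained else 0.0

    lat_on = params.on_latency_ms if on_latency_ms is None else on_latency_ms
    lat_off = params.off_latency_ms if off_latency_ms is None else off_latency_ms

    alpha_weight = np.ones(n_samples)
    driven = np.zeros(n_samples)
    transients = np.zeros(n_samples)

    rng = rng or np.random.default_rng(
        np.random.SeedSequence([params.seed, 7919, block_index])
    )
    # Segment boundaries: each train owns [onset, next onset).
    seg_bounds = list(train_starts) + [n_samples]
    if entrained:
        tau_up = params.engage_periods / f
        tau_down = 1.0 / f
        tau_rec = params.alpha_recovery_tau_s
        hold = params.preservation_periods / f
        harm = params.subharmonic_gain * math.exp(
            -(((multiplier - 0.5) / params.subharmonic_width) ** 2)
        )
        # Oscillator phase offset at each train onset, decaying into lock.
        offsets = rng.uniform(
            -params.train_phase_jitter, params.train_phase_jitter,
            size=len(train_starts),
        )
        supp = np.zeros(n_samples)
        for i, (a, Tend) in enumerate(zip(train_starts, train_ends / fs)):
            b = seg_bounds[i + 1]
            tl = t[a:b] - a / fs          # time since train onset
            dur = Tend - a / fs + hold    # driving + preservation
            ramp = 1 - np.exp(-tl / tau_up)
            level = 1 - math.exp(-dur / tau_up)
            seg_lock = np.where(
                tl < dur, ramp, level * np.exp(-(tl - dur) / tau_down)
            )
            # Alpha suppression tracks the drive but recovers more slowly.
            supp[a:b] = np.where(
                tl < dur, ramp, level * np.exp(-(tl - dur) / tau_rec)
            )
            # Driven phase locked to the flashes once the offset has decayed.
            ph = 2 * np.pi * f * tl + offsets[i] * np.exp(-tl / tau_up)
            wave = gain * np.sin(ph)
            if harm > 1e-6:
                wave = wave + harm * np.sin(2 * ph)
            driven[a:b] = params.alpha_amp * seg_lock * wave
        alpha_weight = 1 - params.alpha_suppression_locked * supp
    elif fused:
        sigma_s = params.transient_width_ms / 1000.0 / 2.3548  # FWHM -> sd
        box = np.zeros(n_samples)
        for i, (a, Tend) in enumerate(zip(train_starts, train_ends / fs)):
            b = seg_bounds[i + 1]
            T0 = a / fs
            box[a:b] = _raised_cosine_edge(t[a:b], T0, 0.1) - _raised_cosine_edge(
                t[a:b], Tend, 0.1
            )
            for tc, scale in (
                (T0 + lat_on / 1000.0, 1.0),
                (Tend + lat_off / 1000.0, params.off_transient_scale),
            ):
                seg = slice(
                    max(0, int((tc - 6 * sigma_s) * fs)),
                    min(n_samples, int((tc + 6 * sigma_s) * fs)),
                )
                transients[seg] += (
                    scale
                    * params.transient_gain
                    * params.alpha_amp
                    * np.exp(-((t[seg] - tc) ** 2) / (2 * sigma_s**2))
                )
        alpha_weight = 1 - params.alpha_suppression_fused * np.clip(box, 0, 1)

    if params.alpha_phase_diffusion > 0:
        steps = rng.standard_normal(n_samples) * np.sqrt(
            params.alpha_phase_diffusion / fs
        )
        alpha_phase = np.cumsum(steps)
    else:
        alpha_phase = 0.0
    bg_amp = params.alpha_amp * math.sqrt(max(1.0 - params.background_split, 0.0))
    source = (
        bg_amp * alpha_weight * np.sin(2 * np.pi * alpha * t + alpha_phase)
        + driven
        + transients
    )
    truth = BlockTruth(
        block_index=block_index,
        multiplier=multiplier,
        stim_freq_hz=f,
        entrained=entrained,
        fused=fused,
        gain=gain,
        preservation_periods=params.preservation_periods if entrained else 0,
        on_latency_ms=lat_on if fused else None,
        off_latency_ms=lat_off if fused else None,
    )
    return SourceBlock(
        source=source,
        sfreq_hz=fs,
        flash_samples=flash_samples,
        train_start_samples=train_starts,
        train_end_samples=train_ends,
        truth=truth,
        alpha_weight=alpha_weight if isinstance(alpha_weight, np.ndarray) else None,
    )


def dipolar_patterns(layout: SensorLayout, poles=RESPONSE_POLES) -> np.ndarray:
    """Fixed dipolar occipital projection: per-channel gain of the source.

    Magnetometers carry a two-pole field pattern over the posterior head;
    the two gradiometers of a triplet carry its x- and y-derivatives,
    mimicking planar gradiometers.  Patterns are scaled so the strongest
    magnetometer sees ``MAG_SCALE_FT`` fT and the strongest gradiometer
    ``GRAD_SCALE_FT_CM`` fT/cm for a unit-amplitude source.
    """
    x, y = layout.coords[:, 0], layout.coords[:, 1]
    sigma = 0.25

    def g(px, py):
        return np.exp(-((x - px) ** 2 + (y - py) ** 2) / (2 * sigma**2))

    mag_pattern = np.zeros(layout.n_channels)
    dx = np.zeros(layout.n_channels)
    dy = np.zeros(layout.n_channels)
    for px, py, s in poles:
        gg = s * g(px, py)
        mag_pattern += gg
        dx += gg * (-(x - px) / sigma**2)
        dy += gg * (-(y - py) / sigma**2)

    pattern = np.zeros(layout.n_channels)
    is_mag = layout.types == MAG
    is_grad = layout.types == GRAD
    # Within each triplet the first gradiometer takes d/dx, the second d/dy.
    grad_rank = np.zeros(layout.n_channels, dtype=int)
    seen: dict[int, int] = {}
    for i in np.flatnonzero(is_grad):
        trip = int(layout.triplet[i])
        grad_rank[i] = seen.get(trip, 0)
        seen[trip] = grad_rank[i] + 1
    grad_pattern = np.where(grad_rank == 0, dx, dy)

    if is_mag.any():
        pattern[is_mag] = mag_pattern[is_mag] / np.abs(mag_pattern[is_mag]).max() * MAG_SCALE_FT
    if is_grad.any():
        pattern[is_grad] = (
            grad_pattern[is_grad] / np.abs(grad_pattern[is_grad]).max() * GRAD_SCALE_FT_CM
        )
    return pattern


def _noise_sd_per_channel(layout: SensorLayout, params: ResponseModelParams) -> np.ndarray | None:
    """Per-channel noise SD: per-type peak alpha amplitude divided by snr."""
    if params.snr is None or not np.isfinite(params.snr):
        return None
    sd = np.zeros(layout.n_channels)
    sd[layout.types == MAG] = params.alpha_amp * MAG_SCALE_FT / params.snr
    sd[layout.types == GRAD] = params.alpha_amp * GRAD_SCALE_FT_CM / params.snr
    return sd


@dataclass
class Session:
    """A lazily materialized synthetic session.

    Holds the protocol, layout, model parameters and per-block ground
    truth; the (potentially large) per-block sensor data are generated on
    demand by :meth:`block` and :meth:`rest`, deterministically from the
    session seed regardless of access order.
    """

    protocol: StimProtocol
    layout: SensorLayout
    params: ResponseModelParams
    ground_truth: list[BlockTruth]
    _pattern: np.ndarray = field(repr=False, default=None)
    _patterns_bg: list = field(repr=False, default=None)
    _bg_detunes_hz: np.ndarray = field(repr=False, default=None)
    _block_seeds: list = field(repr=False, default=None)
    _rest_seed: object = field(repr=False, default=None)
    _on_latency_ms: float = 0.0
    _off_latency_ms: float = 0.0

    @property
    def n_blocks(self) -> int:
        return self.protocol.n_blocks

    @property
    def alpha_hz(self) -> float:
        return self.protocol.alpha_hz

    def truth_for(self, multiplier: float) -> BlockTruth:
        for tr in self.ground_truth:
            if tr.multiplier == multiplier:
                return tr
        raise KeyError(f"no block with multiplier {multiplier}")

    def block_index(self, multiplier: float) -> int:
        return self.truth_for(multiplier).block_index

    def source_block(self, i: int) -> SourceBlock:
        """Noiseless source for block ``i`` (ground-truth inspection)."""
        m = self.protocol.multipliers[i]
        return simulate_source(
            m,
            self.protocol,
            self.params,
            block_index=i,
            on_latency_ms=self._on_latency_ms,
            off_latency_ms=self._off_latency_ms,
        )

    def block(self, i: int) -> Recording:
        """Materialize the sensor-level recording of block ``i``.

        Sensor data are float32: MEG amplitudes of a few hundred fT need
        far less than single precision, and the large per-block matrices
        stay cheap to generate and filter.
        """
        sb = self.source_block(i)
        pattern = self._pattern.astype(np.float32)
        data = pattern[:, None] * sb.source.astype(np.float32)[None, :]
        rng = np.random.default_rng(self._block_seeds[i])
        self._add_background(data, sb.alpha_weight, rng)
        sd = _noise_sd_per_channel(self.layout, self.params)
        if sd is not None:
            noise = rng.standard_normal(data.shape, dtype=np.float32)
            data += sd.astype(np.float32)[:, None] * noise
        events = [(int(sb.train_start_samples[0]), CODE_BLOCK_START)]
        for ti in range(len(sb.train_start_samples)):
            events.append((int(sb.train_start_samples[ti]), CODE_TRAIN_START))
            for s in sb.flash_samples[ti]:
                events.append((int(s), CODE_FLASH))
            events.append((int(sb.train_end_samples[ti]), CODE_TRAIN_END))
        events.append((int(sb.train_end_samples[-1]), CODE_BLOCK_END))
        return Recording(
            data=data,
            sfreq_hz=self.protocol.sfreq_hz,
            events=np.array(events, dtype=np.int64),
            layout=self.layout,
            meta={
                "block_index": i,
                "multiplier": sb.truth.multiplier,
                "stim_freq_hz": sb.truth.stim_freq_hz,
                "truth": sb.truth,
            },
        )

    def rest(self) -> Recording:
        """The pre-stimulation resting segment (background alpha only)."""
        fs = self.protocol.sfreq_hz
        n = int(round(self.protocol.resting_duration_s * fs))
        t = np.arange(n) / fs
        if self.params.alpha_phase_diffusion > 0:
            phase_rng = np.random.default_rng(
                np.random.SeedSequence([self.params.seed, 7919, 10**6])
            )
            phase = np.cumsum(
                phase_rng.standard_normal(n)
                * np.sqrt(self.params.alpha_phase_diffusion / fs)
            )
        else:
            phase = 0.0
        bg_amp = self.params.alpha_amp * np.sqrt(
            max(1.0 - self.params.background_split, 0.0)
        )
        src = bg_amp * np.sin(2 * np.pi * self.alpha_hz * t + phase)
        data = self._pattern.astype(np.float32)[:, None] * src.astype(np.float32)[None, :]
        rng = np.random.default_rng(self._rest_seed)
        self._add_background(data, None, rng)
        sd = _noise_sd_per_channel(self.layout, self.params)
        if sd is not None:
            noise = rng.standard_normal(data.shape, dtype=np.float32)
            data += sd.astype(np.float32)[:, None] * noise
        return Recording(
            data=data,
            sfreq_hz=fs,
            events=np.empty((0, 2), dtype=np.int64),
            layout=self.layout,
            meta={"segment": "rest"},
        )

    def _add_background(
        self,
        data: np.ndarray,
        alpha_weight: np.ndarray | None,
        rng: np.random.Generator,
    ) -> None:
        """Add the free-running background-alpha generators in place."""
        p = self.params
        if p.background_split <= 0:
            return
        fs = self.protocol.sfreq_hz
        n_samples = data.shape[1]
        t = np.arange(n_samples) / fs
        amp = p.alpha_amp * np.sqrt(p.background_split / len(self._patterns_bg))
        for pattern, detune in zip(self._patterns_bg, self._bg_detunes_hz):
            phase = rng.uniform(0, 2 * np.pi)
            if p.alpha_phase_diffusion > 0:
                phase = phase + np.cumsum(
                    rng.standard_normal(n_samples)
                    * np.sqrt(p.alpha_phase_diffusion / fs)
                )
            src = amp * np.sin(2 * np.pi * (self.alpha_hz + detune) * t + phase)
            if alpha_weight is not None:
                src = src * alpha_weight
            data += pattern.astype(np.float32)[:, None] * src.astype(np.float32)[None, :]

    def iter_blocks(self):
        for i in range(self.n_blocks):
            yield self.block(i)


def simulate_session(
    protocol: StimProtocol,
    layout: SensorLayout,
    params: ResponseModelParams,
) -> Session:
    """Build a synthetic session with ground-truth labels for every block.

    The returned :class:`Session` materializes per-block recordings on
    demand; identical parameters and seed give bit-identical data.
    """
    if layout.n_channels < 1:
        raise ValueError("layout must contain at least one channel")
    ss = np.random.SeedSequence(params.seed)
    subject_child, rest_child, *block_children = ss.spawn(2 + protocol.n_blocks)
    jitter_rng = np.random.default_rng(subject_child)
    jit = jitter_rng.standard_normal(2) * params.latency_jitter_sd_ms
    on_lat = max(params.on_latency_ms + jit[0], 20.0)
    off_lat = max(params.off_latency_ms + jit[1], 20.0)
    bg_detunes = jitter_rng.standard_normal(len(BACKGROUND_POLES)) * params.background_detune_sd_hz

    truths = []
    for i, m in enumerate(protocol.multipliers):
        truths.append(
            BlockTruth(
                block_index=i,
                multiplier=m,
                stim_freq_hz=protocol.stim_freq(m),
                entrained=params.is_entrained(m),
                fused=params.is_fused(m),
                gain=params.gain_for(m) if params.is_entrained(m) else 0.0,
                preservation_periods=(
                    params.preservation_periods if params.is_entrained(m) else 0
                ),
                on_latency_ms=on_lat if params.is_fused(m) else None,
                off_latency_ms=off_lat if params.is_fused(m) else None,
            )
        )
    return Session(
        protocol=protocol,
        layout=layout,
        params=params,
        ground_truth=truths,
        _pattern=dipolar_patterns(layout),
        _patterns_bg=[dipolar_patterns(layout, poles=p) for p in BACKGROUND_POLES],
        _bg_detunes_hz=bg_detunes,
        _block_seeds=block_children,
        _rest_seed=rest_child,
        _on_latency_ms=on_lat,
        _off_latency_ms=off_lat,
    )
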