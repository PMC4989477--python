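"""Stimulation protocol for intermittent photic stimulation (IPS) sessions.

A session probes photic driving at 20 stimulation frequencies expressed as
multiples of the subject's individual alpha frequency (the peak frequency of
the resting posterior alpha rhythm).  Each frequency is presented in one
block of 30 trains of 40 flashes, with 4 s of rest between trains.  The
multipliers are presented in a randomized order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["DEFAULT_MULTIPLIERS", "StimProtocol", "generate_protocol"]

#: Stimulation-frequency multipliers of the individual alpha frequency.
DEFAULT_MULTIPLIERS: tuple[float, ...] = (
    0.40, 0.45, 0.50, 0.55, 0.60, 0.70, 0.80, 0.90, 0.95, 1.00,
    1.05, 1.10, 1.30, 1.70, 1.90, 1.95, 2.00, 2.05, 2.10, 2.30,
)

#: Plausible range for an individual alpha frequency (Hz).
ALPHA_BAND = (7.0, 13.0)


@dataclass(frozen=True)
class StimProtocol:
    """Timing structure of one IPS session.

    Parameters
    ----------
    alpha_hz
        Individual alpha frequency of the subject in Hz.  All stimulation
        frequencies are multiples of this value.
    multipliers
        Ordered stimulation-frequency multipliers, one block each.
    trains_per_block
        Flash trains presented (and later averaged) per block.
    flashes_per_train
        Flashes per train; one flash per stimulation period.
    inter_train_rest_s
        Rest between consecutive trains, seconds.
    inter_block_rest_s
        Synthesis pad between blocks, seconds.  The recording pauses of
        roughly two minutes between blocks in the laboratory protocol carry
        no analysis-relevant signal, so the generator uses a short pad.
    resting_duration_s
        Length of the eyes-closed resting segment recorded before
        stimulation, used to estimate the alpha frequency.
    sfreq_hz
        Sampling rate in Hz.
    """

    alpha_hz: float
    multipliers: tuple[float, ...] = DEFAULT_MULTIPLIERS
    trains_per_block: int = 30
    flashes_per_train: int = 40
    inter_train_rest_s: float = 4.0
    inter_block_rest_s: float = 2.0
    resting_duration_s: float = 60.0
    sfreq_hz: float = 1000.0

    def __post_init__(self) -> None:
        if not (ALPHA_BAND[0] <= self.alpha_hz <= ALPHA_BAND[1]):
            raise ValueError(
                f"alpha_hz={self.alpha_hz} outside the plausible alpha band "
                f"{ALPHA_BAND}"
            )
        if self.trains_per_block < 1 or self.flashes_per_train < 1:
            raise ValueError("trains_per_block and flashes_per_train must be >= 1")

    @property
    def n_blocks(self) -> int:
        return len(self.multipliers)

    def stim_freq(self, multiplier: float) -> float:
        """Stimulation frequency in Hz for a given multiplier."""
        return multiplier * self.alpha_hz

    def period_samples(self, multiplier: float) -> int:
        """Nominal stimulation period in samples (rounded)."""
        return int(round(self.sfreq_hz / self.stim_freq(multiplier)))

    def train_duration_s(self, multiplier: float) -> float:
        """Duration of one train (flash onset 1 to end of last period)."""
        return self.flashes_per_train / self.stim_freq(multiplier)

    def with_(self, **kwargs) -> "StimProtocol":
        """Return a copy with selected fields replaced."""
        return replace(self, **kwargs)


def generate_protocol(alpha_hz: float, seed: int) -> StimProtocol:
    """Create a default protocol with multipliers in seed-determined order.

    Parameters
    ----------
    alpha_hz
        Individual alpha frequency; must lie within 7-13 Hz.
    seed
        Seed for the random presentation order.  The same seed always
        yields the same order.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(DEFAULT_MULTIPLIERS))
    multipliers = tuple(DEFAULT_MULTIPLIERS[i] for i in order)
    return StimProtocol(alpha_hz=alpha_hz, multipliers=multipliers)
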