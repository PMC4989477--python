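"""In-memory container for a multichannel MEG segment with event markers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layout import SensorLayout

__all__ = [
    "Recording",
    "CODE_FLASH",
    "CODE_TRAIN_START",
    "CODE_TRAIN_END",
    "CODE_BLOCK_START",
    "CODE_BLOCK_END",
]

# Event codes.  A flash marker is placed at every light-flash onset; train
# and block markers delimit the protocol structure.
CODE_FLASH = 1
CODE_TRAIN_START = 2
CODE_TRAIN_END = 3
CODE_BLOCK_START = 10
CODE_BLOCK_END = 11


@dataclass
class Recording:
    """channels x samples data matrix with channel metadata and events.

    ``data`` is in fT (magnetometers) or fT/cm (planar gradiometers), one
    row per channel of ``layout``.  ``events`` is an (n_events, 2) integer
    array of ``(sample_index, code)`` rows.  ``meta`` carries free-form
    provenance (block index, multiplier, ground-truth labels, ...).
    """

    data: np.ndarray
    sfreq_hz: float
    events: np.ndarray
    layout: SensorLayout
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.events = np.asarray(self.events, dtype=np.int64).reshape(-1, 2)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != self.layout.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} rows but layout has "
                f"{self.layout.n_channels} channels"
            )
        if len(self.events) and (
            self.events[:, 0].min() < 0 or self.events[:, 0].max() >= self.n_samples
        ):
            raise ValueError("event sample indices must lie within [0, n_samples)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq_hz

    def event_samples(self, code: int) -> np.ndarray:
        """Sample indices of all events with the given code, in order."""
        return self.events[self.events[:, 1] == code, 0]

    def copy_with(self, data: np.ndarray) -> "Recording":
        """Same metadata, new data matrix (used by filtering stages)."""
        return Recording(
            data=data,
            sfreq_hz=self.sfreq_hz,
            events=self.events.copy(),
            layout=self.layout,
            meta=dict(self.meta),
        )
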