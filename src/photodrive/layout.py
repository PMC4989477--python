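"""Idealized whole-head MEG sensor layout.

The layout mimics a 306-channel triplet system: 102 sites, each carrying one
magnetometer (field, fT) and two orthogonal planar gradiometers (field
gradient, fT/cm).  Sites are placed on a sunflower lattice over the unit
disk (head seen from above, nose up: +y anterior, -y posterior).  Only the
2-D coordinates and the region tags are used downstream; no realistic
sensor geometry is required.

The 12 most posterior sites are tagged ``occipital``, so exactly 24
gradiometers carry the occipital tag — the channel subset over which
amplitude spectra are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SensorLayout", "default_layout", "MAG", "GRAD"]

MAG = "mag"
GRAD = "grad"

N_TRIPLETS = 102
N_OCCIPITAL_TRIPLETS = 12


@dataclass
class SensorLayout:
    """Channel metadata: names, types, triplet membership, position, region.

    All arrays share the channel axis.  ``coords`` holds (x, y) positions on
    the unit disk; the two gradiometers of a triplet share their site's
    position but measure orthogonal tangential derivatives of the field.
    """

    names: np.ndarray        # str
    types: np.ndarray        # "mag" | "grad"
    triplet: np.ndarray      # int, site index per channel
    coords: np.ndarray       # (n_channels, 2) float
    region: np.ndarray       # "occipital" | "other"

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def mask(self, *, types: str | None = None, region: str | None = None) -> np.ndarray:
        m = np.ones(self.n_channels, dtype=bool)
        if types is not None:
            m &= self.types == types
        if region is not None:
            m &= self.region == region
        return m

    def channel_names(self, *, types: str | None = None, region: str | None = None) -> list[str]:
        return list(self.names[self.mask(types=types, region=region)])

    def occipital_gradiometers(self) -> list[str]:
        """The 24 posterior gradiometer channels used for spectral averaging."""
        return self.channel_names(types=GRAD, region="occipital")

    def subset(self, selection) -> "SensorLayout":
        """Restrict the layout to a boolean mask or a list of channel names."""
        if isinstance(selection, np.ndarray) and selection.dtype == bool:
            idx = np.flatnonzero(selection)
        else:
            name_to_i = {n: i for i, n in enumerate(self.names)}
            idx = np.array([name_to_i[n] for n in selection], dtype=int)
        return SensorLayout(
            names=self.names[idx],
            types=self.types[idx],
            triplet=self.triplet[idx],
            coords=self.coords[idx],
            region=self.region[idx],
        )

    def index_of(self, names) -> np.ndarray:
        name_to_i = {n: i for i, n in enumerate(self.names)}
        return np.array([name_to_i[n] for n in names], dtype=int)


def _sunflower_disk(n: int) -> np.ndarray:
    """n points on the unit disk via the sunflower (golden-angle) lattice."""
    k = np.arange(1, n + 1)
    golden = (1 + np.sqrt(5)) / 2
    theta = 2 * np.pi * k / golden**2
    r = np.sqrt((k - 0.5) / n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def default_layout() -> SensorLayout:
    """Build the idealized 306-channel layout (102 triplets)."""
    sites = _sunflower_disk(N_TRIPLETS)
    # Posterior-most sites form the occipital patch.
    posterior_rank = np.argsort(sites[:, 1])
    occipital_sites = set(posterior_rank[:N_OCCIPITAL_TRIPLETS].tolist())

    names, types, triplet, coords, region = [], [], [], [], []
    for t in range(N_TRIPLETS):
        tag = "occipital" if t in occipital_sites else "other"
        for sub, ch_type in ((1, MAG), (2, GRAD), (3, GRAD)):
            names.append(f"MEG{t:03d}{sub}")
            types.append(ch_type)
            triplet.append(t)
            coords.append(sites[t])
            region.append(tag)
    return SensorLayout(
        names=np.array(names),
        types=np.array(types),
        triplet=np.array(triplet, dtype=int),
        coords=np.array(coords, dtype=float),
        region=np.array(region),
    )
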