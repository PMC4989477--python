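"""Shared fixtures: small layouts and reduced-size synthetic sessions."""

from __future__ import annotations

import numpy as np
import pytest

from photodrive.layout import default_layout
from photodrive.protocol import StimProtocol
from photodrive.synth import ResponseModelParams, simulate_session


@pytest.fixture(scope="session")
def full_layout():
    return default_layout()


@pytest.fixture(scope="session")
def occipital_layout(full_layout):
    return full_layout.subset(full_layout.mask(region="occipital"))


@pytest.fixture(scope="session")
def tiny_layout(full_layout):
    """Two occipital triplets (6 channels) for fast sensor-level tests."""
    occ = full_layout.subset(full_layout.mask(region="occipital"))
    keep = np.isin(occ.triplet, np.unique(occ.triplet)[:2])
    return occ.subset(keep)


@pytest.fixture
def small_protocol():
    """Reduced protocol: few trains/flashes, short rest, one multiplier pair."""
    return StimProtocol(
        alpha_hz=10.0,
        multipliers=(1.00, 2.00),
        trains_per_block=4,
        flashes_per_train=10,
        resting_duration_s=12.0,
    )


@pytest.fixture
def small_session(small_protocol, tiny_layout):
    params = ResponseModelParams(snr=2.0, seed=7)
    return simulate_session(small_protocol, tiny_layout, params)
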