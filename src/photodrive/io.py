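"""Session and recording persistence.

The internal container is HDF5: ``/data`` (channels x samples), ``/events``
(sample, code), ``/channels`` (name, type, region, triplet, x, y) plus
``sfreq`` / ``alpha_hz`` attributes for a single recording, and one group
per segment (``rest``, ``blocks/NN``) for a full session.  A YAML sidecar
stores the protocol, the model parameters and the ground-truth labels.
Recordings can also be exported to Neuromag FIF through MNE when it is
installed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import yaml

from .layout import SensorLayout
from .protocol import StimProtocol
from .recording import Recording
from .synth import ResponseModelParams, Session

__all__ = [
    "write_recording",
    "read_recording",
    "write_session",
    "read_session",
    "write_sidecar",
    "read_sidecar",
    "to_mne_raw",
]

_STR = h5py.string_dtype(encoding="utf-8")


def _write_layout(group: h5py.Group, layout: SensorLayout) -> None:
    ch = np.empty(
        layout.n_channels,
        dtype=[("name", _STR), ("type", _STR), ("region", _STR),
               ("triplet", "i4"), ("x", "f8"), ("y", "f8")],
    )
    ch["name"] = layout.names
    ch["type"] = layout.types
    ch["region"] = layout.region
    ch["triplet"] = layout.triplet
    ch["x"] = layout.coords[:, 0]
    ch["y"] = layout.coords[:, 1]
    group.create_dataset("channels", data=ch)


def _read_layout(group: h5py.Group) -> SensorLayout:
    ch = group["channels"][()]

    def dec(a):
        return np.array([v.decode() if isinstance(v, bytes) else str(v) for v in a])

    return SensorLayout(
        names=dec(ch["name"]),
        types=dec(ch["type"]),
        triplet=ch["triplet"].astype(int),
        coords=np.column_stack([ch["x"], ch["y"]]),
        region=dec(ch["region"]),
    )


def _write_segment(group: h5py.Group, rec: Recording) -> None:
    group.create_dataset("data", data=rec.data)
    group.create_dataset("events", data=rec.events)
    group.attrs["sfreq"] = rec.sfreq_hz
    for key in ("block_index", "multiplier", "stim_freq_hz", "segment"):
        if key in rec.meta and rec.meta[key] is not None:
            group.attrs[key] = rec.meta[key]


def _read_segment(group: h5py.Group, layout: SensorLayout) -> Recording:
    meta = {k: group.attrs[k] for k in group.attrs if k != "sfreq"}
    return Recording(
        data=group["data"][()],
        sfreq_hz=float(group.attrs["sfreq"]),
        events=group["events"][()],
        layout=layout,
        meta=meta,
    )


def write_recording(rec: Recording, path: str | Path, alpha_hz: float | None = None) -> None:
    """Write a single recording as an HDF5 container."""
    with h5py.File(path, "w") as f:
        _write_segment(f, rec)
        _write_layout(f, rec.layout)
        if alpha_hz is not None:
            f.attrs["alpha_hz"] = alpha_hz


def read_recording(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        layout = _read_layout(f)
        return _read_segment(f, layout)


def write_session(session: Session, path: str | Path, *, include_rest: bool = True) -> None:
    """Materialize and write every block (and the rest segment) of a session."""
    with h5py.File(path, "w") as f:
        f.attrs["sfreq"] = session.protocol.sfreq_hz
        f.attrs["alpha_hz"] = session.alpha_hz
        f.attrs["seed"] = session.params.seed
        _write_layout(f, session.layout)
        if include_rest:
            _write_segment(f.create_group("rest"), session.rest())
        for i in range(session.n_blocks):
            _write_segment(f.create_group(f"blocks/{i:02d}"), session.block(i))
    write_sidecar(session, Path(path).with_suffix(".yaml"))


def read_session(path: str | Path) -> dict:
    """Read a materialized session: rest recording plus per-block recordings."""
    with h5py.File(path, "r") as f:
        layout = _read_layout(f)
        out = {
            "alpha_hz": float(f.attrs["alpha_hz"]),
            "sfreq_hz": float(f.attrs["sfreq"]),
            "layout": layout,
            "rest": _read_segment(f["rest"], layout) if "rest" in f else None,
            "blocks": [
                _read_segment(f[f"blocks/{k}"], layout) for k in sorted(f["blocks"])
            ],
        }
    sidecar = Path(path).with_suffix(".yaml")
    if sidecar.exists():
        out["sidecar"] = read_sidecar(sidecar)
    return out


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_sidecar(session: Session, path: str | Path) -> None:
    """YAML sidecar: protocol, model parameters, ground-truth labels."""
    doc = _plain(
        {
            "protocol": dataclasses.asdict(session.protocol),
            "params": dataclasses.asdict(session.params),
            "ground_truth": [t.as_dict() for t in session.ground_truth],
        }
    )
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_sidecar(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def to_mne_raw(rec: Recording):
    """Convert a recording to an MNE RawArray (fT -> T, fT/cm -> T/m).

    Requires ``mne``; use ``raw.save(...)`` for FIF export.
    """
    import mne

    ch_types = ["mag" if t == "mag" else "grad" for t in rec.layout.types]
    info = mne.create_info(
        ch_names=list(rec.layout.names), sfreq=rec.sfreq_hz, ch_types=ch_types
    )
    scale = np.where(rec.layout.types == "mag", 1e-15, 1e-13)
    raw = mne.io.RawArray(rec.data * scale[:, None], info, verbose="error")
    return raw
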