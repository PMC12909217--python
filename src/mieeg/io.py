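"""Reading and writing recordings and derived tables.

Recordings travel either as EDF (read via MNE's built-in reader) or as a
plain numeric-matrix text format: one whitespace-separated row per channel
in uV, with a channel-name sidecar ``<stem>.channels.txt`` whose first line
is ``fs <rate>`` followed by one channel name per line. Derived tables are
flat CSV throughout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .network import BrainNetwork
from .preprocess import RawRecording

__all__ = [
    "write_matrix_recording",
    "read_matrix_recording",
    "read_recording",
    "write_connectivity_csv",
    "read_connectivity_csv",
    "write_network_edges",
    "write_manifest_csv",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + ".channels.txt")


def write_matrix_recording(rec: RawRecording, path) -> Path:
    """Write a recording as a plain numeric matrix plus sidecar."""
    path = Path(path)
    np.savetxt(path, rec.data, fmt="%.6f")
    lines = [f"fs {rec.fs:g}"] + list(rec.ch_names)
    _sidecar_path(path).write_text("\n".join(lines) + "\n")
    return path


def read_matrix_recording(path, meta: dict | None = None) -> RawRecording:
    """Read the plain-matrix format back into a :class:`RawRecording`."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing channel sidecar {sidecar}")
    lines = [ln.strip() for ln in sidecar.read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("fs "):
        raise ValueError(f"sidecar {sidecar} must start with an 'fs <rate>' line")
    fs = float(lines[0].split()[1])
    ch_names = lines[1:]
    if path.stat().st_size == 0:
        raise ValueError(f"empty recording file {path}")
    data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        raise ValueError(f"empty recording file {path}")
    if data.shape[0] != len(ch_names):
        raise ValueError(
            f"{path}: {data.shape[0]} rows but {len(ch_names)} sidecar channels"
        )
    return RawRecording(data=data, ch_names=ch_names, fs=fs, meta=meta or {})


def read_recording(path, meta: dict | None = None) -> RawRecording:
    """Read EDF (via MNE) or the plain-matrix format, dispatching on suffix.

    EDF voltages are converted to uV.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # V -> uV
        return RawRecording(
            data=data, ch_names=list(raw.ch_names), fs=float(raw.info["sfreq"]),
            meta=meta or {},
        )
    return read_matrix_recording(path, meta=meta)


def write_connectivity_csv(conn: ConnectivityMatrix, path) -> Path:
    """Connectivity matrix as CSV with region-name headers."""
    path = Path(path)
    pd.DataFrame(conn.w, index=conn.regions, columns=conn.regions).to_csv(path)
    return path


def read_connectivity_csv(path, band: str = "") -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0)
    return ConnectivityMatrix(band=band, w=df.to_numpy(), regions=list(df.columns))


def write_network_edges(net: BrainNetwork, path) -> Path:
    """Weighted edge list CSV (region_i, region_j, weight)."""
    path = Path(path)
    pd.DataFrame(net.edge_list(), columns=["region_i", "region_j", "weight"]).to_csv(
        path, index=False
    )
    return path


def write_manifest_csv(entries: list[dict], path) -> Path:
    """Provenance manifest: one row per written artifact."""
    path = Path(path)
    pd.DataFrame(entries).to_csv(path, index=False)
    return path


def write_config_json(config: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(config, indent=2, sort_keys=True, default=str) + "\n")
    return path
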