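"""Readers and writers for the delimited-text and HDF5 interchange formats.

Delimited text (CSV/TSV, autodetected or explicit) is the primary exchange
format: numeric matrices are observations x variables with an optional
header row; spike-time lists are two columns (neuron_id, time_ms).  State
series and joint-probability tables additionally round-trip through a small
HDF5 container that carries shape and axis-label metadata.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .discretize import JointDistribution, StateSeries
from .neurosim import SpikeRaster

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_spike_times",
    "write_spike_times",
    "write_states",
    "read_states",
    "write_joint_hdf5",
    "read_joint_hdf5",
]


def _sep(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_matrix(
    path: str | Path, sep: str | None = None, header: bool | None = None
) -> tuple[np.ndarray, list[str] | None]:
    """Read an observations x variables numeric matrix; returns (values, names)."""
    s = _sep(path, sep)
    first = pd.read_csv(path, sep=s, nrows=1, header=None)
    has_header = (
        header
        if header is not None
        else any(isinstance(v, str) for v in first.iloc[0])
    )
    df = pd.read_csv(path, sep=s, header=0 if has_header else None)
    return df.to_numpy(dtype=float), (list(map(str, df.columns)) if has_header else None)


def write_matrix(
    path: str | Path,
    values: np.ndarray,
    names: list[str] | None = None,
    sep: str | None = None,
) -> None:
    df = pd.DataFrame(np.asarray(values), columns=names)
    df.to_csv(path, sep=_sep(path, sep), index=False, header=names is not None)


def read_spike_times(path: str | Path, sep: str | None = None) -> dict[int, np.ndarray]:
    """Read a two-column (neuron_id, time_ms) list into {neuron: times}."""
    df = pd.read_csv(path, sep=_sep(path, sep), header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError("spike-time files need two columns: neuron_id, time_ms")
    out: dict[int, np.ndarray] = {}
    for nid, grp in df.groupby(0):
        out[int(nid)] = np.sort(grp[1].to_numpy(dtype=float))
    return out


def write_spike_times(path: str | Path, raster: SpikeRaster, sep: str | None = None) -> None:
    """Write a raster as (trial, neuron_id, time_ms) delimited rows."""
    rows = []
    for t, per_neuron in enumerate(raster.spike_times):
        for j, times in enumerate(per_neuron):
            for ms in np.asarray(times):
                rows.append((t, j, float(ms)))
    pd.DataFrame(rows, columns=["trial", "neuron", "time_ms"]).to_csv(
        path, sep=_sep(path, sep), index=False
    )


def write_states(path: str | Path, states: StateSeries, sep: str | None = None) -> None:
    df = pd.DataFrame(states.states, columns=states.names)
    df.to_csv(path, sep=_sep(path, sep), index=False)


def read_states(path: str | Path, sep: str | None = None) -> StateSeries:
    df = pd.read_csv(path, sep=_sep(path, sep))
    arr = df.to_numpy(dtype=np.int64)
    return StateSeries(arr, arr.max(axis=0) + 1, list(map(str, df.columns)))


def write_joint_hdf5(path: str | Path, joint: JointDistribution) -> None:
    """Store a joint table with shape and axis-label metadata."""
    with h5py.File(path, "w") as f:
        f.create_dataset("probabilities", data=joint.probabilities)
        if joint.counts is not None:
            f.create_dataset("counts", data=joint.counts)
        if joint.n_obs is not None:
            f.attrs["n_obs"] = joint.n_obs
        f.attrs["axis_names"] = [str(n) for n in joint.names]


def read_joint_hdf5(path: str | Path) -> JointDistribution:
    with h5py.File(path, "r") as f:
        p = f["probabilities"][...]
        counts = f["counts"][...] if "counts" in f else None
        n_obs = int(f.attrs["n_obs"]) if "n_obs" in f.attrs else None
        names = [
            n.decode() if isinstance(n, bytes) else str(n)
            for n in f.attrs.get("axis_names", [])
        ]
    return JointDistribution(p, counts=counts, n_obs=n_obs, names=names or [])
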