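"""Ensemble and trajectory persistence.

Two dialects are supported:

* HDF5 — stacked datasets ``mcs`` (Nc,), ``positions`` (Nc, N, 3, int64),
  concatenated ``bonds`` (M, 3, rows i, j, expiry) with ``bond_offsets``
  (Nc+1,) delimiting each snapshot's slice, and a ``provenance`` JSON attr.

* plain text — per snapshot a ``# MCS <t>`` header line, N whitespace
  coordinate lines ``x y z`` (unwrapped), then one ``LOOP i j expiry`` line
  per active loop bond.

Experimental MSD tables (genomic separation in Mb vs MSD in um^2) are read
as two-column tab-delimited text.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .engine import ConformationEnsemble, Snapshot, Trajectory

__all__ = [
    "save_ensemble_h5",
    "load_ensemble_h5",
    "write_ensemble_text",
    "read_ensemble_text",
    "save_trajectory_h5",
    "load_trajectory_h5",
    "read_experimental_msd",
]


def save_ensemble_h5(ensemble: ConformationEnsemble, path: str | Path) -> None:
    snaps = ensemble.snapshots
    bonds = [s.bonds for s in snaps]
    offsets = np.concatenate([[0], np.cumsum([b.shape[0] for b in bonds])])
    with h5py.File(path, "w") as f:
        f.create_dataset("mcs", data=np.array([s.mcs for s in snaps], dtype=np.int64))
        f.create_dataset(
            "positions", data=np.stack([s.positions for s in snaps]).astype(np.int64)
        )
        f.create_dataset(
            "bonds",
            data=np.concatenate(bonds) if offsets[-1] else np.empty((0, 3), np.int64),
        )
        f.create_dataset("bond_offsets", data=offsets.astype(np.int64))
        f.attrs["provenance"] = json.dumps(ensemble.provenance, default=str)


def load_ensemble_h5(path: str | Path) -> ConformationEnsemble:
    with h5py.File(path, "r") as f:
        mcs = f["mcs"][:]
        positions = f["positions"][:]
        bonds = f["bonds"][:]
        offsets = f["bond_offsets"][:]
        provenance = json.loads(f.attrs.get("provenance", "{}"))
    snaps = [
        Snapshot(
            mcs=int(mcs[k]),
            positions=positions[k],
            bonds=bonds[offsets[k] : offsets[k + 1]].reshape(-1, 3),
        )
        for k in range(len(mcs))
    ]
    return ConformationEnsemble(snapshots=snaps, provenance=provenance)


def write_ensemble_text(ensemble: ConformationEnsemble, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in ensemble.snapshots:
            fh.write(f"# MCS {s.mcs}\n")
            for x, y, z in s.positions:
                fh.write(f"{x} {y} {z}\n")
            for i, j, expiry in s.bonds:
                fh.write(f"LOOP {i} {j} {expiry}\n")


def read_ensemble_text(path: str | Path) -> ConformationEnsemble:
    snaps: list[Snapshot] = []
    mcs: int | None = None
    coords: list[list[int]] = []
    bonds: list[list[int]] = []

    def flush() -> None:
        if mcs is None:
            return
        snaps.append(
            Snapshot(
                mcs=mcs,
                positions=np.array(coords, dtype=np.int64),
                bonds=np.array(bonds, dtype=np.int64).reshape(-1, 3),
            )
        )

    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("# MCS"):
                flush()
                mcs = int(line.split()[2])
                coords, bonds = [], []
            elif line.startswith("LOOP"):
                _, i, j, expiry = line.split()
                bonds.append([int(i), int(j), int(expiry)])
            else:
                parts = line.split()
                if len(parts) != 3:
                    raise ValueError(f"{path}: line {line_no}: expected 'x y z'")
                coords.append([int(p) for p in parts])
    flush()
    if not snaps:
        raise ValueError(f"{path}: no snapshots found")
    return ConformationEnsemble(snapshots=snaps)


def save_trajectory_h5(trajectory: Trajectory, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=trajectory.times)
        f.create_dataset("positions", data=trajectory.positions)
        f.attrs["frame_interval"] = trajectory.frame_interval


def load_trajectory_h5(path: str | Path) -> Trajectory:
    with h5py.File(path, "r") as f:
        return Trajectory(
            times=f["times"][:],
            positions=f["positions"][:],
            frame_interval=int(f.attrs["frame_interval"]),
        )


def read_experimental_msd(path: str | Path) -> np.ndarray:
    """Read a two-column (Mb, um^2) tab-delimited MSD table."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["mb", "um2"])
    arr = df.to_numpy(dtype=float)
    if arr.shape[0] < 1 or np.any(~np.isfinite(arr)):
        raise ValueError(f"{path}: malformed experimental MSD table")
    return arr
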