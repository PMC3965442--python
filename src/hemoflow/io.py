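"""HDF5 snapshots of flow states and CSV profile output."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .grid import AxiGrid
from .state import FlowState

__all__ = ["save_state", "load_state", "save_report"]

_FIELDS = ("rho", "m_r", "m_z", "rho_dl")


def save_state(path, state: FlowState) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        g = state.grid
        f.attrs["nr"], f.attrs["nz"] = g.nr, g.nz
        f.attrs["dr"], f.attrs["dz"] = g.dr, g.dz
        f.attrs["z_min"], f.attrs["ng"] = g.z_min, g.ng
        f.attrs["t"] = state.t
        f.create_dataset("mask", data=state.mask.astype(np.uint8))
        for name in _FIELDS:
            f.create_dataset(name, data=getattr(state, name))


def load_state(path) -> FlowState:
    with h5py.File(path, "r") as f:
        grid = AxiGrid(nr=int(f.attrs["nr"]), nz=int(f.attrs["nz"]),
                       dr=float(f.attrs["dr"]), dz=float(f.attrs["dz"]),
                       z_min=float(f.attrs["z_min"]), ng=int(f.attrs["ng"]))
        fields = {name: f[name][...] for name in _FIELDS}
        mask = f["mask"][...].astype(bool)
        t = float(f.attrs["t"])
    return FlowState(grid=grid, mask=mask, t=t, **fields)


def save_report(path, report, extra: dict | None = None) -> None:
    payload = {
        "steps": report.steps,
        "t": report.t,
        "residual": report.residual,
        "converged": report.converged,
        "reason": report.reason,
    }
    if extra:
        payload.update(extra)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
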