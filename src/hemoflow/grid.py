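"""Regular cell-centered (r, z) grids for axisymmetric fields.

The axis r = 0 lies on a cell *face*: radial centers sit at (i + 1/2) dr so no
cell center is ever exactly on the axis (the 1/r terms stay finite).  Ghost
layers are allocated by the solver, not stored here; field arrays attached to a
grid are plain interior arrays of shape ``(nr, nz)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AxiGrid"]


@dataclass(frozen=True)
class AxiGrid:
    """Cell-centered regular grid on [0, nr*dr] x [z_min, z_min + nz*dz]."""

    nr: int
    nz: int
    dr: float
    dz: float
    z_min: float = 0.0
    ng: int = 3  # ghost-layer width used by the solver stencils

    def __post_init__(self) -> None:
        if self.nr < 1 or self.nz < 1:
            raise ValueError("nr and nz must be positive")
        if self.dr <= 0 or self.dz <= 0:
            raise ValueError("dr and dz must be positive")
        if self.ng < 1:
            raise ValueError("ghost width must be >= 1")

    @property
    def r(self) -> np.ndarray:
        """Radial cell-center coordinates, strictly positive."""
        return (np.arange(self.nr) + 0.5) * self.dr

    @property
    def z(self) -> np.ndarray:
        """Axial cell-center coordinates."""
        return self.z_min + (np.arange(self.nz) + 0.5) * self.dz

    @property
    def z_max(self) -> float:
        return self.z_min + self.nz * self.dz

    @property
    def r_max(self) -> float:
        return self.nr * self.dr

    def cell_volume(self) -> np.ndarray:
        """Volume 2*pi*r*dr*dz of each cell, shape (nr, 1) for broadcasting."""
        return (2.0 * np.pi * self.r * self.dr * self.dz)[:, None]

    def zeros(self) -> np.ndarray:
        return np.zeros((self.nr, self.nz))

    @classmethod
    def for_geometry(cls, geom, dr: float, dz: float, ng: int = 3) -> "AxiGrid":
        """Grid covering a conduit: [0, max radius] x [z_min, z_max].

        nr is rounded so the largest radius falls on a cell face whenever it is
        an integer multiple of dr (walls of constant segments then align with
        faces and the staircase error vanishes there).
        """
        rmax = max(max(s.R_start, s.R_end) for s in geom.segments)
        nr = int(round(rmax / dr)) if abs(round(rmax / dr) * dr - rmax) < 1e-12 * max(rmax, dr) else int(np.ceil(rmax / dr))
        nz = int(round((geom.z_max - geom.z_min) / dz))
        if abs(geom.z_min + nz * dz - geom.z_max) > 1e-9 * (geom.z_max - geom.z_min):
            raise ValueError("dz does not evenly divide the axial extent")
        return cls(nr=nr, nz=nz, dr=dr, dz=dz, z_min=geom.z_min, ng=ng)
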