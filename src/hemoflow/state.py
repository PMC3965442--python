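"""Conservative flow state on an axisymmetric grid."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import AxiGrid

__all__ = ["FlowState"]


@dataclass
class FlowState:
    """Density, momentum and conservative linear-damage fields.

    All arrays have shape ``(grid.nr, grid.nz)`` and are cell-centered.
    ``rho_dl`` is the conservative linear-damage density rho * D_l; the linear
    damage itself is the auxiliary variable that grows linearly in time under
    constant shear stress (see :mod:`hemoflow.hemolysis`).
    """

    grid: AxiGrid
    mask: np.ndarray          # True on fluid cells
    rho: np.ndarray           # kg/m^3
    m_r: np.ndarray           # kg/(m^2 s)
    m_z: np.ndarray           # kg/(m^2 s)
    rho_dl: np.ndarray        # kg/m^3 (dimensionless damage density)
    t: float = 0.0

    @classmethod
    def rest(cls, grid: AxiGrid, mask: np.ndarray, rho0: float) -> "FlowState":
        rho = np.full((grid.nr, grid.nz), rho0)
        z = grid.zeros()
        return cls(grid=grid, mask=mask.copy(), rho=rho, m_r=z.copy(),
                   m_z=z.copy(), rho_dl=z.copy(), t=0.0)

    @property
    def v_r(self) -> np.ndarray:
        return np.where(self.mask, self.m_r / self.rho, 0.0)

    @property
    def v_z(self) -> np.ndarray:
        return np.where(self.mask, self.m_z / self.rho, 0.0)

    @property
    def dl(self) -> np.ndarray:
        return np.where(self.mask, self.rho_dl / self.rho, 0.0)

    def copy(self) -> "FlowState":
        return FlowState(grid=self.grid, mask=self.mask.copy(), rho=self.rho.copy(),
                         m_r=self.m_r.copy(), m_z=self.m_z.copy(),
                         rho_dl=self.rho_dl.copy(), t=self.t)

    def validate(self) -> None:
        for name in ("rho", "m_r", "m_z", "rho_dl"):
            f = getattr(self, name)
            if not np.all(np.isfinite(f[self.mask])):
                ij = np.argwhere(~np.isfinite(f) & self.mask)[0]
                raise FloatingPointError(f"non-finite {name} at cell {tuple(ij)}")
        if np.any(self.rho[self.mask] <= 0):
            raise FloatingPointError("non-positive density on a fluid cell")
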