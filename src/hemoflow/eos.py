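"""Cole (Tait) barotropic equation of state for slightly compressible blood.

p(rho) = p0 + (rho0 c0^2 / gamma) [ (rho/rho0)^gamma - 1 ].

c0 is the sound speed at the reference state.  A *reduced* sound speed (far
below the physical ~1500 m/s) is used by default: it keeps the explicit time
step affordable while leaving density fluctuations of order Ma^2, small
enough not to alter the incompressible-limit solution.  The solver's
reduced-sound-speed invariance test guards this choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EOSParams", "eos_pressure", "eos_density", "sound_speed"]


@dataclass(frozen=True)
class EOSParams:
    p0: float = 0.0          # Pa, reference (gauge) pressure
    rho0: float = 1056.0     # kg/m^3
    c0: float = 10.0         # m/s, reduced sound speed at the reference state
    gamma_ad: float = 7.0    # adiabatic index (Cole's classic value)

    def __post_init__(self) -> None:
        if self.rho0 <= 0 or self.c0 <= 0 or self.gamma_ad < 1:
            raise ValueError("require rho0 > 0, c0 > 0, gamma_ad >= 1")


def eos_pressure(rho, eos: EOSParams):
    """p(rho); exact algebraic relation, dp/drho(rho0) = c0^2."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("density must be positive")
    out = eos.p0 + eos.rho0 * eos.c0**2 / eos.gamma_ad * (
        (rho / eos.rho0) ** eos.gamma_ad - 1.0)
    return float(out) if out.ndim == 0 else out


def eos_density(p, eos: EOSParams):
    """Exact inverse of :func:`eos_pressure`."""
    p = np.asarray(p, dtype=float)
    base = 1.0 + eos.gamma_ad * (p - eos.p0) / (eos.rho0 * eos.c0**2)
    if np.any(base <= 0):
        raise ValueError("pressure outside the EOS range")
    out = eos.rho0 * base ** (1.0 / eos.gamma_ad)
    return float(out) if out.ndim == 0 else out


def sound_speed(rho, eos: EOSParams):
    """c(rho) = sqrt(dp/drho) = c0 (rho/rho0)^((gamma-1)/2)."""
    rho = np.asarray(rho, dtype=float)
    out = eos.c0 * (rho / eos.rho0) ** ((eos.gamma_ad - 1.0) / 2.0)
    return float(out) if out.ndim == 0 else out
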