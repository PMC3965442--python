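"""Blood rheology: effective shear rate and viscosity models.

Three viscosity laws are supported:

* Newtonian: constant mu.
* Carreau-Yasuda (CY): shear-thinning law
  mu(g) = mu_inf + (mu0 - mu_inf) * [1 + (lambda*g)^a]^((n-1)/a),
  interpolating between the zero-shear viscosity mu0 and the infinite-shear
  viscosity mu_inf.
* Casson: yield-stress-like apparent viscosity
  mu(g) = (sqrt(k_tau / g) + sqrt(k_mu))^2,
  divergent as g -> 0 and therefore clamped below a low-shear cutoff
  gamma_cutoff (mu is held at its cutoff value for g < gamma_cutoff).

The effective shear rate is the invariant gamma_eff = sqrt(2 S:S) of the
symmetric strain-rate tensor S = (grad v + grad v^T) / 2, normalized so that
unidirectional shear v_z(r) gives exactly |dv_z/dr|.  This is the only
normalization consistent with both the Poiseuille-based analytic hemolysis
bound and the shear-stress magnitude tau = mu * gamma_eff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "RheologyParams",
    "ShearField",
    "shear_rate_tensor",
    "effective_shear_rate",
    "viscosity",
    "viscosity_field",
]

_MODELS = ("newtonian", "carreau_yasuda", "casson")


@dataclass(frozen=True)
class RheologyParams:
    """Tagged union of the three viscosity-model parameter sets (SI units)."""

    model: str
    # newtonian
    mu: float = 0.0035  # Pa s
    # carreau_yasuda
    mu0: float = 0.16       # Pa s, zero-shear viscosity
    mu_inf: float = 0.0035  # Pa s, infinite-shear viscosity
    lam: float = 8.2        # s, relaxation time
    a_cy: float = 0.64      # transition sharpness
    n_cy: float = 0.2128    # power-law index (< 1: shear thinning)
    # casson
    k_tau: float = 0.0105       # Pa, yield-stress-like coefficient
    k_mu: float = 0.0035        # Pa s, plastic-viscosity-like coefficient
    gamma_cutoff: float = 0.1   # 1/s, low-shear clamp

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown rheology model {self.model!r}")
        if self.model == "newtonian" and self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.model == "carreau_yasuda":
            if not (self.mu0 > self.mu_inf > 0):
                raise ValueError("require mu0 > mu_inf > 0")
            if self.lam <= 0 or self.a_cy <= 0 or self.n_cy >= 1:
                raise ValueError("require lambda > 0, a > 0, n < 1")
        if self.model == "casson":
            if self.k_tau < 0 or self.k_mu <= 0 or self.gamma_cutoff <= 0:
                raise ValueError("require k_tau >= 0, k_mu > 0, gamma_cutoff > 0")

    @property
    def mu_max(self) -> float:
        """Largest viscosity the model can return (used for the viscous CFL)."""
        if self.model == "newtonian":
            return self.mu
        if self.model == "carreau_yasuda":
            return self.mu0
        return float(viscosity(self, self.gamma_cutoff))


@dataclass
class ShearField:
    """Strain-rate tensor components and effective shear rate on a grid."""

    s_rr: np.ndarray
    s_rz: np.ndarray
    s_zz: np.ndarray
    s_tt: np.ndarray  # hoop component v_r / r
    gamma_eff: Optional[np.ndarray] = None


def shear_rate_tensor(v_r: np.ndarray, v_z: np.ndarray, dr: float, dz: float,
                      mask: Optional[np.ndarray] = None) -> ShearField:
    """Symmetric strain-rate components in axisymmetric cylindrical coordinates.

    Centered differences in the interior, one-sided at the array edges; across
    wall (masked) neighbors the velocity is mirrored (-v), which places the
    no-slip zero on the cell face.  On the axis side, v_r is odd and v_z even
    under reflection.  The hoop component v_r/r needs no regularization because
    cell centers never sit at r = 0; its axis limit dv_r/dr is recovered as the
    grid refines.
    """
    nr, nz = v_z.shape
    r = (np.arange(nr) + 0.5) * dr

    if mask is None:
        fluid = np.ones_like(v_z, dtype=bool)
    else:
        fluid = mask.astype(bool)

    # pad with one ring of reflected values: axis (r<0) reflection below row 0,
    # zero-gradient at the other edges, then mirror across solid neighbors
    def padded(f: np.ndarray, odd_axis: bool) -> np.ndarray:
        p = np.empty((nr + 2, nz + 2))
        p[1:-1, 1:-1] = f
        p[0, 1:-1] = (-f[0] if odd_axis else f[0])
        p[-1, 1:-1] = f[-1]
        p[:, 0] = p[:, 1]
        p[:, -1] = p[:, -2]
        return p

    pr = padded(v_r, odd_axis=True)
    pz = padded(v_z, odd_axis=False)
    pf = np.zeros((nr + 2, nz + 2), dtype=bool)
    pf[1:-1, 1:-1] = fluid
    pf[0, 1:-1] = fluid[0]   # axis ghost is fluid wherever row 0 is
    # with an explicit mask the domain top is a wall (mirror); without one
    # the field is treated as unbounded (zero-gradient)
    pf[-1, 1:-1] = mask is None
    pf[:, 0] = pf[:, 1]
    pf[:, -1] = pf[:, -2]

    def deriv(p: np.ndarray, axis: int, h: float) -> np.ndarray:
        c = p[1:-1, 1:-1]
        if axis == 0:
            lo, hi = p[:-2, 1:-1], p[2:, 1:-1]
            flo, fhi = pf[:-2, 1:-1], pf[2:, 1:-1]
        else:
            lo, hi = p[1:-1, :-2], p[1:-1, 2:]
            flo, fhi = pf[1:-1, :-2], pf[1:-1, 2:]
        # mirror solid neighbors: value -> -center (no-slip on the face)
        lo = np.where(flo, lo, -c)
        hi = np.where(fhi, hi, -c)
        return (hi - lo) / (2.0 * h)

    s_rr = deriv(pr, 0, dr)
    s_zz = deriv(pz, 1, dz)
    s_rz = 0.5 * (deriv(pr, 1, dz) + deriv(pz, 0, dr))
    s_tt = v_r / r[:, None]

    for comp in (s_rr, s_zz, s_rz):
        comp[~fluid] = 0.0
    s_tt = np.where(fluid, s_tt, 0.0)
    return ShearField(s_rr=s_rr, s_rz=s_rz, s_zz=s_zz, s_tt=s_tt)


def effective_shear_rate(shear: ShearField) -> np.ndarray:
    """gamma_eff = sqrt(2 S:S); reduces to |dv_z/dr| for simple shear."""
    g = np.sqrt(2.0 * (shear.s_rr**2 + shear.s_zz**2 + shear.s_tt**2
                       + 2.0 * shear.s_rz**2))
    shear.gamma_eff = g
    return g


def viscosity(params: RheologyParams, gamma_eff):
    """Dynamic viscosity mu(gamma_eff) in Pa s for the configured model."""
    g = np.asarray(gamma_eff, dtype=float)
    if np.any(g < 0):
        raise ValueError("effective shear rate must be non-negative")
    if params.model == "newtonian":
        out = np.full_like(g, params.mu)
    elif params.model == "carreau_yasuda":
        lg = params.lam * g
        out = params.mu_inf + (params.mu0 - params.mu_inf) * (
            1.0 + lg**params.a_cy) ** ((params.n_cy - 1.0) / params.a_cy)
    else:  # casson, clamped below the cutoff
        gc = np.maximum(g, params.gamma_cutoff)
        out = (np.sqrt(params.k_tau / gc) + np.sqrt(params.k_mu)) ** 2
    return float(out) if np.ndim(gamma_eff) == 0 else out


def viscosity_field(params: RheologyParams, shear: ShearField) -> np.ndarray:
    """Pointwise viscosity over the effective-shear-rate field."""
    g = shear.gamma_eff if shear.gamma_eff is not None else effective_shear_rate(shear)
    return viscosity(params, g)
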