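"""Independent brute-force oracles used by the tests.

These never call the closed-form implementations they are checking.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad

from hemoflow.geometry import NozzleGeometry
from hemoflow.hemolysis import HemolysisCoefficients


def lagrangian_poiseuille_damage(geom: NozzleGeometry, mu: float, Q: float,
                                 coeff: HemolysisCoefficients) -> float:
    """Flow-averaged damage assuming a Poiseuille profile at every z.

    Direct nested quadrature: for each relative radius s the linear-damage
    rate dDl/dt = C^(1/a) tau^(b/a) is integrated in z via dt = dz / v_z with
    tau(s, z) = 4 mu Q s / (pi R^3) and v_z = 2 Q (1 - s^2) / (pi R^2);
    the un-linearized damage Dl^a is then flow-weight averaged over s with
    weight dF = 4 s (1 - s^2) ds.
    """
    a, b, C = coeff.a_h, coeff.b_h, coeff.C
    pref = C ** (1.0 / a) * (4.0 * mu * Q / np.pi) ** (b / a) * np.pi / (2.0 * Q)

    Iz = 0.0
    for seg in geom.segments:
        f = lambda z: float(seg.radius(z)) ** (2.0 - 3.0 * b / a)
        val, _ = quad(f, seg.z_start, seg.z_end, epsrel=1e-13, limit=200)
        Iz += val

    def dl_of_s(s: float) -> float:
        return pref * s ** (b / a) / (1.0 - s * s) * Iz

    # the s-integrand ~ (1-s^2)^(1-a) has an endpoint kink; substituting
    # 1 - s^2 = x^(1/(2-a)) makes it smooth for the quadrature
    p = 1.0 / (2.0 - a)

    def integrand(x: float) -> float:
        if x <= 0.0:
            return 0.0
        u = x**p
        s = np.sqrt(max(1.0 - u, 1e-300))
        return 2.0 * p * dl_of_s(s) ** a * u * x ** (p - 1.0)

    val, _ = quad(integrand, 0.0, 1.0, epsrel=1e-11, limit=400)
    return val


def damage_piecewise_constant(taus, durations, coeff: HemolysisCoefficients,
                              n_sub: int = 20_000) -> float:
    """Fine-step explicit integration of the linear-damage rate over a
    piecewise-constant stress history, then un-linearized.  Time steps are
    aligned with the history edges so no interval straddles a stress jump."""
    dl = 0.0
    for tau, dur in zip(taus, durations):
        dt = dur / n_sub
        for _ in range(n_sub):
            dl += coeff.C ** (1.0 / coeff.a_h) * tau ** (coeff.b_h / coeff.a_h) * dt
    return dl ** coeff.a_h
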