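# Methods

`hemoflow` simulates laminar blood flow through axisymmetric conduits and
derives blood-damage (hemolysis) indicators from the solution.  This note
documents the models, the numerical choices, the defaults and their
rationale, and what the verification suite does and does not demonstrate.

## Flow model

The fluid is slightly compressible: continuity and momentum equations for
density rho and momentum density m = rho v, closed by the Cole (Tait)
barotropic equation of state

    p(rho) = p0 + (rho0 c0^2 / gamma) [ (rho/rho0)^gamma - 1 ],

with gamma = 7 (Cole's classic value for liquids) and reference pressure
p0 = 0 (gauge; only pressure gradients act on the flow).  Treating blood as
weakly compressible sidesteps the elliptic pressure solve of incompressible
formulations: pressure is an algebraic function of the evolved density.

The price is an acoustic time-step limit.  The physical sound speed
(~1500 m/s) is computationally prohibitive for an explicit scheme, so the
default is a *reduced* sound speed c0 = 10 m/s.  At the benchmark's peak
velocity (~0.83 m/s) this gives Mach < 0.1 and relative density fluctuations
of order Ma^2 (a few 1e-3), small enough that the incompressible-limit
solution is recovered.  The suite checks this directly: doubling c0 changes
the steady velocity field by well under 1% in L2.

Viscous stress is tau = mu (grad v + grad v^T) with spatially varying mu;
the bulk-viscosity contribution is neglected (div v is of acoustic order
only).  Axisymmetry without swirl reduces the problem to (r, z).

## Rheology

Three viscosity laws, selected per run:

* Newtonian: mu = 3.5 mPa s (equal to the Carreau-Yasuda infinite-shear
  value, so "Newtonian" means "high-shear asymptote").
* Carreau-Yasuda: mu = mu_inf + (mu0 - mu_inf)[1 + (lambda g)^a]^((n-1)/a)
  with the Abraham et al. blood calibration mu0 = 0.16 Pa s,
  mu_inf = 3.5 mPa s, lambda = 8.2 s, a = 0.64, n = 0.2128.
* Casson: mu = (sqrt(k_tau/g) + sqrt(k_mu))^2, a yield-stress-like law that
  diverges as g -> 0; below gamma_cutoff the viscosity is clamped at its
  cutoff value.  Defaults k_tau = 0.0105 Pa (a Perktold-type yield stress),
  k_mu = 3.5 mPa s (so the high-shear limit matches the other two models),
  gamma_cutoff = 0.1 1/s (the clamped plateau, ~0.15 Pa s, is then
  comparable to the Carreau-Yasuda zero-shear viscosity).  With these
  defaults the low-shear ordering Casson >= Carreau-Yasuda >= Newtonian
  holds at the cutoff, which is the regime that matters in recirculation
  zones.

The effective shear rate is gamma_eff = sqrt(2 S:S), S the symmetric
strain-rate tensor including the hoop term v_r/r.  This normalization is
fixed by requiring gamma_eff = |dv_z/dr| in unidirectional shear — the only
convention under which the Poiseuille-based analytic hemolysis bound, the
shear-stress magnitude tau = mu gamma_eff, and the viscosity laws are
mutually consistent.

## Numerical scheme

Regular cell-centered (r, z) grid; the axis lies on a cell face, so radial
centers are at (i + 1/2) dr and no 1/r term is ever singular.  Conservative
finite-difference fluxes: face reconstructions of order 2, 4 or 6 (default 6
in the interior, reduced to 4 then 2 as a wall or an axial boundary enters
the stencil), plus a fourth-difference JST-type dissipation flux with
coefficient eps4 = 0.02 scaled by |v|+c on faces with a fully fluid stencil.
The flows targeted here are smooth and laminar, so a limiter-free centered
scheme with high-order background dissipation is appropriate; correctness is
established through convergence and steady-state properties (Poiseuille
recovery, conservation, grid-refinement studies) rather than through the
coefficients of any particular published scheme.  Advective flux through the
axis face is explicitly zero (nothing crosses r = 0).

Time integration is SSP-RK3 (SSP-RK2 selectable) with CFL 0.4 against the
acoustic and viscous limits.  Viscosity and the damage source are evaluated
once per step and frozen across the Runge-Kutta stages (they vary on the
flow timescale, not the acoustic one).

Walls are rasterized to a staircase: a cell is fluid iff its center is
inside R(z).  No-slip enters at flux level: across a fluid-solid face the
neighbor state is mirrored (v -> -v, zero-gradient density), which places
the zero of velocity on the face at second order; wall faces carry no
advective flux.  Sub-cell (volume-of-fluid) wall fractions are out of scope.

In/outflow use characteristic (LODI) closures for the barotropic system: at
the outflow the outgoing wave amplitude is taken one-sided from the interior
and the incoming wave relaxes pressure to the reference value with strength
sigma c0 / L (sigma = 0.25), making the boundary non-reflecting for
outgoing acoustics (verified: a pulse leaves < 5% residual).  At the inflow
the axial mass flux is imposed as rho0 times the Poiseuille profile with
v_max = 2Q/(pi R_in^2) — prescribing the flux rather than the velocity makes
the injected flow rate exactly the theoretical rho0 Q even though the inlet
density is slightly compressed (by dp/(rho c^2), a few 1e-3 at the reduced
sound speed).  The profile is ramped smoothly over ramp_time (default 20 ms)
to suppress start-up transients, while density evolves from the outgoing
characteristic.  Steadiness is declared when the windowed (100-step)
max-norm change of the momentum fields drops below steady_tol (default
1e-8; verification runs use 1e-6 to 1e-7 together with a physical-time
horizon, and report the residual reached).

## Hemolysis

The constant-exposure damage law D = C tau^b t^a (fraction of hemoglobin
released) uses the Giersiepen coefficient set C = 3.62e-7, a = 0.785,
b = 2.416 (tau in Pa, t in s), with hematocrit Hct = 0.45 and hemoglobin
content Hb = 150 g/L; NIH (g/100 L) = 100 (1 - Hct) Hb D.  Because a < 1,
the law is integrated through the linear damage D_l = D^(1/a) with rate
dD_l/dt = C^(1/a) tau^(b/a); D_l is un-linearized *before* any averaging
(averaging D_l first overestimates by Jensen's inequality; the package
quantifies that error explicitly).

Four routes are implemented and cross-checked:

1. **Pathline**: adaptive RK integration of dx/dt = v with D_l as an extra
   ODE component; 64 seeds by default at equal-flow-increment inlet radii
   (equal weights Q/n); trajectories that fail to reach the outlet within
   50 mean transit times (recirculating particles) are flagged and excluded
   from averages — in a steady 2D recirculation they would never exit, and
   their flow weight is correspondingly not transported.
2. **Eulerian**: the conservative field rho D_l advected with the flow with
   source rho C^(1/a) tau^(b/a).  The steady damage field is obtained by a
   frozen-velocity pseudo-time march of the same transport equation after
   the flow has converged (the steady transport solution is identical to
   co-evolution, which remains available, at a fraction of the cost because
   the march is advective- rather than acoustic-CFL limited).  The default
   horizon is 6 mean transit times.  NIH(z) uses the signed axial mass-flux
   weight, i.e. the damage transported downstream through each cut.
3. **Analytic lower bound** (Newtonian): assuming a Poiseuille profile at
   every z, the flow-averaged damage reduces to
   <D> = 2 C (4 mu Q/pi)^b (pi I/(2Q))^a B(b/2+1, 2-a) with
   I = int R(z)^(2-3b/a) dz.  The implementation works in SI units
   throughout; `geometry_integral` offers a mm convention for comparison
   with literature constants quoted in mm.  The closed form is pinned by an
   independent nested-quadrature oracle (agreement to 1e-6 on straight,
   stepped, conical and nozzle geometries).  Real flows have entrance
   regions, jets and recirculation that only add exposure, hence "lower
   bound".
4. **Time-explicit variant**: dD/dt = C a t^(a-1) tau^b along pathlines.
   Exact for constant stress from t = 0, but origin-dependent: shifting the
   time origin earlier strictly decreases the result (t^(a-1) decays), which
   is the documented criticism of this route.

## Indicators

Mass flow rate m_dot(z) is the transverse integral of rho v_z.  The default
quadrature integrates a not-a-knot cubic spline through the cell-center
values of r rho v_z up to the outermost fluid face: the plain midpoint rule
(also available) carries a -(dr/R)^2/3 relative bias on parabolic profiles,
which at an 8-cell throat masquerades as a spurious 0.5% "mass loss".
Centerline values are the first cell row adjacent to the axis.  WSS(z)
samples the shear-stress magnitude two grid cells radially inside the
outermost fluid cell (configurable offset) — a deliberate rule that
suppresses the staircase noise of inclined walls at the cost of a known
inward-offset bias that vanishes under refinement.  The simplified Bernoulli
estimate is dp = rho v_peak^2 / 2 from the peak velocity.

## Verification problem sizes

All solver-based checks run scaled-down configurations chosen so the whole
suite completes on one CPU in well under half an hour; they exercise the
same physics as production runs:

* Straight tube (R = 2 mm, L = 30 mm, Re = 120, 12 radial cells): Poiseuille
  recovery, Hagen-Poiseuille pressure slope, pathline-vs-Eulerian agreement.
* Benchmark nozzle at Re_throat = 500, dr = 0.25 mm / dz = 0.75 mm with
  12 mm inlet and 32 mm outlet pipes, 0.9 s of physical time from a local
  Poiseuille initial guess: Newtonian-vs-Carreau-Yasuda comparisons,
  hemolysis ordering, pressure indicators.
* Finer Newtonian nozzle, dr = 0.125 mm / dz = 0.375 mm with shortened
  pipes: mass-conservation metric and WSS-peak location, both
  resolution-sensitive.
* Half-scale collector+throat geometry at Re = 200 and resolution ratios
  1:2:4: grid-convergence of mass error, WSS and NIH.

What passing these tests shows: the discretization converges on smooth
laminar axisymmetric flows, conserves mass, recovers analytic solutions,
and the four hemolysis routes are mutually consistent.  What they do not
show: behavior in transitional or turbulent regimes (throat Re >= 2000),
3D or azimuthally unstable flow, deformable walls, or agreement with any
particular experimental dataset — the synthetic fixtures contain no
measurement noise and the staircase wall is a first-order geometry
representation.

## Known limitations

* The max-norm mass-flow error over every grid column is dominated by
  single-column artifacts at staircase steps in the conical collector; it
  converges slowly (sub-first-order in the max norm) and at the scaled
  resolutions used here remains around 0.7%, a factor ~1.5 above what
  production-resolution runs of this benchmark report.  Away from step
  columns the cone-region error is 0.4-0.6% and the straight sections sit
  well below 0.1%.  Volume-of-fluid wall fractions would remove most of
  this and are deliberately out of scope.
* The WSS entrance spike at the cone-throat transition requires the
  entrance boundary layer (~0.1 mm) to be resolved; at dr = 0.25 mm the
  sampled WSS peaks at the throat end instead, and only from dr = 0.125 mm
  does the maximum land near the transition.
* Recirculating fluid accumulates damage indefinitely in an ideal steady 2D
  flow; the Eulerian route's finite transport horizon and the pathline
  route's transit cutoff both regularize this, and the two routes are
  compared only through flux-weighted (transported) averages.
* The Casson cutoff value and the blood-composition constants are package
  defaults chosen from standard literature values; both are configurable.
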