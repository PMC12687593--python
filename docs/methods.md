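# Methods

`vwfsim` simulates the shear-regulated aggregation of von Willebrand factor
(VWF) polymers with platelet-like colloids.  This note documents the model,
its parameters, the numerical scheme, and — importantly — what the
desk-scale protocols do and do not show about the full microvascular
problem.

## Reduced units

All internal quantities are expressed in reduced units: length in the
effective red-blood-cell diameter `Dr = sqrt(Ar/pi)` (≈ 6.50 μm for the
membrane area `Ar = 132.83 μm²`), energy in `kBT` at 310 K
(≈ 4.28·10⁻²¹ J), and time in the viscous-elastic scale
`tau = eta·Dr/mu_r` built from the plasma viscosity
(1.2·10⁻³ Pa·s) and the RBC membrane shear modulus (4.83·10⁻⁶ N/m),
`tau ≈ 1.62 ms`.  A shear rate of 2,000 s⁻¹ is 3.23/τ.  The
`UnitSystem` class performs all conversions and carries the bookkeeping of
the underlying mesoscale fluid parameterization (fluid viscosity 100,
`kBT = 0.1` in native units) needed to reproduce printed setup numbers such
as the wall shear rate `f·n·Ly/(2η) ≈ 1,152 s⁻¹` and the
4.8·10⁵-particle fluid budget of the full 80×40×30 μm³ channel.

## VWF chain

Each VWF is a bead-spring chain of `Nm = 30` monomers of diameter
`σ = 0.077 Dr` (≈ 0.5 μm).  Consecutive beads interact through FENE
springs, `U(r) = -(ks/2) rmax² ln(1-(r/rmax)²)` with `ks = 25,000 kBT/σ²`
and `rmax = 2σ` (nearly inextensible), and *all* bead pairs of the same
chain additionally through a full 12-6 Lennard-Jones potential with
`ε = 16 kBT`, cut at `2.5σ`.  The strong self-attraction keeps a quiescent
chain collapsed in a globule; shear unfolds it by the protrusion mechanism
(a bead fluctuating out of the globule is dragged downstream by the local
velocity difference).  The combined FENE + LJ backbone bond has its
minimum near `0.77σ` with a curvature of ≈ 7·10⁷ kBT/Dr², the stiffest
deterministic mode in the system; the integrator timestep is set from it
(below).

Monomer *activation* is purely geometric and recomputed from the current
configuration every step: a monomer is binding-competent iff (i) the angle
between its two backbone bonds is ≥ 150° (180° = straight), with the first,
second, penultimate and last monomers exempt because the angle test is
defined only for strictly interior beads, and (ii) no same-chain,
non-bonded monomer (|i-j| > 1) lies within `1.2σ`.  Collapsed chains are
therefore inert, stretched segments adhesive.  Losing activation blocks
*new* bond formation but does not sever an existing bond — rupture stays
governed by the off-rate law; this choice makes deactivation-upon-collapse
the pathway by which quenched aggregates stop re-binding, while bond
breakage itself always flows through `koff`.

## Platelets

Platelets are rigid oblate colloids (diameter 2 μm, aspect ratio 0.3)
whose surface is sampled by `Nv = 60` receptor vertices — the vertices of a
truncated icosahedron (the edge-trisection points of the icosahedron)
projected to the unit sphere and scaled onto the spheroid.  The convex-hull
surface area of the template is within a few percent of the reference
0.162 Dr² (6.85 μm²).  Rigidity replaces the stiff elastic membrane of the
source model: platelets there are deliberately made nearly undeformable, so
the limit is taken exactly.  Pose is a center of mass plus a unit
quaternion; the template never deforms.

## Adhesion kinetics

Bonds form between *active* monomers and platelet vertices.  Each site
holds at most one bond.  Formation: constant rate `kon = 5,760/τ` within
the capture radius `rcut_on = 0.068 Dr`; rupture: the two-pathway
(catch + slip) law

    koff(r) = kc0 exp(λc (r−xeq) δc / kBT) + ks0 exp(λs (r−xeq) δs / kBT),

with `δc = xc−xeq ≤ 0`, `δs = xs−xeq ≥ 0`, `λc = λs = 1.06·10⁵ kBT/Dr²`.
λ is quoted in kBT-based units, so the exponents are dimensionless with
kBT = 1 in reduced units and no additional thermal factor appears.  A bond
stretched past `xeq` suppresses the catch pathway and amplifies the slip
pathway; for the catch-slip presets the lifetime `1/koff` has an interior
maximum between `xeq` and `xs` (for M1 at r ≈ 0.0648 Dr, about 190× the
rest lifetime).  Five presets are bundled: catch-slip M1/M2/M3, pure slip
(`kc0 = 0`), and a fixed rate (`δc = 0`, `ks0 = 0`).  The formed bond is a
harmonic spring `U = kb (r−r0)²` (no ½ prefactor) with
`kb = 8.45·10⁶ kBT/Dr²`, `r0 = 0.062 Dr`; any bond beyond
`rcut_off = 0.23 Dr` ruptures deterministically.

Both rate equations are integrated per timestep as independent Bernoulli
trials with `p = 1 − exp(−k·Δt)`, exact for a rate held constant over the
step; `koff` is evaluated at the start-of-step length (explicit scheme) and
its exponents are clamped at ±60, beyond which rupture is certain for any
Δt of interest.  Association candidates are processed in a freshly
shuffled order each step with first-come-first-served occupancy, so
conflicts resolve reproducibly under a fixed seed.

## Dynamics

The suspending fluid is **not** solved.  Bodies undergo free-draining
overdamped Brownian dynamics in a *prescribed* flow `u_x(y)` (Couette,
Poiseuille or quiescent; periodic in x and z, walls at y = 0, Ly):

    dx = u(x) dt + (F/ζ) dt + sqrt(2 kBT dt / ζ) N(0,1).

Platelets translate under the summed vertex forces with an isotropic drag
`6πηR_eff` (`R_eff` from the volume-equivalent sphere of the template,
≈ 0.64 μm) and rotate with half the local vorticity plus torque over
`8πηR_eff³`, with matching rotational noise.  Per step the sub-operations
run in a fixed order: move → activation update → dissociations →
associations.

The bead drag is Stokes drag on the bead diameter times a single
dimensionless calibration multiplier, the one free parameter of the fluid
coupling.  It was set **once**, to 0.36, by the single-chain calibration
protocol: sweeping a lone chain over shear rates {250 … 8,000} s⁻¹ and
asking that the mean fractional extension cross 0.3 at ≈ 2,000 s⁻¹, the
experimentally established stretching threshold.  All other dynamical
quantities (timestep, platelet drags) derive from it.

Free-draining prescribed flow deliberately omits hydrodynamic lift,
bead-bead hydrodynamic interactions, and the red blood cells entirely.
Consequently there is **no margination and no cross-streamline migration**:
a body keeps its wall distance up to weak Brownian drift.  Every emergent
result below must be read with that limitation in mind.

### Numerics

* Timestep: `dt = 0.3 ζ_bead / k_max` with `k_max` the stiffest mode
  (backbone FENE+LJ curvature or twice the adhesive spring constant);
  ≈ 5·10⁻⁵ τ at the default calibration.  A FENE domain violation rejects
  the remaining block, retries once at half the step, then raises.
* Deterministic per-step displacements are capped at 0.005 Dr — a
  safeguard against force spikes from transient deep overlaps, kept well
  below the backbone bond scale so that a clipped step cannot ratchet a
  FENE bond toward its divergence; it is inactive in normal operation.
* Pair interactions use a Verlet list with a 0.06 Dr skin over a linked
  cell grid with per-pair-type list ranges, rebuilt adaptively when the
  accumulated drift bound (maximum per-step displacement, advective shear
  drift across the list range, and a 3σ Brownian term) could cross half
  the skin.  An all-pairs fallback
  covers boxes below three cells per periodic dimension, and the cell
  search is verified against a brute-force oracle in the tests.
* Excluded volume: purely repulsive, shifted LJ (WCA) with per-pair
  diameters 0.077 (VWF–VWF), 0.062 (platelet–VWF), 0.046
  (platelet–platelet) Dr and ε = 16 kBT, applied between different bodies
  only; intra-chain pairs get the full attractive LJ instead.
* Walls: specular reflection at one body-radius offset (σ/2 for beads,
  R_eff for platelet centers).
* Determinism: a master generator seeded from the config drives per-block
  kernel seeds; identical configs and seeds give bit-identical
  trajectories and event logs.

## Desk-scale protocols

### Stretch sweep

Single chain, Couette flow, shear rates {250, 500, 1,000, 2,000, 4,000,
8,000} s⁻¹, three independently equilibrated globule replicates per rate,
40 τ each, fractional extension (end-to-end over `29σ`) averaged over the
final 60%.  The run reports the smallest grid rate whose seed-mean
extension exceeds 0.3 — the package's operational critical shear rate; with
the calibrated drag it is 2,000 s⁻¹.  Near the threshold the unfolding is
nucleation-limited and strongly intermittent, so per-seed scatter is large;
the 0.3 threshold and the 40 τ window are part of the operational
definition.

### Shear-quench reversibility

A suspension of 4 VWFs and 16 platelets in Couette flow: phase 1 at
4,000 s⁻¹ (twice the stretching threshold) for 20 τ, during which
activated chains glue platelets into one large aggregate (typically 10–19
of the 20 bodies); then a quench to 50 s⁻¹ for 80 τ.  Phase 1 runs at twice
rather than many times the threshold deliberately: stronger shear activates
nearly every monomer and buries each platelet under long adsorbed runs of
bonded monomers, whose rupture–rebind cycling (rebinding at kon wins any
race against escape) stalls the subsequent dissolution far beyond the
observation window.  The verdict compares
the largest-cluster size at the end of phase 2 (mean over the final 10%)
with the phase-1 peak: REVERSIBLE below 10% retention, IRREVERSIBLE at or
above 80%, AMBIGUOUS between, and a protocol-failure report if no
aggregate (≥3 bodies) ever forms.  Clusters are connected components of
the body-level bond graph (union-find; one live bond joins two bodies).

The box is a thin slab, 16×4×6 μm³.  The thin dimension is the wall
normal: without RBCs there is no mechanism to move bodies across
streamlines, and in a cube-shaped box each chain can only ever harvest the
platelets of its own initial y-layer (aggregates cap at ~5 bodies).  The
slab emulates the RBC-free layer — the few-μm near-wall region where
marginated platelets and VWFs actually meet in the full problem — and
restores realistic encounter rates.  Body volume fractions (platelets
≈ 4.7%) are above physiological, an acceleration of the same kind the
source study uses.

Mechanistically, the quench works through deactivation: at 50 s⁻¹ the
chain segments between bound platelets collapse, freed monomers are
engulfed by the growing globule and fail both geometric criteria, so each
koff-driven rupture becomes permanent instead of re-binding within
`1/kon ≈ 10⁻⁴ τ`.  With catch-slip M1 the rest-length off-rate is
0.577/τ and the aggregate sheds all bonds within tens of τ; with the slip
model the rest-length off-rate is 5.76·10⁻⁴/τ (lifetime ≈ 1,700 τ) and the
aggregate is frozen on any feasible observation window — the
three-orders-of-magnitude lifetime separation that distinguishes reversible
from irreversible aggregation.

### What the desk scale does not show

The full-channel phenomenology — margination into the RBC-free layer,
lift-driven migration of grown aggregates to the channel center,
aggregate sizes of hundreds, and the recurrent aggregation–dissociation
cycle — requires RBC-laden Poiseuille flow at cluster scale and is out of
scope.  The quench experiment probes the same bond-model physics (the
paper's own calibration geometry: pure shear, platelets + VWFs only) at a
size that runs in minutes on one core.

## Problem sizes and runtimes

Chosen so the full test suite and the acceptance script each run on a
single core in well under half an hour: stretch sweep 6 rates × 3 seeds ×
40 τ (≈ 3 min), reversibility 100 τ per run (≈ 2–3 min each; three seeds
per bond model in the tests, one in the acceptance script), with the
compiled engine advancing the 1,080-particle slab at ≈ 50 μs per step.

## Known limitations

* No hydrodynamic interactions or lift: aggregation rates and the
  operational stretching threshold transfer to the source model only
  through the single drag calibration; quantitative aggregate-scale
  observables (asphericity distributions, lifetime time series) are
  qualitative here.
* The activation criteria keep platelet-adsorbed chain runs active
  (locally straight on the platelet surface), so the final stage of
  aggregate dissolution is rate-limited by globule engulfment of the
  adsorbed run; dissolution tails are accordingly tens of τ long.
* A fully stretched chain (≈ 14.5 μm) exceeds the 16 μm box only
  marginally, but excluded volume between a chain and its own periodic
  image is not evaluated; at the simulated densities this is a rare,
  transient configuration.
* The Bernoulli kinetics assume the bond length is constant across one
  step; with `kon·dt ≈ 0.24` the formation probability per step is ≈ 0.21
  and the discretization error on rates is second order.
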