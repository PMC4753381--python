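# Methods

## Model

The reactor chamber is the square Ω_c = (0, L)² with n_b circular beads of
diameter d = 10 µm removed; the fluid domain is Ω = Ω_c minus the beads.  The
boundary splits into the import edge Γ_i = {0}×(0, L), the export edge
Γ_e = {L}×(0, L), impermeable walls Γ_0 and the bead surfaces Γ_b.  Each
metabolite concentration y_j (mol·m⁻²; the model is two-dimensional, so
"concentration" is an areal density and boundary rates are per unit length)
diffuses with diffusivity D_j and reacts only on boundaries: bead-surface
kinetics enter as the flux condition −D∇y·ν = −R^b(y, λ) on Γ_b, export
kinetics as −D∇y·ν = −θᵉR^e(y) on Γ_e, where θᵉ ∈ [0, 1] is the homogenized
membrane permeability (fraction of the membrane occupied by transporter
pores; θᵉ enters the model as a given parameter, 0.15 by default).

In the sucrose-excess (SE) reduction, sucrose and ATP inside the chamber and
G6P/Pi outside are held at fixed bath values, the proton-coupled sucrose
import and ADP bookkeeping are dropped, and Γ_i is impermeable.  Five
unknowns remain: glucose (G), fructose (F), fructose-6-phosphate (F6P),
inorganic phosphate (Pi) and glucose-6-phosphate (G6P).

### Rate laws

Invertase is irreversible Michaelis–Menten in [S]; hexokinase is
irreversible bi–bi ordered in (hexose, ATP), instantiated once for G and
once for F; the isomerase is a reversible Michaelis–Menten difference.  The
G6P/Pi antiporter is a reversible bi–bi ping-pong exchanger with numerator
vmax_f([G6P][Pi_e] − [G6P_e][Pi]/K_eq) and denominator

    [G6P][Pi_e] + K_mPie[G6P] + K_mG6PT[Pi_e](1 + [Pi]/K_iPi)
      + (vmax_f / (vmax_b K_eq)) (K_mPi[G6P_e](1 + [G6P]/K_iG6P)
                                  + [Pi](K_mG6Pe + [G6P_e])).

The denominator is the canonical reversible ping-pong form arranged so that
every tabulated constant appears in its standard position and the rate
vanishes exactly at the exchanger's equilibrium; this resolves a
typographically incomplete printed expression without disturbing either the
equilibrium point or the constants.  All enzymatic rates are exactly linear
in their λ component, which the sensitivity equations exploit.

Maximal velocities derive from turnover numbers as vmax_i = kcat_i·[E]₀ with
[E]₀ the occupied binding-site concentration of a bead (mol·m⁻¹).  The
equal-activity stoichiometry λ^E solves kcat_i λ_i = const on the simplex,
i.e. λ_i ∝ 1/kcat_i.

### Arrangements

* **S1** — every bead fully loaded ([E]₀ = [E]_full = 1.94e-8 mol·m⁻¹);
  total enzyme grows with n_b.
* **S2** — the budget of one fully loaded bead spread over n_b beads
  (per-bead vmax divided by n_b); n_b = 0 dissolves the budget in the bulk.
* **O1/O2** — stoichiometry optimization sweeps over n_b at fixed horizon,
  respectively over the horizon for one bead.

For the bulk case the surface rates (mol·s⁻¹·m⁻¹) are converted to
volumetric rates (mol·s⁻¹·m⁻²) by the factor |Γ_b(one bead)|/|Ω| = πd/L², so
the bulk chamber has exactly the total maximal turnover of one fully loaded
bead — the fixed-budget convention of S2.

## Discretization

Lowest-order Raviart–Thomas mixed elements on conforming triangles, in
hybridized form: the unknowns per species are elementwise-constant
concentrations and single-valued facet traces; the flux is eliminated
element-locally.  The scheme is locally (elementwise) mass conservative —
the accepted-step cell balances hold to the Newton tolerance — which is the
reason for preferring mixed elements over nodal linear elements here:
boundary-driven problems on coarse meshes otherwise produce negative
concentrations.  Boundary kinetics are evaluated at the facet traces with
one-point facet quadrature, consistent with the lowest-order spaces.  A
non-hybridized mixed assembly of the linear diffusion step is kept as a
cross-check and agrees with the hybridized path to 1e-10.

Time integration is implicit Euler (the boundary-coupled system is stiff);
each step is solved by Newton with an exact sparse Jacobian and LU
factorization.  Convergence: relative residual 1e-10, with an absolute floor
set by the roundoff magnitude of the assembled terms; divergence, NaN or 25
iterations reject the step.  A step whose converged *cell* concentrations
are negative (beyond a 1e-12 relative roundoff band, which is clipped) is
rejected and retried at half the step size down to Δt_min; after five
accepted steps the size doubles back toward the base Δt (the base step is
0.25 s by default).  Facet traces are Lagrange multipliers, not cell
concentrations: they may undershoot slightly inside steep bead boundary
layers (the undershoot does not shrink with Δt), so they are only required
to stay within 1e-3 of zero, far from any kinetic singularity; mass balances
are unaffected.

Observables: the G6P outflow rate is the line integral of the normal flux
over Γ_e evaluated from the flux unknowns (identical to the kinetics form
θᵉ∫ r_G6P to solver tolerance); bead production rates are the corresponding
integrals over Γ_b.  The objective J integrates the outflow rate with the
right-endpoint rectangle rule on the accepted-step grid — the quadrature
consistent with implicit Euler; the time-to-half-rate metric interpolates
linearly between steps.

## Sensitivities and optimization

The reduced objective Ĵ(λ) is differentiated with forward (tangent)
sensitivities: for each parameter direction the linearized system (same
mesh, same accepted time grid, zero initial condition) is integrated with
one linear solve per step, reusing the converged forward Jacobian.  Because
the export kinetics do not depend on λ directly, the gradient is the time
integral of −θᵉ(∂_y R^e_G6P · ỹ) over Γ_e, with the same quadrature as J.
The tangent solve runs from the stored (checkpointed every step) forward
trajectory; an adjoint variant is unnecessary at n_p = 2 and out of scope.

λ_pgi is eliminated through the simplex condition, leaving (λ_inv, λ_hk)
with bounds [0, 1] and the inequality λ_inv + λ_hk ≤ 1.  Maximization uses
scipy's trust-constr (an interior-point-type trust-region method) with BFGS
curvature updates, xtol = tol_X = 1e-6, on the objective normalized by |J⁰|
so that tol_fun = 1e-4 acts as a relative stationarity tolerance regardless
of the absolute scale of J (desk-scale J values are ~1e-13 mol).  The start
is whichever of λ^U = (⅓, ⅓, ⅓) and λ^E has the larger J⁰ (two forward
solves).  A safeguard returns the best evaluated iterate if the final one
undercuts J⁰ beyond tol_fun.

## Meshing

No meshing library is assumed: the package carries its own mesher.
Bead-free chambers get exact structured right-triangle meshes.  Chambers
with beads are meshed by a DistMesh-style force-equilibrated Delaunay
smoother (signed-distance geometry, truss relaxation, scipy Delaunay as the
triangulation kernel) followed by exact snapping of boundary vertices onto
the chamber sides and bead circles and a sliver-repair pass.  The mesher is
deterministic: a fixed internal seed thins the initial point lattice, so
repeated builds are bitwise identical.  Default bead-surface edge length is
d/8 (≈ 25 segments per bead; inscribed-polygon perimeter within 0.3 % of
πd); at least 16 segments are required.  Generated meshes satisfy: minimum
angle ≥ 20° (typically ≥ 23°), exact tag partition of the boundary, area
within the chordal-deficit tolerance of |Ω|.  Meshes export/import as Gmsh
MSH 2.2 ASCII with tags preserved; fields write as ASCII VTU.

## Parameters and defaults

All kinetic constants ship as per-variant YAML tables (HsHK2, ScHK2) in SI
surface units taken at face value: concentrations mol·m⁻², surface rates
mol·s⁻¹·m⁻¹, K_eq with its printed concentration scale.  Initial
concentrations of the five unknowns default to zero (products start absent)
and are configurable.  **Diffusivities are not part of the published
parameter set.**  The package default is 1e-9 m²·s⁻¹, equal across species —
the order of magnitude of small metabolites in water; every scenario result
records a `used_default_diffusivity` flag, and quantitative conclusions
should set D explicitly.  Published table values that are themselves derived
(vmax = kcat·[E]_full; the equal-activity λ^E) are recomputed rather than
read: the recomputed vmax agree with the printed ones within 0.5 %
(printed-input rounding), λ^E_inv and the ScHK2 triple agree at 4 decimals,
while the printed HsHK2 λ^E_pgi = 0.0753 differs by ~2 % from the value the
equal-activity condition yields (0.0768); only the consistent components are
pinned by tests.

## Verification strategy and problem sizes

The headline result tables of the study are not exactly reproducible without
the unpublished diffusivities and meshes, so correctness rests on
properties, each exercised by the test suite at sizes chosen for a
single-CPU run:

* manufactured solution (cosine mode with exponential decay, source term
  verified symbolically) on structured meshes n = 8, 16, 32 with Δt ∝ h:
  observed L² order ≈ 0.97;
* elementwise conservation and nonnegativity on a coarse one-bead SE run;
  a saturable-sink fixture (−s·y²/(y²+K²)) forces step rejections and
  recovery;
* well-mixed limit: one-bead chamber with D × 10⁶ matches the 0-D balance
  ODE (solved with LSODA at rtol 1e-10) within 0.5 % per species at
  Δt = 0.1 s over 60 s;
* gradient consistency: tangent gradient vs central finite differences,
  relative error ~1e-7 (bound 1e-3), both hexokinases;
* optimization: an analytic concave quadratic is recovered to tol_X; on the
  scaled one-bead HsHK2 fixture J* ≥ J⁰ and λ*_pgi < 0.01 — the design
  conclusion that the isomerase, driven in reverse by accumulating G6P,
  should be eliminated;
* directional trends at the default D, L = 500 µm, T = 600 s: fixed-budget
  outflow ordering one bead > four beads > bulk, and diminishing outflow
  gain per added fully loaded bead (transporter-limited saturation).

Coarse fixtures use a one-bead chamber at L = 500 µm with ~260 triangles
(16 segments per bead, relaxed size grading) and horizons of 10–600 s with
Δt = 0.1–2 s; these sizes are a deliberate trade between runtime and the
tolerance of each property above.  The full suite runs in a few minutes.

## Known limitations

Two-dimensional geometry only; one compartment (no multichamber
transmission conditions); the full 11-species network is represented only in
the stoichiometric decoupling analysis, not in the PDE solver; the
Kräutle–Knabner decoupled solver itself is not implemented (the SE system
has full rank, so it would not reduce the work); bead positions are a fixed
centered grid; no adaptive meshing or higher-order elements; the optimizer
reports local maxima.  The synthetic scenarios emulate the study conditions
(geometry, kinetics, budgets) but not unmodeled physics of a real device —
membrane fouling, bead aggregation, temperature/pH drifts — so passing
tests validate the numerics and the model's internal conclusions, not
device-level predictions.
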