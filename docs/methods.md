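# Methods

## Model

The package simulates one well of an impedance-based transwell
migration assay as a 1D two-chamber advection–reaction–diffusion
system. The reduction to 1D assumes radial symmetry of the cylindrical
well and of the seeding; the impedance readout integrates over the
electrode plane, so only the axial distribution matters for the
observable. The two fields are the cell line density u(x,t)
(cell·cm⁻¹) and the chemoattractant (FBS) density φ(x,t) (µl·cm⁻¹);
both are treated as continua, justified by the 10⁴–10⁵ cells and the
macroscopic serum amounts involved.

Mechanisms, term by term:

* **Cell diffusion** with constant D_u — unbiased motility in the
  medium.
* **Chemotaxis** up the FBS gradient with saturating sensitivity
  χ(φ) = χ₁φ/(χ₂+φ); χ₂ is the half-saturation density. At the serum
  loads used in the assay (≈18 µl·cm⁻¹ against χ₂ ≈ 5×10⁻⁸) the
  response is fully saturated, so χ₂ is expected (and confirmed by the
  sensitivity analysis) to be almost uninfluential.
* **Spontaneous transport** at constant velocity V_transp directed
  top→bottom — the basal migration through the membrane pores observed
  without any chemoattractant.
* **Adhesion/spreading** g = α₁u(1−u/α₃)·[φ/(α₂+φ)]·[(α₂+φ̄)/φ̄]·W(x):
  the impedance signal grows not only with migrated cell number but
  with adhesion and spreading on the sensor; over a 12 h window
  (≈ the shortest doubling time) this is modelled as logistic growth of
  the effective density, active only near/below the membrane through
  the smooth ramp W (0 above x̄ = x_M − x_bar_offset, 1 below the
  membrane, a C∞ bump-function ramp in between). The serum factor is
  normalised to 1 at the proliferation-assay serum level φ̄, so the
  proliferation fit yields α₁ directly.
* **FBS binding** −δuφ — consumption/internalisation of chemotactic
  agents by cells; enzymatic degradation is neglected on this time
  scale.
* **Membrane (Kedem–Katchalsky)**: the flux of each species through the
  membrane is proportional to the jump of its one-sided traces. For
  FBS the transmission k_φ is constant; for cells
  k_u = k_u1/(1 + k_u2·u_T + k_u3·N_B^p) decreases with crowding on the
  upper membrane face (u_T) and with the cell number already in the
  lower chamber (N_B), with p = 2 by default.
* **Lids**: zero total flux (nothing enters or leaves the well).

Initial data: u = u0 on an interval Ω_u of the upper chamber, φ = φ0 on
the whole lower chamber (φ0 = 0 for basal runs). Where the support of
Ω_u is not dictated by the caller, the package places the slab of
length n_total/u0 immediately **above the membrane** (cells sediment
onto it after seeding); this placement is a package choice and is
configurable through `InitialConditions`. The discrete initial field
is rescaled so its trapezoid integral equals the seeded count exactly,
so conservation statements refer to the true cell number. The
x_bar_offset default of 4×10⁻³ cm represents two ≈20 µm cell diameters.
The 60-minute pre-equilibration of the media before seeding is not
modelled.

Parameter presets for the three cell lines (Sarc, HT1080, A375) carry
the calibrated constants of the assay (units in the `ModelParameters`
docstring); the seeding densities u0 are keyed by cells/well
(2–4×10⁴).

## Discretisation

Mesh: coarse spacing Δx (default 10⁻² cm) away from the membrane,
refined to Δx_f (default 10⁻⁶ cm) inside [x_M − Δx, x_M + Δx]. The
membrane node is **duplicated**: the two trace nodes at x_M carry the
one-sided limits u_T/φ_T and u_B/φ_B, which are genuinely discontinuous
across a Kedem–Katchalsky interface. The refinement is what keeps the
solution non-negative near the interface at practical time steps.

Time stepping (default Δt = 10⁻³ h, the largest step that keeps the
default runs stable and non-negative):

* φ: central second differences, implicit in time; the binding term
  −δuφ explicit at the previous level.
* u: implicit central diffusion; explicit centred advection with a
  Rusanov-type artificial viscosity (|V|-weighted second difference) —
  on a uniform mesh the pair is algebraically first-order upwinding;
  explicit adhesion/spreading source. The advective velocity
  V = χ(φ)∂xφ + V_transp uses centred gradients per chamber (one-sided
  at chamber ends, second order, via `numpy.gradient`).
* Ordering within a step: φ first, then u, both reading the level-k
  cross-couplings (u's velocities and the interface coefficients are
  evaluated at the pre-update φ).
* Membrane rows are assembled **into the implicit solve** with the
  chemotactic coefficient and k_u frozen at the previous level; the
  interface gradient of φ in the cell flux is eliminated through the
  FBS membrane condition (∂xφ = k_φ(φ_B−φ_T)/D_φ). Freezing the
  nonlinear coefficients keeps the per-step systems linear and banded
  while avoiding an O(Δt) operator-splitting error at the interface.
* At the coarse/fine junction the standard three-point stencils on
  non-uniform spacing are used (locally first order, immaterial at the
  junction's resolution). All interface prefactors use the local fine
  spacing.
* Each linear system is pentadiagonal and solved with LAPACK's banded
  solver (`scipy.linalg.solve_banded`); only the two membrane rows of
  the u system change between steps.

**Conservation and closures.** Interior rows are assembled in
volume-scaled flux form: each face carries one conductance Δt·D/h and
one explicit advective/viscous flux value shared with opposite signs by
the two adjacent rows, so the trapezoid mass telescopes exactly — in
floating point, not just analytically — down to the four closure rows
(two lids, two traces). Two closures are provided:

* `conservative` (default): half-cell finite-volume balances of the
  zero-flux lid conditions and of the membrane jump fluxes. Total cell
  mass is conserved to banded-LU round-off when α₁ = 0 (measured
  ≈ 4×10⁻⁸ relative over the 12 h default-mesh run), and total FBS
  likewise for δ = 0 (≈ 2×10⁻⁸ at the default mesh, where the
  fine-zone operator has condition ≈ 4×10⁹; exactly machine-level on
  coarser meshes).
* `one_sided`: algebraic rows with second-order one-sided difference
  stencils for the lid and trace derivatives. Formally second-order
  but not discretely conservative (the lid closures leak mass at
  O(Δx²), ≈10⁻⁴ relative over 12 h at the default mesh) and prone to a
  small extrapolation undershoot at the lids on coarse meshes. Both
  closures agree on the migrated-cell observable to well under a
  percent; the conservative closure is the default because exact
  discrete conservation is the stronger correctness invariant.

**Non-negativity policy.** After each solve the fields are checked; a
value below −10⁻¹²·max(field) aborts with `StabilityError` (no
clipping): a genuinely negative density means the chosen Δt/mesh pair
is outside the scheme's stability region and the result would not be
trustworthy. The guard is configurable (`neg_tol`) for deliberate
coarse-mesh experiments with the one-sided closure.

## Observables and comparison

The migrated-cell number N_B(t) is the trapezoid integral of u over the
lower chamber including the lower trace node. The Cell Index is an
affine map CI = a·N_B + b of the migrated cell number; since the
instrument slope is not part of the model, relative quantities
(sensitivity indices, relative MSE) are computed with a proportional
map (b = 0), under which they are independent of a. Curve agreement is
the relative MSE Σ(ĉᵢ−cᵢ)²/Σcᵢ², with the simulated curve linearly
interpolated onto the reference time grid and no extrapolation outside
the simulated range. Simulated curves are sampled every 0.25 h by
default (the recording cadence of the instrument exports is
configurable).

## Sensitivity analysis

Local, one-at-a-time: each constant is perturbed by ±ε (default
ε = 0.05·p₀) around the calibrated point, the full migration model is
re-simulated, and the output functional f — the Cell Index at 12 h —
yields Δf_rel = 100·(f(p₀±ε)−f(p₀))/f(p₀) (signed) and
S = |Δf_rel/100|·(ε/p₀)⁻¹ (magnitude). S = |Δf_rel|/5 holds exactly at
the 5% default by construction. Interactions between parameters are
by design not captured; the method is a first screening of the
parameter space, not a global analysis.

## Calibration

Staged, mirroring how the assay's information is layered:

1. **Proliferation**: a logistic trajectory is least-squares fitted
   (`scipy.optimize.curve_fit`) to the proliferation Cell-Index curve
   recorded at serum level φ̄, giving α₁ (the rate is α₁ directly
   because the serum factor is normalised at φ̄) and the carrying
   capacity. When the seeded cell count is known, the proportional
   Cell-Index slope a = c₀/n_seeded converts the capacity to α₃ in
   cell-number units; this conversion slope is an output of the fit,
   not an input. A log-linear helper estimates doubling times on an
   exponential window.
2. **Basal** (χ₁ = α₁ = 0): D_u, V_transp, k_u1, k_u2, k_u3 against
   basal-migration curves.
3. **Migration**: χ₁, χ₂, α₂, δ, k_φ against full-migration curves,
   with stage-1/2 results frozen. The stage machinery enforces this
   ordering (freeing a chemotactic constant in the basal stage is an
   error).

Stages 2–3 minimise the relative MSE with a bounded Nelder–Mead simplex
in log-parameter space (all constants are positive scale parameters),
restarted from a fixed-seed set of interior points; a derivative-free
method is appropriate because the objective comes from a PDE solve and
is only a few parameters wide. If no Cell-Index map is supplied, the
proportional slope is profiled out by least squares at every
evaluation; supplying the proliferation-stage map instead retains the
amplitude information, which is what identifies D_u and k_u1.

**Identifiability.** At the calibrated constants the membrane is far
from limiting, so the crowding parameters (and with a profiled slope
even D_u and k_u1) move the objective very little — consistent with
their tiny sensitivity indices. Joint fits of all five basal
parameters sit on a compensation ridge: near-zero objectives occur far
from the generating values. `calibrate` therefore reports **near-flat
directions** (free parameters whose ±20% perturbation at the optimum
changes the MSE by less than 10⁻⁴) instead of returning them silently,
and parameter-recovery claims in the test suite are made for the
identifiable subset at a membrane-limited synthetic truth.

## Synthetic data generator

`synthesize_experiment` emulates the instrument's export format: one
table per independent experiment with time, mean Cell Index of
n_replicates wells (default quadruplicate, the standard plate layout)
and their sample SD, sampled at the recording cadence, with independent
additive homoscedastic Gaussian noise per well and time point (default
SD 0.05 Cell-Index units, a typical well-to-well scatter for such
assays; a mean-proportional heteroscedastic option is deliberately not
modelled). Fixed seeds make exports byte-reproducible. What the
generator does **not** emulate: baseline drift, well-position effects,
correlated (in time or across wells) noise, edge evaporation, or any
systematic model misspecification — so passing recovery/agreement tests
on synthetic data demonstrates the correctness of the pipeline, not
that the model captures every feature of real instrument data.

## Problem sizes and tolerances used in the tests

Most tests run on a uniform Δx = 0.05 cm mesh with Δt = 10⁻² h (runs in
≈0.1 s); the conservation, sensitivity-table and Δt-convergence
acceptance checks run at the full production resolution (Δx = 10⁻² cm,
Δx_f = 10⁻⁶ cm, Δt = 10⁻³ h; 20 180 stored nodes, 12 000 steps, tens of
seconds per run). Calibration-recovery experiments use Δt = 2×10⁻² h
and a ≈500-evaluation budget. The method-of-lines oracle integrates
the same spatial semi-discretisation with `scipy.integrate.solve_ivp`
(BDF, rtol 10⁻⁸) and agrees with the time-marched solver within the 2%
band expected from their different time discretisations.

## Known limitations

* 1D only; no radial structure, no multiple chemoattractant species,
  no enzymatic serum degradation.
* The adhesion/spreading term conflates adhesion, spreading and
  division — adequate within the 12 h window, not beyond.
* The Cell-Index map is assumed linear with the migrated cell number;
  impedance physics (field fringing, confluence nonlinearity) is out of
  scope.
* First-order accuracy in time and (at the advection terms) in space;
  no adaptive stepping or flux limiting.
* The crowding constants are structurally weakly identifiable from a
  single migration curve; treat fitted values of k_u2/k_u3 as order-of-
  magnitude unless multiple seeding densities are fitted jointly.
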