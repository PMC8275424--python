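# Methods

## The model

A single cubic brain unit of edge `x_r = l_cap + 2r` (55 μm with the rat
defaults: intercapillary distance 50 μm, capillary radius 2.5 μm) contains
three coupled subsystems.

**Capillary plasma.** Plasma diffusion is negligible next to blood flow, so
each of the twelve cube-edge capillaries is a 1-D advection channel at the
common speed `v_blood`, directed away from the arteriole corner
`W_in = (0,0,0)`. The inlet concentration follows the Bateman profile of a
one-compartment oral dose (bioavailability `F`, dose, distribution volume
`V_d`, absorption/elimination constants `K_a ≠ K_e`); the venule corner
`W_out` drains instantly (Dirichlet μ = 0). At an interior vertex the
outgoing edges receive the arithmetic mean of the incoming end
concentrations: with equal vessel calibers and speeds this equal-volume
mixing is the only junction rule consistent with volume balance at the
vertices. Volumetric flow then splits 3-ways at `W_in` and 2-ways at the
inlet-adjacent corners, so the six middle edges carry half the flow of the
six terminal ones; node "volumes" weighted by this flow share make the
upwind discretization conserve the discrete plasma mass exactly, which the
tests exploit (weighted column sums of the advection operator vanish on all
interior columns).

**Blood–brain barrier.** Exchange acts on the two x-normal planes `x = r`
and `x = x_r − r`. The per-area flux combines passive permeation
`P(μ − ρ)` with saturable carrier influx/efflux
`T_m·c / (SA_BBB·(K_m + c))`. The model statement writes the barrier
conditions with time derivatives (`D* ∂ρ/∂t = ±f`); dimensional analysis
and conservation require a flux reading, so the implementation treats `f`
as a membrane flux density balanced against the wall: each barrier-face
cell of the ECF grid gains `f · A_face` μmol/s and a paired plasma node
loses exactly the same amount. The inlet and outlet corners are excluded
from the exchange (they are clamped reservoir nodes; letting them exchange
silently creates or destroys drug).

Two coupling modes exist. The default, `plane_mean`, evaluates `f` with the
flow-weighted mean plasma concentration of each barrier plane and
distributes the plasma-side loss over the plane's nodes in proportion to
their current drug content (falling back to volume shares when the plane
gains drug). This keeps the ECF boundary data independent of y, so the ECF
solution is exactly symmetric under `y → y_r − y` — the symmetry the
model's construction promises — and it never overdraws an empty node. The
alternative `per_node` mode evaluates `f` with each cell's nearest plasma
node; it resolves the along-capillary concentration profile but breaks the
y-symmetry of the ECF field (the inlet corner sits at y = 0), which is a
physical feature of that refinement, not a bug. Both modes are
conservative pair by pair.

**Brain ECF.** Free drug diffuses with the tortuosity-corrected coefficient
`D* = D/λ²`, is advected by the bidirectional bulk flow (equal components
along +x and +z), and exchanges reversibly with two uniformly distributed,
immobile binding pools: specific targets (B1, small capacity, here
0.05 μmol/L) and nonspecific tissue sites (B2, 50 μmol/L). All non-barrier
faces are sealed. Initial state is drug-free everywhere.

## Units

Internally: lengths m, time s, concentrations μmol·m⁻³
(1 μmol·L⁻¹ = 10³ μmol·m⁻³). This single volume basis makes the passive
term `P(μ−ρ)` (m s⁻¹ × μmol m⁻³) and the carrier term `T_m/SA_BBB`
(μmol s⁻¹ m⁻²) dimensionally commensurate — the parameter tables that mix
L-based concentrations with m-based geometry leave that conversion
implicit. All public constructors and the config file accept the
conventional printed units; association constants `(μmol L⁻¹ s)⁻¹` shrink
by 10³ on conversion.

## Discretization

- ECF: cell-centered grid on `[r, x_r − r] × [0, y_r] × [0, z_r]`
  (default 23³ cells), 7-point Laplacian with homogeneous Neumann closure,
  flux-form first-order upwind advection with zero advective flux through
  the outer faces. The flux form (rather than one-sided zero-gradient
  differences) is what makes the advection operator's column sums vanish,
  i.e. mass-conservation exact; over the 14 s horizon the bulk flow moves
  drug ~7 μm, so the sealed outflow face is never stressed.
- Plasma: first-order upwind along each edge, n = 23 nodes per edge by
  default.
- Time: backward Euler everywhere, `dt = 0.01 s`, horizon 14 s, snapshots
  at t = 2, 8, 14 s. `dt` must divide the snapshot times (snapshots are
  captured, never interpolated).
- Binding is made implicit without a Newton loop: lagging ρ only in the
  denominator gives `B^{n+1} = (B^n + dt·k_on·B_tot·ρ^{n+1}) /
  (1 + dt(k_on ρ^n + k_off))`, affine in `ρ^{n+1}`; substituting the exact
  increment `(B^{n+1} − B^n)/dt` into the ρ equation keeps the step one
  linear solve *and* transfers mass between free and bound pools exactly.
  Plain lagging of `(B_tot − B)` would leak O(dt²) mass per step and could
  not meet the 10⁻⁹ sealed-box conservation bound. The scheme preserves
  `0 ≤ B ≤ B_tot` for the parameter regimes simulated; violation is a
  hard failure, never clamped.
- BBB fluxes are evaluated from the previous step's (μ, ρ) and held fixed
  during the step (Gauss–Seidel-style splitting, first-order consistent
  with the integrator). Per-step operator order: inlet value at the new
  time level → exchange fluxes → implicit plasma step → implicit ECF step
  → audit.

## Linear solves

The plasma system (≈260 unknowns) is LU-factorized once per run. The ECF
backward-Euler matrix is `I + K + diag(β)` with `‖K‖∞ ≈ dt·(2v/h + …)`
≈ 10⁻² at desk scale, so a plain fixed-point iteration
`x ← rhs − (K + β)x` converges geometrically to the rounding floor in a
handful of sparse matvecs; iteration stops when the update stalls at that
floor. For `‖K‖∞ + max β > 0.5` (large dt) the step falls back to a sparse
LU per step. Both paths are deterministic; results are bit-identical
across reruns.

Positivity and box invariants are checked after every step with a
round-off guard of 10⁻¹¹ relative to the field scale: drug-free regions
accumulate harmless ±10⁻²² noise that a strict `≥ 0` test would misread as
a solver defect. Values are never clamped.

## Verification

Independent oracles (no shared discretization code with the solvers):

- the inlet profile re-evaluated in 50-digit decimal arithmetic and its
  peak located by bounded scalar maximization against the closed form
  `ln(K_a/K_e)/(K_a − K_e)`;
- the identical semi-discrete ECF system re-assembled from face fluxes by
  array slicing and integrated with a high-order adaptive explicit method
  (DOP853, rtol 10⁻¹¹); the implicit solver's deviation must halve with dt
  (Richardson ratio in [1.6, 2.4] — measured ≈ 1.99);
- the passive uniform steady state: with plasma clamped at `c`, ρ → c and
  each `B_i` → `B_tot·k_on·c/(k_on·c + k_off)` monotonically. This check
  runs with a larger `D* = 5×10⁻¹² m² s⁻¹` and `P = 10⁻⁶ m s⁻¹` so that the
  binding-buffered equilibration (retardation factor ≈ 1 + ΣdB/dρ ≈ 5.5)
  completes on a convenient horizon; the property itself is
  parameter-independent.

Oracle tolerances: 10⁻¹⁰ relative for closed forms, 10⁻⁶ for the fine-step
reference, 10⁻⁴ for the steady-state field.

## Scenario presets and problem sizes

The nine presets cover the plasma sweep (P, v_blood) and the binding sweep
(k_on, k_off per pool) at the captioned values, including the deliberately
odd ones (`P = 2×10⁻⁶·⁹ m s⁻¹`, `v_blood = 1.1×10⁻⁵·⁹⁵ m s⁻¹`,
`k2_off = 3×10⁻⁰·² s⁻¹`). One source gives conflicting specific-site
association values for the nonspecific-varied case (10⁻¹ in the figure
caption vs 1 in the body text); the captioned 10⁻¹ is used. Parameters are
range-checked against the literature table (e.g. `P ∈ [10⁻¹⁰, 10⁻⁵] m s⁻¹`)
with an explicit `allow_out_of_range` escape hatch; every preset passes
without it.

Desk scale — 23³ ECF cells, 23 nodes/edge, dt = 0.01 s, 1 400 steps — was
chosen to resolve the 55 μm unit while keeping a full preset run at a few
seconds on one core; tests and the acceptance script use this scale except
where a smaller grid (5³–9³) isolates a property.

## What the simulations do and do not show

The plasma sweep reproduces the expected orderings (higher P drains plasma
and fills the ECF; the free pool rises ~12× for the high-P case), and the
binding sweep reproduces the pool orderings (B2 ≫ B1 at base kinetics;
raising k_off empties the bound pools while the released drug stays mostly
free; lowering k_on suppresses both pools at every snapshot). These are
directional statements about the model, not calibrated predictions: the
single cubic unit ignores anatomical heterogeneity, intracellular uptake,
metabolism, plasma protein binding and transporter heterogeneity along the
capillary, and the 14 s horizon sits on the rising flank of the ~9 240 s
dose curve, so absolute amounts are far below steady state.

## Archive format

Results serialize to a directory: `fields.nc` (NetCDF3 via xarray's scipy
backend — self-describing, bit-exact float64 round-trip) holding ρ, B1, B2
on (time, x, y, z), μ on (time, node) and the audit series, plus
`config.cfg`, the resolved parameters in the package's flat INI dialect.
Slice exports write tab-delimited text at 12 significant digits and
optional PNG renderings.
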