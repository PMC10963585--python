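# Methods

## Model overview

`lobulefem` simulates the interplay of blood microperfusion, solute supply
and fat accumulation in the hexagonal functional unit of the liver, the
lobule. The tissue is treated as a saturated porous mixture of three
immiscible phases — solid liver tissue (S), fat tissue (T) and blood (F) —
whose volume fractions satisfy `n_S + n_T + n_F = 1` at every material
point. Dissolved in the carriers are miscible components: glycogen in the
solid, and glucose, lactate, free fatty acids (FFA) and oxygen in the
blood. Glucose/lactate/glycogen are carried as transportable species with
their kinetics off by default; the fat module couples only FFA and oxygen.

The macroscale fields are the solid displacement `u_S`, the pore pressure
`p` (the Lagrange multiplier of the saturation constraint), the tissue and
fat fractions `n_S`, `n_T`, and the solute fields (solved in concentration,
reported also as ideal-dilute chemical potential
`mu = mu0 + R θ ln(c/c_ref)`). Constitutive laws are the admissible
restrictions of the mixture's entropy inequality:

* effective Neo-Hookean stress of the tissue phases plus the
  `-λ (n_S+n_T) I` pressure contribution; the fluid partial stress is
  `-n_F (λ + Π) I` with osmotic pressure `Π = c R θ`. Summing all partial
  stresses, the osmotic terms cancel and the total stress is
  `σ_eff(u) - p I`, the form used by the momentum solve.
* Darcy flow, `n_F w_FS = K_F (-∇p)`, with the transverse-isotropic
  permeability `K_F = k_eff(n_F) [(1-ω) I + ω d⊗d]`, where `d` is the unit
  vector toward the central vein, `ω = 0.5`, and
  `k_eff = k_D/(ρ_FR g) · (n_F/n0_F)^m` with `m = 1`. Fat growth shrinks
  `n_F` and throttles perfusion nearly linearly.
* solute seepage with Fickian diffusion down the osmotic-pressure gradient
  and advection with the blood. The drag coefficients behind these laws are
  not observable individually; they are parameterized directly by
  diffusivities (oxygen 1e-10 m²/s, FFA 2e-11 m²/s — see *Calibration*)
  and an advective factor of 1 (solutes carried at the blood velocity).
  The printed form of the interaction-force restrictions is sign-ambiguous;
  we fix the signs so that diffusion is strictly down-gradient and
  advection follows the flow, which also makes the Darcy and diffusive
  entropy production non-negative pointwise (checked numerically).

Growth enters exclusively through the mass-exchange route: the fat-phase
balance `(n_T)'_S + n_T ∇·x'_S = ρ̂_T/ρ_TR` carries the production, and the
mixture mass balance carries the compensating sink, so the saturation
constraint is preserved step by step. No independent growth-deformation
tensor is tracked: the weak forms being solved contain no such unknown, and
the quasi-static small-strain regime makes the multiplicative split
unobservable at the field level.

## Cell scale

Each quadrature point (one per triangle) carries a three-variable
hepatocyte state: intracellular FFA, intracellular oxygen (mmol/l) and the
triglyceride (TG) store (kg/m³ of cell volume). Rates: Michaelis–Menten
uptake of plasma FFA and oxygen; TG synthesis `v_syn = k_syn·c_FFA_int`;
oxygen-saturable β-oxidation `v_oxy = k_oxy·c_FFA_int·c_Ox/(KM_oxy+c_Ox)`
consuming both FFA and oxygen; a background oxidative load
`v_deg = k_deg·c_Ox`; and first-order TG export. The competition between
synthesis and oxidation is the zonation mechanism: oxygenated periportal
tissue oxidizes FFA away, hypoxic pericentral tissue esterifies it.

Scale coupling is weak and staggered: per macro step the plasma
concentrations are frozen at the quadrature points, the cell ODEs are
integrated over `dt`, and the reaction extents return as mass-exchange
terms — a fat production `ρ̂_T = n_S·Δtg/dt`, solute sinks
`ρ̂_Fβ = -M_β·n_S·⟨uptake⟩`, and a compensating fluid-phase exchange chosen
so that the total exchange sums to zero exactly (machine precision,
asserted every step). Cell rates are per unit hepatocyte volume and scale
by `n_S` when lifted to the continuum; an availability limiter caps the
uptake at a fraction (default 0.5) of the locally stored solute per step so
the explicit sink can never overdraw a node.

## Discretization

* Triangulated meshes only. The hexagon is subdivided structurally (six
  sectors × n² congruent triangles), so refinement is deterministic, the
  boundary is exact, and the 7-lobule group is conforming by construction.
  The central vein is cut out (disc of 8 % of the circumradius, or one cell
  ring on very coarse meshes) and its rim carries the outflow condition.
  Portal corners (8 % of the circumradius) and venule bands (15 % of each
  edge, centred) are tagged on the boundary; meshes too coarse to resolve
  any inflow band are rejected with a diagnostic.
* Taylor–Hood pairing: quadratic (P2) displacement, linear (P1) pressure,
  fractions and solutes. The momentum solve is quasi-static plane-strain
  linear elasticity with effective Lamé constants `λ_S+λ_T`, `μ_S+μ_T`,
  loaded by `∫ p ∇·δu`; displacements are fixed at the tagged inflow and
  outflow nodes.
* All first-order evolution equations use backward Euler (default
  `dt = 10 s`, horizon 1610 s). A second-order structural integrator for
  the displacement block is accepted as a settings option but reduces to
  the same static solve because accelerations are zero by assumption.
* Each block of the staggered step (pressure, per-solute transport,
  displacement) is affine in its own unknown; the generic Newton driver
  therefore converges in one iteration per block and reports it. Transport
  uses the non-conservative advection form `∫ φ (q·∇c)`; because the
  discrete pressure solve makes the weighted divergence of `q` vanish on
  interior rows, discrete solute conservation holds up to boundary fluxes.
  Cell Péclet numbers are ≤ O(0.1) at the default resolution, so no
  stabilization is required.
* The cell ODEs are integrated by a vectorized backward-Euler Newton scheme
  (2×2 analytic Jacobian, 5 substeps per macro step) inside the coupled
  driver; the backward-Euler reaction extents close the FFA budget to
  machine precision, which is what the global mass audit checks. The
  stand-alone single-trajectory integrator is an adaptive implicit
  trapezoid with step-doubling error control (A-stable, rejects steps that
  would go negative) and agrees with a high-accuracy Radau reference to
  better than 1e-9 relative over the full horizon.
* Concentrations are floored at 1e-9 mol/m³ before logarithms; floor
  activations are counted and reported, not silently ignored.

## Scenarios

Boundary pressures follow the 1 mmHg convention: inflow 133 Pa over an
outflow gauge of 0 Pa at the central veins.

* **undisturbed** — inflow on all portal corners and venules (interior
  portal fields of the group included), outflow at every central vein.
  Lobules are hydraulically independent (interfaces sealed by node
  duplication), and all seven pressure fields agree to round-off.
* **outflow_obstruction** — the left lobule's vein is blocked and its
  periphery held at 100 Pa; the stationary field there is constant, so no
  advection survives. Its solute supply is restricted to the
  outer-periphery portal/venule bands: the sealed interfaces carry no
  plasma. This is the reading of the (under-specified) obstructed-lobule
  inflow that expresses the metabolite starvation the scenario is about.
* **obstruction_with_drainage** — the lobules are connected, pressure is
  applied only at the portal triads and raised by 30 %, and the obstructed
  lobule drains through its neighbours' central veins (verified by
  streamline tracing through the stationary velocity field).

## Calibration and what it shows

The cell-scale rate constants are not literature transcriptions (the
kinetic details live in cited prior work); they were calibrated once, with
`scripts/calibrate_kinetics.py`, to reproduce the qualitative verification
patterns on the default geometry: inflow FFA 3 mmol/l with oxygen
0.091 mmol/l yields pericentral steatosis, inflow FFA 0.2 mmol/l yields
periportal steatosis, and the obstruction scenario moves the obstructed
lobule's pattern toward periportal. The shipped values are
`vmax_FFA = 1.05e-4`, `KM_FFA = 0.35`, `vmax_Ox = 2.5e-4`, `KM_Ox = 0.04`
(mmol/l, s), `k_syn = 2e-3`, `k_oxy = 2e-2`, `KM_oxy = 0.03`,
`k_deg = 5e-3`, `k_exp = 1e-4` (1/s), interior initial concentrations 3 %
of the inflow values.

Two deliberate departures from literal physiology:

* `rho_conv = 900 kg/mol` (TG mass per mole of esterified FFA) is ~3000×
  the stoichiometric value. Steatosis develops over weeks; the simulated
  horizon is 1610 s, so the lipid-store dynamics are time-compressed into
  the window where the perfusion–growth feedback is observable. The FFA
  mole bookkeeping is unaffected (the audit is formulated in moles).
* With the tabulated Darcy coefficient (4.5e-10 m/s, converted to a
  hydraulic mobility by dividing by `ρ_FR·g`) and the 133 Pa difference,
  the blood transit time across a 0.5 mm lobule is ≈ 3000–5000 s, longer
  than the horizon. Solute delivery to the lobule centre within 1610 s is
  therefore shared between advection, diffusion and the initial interior
  fill. A consequence: blocking advection (outflow obstruction) weakens but
  does not fully invert the pericentral pattern — the obstructed lobule
  loses its pericentral classification and its zone-3/zone-1 fat contrast
  drops by ≈ 20 % relative to the undisturbed lobules, without crossing
  into a strict periportal classification. A full inversion would require a
  transport regime (fast advection, slow diffusion) under which the
  low-FFA periportal verification case no longer works; the shipped
  parameters resolve that tension in favour of the two primary zonation
  patterns.

What passing tests show — and do not show — about real tissue: the suite
verifies internal consistency (conservation, closure, convergence orders,
oracle agreement) and that the qualitative pattern logic (oxygen gradient
vs FFA supply) behaves as in the idealized geometry. Real lobules are
irregular, three-dimensional, have heterogeneous sinusoid networks and
much slower lipid dynamics; none of that is represented.

## Numerical choices and degenerate inputs

* Mesh preconditions: `0 < target_edge_length < circumradius/4`; inverted
  triangles, untaggable boundaries and unsupported group sizes raise typed
  errors. The anisotropy direction falls back to a fixed unit vector (and
  flags it) only for a cell exactly at a vein centroid, which the vein
  cut-out makes unreachable in practice.
* All-Dirichlet-free (pure Neumann) pressure problems are rejected as
  singular rather than regularized.
* The fat fraction is a hard invariant: leaving `(0, 1-n_S)` aborts the
  step with the failing time, rather than clamping.
* Determinism: there is no random number generator anywhere in the
  pipeline; identical configurations produce bit-identical zone summaries
  (asserted in the suite).

## Problem sizes

Default single-lobule runs use a circumradius of 0.5 mm with a target edge
length of r/16 (≈ 1.5k triangles, 161 time steps); group runs use r/8 per
lobule (≈ 2.6k triangles). These resolutions are the package's reference
configurations: the spatial convergence and refinement tests justify them,
and all calibrated pattern statements above refer to them.

## Known limitations

Two-dimensional, idealized hexagons only; glucose/lactate/glycogen kinetics
stubbed; no thermal, viscoelastic or remodelling effects; staggered
coupling is first-order in `dt`; the advective solute factor and the drag
coefficients are effective parameters, not measured quantities.
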