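# Methods

This note records the models implemented in `oxyfuse`, the assumptions and
numerical choices behind them, what the synthetic networks do and do not
emulate, and the known limitations. Everything quantitative stated here is
computed by the test suite or `scripts/acceptance.py`; nothing is quoted
from elsewhere.

## 1. Physiology

All internal quantities use µm, s, mmHg and µM. Hemoglobin saturation
follows the Hill equation S(P) = Pⁿ/(Pⁿ+P50ⁿ); dissolved oxygen follows
Henry's law C = P/H with the blood/tissue solubility α = 1/H (an
alternative solubility input in µl O₂/g/mmHg is accepted by the unit
converter and transformed through the 22,400 cm³/mol molar volume, the
convention of the classical oxygen-transport literature). Tissue
consumption is Michaelis–Menten, M(P) = M₀·P/(P+K_m).

Defaults (tumor): H = 0.74 mmHg/µM, D = 2000 µm²/s, C′ = 8800 µM, n = 3,
P50 = 26 mmHg, M₀ = 0.0004 cm³O₂/cm³/s ≈ 17.86 µM/s. The brain preset
uses M₀ = 0.0025 cm³O₂/cm³/s ≈ 111.6 µM/s. **K_m is not a tabulated
constant of the datasets this package emulates**; the default 1.0 mmHg is
the value typical of Green's-function microvascular modeling and is
configurable (`PhysiologyParams(Km=...)`). C′ is used directly, without
per-segment hematocrit scaling; hematocrit is carried on segments for
future refinement but does not enter the oxygen computation.

The dissociation-slope factor m = H·C′·dS/dP is the hemoglobin buffering
factor: blood's effective oxygen capacity per unit free-pO₂ change is
(1+m) times the dissolved capacity. It is evaluated once per voxel at the
inlet pO₂ — re-evaluating it locally would invalidate the closed-form
voxel solution.

## 2. The voxel model (MPO2)

A voxel of edge L is represented by one straight vessel of effective
radius r_c on the axis of a tissue cylinder of radius r_T. We take
r_T = L/√π so the cylinder volume πr_T²L equals the voxel volume L³ —
the tissue mass the voxel represents is conserved. The field is

    pO₂(r,z) = pO₂(0) − [M·H/((1+m)F)]·G₂(z) − [M·H/(2D)]·G₁(r).

The two form factors are reconstructed from the Krogh assumptions so that
the printed prefactors are dimensionally consistent and the single-vessel
finite-difference oracle is reproduced:

* G₁(r) = r_T²·ln(r/r_c) − (r²−r_c²)/2 is the Krogh–Erlang annulus
  solution of Dα·(1/r)(rP′)′ = M with zero flux at r_T; the tests verify
  it against direct numerical integration of that ODE to 1e−6 relative.
* G₂(z) = (z/L)(1 − r_c²/r_T²) is the cumulative fraction of the
  cylinder's demand delivered by axial position z under uniform
  consumption.

Both sit behind dedicated functions so alternative reconstructions can be
swapped in and judged by the same oracle test.

MPO2 is the volume-weighted mean over r ∈ [r_c, r_T], z ∈ [0, L], in
closed form when the field is nonnegative and by midpoint quadrature in
(r², z) when clamping at zero is active (the clamped fraction is
reported; clamped voxels count as hypoxic downstream). Negative voxel
means are clamped to zero and flagged. By default the consumption is
iterated to Michaelis–Menten consistency with the voxel mean,
M ← M₀·MPO2/(MPO2+K_m), to 0.01 mmHg; a constant-M mode implements the
pure closed-form model.

Effective inputs per voxel (V = volume of voxel ∩ tissue domain; for
interior voxels V = L³):

* fvv = Σᵢ πrᵢ²·lenᵢ/V over segment pieces clipped to the voxel;
* r_c = L·√(fvv/π): the radius of a single spanning vessel of equal
  volume, exact when the voxel really contains one spanning vessel;
* F = Σᵢ |Qᵢ|·(lenᵢ/ℓᵢ)/V, where ℓᵢ is the crossing length of the voxel
  volume along vessel i's direction — each vessel's flow weighted by the
  fraction of a full crossing it completes; reduces to Q/L³ for a
  spanning vessel and keeps boundary-clipped voxels at their true local
  perfusion;
* voxel SaO₂ = Σᵢ SaO₂(i)·vol(i)/Σᵢ vol(i), with segment saturation taken
  from the reference solver's subsegment lumen profile (midpoints inside
  the voxel, falling back to the segment mean);
* pO₂(0) = Hill⁻¹(voxel SaO₂), m evaluated there.

Because the voxel SaO₂ is a volume mean along the vessel, using it as the
*inlet* value double-counts roughly half the axial drop; the bias is
proportional to the advection term and vanishes in the Krogh (high-flow)
limit. This is inherent to deriving the initial pO₂ from a single
voxel-level saturation measurement, which is exactly what an imaging
modality provides.

Voxels without vasculature are invalid (no MPO2); the six-neighbor
correction can fill them afterwards.

## 3. The reference solver (LPO2/GPO2)

The tissue field is P(x) = Σⱼ qⱼ·Gⱼ(x) + ψ(x): exact free-space
finite-line potentials Gⱼ for every ≤50 µm vessel subsegment, plus a
residual ψ that carries the Michaelis–Menten sinks and the sealed-box
boundary. Strengths qⱼ are fixed by collocation: tissue pO₂ at each
subsegment wall equals the lumen pO₂ there, where lumen pO₂ follows from
marching total blood O₂ content (P/H + C′·S(P)) down the flow graph,
subtracting the released q along the way and mixing flow-weighted at
junctions. Because near saturation the tissue level responds very
stiffly to the total release, the wall system is solved jointly with a
linearized uniform level shift; the outer loop damps q adaptively.

ψ solves the cell-centered discrete Neumann problem
L·ψ = M(P)/Dα + boundary forcing, where the forcing cancels the analytic
vessel flux through the box faces (per-source columns normalized to the
exact closed-surface integral −q/Dα). Subsegments within 1.5 lattice
spacings of a face carry explicit mirror images, whose paired flux
through the near face cancels identically — the face-center quadrature
could not resolve it otherwise. The nonlinear solve is a semismooth
Newton iteration: sparse 7-point Laplacian, conjugate gradients with an
exact DCT spectral preconditioner for (−∇²+c̄), an Armijo line search on
the residual norm, and a separate 1-D root solve for the stiff uniform
level mode (the Neumann operator is blind to constants while consumption
near saturation barely responds to them). At convergence the discrete
operator enforces total release = total consumption exactly; the
conservation check in the results is therefore a genuine convergence
diagnostic, not an imposed constraint.

Numbers: lattice spacing 15 µm (cell-centered, so a 150 µm edge holds 10
cells each owning (15 µm)³), subsegments ≤50 µm split equally, outer
tolerance 0.01 mmHg max change, damping 0.5 halving on stagnation,
line-potential radial floor at the vessel radius (lumen points see the
wall value). Wall collocation points sit one radius off the subsegment
midpoint, perpendicular to the axis. A free-space (open) mode without the
boundary machinery is kept for comparison. Segments with zero flow are
passive (q = 0).

GPO2 is the arithmetic mean of LPO2 over lattice cell centers inside each
half-open voxel; voxels containing no lattice point are invalid.

### The finite-difference oracle

`fd_oracle` solves Dα∇²P = M(P) − (vessel source density) on a fine
cell-centered grid (3 µm in the cross-checks), depositing the converged
subsegment strengths along their axes, with zero-flux (or zero-pressure
"open") faces and Newton iterations on the Michaelis–Menten term. It
shares no discretization machinery with the superposition solver beyond
the physiology functions, and is used only as a check: interior RMS
agreement is 0.05 mmHg on the single-vessel fixture and 0.04 mmHg on the
four-vessel fixture (tolerance 2 mmHg), measured ≥15 µm from vessel axes
and ≥10 µm from the boundary.

## 4. Synthetic networks

No real window-chamber reconstructions ship with this package, so three
generators emulate their salient features. All are bit-reproducible for a
fixed seed.

* **Single vessel**: one straight segment centered in a box; the Krogh
  fixture uses a 120 µm cube, r_c = 6 µm, arteriole-like flow 8×10⁵ µm³/s
  and inlet SaO₂ 0.95, putting the model in the weak-advection regime the
  Krogh-limit check targets.
* **Parallel array**: vessels along z on a jittered square grid. Inlet
  saturations follow a smooth diagonal ramp plus small noise (σ = 0.02)
  rather than independent draws — microvessels in a real bed branch from
  common feeding arterioles, so neighbors carry similar saturations; with
  independent draws the reference field becomes dominated by inter-vessel
  oxygen exchange that no sealed per-voxel model could represent. The
  fidelity fixture uses 25 vessels at 125 µm spacing: a coupling estimate
  (exchange flux 2πDα·δP/ln(s/r_c) against per-vessel load M₀s²) shows
  the sealed voxel model can only track the reference when that ratio is
  ≲0.1, which with the tumor consumption rate requires s ≈ 125 µm — the
  upper end of measured inter-vessel spacings.
* **Tumor-like bed**: tortuous paths march across the
  990 × 810 × 150 µm³ window-chamber domain from the low-x face with
  transverse jitter, branching with probability 0.12 per step, radii
  uniform in [3, 15] µm, until the vascular volume reaches 2% of the
  domain. Paths never approach another vessel closer than 12 µm
  wall-to-wall (the low end of measured inter-vessel spacing); candidate
  steps are re-aimed and a boxed-in path terminates. Leaf tips drain as
  outlets — in a 150 µm-thin observed slab a mid-tissue dead end stands
  for a vessel diving out of the imaging plane — so every segment is
  perfused. Flows come from a Poiseuille pressure solve (constant
  viscosity 4 mPa·s, no radius-dependent rheology: flows are inputs, not
  claims) rescaled so total inflow is 230.37 nL/min (10.8 nL/min for the
  brain preset's 150 × 160 × 140 µm³ domain, which is denser, straighter
  and more saturated, emulating normal cortex).

What these fixtures do **not** emulate: real branching statistics and
diameter taper, phase-separation hematocrit heterogeneity, measured
per-segment flows/saturations, anisotropy of real tumor beds, or any
imaging point-spread function. Passing tests therefore demonstrate the
internal consistency and the resolution behavior of the fusion method
under controlled, physiologically plausible conditions — not agreement
with any particular animal's vasculature.

## 5. Evaluation choices

* Regressions are unweighted OLS of MPO2 on GPO2 (scipy), voxels valid in
  both maps; grids at ≥200 µm pool five random translations (uniform in
  (−L/2, L/2)³, untranslated grid first) to populate the scatter.
* Hypoxic fraction: count(pO₂ < threshold)/count(valid); ladders
  2.5–15 mmHg (tumor) and 16–22 mmHg (brain); zero-clamped voxels are
  hypoxic at any positive threshold.
* Six-neighbor correction: default mode replaces each voxel by the mean
  of its existing face-adjacent valid neighbors; an include-self mode is
  provided (the two published descriptions of this step differ). The
  before/after r² comparison uses the same (vessel-containing) voxel set:
  neighbor-filled empty voxels carry averages rather than model output,
  and grading them would measure the filling, not the model.
* Sensitivity scan: one input at a time × {0.8, 0.9, 1.1, 1.2}, percent
  change of the mean MPO2 over voxels whose baseline exceeds 1 mmHg (a
  relative deviation is meaningless for clamped voxels). The scan runs
  the voxel model in constant-M mode: M₀ is itself one of the varied
  inputs, and feeding it back through the Michaelis–Menten coupling would
  cancel part of the response being measured. SaO₂ scaling re-clips at
  0.99 — the inverse Hill relation diverges at S = 1, so saturated voxels
  respond with disproportionately large pO₂ jumps (visible as the large
  SaO₂ percentages on well-saturated fixtures).
* Error propagation: per voxel, ten replicates of the target input drawn
  from Normal(value, σ) with FWHM = 2.355σ = 20% of the value,
  non-positive draws redrawn (≤100 times); per-voxel CV = SD/mean,
  averaged over voxels with positive means. Streams derive from
  (seed, voxel index), so results are independent of iteration order.

## 6. Problem sizes and runtime

The packaged study sizes are chosen so a full validation run (reference
solve of a ~300-segment tumor bed on a 66×54×10 lattice, six voxel-size
fusions, FD cross-checks at 3 µm on the small fixtures, sensitivity and
noise scans) completes in a few minutes on one CPU. Larger domains or
finer lattices only change memory/time through the dense
(lattice × subsegment) potential matrix and the per-iteration sparse
solves.

## 7. Known limitations

* The voxel model inherits the closed form's assumptions: constant m per
  voxel, sealed voxel boundary, single straight vessel. Its accuracy
  collapses when voxels grow past the inter-vessel spacing regime
  (visible in the 200–300 µm slopes) and degrades when neighboring voxels
  exchange much oxygen (visible at 50 µm before the neighbor correction).
* The relative sensitivity of consumption (M₀) versus vessel radius
  depends on the per-voxel vascular fraction: analytically the ratio of
  radius to consumption effects is ≈0.915/(ln(r_T/r_c) − 3/4), crossing
  unity near fvv ≈ 2.4%. At this package's 2% tumor fixture the two
  effects are nearly equal, so the "consumption dominates, radius
  weakest" ordering seen on sparser beds holds only by a thin,
  seed-dependent margin here.
* The reference solver's boundary treatment (sealed box) and the absence
  of intravascular transport resistance (wall pO₂ = lumen pO₂) are
  modeling choices; both are isolated (boundary mode flag, wall
  collocation) for future refinement.
* Hematocrit, Bohr-effect P50 shifts, myoglobin, vessel-wall oxygen
  permeability and time dependence are out of scope.
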