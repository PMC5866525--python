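# Methods

`oargroup` is a desk-scale sandbox for studying one planning idea: in daily
adaptive radiotherapy of pancreatic cancer, replace the four separately
weighted gastrointestinal organs at risk (stomach, duodenum, small bowel,
large bowel) in the plan objective with a *single grouped structure* — the
union of their portions within 3 cm of the planning target volume (PTV) —
and keep that simplified objective frozen across every re-planned treatment
fraction. This note records the models, parameters and numerical choices
behind the package, and what its synthetic experiments do and do not show.

## Plan objective

A plan is a vector of nonnegative beamlet weights `w`; dose is linear in
the weights, `D = Aᵀw`, with `A` the beamlet-by-voxel influence matrix.
The objective is a volume-weighted sum of one-sided power penalties:

- each OAR with parameters `θ = {ω, u, T}` contributes
  `Σ_v v_vox · ω · max(0, D_v − T)^u` — cost accrues only above the
  threshold `T` (Gy), with importance `ω` and power `u ≥ 1`;
- the target with `θ_t = {ω_lt, ω_ut, l_t, u_t, D₀, offset}` contributes
  `Σ_v v_vox · [ω_lt · max(0, P − D_v)^{l_t} + ω_ut · max(0, D_v − P)^{u_t}]`
  around the pivot `P = D₀ + offset`.

Three choices here deserve a word:

- **Sum, not mean.** Aggregating over voxels with a volume-weighted sum is
  what makes the grouped term algebraically equal to the sum of per-organ
  terms whenever the organs are disjoint, lie inside the grouping ring and
  share one parameter set. That identity is the whole point of the
  simplification, and it is asserted exactly (1e-10 relative) in the tests.
- **Single pivot.** Both target branches hinge on the same pivot
  `P = D₀ + offset`. A symmetric dead-band variant (no cost inside
  `[D₀ − offset, D₀ + offset]`) is available via `pivot_mode="deadband"`
  but is not the default.
- **Strict excess.** At `D = T` exactly the cost contribution is zero, and
  the one-sided derivative 0 is used at kinks; with all powers ≥ 1 the
  objective is convex in dose (checked by random midpoint tests).

Conventional mode binds each primary OAR separately (4 organs × {ω, u, T} =
12 tunables); grouped mode binds one triple to the grouped structure
(3 tunables) — a factor-of-four reduction. Remaining OARs (spinal cord,
kidneys) keep individual terms in both modes.

## Geometry

All structures are boolean masks on one regular, possibly anisotropic voxel
grid. Distances are 3-D Euclidean, measured voxel-center to voxel-center
with the grid spacing, and boundary-inclusive: the grouped structure keeps
primary-OAR voxels whose distance to the nearest PTV voxel is ≤ 30 mm.
Overlapping organs are unioned (each voxel counted once). PTV-OPT — the
portion of the target where full dose is achievable — is the PTV minus each
primary OAR expanded by a margin (default 5 mm, configurable; typical
clinical overlap margins are 3–5 mm, and no single standard value exists).
An empty PTV-OPT is a legitimate anatomy and is reported as not-applicable,
never as 0% coverage. Volumes are whole-voxel counts (no sub-voxel
partials) in cm³.

## Dose engine

Dose calculation is deliberately simple plumbing — the planning method does
not depend on its details, only on linearity. Each beam is a parallel
bundle of pencil beamlets on a square fluence grid rotating about the grid
center in the axial plane; a beamlet deposits
`exp(−μ·depth) · exp(−r²/2σ²)` (truncated at 3σ) per unit weight, in Gy.
Defaults: μ = 0.005 /mm, σ = 4 mm, 5 mm beamlet pitch, 7 equispaced gantry
angles, a 20×20 beamlet array per beam — scaled to give realistic-looking
gradients on 2–4 mm voxels. An optional density field converts geometric to
radiological depth via a midpoint-rule line integral (24 samples). There is
no divergence, scatter modeling, or machine model; deliverability and
beam-on time are out of scope, with the total beamlet weight reported as a
crude comparability proxy between the two modes' simulation plans.

## Optimizer

Fluence-map optimization is projected gradient descent over `w ≥ 0` with
Barzilai–Borwein spectral steps safeguarded by Armijo backtracking. The
backtracking guarantees a non-increasing objective trace by construction —
an invariant the tests rely on. Initialization is uniform weights scaled so
the mean target dose equals `D₀`, making the solver fully deterministic
(bit-identical results for identical inputs; no seed enters the solver).
Termination: the relative objective decrease must stay below the tolerance
(default 1e-6) on three consecutive iterations — BB steps make single
decreases oscillate, so one quiet iteration is not a convergence signal —
or the iteration cap (default 500) is reached.

The adaptive step freezes the objective parameters chosen at simulation and
re-optimizes against each fraction's anatomy. In grouped mode the grouped
mask is *rebuilt from the fraction anatomy* before every re-optimization —
parameters frozen, geometry fresh — and the plan records which anatomy the
mask came from. Passing a fraction anatomy that already contains a grouped
structure is rejected, precisely to prevent a stale simulation-day mask
from leaking into an adapted plan.

## Constraints and normalization

The constraint set mirrors standard pancreatic practice: each primary OAR
< 0.5 cm³ at 45 Gy; spinal cord hard maximum 40 Gy (the "0 cm³ at 40 Gy"
reading); paired kidneys (one unioned mask) D50% ≤ 15 Gy. Before any
comparison, every plan is normalized by a single multiplicative dose scale
until the *first* constraint is met with equality — implemented as the
minimum of limit/metric over the constraint set, which is the unique global
scaling at which one constraint binds and none is exceeded (all metrics are
homogeneous of degree 1 in dose). D0.5cc and D50% use linear interpolation
between sorted voxel doses on the exact (unbinned) DVH. Normalization of a
zero-dose plan is undefined and raises.

Coverage metrics are the study's three: PTV D95, PTV D100 and PTV-OPT D95 —
the percentage of the structure receiving ≥ 95%/100% of the prescription.
The prescription dose is a required configuration input (default 50 Gy);
the clinical cohort's prescription is not part of what this package
reproduces. In the comparison report, ties count as "not improved".

## Synthetic phantoms and deformation

Phantoms emulate the cohort geometry: a central ellipsoidal PTV of the
requested volume (default the cohort mean 160.5 cm³; requests outside the
cohort range 57.7–356.3 cm³ are refused unless explicitly allowed),
stomach and small bowel abutting it, the duodenum hugging its right side,
the large bowel passing nearby, the cord posterior and kidneys
posterolateral, with seeded jitter of positions (±5 mm), sizes (±8%) and
PTV aspect ratio (volume preserved analytically, so the rasterized volume
stays within a few percent of the request at 4 mm voxels). Primary organs
are clipped against the cord/kidneys so those never overlap.

Inter-fraction change is per-organ rigid translation (uniform within
±8 mm per axis by default, rounded to whole voxels), morphological volume
scaling (factor uniform within ±15%) realized as an exact voxel-count
adjustment — voxels ranked by signed Euclidean distance to the organ
boundary, ties broken by flat index — plus an optional smooth random
displacement field (Gaussian-filtered noise, 25 mm correlation length,
off by default). The kidneys translate at half range without volume
change; the cord is fixed; the PTV contour is held constant across
fractions, as in the clinical workflow being emulated. The ±8 mm / ±15%
defaults are plausible abdominal inter-fraction magnitudes chosen once as
the study conditions; no cohort deformation statistics exist to estimate
them from.

Conventional weighting in generated objective specs is distance-informed,
as planners in practice weight organs largely by proximity: ω = 60 for
organs within 5 mm of the PTV at simulation, 25 inside the 30 mm ring, 4
beyond it (equal-weight variant: 40 everywhere); u = 2, T = 35 Gy for all
primary organs; target ω_lt = 60, ω_ut = 8, powers 2, offset 0.

Two scripted scenarios bracket the method's behavior:

- **Mismatch** (`scenario_mismatch`): the large bowel sits beyond the ring
  at simulation (hence ω = 4) and adjacent to the PTV (≤ 5 mm, pressing
  into its margin) at the fraction. The conventional re-optimized plan
  overdoses it; normalization then drags the whole plan down and PTV D100
  collapses, while the grouped objective — whose mask is rebuilt daily —
  penalizes the newly adjacent portion at full weight and keeps coverage.
- **Comparable** (`scenario_equal_weights`): four compact disjoint organs
  entirely inside the ring with equal weights; the two objectives are the
  same function and the two modes' plans coincide bit for bit.

## What the synthetic study does and does not show

Passing tests demonstrate the *mechanism*: the algebraic equivalence in the
comparable regime, and the directional benefit of grouping under weighting
mismatch, on anatomies whose deformations are simple rigid-plus-scaling
motions of smooth shapes. They do not reproduce any clinical cohort's
coverage statistics: real anatomy has sliding organ interfaces, gas and
filling changes, correlated multi-organ motion and planner-tuned
objectives, none of which the generator models. Reported improvement
percentages from the pipeline characterize this sandbox, not patients.

## Problem sizes

Default study grids are 64³ voxels at 4 mm (unit tests use 24³–32³ at
8–10 mm); the bundled acceptance script runs two synthetic patients × five
fractions plus five mismatch seeds on the 64³ default. These sizes were
chosen so a full run completes in minutes on a laptop while keeping ≥ 2
voxels across every organ's thinnest dimension.

## Known limitations

- The penalty form (sum vs mean, normalization conventions) of commercial
  systems is proprietary; the form here is declared, not reverse-engineered.
- Parallel-beam, homogeneous-medium dose with a Gaussian penumbra; no
  heterogeneity corrections beyond the optional density scaling.
- Normalization is a pure dose rescaling; re-optimizing to the constraint
  instead would be a different (nonlinear) operation.
- Whole-voxel DVHs: metrics on structures of a few voxels are coarse.
- The deformation model preserves topology and cannot create the
  appearance/disappearance of gas pockets or drastic re-folding of bowel.
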