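# oargroup

**Organ-at-risk grouping for daily adaptive radiotherapy planning — a
property-tested IMRT planning sandbox.**

In daily adaptive radiotherapy of pancreatic cancer, the plan objective
built at simulation is re-used to re-optimize the plan on each treatment
day's anatomy. Four gastrointestinal organs at risk (OARs) — stomach,
duodenum, small bowel, large bowel — surround the target and share one dose
constraint (< 0.5 cm³ at 45 Gy), yet conventionally each carries its own
weighting parameters `{ω, u, T}`, tuned largely by the organ's proximity to
the planning target volume (PTV) *on simulation day*. When the anatomy
shifts, those frozen weights can badly misrepresent the new geometry: a
down-weighted organ that drifts against the target gets overdosed on
re-optimization, and once the plan is normalized back under the organ's
dose limit, target coverage collapses.

`oargroup` implements and stress-tests the grouping alternative: replace
the four organs' separate penalty terms with **one term on the grouped
structure** — the union of their portions within 3 cm of the PTV, rebuilt
fresh from each day's anatomy. The conventional objective

```
f_total(D|θ) = Σᵢ₌₁..k f_ci(D|θᵢ) + f_t(D|θ_t) + Σⱼ₌₁..l f_rOAR(D|θⱼ)
```

becomes

```
f_total(D|θ) = f_c(D|θ_c) + f_t(D|θ_t) + Σⱼ₌₁..l f_rOAR(D|θⱼ)
```

cutting the tunable primary-OAR parameters from 12 to 3 (a factor of four)
while leaving the remaining-OAR terms (spinal cord, kidneys) untouched.
Each OAR term is a one-sided power penalty `Σ_v v_vox·ω·max(0, D_v − T)^u`;
the target term penalizes deviation from the pivot `D₀ + offset` with
separate lower/upper importances and powers. Because the terms are
volume-weighted *sums*, the grouped objective is an exact algebraic rewrite
of the conventional one whenever the organs are disjoint, lie inside the
ring and share parameters — the package asserts this to 1e-10.

Everything runs on synthetic, seeded phantoms (no clinical data are used or
required): ellipsoid/tube organs around a PTV of cohort-realistic volume,
deformed between fractions by rigid translation, exact-volume morphological
scaling and optional smooth warps. A toy parallel-beam beamlet dose engine
supplies the linear dose map; plans are optimized by monotone projected
gradient descent and normalized to the shared constraint set before every
comparison. Intended users: medical-physics researchers and students who
want a transparent, fully reproducible environment for adaptive-planning
objective design, not a clinical system.

## Worked example: the weighting-mismatch mechanism

```python
from oargroup import (BeamConfig, adapt_plan, build_influence, coverage_at,
                      pancreatic_constraints, scenario_mismatch)

# simulation day: large bowel far from the target and down-weighted;
# treatment day: it now presses against the PTV
sim, fraction, conv_spec, grouped_spec = scenario_mismatch(seed=7)
influence = build_influence(sim.grid, BeamConfig())
constraints = pancreatic_constraints()

for name, params in conv_spec.primary_oar_bindings:
    print(f"{name:<12} importance = {params.importance}")

for label, spec in (("conventional", conv_spec), ("grouped", grouped_spec)):
    plan = adapt_plan(spec, fraction, influence)   # frozen spec, fresh anatomy
    norm = plan.normalize(constraints)
    d95 = coverage_at(norm.dose, fraction.target, 0.95, 50.0)
    d100 = coverage_at(norm.dose, fraction.target, 1.0, 50.0)
    print(f"{label:<12} scale={norm.scale:.3f} binds {norm.binding_constraint.structure:<12}"
          f" PTV D95={d95:5.1f}%  D100={d100:5.1f}%")
```

prints

```
stomach      importance = 60.0
duodenum     importance = 60.0
small_bowel  importance = 60.0
large_bowel  importance = 4.0
conventional scale=0.896 binds large_bowel  PTV D95=  1.3%  D100=  0.0%
grouped      scale=1.001 binds large_bowel  PTV D95= 92.1%  D100= 68.5%
```

Read: at the fraction, the conventional re-optimized plan overdoses the
(still down-weighted) large bowel, so normalization must scale the whole
dose field by 0.896 to pull its D0.5cc back to 45 Gy — and target coverage
collapses. The grouped objective rebuilt its mask from the day's anatomy,
penalized the newly adjacent bowel portion at full weight, and keeps 92%
of the PTV at the 95% isodose. In the opposite regime — equal conventional
weights, all OAR voxels inside the ring (`scenario_equal_weights`) — the
two modes produce bit-identical plans, so grouping costs nothing when the
conventional weighting already approximates it.

## Command-line pipeline

```
oargroup run-all --config study.yaml --seed 11 --outdir out/
```

runs phantom generation → simulation planning (both modes, one shared
influence matrix) → per-fraction deformation, frozen-objective
re-optimization and normalization → the coverage comparison report
(`report.csv` / `report.json`: per-fraction PTV D95, PTV D100, PTV-OPT D95
for both modes, fraction-improved percentages and difference statistics).
The steps are also available individually (`make-phantom`, `plan`, `adapt`,
`report`). Identical seeds reproduce every output byte for byte.

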