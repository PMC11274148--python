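# dissectwall

Hemodynamic and geometric assessment of **residual type B aortic dissection**,
built on fully synthetic, analytically driven surrogates.

After a type A dissection is repaired, many patients are left with a residual
dissection of the descending aorta: the intimal flap divides the vessel into
the original **true lumen (TL)** and a newly formed **false lumen (FL)** that
communicate through an entry tear. A fraction of these aortas degenerate into
aneurysms, and wall shear stress (WSS), lumen geometry, flow partition and
inter-lumen pressure are the candidate markers for predicting who. This
package re-creates that assessment pipeline — normally run on patient CT
reconstructions and a transient CFD solver — as reusable, tested code driven
by a synthetic cohort generator, so every stage can be exercised and verified
without clinical data or a flow solver.

## What it computes

**Wall descriptors** (per vertex of a labeled surface, from one cycle of WSS
vectors τ(t), period T):

    TAWSS = (1/T) ∫ |τ| dt
    OSI   = ½ (1 − |∫ τ dt| / ∫ |τ| dt)          ∈ [0, ½]
    RRT   = [(1 − 2·OSI) · TAWSS]⁻¹

with area-weighted regional summaries (TL, FL, tear margin, …) and the
tear-margin statistic *peak TAWSS × entry-tear perimeter* (Pa·mm).

**Pulsatile flow surrogate**: the Womersley solution in a rigid tube. A
periodic flow waveform Q(t) is decomposed into harmonics Qₙ; each drives

    uₙ(r) = (Qₙ/πR²) · (1 − J₀(ζ r/R)/J₀(ζ)) / g(ζ),   ζ = i^{3/2} αₙ,
    g(ζ)  = 1 − 2 J₁(ζ)/(ζ J₀(ζ)),                      αₙ = R√(nω/ν),

with wall shear τₙ = −μQₙ/(πR³) · ζJ₁(ζ)/(J₀(ζ) g) from the analytic
derivative (the n = 0 term is Poiseuille, 4μQ/πR³). Flow-regime screening
computes Womersley/Strouhal numbers, the peak Reynolds number and a critical
Reynolds number Re_crit = 169 α^0.83 St^−0.27 (pluggable correlation).

**Geometry**: centerline tortuosity (arc/chord), cross-section TL/FL areas by
plane-slicing the labeled surface, the TL/DA area ratio averaged over three
surveillance planes, circle-equivalent tear area/perimeter, and rapid-growth
classification (≥ 3 mm/yr at any plane).

**Flow & pressure**: FL flow fraction at the systolic peak, the 55%/45%
area-weighted outflow split between the descending aorta and arch branches,
and FL−TL pressure profiles at systolic peak / deceleration / diastole.

**Cohort statistics**: Shapiro–Wilk-gated t or Mann–Whitney comparisons,
Fisher's exact test by full hypergeometric enumeration, Pearson correlation,
and two-group summary tables with outcome rates.

**Synthetic cohort**: parameterized dissected-aorta meshes (swept tube, planar
zero-thickness flap, elliptical tear with labeled rim, arch branches),
Womersley-driven WSS/pressure fields with a controllable FL disturbance, and
22-patient cohorts with configurable group effects. Everything is
reproducible from one seed.

## Worked example

```python
from dissectwall import *

params = DissectionParams(seed=1)                     # one synthetic patient
mesh, centerline, tear = build_dissected_geometry(params)
wss, planes = synthesize_fields(mesh, FlowWaveform.default(),
                                FluidProperties(), params, centerline=centerline)
hwd = compute_hwd(wss)
print(round(tl_da_ratio(mesh, centerline), 3),       # 0.42
      round(fl_flow_fraction(planes), 1),            # 55.0
      round(tear_margin_tawss(hwd, tear, mesh), 1))  # 534.0
```

`0.42` is the true-lumen share of the descending cross-section (the generator
was asked for 0.42 and the slicer recovers it), `55.0` is the percentage of
descending flow entering the false lumen at the systolic peak, and `534.0`
Pa·mm is the peak tear-margin TAWSS distributed over the tear perimeter.
The same pipeline is available from the shell:

```bash
dissectwall generate --seed 1 --out out/        # cohort.csv, mesh, fields, plots
dissectwall stats out/cohort.csv --report out/report/
dissectwall meshcheck study.csv --tolerance 2
```

`dissectwall stats` prints, for a default seed-1 cohort:
`n = 22; re-intervention 36%, death 27%` and writes the group, subgroup and
mortality tables.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch at the given seed — patient
geometry and fields, wall descriptors, flow partition, inlet flow-regime
screening, a 22-patient cohort with its statistical report, and the
mesh-sensitivity/CFL utilities — prints a JSON summary and writes the results
file.
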