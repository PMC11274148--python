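# Methods

## Model and scope

The package treats the post-repair dissected aorta as a rigid-walled lumen
carrying incompressible Newtonian blood (ρ = 1060 kg/m³, μ = 0.00319 Pa·s,
defaults of `FluidProperties`). The transient three-dimensional flow solve is
replaced by the analytic Womersley solution in a straight rigid tube, applied
per lumen with an effective radius and a configured flow share. That choice
gives exact, testable wall-shear and pressure-gradient references at the cost
of all secondary-flow physics (jets, recirculation, helicity); the package is
therefore a verification and methods artifact, not a CFD replacement.

## Pulsatile flow

A periodic waveform Q(t) (default: packaged 0.8 s cycle, peak 2.9·10⁻⁴ m³/s,
mean ≈ 6·10⁻⁵ m³/s, a systolic sin^1.5 pulse with a dicrotic notch) is
Fourier-decomposed; each harmonic drives the classical profile with
ζ = i^{3/2}αₙ. Numerical notes:

- Wall shear and pressure gradient use the analytic J₁-based expressions;
  their ζ→0 limits reproduce Poiseuille exactly (g(ζ) → −ζ²/8).
- For |ζ| > 600, where scipy's Bessel evaluation would overflow, the
  large-argument asymptotics J₀(ζx)/J₀(ζ) → x^{−1/2}e^{iζ(1−x)} and
  J₁/J₀ → i are substituted, so extreme Womersley numbers degrade gracefully
  instead of returning NaN.
- The default field synthesis keeps 16 harmonics: the truncated inflow then
  stays within 1% of the raw waveform at every sample, which is the
  mass-conservation tolerance asserted for plane fluxes.

Flow-regime screening: α = (D/2)√(ω/ν), Re_peak = ρU_peak D/μ, St = fD/U with
U the **peak** velocity by default, and Re_crit = 169 α^0.83 St^−0.27. With a
mean-velocity Strouhal number the same correlation lands near Re_crit ≈ 3200
at physiologic α and would misclassify normal aortic inflow as supercritical;
the peak-velocity choice reproduces the expected 4400–5500 critical range and
the subcritical finding for inlet diameters of 2–3.5 cm. Both the
characteristic velocity and the correlation are arguments.

## Wall descriptors

TAWSS, OSI and RRT use the standard definitions (README) with periodic
trapezoid integration (the wrap-around sample is appended). Vertices whose
shear magnitude integrates to zero get OSI = 0 and infinite RRT; denominators
within 10⁻¹² of zero (relative) are treated as full reversal, also infinite
RRT. Regional summaries weight vertices by one third of their incident
triangle areas; empty regions are omitted rather than reported as zero. The
tear statistic defaults to *peak TAWSS over the rim × circle-equivalent
perimeter*; a rim line-integral ∮TAWSS dl is available as `method=
"line_integral"` since the published construct is ambiguous between the two.

## Geometry metrics

- Tortuosity is the arc/chord ratio of the supplied centerline. The generator
  returns the **descending (dissected) vessel** centerline, so an unperturbed
  tube scores exactly 1.0; whole-aorta tortuosity would carry a constant
  arch-dependent offset that is uninformative for a fixed synthetic trunk.
- Cross-sections slice the labeled surface with the plane normal to the
  centerline; the outer-wall trace is chained into a closed polygon via
  shared-edge keys, the flap trace supplies a chord whose endpoints are
  inserted on the polygon edges, and the two arc+chord sub-polygons partition
  the total area exactly (shoelace). Vertices lying exactly on the plane are
  nudged by 10⁻⁹ of the coordinate span to keep crossings strict.
- Tear area is circle-equivalent with d = (h+w)/2 — exact when h = w, and
  within ~15% of the ellipse formula (also provided) at reported aspect
  ratios.
- Growth rate is the two-point endpoint slope per surveillance plane;
  "rapid" means ≥ 3 mm/yr (inclusive) at any plane.

## Synthetic generator: what it emulates, and what it does not

Geometry: ascending limb (70 mm, radius 15 mm), semicircular arch (radius
40 mm) blending to the descending radius, 220 mm descending limb with an
optional sinusoidal perturbation (amplitude A ≈ (λ/π)√(τ−1) targets
tortuosity τ), planar zero-thickness flap covering the descending length
minus 15 mm margins at the area fraction requested, an elliptical tear
through the flap with its rim labeled as a single closed polyline, and three
abutting branch tubes on the arch. The flap seam meets the wall on the
analytic circle rather than on polygon vertices (snapping would quantize the
TL fraction by ~3%); the resulting seam gap is below the polygon sagitta.
Branch tubes are not boolean-united with the trunk — watertightness holds per
component (no edge bounds more than two triangles), which is sufficient for
every metric computed here.

Fields: TL vertices carry the TL-share Womersley wall-shear magnitude along
the local axial tangent; FL vertices are phase-lagged, attenuated and given a
diastolic sign-reversing component so FL OSI exceeds TL OSI by construction
(setting `fl_oscillation=0` with zero noise yields OSI = 0 everywhere — a
test anchor). Tear-margin vertices carry an amplified copy of the
descending-lumen magnitude: amplification = 30·(A_tear/150 mm²)^0.3·(FL
share/0.55), a surrogate chosen to mirror the reported direction of the
group contrasts (larger tears and higher FL flow → higher margin TAWSS); it
is not asserted as jet physics. Gaussian noise (default sd 0.05 Pa) is
projected onto the tangent plane. Plane pressures integrate the TL Womersley
pressure gradient from a 100 mmHg reference; the FL plane pressure is the TL
pressure plus a configurable offset (default: ≈ −80 Pa at systolic peak,
≈ +40 Pa in diastole, mimicking the commonly observed diastolic FL
pressurization). Plane fluxes split the descending inflow by the configured
share at every sample, so TL+FL mass conservation is exact by construction.

Cohort: features are drawn per group from the published summary
distributions (means/sds of the two-group and subgroup tables), truncated at
±3 sd and physical bounds; the tear-area/FL-flow pair is drawn with a 0.55
correlation imposed on the censored deviate (so truncation does not dilute
it). Outcome flags follow a deterministic risk score
1.2·(FL flow/100) + 0.8·(tortuosity−1) + 0.25·ln(tear area/100 mm²) with
thresholds 1.234 (re-intervention) and 1.289 (death), calibrated once so the
default cohort reproduces 41%/36% outcome rates in expectation. Subgroups are
outcome-defined (adverse = death among stable-size patients); their feature
contrasts are emergent through the score, not separately drawn. Hemodynamic
features are computed through the Womersley surrogate at each patient's drawn
geometry, not sampled from the tables.

A green test on this generator therefore establishes that the *post-
processing* is correct and that the *stated* cohort effects are recovered; it
says nothing about patient-specific flow structures, flap motion, thrombus,
or imaging error, none of which are modeled.

## Numerical and design choices

- Integration grids: 64 time samples per cycle (open, uniform); descriptors
  require ≥ 8 samples and reject NaN with the offending vertex index.
- Mesh resolution defaults: 64 circumferential vertices (polygon area deficit
  0.16%, inside the 0.5% section-area tolerance), 3 mm ring spacing.
- Mesh-sensitivity acceptance requires BOTH mean and max WSS within the
  tolerance (default 2%) of the finest mesh; the finest always qualifies, so
  the warn-and-return-finest path only triggers for infeasible tolerances.
- CFL helper reports dt = C·h/u and whether it falls in the 0.5–2 ms band.
- Statistics: normality gate at α = 0.05 per group; the only transformation
  attempted is the natural log (positive data), then Mann–Whitney (exact for
  tie-free samples with n ≤ 10 per group, otherwise tie-corrected normal
  approximation). Constant samples skip the gate with a warning. No
  multiple-testing correction, matching per-variable clinical reporting.
- The cardiac cycle is 0.8 s; a "76 bpm" label would be inconsistent with it
  and is not used anywhere (0.8 s ⇒ 75 bpm).

## Known limitations

- Two-sample power at the default TL/DA group effect (Δ = 0.13, sd
  0.11–0.12, n = 11/11) is ≈ 0.71–0.75 by the noncentral-t closed form; the
  generator cannot exceed that, so detection of this effect in a single
  22-patient cohort fails ~27% of the time — inherent to the stated sample
  size, not a defect.
- Realized mesh tortuosity saturates near 1.40 (amplitude capped to keep the
  centerline bend radius above the tube radius); cohort records carry the
  drawn "measured" tortuosity, which may exceed what the mesh realizes.
- Re-entry tears are a recorded count only; they are not carved into the
  flap, and the re-entry flow path is not modeled.
- Branch WSS uses the TL series for simplicity; branch-specific Womersley
  solutions would change nothing tested here.
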