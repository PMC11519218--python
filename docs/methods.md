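# Methods

This note documents the models, numerical choices and calibrations behind
`tibiafit`, in the spirit of a package methods appendix. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Population model

Cohorts are sex-stratified Bernoulli draws (default female fraction
137/319). Within a sex, body height and the ground-truth resection area are
coupled by a Gaussian copula: a latent bivariate standard normal with
correlation ρ is pushed through the inverse CDFs of the two marginals.

| quantity | model | female | male |
|---|---|---|---|
| height [cm] | trunc. normal | 165 ± 8.5, range [146, 180] | 180 ± 10.25, range [162, 203] |
| area [mm²] | trunc. normal | 1064.0 ± 102.9, range [810.3, 1335.3] | 1341.2 ± 153.0, range [997.3, 1856.7] |
| latent ρ | copula corr. | 0.49 | 0.42 |
| BMI [kg/m²] | trunc. normal, indep. | 23.4 ± 7.5 | 23.7 ± 5.8 |
| age [y] | trunc. normal, indep. | 54 ± 16.5 | 43.5 ± 18.25 |

Centres are the reference medians (means for area); where only a range is
published the spread is one quarter of the range width; truncation is at the
published observed range. Weight is derived from BMI and height so the BMI
identity holds exactly; BMI deliberately does not drive anatomy (in the
reference data the resection area is essentially unrelated to BMI).

Two modelling points deserve emphasis:

* **Truncation at the observed ranges** (rather than a symmetric ±3 SD cut)
  matters: the reference population contains no male resection below
  997.3 mm², and the qualitative selection result "size 1 occurs only in
  women" is reachable only if the male area support respects that floor.
  The truncation shifts the realized male mean by ≈ +5 mm² and shrinks the
  SD by ≈ 4%, both inside the validation tolerances.
* **Latent ρ = printed r.** With these marginals the copula's realized
  Pearson correlation is attenuated only mildly (Monte-Carlo: 0.487 at
  ρ = 0.49; 0.417 at ρ = 0.42), well inside the ±0.03 acceptance band, so
  no compensation of the latent correlation is applied.

## Synthetic anatomy

The generator is contour-first. The resection-level cross-section is built
in a unit frame and then scaled:

1. an ellipse of medio-lateral/antero-posterior aspect 1.35, narrowed
   posteriorly by a linear taper (25% at the posterior pole) — the rounded
   trapezoid of a distal tibia;
2. low-order radial Fourier perturbations (harmonics 2–6, relative scale
   0.008, random amplitudes/phases per subject) — individual shape
   variability;
3. a straight anterior chord spanning 45% of the half-width — the anterior
   cortical flat that the ventral prosthetic shield must parallel;
4. isotropic rescaling so the dense-polygon (2048-vertex shoelace) area
   equals the subject's target area exactly; `true_area` records it;
5. a radial Gaussian bump at the medial pole (amplitude 0.95 mm ± 35%,
   angular half-width 0.20 rad ± 35%) — the base of the medial malleolus.
   Three margin points are placed where the bump crosses the medial tangent
   line of the bump-free contour, at three z levels, emulating margins
   transferred from three coronal sections. The bump adds ≈ 3–5 mm² of
   bone that is excluded from the implantable region.

The 3D surface stacks z-scaled copies of this contour: cylindrical (scale
1) in a band around the resection level, then narrowing quadratically to
75% over the shaft (60 mm modelled); distally a concave articular dome
(paraboloid, depth 7 mm) whose apex is a recorded landmark; proximally a
flat cap. Meshes are watertight by construction (128 vertices per ring,
~4.4k triangles). Frame: +z proximal, +y anterior, +x medial (right leg).

Because the wall is exactly cylindrical around the cut, the 4°-inclined
section is the cylinder ellipse: measured area = true_area / cos 4°
(+0.244%), which the validation tolerances absorb. What the generator does
**not** emulate: cortical vs trabecular interior, osteophytes or joint
defects (the reference study excluded non-intact joints), the fibula,
left/right asymmetry, and realistic inter-subject variation of aspect ratio
or flat width (these are fixed family constants so that footprint congruence
is meaningful). Passing tests therefore validate the pipeline's geometry and
statistics, not its robustness to pathological anatomy.

## Resection geometry

The plane origin is the apex displaced `proximal_offset` (default 2 mm)
along the shaft axis; the normal is the shaft axis rotated by
`posterior_inclination` (default 4°) about the medial axis, with the sign
convention that points posterior of the origin lie more distal (posterior
slope). In-plane frame: u = medial projected into the plane, v = normal × u
(anterior). Triangle–plane intersection segments are chained into loops
with endpoint matching at 1e-6 mm (KD-tree radius merge, robust to
floating-point jitter); zero loops is an error, more than one loop is an
error — never silently resolved. The loop is projected to (u, v), oriented
CCW and resampled to 256 equal-arc-length points.

The anterior flat is detected as the longest run (≥ 10 points) of contour
points with discrete curvature < 0.02 mm⁻¹ and anterior-facing outward
normal, ties broken by lower mean curvature. Sections without such a run
(e.g. analytic cylinders) carry `anterior_arc = None`; they can be measured
but not fitted. The malleolus border is the total-least-squares line through
the three projected margin points; the half-plane medial of it is forbidden
for implant coverage.

## Area measurement

Periodic cubic interpolating spline (chord-length parameterization,
C² closure) through the contour points; area by Green's theorem on a
uniform 2048-node grid. Convergence: halving/doubling the node count moves
the area by < 0.01%; against dense-polygon shoelace values the spline area
agrees to < 0.1% on the shape family. Known artifact: at exact right-angle
corners the interpolant overshoots outward (~0.13 mm² per corner on a
10×10 mm square sampled with 32 points, +0.52% total); anatomical contours
have no such corners.

## Implant fitting

The five footprints share the base outline (aspect 1.35, taper 0.25, flat
0.45 — congruent with the anatomy family, as a templating system designed
for this bone would be) scaled isotropically so the spline-integrated area
equals each nominal area (884.40 … 1600.80 mm²) to machine precision.

Placement is deterministic: rotation is fixed to align the shield with the
anterior-flat direction (the ±2° tolerance in the config documents the
acceptance band; the optimizer sets the angle exactly); translation is
searched on a 1 mm grid (±4 mm) then refined at 0.1 mm (±0.5 mm), both in
the shield-aligned frame so the search is exactly equivariant under rigid
motions of the section. Per candidate, polygon booleans (shapely) give

* `overhang` = footprint area − footprint∩bone area,
* `intrusion` = footprint∩bone area medial of the malleolus border,
* `contact` = fraction of the 128 perimeter points within 1.5 mm of the
  cortical contour (side-agnostic: a point counts whether it sits just
  inside or just outside the discretized rim; gross protrusion is already
  capped by the overhang tolerance).

Feasibility requires intrusion = 0 (zero tolerance — the malleolus "must
not be affected") and overhang ≤ 60 mm². The objective is lexicographic:
feasibility, then maximal contact, then minimal overhang. Size selection
runs all five trays and keeps the feasible one with the highest contact;
contacts within 0.01 are ties, resolved toward the larger tray (more
cortical coverage), then the smaller overhang. Infeasibility of all sizes
is a result (`size_id = None`), not an error.

**Why an absolute overhang tolerance of 60 mm².** The reference selections
imply that a resection of 997.3 mm² (the smallest male) received at least
size 2 (1028.6 mm²), i.e. ≥ 31 mm² of tolerated uncovered footprint before
counting the malleolus exclusion (≈ 4 mm²) and shape mismatch. A relative
2% tolerance (≈ 21 mm²) is inconsistent with that. A fixed ≈ 60 mm²
allowance reproduces both the floor case and the reference pattern that
effective size-switch thresholds approach the nominal areas from below as
size grows. With the default calibration the resulting effective thresholds
are ≈ nominal − 52 mm² with ± few mm² per-subject jitter from the bump and
Fourier terms; that jitter is what makes neighbouring per-size area
intervals overlap, as observed in the reference data.

## Statistics

Normality: one-sample KS with estimated parameters, i.e. Lilliefors
(statsmodels implementation, table p-values); decision at α = 0.05,
two-sided throughout. Sex comparison: unpaired two-tailed Student t when
both groups test normal, otherwise the two-sample Mann–Whitney rank-sum
test — a signed-rank test is undefined for independent groups of unequal
size, so the rank-sum test is the nonparametric alternative used here.
Correlation: Pearson when both variables test normal, Spearman otherwise.
Degenerate inputs (constant samples, n below the test minimum) raise typed
errors rather than returning silent NaNs; the report builder records them
as notes.

## Reproducibility and problem sizes

Every stage is deterministic given (config, seed): cohort draws, per-subject
anatomy seeds (spawned from the master seed) and the grid-based placement.
`run_pipeline` hashes all outputs into a manifest; reruns are byte-identical.

Validation problem sizes: single cohorts at the reference sizes (137 F /
182 M / 319 total) for mean/SD recovery and selection structure; 50
replicate cohorts per sex for the correlation targets (the per-cohort
Pearson r has SD ≈ 0.067, so the mean over 50 replicates resolves the
±0.03 band comfortably); 20 000 draws for marginal calibration checks;
analytic cylinders (r = 10–20 mm, 0–10° inclination) for the slicing
oracle.

## Known limitations

* The footprint outline is a stylized stand-in constrained only by the five
  nominal areas and the straight-shield feature; real tray outlines differ,
  so absolute per-size counts are not comparable to the reference study —
  only the qualitative structure is claimed.
* Strictly 2D: no keel/stem, no talar component, no density weighting.
* Apex and malleolus margins are required landmark inputs for imported
  meshes; the package does not detect them from raw geometry.
* The placement search is a translation grid; its 0.1 mm refinement bounds
  the placement precision, which is ample for size selection but not for
  sub-0.1 mm positioning studies.
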