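# Methods

`ektopo` models the optics of the cornea after endothelial keratoplasty
(EK) well enough to reproduce, on synthetic cohorts, the group-level
topographic findings reported for DMEK and DSAEK eyes: Zernike aberration
profiles of the anterior, posterior and total cornea; an automated 0–5
color grade of the posterior refractive power (PRP) map; and the
correlation structure linking both to visual acuity. This note records the
models, the numerical choices, and what the synthetic cohorts can and
cannot show.

## Surface model and optical path difference

A cornea is two refracting surfaces on a shared Cartesian grid (default
0.05 mm spacing, 7 × 7 mm extent, vertex on a sample). Each surface is a
vertex-referenced sag map z(x, y) in µm, positive toward the retina. The
wavefront contribution of a surface is taken in the thin-phase (paraxial)
approximation,

    OPD(x, y) = Δn · z(x, y),

with Δn = 1.376 − 1.000 = 0.376 for the anterior surface and
Δn = 1.336 − 1.376 = −0.040 for the posterior surface (stroma 1.376,
aqueous 1.336). The total corneal OPD is the pointwise sum — additivity is
a contract of this package, not a claim about any device's ray tracer. The
thin-phase error is O(slope²); it changes coefficient values relative to a
full ray trace but not the algebraic structure (linearity, rotation
behavior, zone scaling) that the metrics rely on. Corneal thickness is
carried for reporting but does not enter the OPD.

## Zernike analysis

OPD maps are expanded in RMS-normalized (OSA/ANSI) Zernike polynomials
through radial order 8 (45 terms), single index j = (n(n+2)+m)/2, by
ordinary least squares over the valid in-pupil samples; no regularization,
and maps with fewer than 10 samples per coefficient are rejected rather
than smoothed. With the RMS normalization the root-sum-square of
coefficients equals the wavefront RMS, which is what the summary metrics
presuppose:

* **HOA** = RMS of all coefficients with 3 ≤ n ≤ 8 (j = 6..44),
* **SA** = RMS of Z(4,0) and Z(6,0),
* **Coma** = RMS of Z(3,−1) and Z(3,1),

each evaluated for anterior, posterior and total OPD over the 4.0- and
6.0-mm zones. Piston, tilt and defocus are fit but excluded from every
metric, so no reference-sphere subtraction is needed. Orthonormality of
the implemented basis is checked numerically (`zernike.gram_matrix`,
pixel-center quadrature with fractional-area weights at the rim;
off-diagonal < 1e−3 at 512² sampling).

## Posterior power map and color grade

The posterior axial (sagittal) radius is computed on the grid from the
radial slope, R_a = r·√(1+z′²)/z′ (z in mm), with the vertex limit taken
from a local quadratic fit; the instantaneous (tangential) radius is
available as an option but axial is the default, matching clinical axial
maps. Posterior refractive power is PRP = (1.336 − 1.376)/R_a in diopters
(negative; a 6.349-mm sphere gives −6.30 D, a 5.797-mm sphere −6.90 D).

The device color scale is reduced to four bands: cool above the yellow
band, a yellow band of width 0.3 D centered at −6.3 D (the printed scale
places yellow at exactly −6.3 D; a measure-zero band cannot classify
area), orange between yellow and −6.9 D, red below −6.9 D. Both the zone
(6 mm, matching the aberration zone) and the band parameters are
configurable.

The 0–5 grade is a monotone decision rule over the zone's band
composition:

* red fraction ≥ 3/4 → **5** (red background),
* red fraction ≥ 1/2 → **4**,
* red fraction ≥ 1/4 → **3** (boundaries closed on the higher grade),
* otherwise the band of the area-median PRP value: cool → **0**,
  yellow → **1**, orange → **2**.

"Background" is thus read as the color of the area-median sample rather
than the modal band. On typical corneal maps (radially monotone power
profiles) the two coincide; they differ on contrived compositions, where
the modal reading is not monotone: steepening a map everywhere can shrink
the orange area into red while the yellow area grows, flipping the modal
band cooler and lowering the grade — we observed exactly this on
randomized maps. The median reading cannot do that: a uniform negative
PRP offset moves every sample warmer, so the red fraction and the warmth
of the median band are both non-decreasing, and the grade never falls.
The red-fraction tiers extend the published orange-background rules to
maps whose residual background is not orange, a case the published
definitions leave open. All published worked examples (uniform cool map →
0, uniform red map → 5, orange map with 35 % red → 3) are unchanged.
Known quirk: ring-shaped steepening at extreme amplitudes can park a map
at a tier boundary; grades remain monotone in uniform offsets but not
formally in every conceivable shape parameter.

## Synthetic cohorts

No patient-level data are available, so the package ships a seeded
generator whose three arms emulate the study groups. All distributions
below are artifact constructs — declared, not measured.

* **Geometry.** Both surfaces are conicoids with per-eye Gaussian apical
  radii and asphericities. Higher-order irregularity is added as a random
  Zernike combination over orders 3–8 (coma-dominant weight profile, a
  deliberate Z(4,0) share, 1/n² decay over orders 5–8), scaled per surface
  so the OPD-domain HOA matches the group target; per-eye amplitude is
  log-normal.
* **DMEK** adds a central stromal-dehydration feature: the central zone
  deturgesces first, displacing the central posterior surface anteriorly
  relative to the edematous periphery; the curvature change concentrates
  in a raised-cosine annulus at the zone margin. A separate, decaying
  global posterior steepening models residual early-postoperative edema —
  without it the 1-month background is too cool to reach the observed
  grade ≈ 2.3.
* **DSAEK** adds a meniscus-shaped lenticule (donor stroma), thickest
  centrally and tapering to the graft edge, protruding into the anterior
  chamber — central posterior power steepens into orange/red for any
  positive amplitude.
* **Longitudinal structure.** Each eye draws its latents once;
  timepoints reuse them with multiplicative decay factors in (0, 1]
  (separate factors for bump amplitude, HOA scale, anterior asphericity
  shift, posterior steepening), so per-eye recovery is monotone.
  Preoperative edema is modelled as the undecayed state plus elevated
  central thickness (714/759 µm group means).
* **Visual acuity.** Postoperative and control BSCVA responds linearly to
  the *computed* grade and total 6-mm HOA:
  bscva = max(−0.08, −0.255 + 0.13·grade + 0.12·HOA + N(0, 0.21)) logMAR.
  Preoperative BSCVA of surgical eyes is drawn directly from the group
  distribution: preoperative acuity is edema-dominated and outside the
  topographic response model.

Determinism: a cohort is a pure function of (config, seed), via per-eye
spawned seed sequences; re-running a study reproduces byte-identical
tables.

### Calibration

Preset parameters were tuned once against the published group-level
summaries — control grade 0.44, DMEK grades 2.3/1.4/1.2 and DSAEK
4.4/3.6/2.8 at 1/3/6 months, total 6-mm SA 0.13/0.19/0.34 µm
(control / DMEK 6 m / DSAEK 6 m), DMEK 6-month BSCVA 0.03 logMAR, pooled
postoperative BSCVA–grade correlation 0.664 — by iterating
`scripts/calibrate.py`, which prints measured cohort means next to the
targets. The tuned values are frozen in `ektopo.synthetic`; the anterior
and posterior Q values in particular absorb the offset between thin-phase
OPD and device ray tracing and should not be read as anatomical
asphericities. Group summaries are recovered at n = 200 eyes/group
(standard errors a few percent of the means); the shipped default study
uses the original 18/19/23 group sizes.

### What the synthetic cohorts do not show

The generator reproduces group-level means, orderings and correlations of
the postoperative study; it does not model graft detachment, rebubbling,
endothelial-cell dynamics, interface haze or forward scattering, and its
preoperative aberration magnitudes overshoot the printed preoperative
rows (preoperative geometry only seeds the longitudinal decay). Passing
the cohort-level tests therefore demonstrates internal consistency of the
pipeline and faithfulness to the published summaries — not biophysical
fidelity of individual synthetic corneas.

## Statistics

Mann–Whitney U (exact for ≤ 8 per group without ties, otherwise normal
approximation with tie and continuity correction), Wilcoxon signed rank
(zeros dropped; exact for ≤ 12 nonzero differences), Kruskal–Wallis with
tie correction, Pearson chi-square without continuity correction, and
Pearson correlation all delegate to scipy.stats behind typed result
containers. Dunn's multiple-comparison test is implemented here: pairwise
z = (R̄ᵢ − R̄ⱼ)/√((N(N+1)/12 − T)(1/nᵢ + 1/nⱼ)) with tie term
T = Σ(t³−t)/(12(N−1)), two-sided normal p, Bonferroni-multiplied and
capped at 1 (the cap is why published pairwise tables contain entries of
exactly 1.000). Exact-vs-approximate thresholds are declared constants.
Type-I error of the three rank tests is verified at 0.05 ± 0.01 over
5,000 null replicates (n = 20/group).

One printed demographic p-value does not reproduce: the sex-ratio table
(6/12, 4/15, 5/18) gives Pearson chi² = 0.955, p = 0.620, not the printed
0.644 (likelihood-ratio and Yates variants do not give it either); the
eye-laterality table does reproduce (0.516 vs printed 0.513). The Pearson
form is kept and the tests freeze the hand-verified value.

## Numerical choices and degenerate inputs

* Grid: 141 × 141 at 0.05 mm; the 6-mm pupil holds ~11,300 samples, a
  250-fold oversampling of the 45 coefficients. Fit operators
  (pseudo-inverses) are cached per grid/pupil geometry.
* Finite-difference slope error in the axial radius is O(h²)
  (~1.4e−4 mm at the default spacing against the conicoid closed form) —
  negligible against the 0.3 D band width.
* Flat or inverted meridians yield invalid (NaN) radius samples; a zone
  with under 50 % valid samples is rejected, not imputed.
* Band boundaries: red is strict (< −6.9 D), yellow closed on both edges,
  implemented as a gapless nested partition so floating-point boundary
  values classify consistently.
* Red-fraction tiers are closed on the higher grade (exactly 1/4 → 3,
  exactly 1/2 → 4).
* Zero-amplitude bumps return the input surface unchanged; conicoids are
  rejected where the conic is undefined on the grid.

## Limitations

Thin-phase OPD, not ray tracing; additivity of surface OPDs by contract;
grading zone fixed to 6 mm by default (the published grading zone is not
stated); the color scale is absolute, not auto-scaled per eye; pooled
groups only (no FECD/PBK/ALI subgroup parameterization — no subgroup
summaries exist to calibrate against); orders above 8 and whole-eye
optics are out of scope.
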