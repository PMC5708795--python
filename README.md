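# ektopo

Corneal topography analysis after endothelial keratoplasty (DMEK / DSAEK):
Zernike wavefront aberrometry of the anterior, posterior and total cornea,
an automated 0–5 color grade of the posterior refractive power map, and a
calibrated synthetic cohort generator with the accompanying nonparametric
statistics.

## The problem

Eyes can see poorly after endothelial keratoplasty despite a perfectly
clear graft. The optical culprit is the *posterior* corneal surface: a
DSAEK graft adds a meniscus-shaped stromal lenticule that steepens the
central posterior cornea, and even DMEK — which transplants only
Descemet's membrane and endothelium — leaves a centrally dehydrated,
steepened posterior surface during recovery. Both raise higher-order
aberrations and depress best spectacle-corrected visual acuity (BSCVA).
`ektopo` provides the computational toolkit used to quantify this:

* **Zernike aberrometry** (`ektopo.zernike`, `ektopo.wavefront`) —
  elevation maps are converted to optical path difference by the
  thin-phase rule OPD = Δn·z (Δn = 0.376 anterior, −0.040 posterior) and
  expanded in RMS-normalized Zernike polynomials Z_n^m through order 8
  over 4- and 6-mm zones, single index j = (n(n+2)+m)/2. Summary metrics:
  HOA = RMS of orders 3–8, SA = RMS{Z₄⁰, Z₆⁰}, Coma = RMS{Z₃⁻¹, Z₃¹}.
* **Posterior color grading** (`ektopo.grading`) — the posterior axial
  radius map gives PRP = (1.336 − 1.376)/R_a (diopters); the map is
  partitioned into cool / yellow (−6.3 D band) / orange / red (< −6.9 D)
  and scored 0–5 by a monotone rule over the red area fraction (≥ 1/4 → 3,
  ≥ 1/2 → 4, ≥ 3/4 → 5) and the area-median band (cool 0, yellow 1,
  orange 2).
* **Synthetic cohorts** (`ektopo.synthetic`) — seeded generators for
  control, DMEK and DSAEK eyes across pre-op/1/3/6-month visits,
  calibrated so the full map→metrics→grade→acuity pipeline reproduces the
  published group-level summaries.
* **Statistics** (`ektopo.stats`) — Mann–Whitney U, Wilcoxon signed rank,
  Kruskal–Wallis with Dunn's Bonferroni-capped post hoc, Pearson χ², and
  Pearson correlation, with exact small-sample paths.
* **Pipeline & CLI** (`ektopo.pipeline`, `ektopo` command) — a seeded,
  config-driven study runner emitting demographics, aberration and
  correlation tables plus grade trajectories, with lossless CSV round
  trips for every map.

## Worked example

Generate one synthetic DSAEK eye six months after surgery and analyze it:

```python
from ektopo import CohortConfig, sample_cohort, aberration_profile, prp_map, grade

cfg = CohortConfig(sizes={"DSAEK": 1}, seed=7, timepoints={"DSAEK": ("6m",)})
eye = sample_cohort(cfg)[0]

prof = aberration_profile(eye.cornea)          # HOA/SA/Coma x surface x zone
res = grade(prp_map(eye.cornea.posterior))     # posterior color grade
```

Output for this seed:

```
eye DSAEK-001 at 6m: CCT 530 um
total 6 mm:     HOA 0.480  SA 0.375  Coma 0.203 um
posterior 6 mm: HOA 0.232  SA 0.028  Coma 0.192 um
posterior color grade 2 (background orange, red fraction 0.16)
```

Read: this eye's total corneal higher-order RMS at 6 mm is 0.48 µm
(roughly the DSAEK 6-month group mean, vs ≈ 0.2 µm for a healthy cornea),
dominated by spherical aberration from the meniscus-shaped graft; its
posterior power map is orange-backed with 16 % of the zone steeper than
−6.9 D, i.e. grade 2 on the 0–5 scale.

The same grading is available from the shell, for a stored PRP or
elevation map:

```bash
ektopo grade posterior_prp.csv            # -> {"grade": 5, "background_band": "red", ...}
ektopo study --seed 20170 --out report/   # full simulate-analyze-report run
```

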