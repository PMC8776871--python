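# Methods

## Problem and scope

`pltmorph` quantifies the ultrastructure of blood platelets segmented from
electron cryo-tomograms across the development of acute myeloid leukemia
(AML) in a transplant mouse model, and turns the resulting rare
"abnormal mitochondrion" phenotype into a cell-sampling screening design.
The package consumes *label maps* (integer rasters, one label per organelle
instance, plus a label→class table); tomogram reconstruction and the
neural-network segmentation that produces such maps are upstream and out of
scope. Because the study's raw tomograms are not required, a synthetic
scene generator reproduces the cohort statistics, so the entire pipeline is
testable from a clean checkout.

## Morphometry

All measurements follow central-slice conventions:

* **Central slice.** For a 3D label, the z slice at the midpoint of the
  label's z extent, `(z_min + z_max) // 2`. This is deterministic; a
  maximum-area alternative (`rule="max_area"`) is available since a human
  annotator plausibly picks the widest section. For 2D scenes the slice is
  the scene itself.
* **Area.** Pixel count × pixel area (nm²). Platelet-scale areas are also
  reported in 10⁵ nm², the scale used for whole-platelet figures. The
  platelet's own area is measured on the *filled union* of all labels on
  the body's central slice, because organelle labels punch holes in the
  body label on a single raster and the biological quantity is the whole
  cell footprint. Treating the central slice as a stand-in for the study's
  single projection image assumes near-uniform platelet thickness — a
  documented approximation.
* **Perimeter.** Length of the 0.5 iso-contour (marching squares) of the
  mask after Gaussian anti-aliasing with σ = 1.5 px. The raw iso-contour of
  a binary raster overestimates the perimeter of smooth shapes by ≈5%
  independent of resolution, which would bias the circularity of a perfect
  disk to ≈0.90 and never converge to 1; smoothing removes the staircase
  bias (disk error < 0.01 for radii ≥ 15 px, 2:1-ellipse circularity within
  0.003 of the Ramanujan value) while leaving wavelengths well above a few
  pixels intact. Regions under 25 px are measured on the unsmoothed contour
  because anti-aliasing can erase them. Crofton (4-direction) perimeters
  were evaluated as an alternative and are slightly biased high
  (disk C ≈ 1.004–1.009).
* **Circularity.** C = 4πA/P², capped at 1.02 to absorb residual raster
  bias on small near-circular regions.
* **Classification.** A mitochondrion is *abnormal* when C ≥ 0.90
  (configurable). The two observed populations sit near 0.97 (round,
  cristae-depleted) and 0.73 (irregular, normal), each several group
  standard errors away from 0.90, so the exact cutoff and its boundary
  convention are immaterial for data shaped like the study's.
* Microtubules are never measured (unresolvable along z due to the missing
  wedge); one label = one organelle instance, and multi-component labels
  raise an error instead of being silently split.

Default pixel size for reading real scenes is 3.6 nm (bin-2 of the ~18 Å
tomogram sampling), always overridable.

## Synthetic cohorts

The generator emulates five groups — un-irradiated WT, 1- and 3-week
bone-marrow-transplant controls, pre-AML (1 week after leukemic
transplant), AML (3 weeks) — with group sizes 94/34/34/72/120. Published
group sizes are used where printed; the control-group sizes are not
printed and default to 34.

* **Platelet areas** (10⁵ nm²) are normal draws: WT 75.6 (SEM 1.84),
  3-week control 68.4 (3.03), AML 15.6 (1.00), pre-AML and 1-week control
  ~73.0 (no printed SEM; SD borrowed from WT). SDs are recovered as
  SEM × √n. AML is generated as a mixture: ghosts (probability 110/120)
  with a mean chosen so the *group* mean matches 15.6, and rare
  normal-sized platelets drawn from the WT distribution — a pure normal
  at mean 15.6 would make the non-ghost AML platelets (which the study
  describes as normal-sized) impossible to furnish with organelles.
* **Organelle inventories.** Poisson counts around the printed means
  (α granules 15.9 WT / 11.3 pre-AML; dense 12.5 / 9.7), mitochondria
  uniform on 1–23; instance areas are gamma-distributed around the printed
  class/group means with CV 0.3 (spread not printed; chosen as a
  field-typical heterogeneity). Control groups share the pre-AML granule
  parameters (the study found no significant control-vs-pre-AML granule
  differences) and mitochondrial mean area 0.5. Gamma-granule, glycogen
  and OCS parameters are not printed; values (mean 2 gamma granules,
  ~25 glycogen particles of 20–36 nm, ~5 OCS blobs of ~0.25×10⁵ nm²)
  were chosen once as realistic and are configurable.
* **Phenotype.** A pre-AML platelet carries ≥1 abnormal mitochondrion with
  probability 17/72; given at least one, exactly one with probability
  13/17, else uniform on 2–7. Abnormal mitochondria draw circularity
  targets from N(0.968, 0.015) clipped to [0.92, 0.995]; normal ones from
  N(0.729, 0.055) clipped to [0.45, 0.85]. The clips keep the populations
  on their own sides of the 0.90 threshold (the printed class SEMs do not
  determine the instance-level SD, so the spreads are modelling choices).
  Each abnormal mitochondrion is flanked by 2–6 empty vesicles of diameter
  100–300 nm; tubule structures appear in 75.5% of normal-type platelets;
  ghosts contain only glycogen, OCS and (half the time) a few vesicles.
* **Shapes.** Radial harmonic perturbations of a disk,
  r(θ) = r₀(1 + a·Σₖ aₖ sin(kθ+φₖ)) with k ≤ 5, where the amplitude `a`
  is tuned by bisection so the *continuous* outline hits the requested
  circularity before rasterization; granule ellipses invert a precomputed
  aspect-ratio→circularity table. Measured circularity therefore tracks
  the target up to raster bias (≲0.03 at mitochondrion scale, biased
  slightly high for irregular blobs because anti-aliasing smooths the
  shortest wiggles).
* **Placement** is rejection sampling inside the body with a ≥2 px
  separation margin, largest organelles first (required abnormal
  mitochondria before everything). At WT organelle loads (~50% packing)
  occasional instances do not fit and are skipped with a debug log — a
  small downward bias on counts in crowded platelets, never on the
  abnormal-mitochondrion phenotype, which is placed first and raises a
  capacity error if it cannot fit.
* **Sampling.** Scenes default to 7.2 nm/px (bin-4) so a typical WT
  platelet (equivalent diameter ≈3.1 µm) fits a 512 px canvas; the canvas
  auto-grows for larger draws. At this sampling a mitochondrion is ~19 px
  in radius, where the disk calibration error is well under 0.01.
  Measurement is scale-invariant (property-tested), so this choice only
  sets the raster bias floor.
* **Determinism.** Scene *i* of each group derives its RNG from a child
  seed of the cohort seed, so cohorts are byte-reproducible and a group
  subset reproduces exactly the same scenes.

What the generator does *not* emulate: tomographic noise and the missing
wedge, membrane substructure (cristae, bull's-eye cores), organelle
clustering beyond the abnormal-mitochondrion vesicle clusters, 3D
geometry (scenes are single central slices; a thin-slab mode would add
little to the quantities tested). Passing recovery tests therefore shows
the *pipeline* is unbiased on cleanly segmented data, not that
segmentation of real tomograms is solved.

## Statistics

Mean ± SEM per group with the platelet as the unit of analysis; two-group
comparisons by pooled-variance Student's t (Welch optional) and
Mann–Whitney U (exact for small tie-free samples, tie-corrected normal
approximation otherwise — SciPy's automatic rule). Phenotype prevalences
are binomial fractions with exact Clopper–Pearson intervals from beta
quantiles. No multiple-testing correction by default, matching the
per-comparison reporting convention; Benjamini–Hochberg is available
behind a flag. Degenerate inputs: empty groups are omitted with a warning
(never NaN rows); a single-platelet group reports SEM 0 with a flag; two
zero-variance equal-mean samples return t = 0, p = 1.

## Screening design

With per-cell prevalence p, sampling n cells detects ≥1 positive with
probability 1 − (1−p)ⁿ; the minimum n for a target detection probability
is ⌈ln(1−target)/ln(1−p)⌉, verified by direct evaluation. When 0 positives
are seen among N reference cells, the exact one-sided Clopper–Pearson
upper bound on the per-cell false-positive rate is 1 − α^(1/N) (≈2.79%
for N = 106 at α = 0.05, printed as 2.8%); the rule of three 3/N (≈2.83%)
is exposed as the familiar approximation. Cells are assumed independent
draws from a well-mixed platelet population — the assumption implicit in
the arithmetic. Prevalence estimates carry exact CIs, and the report also
evaluates detection at the CI's lower bound as a conservative design
point.

## Problem sizes used in validation

The recovery checks use a 10,000-platelet pre-AML cohort (test suite;
prevalence tolerance ±0.01 is ≈2.4 binomial SDs at that size) or a
2,000-platelet cohort (acceptance script default, adjustable with
`--n-pre`), a 94-platelet WT cohort and a 120-platelet AML cohort at the
study's group sizes, 10⁶ simulated 12-cell screens, and 1,000 null
simulations for t-test calibration.

## Known limitations

* Perimeter smoothing makes measured circularity of *strongly* irregular
  outlines slightly optimistic (≈ +0.02 at mitochondrion scale); both
  generator and validation bands account for this.
* The ghost/normal AML area mixture reproduces the group mean, but the
  printed group SEM cannot be reproduced exactly: a 110:10 mixture of
  ~10×10⁵ nm² ghosts and WT-sized platelets has a between-component
  spread alone exceeding SEM·√n. The ghost component uses SD = mean/3,
  which keeps low-end truncation (areas are floored at a feasible
  minimum) from biasing the group mean.
* `min_sample_size` and the zero-event bound treat the prevalence as
  known; uncertainty is surfaced through the CI-based conservative
  detection estimate rather than a Bayesian treatment.
* MRC I/O stores label volumes as float-valued maps (standard for the
  format) and validates integrality on read.
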