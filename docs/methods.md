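# Methods

## Calibrated stacks

All images are 3D intensity arrays in (z, y, x) order with explicit physical
voxel sizes; every public quantity is in μm/μm²/μm³. Voxels are anisotropic
by default (the reference acquisition is 375/1024 ≈ 0.366 μm laterally and
1.5 μm axially) and are never resampled implicitly — all estimators consume
the raw calibration. Index boxes are 0-based and half-open, so two crops that
share a face share no voxel. TIFF I/O is lossless for integer intensities up
to 16 bit; multi-channel files are rejected with an instruction to select a
channel, rather than guessing.

## Phantom generator

The generator emulates the features of DAPI-stained root sections that the
measurement methods must cope with, and nothing more:

* **Plant nuclei** — soft-edged ellipsoids whose volumes are drawn from a
  lognormal mixture with components at 30/55/80/105 μm³ (weights
  0.45/0.30/0.15/0.10, per-component σ = 0.12), mimicking a population
  spanning several ploidy classes. Nuclei are mildly oblate (axial radius =
  0.6 × lateral, with ±8% lateral jitter), as in sectioned tissue; the
  resulting equatorial areas fall in the ~15–45 μm² range typical of these
  nuclei.
* **Fungal nuclei** — 1 μm-radius spheres, bright but far below the 15 μm²/
  15 μm³ gates.
* **Wall artifacts** — faint 12 × 0.8 μm axis-aligned rods (peak 60 vs 200
  for nuclei), which fail the circularity gate when they survive
  thresholding at all.
* **Depth attenuation** — intensities are multiplied by exp(−z/L) with
  L = 45 μm by default, reproducing the loss of staining contrast deep in
  thick sections.
* **Noise** — Poisson photon noise plus additive Gaussian read noise
  (σ = 2), both optional; `PhantomConfig.noise_free()` disables noise,
  background and attenuation for geometric ground-truth tests.

The intensity profile of each object is 1 inside, a linear ramp of relative
half-width 0.15 across the boundary, and 0 outside, crossing half-maximum
exactly on the analytic ellipsoid. This makes half-max binarization recover
the true support, and keeps threshold-based volumetry well-behaved for any
threshold near half peak — a property filled (chromatin-dense) nuclei share
and pure Gaussian blobs do not. Truth volumes are always the analytic
4/3·π·rz·ry·rx, never measured.

Objects are packed by rejection sampling with a minimum center-to-center
separation (default 10 μm) and must fit entirely inside the stack; a single
`numpy` generator seeded per run makes stacks bit-reproducible. What the
phantom deliberately does **not** model: optical PSF blur beyond the soft
edge, chromatin texture, irregular nuclear shapes, touching tissue
structures, or root anatomy. Passing phantom tests therefore demonstrates
the correctness of the estimators and gates, not the field performance of
segmentation on real, lower-contrast tissue.

## Slice tracking

Per-section detection runs scale-normalized LoG over a ~4× scale range
centred on the nominal 10 μm diameter; the per-section diameter dᵢ is then
refined from the half-max connected region around each maximum, since a
single nominal scale cannot provide the per-section diameters the slab sum
needs. Quality is the LoG response at the detected scale weighted by the
centroid brightness; the default quality cut is an Otsu split of the
per-stack quality distribution (overridable), selecting "the brightest
nuclei" without a hand-tuned constant.

Linking treats "same x-y centroid" as distance ≤ 5 μm (half the nominal
nuclear diameter — pixel discreteness and noise make exact coincidence
meaningless) solved per slice as an optimal assignment, which is
deterministic and resolves ties by total distance. The gap budget defaults to
0 (strictly consecutive sections). Volumes use the ≥ 3-section rule; areas
are reported for all tracks.

## Round-surface detection

Substack thickness defaults to 6 sections (9 μm at the reference z-step,
about one nuclear diameter): thick enough that a nucleus rarely straddles two
substacks, thin enough that distinct nuclei rarely overlap within one.
Background subtraction uses a rolling ball of 20 μm radius (comfortably above
the largest nuclear radius); the threshold defaults to Otsu on the
background-subtracted projection. The mask is smoothed with a 3×3 mean filter
(re-binarized at 0.5), hole-filled, and split by a distance-transform
watershed with watershed lines removed.

Circularity uses the Crofton perimeter estimator: the naive pixel-edge
perimeter overestimates boundary length by up to 4/π and would push small
digitized discs below the 0.7 gate. Objects from *adjacent* substacks whose
centroids coincide within 3 μm are treated as one nucleus re-detected across
the cut, keeping the larger (closer-to-equatorial) area; the deduplication is
idempotent and replaces interactive duplicate inspection with a fixed rule.

## 3D voxel volumetry

Default connectivity is 26. One global threshold per stack is intentional:
with depth-attenuated staining it progressively under-covers deep nuclei, and
this documented failure mode is reproduced (and asserted in the tests), not
patched. Lobedness = 1 − solidity (component volume over convex-hull volume)
with a 0.25 flag threshold automates the manual deletion of merged-nuclei
"lobed objects": two equal touching spheres score ≈ 0.3 once rasterized,
single convex nuclei well below, provided they span a handful of sections.
Planar or linear components, whose 3D hull is degenerate, are scored 0 — a
flat object cannot be a merged cluster. Volume bounds default to 15–250 μm³
(the 15 μm³ floor mirrors the 15 μm² area gate). Border-touching components
are flagged but kept by default; every exclusion carries a machine-readable
reason so audits can recount.

## Statistics

* **Classing** — classes are [anchor + k·w, anchor + (k+1)·w), half-open
  above, with anchor 20 μm³ and width 25 μm³ by default (the class limits of
  the reference analysis: 20–45, 45–70, … 195–220). Values below the anchor
  fold into class I and a maximum landing exactly on the top boundary closes
  the last class, so a 20–220 population yields exactly eight classes while
  45 still belongs to class II. The bare Sturges width R/(1 + 3.322 log₁₀ N)
  is computed and reported alongside; on the reference ranges it gives
  10.1/18.5 μm³ rather than the adopted 25 μm³, so the adopted width is an
  explicit, overridable default rather than something the formula is forced
  to produce.
* **Median test** — pooled grand median, ties counted as "not above"; exact
  (Fisher/hypergeometric) for pooled n ≤ 200, chi-square with continuity
  correction above. Degenerate splits return p = 1 with a warning.
* **Distribution choice** — lognormal and gamma are ML-fitted with a fixed
  zero location; both AIC and the Anderson–Darling statistic are reported and
  the lower-AIC family is selected.
* **Bootstrap moments** — per iteration: resample 500 values with
  replacement, ML-fit a lognormal (closed form on logs), regenerate 500
  fresh points, compute mean/SD/CV/skewness/kurtosis. The regeneration step
  is read as *per iteration* (the alternative — one regeneration per starting
  sample — would make the 1000 iterations redundant). Skewness and kurtosis
  use the bias-corrected sample estimators and kurtosis is reported as
  *excess*; with σ = 0.5 lognormal input the aggregate skewness reproduces
  the closed form (e^σ²+2)√(e^σ²−1) ≈ 1.75. Iterations with degenerate
  (constant) resamples are skipped and counted; > 5% skips is an error.
* **Moment comparison** — each group's per-iteration moments pass a
  Shapiro–Wilk gate; if any group fails at α = 0.05 (and the response is
  non-negative) the response is square-root transformed, then a
  Gaussian-family linear model with the group factor is fitted and all pairs
  compared with Tukey's HSD. "GLM" here means exactly that Gaussian linear
  model: no other family/link is implied by the procedure.
* **Kruskal–Wallis + Dunn** — tie-corrected H; Dunn z on rank means with the
  standard tie-corrected variance, Bonferroni-multiplied by the number of
  pairs and capped at 1. An `exact=True` mode enumerates all assignments for
  pooled n ≤ 12, used to validate the implementation against brute force.
  All-identical inputs are maximally tied and return H = 0, p = 1.
* **Case-study summaries** — per-group n/mean/SD/median/quartiles plus
  compact-letter displays derived from the Dunn results (groups ordered by
  mean; maximal runs of mutually non-significant groups share a letter).

Cell-category labels (arbusculated / neighbouring / far, split / undivided)
are consumed from the input table; nothing infers them from images.

## Problem sizes and numerical choices

Tests and the acceptance script use phantoms of roughly 256–320 px laterally
and 48–72 sections with 0.4–0.5 μm z-steps: small enough to run in seconds,
while keeping every nuclear radius above ~3 voxels on all axes so that
discretization (independently quantified at < 5% for radii ≥ 5 voxels, worst
case over generic sub-voxel alignments) does not dominate the method errors
being measured. Geometric accuracy claims always refer to noise-free,
well-separated phantoms; the noisy, attenuated default config exists to
exercise the documented failure modes, not to certify accuracy under them.
Random draws everywhere go through explicitly seeded `numpy` generators, and
rerunning any pipeline with the same config and seed reproduces every output
byte for byte.

## Known limitations

* The slice-tracking volume estimate inherits every per-section diameter
  error and the ≥ 3-section rule discards small or boundary nuclei; on
  coarse z-steps (1.5 μm) most nuclei of 30–100 μm³ span fewer than three
  sections and receive no volume, which is the method's documented weakness,
  not a defect of the implementation.
* A single global threshold under-segments depth-attenuated stacks; the
  optional per-substack threshold mode mitigates this but is off by default
  to preserve the reference behavior.
* The lobedness flag is a proxy for a human decision; its 0.25 default was
  chosen from the geometry of touching equal spheres and is tunable.
* Putative ploidy labels are exactly that — labels on volume classes. No
  cytometric calibration is performed.
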