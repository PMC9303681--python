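# Methods

## Problem and approach

`golgicoloc` quantifies the spatial segregation of two membrane cargo
proteins within Golgi sub-compartments, the measurement underlying the
finding that the protease BACE1 and its substrate APP occupy distinct
subdomains throughout the Golgi.  Because raw super-resolution cell images
and the proprietary processing chain (Huygens deconvolution, Imaris
surface-surface colocalization) are not available, the package pairs the
quantification with a synthetic-scene generator whose voxel-level ground
truth is known exactly.  Every stage of the measurement — deconvolution,
automatic segmentation, mask-restricted directional volume coefficients,
ministack co-occurrence — is therefore testable against oracles.

## The coefficient

For segmented binary volumes A and B inside a region mask R (built as the
union of one or more marker channels, e.g. two trans-Golgi markers combined
as "TGN"):

    coefficient 1 = V(A ∩ B ∩ R) / V(A ∩ R)
    coefficient 2 = V(A ∩ B ∩ R) / V(B ∩ R)

with V a voxel count — a Manders-style object-based statistic with no
intensity weighting.  The integer identity `c1·V(A) = V(A∩B) = c2·V(B)`
holds exactly on every result.  A channel that is empty inside R leaves its
coefficient *undefined* (reported missing), never zero, so cohort means are
not silently deflated.

Raw coefficients are interpreted through calibration bands derived from
control marker pairs: cis-versus-trans Golgi markers define the negligible
(chance) level, two distinct trans-Golgi markers the moderate level, and
dual-antibody staining of a single protein the perfect level.  The packaged
reference bands are the means of the published HeLa control coefficients
(0.16/0.22, 0.52/0.59, 0.99/1.0 → 0.19, 0.555, 0.995).  Classification is
inclusive-below at band edges.

## Synthetic scenes

Ground truth lives on a 10 nm isotropic grid — at least 3× oversampling of
the 35 nm acquisition pixel, so voxelization error is sub-pixel.  Modes:

* **ribbon** — one curved Golgi sheet (default: radius 1.8 µm, 160° span,
  600 nm band width, i.e. ≈5 µm of ribbon arc, the scale of a HeLa
  perinuclear ribbon).  Cisternal marker layers (cis/medial/trans) are
  150 nm-thick slabs at 0/150/300 nm axial offsets; the three layers tile
  the stack contiguously, so a ministack's marker union is one connected
  object.
* **ministacks** — n disjoint mini-stacks (300 nm disk radius, all
  cisternal layers), placed by rejection sampling with ≥1.5 µm center
  separation (retry budget 1000, then a placement error).
* **er_bfa / er_rush** — a tubular network (random-walk tubules, 60 nm
  radius) carrying both cargoes; RUSH-style co-retention corresponds to
  mixing φ = 1.
* **beads** — sub-resolution spheres (default 100 nm) on one z-plane with a
  minimum separation, for PSF/FWHM calibration.

Cargoes are assigned to square lateral membrane subdomains (150 nm patches)
on the cargo-bearing cisterna.  With probability φ a patch is *shared* —
a single occupancy draw (probability `cargo_density`) places both cargoes
together — otherwise the patch is exclusive to cargo A or B (50:50).
φ = 0 yields disjoint cargo fields, φ = 1 identical fields; the expected
overlap rises monotonically in between.  In ministacks mode the per-stack
cargo presence can instead be drawn directly from category probabilities
(both / A-only / B-only / neither), with at least one patch forced for a
present cargo so the recorded category always matches a voxel recount.

The physical scale of intra-cisternal segregation is not an inferred
biological quantity: the 150 nm subdomain scale is a free parameter chosen
to sit at the resolution limit of the modelled microscope.

## Forward imaging model

The PSF is a separable anisotropic Gaussian, σ = FWHM/(2√(2 ln 2)) per
axis; defaults 150 nm lateral / 400 nm axial FWHM mirror the measured
regime of a deconvolution-ready super-resolution acquisition (149 nm raw at
488 nm excitation), without claiming to reproduce those measurements.  The
axial default is a plumbing choice (no axial value is published).
Rendering blurs the fine-grid occupancy with the *analytic* Gaussian
(separable passes, truncated at 4σ; the truncated kernel from `make_psf` is
used only for deconvolution on the acquisition grid), then integrates
photons onto the 35/35/159 nm voxel grid by block summation — photon
conserving, no interpolation.  Expected counts are `gain · signal +
background`; noise is Poisson shot noise plus additive Gaussian read noise,
clipped at zero, all drawn from one seeded generator.  Two exact
optimizations: separable blur passes are reordered around the block
integration of the *other* axes, and fields made of many disjoint
components (spheres, ministacks, beads) are blurred per component — both
bit-equivalent to the naive order by commutation/linearity, verified in
tests.

A single shift-invariant Gaussian PSF is a deliberate simplification of a
detector-array microscope whose effective PSF varies across the field;
bleed-through and chromatic aberration are not modelled.

## Restoration and resolution

Deconvolution is plain Richardson–Lucy (scikit-image implementation),
default 30 iterations, no regularization; non-negativity is inherent.  This
stands in for a proprietary "conservative" deconvolution mode: the property
the analysis relies on — FWHM reduction without artefacts at high SNR — is
preserved, and the iteration count is a config parameter.

Resolution is reported as the lateral FWHM of beads: sub-voxel centroids by
intensity-weighted center of mass (3×5×5 neighborhood), x/y line profiles
sampled at integer pixels along the row/column nearest the centroid (the
Gaussian fit estimates the sub-pixel center; skipping interpolation avoids
its extra smoothing), fitted with a Gaussian + constant offset.  The fitted
σ receives Sheppard's correction (σ² − p²/12, p = 35 nm) for pixel
integration, which keeps the estimator unbiased within ~3% down to 90 nm
FWHM.  Bead diameter is *not* corrected for — the raw FWHM of 100 nm beads
is reported as "resolution", inflating it by roughly 5–10%, matching field
practice.  Beads near the lateral border or within 2 FWHM of another bead
are excluded; the cohort is mean ± SEM.

## Segmentation

Per channel: subtract a heavily Gaussian-smoothed copy (default σ = 1 µm,
clipped at zero), threshold with Otsu's method (parameter-free,
oracle-checkable against exhaustive between-class-variance search), label
connected components (26-connectivity by default — appropriate for the
anisotropic 35/159 nm voxel), and drop components below 4 voxels
(shot-noise singletons).  "Volume" always means voxel count of these binary
masks; no surface smoothing or meshing is applied, and whether the original
surface-rendering software smooths before voxelization is unknown and not
emulated.  A constant channel yields a flagged empty result, not an error.

## Ministack co-occurrence

A ministack is a connected component of the Golgi region mask (union of the
cisternal marker channels).  A cargo is present in a stack iff ≥
`presence_min` (default 2) of its segmented voxels fall inside it — a
1-voxel criterion is shot-noise fragile.  Stacks touching the image border
are retained but flagged (no exclusion rule is published).  Categories
both / A-only / B-only / neither partition the retained stacks; fractions
sum to 1, and the denominator includes marker-positive stacks empty of both
cargoes.

## Cohort statistics

The cohort unit is the cell; per-experiment nesting is not modelled.
Summaries are mean ± SEM (sample SD, n−1); group comparisons are unpaired
two-tailed t-tests, Welch by default (the variance-robust choice; Student's
is available since the original software's variant is unstated).
Classification of a cohort uses its mean, as bar-chart annotations do.
Linescans sample channels along a segment of one z-plane at half-pixel
spacing by bilinear interpolation.

## Determinism

Every run is a pure function of (config, master seed).  Child seeds are
derived per cell by fixed arithmetic (`SeedSequence(master, spawn_key)`,
reduced below 2³¹), so cohorts extend without reshuffling existing cells.
Outputs (CSV with 4-decimal coefficients, JSON at full precision) are
byte-identical across reruns; the run manifest lists every output file with
a SHA-256 checksum.

## Validation experiments and their scale

`golgicoloc.experiments` packages the calibration controls end to end:

* **dual-label control** — a rendered channel against an exact copy of
  itself: coefficients exactly 1.
* **perfect control** — 20 cells, each the same ground-truth ribbon
  rendered twice with independent noise (peak ≈ 400 expected photons,
  background 5, read noise 3), deconvolved and segmented independently;
  cohort mean coefficient ≥ 0.99.
* **chance control** — 20 cells, each a ribbon plus 40 lysosome-like
  spheres (250 nm radius) placed uniformly in a 10×10 µm field,
  independent of the Golgi; cohort mean coefficient at the few-percent
  level, far below the 0.16 negligible band.
* **mixing recovery** — 20 cells per φ ∈ {0, 0.25, 0.5, 0.75, 1} on
  compact ribbon scenes: mean coefficient strictly increasing in φ, with
  φ = 0 classifying as negligible.

Cohort sizes (20 cells) and field sizes (6–10 µm) are desk-scale choices
that keep the full suite reproducible on one CPU while leaving the
statistical conclusions unchanged.

## What the synthetic data does and does not show

The generator reproduces the *geometry and statistics* the measurement
depends on — stacked cisternae at sub-resolution spacing, lateral cargo
subdomains, dispersed stacks, independent organelles, realistic photon
counts — but not membrane biophysics, cargo kinetics, antibody labelling
stochasticity, or spatially varying PSFs.  Passing tests therefore
demonstrate that the *measurement chain* is unbiased and correctly
calibrated on scenes with known truth; they do not by themselves validate
biological conclusions drawn from any particular real dataset.

## Numerical notes and edge cases

* Richardson–Lucy runs in float32 internally (float64 I/O); a size-1
  (delta) kernel short-circuits to the identity; an all-zero channel
  returns zeros.
* Otsu on a constant channel returns a flagged empty segmentation.
* Fine-grid steps that undersample the voxel (step > min(voxel)/3) are
  rejected at render time.
* Band calibration enforces 0 < negligible < moderate < perfect ≤ 1 and
  fails loudly otherwise.
* Classification ties at band edges take the lower category.
* Bead fits that fail are excluded with a warning, not fatally.
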