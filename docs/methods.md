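# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `nucleoquant`. Everything stated here is computed by the
package's tests or its acceptance script; nothing is asserted beyond what
those runs show.

## Intensity scale

All pixel data are carried as 64-bit floats in arbitrary fluorescence units
(a.u.) on [0, 1]. Integer TIFFs are scaled on read by their bit depth
(65535 for 16-bit), and simulated channels are written to, and read back
from, 16-bit TIFF before analysis, so simulated summaries live on the same
quantized scale as real acquisitions (round-trip error ≤ 1/65535).

## Synthetic-image generator

The simulator is first-class, tested code: it defines the study conditions
under which the pipeline is validated, and emits complete per-nucleus
ground truth (geometry, true channel means, focus positions).

**Culture mode.** Nuclei are mildly eccentric ellipses (semi-axis jitter
uniform on [0, 0.15] by default) placed by rejection sampling with no
overlap, a clearance of `min_gap` = 6 px, and a border margin that keeps
every nucleus plus its PSF tail inside the frame. An optional
`touching_pairs` setting places pairs at 1.5 × radius separation to
exercise watershed splitting. Per-nucleus mean intensities are lognormal,
parameterized by arithmetic mean and CV — positive and right-skewed, the
shape single-cell intensity histograms show. Defaults: DNA mean 0.38,
protein mean 0.30 (the early-passage fibroblast condition; presets carry
the other published condition means), CV 0.3 per channel. An optional
third channel models an immunofluorescence target the same way.

**Tissue mode.** Each nucleus is a sphere of radius R (lognormal, CV 0.08)
cut by the focal plane at depth offset dz ~ U(−R, +R); the rendered object
is the bisecting circle of radius √(R² − dz²), recorded exactly in the
ground truth. The protein channel has a bright extranuclear cytoplasm
field (0.2 a.u. by default, emulating protein-rich tissue such as liver).
Per-nucleus intensity follows a **ratio model**: the protein/DNA ratio r is
drawn and the protein mean set to r × (DNA mean), so the generative
NO/DAPI ratio is known per nucleus. The young-liver preset draws r
lognormal with mean 0.29; the old-liver preset uses a two-component
mixture, weight 0.8 at mean 0.31 and weight 0.2 at 1.8 × 0.31, giving an
overall mean of 0.36 (a 1.24-fold shift) with a heavier right tail. The
mixture weight is a free parameter: the true in vivo generative process
behind the old-liver tail is unknown, and only the mean shift and tail
direction are constrained.

**Foci.** Heterochromatic DNA foci (default 3 per nucleus, radius 1.5 px,
2× the nuclear DNA mean) are rendered in tissue nuclei of both conditions;
the old condition adds protein foci (default 4 per affected nucleus, 3× the
nuclear protein mean), a configurable fraction of which (default 0.8) is
placed exactly on DNA focus centers. Placement keeps foci resolvable:
colocalizing foci take distinct DNA foci, all foci keep a pairwise
separation of 2·r_focus + 4·σ_PSF + 1 (so two blurred foci cannot merge
into one connected component), and non-colocalizing foci stay
r_focus + 2·σ_PSF + 1 clear of DNA foci (so their centroids cannot fall
inside a detected DNA-focus region by construction). Foci that cannot be
placed under these constraints in small nuclei are skipped; the ground
truth records exactly what was rendered, and recovery tests compare
detection against the realized ground truth.

**Rendering and noise.** Nuclei are binary-rasterized at their drawn mean
value over a constant background (0.05 a.u.; cytoplasm level in the tissue
protein channel), so with PSF and noise off the mean pixel value inside a
footprint equals the ground-truth mean exactly — the basis of the exact
oracles in the tests. Degradation order: optional DNA→protein crosstalk
(single coefficient, default 0) → isotropic Gaussian PSF (σ = 1 px) →
Poisson photon noise (2000 photons at 1.0 a.u.) → Gaussian read noise
(σ = 0.003) → clip to [0, 1]. Each stage is independently switchable off.
All draws come from one generator seeded by the config seed; identical
config + seed is bit-identical.

**What the simulator does not emulate.** Real chromatin texture,
nucleoli, uneven illumination, vendor PSFs, spectral bleed-through beyond
the single crosstalk coefficient, autofluorescence, sectioning artifacts,
3-D stacks, or cytoplasm segmentation. Passing tests therefore demonstrate
that the pipeline recovers known effects under idealized optics with
realistic intensity statistics; they do not certify performance on any
particular real specimen.

## Segmentation

Gaussian smoothing (σ = 1 px) → global Otsu threshold per image (or a
fixed threshold) → hole filling → optional watershed split → area filter
(default 40–100 000 px) → removal of border-touching objects →
consecutive relabeling. Labeling is 4-connected; coordinates are 0-based
(row, col). The watershed stage seeds markers at maxima of the lightly
smoothed Euclidean distance transform separated by at least 7 px; each
connected component receives at least one seed, so isolated nuclei pass
through unsplit, and marker/flooding order is deterministic. Border
objects are excluded because their areas and intensities are censored.

A global threshold cannot recover nuclei whose stain intensity approaches
the background: the package's recovery guarantees (exact counts on clean
fields, Jaccard ≥ 0.9 under default noise) are stated for nuclei at ≥ 3×
background contrast, and the recovery fixtures draw DNA means with CV 0.1
so every nucleus meets that precondition. Under the wider default CV of
0.3, a few percent of dim nuclei per field are expected to drop out; this
censors dim-DNA nuclei but does not bias protein fold-change estimates,
which the end-to-end recovery test confirms.

## Measurement

Totals are exact sums of channel pixels over the DNA-defined region; means
are total/area; the per-nucleus NO/DAPI ratio is protein mean / DNA mean,
undefined (NaN, logged) when the DNA mean is 0. No background subtraction
by default — whether published intensities were background-subtracted is
generally unstated, so raw is the safer default; per-image median
subtraction is available behind a flag. A diagnostic `erode_px` option
measures inside an interior margin: with the default 1-px PSF, a 2-px
margin (the threshold boundary sits ~1 px outside the true edge) brings
measured means within 1% of the generative truth.

## Tissue central-section filter

"Largest objects" is operationalized as area ≥ f × (p-th percentile of
areas in the same image), defaults f = 0.7, p = 90. A percentile rather
than the maximum is robust to outliers, and the rule maps to a closed-form
depth bound on simulated spheres (|dz| ≤ √0.3 · R when the 90th-percentile
area equals the full cross-section), which is how fidelity to the intent —
"retain nuclei bisected near their centers" — is verified. The threshold
is computed once per image and frozen; re-application with the frozen
threshold is a no-op. In practice retention is ~40% rather than the
idealized √0.3 ≈ 55%, because the percentile is computed on the segmented
population (the minimum-area filter has already removed the smallest
sections, raising the percentile) and radius variability widens the area
distribution.

## Population statistics

Summaries are means and sample SDs (n−1) of per-nucleus means; populations
below 500 nuclei trigger a warning. Two distinct normalized statistics are
computed and labeled: the condition-level ratio of means (culture summary
tables) and the per-nucleus NO/DAPI ratio (tissue comparisons). Culture
comparisons test raw per-nucleus protein means; tissue comparisons test
per-nucleus ratios; the choice is a mode default, overridable.

Tests: Welch's two-tailed t (the variance-equality assumption is not
defensible between conditions), two-sample KS, and Wilcoxon rank-sum —
exact enumeration when both samples are ≤ 20 and tie-free, otherwise the
normal approximation with tie and continuity corrections. No
multiple-testing correction is applied: one pairwise test per channel is
reported. Type-I calibration (5% ± 2% at α = 0.05 over 200 replicate null
pairs of n = 1000) and agreement with brute-force oracles (ECDF max-gap;
pairwise U count; exact enumeration at tiny n) are asserted in the
acceptance suite.

Histograms use left-closed right-open bins with the last bin closed,
heights as percent of total (summing to 100 within 1e-9). Pooling
concatenates per-source tables under a shared schema, preserving a
`source` provenance column.

**Printed-table arithmetic.** Derived columns of a condition summary table
are the ratio of means, the protein fold-change (condition/reference), and
the DNA-normalized fold-change. Published tables round to 2 decimals and
compute the DNA-normalized fold-change **from the rounded ratio column**;
`derived_columns` returns both full precision and the 2-dp convention
(`fold_ratio_2dp`), which is the one that reproduces printed values (for
the mouse-fibroblast pair, 2.11/1.16 = 1.82 at 2 dp, whereas full
precision gives 1.81).

## Focus detection and colocalization

Foci are not a formally defined structure, so the operational rule is
deliberately simple: within each nucleus, (1) erode a 2-px rim margin (in
tissue, the bright cytoplasm blurs across the boundary and would otherwise
be detected as a rim band), (2) enhance with a white top-hat (disk radius
5 px > focus size), (3) keep pixels that both exceed the nucleus median by
k · 1.4826 · MAD (k = 3) on the raw image and exceed the same offset after
enhancement, (4) keep 4-connected components of 4–400 px. Requiring the
raw-pixel condition suppresses the positive bias a top-hat of pure noise
carries (the enhanced value is measured against a local opening, i.e. a
low baseline). In noise-free images the MAD degenerates to 0, which would
make any bump a focus; a relative contrast floor (`min_contrast` = 0.1 ×
nucleus median) guards that case, so a 1.05× bump is below threshold while
a 3× focus is far above. Median, MAD and the floor all scale with the
data, so detection is invariant to multiplying a channel by a constant.
Nuclei smaller than the structuring element are skipped with a warning.

Colocalization between two channels' focus sets from the same image:
primary measure is the fraction of channel-a focus centroids falling
inside a channel-b focus region (and the swap); pixel overlap |A∩B|/|A| is
reported secondarily. On simulated old-tissue images with ≥ 500 rendered
foci the detected fraction recovers the realized generative fraction
within 5 points. Prevalence is the per-condition fraction of nuclei with
at least one protein focus.

## Pipeline and provenance

A run is defined by a single configuration (YAML-loadable): mode, per-
condition simulator presets/overrides or input TIFF paths, stage
parameters, master seed. Per-image seeds derive from the master seed via
a seed sequence. Every output CSV header carries the package version, a
hash of the scientific configuration (the output directory is not part of
a run's identity) and the master seed; rerunning an identical
configuration reproduces byte-identical tables. Any stage failure removes
the partial outputs of the run and raises a stage-labeled error.

## Problem sizes used by the validation runs

The acceptance suite runs the culture comparison at 1000 nuclei per
condition (4 fields of 1024² px each) and the tissue comparison at ~4000
simulated nuclei per condition (4 fields of 1800² px); the acceptance
script scales the tissue study to 8 fields × 1250 nuclei per condition so
that ~4000 nuclei per condition survive the central-section filter. These
sizes reproduce the studied effects comfortably on a single CPU.

## Known limitations

- No mixed-effects modeling of animal-level clustering: tissue nuclei are
  pooled across simulated "mice", so p-values treat nuclei as independent.
- Global thresholding censors very dim nuclei (see Segmentation above).
- No machine-learned segmentation or classification, no 3-D stacks, no
  cytoplasm measurements, no texture/granularity features.
- The old-liver generative model (mixture weight, tail scale, foci counts)
  is a plausible parameterization, not an inference from data.
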