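# Methods

This note documents the models, parameter choices and limitations behind
`stemstate`: what the synthetic microscopy emulates, how each analysis
stage works, which knobs matter, and what passing tests do and do not
demonstrate about real data.

## The measurement model

MSC differentiation is read out from two label-free contrasts.  The
NAD(P)H autofluorescence decay is modelled as a bi-exponential,

    I(t) = A [ a1 exp(-t/τ1) + a2 exp(-t/τ2) ],    a1 + a2 = 1,

with τ1 the free-NAD(P)H lifetime, τ2 the protein-bound one, and a2 — the
bound fraction — the metabolic readout: it rises as cells shift from
glycolysis toward oxidative phosphorylation during differentiation.  The
amplitude-weighted mean lifetime is τm = a1·τ1 + a2·τ2.  The SRS lipid
channel (2850 cm⁻¹, CH₂ stretch) reports lipid-droplet accumulation during
adipogenesis as an increase in the mean grey value of the cell region.

Cells are clustered, not classified: per-cell feature vectors are grouped
with K-means++ and the clusters are interpreted as undifferentiated /
differentiating / differentiated states from how their occupancy drifts
over the induction timecourse.

## Synthetic data generator

No public raw images exist for this kind of experiment at the scale the
analysis needs, so the package ships a generator whose defaults *are* the
study conditions; all downstream stages are validated against its exact
ground truth.

**Geometry.** Cells are ellipses with a sinusoidal boundary ripple
(amplitude 6%, 3–6 lobes) — a controllable stand-in for spindle-shaped
MSCs that makes area/perimeter/circularity analytically known.  Nuclei are
rounder ellipses (eccentricity 0.2–0.5) of 6.25% of the cell area, centred
in the cell with ≤2 px jitter.  Cells may touch (boundaries are genuinely
ambiguous in adherent monolayers); nuclei never overlap; a 24 px border
margin keeps every cell fully inside the field.  Coordinates are 0-based,
row-major, origin top-left.  Image rasters are 512×512 px by default
(float32 for a2 maps, uint16 for SRS); no physical pixel size is claimed
because none is identifiable from the problem.

**States.** Three state configurations set the per-cell distributions
(all overridable):

| state           | a2 peak     | a2 width σ | droplets | area px²  | eccentricity |
|-----------------|-------------|------------|----------|-----------|--------------|
| undiff          | 0.19 ± 0.02 | 0.030      | 2        | 2600 ± 350| 0.85–0.95    |
| differentiating | 0.26 ± 0.02 | 0.045      | 12       | 3500 ± 400| 0.70–0.88    |
| diff            | 0.34 ± 0.02 | 0.060      | 30       | 4600 ± 500| 0.45–0.75    |

The a2 anchors reflect the field's convention that undifferentiated MSCs
peak near 19% bound NAD(P)H and differentiated cells sit above 30%; the
transitional state is placed between them.  Droplet counts, areas and
shapes encode the standard morphological trajectory (cells grow and round
up as they mature).  Default timepoint mixtures drift from 80/10/10 on
Day 1 to 2/30/68 on Day 28 across five timepoints (Days 1, 7, 14, 21, 28).

**Rendering.** Inside a cell, a2 pixels are N(peak, width) clipped to
[0, 1]; the nucleus and the background render as zeros with 2% dim speckle
(0.01–0.04), emulating pixels below the photon threshold of the lifetime
fitter.  A 1-px rim of each cell also renders as background: optically
thin cell margins are photon-starved in real acquisitions, and this seam
is what lets adjacent cells remain separable by thresholding while still
appearing contiguous.  SRS images are Poisson draws around λ = 1500
(background, nuclei), 20000 (cytoplasm), plus droplet disks of radius 3 px
and state-dependent amplitude; this yields cell-region means in the
20000–35000 grey-level range typical of 16-bit lipid-channel images.

**Decays.** `generate_decay` draws a multinomial sample over 256 uniform
bins spanning 10 ns from the exactly integrated bi-exponential density —
the forward model of the fitter, used for parameter-recovery tests.

**What is deliberately not emulated:** optical point-spread functions,
instrument response functions, 3-D structure, time-lapse correspondence,
uneven illumination, and genuinely overlapping cytoplasm textures.
Passing tests therefore demonstrate algorithmic correctness and
calibration on idealized-but-structured scenes, not robustness to every
real-microscope artefact.

## Decay fitting

Fits are nonlinear least squares on binned counts with Poisson weights
(√max(counts, 1)), parameterized as (amplitude, a2, τ1, τ2) so that
a1 = 1 − a2 holds by construction rather than by renormalization.  Box
bounds τ1 ∈ [0.1, 1.0] ns and τ2 ∈ [1.0, 6.0] ns cover the standard
NAD(P)H ranges and enforce τ1 ≤ τ2.  The starting point seeds a2 from the
empirical mean arrival time (τ̄ ≈ a1τ1 + a2τ2 when lifetimes are short
relative to the window).  Decays with fewer than four non-empty bins are
refused rather than silently defaulted.  A global-lifetime mode fits
τ1/τ2 once on the pooled field decay and then only a2 per pixel; per-pixel
fitting is the default.  Pixels under 100 photons are flagged background
and written as a2 = 0.  At 10⁵ photons the median |â2 − a2| is ~0.003
across a2 ∈ [0.1, 0.4] (the acceptance script recomputes this).

## Segmentation

Dense adherent monolayers defeat watershed and out-of-the-box learned
segmenters, so detection is exhaustive screening of candidate windows:

1. **Window matrix.** From ~50 measured cell bounding boxes, the sizes at
   the 25/50/75/95th area percentiles are inflated by 20%; entries within
   20% of a kept entry's area are dropped as redundant.
2. **Sliding.** Each window size slides at ⌈10%⌉ steps with the last
   row/column clamped to the border, so the union of windows covers every
   pixel.
3. **Screening.** Per crop: histogram-peak binarization → 5×5 elliptical
   closing → speckle components under 20 px erased → contours traced and
   ranked by area.  The largest contour is taken as the cell, the second
   as the nucleus (nuclei are signal holes).  The convex hull of the
   nucleus contour must have circularity ≥ 0.7 and sit within 15% of the
   window diagonal from the window centre.  Plausibility guards (cell
   ≥ 300 px², nucleus ≥ 40 px² and ≤ 50% of the cell, window foreground
   fraction in [0.08, 0.85], central-quarter coverage ≥ 0.15) encode the
   cell/nucleus reading of the ranking and reject windows that sit in
   background or deep inside a cell.  All thresholds are `ScreenParams`
   config keys.
4. **Deduplication.** Overlapping windows re-detect the same cell;
   detections are reduced by greedy non-maximum suppression on
   nucleus-hull IoU (> 0.3), keeping the best-centred window.

Two O(1) integral-image prefilters (whole-window and central-quarter
foreground fraction) skip the large majority of windows and keep a
1024×1024 field at ~15 s on one CPU.  On ten 50-cell non-touching fields
the detector scores recall ≈ 0.98–1.0 and precision ≈ 1.0; both are
recomputed by the acceptance script.

The adaptive threshold itself — the upper edge of the modal bin of a
3-bin-smoothed, 256-bin fixed-range histogram — is shared verbatim between
the screener and the mask builder.  Fixed-range binning (per-dtype full
scale) keeps the background mode in one or two bins regardless of scene
content, which is what makes "greater than the peak" a usable binarizer.

## Feature extraction

The cell mask is threshold → dilation (5×5 ellipse) → 3×3 mean filter
re-binarized at 0.5 → largest connected component.  The dilation
compensates pixels lost at binarization; masks overlap the rendered cell
polygon with median IoU ≈ 0.85.

FLIM features: mask area; peak (modal-bin centre) and FWHM of the a2
histogram at 0.01 bin width over [0, 1] — 1 percentage point, matching the
precision with which such peaks are conventionally reported.  Exact zeros
are excluded from the histogram because the fitter writes a2 = 0 at
background-flagged pixels, and the dilated mask ring would otherwise make
bin 0 the mode.  The FWHM is measured by linear interpolation of the
half-maximum crossings around the global modal bin only; on Gaussian cells
it lands within ~5% of 2√(2 ln 2)·σ at 10⁴ pixels.

SRS features: area (pixel count), perimeter (length of the traced outer
boundary polygon; marching-squares contours are lightly smoothed with a
3-point circular moving average, removing the staircase bias that would
otherwise inflate perimeters ~5%), circularity 4πA/P², and mean grey.
Area/perimeter agree within 2% with the independent shapely-based
measurements carried on segmentation contours (a deliberate dual-tracing
cross-check).

`extract_features(..., extra_morphology=True)` appends perimeter and
circularity to the FLIM set, so the ablation of clustering with and
without the extra shape features is one flag away; the lean set is the
default because the metabolic features carry the discriminative signal.

Features are min–max normalized to [0, 1] per column before clustering;
the (min, max) pairs are retained so held-out cells can be projected and
tables denormalized.  Constant columns map to 0 with a warning.

## Clustering and model selection

`KMeansPlusPlus` is implemented in-package (D²-weighted seeding exactly as
described in the glossary: first centroid uniform, subsequent ones drawn
with probability ∝ squared distance to the nearest chosen centroid,
followed by Lloyd iterations) and wrapped in the scikit-learn estimator
protocol.  Defaults: 10 restarts, 300 max iterations, tolerance 1e-6 in
normalized units; empty clusters are re-seeded at the farthest point.  At
enumerable sizes (n ≤ 8) the fitted WCSS equals the exhaustive-partition
optimum on 50/50 random instances, and on larger data it matches
scikit-learn's KMeans inertia (used in tests only, never as the
implementation).

**Elbow rule.** WCSS is computed for k = 1…8, each k warm-started from the
previous k's centroids plus the farthest point (guaranteeing a
non-increasing curve) in addition to the random restarts.  The knee is the
interior k farthest below the chord joining the normalized curve's
endpoints — the "kneedle" criterion.  A raw maximum-second-difference knee
was evaluated first and rejected: because the three states lie mainly
along one direction of feature space (a differentiation trajectory), the
k = 1→2 WCSS drop always dominates the second difference and the rule
degenerates to k = 2 regardless of the true cluster count.  The chord
criterion formalizes what a reader of the elbow plot actually does and
selects k = 3 on both modalities' feature tables in 10/10 seeds.  When
the strongest knee's normalized chord distance is below 0.45 the result
carries a `flat` flag (calibrated for the 3–4 feature dimensions used
here); a single Gaussian cloud triggers it.

**State assignment.** With k = 3 and at least two induction days, the
cluster whose occupancy falls most between the earliest and latest day is
labelled undifferentiated, the one that rises most differentiated, and the
remainder differentiating.  Absent any drift the assignment raises an
explicit ambiguity error instead of guessing.

**Proportion tables** report per-day, per-cluster mean ± SD of per-field
fractions (sample SD across replicate fields; 0 with a single field), plus
the differentiating + differentiated sum — the label-free analogue of a
stained-cell fraction in an enzymatic-staining validation.

## Statistics

Cell counts per condition (150–300) justify large-sample Z-tests: two-sided
tests on feature means from summary statistics, and pooled two-proportion
tests for cluster occupancies.  Significance labels follow the NS / * /
** / *** convention with the 0.05 boundary assigned to NS.  Zero-variance
degenerate inputs return z = 0, p = 1 when means agree and an explicit
infinite-z flag otherwise.  Groups under 30 trigger a warning rather than
an error.  No multiple-testing correction is applied — comparisons are
reported pairwise as is conventional for these timecourse annotations —
which is a known limitation.  Under the null the empirical type-I error at
α = 0.05 is within [0.04, 0.06] (5000 replicates, recomputed by the
acceptance script).

## Pipeline and reproducibility

One `RunConfig` drives synth → segment → features → cluster → stats per
modality arm.  Fields are synthesized per timepoint until 150–200 accepted
single cells are collected (18 cells per 512² field by default — a
realistic density for large MSCs at 60× magnification, at which the
mask-merging of touching cells stays rare enough for the area feature to
remain informative; higher densities are a config choice and degrade the
elbow's margin, see Limitations).  Every stage seed derives from the
single master seed via spawn keys, so identical configs reproduce every
artifact bit for bit; the run manifest maps each artifact to a SHA-256 of
its canonical serialization and the acceptance script asserts two full
runs agree.  A fixed `k` in the config skips the elbow stage.

Problem sizes used by the shipped checks — 150 cells × 5 timepoints for
feature-table clustering, ten 1024² fields of 50 cells for segmentation,
100 decays × 4 bound fractions at 10⁵ photons for fit recovery, 5000
replicates for test calibration, and one full default pipeline run
executed twice — were chosen so the whole battery completes comfortably on
a single CPU while keeping every estimate's Monte-Carlo error well inside
the asserted tolerances.

## Known limitations

* No IRF deconvolution: fitted lifetimes are only meaningful for decays
  already free of instrument response, as the synthetic ones are.
* The histogram-peak binarizer assumes a dark, unimodal background; it
  would need re-tuning for brightfield-like contrast.
* Touching cells whose masks merge inflate the area feature; at high
  densities this erodes the elbow's k = 3 margin even though the
  metabolic features still separate the states.
* The flatness threshold of the elbow flag is calibrated for 3–4 feature
  dimensions; strongly different dimensionalities would need a new value.
* State assignment presumes a monotone differentiation drift between the
  first and last timepoints; protocols with transient de-differentiation
  would confound it.
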