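# Methods

`partiquant` quantifies the insoluble-particle burden of cotton-filtered
slow-release morphine tablet extracts from brightfield whole-slide scans,
together with the morphine-recovery statistics of the extraction
experiment. Because no real scans are distributed with the package, every
stage is exercised on a seeded synthetic-slide generator whose statistical
structure mirrors the study design; this note documents the models, the
defaults, and what the synthetic validation does and does not establish.

## The synthetic slide model

A slide is a 2-D uint8 grayscale raster with a physical calibration in
microns per pixel (mpp). The generator composes, in a fixed order driven
by a single `numpy` Generator seeded per slide:

1. **Background** — pale fluid at grey level 200 with a random linear
   illumination gradient (amplitude 8 grey levels across the raster) and
   i.i.d. Gaussian sensor noise (SD 3). The gradient and noise give the
   texture features of the region classifier something to discriminate.
2. **Edge disturbances** (per condition) — dark bands (grey ~45) of random
   width 6–20 px along each border, labelled `edge_artifact`.
3. **Air bubbles** — Poisson-count bright discs (interior 238) with dark
   rims (70), radius log-normal (median 120 µm, GSD 1.5), labelled
   `air_bubble`.
4. **Particles** — three morphologies: `black_dot` (filled disc, grey
   ~25; emulating insoluble coating fragments), `crystal` (rotated
   ellipse with aspect ratio 3–5, grey ~100), and `cotton` (irregular
   star-shaped blob with ragged border, grey ~120). Counts per morphology
   are Poisson with mean *density × artifact-free area*; sizes are
   log-normal per morphology. Particles are placed uniformly over the
   artifact-free area, rejection-sampled (200 tries) so that footprints
   keep a one-pixel separation from artifacts *and from each other*; the
   separation keeps ground-truth counts identifiable by connected
   components, which the parameter-recovery validation relies on. Placed
   counts are therefore Poisson thinned by a (vanishingly small at the
   default occupancies) rejection probability.

**Size definition.** A particle's size is its maximum caliper (Feret)
length: the maximum pairwise distance between boundary pixel centres plus
one pixel pitch, times mpp. The renderer guarantees the rendered footprint
reproduces the requested size within one pixel pitch for all three
morphologies (the cotton blob rotates its extremal vertex pair onto the
x-axis before rasterising, and the crystal draws its major axis with
endpoints snapped to the best integer pair, so quantisation cannot shave
the caliper). The same caliper definition is used by the measurement side,
making generator→measurement round trips exact to ±1 px. The alternative
equivalent-circular-diameter metric was considered and rejected as the
default: the caliper is the conservative choice for an
injection-hazard-oriented size, and it is well defined for the elongated
crystal fragments.

**Condition table.** The five default conditions (protocols A–D and the
blank filtration control) are parameterised per morphology as
(density /mm², median µm, GSD). Only one density scale is reported for the
real data (small-fragment density of protocol A, ~245/mm²), so the table
is constrained qualitatively: A is dominated by small dark fragments
(<100 µm), B (crushing) has the densest >500 µm load, C the densest
100–500 µm load, D (long boiling) is sparsest in every bin, and the blank
carries a trace 0.01/mm² contamination rate. Two additional constraints
fix the numbers: the expected-occupancy identity Σ density·E[footprint
area] must stay well below 1 (the defaults sit near 30% for A–C) or
non-overlapping placement becomes infeasible, and the per-bin expected
rates must separate the conditions by comfortable Poisson margins at
desk-scale slide areas (verified analytically from the log-normal mixture
CDF before any simulation).

**Measurements.** Replicate morphine masses (filtrate `extracted_mg` and
cotton-wash `remaining_mg`) are independent normals at the reported
per-protocol means/SDs (n=6 for A and C, n=3 for B and D), truncated at
zero; at the default parameters the truncation is negligible (the closest
margin is 2.5 SD), so sample moments converge to the configured values.

## Valid-area classification

Particle densities are reported per mm² of *valid fluid* — the analyzable
area after excluding air bubbles and edge disturbances. Detection is
two-stage:

- **Thresholding.** Pixels ≥ `bright_cutoff` (default 225) seed bubble
  candidates; components below `min_area_px` (default 100) are dropped as
  speckle, holes are filled, and the mask is grown by `rim_pad_px`
  (default 3) to cover the dark rim. The whole border band
  (`border_band_px`, default 24) is excluded as edge disturbance, together
  with any dark (≤ `dark_cutoff`, default 90) structure 8-connected to the
  band. Excluding the full band — not only its dark pixels — is a
  deliberate conservative choice: it makes valid area monotone
  non-increasing in the band width and removes the partially-imaged frame
  where sizes are unreliable. Ties at a cutoff go to the artifact class.
- **Pixel classification.** Remaining pixels are classified valid-vs-
  artifact by a 100-tree random forest over a per-pixel feature stack:
  raw intensity; Gaussian-smoothed intensity and local SD at each
  configured scale (default scales 1 and 4 px); Sobel gradient magnitude;
  3×3 local variance; and white/black top-hat residuals (disk radius 3).
  Training pixels come from labelled ROIs (both classes required),
  subsampled deterministically to 50k.

The final mask is a partition: thresholded labels are kept, classifier
labels fill the rest, and per-class areas sum exactly to the raster area.
Note the thresholding defaults are deliberately *mis*matched to the
generator (the 24 px band is wider than the rendered 6–20 px bands):
counts and valid area shrink together, and it is the *density* that is
invariant — comparisons between learned and oracle masks are therefore
made on densities, not raw counts.

## Dual-learner segmentation and agreement-ranked annotation

The particle segmenter is an ensemble of two per-pixel binary classifiers
with deliberately different configurations: learner-1 is a random forest
over filter-bank scales (1, 2, 4) px, learner-2 an extra-trees ensemble
over scales (1, 3, 6) px, with different seeds. They stand in, at desk
scale, for two differently-backboned convolutional networks; the
interface (`fit`/`predict` on fixed-size patches) accepts any per-pixel
segmenter, so a CNN can be plugged in without touching the loop.

Slides are tiled into fixed-size patches (default 2048 px at downsample 4,
strided subsampling) with zero-padded edge tiles and validity masks;
padded pixels are forced to background in every prediction.

The annotation loop ranks unannotated patches by the IoU between the two
learners' predicted masks and sends the top `batch` patches to the oracle
each round, retraining both learners on the grown annotation set. Two
conventions matter:

- **Both-empty IoU is 1.** Blank patches genuinely agree; with
  high-agreement-first ranking they are annotated early (cheaply). This is
  documented because it drives the ranking of empty patches.
- **Ranking direction.** High-agreement-first is the default, matching the
  protocol this package models (model-assisted annotation of confident
  patches). Classical uncertainty sampling would rank *low* agreement
  first; both directions are supported via the `direction` flag, and the
  loop logs the selection-time IoU of every annotated patch so either
  strategy can be audited. The package does not guess which the original
  authors intended; it implements what they describe and exposes the
  alternative.

The final slide-level mask is the union of learner-1's per-patch
predictions (learner-2 is retained for agreement diagnostics); isolated
predictions of ≤3 px are dropped as specks before upsampling back to full
resolution. How the two learners should be merged is genuinely open; the
primary/diagnostic split is the simplest auditable choice.

## Quantification

Binary masks decompose into 8-connected components (8-connectivity avoids
splitting thin diagonal crystal fragments), each sized by the caliper
metric above and assigned to half-open bins [0,100), [100,250), [250,500),
[500,∞) µm — lower edge inclusive, so exactly 100.0 µm falls in "100-250"
and exactly 500.0 µm in ">500". A detection is retained iff ≥ 50%
(`min_overlap`) of its footprint lies in valid fluid; removals are logged
with the offending valid fraction. Densities are per-bin counts divided by
the valid area, with zero-count bins reported explicitly.

## Recovery statistics

- Dilution fold = final volume (ml) × 1000 / aliquot volume (µl); the
  protocol's 25 µl → 25 ml step gives 1000.
- Back-calculation: mg in flask = vial concentration (µg/ml) × fold ×
  flask volume (ml) / 1000, with 50 ml (filtrate) and 10 ml (cotton wash)
  flasks; concentrations outside the calibration range warn.
- Summaries use n−1 SDs and full precision internally; rounding to one
  decimal happens only at report rendering. This matters because the
  published per-protocol efficiencies are not all reproducible from their
  own printed (rounded) components — C prints 88.8% where the printed
  components give 88.9%, D prints 81.2% vs 81.1% — so only internally
  consistent cells are asserted exactly.
- Welch's t uses the summary-statistic form with Welch–Satterthwaite
  fractional degrees of freedom and a two-tailed t-distribution p-value;
  it reduces exactly to the pooled t when variances and group sizes are
  equal. Significance stars use strict thresholds (*** p<0.001, **
  p<0.01, * p<0.05; p=0.05 exactly earns no star).
- The per-bin ANOVA is one-way fixed effects on per-slide density values
  (slides are treated as the replicate unit), F with (k−1, N−k) df.

## Validation experiments and their scope

`partiquant.benchmarks` (shared by the test suite and
`scripts/acceptance.py`) runs:

- **Density recovery** — one slide per condition at 1000×1000 px, 2 µm/px
  (~3.9 mm² valid area), quantified through ground-truth masks; per-bin
  counts must match the configured log-normal-mixture rates within
  max(3√λ, 3) counts. The floor of 3 counts exists because a literal
  3σ band is narrower than one count for near-empty bins (λ < 1/9) and
  discreteness would make the check vacuous-or-impossible there.
- **Ordering** — 10 seeds × 5 conditions at 700×700 px, 2 µm/px, pooled
  counts/areas; the five qualitative checks listed above. D's minimality
  is tested non-strictly because sparse bins can tie at zero counts.
- **Active learning** — 10 seeded runs on pools of 50 annotatable patches
  (96×96 px) plus 10 held-out patches, 5 initial annotations (~10%),
  4 rounds × batch 5. Patches carry extra sensor noise (SD 35) on top of
  the rendered image: without it the filter-bank learners segment the
  clean renderings perfectly from a handful of patches and the learning
  curve is flat. The criterion is held-out mean IoU after ≥ before in
  ≥ 80% of runs — a statistical, not per-seed, guarantee.
- **Welch type-I error** — 5000-rep null simulation (equal means, SDs 1
  vs 3, n=3 vs 6); the rejection rate at α=0.05 must lie in [0.03, 0.07].
- **Oracle equivalence** — IoU vs naive pixel counting, caliper vs
  all-pairs brute force, component counts vs stack-based flood fill,
  Welch/ANOVA vs the reference implementations in scipy (which are never
  used in the implementation path).

Raster sizes in these experiments (and the 4096² px / 1.0 µm/px generator
default) are package choices: the experiments scale linearly in slide
area, and the chosen areas already put the Poisson margins far from the
decision boundaries.

**What passing does not show.** The generator's particles are
high-contrast, noise-free-edged, and mutually separated; real scans
contain touching particles, focus gradients, debris that mimics particle
texture, and annotation noise. Synthetic validation therefore establishes
the *accounting* (areas, sizes, bins, densities, statistics) and the
*mechanics* of the dual-learner loop, not the segmentation difficulty of
real slides. The published absolute densities from the real scans are not
reproducible from this package and are used only to set one generator
scale; likewise the published significance stars that cannot be recomputed
from printed summary statistics are not asserted.

## Degenerate inputs and tie-breaks

Single-pixel footprints measure one pixel pitch. Empty masks give empty
detection lists; two empty masks have IoU 1. Zero valid area makes density
undefined and is rejected, as are single-class region annotations,
untrained learners, inverted thresholds, non-positive mpp, and SDs that
are all zero in the Welch test. Agreement ties rank by ascending patch id.
All randomness flows through explicit integer seeds; identical
(config, seed) pairs give byte-identical rasters, tables and CSVs.
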