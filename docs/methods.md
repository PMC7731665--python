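# Methods

This note records the models, conventions and design choices behind
`cytozone`, including the points where the underlying procedure was
genuinely open and a decision had to be made.

## Image model and conventions

A FOV is a set of co-registered single-channel integer rasters keyed by
role (`nuclear`, `cytoskeleton`, `cytoplasm`, `antibody`), nominally
16-bit. Coordinates are row-major, origin top-left, 0-based. Channel
*order* never matters; all access is by role. Foreground objects are
8-connected; background (hole detection) is 4-connected — the standard
complementary pairing, fixed so that every morphological contract is
exact. Categorical ground truth uses a fixed 5-class legend:
0 background, 1 target-cell subcellular, 2 target nucleus, 3 other-cell
subcellular, 4 other nuclei. Nuclear "boundary" classes are filled
nuclear objects, not 1-px contours: filled objects make class areas well
defined and conserved under the class/mask round trip.

## Autothresholding

All three thresholds operate on a 256-bin equal-width histogram over the
full container range (for 16-bit data the bin index is `value // 256`),
reproducing the discretisation of the classical ImageJ-style threshold
functions. Foreground is *strictly greater than* the threshold bin, so
an all-foreground mask is impossible by construction.

* **Otsu**: exhaustive argmax of between-class variance over all
  candidate bins; ties break to the lowest bin.
* **Moments (Tsai)**: the two-level image preserving the first three
  gray-level moments is solved in closed form; the threshold is the
  first bin whose cumulative fraction reaches the below-level fraction
  p0. A 1e-9 tolerance absorbs float noise when p0 lands exactly on a
  cumulative step (p0 and the cumulative distribution are O(1)
  quantities).
* **Percentile (Doyle)**: smallest bin where the cumulative count
  reaches `fraction` (default 0.5) of all pixels.

Default channel pairing is nuclear→Otsu, cytoskeleton→Moments,
cytoplasm→Percentile; the alternative manual-workflow pairing
(nuclear→Moments, cytoskeleton→Otsu) is a config override. Degenerate
(single-level) histograms raise rather than return an arbitrary bin.

## Morphology

`despeckle` is one round of isolated-speck removal: 8-connected
foreground components smaller than `min_size` (default 2 px, i.e. only
isolated pixels) are deleted. This operation is idempotent, which a
single binary median pass is not — we verified empirically that one 3×3
median pass differs from two on ~99% of random 16×16 masks and ~98% of
realistic blob masks — and it matches the binary-despeckling practice of
MATLAB-style pipelines (`bwareaopen`). A square-window intensity median
filter is provided separately (`median_filter_2d`). `fill_holes` fills
background components not 4-connected to the border;
`largest_component` keeps the largest 8-connected component, ties
breaking to the earliest raster-scan first pixel.

## Classical per-cell assignment

The training-free backend assigns every structure-foreground pixel to
its nearest nucleus by geodesic distance within the traversable region
(structure foreground ∪ all nuclei), 8-connected with diagonal steps
costing √2. Pixels unreachable from every nucleus fall back to Euclidean
distance to nucleus centroids. Distances are rounded to 6 decimals
before comparison so "exact tie" is well defined despite
floating-point path-sum ordering; ties go to the lower label (labels are
raster-scan order of nucleus first pixels). The implementation uses
minimum-cost-path search; tests verify it pixel-for-pixel against an
independent sparse-graph Dijkstra oracle on scenes up to 32×32.

## Trained backend

The trained backend is a per-pixel 5-class multinomial softmax
classifier over a 12-feature stack per pixel: the three binary planes,
Gaussian smoothings of each (σ = 2 and 6 px for the nuclear planes, 2 px
for structure), Euclidean distance transforms to the green and red
nuclei (normalised by the image diagonal), their signed margin, and the
margin gated by the structure plane. Features are standardised with
training-set statistics stored in the model.

Optimisation follows the pipeline's SGD contract: momentum 0.9, base
learning rate 1e-3 with a piecewise schedule dropping ×0.3 every 690
iterations, 2300 iterations, cross-entropy loss with
inverse-pixel-frequency class weights (w_c ∝ 1/count_c, mean-normalised;
a class absent from training raises an error naming it), and train-time
augmentation by right-angle rotation, isotropic scale (0.8–1.25) and
x/y reflection applied to whole composite/truth pairs before feature
extraction. Training is deterministic given the seed; predictions are
restricted to the structure foreground, which class-1 pixels are a
subset of by definition. Two independent models are intended, one per
structure channel, because fibrillar and diffuse foreground have
different pixel statistics; the backend interface hides which is in use.

For desk-scale tests and the acceptance script the backend is trained at
reduced scale: 6 composite/truth pairs from two small scenes, 250
iterations, and a base learning rate of 0.5 appropriate for a linear
softmax on standardised features (the 1e-3 default is calibrated for
deep-network training). This scaled-down configuration is an overfit
sanity check — it shows the optimiser, weighting and feature machinery
work — not a claim about generalisation to real micrographs.

## Whole-cell assembly and zones

whole = hole-filled union of nuclear, cytoskeleton and cytoplasm masks;
components of the filled union containing no nuclear pixel are dropped
(stray thresholding speckle cannot join a cell). Cells whose nucleus
touches the frame border are retained but flagged.

Zones per cell: `nuc` (clipped to whole), `vim_hi` = FOV-level
high-cytoskeleton mask ∩ whole — deliberately *not* clipped away from
the nucleus, so fibrils crossing the nucleus stay in the vim_hi zone and
overlap analyses (e.g. `nuc ∖ vim_hi`) remain possible —
`cytoplasm = whole ∖ nuc` and `vim_lo = cytoplasm ∖ vim_hi`. Area
conservation (`nuc + cytoplasm = whole`;
`vim_lo + (vim_hi ∩ cytoplasm) = cytoplasm`) is asserted on every zone
set. The `vim_hi` source defaults to the FOV-level autothreshold
(matching the manual workflow); the per-cell backend output can be used
instead. Zone algebra supports union and difference with explicit
parentheses required for mixed operators — there are no precedence
rules, avoiding silent mis-parsing. Tissue mode skips cell decomposition
entirely: one zone set per FOV with whole = full frame and nuc/vim_hi
straight from the autothresholds.

## Quantification and statistics

MPI is the arithmetic mean of channel values over mask pixels; empty
zones are an explicit error (or a flagged missing row in tables, never a
silent drop). Colocalization is the Pearson correlation of matched pixel
intensities within a scope mask: per cell (whole-cell mask — a
background-masking choice the FOV-level workflow does not make) and per
FOV (all pixels, background included). Zero-variance scopes return a
missing value with the reason.

Group comparisons are two-sided. For samples with n ≤ 10 per group the
p-value is computed by exact enumeration — all group relabellings for
Mann-Whitney, all sign patterns for the paired Wilcoxon, with midranks
for ties and the symmetric-deviation two-sided rule
p = P(|T − E[T]| ≥ |t_obs − E[T]|) — which handles ties exactly where
standard exact routines refuse them. Larger samples use the normal
approximation with tie correction (scipy). Identical paired samples have
no nonzero differences and return p = 1.0 by convention.
Benjamini-Hochberg q-values are the standard step-up adjustment
(delegated to statsmodels; tests pin it to the closed-form oracle).

IOU of two empty masks is defined as 1.0 with a warning flag — vacuous
agreement, excludable by the caller. Spearman rho uses midrank ties.

## Synthetic scenes

The generator emulates a desk-scale confluent monolayer: default
256×256 px, 5 cells (nucleus semi-axis 11–15 px, cell semi-axis
34–44 px, axis ratio 0.75–0.95), 6 fibrils per cell drawn as smoothed
random-walk polylines anchored near the nucleus (so they may cross it)
and clipped to their cell, dilated to ~3 px width. Channel intensities:
nuclear 30000, cytoskeleton 28000, cytoplasm 16000, antibody scale
20000 over a background of 300, Gaussian noise σ = 300 (1.5% of the
antibody scale), Gaussian blur σ = 0.8 before noise. The antibody
channel is a planted mixture of the unit-normalised blurred structural
patterns with weights (w_vim, w_nuc, w_cyto) = (0.85, 0.15, 0.25) by
default — a vimentin-dominant antibody; recovery tests draw the
vim/nuc weights as dominant/weak pairs (0.6–1.0 vs 0.05–0.3),
emulating antibodies with a preferred compartment. Placement is
largest-first greedy with full restarts under a bounding-circle
non-overlap criterion; truth masks are emitted before blur and noise.

What the generator does *not* emulate: realistic point-spread optics,
intensity vignetting, touching/overlapping cells, nuclear texture, and
tissue architecture. Passing tests therefore demonstrate the internal
correctness and calibration of the pipeline on geometry it can represent
exactly, not segmentation accuracy on real micrographs — the trained
backend in particular is exercised as a contract (reproducibility,
class weighting, overfit capacity), not as a reproduction of any
published network's scores.

## Problem sizes

Default test/acceptance scales were chosen to keep the whole suite in
tens of seconds on one CPU: 128×128 3-cell scenes for property sweeps
(100 seeds), 256×256 5-cell scenes for segmentation scoring, 96×96 for
trained-backend unit tests, and 250-iteration scaled-down training runs.

## Known limitations

* Touching nuclei are not declumped (no watershed separation); each
  8-connected nuclear component is one marker.
* The percentile threshold's default fraction (0.5) presumes roughly
  half the frame is stained — appropriate for confluent monolayers,
  conservative for sparse fields (the component filter in whole-cell
  assembly absorbs the resulting background speckle).
* Zone algebra is 2-D set algebra only; no distance-banded
  (peri-nuclear shell) or 3-D zones.
* The trained backend is a linear classifier over hand-built features;
  it shares the contract, not the capacity, of a deep encoder-decoder.
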