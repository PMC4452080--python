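# Methods

This note documents the models, estimators, parameter choices, and known
limitations of the `dynsurf` pipeline, in the order the stages run.

## Pattern geometry and migration-distance zones

A pattern is a circle (center, radius) or an infinite line band (axis
point, unit direction, half-width), in continuous µm coordinates with an
arbitrary origin. Migration distance is measured from the pattern
*boundary*: `max(0, ‖p − c‖ − R)` for circles and
`max(0, |perpendicular offset| − half_width)` for lines; longitudinal
position along a line is ignored. The analysis assumes cells initiated
migration at the boundary, so interior points all have distance 0.

Zones are half-open distance intervals `((k−1)·w, k·w]` of width `w`
(`zone_width`); a point exactly on an edge belongs to the inner zone, and
zone 0 is exactly the pattern. The default `w` equals the pattern radius
(circles) or the full width (lines), so the natural distance classes of
the three study geometries (165 = 3×55, 80 = 1×80, 180 = 1×180 µm) land
on zone boundaries. `zone_width` is a reported analysis parameter, not
something inferred from data.

Image coordinates use 0-based pixel indexing with pixel centers at
half-integers, converted through `pixel_size` (µm/px).

## Synthetic data

All generators draw from named substreams of a single master seed
(`default_rng([seed, stream_id, salt…])`, salts being chip index,
condition label CRC, cell index, …), so each data type is reproducible in
isolation and bit-identical for identical (seed, config).

**Patterned nuclei.** Per chip, each zone receives a configured number of
nuclei placed uniformly in its region by rejection sampling under a
global minimum center-to-center separation. The user-facing default
separation is 12 µm (a realistic fibroblast-nucleus scale); the pattern
presets use 4 µm so that confluent-pattern densities (hundreds of nuclei
in a 55-µm-radius island) are geometrically placeable. Each nucleus is
labeled by an independent Bernoulli draw with its zone's probability. The
preset probabilities anchor zone 0 and the outermost analyzed zone at the
assay's basal and far-field labeling levels (small circle 27.5% → 65%,
large circle 31.2% → 65%, line 48.4% → 65%); intermediate zones are
interpolated monotonically, since only the endpoints are constrained.
Per-zone counts are sized so that the pooled binomial sampling error over
6 chips (~1 point SE) is small relative to the few-point differences the
zone profile is meant to resolve; outer-zone counts grow with zone area
while areal density still thins outward. An optional chip-level random
effect (a Normal shift on the labeling log-odds, default off) is exposed
rather than guessing an inter-chip variability the assay does not
constrain.

**Images.** Each nucleus is an isotropic Gaussian spot (σ = 4 µm,
amplitude 1000) on a constant background (100) with additive Gaussian
noise (σ = 10 by default, SNR ≈ 100); the BrdU channel renders the
labeled subset at identical positions, so its spot set is a subset of the
DAPI channel's by construction. 16-bit two-channel TIFF output.

**Trajectories.** A persistent random walk at the sampling interval
(default 1 h over 30 h): step lengths are Gamma(shape 4, mean =
speed × interval), so the expected hourly path increment equals the
configured condition speed exactly and the slope estimator is unbiased;
headings accumulate wrapped-normal turning noise with concentration set
by ρ = E[cos Δθ] (default persistence 0.7, σ_θ = √(−2 ln ρ)). The six
condition presets carry the measured mean speeds (dynamic linear 12.3,
dynamic cyclic 11.6, non-dynamic linear 1%/2% 7.3/7.8, non-dynamic
cyclic 1%/2% 4.4/3.1 µm/hr). The walk reproduces observed speed
statistics only — no contact inhibition, no mechanism, no interaction
between cells.

**Voltammograms.** Gaussian faradaic peaks (default HWHM 30 mV) on a
linear capacitive baseline (±1.5 µA offset per sweep direction, 0.002
µA/mV slope), two 400-point segments over 100–800 mV at 50 mV/s on a
1 cm² electrode. Peak amplitude is scaled so the integrated wave charge
equals `nFAΓ` exactly, making the integration → coverage pipeline
invertible up to numerical error. Default couple positions:
hydroquinone/quinone 540 (ox) / 320 (red) mV; oxime 620 / 480 mV.
Coverage default Γ = 2.3 × 10⁻¹⁰ mol/cm²; n = 2 electrons for both
couples (two-electron, two-proton chemistry), exposed as a parameter.

**Kinetics.** `f(t) = 1 − exp(−kt)` with k = 0.040 min⁻¹, multiplied by
(1 + ε), ε ~ N(0, 0.02), clipped to [0, 1]; default grid every 10 min
over 120 min.

**Expression.** Per gene a log-normal baseline (log2 mean 10, sd 1.5)
shared by both channels; 5 conditions × 4 replicate arrays. Channel noise
is multiplicative log-normal at 15% CV per channel (a realistic two-color
array noise level; the log-ratio of a null gene is then exactly normal,
which makes the replicate t-test calibrated by construction). A
`de_fraction` (default 5%) of genes get the sample channel multiplied, in
one random condition, by a fold drawn log-uniformly from 2.5–25, up- or
down-regulated with equal probability (both directions occur in the
assay). An optional smooth intensity-dependent bias — a sine of the
standardized mean log-intensity — can be injected to exercise the lowess
correction (default off).

What the generators deliberately do *not* model: optical aberrations and
uneven illumination, touching/overlapping nuclei, cell division and
field-exit during tracking, electrode fouling or peak asymmetry
(Laviron-type kinetics), spatial spot artifacts and background on
arrays, and any cell-cell or mechanistic coupling. Passing tests
therefore demonstrate correctness of the estimators under clean,
known-truth conditions, not robustness to every real-data pathology.

## Nucleus detection and labeling

Detection is point-detection, not segmentation — the analysis needs
counts and positions only, which keeps the ground-truth comparison exact.
The image is Gaussian-smoothed at *half* the expected spot scale (enough
to suppress pixel noise without blending neighbors); local maxima above
`rel_threshold` (default 0.2) of the smoothed dynamic range are kept,
with a Euclidean separation floor of 2σ enforced by a disk footprint plus
a brightest-first spacing pass (deterministic tie-break by array order).
Spots closer than 2σ merge into one detection; merges are a documented
QC behavior, not silently resolved. On generator images with separation
≥ 3σ and SNR ≥ 10, recall and precision are 1.0 (tested).

Labeling matches BrdU detections to DAPI detections greedily,
nearest-first within `match_radius` (default 6 µm, about a nucleus
radius), each BrdU spot consumed at most once, ties broken by smaller
index; unmatched BrdU detections are reported as a QC count.

## NLI statistic

Per zone and chip, `NLI_chip = 100 · labeled/total`, computed only for
chips with at least `min_count` nuclei in that zone (default 5 — 0/1
count ratios are unstable; the threshold is configurable and reported).
The headline per-zone estimate is the mean of per-chip NLIs — the chip is
the experimental unit, matching a design with 6–8 replicate substrate
chips — with SEM = (population SD of per-chip NLIs)/√n_chips, reported
only for ≥ 2 chips. With one chip the estimate equals the pooled ratio
exactly. Across-chip (not across-cell) dispersion is an interpretive
choice; the assay's replication structure counts chips. A nucleus is a
single point; no fractional assignment across the boundary.

## Tracking and velocity

`link_tracks` is greedy nearest-neighbor frame-to-frame linking with a
`max_step` gate; candidate links are consumed in order of (distance,
track index, detection index), so the output is deterministic; crossing
cells within the gate may swap identity (documented greedy behavior).
Unlinked detections start new tracks; singleton tracks are excluded
downstream.

`cumulative_distance` resamples positions to an hourly grid by taking the
*nearest* recorded sample — not interpolating — so measured path lengths
are preserved, then sums Euclidean displacements between consecutive grid
positions. The velocity is the OLS slope of cumulative distance on time
*with intercept*: "slope of the best-fit line" is ambiguous, and a free
intercept absorbs the migration-initiation lag seen on line patterns
without biasing the steady-state slope. Per-condition summaries are
mean ± SEM over cells. Tracks are truncated at division or field exit;
no stitching. MSD, persistence statistics, and chemotaxis indices are out
of scope.

## Electrochemistry

Peak detection fits a linear baseline to the flanking 10% of each sweep
segment, then finds prominence-ranked extrema of the corrected current
(maxima anodic, minima cathodic; floor 0.5 µA) with 3-point parabolic
position refinement, so peak positions are sub-grid accurate.

Wave integration uses a chord baseline between the window endpoints — a
simple, deterministic choice adequate for monolayer waves on a linear
capacitive background — and the trapezoid rule;
`Q = (1/ν)∫|i − chord| dE` with µA·mV/(mV/s) → 10⁻⁶ C. Integration
matches the analytic Gaussian integral within 0.5% at ≥ 200
points/segment (tested). `Γ = Q/(nFA)` exactly.

The kinetics fit minimizes least squares of `f(t) = 1 − exp(−kt)`,
initialized from the through-origin linearized regression of −ln(1−f) on
t excluding near-saturated points (f ≥ 0.99); all-zero or overall
non-increasing series fail with a diagnostic rather than returning a
spurious rate. Conversion fraction is defined as oxime reductive charge
over initial quinone reductive charge; the fitter accepts any fraction
series regardless of provenance.

## Expression filtering

Per-spot ratios are the plain two-channel ratios (no background
subtraction — the upstream feature extraction is out of scope). The
lowess correction (statsmodels, span 0.4, delta = 1% of the A-range for
speed) is per chip; spots with a non-positive intensity in either channel
are excluded from the fit and set missing. The replicate test is a
two-sided one-sample t-test of the 4 per-condition replicate corrected
log-ratios against 0 — the common reference channel on the same array is
the comparator; replicate pairing is per-condition. A zero replicate
variance with non-zero mean is floored at machine epsilon (scaled by the
mean), so identical non-null replicates give a vanishing p rather than
0/0. No multiple-testing correction is applied by default (the filter
rule is a raw p < 0.05); this is a faithful-reproduction choice.

Selection: a gene passes when some condition has p < α (0.05) and its
condition-mean fold `2^(mean corrected M)` meets the threshold (default
2.5). The default direction is `both` (≥ 2.5 or ≤ 1/2.5): the filter's
"larger than 2.5" phrasing conflicts with the "differed 2.5-fold or more"
description, and clearly down-regulated genes are among the highlighted
results, so magnitude-in-either-direction is the default with `up`
available. Raising the fold threshold or lowering α never adds genes
(tested). Simulations default to 5,000 genes standing in for a ~41k-probe
array — large enough to calibrate the type-I rate within a point while
keeping the suite fast.

Clustering is average-linkage on 1 − Pearson correlation over
condition-mean log-ratio profiles, with optimal leaf ordering for a
deterministic dendrogram; constant profiles (undefined correlation) get
the maximum distance 2 with a warning.

## Problem sizes and tolerances

Default sizes throughout are those of the study conditions (6 chips;
12 cells × 30 h; 13 kinetic timepoints; 400 points per CV segment) or,
where the study does not fix them, chosen so Monte-Carlo error is small
against the differences being resolved (per-zone nucleus counts; 5,000
genes). Deterministic numerical checks use 0.5% (integration) or
machine-precision (noiseless fits) tolerances; stochastic recovery checks
use seeded runs at the sampling error implied by these sizes.

## Known limitations

- Greedy linking and greedy label matching are not globally optimal
  (no Hungarian assignment); adequate at the assay's densities.
- The chord baseline under-integrates strongly overlapping redox couples;
  no peak deconvolution is attempted.
- The NLI pipeline treats nuclei as points; touching-nucleus splitting
  and stain bleed-through are out of scope.
- Only circle and line patterns are supported — the two geometries the
  assay uses; arbitrary polygons are not.
- The expression stage models no probe annotation or enrichment analysis;
  it ends at the filtered, clustered gene × condition table.
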