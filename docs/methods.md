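# Methods

This note records the models implemented, the defaults chosen where the
underlying assay conventions leave freedom, and what the synthetic-data
generator does and does not emulate.

## Image model and segmentation

Nuclei are rendered as hard disks at background + signal on a uniform
background with additive Gaussian camera noise, clipped to 16-bit. There is
no point-spread function, no illumination gradient by default, and no texture
inside nuclei. This is the simplest model that exercises every downstream
contract (thresholding, watershed splitting, ring geometry, background
subtraction); passing segmentation tests on it demonstrates correctness of
the mask logic, not robustness to real microscopy artefacts (debris,
out-of-focus nuclei, uneven illumination).

DNA content is encoded the way interphase DAPI staining behaves: the DAPI
*mean* is held constant while nuclear *area* scales linearly with content
(radius ∝ √content), so integrated DAPI ∝ DNA content. Mitotic nuclei are
rendered condensed — half the G1 area at 4× the interphase DAPI mean — which
preserves integrated DAPI ∝ content while giving the DAPI-MFI mitosis gate a
real signal to detect.

Segmentation: global Otsu on DAPI, hole filling, watershed on the Euclidean
distance transform with peak markers separated by at least √(min_area/π)
pixels (ties resolved row-major, i.e. to the lowest label), area filter
[80, 5000] px at the synthetic scale, border-touching components excluded by
default. The cytoplasm is approximated by a dilation ring (gap 1 px, width
5 px) because no cell-border channel exists in this data model; contested
ring pixels go to the nucleus with the nearer centroid and rings never
overlap nuclei. Background is the per-field 25th-percentile pixel intensity
(linear-interpolation percentile), subtracted from means and floored at 0.

## Cell-cycle gating

The EdU threshold is fitted first (Otsu on log EdU); the two-component
Gaussian mixture for the 2N/4N peaks is then fitted by EM on log integrated
DAPI of EdU-negative cells only, so the S-phase continuum between the peaks
cannot bias them. Phase windows are mode ± 2.5 component s.d. (log space).
Rule order: S by EdU first, then the 2N window (G1), then the 4N window
within which DAPI MFI above an Otsu threshold (restricted to 4N cells) calls
M; an H3pS10 channel overrides the DAPI-MFI rule when supplied. The M gate
is only armed when the 4N DAPI-MFI split is bimodal enough (upper/lower mean
ratio > 1.5); otherwise no M calls are made rather than splitting G2 noise.
Cells outside every window stay `unclassified` and are excluded from
summaries. Gates are scale-free: multiplying all intensities by a constant
shifts every fitted threshold correspondingly and leaves calls unchanged.

Condition contrasts follow the assay's reporting conventions: one-way ANOVA
across conditions per phase, pairwise comparisons against the reference
condition with Šídák adjustment (p' = 1 − (1−p)^m, m = comparisons per
phase), and seeded bootstrap percentile CIs (2,000 resamples) on ratios of
means.

## Screen normalization and hit calling

Raw per-well values are mapped per plate through the control anchors (cGAS
siRNA mean → −1, negative-control mean → 0, epoxomicin mean → +1) by the
continuous piecewise-linear transform with distinct slopes below/above the
negative anchor; three anchor points are not generally collinear, so a
single linear map cannot satisfy all three. Scores are invariant to any
positive per-plate affine transform of the raw intensities. Plates whose
anchors are not ordered c− < c0 < c+ are flagged invalid and excluded.

**The 3-s.d. population.** The hit rule compares each well's score to the
negative-control mean. With only two negative wells per plate, those same
wells define the plate's zero anchor, which makes their own score spread a
biased yardstick: per-plate centering leaves the negative scores with
variance σ²/2 while sample scores carry the anchor-estimation error on top
of their own noise (≈1.5σ²). A threshold of 3 × s.d.(negative scores) would
therefore flag ~5% of null wells rather than 2·Φ(−3) ≈ 0.27%. The default
s.d. is instead estimated from the sample wells themselves — the standard
deviation after excluding wells more than 3.5 normal-scaled MADs from the
median, so that genuine hits cannot inflate the estimate — which restores
the Gaussian calibration. The literal negative-control variant remains
available (`sd_method="negatives"`) for comparison with the published
convention.

A second, smaller effect is worth knowing: because each plate's anchors are
re-estimated from noisy control wells, the anchor error enters both the
numerator and the slope of every score on that plate. The induced
correlation slightly damps the 3σ tails of the end-to-end null score
distribution (empirically ~0.20–0.23% two-sided at the default noise instead
of 0.27%). This is a structural property of anchor normalization with two
negative wells per plate, not an estimator defect; the acceptance script
reports both the rule-level (Gaussian-score) and the end-to-end null hit
fractions.

**Generator noise default.** Well noise is drawn in anchor-score space
(s.d. 0.04) and mapped through the inverse normalization, guaranteeing that
a gene's expected score equals its planted effect. The default corresponds
to a Z′ factor of ≈ 0.76 against the epoxomicin anchor — a high-quality
strong-control imaging assay; the well-to-well variance structure of any
real screen is unknown here, so this is a declared free parameter, not an
estimate. Gene-level calls default to ≥1 of 3 siRNA wells hitting in a
consistent direction; wells under 50 cells are flagged and excluded from
s.d. estimation but kept in reports.

## Decay and tracking

Chase and post-mitotic decay are fitted as N(t) = N₀e^(−kt) by ordinary
linear regression of log N on t — closed-form and unbiased under the
generator's median-preserving lognormal noise, and adequate for 4-point
chases; a nonlinear refinement on the original scale is available
(`refine=True`). Increasing series clamp k to 0 (half-life ∞) with a
warning. t½·k ≡ ln 2 whenever k > 0.

Tracking is greedy nearest-centroid frame-to-frame linking (ties by smaller
distance, then lower label; default max displacement 20 px; default frame
interval 5 min), justified by near-stationary interphase nuclei; it is not a
global assignment and will not survive dense crossing traffic. Relative MFI
is per-track, first post-mitotic frame = 1; normalization to a population
mean is the caller's choice of reference index. PCNA texture is summarized
as (P99 − median)/median of the smoothed in-nucleus intensities; punctate
iff strictly above 1.0. G1→S is the first frame opening ≥3 consecutive
punctate frames, S→G2 the first subsequent run of ≥3 diffuse frames;
single-frame flickers are ignored.

## Binding kinetics

The 1:1 Langmuir model is fitted globally across all concentrations with
shared k_on, k_off and R_max, in log-parameter space (positivity by
construction), by Levenberg–Marquardt from a 3×3 multi-start grid: k_off
initial guesses span 0.1–10 times 1/t_split and k_on guesses are tied to the
median analyte concentration. The best residual sum of squares wins.
Default timing is 300 s association / 600 s dissociation. Dissociation-only
input yields k_off from the log-linear decay with k_on flagged unreliable.
Baseline subtraction (pre-association mean) is available but off by default
since the generator plants no drift.

## Problem sizes and numerical choices

The test suite and acceptance script use populations of 5,000 cells for
gating, 420×420 px fields with ~45 nuclei for segmentation, a 10,032-well
null screen plus a 100-gene planted screen for hit calibration, 500 noisy
chase replicates, and 5 binding fits over a 50–5000 nM K_d grid at 1%
full-scale noise with 2 s sampling — sizes at which every Monte-Carlo
tolerance asserted is several binomial/empirical standard errors wide while
the whole suite stays fast. All randomness flows through
`numpy.random.default_rng` seeds; Gaussian-mixture fits use fixed
initialization (quartile means) and a fixed random state, so gate fitting is
deterministic for a given table.

## Known limitations

The generator does not emulate illumination gradients (an optional shading
stress exists), segmentation-error-correlated feature noise, plate spatial
effects (edge rows, gradients) or siRNA off-target structure; screen results
therefore validate the scoring conventions, not robustness to those
artefacts. Phase-fraction recovery assumes well-separated EdU and DAPI-MFI
populations, as planted; heavily overlapping populations would need the
`quality="degraded"` escape hatches. Tracking assumes no divisions within a
track (lineage splitting is out of scope).
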