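# Methods

## The completeness model

Spinal ultrasound sweeps frequently miss vertebrae — rib shadowing, narrow
acoustic windows, and depth attenuation make some levels invisible — yet
standard object-detection metrics (mAP, precision/recall) say nothing about
*which* anatomy was covered.  `vpmkit` represents coverage explicitly.  The
thoracolumbar spine is a fixed ordinal scale of V = 17 levels, T1…T12
followed by L1…L5 (ordinals 1…17).  For frame *i*, the ground-truth
presence vector is

    y_i = [y_i,1 … y_i,17] ∈ {0,1}^17,   y_i,v = 1 iff level v is annotated,

and the predicted vector thresholds detector confidences:

    ŷ_i,v = 1  iff  ∃k : s_i,v^(k) ≥ τ,

where s_i,v^(k) is the confidence of the k-th detection for level v.
Stacking frames gives the Vertebra Presence Matrix (VPM), an N×17 binary
table.  In evaluation mode a detection must additionally overlap a
same-level ground-truth box at IoU ≥ 0.5 to count (the validity rule used
when scoring detector output against annotations); in prediction-only mode
the gate is off because there is nothing to gate against.

Completeness is summarised as

* overall accuracy: (1/NV) Σ_i Σ_v 1[y_i,v = ŷ_i,v];
* per-level accuracy: (1/N) Σ_i 1[y_i,v = ŷ_i,v];
* per-scan completeness rate: the fraction of scans whose OR-aggregated
  prediction covers every level the OR-aggregated truth marks visible;
* mean missing-vertebra frequency: the mean over scans of
  |{v : gt=1, pred=0}| / |{v : gt=1}|.

The scan-level pair is defined so that a perfect predictor scores (1, 0)
and a predictor that misses everything scores (0, 1).

Two reduction modes exist because the natural evaluation unit differs by
dataset type.  On full-spine frames every (frame, level) cell is a trial
(`all-levels`, the N·V denominator above).  On vertebra-centric crop
datasets each image contains exactly one annotated vertebra, so only that
cell is a meaningful trial (`annotated-only`); per-level counts are then
vertebra–image pairs.  In `all-levels` mode the overall accuracy is exactly
the pair-weighted mean of the 17 per-level accuracies (asserted as a
property test).

## Geometry

Boxes are half-open, continuous-pixel, origin top-left, y running
cranio-caudally.  The full-spine ROI of a subject is the minimal rectangle
enclosing all of its annotated boxes, applied unchanged to every frame of
that subject (no registration is attempted).  A vertebra-centric crop
scales a box about its center by (1+α_lat)·s laterally and (1+α_long)·s
longitudinally, with α_lat = 0.15, and α_long = 0.20 for thoracic levels
(to retain adjacent rib cues) but α_lat for lumbar levels (symmetric
padding).  The "slightly larger" thoracic padding is not quantified in the
source analysis; 0.20 is the package default as the smallest round
increment preserving the stated asymmetry, and it is configurable.  The
crop-scale sweep s ∈ {1.00, 1.25, 1.50, 2.00} composes multiplicatively
with α (s = 1 reproduces the plain padded crop); whether the original
analysis composed or replaced α is unstated, and composition is the
package's choice because it keeps the sweep a pure scale factor.  Crops are
clamped to the frame and an entirely out-of-frame crop is an error.

Detection–annotation matching is greedy in descending confidence with a
0.5 IoU floor and level agreement when both sides carry labels — the
standard detection-evaluation convention.  Exhaustive (Hungarian-style)
matching was not used; a unit test compares the greedy result against the
obviously-optimal answer on a constructed two-detection instance to document
the behavioural difference.

Frames are standardised to 640×640 grayscale in [0,1]; integer inputs are
divided by 255, float inputs are required to be in [0,1] already, resizing
is bilinear, and same-size inputs pass through bit-exactly.

## Sequence correction

Crop-level classification cannot reliably identify a vertebra's level:
adjacent thoracic vertebrae look nearly identical and the crop discards
global position.  The observed failure mode is high-confidence label
collapse (mid-thoracic crops labelled T1 at confidence > 0.9).  The
correction layer repairs this globally.  Given detections ordered by sweep
position, it solves the maximum-weight monotone assignment

    maximise  Σ_assigned [ w_label · c_i · 1(pred_i = level) + w_pos · prior_i(level) ]
              − penalty · #suppressed
    subject to assigned levels strictly increasing in position order,

with prior_i(v) = 1 − |ρ_i − (v−0.5)/17| and ρ_i = (rank_i − 0.5)/n the
rank-normalised position.  Rank normalisation needs no physical
calibration and treats sweep indices and pixel coordinates identically.
The optimum is exact via dynamic programming over (item, level) states in
O(n·17) (O(n²·17·g) when the optional hard max-gap g is enabled; by default
implausible jumps are discouraged only by the prior).  Defaults
w_label = 1, w_pos = 1, penalty = 0.05 let a full sweep's positional
evidence override any single corrupted label while still letting strong
label agreement win locally.

Ties are broken deterministically: higher objective (within 1e-9), then
more items assigned, then the prefix-lexicographically smaller level
sequence.  This guarantees reproducibility; it enforces lexicographic
minimality through prefix comparisons rather than by enumerating the full
equal-objective set, which matters only on exactly-tied objectives.

The layer never invents detections: every item is either assigned or
suppressed (a conservation property asserted on every result).  Missing
levels are split into interior gaps (inside the assigned span — genuinely
undetected anatomy) and uncovered levels (outside the span — possibly
simply outside the imaged field).  Correction is idempotent in the
following sense, asserted as a property test: re-running with all items
kept, assigned items relabelled to their final levels and suppressed items
keeping their raw predictions, reproduces the identical assignment.  (The
variant that feeds back only the assigned items changes the position ranks
and hence the prior, and is not an invariant of the objective.)

The DP is verified against an independent brute-force oracle — exhaustive
enumeration of every subset of items crossed with every strictly increasing
level tuple — on 200+ random instances with ≤ 6 items.

## Statistics

Blind zones (levels with reproducibly reduced completeness) are tested
with paired Wilcoxon signed-rank tests per level, comparing per-frame
completeness scores between two detector configurations, with Bonferroni
control at α = 0.05/17 over the 17-level family.  Pairing is by frame and
is required explicitly; unpaired input is refused rather than silently
aligned.  Effect size is r = |Z|/√N with N the number of paired samples
supplied (zero-difference pairs are discarded for the statistic, classic
Wilcoxon style, but N in r refers to the supplied pairs; the nonzero count
is reported alongside).

The signed-rank p-value is exact for ≤ 25 nonzero pairs — the null
distribution of W⁺ is enumerated by a subset-sum DP over the (possibly
tied, average-assigned, half-integer) ranks, so exactness survives ties —
and a tie-corrected normal approximation beyond that.  The approximation
is cross-checked against `scipy.stats.wilcoxon` and the exact branch
against both SciPy (tie-free cases) and hand-enumerated examples.  Under a
simulated continuous null the empirical type-I error at nominal 0.05 stays
within 3 Monte-Carlo standard errors over 2000 replicates (asserted).

Pooled contrasts (one level against the other 16 pooled) use the pooled
two-proportion z-test, two-sided, without continuity correction: on the
reference counts (35/48 at T7 vs 573/681 pooled) the uncorrected variant
yields z ≈ −2.02, p ≈ 0.043, matching the published contrast, which a
continuity-corrected variant does not.  Binomial intervals default to
Wilson score (whose upper bound reproduces the published 0.834 at T7; the
published lower bound 0.595 matches neither Wilson ≈ 0.590 nor
Clopper–Pearson exactly and is recorded, not asserted).  Both delegate to
`statsmodels.stats.proportion` with closed-form oracles in the tests.

## Synthetic data

No clinical scans ship with the package, so a simulator generates
detection-level data with the structure the analysis assumes.  A scan is a
sweep of 10–40 frames (uniform); each of the 17 levels occupies a canonical
horizontal band of a 640×640 frame at its axial midpoint.  Per frame and
level: the level is annotated with probability `p_visible` (default 1 —
every in-ROI level is annotated); a detection fires with per-level
probability `p_detect`, whose default profile is the observed per-level
completeness of a 17-class crop detector (lowest at T7 ≈ 0.729, dips at
T10 and the lower lumbar levels); the predicted label is drawn from a
confusion kernel with mass 0.90 on the true level, 0.06 split between
existing neighbours, and 0.04 collapsed to T1 (the observed failure mode;
illustrative, not fitted); confidence is Beta(8,2) for label-correct and
Beta(5,2) for confused detections — the confused shape deliberately admits
confidences above 0.9; the detected box jitters by a 2 px Gaussian on the
center.  Streams are seeded by (seed, scan_index), so individual scans are
independently reproducible.

All simulated geometry and confidences are quantised to the 1e-6
normalised-coordinate grid of the YOLO text format via the same conversion
helpers the readers use, which makes write → read → write byte-identical.

What the simulator does *not* emulate: ultrasound pixel appearance
(speckle, shadowing), partial per-frame fields of view (every visible
level appears in every frame by default), inter-frame correlation of
misses, and operator behaviour.  Two consequences worth knowing: passing
tests demonstrate the *analysis* pipeline is correct, not that any
detector performs well on real scans; and because per-frame detection is
independent across 10–40 frames, OR-aggregation saturates scan-level
coverage under the defaults (per-scan completeness ≈ 1, missing frequency
≈ 0), so the frame-level metrics are the informative simulated outputs.

Two deterministic fixtures reproduce published evaluation inputs exactly:
`reference_per_level_fixture()` realises the per-level vertebra-image-pair
and correct-match counts of a 729-crop validation table (each "correct"
frame carries a same-level detection at IoU 1, confidence 0.9 > τ; the
rest carry none), and `corrupted_sweep_fixture()` the five recorded
high-confidence misclassifications (T8→T1 @0.99, T9→T1 @0.95, L1→T12
@0.88, T2→T7 @0.81, T3→T1 @0.91) in an otherwise correctly labelled
17-crop sweep.

## Numerical and interface choices

* τ defaults to 0.25 (the detector's inference confidence threshold);
  IoU validity threshold 0.5; both exposed everywhere.
* Report accuracies are printed at 3 decimal places, half-up.  Two rows of
  the reference table are internally inconsistent with their own counts
  (22/23 = 0.957 vs a printed 0.913; 52/61 = 0.852 vs a printed 0.853);
  the package always trusts the counts.
* A per-level accuracy with no evaluated pairs raises
  (`UndefinedMetricError`) rather than imputing 0, 1 or NaN silently, so
  downstream blind-zone statistics cannot be quietly biased; the assembled
  report marks such levels NaN explicitly.
* Class-index mapping in label files is 0→T1 … 16→L5; detections append
  confidence as a sixth column.  Train/validation splits are tagged per
  subject and validated to be subject-disjoint; leakage is a hard error.
* Single-class (no-label) detections are rejected by the presence
  thresholder with a pointer to the two supported labelling routes — IoU
  matching against ground truth, or positional assignment through the
  correction layer.  Which route the original analysis used for its
  single-class variants is unknown, so neither is silently assumed.

## Problem sizes in the shipped checks

The test-suite simulations use 80 scans × 20–30 frames (~2000 frame-level
trials per level) for parameter recovery, 2000 replicates × 20 pairs for
the Wilcoxon null calibration, and 200+ random ≤ 6-item instances for the
DP-vs-enumeration equivalence; the acceptance script simulates the default
40-scan, 10–40-frame study shape.  These sizes put Monte-Carlo error well
inside the asserted 3-standard-error bands while keeping the whole suite
in the seconds range.

## Known limitations

* Scan-level metrics require an external grouping of frames into scans
  (the manifest); there is no inference of scan boundaries.
* The ROI is propagated per subject verbatim; no frame registration.
* The correction prior assumes the sweep spans the spine roughly
  uniformly; strongly non-uniform sweeps would bias the rank-normalised
  positions (a hard max-gap can partially compensate).
* Temporal smoothing across cine frames is out of scope.
* mAP/precision/recall and detector training are out of scope; the package
  consumes detector output, it does not produce it.
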