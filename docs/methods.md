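# Methods

`erpmarker` re-implements, as a reusable library, an event-related-potential
(ERP) neuromarker pipeline for early-stage Parkinson's disease (ESPD): from
multichannel task EEG epochs, through spatiotemporal parcel features, to a
cross-validated logistic-regression marker with ROC and correlation-based
evaluation. Because no public recordings accompany the original study design,
the package ships a first-class synthetic cohort generator that emulates the
study's two cognitive tasks and its reported group effects; every downstream
stage is exercised end to end on that generator.

## The synthetic cohort

**Task designs.** Each subject performs an auditory Oddball task (AOB: 400
tones, 80% Frequent / 10% Target / 10% Novel, stimulus-locked epochs
−200..+1200 ms) and a visual Go/No-Go task (VGNG: 400 letters, 80% Go / 20%
No-Go, stimulus-locked −200..+800 ms, plus response-locked Go epochs
−400..+500 ms). All data are 64-channel (10-10 layout with TP9/TP10 mastoids,
FCz as the absent recording reference) at 250 Hz. Condition counts are exact
at the design trial count; epoch windows are half-open `[start, end)`, so a
VGNG stimulus epoch has exactly 250 samples.

**Signal model.** Every trial is a sum of component "bumps", each separable
as Gaussian-in-time × Gaussian-in-montage-distance, multiplied by a cosine
carrier at the center of the component's frequency band, plus white Gaussian
noise (default SD 6 µV per sample). The carrier guarantees each planted
component survives band-pass filtering into its own band and is recoverable
by peak detection. The default inventory: P50 (+, 50 ms, beta), N100 (−,
100 ms, alpha), P200 (+, 250 ms, alpha), N2 (−, 300 ms, alpha; Novel and
No-Go only), P300 (+, 400 ms, delta; response-relevant conditions), and a
response-locked motor-preparation P-200 (+, −200 ms, alpha, over the left
motor cortex). Carriers are spread across bands because a band of width B Hz
cannot temporally resolve events closer than roughly 1/B — stacking four
close-spaced components inside the 6 Hz-wide alpha band would produce one
continuous oscillation whose extrema sit between the planted latencies. The
three alpha components sit on the phase-coherent 10 Hz carrier grid (crests
at 50 + k·100 ms, troughs at 100 + k·100 ms), so their mutual ringing
reinforces every planted peak instead of displacing it; the delta carrier
(2.5 Hz) sits high enough in its band that the P300 peak stays sharp and
clear of the theta passband.
Topographic centers coincide with electrode positions (Fz, Cz, Pz, C3);
centers between electrodes make the detected peak channel flip from subject
to subject and split group clusters. Between-subject variability enters via
per-subject draws of latency (SD 6–18 ms), amplitude (SD ~20% of the mean)
and scalp position (SD 0.05 montage units). Amplitude and latency values are
package choices — the study reports no component-level distributions — and
are owned by `CohortDesign`.

**Group effects.** Early-stage patients carry a latent severity scalar
s ~ N(1, 0.3) truncated at 0.2 (established patients N(1.35, 0.45)) that
scales five default effects: No-Go P50 amplitude +1.2 µV, Novel N100 latency
+16 ms, Frequent P200 amplitude −1.2 µV, and per-trial topographic jitter of
SD 0.5 montage units for Novel P200 and response-locked P-200. Trial-level
topographic jitter spatially smears the patient's average response, which
lowers both its topographic similarity to the healthy template and (as a
physically coherent side effect) its measured amplitude. The jitter SD is
large relative to the component's spatial width (ratio 1) because the patch
correlation is insensitive to smaller smearing: for Gaussian spatial
profiles the similarity falls as 2ab/(a²+b²) with a the template width and
b the smeared width, ≈ 0.94 at ratio 1. Severity also enters the motor UPDRS
score linearly (20 points per unit severity, noise SD 6), so a marker-mUPDRS
correlation near 0.7 is recoverable by construction at n = 20. LEDD is drawn
independently of severity, so its null correlation with the marker is also
by construction.

**Behavior.** Response times are lognormal (median 420 ms for Go, 490 ms for
Target; shape 0.21, giving an RT SD near 90 ms); accuracy parameters follow
the reported task-performance table (e.g. Go accuracy 95% controls vs 92%
patients). Behavior never enters the marker directly, but it does shape it
indirectly: only correct trials are averaged, so a group that commits more
errors has fewer trials per ERP — higher variability scores and noisier
peaks. That accuracy gap is therefore treated as part of the disease effect
and is scaled down together with the component effects (`effect_scale`), so
a zero-effect cohort is exchangeable between groups in every respect.

**What the generator does not emulate.** No volume conduction or forward
modeling, no 1/f background spectrum or oscillatory rhythms, no eye/muscle
artifacts, no electrode impedance drift, no missing channels. Passing tests
therefore demonstrate that the pipeline recovers the statistical structure it
assumes — planted components, group shifts, severity coupling — not that it
would survive the artifact load of real recordings, whose cleaning is out of
scope here.

## ERP processing

Epochs are re-referenced to the mastoid average (mastoid channels stay in
the array so the channel axis keeps matching the montage, but all feature
code restricts itself to the 62 scalp channels). Band-pass filtering uses a
zero-phase forward-backward 2nd-order Butterworth per band (delta 0.5–4,
theta 3–8, alpha 7–13, beta 12–30, broadband 0.5–30 Hz): unit gain at band
center, >20 dB one octave outside the edges, and no group delay, so peak
latencies are unbiased. The low order was chosen deliberately: higher-order
IIR bandpasses ring longer than the inter-component spacing and displace
measured peaks on short epochs. Averages use correct trials only. Because
filtering and averaging are both linear, `average_erp` averages first and
filters once (a property test asserts commutation to 1e-8 relative).
Baseline correction subtracts the per-channel mean of the pre-stimulus
interval; response-locked epochs use the earliest 100 ms of their window
instead, since the immediate pre-response interval contains the motor
preparation being measured.

## Parcel features

**STEP extraction** finds per-channel temporal peaks of both polarities with
prominence ≥ 0.5 µV, then applies non-maximum suppression across space and
time (radius 1.2 montage units × 60 ms, same polarity only), keeping the
largest-|amplitude| extremum with deterministic tie-breaks (earlier latency,
then more posterior channel). Each parcel carries a ±100 ms × all-scalp-
channels patch, zero-padded at window edges.

**Group clustering** pools the reference group's parcels per (band, task,
condition, lock, polarity) and clusters them by average-linkage agglomeration
in normalized (time, lr, pa) space — 50 ms of latency ≙ 0.3 montage units,
cutoff 1.5 — keeping at most one parcel per subject (nearest to the cluster
mean) and retaining clusters present in ≥ 70% of subjects. The reference
group is, by default, a separate synthetic normative pool of healthy
subjects (24 unless configured otherwise), standing in for the proprietary
age-binned normative database; building templates from the cohort's own
controls is available as an option (`reference="hc"`) but is circular — the
controls' patches are inside the templates they are scored against, which
inflates their match rates and similarity scores and, empirically, drives
the cross-validated AUC of a zero-effect cohort to ≈ 0.8. A disjoint pool
restores the null. Cluster means define the template (time, location,
patch, amplitude).

**Component labels** map (polarity, latency window, lock) to canonical names
(P50 +30..80, N100 −80..150, P200 +150..275, N2 −200..350, P300 +275..600,
P-200 +−250..−150 response-locked; half-open windows, validated to be
non-overlapping per polarity and lock). When several templates of one band
and condition fall in a window, the plain label goes to the largest-amplitude
one — the conventional reading of "the" P200 of a band ERP — because filter
side lobes of neighboring components also produce consistent, smaller
templates in the same window.

**Matching and scoring.** Subjects are matched one-to-one to templates
(greedy by ascending normalized distance, gated at 80 ms and 0.6 montage
units); templates with no admissible parcel are missing, never forced. Five
attributes per matched template (amplitude, latency, lr, pa, topographic
similarity) plus nine-region ERP variability scores per epoch set form the
feature table. Topographic similarity aligns the subject patch to the
template peak in time (patches are peak-centered) and space (nearest-channel
translation), then takes the Pearson correlation of the overlapping samples.
ERP variability is the across-trial standard error of the broadband-filtered
single trials per electrode, averaged over the epoch and then over each of
nine scalp regions (anterior/central/posterior × left/midline/right, derived
from 10-10 channel-name geometry; the original region table is unavailable,
so the grid is shipped as editable configuration).

## Classifier protocol

Features are selected per training set by a univariate two-sample F-test at
false-positive rate alpha = 0.05 (the conventional test behind this selection
method; the study names the method but not the test or alpha). The logistic
model p = 1/(1 + e^−(b0 + Σ b_i x_i)) predicts the probability of being
healthy and is fitted by maximum likelihood with a weak ridge penalty
(inverse strength C = 100) purely for separable-data stability; features are
standardized and missing values imputed by medians, all recomputed inside
each training fold so nothing leaks from held-out subjects. Cross-validation
is stratified 10-fold; because 19 patients cannot split into ten folds of
two, nine folds hold out 2 patients and one holds out 1 (the printed "3 + 2
per fold" is consistent only with 20 patients). Established patients never
enter training; they are scored by the final model's linear term b0 + Σ b_i
x_i, which is monotone in the probability and suited to linear correlation.
Feature importance is |b_i| normalized by the sum over selected features.

## Evaluation

ROC analysis uses pooled out-of-fold scores with patients as the positive
class; the AUC equals the pairwise Mann-Whitney win probability with ties
counted 1/2. Its 95% CI is Hanley-McNeil with the patient count in the
(n_pos − 1)(Q1 − A²) term, which reproduces the published interval for
AUC 0.79 at 19 vs 30; a DeLong-style bootstrap is cross-checked in tests.
The operating point maximizes sensitivity subject to specificity > 0.5, ties
broken by specificity then lower threshold. Group separation uses the
Mann-Whitney U with the continuity-corrected, tie-corrected normal
approximation (the continuity correction is required to reproduce the
published Z = −3.38 from U = 120; without it Z = −3.39). Correlations are
Pearson with Student-t p-values (n − 2 df) and Fisher-z intervals. The 2×2
chi-square is Pearson's without continuity correction (Yates behind a flag);
neither standard variant reproduces the study's printed gender p = 0.012
(uncorrected gives 0.0155, Yates 0.034), so that value is documented as not
reproducible rather than matched. The gender-balance check subsamples the
control group to all male controls plus 3 female controls drawn without
repetition across 5 iterations (15 females are exactly exhausted) and
reports the mean and range of the AUC.

## Problem sizes and tolerances

The repeated-cohort acceptance suites run the full pipeline at reduced
trial counts (30% of the design for the 20-seed recovery suite with the
30 + 19 group sizes unchanged; 10% with 10 + 8 subjects for the 20-seed
zero-effect null), sizes chosen so the whole suite runs on one desktop CPU
while every planted effect remains reliably recoverable. Planted-template
recovery (±2 samples) and the five effect directions are checked on a
full-design (400-trial) cohort, where the recovery guarantee holds; the
acceptance script's study replica also runs the full designs with all three
groups.
Numerical tie-breaks are deterministic throughout; all randomness flows from
`numpy.random.SeedSequence` spawning, so a run is bit-reproducible given its
seed. Simulated epochs are stored float32 for memory; statistics are
computed float64.

## Known limitations

- The similarity and ERP-variability definitions follow the published
  outline ("correlation after aligning peaks", "based on the standard
  error") but the proprietary reference implementation may differ in patch
  window, aggregation, or matching policy (one-to-one greedy here).
- The feature manifest size is data-dependent (several hundred on the
  synthetic cohort, including band-leakage and side-lobe templates); the
  published 199-feature count depended on proprietary normative templates
  and is not reproducible.
- With strong planted effects the synthetic replica separates groups more
  cleanly (AUC ≈ 0.9+) than the published cohort (AUC 0.79); the acceptance
  criteria are therefore directional and threshold-based, not point matches
  to published classification numbers.
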