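# Methods

This note documents the models, heuristics and numerical choices behind
`catransient`: what each stage computes, which parameters matter, what
the synthetic-data generator does and does not emulate, and where the
design was genuinely open.

## Signals and units

A signal is one cell's Fura-2 340/380 nm ratio trace, uniformly sampled
at `F` Hz (study regimes ≈ 8.3, 11 and 23 Hz; each class was recorded
predominantly at one rate: LQT1 at 8.3 Hz, HCM and WT at 23 Hz, CPVT at
11 Hz). Timestamps are implicit (`t = index / F`); all time quantities
are index differences divided by `F`. Ratio values are arbitrary units;
amplitudes, derivative extrema and areas are reported in those raw units
and their time derivatives, durations and the peak-to-peak interval Δ in
seconds. Every derived variable is invariant to a constant baseline
offset, and the analysis is scale-invariant after standardization, so the
absolute ratio calibration never matters.

## Peak delineation

The delineation contract is three landmarks per transient: beginning
`a`, top `c`, end `g`. The detector is a documented heuristic (the
recognition algorithm used on the original data is not public):

1. smooth with a moving average of width `⌈0.1 s · F⌉` (forced odd);
2. estimate the noise SD from successive differences restricted to quiet
   samples (lowest quartile of the smoothed trace) — peak flanks dominate
   the raw median otherwise — and scale by the smoothing window;
3. find local maxima with prominence ≥ 5 noise SDs;
4. merge adjacent maxima whose separating valley stays above 40 % of the
   lower maximum's height over baseline (10th percentile): a shoulder or
   notch on a flank is a deformity of one transient, not a new one;
5. walk outward from each (group of) maxima to the feet: descend while a
   3-sample lookahead still undercuts the current level by 3 noise SDs,
   then snap to the first crossing of the local quiet level (30th
   percentile of a window past the stop, tolerance 3 noise SDs); the
   rise onset is finally snapped forward on the raw trace while it sits
   at baseline level, because smoothing spreads the onset leftward;
6. reject peaks with fewer than 2 sample intervals per side, clip
   overlaps so `g_i ≤ a_{i+1}`, and drop candidates whose amplitude
   (max of the two side amplitudes) is below 2 % of the largest peak
   amplitude **in the same signal** — the noise-blip rule; the 2 %
   reference is always per-signal, never a global constant.

Peaks truncated by a recording edge are flagged and excluded from
feature tables (their durations would be biased). Delineation is
deterministic and idempotent. On simulated normal signals at 23 Hz the
detector recovers ≥ 95 % of peaks with all three landmarks within ±2
samples of ground truth; at 8.3 Hz a typical rise is only 2–4 samples
long, so landmark precision degrades with the grid, not the algorithm.

All thresholds live in `DetectionParams` (`min_prominence_frac = 0.02`,
`smooth_window_s = 0.1`, `merge_valley_frac = 0.4`).

## Abnormality rules

Each retained peak is labeled abnormal if any of three rules fires,
mirroring the visually described motifs:

* **small**: amplitude below 30 % of the largest peak amplitude in the
  signal (`small_peak_frac = 0.30`);
* **asymmetric**: `|A_l − A_r| / max(A_l, A_r) > 0.40` (`asym_frac`);
* **deformed**: a secondary local maximum inside `[a, g]` with prominence
  (measured down to the valley separating it from the top) above 15 % of
  the peak amplitude (`deform_frac = 0.15`).

A signal is abnormal iff at least one peak is abnormal — an identity of
the annotation object, not a separate computation. Externally supplied
per-peak labels (e.g. an expert's) can override the heuristic. The rule
thresholds are package choices; against the generator's motif labels the
heuristic agrees on ~99 % of peaks at 23 Hz. Missed cases are mostly
deformed shoulders whose bump flattens below the prominence threshold
after smoothing.

## The ten peak variables

Amplitudes and durations are exact index arithmetic. Derivatives are
first central differences scaled by `F` (one-sided at segment ends),
applied over `[a, g]`; the first-derivative extrema are searched on
`[a, c]` (rising) and `[c, g]` (falling), and **both** second-derivative
extrema on the falling segment `[c, g]`. No extra smoothing is applied
beyond the detector's; the differencing choice is isolated in one
function.

The area `R` integrates the curve over `[a, g]` by the trapezoidal rule
and subtracts the trapezoid under the straight chord from `(a, s(a))` to
`(g, s(g))` — the geometric "area between curve and chord". A printed
variant of this formula subtracts only the `s(g)` half of the chord term,
which coincides with the chord correction exactly when `s(a) = s(g)`;
`compute_area(..., mode="strict")` reproduces that literal form, the
chord-corrected version is the default. Curve segments below the chord
contribute negatively.

Δ is top-to-top; the first peak's Δ is measured from the signal start to
its top. Per-signal aggregation for classification defaults to the mean
of the per-peak vectors (`mean_sd` and `per_peak` are available; whether
abnormal peaks contribute is a flag, default on — the study pools normal
and abnormal material at signal level and is silent at peak level).

## Synthetic data

Real recordings are not public, so the generator defines the test
conditions. Two routes:

**Signal space.** A signal is a flat baseline (100 units) plus a train
of unimodal templates: quarter-sine rise over `D_l` (non-zero onset
slope, so the foot is identifiable), exponential-like decay over `D_r`
(shape `(e^{−3v} − e^{−3})/(1 − e^{−3})`). Per-peak `D_l`, `D_r` and Δ
are independent truncated normals with the published class-conditional
moments (durations truncated at `2/F`; Δ truncated below at
`D_l(j) + D_r(j−1) + 3/F` so peaks never overlap — for classes whose
durations are long relative to Δ, notably HCM, the realized Δ mean
therefore exceeds the nominal parameter, and Monte-Carlo tests compare
against the generator's own truncated-normal mean). Amplitude draws are
hierarchical: one truncated-normal signal level, per-peak jitter within
±15 % ("successive harmonious peaks"); `A_r` equals `A_l` for normal
peaks because both feet return to the local baseline — the published
`A_r` marginals are near-identical to `A_l`'s, so nothing is lost.
Abnormal signals carry one or two motif peaks: *small* (5–25 % of the
in-signal maximum), *asymmetric* (`A_r` at 25–50 % of `A_l`, the decay
ending on an elevated plateau before relaxing), *deformed* (a Gaussian
shoulder bump of 20–30 % of the amplitude at 35 % of the decay). Noise
is white (SD 1 unit ≈ 0.5 % of a typical amplitude); noise blips are
narrow sub-2 %-amplitude bumps placed at most one per inter-peak gap,
clear of the feet. Ground truth records every landmark, label, motif and
realized variable. Defaults: cohort counts 90/71/233/133
(LQT1/HCM/CPVT/WT), per-class peak counts tuned to the published totals
(~18 peaks per LQT1/HCM signal, ~10 CPVT, ~9 WT), native per-class
sampling rates as above. The control class's abnormal-signal fraction is
its reported 13/133; the disease classes' fractions are not published and
default to 0.5.

**Feature space.** `simulate_feature_table` draws the ten variables per
signal directly from independent truncated normals with the published
moments. The derivative-extremum variables are consequences of the
template shape in signal space and cannot be imposed there; the
feature-space route draws them faithfully and is the right input for
classifier benchmarking.

What the generator does **not** emulate: covariances between variables
(none are published; independence is the minimal assumption),
photobleaching/drift, biophysical Ca²⁺ cycling kinetics, cell-line
structure (each signal is independent), or realistic derivative extrema
in signal space. Two consequences for interpreting results: classifier
accuracies on synthetic data reflect the separation implied by
independent marginals, not the real data's covariance structure; and
because each class keeps its characteristic sampling rate (as in the
study), duration quantization itself carries class information in the
signal-space route — the feature-space route has no such artifact.
Passing tests therefore demonstrate correctness of the machinery and a
qualitative echo of class separability, never a replication of the
published accuracies.

## Statistics

Per-class summaries are sample means and SDs at peak granularity (the
published summary table is peak-level). Pairwise one-way ANOVA uses
`scipy.stats.f_oneway` per class pair and variable (6 × 10 = 60 tests
with four classes), flagged at the two reported thresholds p < 0.001 and
p < 0.02; raw p values are reported to match the study's practice, with
a Bonferroni column added for transparency. Two constant groups with
equal means get F = 0, p = 1 by convention.

The separability score is a documented **variant** of the Scatter
method, not a replication (the original algorithm is not reprinted
here): features are z-scored, a nearest-neighbor chain starts at the
case closest to the grand centroid and repeatedly visits the nearest
unvisited case (euclidean; index order breaks exact ties), and the
number of label changes `L` along the chain is compared with its mean
over ≥ 200 random label permutations: `power = 1 − L / E[L_perm]`,
clipped to [0, 1]. The chain depends only on geometry, so permutations
reuse it. Reported overall, per class (one-vs-rest on the full space)
and per single variable (chain rebuilt on that variable). The score is
exactly invariant to affine rescaling of any variable and monotone in
class separation on Gaussian test beds.

## Classification

Arrangements: 1.1/1.2/1.3 are normal-only / abnormal-only / pooled
signals of the three diseases; 2.1 is normal-only signals of all four
classes; 2.2 is everything. The handful of abnormal control signals
always stay inside WT — they are never a class of their own.

Standardization is global by default (z-score the whole table before
leave-one-out, the study's stated order of operations); a leakage-safe
per-fold mode is available and, on well-separated synthetic data, differs
by well under 2 accuracy points.

Leave-one-out runs exactly n fits. kNN computes distances per fold
(cityblock, euclidean, or Mahalanobis with the training fold's covariance
plus a ridge of `10⁻⁶ × mean diagonal`; a still-singular covariance
raises with advice to fall back to euclidean). Vote weights are 1, 1/d
or 1/d²; an exact-duplicate neighbor (d ≈ 0) dominates the vote. Ties
are broken by a class priority permutation drawn once per evaluation from
the run seed. Random forests use scikit-learn with the published tree
counts (35 for three classes, 54 for four), √p features per split and a
fixed seed. The LS-SVM solves the least-squares SVM linear system
`[[0, yᵀ], [y, Ω + I/C]] [b, α]ᵀ = [0, 1]` with `Ω = yyᵀ∘K` per binary
problem and combines classes one-vs-one by voting; kernels are linear,
cubic polynomial `(xᵀz + 1)³` (`C = 2⁻⁵` in the grid) and RBF
`exp(−‖x−z‖²/(2σ²))` (`C = 2, σ = 2` and `C = 2⁴, σ = 2`). The exact
toolbox conventions behind the original LS-SVM runs are unknown; this is
the standard formulation of the named method.

Reports carry the confusion matrix, per-class TPR
(`100 · diagonal / row total`) and accuracy (`100 · trace / n`);
baselines are `100/#classes` (random) and `100 · max count / total`
(majority; 44.2 % for the 90/71/233/133 cohort).

## Problem sizes and runtime

The shipped analyses run on one CPU in minutes: the full cohort-scale
pipeline (527 signals, ~6 500 peaks) simulates and delineates in ~5 s;
one leave-one-out pass of the full four-class grid on 527 signals takes
~1 minute (random forests dominate). Delineation fidelity and
abnormality agreement are each assessed on 100 signals at 23 Hz; the
ANOVA null calibration uses 1 000 replicates of two groups of 50.

## Known limitations

* The delineation and abnormality heuristics are contracts-compatible
  stand-ins for unpublished algorithms; their thresholds are package
  defaults, all exposed in configuration.
* Independence of the ten variables in the generator is a simplification;
  real peaks have strong within-peak correlations (e.g. `A_l` with `R`).
* Leave-one-out is per signal, as stated in the protocol; recordings from
  the same cell line are not grouped, so cell-line leakage (if lines
  contribute many signals) is not modeled. A group-aware mode would be a
  natural extension.
* At 8.3 Hz, rises of 2–3 samples make side-amplitude geometry coarse;
  abnormality-rule agreement is therefore quoted at 23 Hz.
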