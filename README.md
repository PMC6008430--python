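# catransient

Morphological analysis and machine-learning classification of single-cell
Ca²⁺ transient recordings from human iPSC-derived cardiomyocytes.

Cardiomyocytes carrying mutations for long QT syndrome type 1 (LQT1),
hypertrophic cardiomyopathy (HCM) or catecholaminergic polymorphic
ventricular tachycardia (CPVT) show disease-specific distortions of their
Ca²⁺ cycling. `catransient` turns a raw fluorescence-ratio time series
(Fura-2 340/380 nm, sampled at ~8.3, 11 or 23 Hz) into a quantitative
phenotype and asks whether the four classes — three diseases plus healthy
controls (WT) — can be told apart from that phenotype alone.

## The method

Each transient peak of a signal `s` is delineated by three landmarks:
beginning `a`, top `c` and end `g` (sample indices). Ten variables are
computed per peak:

| variable | definition |
|---|---|
| `A_l`, `A_r` | side amplitudes `s(c) − s(a)`, `s(c) − s(g)` |
| `D_l`, `D_r` | side durations `(c − a)/F`, `(g − c)/F` (s), `F` = sampling rate |
| `max s′`, `\|min s′\|` | first-derivative extrema on the rising / falling side |
| `max s″`, `\|min s″\|` | second-derivative extrema on the falling side |
| `R` | trapezoidal area between the curve and the chord from `(a, s(a))` to `(g, s(g))` |
| `Δ` | top-to-top interval (first peak: time from signal start to its top) |

Peaks below 2 % of the largest peak amplitude *within the same signal*
are discarded as noise. Each retained peak is labeled normal or abnormal
by three morphology rules (small relative amplitude, left/right amplitude
asymmetry, deformed shape); a signal is abnormal iff any of its peaks is.

Per-signal feature vectors (mean of the peak variables) are standardized
and classified under a leave-one-out protocol with the studied grid of
classifiers: kNN (cityblock / euclidean / Mahalanobis distance; equal,
1/d or 1/d² vote weighting), random forests, and least-squares SVMs
(cubic polynomial and RBF kernels), reporting per-class sensitivity (TPR)
and overall accuracy against the random-guess (25 %) and majority-class
(44.2 %) baselines. Preliminary statistics — per-class summaries,
pairwise one-way ANOVA per variable, and a nearest-neighbor-chain
class-separability score in [0, 1] — are included.

Because the original recordings are not public, the package ships a
synthetic-data generator whose per-peak variables follow the published
class-conditional means and SDs, including abnormal-peak motifs,
sub-2 %-amplitude noise blips and the three sampling-rate regimes; every
stage is tested against this generator's ground truth.

## Worked example

```python
from catransient import (SimConfig, simulate_dataset, annotate_signal,
                         build_feature_table, select_arrangement, run_grid,
                         GRID_4CLASS, baselines)

signals, truth = simulate_dataset(SimConfig(seed=7))   # 527 signals, 4 classes
annotations = [annotate_signal(s) for s in signals]    # peaks + abnormality
features = build_feature_table(signals, annotations)   # one row per signal

random_acc, majority_acc = baselines(features.label.value_counts().to_dict())
print(f"baselines: random {random_acc:.1f}%, majority {majority_acc:.1f}%")

pooled = select_arrangement(features, "2.2")           # all four classes
reports, ranked = run_grid(pooled, ["2.2"], list(GRID_4CLASS))
cols = ["method", "TPR_LQT1", "TPR_HCM", "TPR_CPVT", "TPR_WT", "accuracy"]
print(ranked[cols].round(1).to_string(index=False))
```

Output:

```
baselines: random 25.0%, majority 44.2%
                                                  method  TPR_LQT1  TPR_HCM  TPR_CPVT  TPR_WT  accuracy
             kNN, cityblock metric, equal weighting, k=5      78.9    100.0      82.4    83.5      84.4
           kNN, cityblock metric, inverse weighting, k=5      78.9    100.0      82.4    87.2      85.4
   kNN, cityblock metric, squared inverse weighting, k=5      72.2    100.0      84.1    88.7      85.4
           kNN, mahalanobis metric, equal weighting, k=1      85.6    100.0      88.8    92.5      90.7
         kNN, mahalanobis metric, inverse weighting, k=1      85.6    100.0      88.8    92.5      90.7
kNN, mahalanobis metric, squared inverse weighting, k=11      88.9    100.0      91.4    88.0      91.3
                                Random forests, 54 trees      84.4    100.0      94.0    96.2      93.7
                        LS-SVM RBF kernel, C=16, sigma=2      96.7    100.0      97.4   100.0      98.3
```

Every row is one classifier evaluated leave-one-out on the 527 simulated
signals: TPR columns give the fraction of each class recovered, and all
configurations sit far above the 44.2 % majority baseline — on synthetic
data the four phenotypes are clearly separable from the ten peak
variables. (Accuracies on synthetic data depend on the generator's
independence assumptions and are not estimates of real-data performance;
see `docs/methods.md`.)

The same pipeline is available from the shell:

```sh
catransient run-all --out report/ --seed 7
catransient simulate --seed 1 --out signals.csv --truth truth.csv
catransient detect --in signals.csv --out annotations.csv
```

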