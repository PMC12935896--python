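# hrvbalance

Hybrid resampling for small, severely imbalanced multiclass tabular cohorts,
built around heart-rate-variability (HRV) classification of autonomic-
nervous-system (ANS) states. The package is aimed at researchers who need to
train classifiers on clinical HRV tables where one class dominates (e.g. 195
"balanced" participants against a 6-member disorder class) and who want the
resampling, the evaluation protocol and the data leakage question handled
explicitly.

## Method

Given a feature matrix standardized column-wise (z = (x − μ)/σ), the
**refined SMOTE** stage oversamples each minority class up to a target count
by interpolating between a seed sample x_i and one of its k = 3 same-class
nearest neighbours x_j:

* *in-line*: x = x_i + λ(x_j − x_i), λ ~ U[−1, 1] — classic SMOTE widened to
  allow extrapolation beyond the seed;
* *off-line*: x on the circle with diameter x_i–x_j, at distance d·cos θ
  from x_i (θ ~ U[−π/2, π/2], d = ‖x_j − x_i‖). Every off-line point
  satisfies the Thales right-angle identity (x − x_i)·(x − x_j) = 0; θ = 0
  lands on x_j and θ = ±π/2 on x_i. In more than two dimensions the
  construction uses a random unit direction orthogonal to x_i→x_j and
  reduces exactly to the planar formula in 2-D.

The **refined ENN** stage then removes noise: a row whose label disagrees
with the strict majority of its 3 nearest neighbours (any class) is flagged
as a boundary row, and all but a retained fraction (default 15%, drawn at
random, stratified per class) of the flagged rows are deleted. Retaining
part of the boundary keeps the cleaned training set from becoming
artificially separable.

Four classifiers evaluate the result — SVM (RBF, C = 10, γ = 1), random
forest (1000 trees, entropy, no bootstrap), a 256/128/64 ReLU network with
early stopping, and 3-NN — with confusion matrices, macro
precision/recall/F1, one-vs-rest ROC/AUC, and cross-model permutation-
importance mean ranks. Because the study design this emulates resampled
*before* splitting (a leakage the analysis itself flags), both protocols are
provided: `paper_faithful` and the default `leakage_safe` (split first,
resample the training partition only).

A synthetic cohort generator (class-conditional correlated log-normal
features, exact LF/HF ratio, TSP ≈ VLF + LF + HF, class counts
{63, 6, 9, 195, 12, 24, 12}) stands in for the private clinical data. See
`docs/methods.md` for assumptions and limitations.

## Worked example

```sh
$ hrvbalance generate --out cohort.csv --seed 7
cohort: 321 rows, class counts {1: 63, 2: 6, 3: 9, 4: 195, 5: 12, 6: 24, 7: 12}

$ hrvbalance resample --in cohort.csv --out train.csv --test-out test.csv \
      --mode leakage_safe --seed 42 --report counts.json
train: 1027 rows (leakage_safe); test: 65 rows

$ hrvbalance benchmark --train train.csv --test test.csv \
      --models svm,rf,nn,knn --out report --seed 0
svm: accuracy=0.800 precision=0.640 recall=0.794 f1=0.658 macroAUC=0.962
rf: accuracy=0.785 precision=0.587 recall=0.773 f1=0.627 macroAUC=0.980
nn: accuracy=0.785 precision=0.602 recall=0.790 f1=0.631 macroAUC=0.977
knn: accuracy=0.785 precision=0.607 recall=0.790 f1=0.638 macroAUC=0.890
```

The resample step reports Table-style bookkeeping per class (`counts.json`):
for example the 6-member disorder class keeps its 5 training originals,
gains 151 synthetic rows and loses 8 to editing, ending at 148. The
benchmark metrics are macro averages over the seven states on the held-out,
all-original test partition: accuracies around 0.8 with macro AUC above 0.89
on a 65-row test set, where the same cohort without resampling misclassifies
most minority-state rows. The `report/` directory contains the metrics
table, per-model confusion matrices, ROC curve points and the importance
rank table as CSV.

The same machinery is available as a library:

```python
import hrvbalance as hb

cohort = hb.generate_cohort(hb.default_cohort_config(seed=7))
train, test, result = hb.run_protocol(cohort, mode="leakage_safe",
                                      split=hb.SplitSpec(stratified=True, seed=42))
report = hb.run_benchmark(train, test)
print(report.metrics_table())
```

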