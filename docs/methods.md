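# Methods

## Model and procedure

The package scores and selects features for binary classification of a
numeric expression matrix Z (p genes × n samples) with class labels
w_i ∈ {0, 1}. The premise is geometric: a gene is informative exactly
to the extent that the bulk of its class-0 and class-1 expression
values occupy disjoint ranges. "Bulk" is made precise with a robust
core interval per class,

    R_{j,c} = [Q1_{j,c} − k·disp_{j,c},  Q3_{j,c} + k·disp_{j,c}],

where the dispersion is the raw median absolute deviation by default
and the interquartile range in the baseline variant, and k is a width
multiplier. From the two intervals the pipeline derives, per gene:

* the overlap region R^v_j = R_{j,0} ∩ R_{j,1} (empty if disjoint);
* the total core interval R_j spanning both (gaps included);
* the non-outlier set N_j — samples inside their own class interval,
  with closed-endpoint membership so boundary values are kept;
* the partition of N_j into overlapped samples O_j (values in R^v_j)
  and unambiguous samples O′_j;
* the gene mask m_j ∈ {0,1}^n, the indicator of O′_j;
* the score RPOS_j = 4·(|R^v_j|/|R_j|)·(|O_j|/|N_j|)·φ_0·φ_1 with
  φ_c = |O_{j,c}|/|O_j|, lying in [0, 1] because each ratio is ≤ 1 and
  4·φ_0·φ_1 ≤ 1 when φ_0 + φ_1 = 1;
* the relative dominant class RDC_j, the class with the larger
  fraction of mask-marked samples (ties to class 0).

Selection composes a greedy set-cover stage over the masks (pick the
gene covering the most still-uncovered samples; break ties by smaller
RPOS, then gene id; remove covered samples; stop at r picks or
exhaustion) with a round-robin ranking of the rest (the two RDC
groups, each ascending in RPOS, interleaved starting with the class-0
group). The final set T takes the greedy picks first and tops up from
the ranked list to r genes.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `mad_multiplier` (k) | 0.9 | half-width added to the quartiles, in dispersion units; larger widens every interval and inflates overlap |
| `dispersion` | `mad` | `mad` (breakdown 50%) or `iqr` (breakdown 25%, baseline) |
| `n_genes` (r) | 10 | size of the final selected set |
| `greedy_full_cover` | off | run the greedy stage to mask exhaustion instead of capping at r |
| evaluation `runs` | 500 | repeated random splits |
| `train_fraction` | 0.70 | plain (unstratified) random split |
| `gene_counts` | 5–30 by 5 | gene-set sizes evaluated |
| `knn_k` | 5 | k-NN neighbourhood size; other classifiers use scikit-learn defaults |

The 0.9 multiplier is the method's conventional constant; it is
configurable but there is no principled calibration for it. The MAD
carries no 1.4826 consistency factor — the multiplier already sets the
interval width, and adding a normality-referenced rescaling would
change the meaning of the constant.

## Numerical choices

* **Quantile convention.** Quartiles use linear interpolation of order
  statistics at h = q·(n−1)+1 (the numpy/R type-7 default). Every
  interval endpoint, and hence every score, depends on this choice, so
  it is fixed and documented rather than left to ambient defaults.
* **Degenerate genes.** |O_j| = 0 scores 0 (no ambiguity at all);
  |N_j| = 0 or a zero-length total interval (constant gene) scores 1,
  pushing geometry-free genes to the back of every ranking.
* **Tie-breaks.** All orderings are total: greedy picks break ties by
  popcount, then RPOS, then gene identifier; ranked lists by RPOS then
  gene identifier. The identifier (not the storage index) is the final
  key so that the selected identity set is invariant under permutation
  of gene storage order — score ties are common, since every cleanly
  separated gene scores exactly 0.
* **Greedy cap.** The greedy stage stops at r picks by default; the
  alternative reading (full coverage before truncation) is available
  as `greedy_full_cover` and changes only how much of T the greedy
  stage supplies.
* **Degenerate splits.** Evaluation splits are plain random draws;
  draws leaving the training part single-class, or the test part
  without the positive class (sensitivity would be undefined), are
  redrawn from the next derived seed.
* **Scoring path.** `score_all_genes` is vectorised across genes; the
  per-gene operations (`non_outlier_set`, `partition_overlap`, …)
  implement the same definitions one gene at a time and agree with the
  vectorised path bit-for-bit (same numpy primitives, same order).

## Synthetic data

The generator draws unit-variance Gaussian expression: noise genes at
mean 0 in both classes, informative genes with the class-1 mean
shifted by `effect_size` δ (in SD units). Contamination replaces
floor(ε · class size) values per gene per class — independently, the
unit at which the intervals are estimated — by the gene's empirical
class mean + K. Contamination is one-sided (upward) deliberately: it
attacks the upper interval endpoint Q3 + k·disp, where the MAD/IQR
breakdown difference is visible; symmetric contamination would partly
cancel in the quartiles.

Defaults mirror the study conditions used throughout the tests:
p = 1000 genes, 20 informative, δ = 2, 50 samples per class, ε = 0
(clean) or ε = 0.3 with K = 10 (contaminated, chosen between the IQR's
25% and the MAD's 50% breakdown points).

What the generator does not emulate: probe/batch effects,
heteroscedastic or heavy-tailed noise, correlated genes, class
imbalance beyond what `n_per_class` sets. Passing tests therefore show
that the implementation realises the method's geometry and its
robustness ordering under the stated model — not that the method wins
on any particular real platform's data.

## Evaluation protocol

Repeated random splits (default 500 runs, scaled down in tests to keep
the suite fast: 20 runs and gene counts {5, 20} for the harness check,
2–4 runs for unit tests). Per run: split; select genes on the training
part only; fit the configured classifier (random forest, k-NN with
k = 5, or SVM with probability outputs, all via scikit-learn behind a
minimal adapter) on the training samples restricted to the selected
genes; compute error rate, binary Brier score, and sensitivity on the
test part. No information from the test part can reach selection — a
property the tests assert mechanically by mutating test values.

The standard binary Brier score (mean of (p̂ − y)²) is reported;
no alternative scaling or aggregation is applied.

## Calibrated constants

The recovery floor used by the test suite was calibrated once by
simulation under the clean study conditions above: mean fraction of
planted genes in the top-20 ranking over 50 seeds = 0.999 (SE 0.001),
frozen and asserted as mean ≥ floor − 2·SE. Chance level for this
quantity is 20/1000 = 0.02.

## Known limitations

* Binary classes only; no multiclass extension.
* The greedy stage approximates minimum set cover; no global optimality
  is claimed, and no redundancy filtering is applied among selected
  genes (two selected genes may be near-duplicates).
* Expression values are consumed as given — no normalisation, no
  log-transform, no missing-data handling (missing values are
  rejected at read time).
* RPOS is a filter score without a significance calibration; it orders
  genes but attaches no p-value.
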