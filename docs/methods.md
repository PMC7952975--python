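# Methods

## Model and assumptions

`stagedfs` treats tumor-vs-normal classification as a supervised learning
problem over a deliberately reduced feature space. The underlying biological
assumption is that genes driving the disease are *recurrently mutated across
patients* and that their mutations *perturb expression*; genes carrying only
one of the two signals are down-weighted by the staging. The stages are
strictly ordered filters:

1. mutation recurrence (a marginal count over the binary incidence matrix),
2. differential expression (fold change + FDR, a univariate two-sample test),
3. mutual information with the label (a univariate dependence measure that
   also captures non-monotone effects),
4. an embedded tree-ensemble model whose own training selects interactions
   among the survivors.

Each stage sees only the features its predecessor passed, so the pipeline is
a conjunction of evidence, not a union. Stages 2–4 are re-fit inside every
evaluation repetition on the learning samples only; the held-out test split
never influences selection or tuning.

## Parameters

| parameter | default | units / range | why |
|---|---|---|---|
| `freq_threshold` (p) | 0.01 | fraction of mutation-matrix samples | recurrence floor; `min_count = ceil(p·n)`, inclusive |
| `fdr_threshold` | 0.05 | BH-adjusted q | conventional FDR level |
| `lfc_threshold` | 1.0 | log2 fold change | "difference multiple" of 2 on the linear scale |
| `pseudocount` | 1.0 | CPM | guards zero class means in the FC ratio |
| `top_m` (M) | 50 | genes | size of the final ranked feature set |
| `mi_bins` | 10 | equal-frequency bins | plug-in MI needs discrete levels; 10 keeps ≥ ~15 samples per bin at cohort scale |
| `min_cpm`, `min_sample_frac` | 1.0, 0.1 | CPM, fraction | a gene must reach 1 CPM in ≥10% of samples to survive the low-expression filter |
| `n_iter` | 300 | optimizer trials | search budget; tests and the acceptance script scale it down (30) |
| `cv_folds` (k) | 5 | stratified folds | objective = 1 − mean fold accuracy |
| `n_rep` | 10 | repetitions | the repeated 80/20 → 60/40 split protocol |
| `test_frac`, `val_frac` | 0.2, 0.4 | fractions | 80/20 learning/test, 60/40 train/validation |
| `weight_mode` | normalized | {normalized, raw} | see "Weighted balanced accuracy" |
| `tune_scope` | train | {train, learning} | see "Hyperparameter tuning" |

Search-space box (all configurable): learning_rate log-uniform [0.01, 1],
max_depth int [3, 50], min_samples_leaf int [1, 100], min_samples_split int
[2, 100], n_estimators int [50, 500], subsample uniform [0.5, 1].

## Normalization and differential expression

Counts are normalized to `log2(1 + CPM)` per sample; the low-expression
filter and all downstream statistics operate on this scale (fold change
converts back to linear CPM for the ratio of class means). This is a
deliberate substitution of an explicit, dependency-free rule for
library-normalization packages: the downstream stages (a ratio of means, a
rank-driven MI, trees) need only a monotone within-sample transform, so TMM
or quantile scaling factors would not change selections or rankings
materially and are out of scope. The per-gene test is a two-sided Welch
t-test on log2-CPM; genes with zero variance in both classes get p = 1 when
the class means agree (and 0 when they differ, which count data never
produces). Multiplicity is controlled by Benjamini–Hochberg step-up,
delegated to statsmodels and cross-checked in the tests against an explicit
min-over-tails oracle.

## Mutual information

`MI(G, L) = H(G) + H(L) − H(G, L)` with plug-in empirical probabilities and
log base 2, after equal-frequency discretization of the expression values
into at most `mi_bins` levels (quantile edges; duplicate edges collapse, so
discrete inputs with few levels are preserved when `bins` is large). The
estimate is clamped at ≥ 0 against floating-point rounding. Ranking ties are
broken by larger |log2 FC|, then lexicographic gene symbol, so the top-M set
is fully deterministic. The base only rescales values (bits); it never
reorders a ranking.

## Hyperparameter tuning

The Tree-structured Parzen Estimator here is the classic formulation,
implemented on numpy: after 10 random startup trials the history is split at
the γ = 0.25 loss quantile into good/bad sets; 24 candidates per iteration
are drawn from a per-dimension Gaussian Parzen mixture over the good set
(with a uniform prior component; bandwidth `(hi−lo)/√n_good`, floored at
0.1% of the axis) and scored by the log-density ratio good/bad; the best
candidate is evaluated. Integer dimensions round on the transformed axis and
are re-snapped before scoring; log-uniform dimensions work in log space.
While the history contains fewer than two distinct finite losses the sampler
stays uniform — without this, a run whose startup trials all land on
degenerate points (e.g. `min_samples_leaf` larger than a fold can support,
which yields a constant predictor and identical losses) would lock onto that
region. Failed trials are recorded with infinite loss and skipped when
choosing the best. Both optimizers are pure functions of `(space, objective,
n_iter, seed)`.

The CV objective's fold assignment is frozen per optimization run so all
trials are comparable. By default tuning runs on the *train* subset
(`tune_scope="train"`), the same sample scale at which the final model is
refitted: tuning on the larger learning split (the `"learning"` option) lets
the objective favour points — large leaf/split minima especially — that are
viable at fold size but degenerate to constant predictors at the train size,
which measurably collapses specificity at the scales this package is tested
at. The CV loss is 1 − accuracy by default, with 1 − macro-average recall
available (`objective_metric="balanced_accuracy"`).

## Weighted balanced accuracy

Per repetition the model is fitted on the train subset; its per-class
accuracies on the validation subset, averaged over all repetitions, give raw
weights `(w_n, w_t)`. As printed, `acc_n·w_n + acc_t·w_t` with raw weights
can exceed 1 (both terms can approach 1), so the default normalizes the
weights to sum to one, keeping the metric in [0, 1] and reducing it exactly
to macro-average recall `(SES + SPC)/2` when the weights are equal. The raw
variant stays available (`weight_mode="raw"`) for fidelity experiments.

A known pathology, kept deliberately because it is what the definition
implies: if a classifier never predicts the minority class, its validation
accuracy on that class is 0, the normalized weight of that class is 0, and
the majority-vote predictor scores a balanced accuracy of 1. The
per-repetition `acc_n`/`acc_t` columns in the report expose this immediately;
inspect them rather than the scalar when a run looks too good.

Metrics with zero denominators are reported as NaN with a warning, never
silently coerced to 0. AUC is computed from predicted tumor probabilities
(rank-based ROC).

## Synthetic cohorts

The generator emulates a bulk RNA-seq tumor/normal cohort with a matched
somatic-mutation call set: per-gene baseline means are log-normal
(σ = 1) around `baseline_mean` (default 100 counts), counts are negative
binomial with shape `dispersion` (default 2, i.e. strongly overdispersed),
and a chosen set of driver genes has its tumor-group mean multiplied by
`2^driver_log2fc` (default 4×). Mutations exist only for tumor samples, one
Bernoulli draw per (gene, sample) at the driver (15%) or passenger (0.5%)
rate, with the variant type drawn uniformly from {SNP, INS, DEL} — the
method codes presence/absence, so composition is cosmetic. Defaults mirror a
down-scaled imbalanced cohort (120 tumor / 30 normal, 2 000 genes,
40 drivers). All randomness flows from one seed through named substreams, so
expression and mutations can be regenerated independently and all outputs
are byte-reproducible.

What the simulator does *not* model: library-size variation beyond the
Poisson-gamma noise, batch effects, mutation signatures and hypermutators,
copy-number change, correlated co-expression modules, or any coupling
between a sample's mutation status and its own expression (drivers shift the
whole tumor group mean). Passing tests therefore demonstrate that the
machinery recovers planted marginal signals under overdispersed noise and
class imbalance — not that it handles the full covariance structure of real
cohorts.

## Evaluation protocol and problem sizes

"Repeat the split 10 times" is implemented as 10 independent stratified
draws of the full 80/20 → 60/40 scheme, which keeps every subset two-class
even for small cohorts; a literal 10-way partition (each repetition confined
to one tenth of the data) is available as `split_mode="partition"`.
Aggregates report the mean and sample variance (ddof = 1) over repetitions.

The test-suite and acceptance-script problem sizes are the package's own
operating points for a desk-scale demonstration: planted-driver cohorts of
2 000 genes × 150 samples with the optimizer budget at 30 trials, null-FDR
checks over 50 simulated cohorts, and the TPE surrogate check over a
4 001-point grid oracle. At these scales the full tuned pipeline recovers
all planted drivers and classifies held-out samples with accuracy ≈ 0.99 and
balanced accuracy ≈ 0.98 (recomputed, not asserted, by
`scripts/acceptance.py`).

## Known limitations

- The MI stage is univariate: it ranks relevance but applies no redundancy
  criterion, so strongly correlated drivers all rank high and the top-M set
  can be redundant.
- Welch's t-test on log2-CPM is a pragmatic, dependency-light DE test; it is
  not a count-model test and is anti-conservative for very low counts. The
  test sits behind a single function and is straightforward to swap.
- The weighted balanced accuracy degenerates when a class weight collapses
  to 0 (see above).
- Barcode reconciliation between mutation and expression files is by string
  prefix (default 12 characters, patient level) — adequate for TCGA-style
  barcodes, not a general sample-matching solution.
- CV-loss ties at small n (many hyperparameter points reaching loss 0) make
  the "best" point arbitrary among ties; the tie is broken by iteration
  order, which is seed-deterministic but not meaningful.
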