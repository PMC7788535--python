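# Methods

## Problem setting

A perturbational compendium records, for each treatment of a cell line
with a compound, the differential expression of 978 directly measured
landmark genes as z-scores. Compounds sharing a mechanism of action (MOA)
tend to induce related expression changes, but the shared component is
easily masked by off-target expression, batch effects and common
responses, which limits similarity-based (GSEA-style) MOA inference. The
package instead trains a supervised classifier per MOA and turns its
per-signature probabilities into compound-level enrichment statistics.

## Representative-signature reduction

Within each (compound, cell line) group, the retained signature is the one
whose mean Pearson correlation (over all feature genes) with the group's
other signatures is maximal. A single-signature group is kept as is. Ties
— exact in the two-signature case, where both mean correlations equal the
single pairwise correlation — break to the lexicographically smallest
signature id, for determinism. A zero-variance signature column would make
Pearson correlation undefined; its correlations are treated as 0 and a
warning is emitted rather than failing, since such columns are degenerate
but harmless. Negative compounds are reduced exactly like positives.

## Classifier

A feed-forward binary network: input = feature genes (978 by default),
hidden ReLU layers of 978/512/256 units with dropout 0.1 applied after
each hidden activation (inverted scaling), one sigmoid output. Training
minimizes class-weighted binary cross-entropy plus an L1 penalty on all
weight matrices, by mini-batch Adam for a fixed number of optimizer steps.

Tunable parameters (defaults in parentheses):

* `hidden_layers` (978, 512, 256) — layer widths.
* `iterations` (2000) — optimizer *steps*, not epochs; with mini-batches
  the step count, not the data size, fixes the training budget.
* `dropout_rate` (0.1) — hidden-unit drop probability during training
  only; scoring always runs with dropout disabled.
* `l1_lambda` (1e-4, dimensionless) — L1 weight-penalty coefficient; the
  penalty gradient uses the subgradient sign(W).
* `learning_rate` (1e-3) and `batch_size` (128, capped at the training-set
  size) — standard Adam settings (β₁ = 0.9, β₂ = 0.999, ε = 1e-8).
* `class_weighting` ("balanced") — positive/negative samples reweighted to
  equal total mass, countering the strong imbalance of MOA training sets
  (a handful of positives against hundreds or thousands of inert
  negatives); "none" disables it. Ranking, the downstream use of the
  probabilities, is unaffected by the monotone shift weighting induces.
* `seed` — drives weight initialization (He normal), batch sampling and
  dropout masks through one `numpy` generator; identical seed and inputs
  give bitwise-identical weights and probabilities.

Input z-scores are used raw — they are already standardized by
construction, and re-scaling them would distort the relative magnitude
structure the signatures encode.

The estimator follows sklearn conventions (`fit`/`predict_proba`,
`get_params`/`set_params`, trailing-underscore fitted attributes) so it
can be dropped into sklearn pipelines and model selection.

## Drug-level cross-validation

Folds are planned at compound granularity so no drug contributes
signatures to both sides of a split: positives and negatives are
independently shuffled and dealt into K near-equal groups (sizes differing
by at most one), and fold i pairs positive group i with negative group i
(stratification). K follows the positive drug count N: K = N for
2 ≤ N ≤ 4, K = 5 for 5 ≤ N ≤ 9, K = 10 for N ≥ 10; for N = 1 the lone
positive compound's signatures themselves are partitioned into K = (its
signature count) folds while negatives still split by compound. Per-fold
AUROC is computed on held-out signature labels; a fold whose held-out
labels are single-class has no defined AUROC and is excluded from the mean
with a warning rather than imputed at 0.5, which would bias the
well-trained threshold. The model-acceptance rule is mean AUROC ≥ 0.6.

## Enrichment statistic and permutation null

With n scored signatures and a compound's k ranks R(1) < … < R(k)
(rank 1 = highest probability, ties broken by ascending signature id):

    a = max_i [ i/k − R(i)/n ]       (hit excess)
    b = max_i [ R(i)/n − (i−1)/k ]   (miss deficit)
    ES = a if a > b; −b if b > a; 0 if a = b

Both deviations are bounded by 1, so ES ∈ [−1, 1]. An alternative form of
the miss deviation with denominator k instead of n is available behind
`literal_eq2=True`; it is not the default because it can exceed 1 (take
R(i) = n > k) and thereby loses the Kolmogorov–Smirnov interpretation that
motivates the statistic.

The null distribution draws k distinct ranks uniformly from [1, n]
(combinations without replacement, vectorized over repetitions), 1000
repetitions by default. The default p-value is the upper tail,
p = frequency(null ES ≥ observed ES), so that strongly top-enriched
compounds receive small p and survive the p < 0.05 filter; the opposite
direction (frequency of null ES < observed) is available behind
`literal_direction=True` for comparison, but with it the p < 0.05 filter
would select *depleted* compounds, contradicting the intended use of the
ranked list. No add-one smoothing is applied — the p-value is a plain
frequency and can be 0 at finite repetitions. The final filter keeps
compounds with p < 0.05 (strict) and more than 4 replicate signatures
(k ≥ 5), ranked by descending ES with compound-id tie-breaks; filtered-out
compounds are retained unranked, including negative-ES compounds.

Scoring for the ranking step uses the *full* compendium (minus training
compounds), not the reduced one, so k reflects all replicate signatures of
a compound; the reduction exists to de-bias training, not to discard
evidence at ranking time.

## GSEA baseline

Per compound, all signatures are converted to gene rankings (descending
z-score, gene-id tie-break) and Borda-merged by mean rank (gene-id
tie-break). Similarity between two compounds a, b uses the unweighted KS
running statistic ES(S, r) — steps +1/m at members of S, −1/(G−m)
elsewhere, signed maximum excursion, exact excursion ties giving 0 — on
the top/bottom m = 20 gene sets:

    s(a, b) = [ES(up_a, r_b) − ES(down_a, r_b) + ES(up_b, r_a) − ES(down_b, r_a)] / 4

which is symmetric and bounded in [−1, 1]; identical rankings give +1 and
exact reversals −1. The benchmark ranks all positive–positive (true
positive) and positive–negative (false positive) compound pairs by s and
reports AUROC and average precision.

## Synthetic compendium generator

Each signature is `effect + batch + noise` on the z-score scale:

* an MOA's prototype effect puts ±`amplitude` on `effect_genes` randomly
  chosen genes (signs random), zero elsewhere;
* each member compound adds Gaussian jitter (sd
  `compound_effect_jitter_sd`, all genes) to the prototype — this models
  compound-specific off-target expression, the mechanism by which limited
  top/bottom gene sets fail to capture the shared MOA component;
* the compound effect is zeroed in cell lines outside the MOA's
  `expressing_cells` (target not expressed);
* `batch` is a Gaussian offset (sd `batch_sd`) shared by all signatures
  assigned to the same of `n_batches` plate groups, modeling batch
  interference that inflates pairwise similarity between unrelated
  compounds;
* `noise` is i.i.d. N(0, `noise_sd`²) per gene, `noise_sd` = 1 so values
  sit on the z-score scale;
* negative compounds have zero effect everywhere.

Preset scenario conditions (978 genes, 4 cell lines, one MOA of 10
compounds, 200 negative compounds, 3 replicates per cell line, batch sd
0.8, jitter sd 0.8): `strong_consistent` (amplitude 2.0 on 60 genes, all
cells), `cell_dependent` (same, but expressed in 2 of 4 cell lines),
`weak_signal` (amplitude 0.5), `null` (amplitude 0). Jitter and batch
levels were chosen so that a compound's own top-20 genes are dominated by
its private jitter rather than the 60 shared effect genes — the regime in
which pairwise similarity methods degrade while a classifier pooling many
positive compounds can still isolate the shared subspace. Sizes (≈2500
signatures before reduction, 840 after) are desk-scale: every scenario
generates in under a second and a full 10-fold drug-level CV runs in
seconds.

What the generator does **not** emulate: dose–response structure, time
courses, the ~11,350 inferred non-landmark genes, heavy-tailed or
correlated technical noise, cell-line-specific baseline transcription, and
MOA hierarchies (overlapping or nested mechanisms). Passing tests on this
synthetic model demonstrate the pipeline's statistical machinery —
reduction, drug-disjoint validation, enrichment calibration, the
cell-dependence and classifier-vs-GSEA directions — not performance on
real compendia.

## Problem sizes used in tests and the acceptance script

Cross-validation checks use a reduced network (hidden layers 64/32, 300
Adam steps, batch 64) on the preset scenarios; the published-scale
architecture (978/512/256 × 2000 steps) remains the library default. The
reduced setting is already deep into the signal-saturated regime for the
synthetic scenarios (strong-scenario CV AUROC ≈ 1.0), so the larger
default would not change any qualitative outcome, only the runtime.

## Known limitations

* Optimizer, learning rate, L1 strength, batch regime and the absence of
  early stopping are package choices exposed in `ModelConfig`, not
  canonical values; conclusions that depend on them should sweep them.
* The Monte-Carlo permutation p-value has resolution 1/repetitions;
  compounds tied at p = 0 are ordered by ES alone.
* `cross_validate` retrains one model per fold; wall time scales linearly
  with K and `iterations`.
* The GSEA baseline implements mean-rank Borda merging and the unweighted
  KS set statistic; weighted GSEA variants and other similarity metrics
  (cosine, Jaccard, Fisher) are out of scope.
* The enrichment ranking assumes every scored signature has metadata; the
  compound universe of the ranked list is whatever the metadata covers.
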