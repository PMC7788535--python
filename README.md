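# moarank

Modeling drug **mechanism of action (MOA)** from large-scale perturbational
gene-expression signatures.

Given a compendium of L1000-style differential-expression z-score profiles
(978 landmark genes × many signatures, each signature one compound treated
in one cell line at one dose/time), `moarank` trains a binary deep
classifier for a user-defined MOA and ranks the remaining compounds of the
compendium by how strongly their signatures are enriched among the
top-scoring profiles. A classical GSEA pairwise-similarity baseline is
included for comparison, and a synthetic compendium generator with known
ground truth makes the whole pipeline testable without any data download.

## The method

1. **Representative signatures.** For every (compound, cell line) pair the
   compendium is reduced to the single signature with the highest mean
   Pearson correlation to the compound's other signatures in that cell
   line.
2. **Training set.** A user-supplied positive compound list (MOA members)
   and negative list (transcriptionally inert compounds) label the reduced
   signatures.
3. **Classifier.** A feed-forward network — hidden layers of 978/512/256
   ReLU units, dropout 0.1, single sigmoid output — trained with L1-penalized
   cross-entropy for 2000 Adam steps. Output is P(signature is
   positive).
4. **Drug-level cross-validation.** K folds split at *compound*
   granularity (no drug in both train and test): K = N positive drugs for
   N ∈ [2, 4], K = 5 for N ∈ [5, 9], K = 10 for N ≥ 10, and K = number of
   signatures when N = 1. A model with mean AUROC ≥ 0.6 is "well trained".
5. **Enrichment ranking.** All non-training signatures are scored and
   ranked (rank 1 = most positive-like). For a compound with k of the n
   scored signatures at ranks R(1) < … < R(k), the enrichment score is the
   signed Kolmogorov–Smirnov maximum deviation

       a = max_i [ i/k − R(i)/n ],   b = max_i [ R(i)/n − (i−1)/k ]
       ES = a if a > b,  −b if b > a,  0 on a tie

   with significance from a 1000-draw permutation null (k distinct ranks
   drawn uniformly; p = frequency of null ES ≥ observed ES). Compounds
   with p < 0.05 and more than 4 replicate signatures enter the final list,
   ranked by descending ES.
6. **GSEA baseline.** Each compound's signatures are Borda-merged (mean
   rank) into one gene ranking; the top/bottom-20 genes of each compound
   are tested for enrichment in the other's ranking (unweighted KS running
   statistic, symmetric average); positive–positive pairs are true
   positives and positive–negative pairs false positives for ROC/PRC.

## Worked example

Simulate a strong, consistent MOA (10 positive compounds, 200 inert
negatives, 4 cell lines, 3 replicates each), hold out 3 positives, and run
the drug-prediction pipeline:

```sh
moarank simulate --scenario strong_consistent --seed 0 --out-dir sim
# train on 7 of the 10 positives (sim/labels_train.csv), rank the rest
moarank predict --matrix sim/matrix.gct --meta sim/metadata.tsv \
    --labels sim/labels_train.csv --hidden 64,32 --iterations 300 \
    --batch 64 --seed 0 --out-dir pred
```

prints

```
mean CV AUROC=0.997 well_trained=True; 4/53 compounds pass the p<0.05, k>=5 filter
```

and `pred/predictions.csv` begins

```
compound_id,es,p_value,k,passes_filter,rank
moa1_cpd008,0.959...,0.0,12,True,1
moa1_cpd009,0.921...,0.0,12,True,2
moa1_cpd007,0.858...,0.0,12,True,3
neg_cpd0151,0.355...,0.032,12,True,4
```

The three held-out positives (`moa1_cpd007/8/9`, never seen during
training) top the ranked list with enrichment scores near 1 and permutation
p-values of 0: their 12 replicate signatures concentrate at the very top of
the probability ranking. The cross-validation report (`pred/cv_report.csv`)
shows the model is well trained (mean drug-level CV AUROC 0.997 ≥ 0.6).

The same library surface is available in Python
(`moarank.reduce_compendium`, `moarank.assemble`, `moarank.plan_folds`,
`moarank.cross_validate`, `moarank.rank_predictions`, …), and the
classifier itself is an sklearn-compatible estimator
(`moarank.SignatureMLPClassifier`) usable in sklearn pipelines. The reverse
direction — score a query profile against a directory of serialized MOA
models and return the top MOAs by mean probability — is
`moarank predict --direction moa --models-dir <dir>`.

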