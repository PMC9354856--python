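# raidkit

A virtual DNA microarray for toxicogenomics read-across: per-gene penalized
regression models that predict **in vivo** liver gene-expression fold changes
from chemical structure descriptors plus **in vitro** hepatocyte transcriptome
data, with the analytics needed to use those predictions for mode-of-action
inference and quantitative in vitro to in vivo extrapolation (QIVIVE).

Who it is for: computational toxicologists and cheminformaticians who have
(a) replicate-level expression tables or fold-change matrices from a paired
in vitro / in vivo design (e.g. TG-GATEs-style rat liver and primary
hepatocyte microarrays), (b) a numeric chemical descriptor table, and
optionally (c) hepatotoxicity class labels — and who want animal-free
estimates of in vivo transcriptome responses for new substances.

## The model

For each retained gene *g*, the in vivo log2 fold change *y* is modeled as a
weighted elastic net over two feature blocks — curated/normalized chemical
descriptors and the in vitro log2 fold changes of all retained genes:

    min over (b0, b):  (1 / 2Σw) Σᵢ wᵢ (yᵢ − b0 − xᵢᵀb)²
                        + λ [ α‖b‖₁ + ((1−α)/2)‖b‖₂² ]

with per-substance weights *w* emphasizing responsive training samples
(fold change ≥ 1.5 → w = 1.5, ≥ 4 → w = 2). The hyperparameters (α, λ) of
every model are tuned by 5-fold cross-validation over an α-grid and a
100-point λ-path, taking the largest λ within one standard error of the CV
minimum. The collection of fitted models — the *virtual microarray* — maps a
descriptor vector (plus an optional, possibly partial in vitro profile,
median-imputed where missing) to a predicted in vivo expression profile.

Before training, fold changes pass a reliability adjustment driven by MAS5
detection calls and Welch p-values: fully Absent cells are set to 1 (no
differentiation), p > 0.1 shrinks the fold-change increment to a quarter
(1.4 → 1.1), and Absent-call counts at the source threshold or p in
[0.05, 0.1] halve it (1.5 → 1.25). Genes differentially expressed
(≥ 1.5-fold) in fewer than 10 substances are dropped. Descriptors are curated
(missing values, constants, pairwise |r| > 0.95) and each column gets the
best normalizing transform among Yeo–Johnson, Box–Cox, log10, square root,
arcsine and identity.

Downstream analytics: centered PCA with deterministic loading signs, quadrant
gene rankings by loading length √(PC1² + PC2²), PC-related gene sets (top and
bottom 30 loadings per component) with Venn partitioning across data sources,
per-gene normalized-RMSE comparison of predictions vs raw in vitro data
(Welch's t-test), projection of external substances into the training PCA,
nearest-neighbor retrieval for read-across, and a minimal 2-component PLS-DA
on toxicity labels.

## Worked example

`examples/01_fold_change_adjustment.py` builds a 6-substance × 4-gene study
with hand-chosen replicate signals and runs the reliability adjustment:

```
cell        raw F   flagA  p-value   adjusted  weight
(S1, g1)     1.50   2        1e-06      1.25   1.0
(S2, g2)     1.40   0          0.5       1.1   1.0
(S3, g3)     2.00   3        1e-07         1   1.0
(S4, g4)     3.00   0        2e-08         3   1.5
```

Reading the rows: a 1.5-fold change measured with 2 of 3 treated replicates
flagged Absent keeps only half its increment (1.25); a 1.4-fold change with a
Welch p of 0.5 keeps a quarter (1.1); a cell whose calls are all Absent in
both data sources is treated as no differentiation (1.0); a clean 3-fold
change is kept as-is and enters training with weight 1.5.

`examples/04_qivive_evaluation.py` trains a bank on 60 simulated substances
and evaluates 30 held-out ones:

```
mean per-gene RMSE, predictions vs in vivo: 0.095
mean per-gene RMSE, in vitro vs in vivo:    1.398
Welch's t = -6.91, p = 1.3e-06
PLS-DA held-out accuracy on predicted profiles: 0.78
```

The predictions sit an order of magnitude closer to the in vivo profiles than
the raw in vitro data they were partly built from — the quantitative IVIVE
effect the method exists to deliver.

The other examples cover training/importance inspection
(`02_train_virtual_microarray.py`) and PCA read-across with external-substance
projection (`03_read_across_pca.py`). The same workflow is scriptable through
the `raid` command line tool (`raid simulate | preprocess | descriptors |
train | predict | readacross | evaluate | run`).

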