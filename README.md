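# vfipred

Gene-specific prediction of missense-variant pathogenicity and phenotype
severity for clinically variable ion-channel genes, built around an
allele-frequency tolerance score.

Genome-wide variant effect predictors are inconsistent on genes whose
variants range from silent to severe: they over-call pathogenicity at
conserved positions and miss the tolerated variants that carriers live with.
`vfipred` implements the alternative: a *gene-specific* supervised model
whose primary descriptor is the **Variant Frequency Index (VFI)**, a
per-position measure of how much missense variation a residue tolerates in
population sequencing panels, combined with physico-chemical,
evolutionary and structural features, an ensemble training protocol, and
Shapley-value interpretation. A deterministic synthetic-gene generator
emulates every input (coding sequence, gnomAD-style allele tables, homolog
MSA, AlphaFold pLDDT, domain map, labeled variants), so the whole pipeline
builds and tests offline.

## The score

For residue position *n* with observed missense allele count
*missense_observed* summed over that codon's variants, *N* total alleles in
the panel and *missense_possible* distinct single-base-reachable missense
residues:

```
f_n   = missense_observed / (N · missense_possible)        raw tolerance
F_n   = f_n / (f_n + α)                                    rational squash, F(α) = 0.5
VFI_n = Σ_j K_j · F_{n−j}      K_j ∝ exp(−j²/2σ²)          Gaussian smoothing
```

The kernel is truncated and renormalized at the sequence ends; a 31-residue
rectangular kernel (the classical sliding-window regional-intolerance
baseline) is available for comparison. Multi-panel allele tables are merged
per variant, keeping the record from the larger panel.

## The protocol

For each candidate algorithm (logistic regression, SVM, random forest,
gradient boosting via sklearn/LightGBM/XGBoost, KNN, LDA, Gaussian naive
Bayes, Gaussian process): forward greedy feature selection scored by
stratified 5-fold AUC-ROC with patience 10, a seeded random hyperparameter
search, and performance estimation by 5-fold cross-validation repeated 25
times under reshuffled splits. Tuned models are combined by greedy
soft-vote ensemble selection on shared out-of-fold predictions. Held-out
test rows are sealed behind a split guard until final evaluation. The
severity task (benign vs. severe phenotype among pathogenic variants) adds
three-state label merging, a hard ban on substituted-residue one-hot
features (they memorize the training set), and a decision threshold
optimized for balanced accuracy on training data only.

## Worked example

```python
from vfipred import simulate, PathogenicityModel
from vfipred.explain import attribute, summarize

gene = simulate.make_gene(simulate.GenePreset(master_seed=7))
data = simulate.make_labels(gene, "pathogenicity")
model = PathogenicityModel.from_gene(
    gene, data, candidates=("logistic_regression", "svm", "lda")
)
results = model.fit(repeats=5, n_draws=8, seed=1)
print(results.summary())
print(results.evaluate_test())
```

prints (abridged):

```
model                            AUC-ROC       Bal. acc.     Sensitivity     Specificity
logistic_regression         0.982 (0.014)    0.939 (0.026)    0.931 (0.037)    0.948 (0.037)
svm                         0.970 (0.019)    0.928 (0.025)    0.943 (0.026)    0.913 (0.039)
lda                         0.983 (0.015)    0.946 (0.024)    0.959 (0.034)    0.932 (0.037)
ensemble (soft vote)        0.983 (0.015)    0.950 (0.024)    0.951 (0.032)    0.948 (0.034)

ensemble members: lda, logistic_regression
{'auc_roc': 0.986, 'balanced_accuracy': 0.965, 'sensitivity': 0.968, 'specificity': 0.963}
```

Each row is the mean (sd) over the 25 (here 5) × 5 cross-validation splits;
sensitivity is the true-positive rate on the pathogenic class, and the last
line is the sealed test split scored once after fitting. Attribution of the
linear member (`attribute` + `summarize`) ranks `vfi` first by mean
absolute Shapley value — the tolerance score drives the predictions, with
domain context adjusting them.

The same flow is scriptable from the shell:

```
vfipred make-fixtures --seed 7 --out-dir fx/
vfipred compute-vfi --alleles fx/alleles.tsv --cds fx/cds.fasta --sigma 2 --out profile.tsv
vfipred featurize --data fx/labels_pathogenicity.csv --profile profile.tsv \
    --plddt fx/plddt.json --msa fx/msa.fasta --secondary fx/secondary.txt \
    --domains fx/domains.tsv --out features.csv
vfipred train --features features.csv --seed 1 --out model.bundle
vfipred predict --model model.bundle --in features.csv --out predictions.csv
vfipred explain --model model.bundle --in features.csv --out-dir shap/
```

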