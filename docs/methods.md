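# Methods

## The tolerance model

The package treats per-position population variation as a noisy readout of
a residue's tolerance to substitution. Three quantities are computed:

* **Raw tolerance** `f_n = missense_observed / (N · missense_possible)`.
  `missense_observed` is, by default, the *summed allele count* of missense
  variants at the position; dividing by `N`, the panel's total allele
  count, makes `f` a frequency. A `count_mode="variants"` switch counts
  distinct observed variants instead, for users who prefer the
  presence/absence convention. `missense_possible` is the number of
  distinct missense residues reachable from the codon by one base change,
  computed by exhaustive enumeration under the standard genetic code.
  `N` is one gene-wide denominator (given explicitly, or the largest
  `total_alleles` after merging) rather than per-position, matching the
  notion of a single sequenced cohort.
* **Squash** `F = f/(f+α)` maps `f` monotonically onto [0, 1). `α` is the
  half-saturation point — the raw tolerance at which `F = 0.5`. Default:
  the median of the non-zero per-position `f` over the gene, which centres
  the squash on typical tolerance; any positive value can be given.
* **VFI**: discrete convolution of `F` with a normalized Gaussian kernel of
  standard deviation `σ` (positions). Default `σ = 2` — wide enough for
  statistical support, narrow enough to keep positional resolution. Kernel
  half-width is `ceil(4σ)` (>99.99 % of the mass); at the sequence ends the
  kernel is truncated to in-range positions and renormalized, so constant
  profiles are preserved exactly and no out-of-range padding value is
  invented. The 31-residue running mean (`sliding_window_score`) is the
  classical regional-intolerance baseline and is exactly the same smoother
  with a rectangular kernel.

Multi-panel allele tables (e.g. two releases of a population database) are
merged one-row-per-variant, keeping the record from the panel with more
total alleles — the better-powered frequency estimate; the discarded rows
are redundant re-observations.

## Features

Per variant: six physico-chemical deltas (alt minus ref) — charge at pH 7
(His neutral), Kyte–Doolittle hydrophobicity, residue mass, binary
polarity, binary aromaticity, normalized maximum solvent accessibility —
plus transition flags (polar→non-polar and the reverse, charge
gain/loss by magnitude, aromaticity change), a first-position flag
(initiator-codon variants), one-hot topology (extracellular /
transmembrane / cytoplasmic), one-hot functional domain plus the
`unknown_function`, `calmodulin_interaction` and `selectivity_filter`
flags, per-column Shannon entropy of the homolog MSA (log base 2, gaps
excluded from the frequencies to avoid entropy inflation by alignment
artifacts; an all-gap column is an error), the VFI value, the pLDDT value,
a 3-state secondary-structure one-hot, and (pathogenicity task only) 20+20
one-hots for the initial and final residues. Scale tables are editable
(`AminoAcidScales.from_yaml`); the shipped values are the conventional
ones named above. Missing values are an error, never imputed — a variant
without full annotation should fail loudly.

## Training protocol

Numbers below are defaults, all overridable.

* **Greedy feature selection** (per algorithm): forward search, adding at
  each step the feature with the best stratified 5-fold mean AUC-ROC; stop
  after 10 consecutive non-improving additions; return the best-scoring
  prefix. Ties break by feature-name order for determinism. Candidates
  whose evaluation raises (e.g. LDA's SVD on a constant one-hot column)
  are treated as non-improving and skipped.
* **Random hyperparameter search**: seeded draws from shipped
  per-algorithm spaces (log-uniform regularization strengths 1e−3…1e3,
  tree counts 100–400, depths 2–16, …); best mean 5-fold AUC-ROC wins,
  ties by draw order.
* **Selection-time scoring** uses cheaper but rank-equivalent stand-ins:
  AUC needs only a ranking, so models are scored by `decision_function`
  where available, SVMs skip Platt calibration, and tree ensembles use
  fewer trees *while comparing candidate feature sets and hyperparameter
  draws*. Final models are always fit from the full configuration.
* **Repeated stratified CV**: 5 folds × 25 repeats with reshuffled splits;
  per-split AUC-ROC, balanced accuracy, sensitivity (class 1 =
  pathogenic/severe) and specificity, aggregated as mean and sd. Every
  sample is held out exactly 25 times, which supports the per-variant
  error-rate map (misclassifications / 25; chronic failures flagged above
  50 %).
* **Ensembling**: members are picked greedily on out-of-fold predictions
  computed on shared folds (so ensemble scoring needs no refits), and the
  best-scoring subset is returned — its size emerges from the search. Soft
  voting averages member probabilities; hard voting takes the majority
  label with ties to the positive class; stacking fits a logistic
  regression on out-of-fold member probabilities (out-of-fold, not
  in-fold, to keep the meta-learner from reading the members' training
  fit).
* **Split hygiene**: rows marked `test` are sealed inside the dataset
  object; any metric computation on them before an explicit `finalize()`
  raises. All randomness flows from one master seed through spawned child
  seeds.

The severity task differs in three ways: the three-state labels
(benign / benign-and-severe-reports / severe) merge to binary with severe
as the positive class; substituted-residue one-hots are rejected outright
(with them, models memorize mutation patterns — training error falls while
cross-validation error rises); and the decision threshold is chosen to
maximize balanced accuracy on training scores (candidates: midpoints of
adjacent sorted unique scores plus 0.5, ties toward 0.5), then applied
unchanged to test data. With a ~2.7:1 severe:benign imbalance the default
0.5 threshold over-calls severe; the optimized threshold narrows the
sensitivity–specificity gap.

## Shapley attribution

Attributions satisfy local accuracy: base value + per-feature values =
model output for each sample, relative to a background sample (training
matrix; seeded subsample above 200 rows). Three routes:

* linear models (logistic regression, LDA): exact closed form
  `w_i (x_i − mean(z_i))` on the log-odds scale, with scaler-wrapped
  pipelines composed into effective weights;
* scikit-learn tree ensembles: exact interventional values — for each
  (sample, background row) pair the two-point coalition game is solved by
  one recursion over each tree, averaged over the background. Random
  forests report on the probability scale; gradient boosting reports on
  the log-odds scale because only the margin is additive over trees (the
  probability is a sigmoid of the sum, which would break local accuracy).
  LightGBM/XGBoost use their native per-feature contribution output
  (path-dependent, log-odds);
* anything else (kernel machines, neighbours, heterogeneous ensembles):
  seeded permutation sampling on the probability scale; local accuracy
  holds in expectation.

The output scale and method are recorded in the report. Summaries rank
features by mean absolute attribution with name tie-breaks; a long-format
export carries (sample, feature, attribution, feature value) for beeswarm
plotting.

## The synthetic generator

The generator produces a statistical stand-in for a curated ion-channel
variant study — never a model of any real gene's biology. A fixed
membrane-protein-like region layout (cytoplasmic termini, six
transmembrane segments, a pore with selectivity filter,
calmodulin-interaction helices, an unknown-function region) defines a
per-position tolerance landscape `t(p) ∈ [0,1]` with smooth seeded wiggle.
Every input derives from it:

* **CDS**: uniform random sense codons (872 of them; only positional
  structure matters downstream).
* **Allele tables**: per possible missense variant, Poisson counts with
  rate ∝ `t(p)`, expected ~16 alleles per fully tolerant position in the
  larger panel; two panels (150 k / 280 k alleles) with the smaller one
  rate-scaled, exercising the merge rule.
* **pLDDT**: affine in the smoothed landscape (35 + 50·smooth) plus sd-7
  noise, clipped to [0, 100] — positively correlated with VFI by
  construction (r ≈ 0.8 at defaults).
* **MSA**: 48 sequences; column conservation `1 − 0.6 t(p)` with sd-0.15
  jitter, so Shannon entropy rises with tolerance but is a noisier signal
  than VFI; 2 % gaps.
* **Secondary structure**: helix in membrane segments and C-terminal
  helices, strand in the filter, coil elsewhere, with a 20 % per-residue
  error rate — as a *predicted* annotation would have, and enough that it
  cannot stand in for the landscape itself.
* **Labels**: pathogenicity propensity is a steep logistic
  (`effect_size = 60`) of the σ-smoothed landscape around 0.45, plus
  bonuses for filter/calmodulin/transmembrane context; exact class counts
  (285 tolerated / 269 pathogenic) are drawn by propensity-weighted
  sampling without replacement, split 206 P + 10 T train / 62 P + 27 T
  test / rest unassigned. An extra 208-variant tolerated training batch
  emulates primate-derived heuristic labels and carries the preset's 5 %
  label noise (that fraction is drawn from pathogenic-propensity
  positions). Severity labels (62 / 32 / 180) depend on positional
  context only — never on residue identity — so endpoint one-hots carry no
  severity signal by construction, and the split is 80/20 per class.

Everything is deterministic under the master seed (byte-identical files).

**What passing tests do and do not show.** The generator guarantees the
designed signal hierarchy (VFI dominant; pLDDT a slightly weaker
correlate; conservation weaker still; domain flags adjustments), smooth
region structure, and exact class counts. Real curated datasets have
phylogenetically structured MSAs, non-uniform codon usage, database label
noise that is not independent of position, and far sparser allele coverage
(~7 % of possible variants observed, versus near-complete coverage here at
desk scale). Recovery of the designed regime therefore validates the
machinery — formulas, protocol, guards, determinism — not clinical
accuracy on any real gene.

## Problem sizes and numerical choices

The shipped end-to-end checks run the full protocol (greedy selection →
25×5 repeated CV → greedy soft-vote ensemble) on the default preset
(n = 554 labeled variants + 208 heuristic rows, 424 training rows) with
the three fast candidate algorithms (logistic regression, SVM, LDA); tree
ensembles are exercised in unit tests. The severity check uses two linear
candidates at 5 repeats. Convolutions are float64 with oracle agreement at
1e−12; tree-Shapley coalition weights use exact rational arithmetic before
conversion to float; AUC uses the rank statistic with ties averaged.
Degenerate inputs fail loudly: empty profiles, even windows, one-class
label vectors, all-gap columns, non-positive α or σ, allele counts
exceeding panel size.

## Known limitations

* Variants enter at protein level; there is no genome-coordinate liftover
  and no VCF path.
* Stop-gain/-loss, frameshift and synonymous changes are rejected at parse
  time; the models say nothing about them, nor about gain- vs
  loss-of-function.
* The gradient-boosting zoo covers scikit-learn, LightGBM and XGBoost;
  no CatBoost backend is provided.
* `α` and the production kernel radius for real cohorts are
  dataset-dependent and must be chosen by the user; the defaults are
  desk-scale conventions.
* Severity prediction inherits the task's intrinsic difficulty: scarce
  labels, class imbalance, and features that carry positional context
  rather than mechanism.
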