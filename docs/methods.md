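# Methods

This note documents the models, the synthetic-data design, and every
numerical convention frozen in `odorpred`, in the package's own words.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Task and model family

The task is multi-label binary classification `f : M → {0,1}^K` from
molecular structure, with K = 6 odor types (fruity, green, sweet,
floral, woody, herbal) whose positive rates span roughly 13–31%. Two
representation routes are implemented:

1. **Learned graph representations.** A molecule is a graph of heavy
   atoms (hydrogens implicit) with a 25-dimensional atom feature vector
   and 6-dimensional bond vector, both with frozen slot order (see
   `featurization.py`). Three message-passing layers are authored in
   the package on a NumPy reverse-mode autodiff core:
   * GCN: symmetric-normalized neighbor averaging with self-loops,
     `h'_i = σ(Σ_{j∈N(i)∪{i}} W h_j / √((d_i+1)(d_j+1)))`;
   * GAT: additive multi-head attention with softmax over each
     neighborhood N(i)∪{i}; hidden layers concatenate heads
     (`hidden_dim` must divide by `gat_heads`); α_ij is cached per
     layer/head for interpretability;
   * NNConv: an edge network (6 → 16 → in·out MLP) maps each bond
     vector to a linear transform; messages `Θ(e_ij)·h_j` are
     aggregated by **mean** (sum scales with degree and destabilizes
     training on mixed-size molecules), plus a root transform.
   Each layer is followed by batch normalization (momentum 0.1,
   ε = 1e-5), ReLU and dropout; graphs are pooled by global mean and
   classified by a two-layer sigmoid head. Raw count features (Z,
   valence, H counts) are not pre-scaled: batch normalization absorbs
   scale.
2. **Descriptor tables** processed by Strategies A/B/C (below) and fed
   to six classical learners (RF, RBF-SVM, GBDT, MLP, XGBoost,
   LightGBM) as independent per-label binary classifiers
   (binary relevance), grid-searched by stratified cross-validated F1.

## Losses for imbalance

Three training losses operate on clamped probabilities
(ε = 1e-7): plain BCE; weighted BCE with positive-term weight
`w_k = (N − n_k)/n_k` from training-label counts; and focal loss
`L = −(1/N) Σ_i Σ_k α_k (1−p_ik)^γ log p_ik` with `p_ik` the confidence
in the true class. Defaults α = 0.25, γ = 2 (the standard focal
setting); at γ = 0, α = 1 the focal loss reduces exactly to BCE, which
the suite asserts to 1e-9.

## Training protocol

Adam (lr 1e-3), mini-batches of 32, validation macro F1 at a fixed 0.5
threshold as the monitored quantity (calibration is deliberately
post hoc), early stopping with patience 20, plateau LR decay ×0.5 after
10 non-improving epochs, best-validation checkpoint restored. Default
capacity is 3 layers × 64 hidden units × 4 heads with dropout 0.2 —
sized for desk-scale CPU runs; all randomness (init, shuffling,
dropout) flows from one integer seed through one generator, so repeat
runs are bit-identical.

## Descriptor processing

* **Strategy A.** Per-column missing rate decides the tier: <5% median
  imputation; 5–30% k-NN imputation (k = 5, Euclidean distance over
  median-pre-imputed copies — pre-imputation breaks the circular
  dependence of distances on the values being imputed; the imputed
  value is the mean of the k nearest training rows that observed the
  column); >30% column removal. Surviving columns are clipped to
  [Q1 − 1.5·IQR, Q3 + 1.5·IQR] and z-scored. All statistics come from
  training rows only. Quartiles and all percentiles use linear
  interpolation (the common "type 7"); clip bounds depend on this, so
  it is frozen package-wide. **Degenerate guard:** when IQR = 0 (e.g.
  a binary indicator with under 25% positives) the clip rule would
  collapse the entire column to a constant, so such columns are left
  unclipped; truly constant columns are still dropped with a warning.
* **Strategy B.** Variance filter (τ = 0.01) and a global pairwise
  correlation filter (|ρ| > 0.95; columns scanned left-to-right, the
  later member of a violating pair dropped — deterministic) applied
  once, then per label: mutual-information ranking (k-NN estimator,
  k = 3) keeps the top 64 candidates, and recursive feature
  elimination with an L2 logistic model produces a full ranking in one
  elimination pass; the subset size is chosen over the grid
  {12, 16, 20, 24, 28, 33} by 5-fold cross-validated F1 (ties toward
  the smaller size). The MI cap, fold count and size grid are package
  decisions; the correlation filter is global rather than per-label so
  every label selects from one shared decorrelated pool.
* **Strategy C.** PCA keeps the smallest component count reaching 95%
  cumulative explained variance; kernel PCA uses an RBF kernel
  (bandwidth 1/n_features) with the analogous cumulative-eigenvalue
  rule. Projections are fitted on training rows only.

## Threshold calibration

For each label independently, the threshold maximizing validation F1 is
chosen from the grid {0.01, …, 0.99} (step 0.01); prediction uses
`score ≥ t`. Ties break toward the smaller threshold, which favors
recall — the sensible direction for conservative scorers. A label with
no validation positives gets t = 0.5 with a warning. F1 with zero
predicted and zero true positives is defined as 0. By construction the
calibrated validation macro F1 can never fall below the 0.5-threshold
macro F1 (0.5 is in the grid); the suite asserts the optimizer against
exhaustive brute force on 200 random instances.

## Evaluation

Per label: precision, recall, F1 (0 when P + R = 0), ROC-AUC
(trapezoidal, equal to the normalized Mann–Whitney statistic, asserted
exactly on small instances) and PR-AUC (step/average-precision
interpolation, which avoids the optimistic bias of trapezoidal PR
interpolation). Aggregates: macro means, Hamming loss, subset accuracy.
A label that is single-class in the evaluation rows has undefined AUCs:
they are reported as NaN with a warning and excluded from (not imputed
into) the macro average.

## Applicability domain

Tanimoto AD: radius-2, 2048-bit circular fingerprints; a test molecule
is in-domain when its maximum similarity to the training set is ≥ 0.5.
Distance AD: minimum Euclidean distance from the test vector to the
training set — processed descriptors for tabular models, the pooled
graph embedding (the vector entering the classification head) for
GNNs — against the 95th percentile of the training set's
**leave-one-out nearest-neighbour** distances. "95th percentile of
training set distances" is ambiguous as stated; the LOO-NN reading is
the only one whose scale matches a minimum-distance statistic, and it
is frozen here. Combined judgment = logical AND; agreement = fraction
of samples where the methods concur. The combined in-domain percentage
is bounded by each method's percentage, asserted on every run.

## Interpretability

Gradient attribution is the sum over the 25 feature slots of the
absolute input-gradient of a label's pre-sigmoid logit — the
least-assumption "gradient-based" variant (gradient×input was the main
alternative; absolute gradient was chosen and frozen). Attention
importance is `I_i = (1/(L·H)) Σ_l Σ_h Σ_{j∈N(i)} α_ij^{(l,h)}` over
proper neighbors; a singleton graph carries its self-attention so the
score is well-defined. Nodes at or above the **per-molecule** 75th
percentile (ties included) form BFS components over bonds; each
component takes the highest-priority functional group from the shipped
40+-pattern SMARTS library (`data/smarts_library.txt`, priority =
specificity, esters/acids before generic carbonyl before
methyl/methylene) whose match overlaps it, else "small fragment".
Per label, fragments from up to 30 correctly predicted positive test
molecules are pooled and ranked by total aggregated importance
(count × mean).

## Synthetic data: what it emulates and what it does not

Molecules come from a fragment grammar — scaffolds (C2–C7 chains,
benzene, cyclopentane, cyclohexane) plus 1–3 decorations (ester,
aldehyde, ketone, alcohol, thiol, amine, methyl, F/Cl/Br, phosphine,
sodium alkoxide at low rate, exercising the full 9-element one-hot
without exotic valences) — so every output is valid by construction,
with no rejection sampling. Labels are planted by SMARTS rules
(activation probability 0.90 on match, background 0.03 otherwise); the
decoration weights were tuned once so realized label frequencies span
≈13–31% in the Table-11-like ordering (fruity most frequent, herbal
rarest) and then frozen. The descriptor table mixes exact
structure-derived columns (heavy-atom/ring/heteroatom/aromatic counts
and one rule-match indicator per label — simple constitutional
descriptors are exact by construction, so missingness' >30% tier and
outlier injection apply to noise columns only) with log-uniformly
scaled Gaussian noise columns (scales 1e-2–1e6, emulating
heterogeneous descriptor magnitudes), tiered missingness and
multiplicative outliers.

What passing tests on this generator show: the pipeline recovers a
planted, rule-based structure–odor signal end to end (graph models,
feature selection, calibration, attribution). What they do not show:
performance on real odor data — real structure–odor relationships are
many-to-many, context-dependent and noisy in ways no SMARTS rule
captures; the generator has no stereochemistry, no 3D conformers, no
realistic odorant distribution. Absolute metric values on synthetic
data (macro F1 ≈ 0.8 at n = 600) are therefore not comparable to
published real-data scores (≈0.52), and the attention–gradient
correlation measured on small synthetic GAT models is weak — the two
attribution routes agree on real-data-scale models far better than the
desk-scale study can demonstrate.

## Splitting

64/16/20 train/validation/test by default. Stratified mode uses
iterative stratification with exact target sizes (largest-remainder
apportionment; rarest label first; each positive goes to the open
split with the largest unmet desired count): every label's positive
rate per split stays within ±5 percentage points of the global rate,
warned otherwise. A label with fewer than 3 positives makes
stratification infeasible → random fallback with a warning. Stratified
is the default for **all** model families (random splits are available
by flag): stratification is strictly safer and there is no principled
reason to treat GNNs differently. Calibration sees validation rows
only; test rows are scored once, after thresholds freeze.

## Problem sizes

The test suite and acceptance script run at desk scale by design:
600-molecule studies (384/96/120 splits) for signal recovery,
300-molecule tables for selection tests, 3–5 seeds per stochastic
claim. These sizes were chosen so the planted effects are comfortably
detectable while whole-suite runs stay in the low minutes on one CPU.

## Known limitations

* 2D graphs only: no conformers, stereo flags or isotopes.
* The GNN stack is float64 NumPy on CPU — excellent for
  reproducibility and desk-scale studies, not for thousand-molecule
  batches per second.
* Strict element policy: molecules outside the 9-element vocabulary
  are rejected (lenient mode zeroes the identity block and warns);
  how curation handled such molecules upstream is not recoverable.
* The published per-label hyperparameter grids are not public;
  defaults here are deliberately small and documented rather than
  exhaustively searched.
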