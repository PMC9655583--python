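# Methods

## Problem setting

5-methyluridine (m5U) is abundant on tRNA (the T-loop position 54) but
sparse on mRNA, where experimentally mapped sites number only in the
hundreds. `seqdsn` treats mRNA m5U prediction as a transfer-learning
problem: tRNA and other non-mRNA sites form a label-rich **source
domain**, mRNA sites the scarce **target domain**, and a
domain-separation network learns the sequence features the two domains
share. Inputs are fixed-length windows (default 41 nt) centred on a
candidate uridine, one-hot encoded with channel order (A, C, G, U) and
`N` as the all-zero row.

## Model

Three architecturally identical encoders map a window to a d = 16
dimensional representation: a shared encoder `E_c` applied to both
domains and a private encoder per domain (`E_p^s`, `E_p^t`). Each
encoder is `conv1d(4 -> 16 filters, kernel length 2, symmetric zero
padding 2)` -> batch norm -> ReLU -> `LSTM(hidden 8)` final state ->
batch norm -> dense. Per domain a linear decoder reconstructs the input
window from `h_p + h_c` (concatenation selectable), so the encoder pair
jointly preserves the input. Classifiers are linear heads with
log-softmax outputs and read **only** the shared representation: a
source classifier always, plus a target classifier in the
dual-classifier operating mode.

Two operating modes reflect data availability:

* **mode 1** (`source_only_classifier`) — no target labels exist; the
  target stream carries only negatives, contributing sequence context
  through the reconstruction, orthogonality and similarity terms.
* **mode 2** (`dual_classifier`) — known target positives additionally
  supervise a second classifier.

The "kernel size (2, 1) with padding 2" convolution is read as a 1-D
convolution of length 2 along the sequence with 2 zeros per side
(output length L + 3); the recurrent layer is length-agnostic, so the
exact padding convention only shifts its input length.

## Objective

    L = alpha * L_recon + beta * L_difference + gamma * L_similarity
        + L_source + delta * L_target

with defaults alpha = 0.02, beta = 0.075, gamma = 0.25, delta = 1, and
the target term dropped in mode 1.

* **Reconstruction** — scale-invariant MSE by default (MSE minus the
  squared mean error, which forgives a constant offset); plain MSE
  selectable. Summed over the two domains.
* **Difference (soft subspace orthogonality)** — each representation
  matrix is column-mean-centred and row-L2-normalised (zero rows stay
  zero); the penalty is the squared Frobenius norm of the inter-sample
  cross-product `H_c H_p^T`, i.e. the sum of squared inner products
  between every shared row and every private row, divided by the number
  of row pairs. It is zero exactly when shared and private
  representations span orthogonal subspaces, and a single unit-norm
  sample against itself scores 1. The batch-pair normalisation keeps
  the term at the same order of magnitude as the classification loss at
  any batch size; without it the raw sum grows with batch² and its
  beta-weighted gradient dominates early training.
* **Similarity** — default is the unbiased squared maximum mean
  discrepancy between the two domains' shared representations under a
  fixed mixture of RBF kernels with bandwidths {1, 2, 4, 8, 16} times
  the median pairwise squared distance of the first training batch
  (frozen thereafter), clamped at zero. An adversarial variant (DANN) is
  available: a linear domain discriminator trained through gradient
  reversal. MMD is the default because it is deterministic given a
  batch and adds no parameters.
* **Classification** — mean negative log-likelihood of the true class.

## Training

Batch size 64. The target domain is first upsampled to the source size
so every optimizer step carries one batch from each domain; within each
domain the positive class is upsampled (with replacement, every
original kept at least once) to the negative count before streaming.
Upsampling is train-time only — validation and test splits keep their
construction ratios.

Learning rate 0.005 with step decay: multiplied by 0.9 every 600
optimizer steps. 20 epochs. The default optimizer is **Adam**;
momentum-SGD (0.9) is selectable but at the benchmark's data scale
(~2000 windows per domain, ~600 optimizer steps total) it reliably
underfits within the fixed epoch budget, so Adam is the default the
package ships. Gradient norms are clipped at 5 (switchable off).

Model selection: 10% of the training data per class per domain is held
out before any upsampling; after each epoch the shared-representation
classifier scores this pool and the best epoch by average precision
(AUC selectable) is restored at the end. The test fold never
participates. For studies on the small synthetic benchmark the
experiment driver optionally trains a few restarts from derived seeds
and keeps the best by the same validation metric — a standard guard
against a small recurrent network occasionally failing to leave its
initialisation basin; selection never touches the test split.

Batch-norm layers use batch statistics in training and frozen running
statistics in evaluation. The shared encoder processes the source and
target sub-batches as **one concatenated batch**, so its statistics
describe the domain mixture. (Normalising each domain separately makes
the shared encoder silently re-align the domains during training —
an effect that evaporates at evaluation time and costs most of the
transfer gain.)

## Data pipeline

Negatives are undetected uridines sampled without replacement from the
same transcripts that carry positives: 10 per positive for mRNA-like
sets (the natural sparsity of the modification), or every undetected
uridine for tRNA (about 1:3). All sampling happens after a canonical
sort by (transcript id, position), so results are independent of input
row order. Windows that overlap a transcript end are N-padded (all-zero
rows) and flagged; a strict mode drops them instead.

Cross-validation partitions target positives and negatives into six
near-equal groups each; every (positive group, negative group) pairing
serves once as the test set — 36 folds, each retrained from scratch
with a fold-derived seed, the source domain fully in training. Fold
metrics are averaged with equal weight.

## Synthetic benchmark

The generator emulates the two-domain structure without any download.
Backgrounds are i.i.d. per position with a domain-specific G+C fraction
(source 0.55, target 0.40 by default; G and C equiprobable, likewise A
and U); the centre base is always U. Positives receive a shared 6-mer
(default `GUUCGA`, a T-loop-like mnemonic — nothing depends on the
letters) at anchor 6 with uniform jitter of up to 3 nt, with
probability 0.9; each domain's positives additionally receive a private
confounder 6-mer at a disjoint anchor (28 ± 3) with probability 0.6.
Every insertion is recorded in a planting log. All presets share one
scale — source 1000+1000, target 180+1800 (the 1:10 ratio) — and
differ only in signal structure: `easy` (shared motif in every
positive, no confounders, matched backgrounds), `shifted` (composition
shift only), `confounded` (the full condition).

What the generator does **not** emulate: positional dependence of the
background, transcript-level structure shared between sites, read-level
detection noise, and motif degeneracy. Passing tests therefore
demonstrate that the implementation realises the method's mechanics and
its qualitative behaviour (transfer gain, shared-feature recovery) —
not performance on real transcriptomes.

## Evaluation

Accuracy, specificity, precision, recall and F1 at a 0.5 threshold on
the positive-class probability; AUC by trapezoid over score-sorted
thresholds (equal to the all-pairs statistic with ties counted 1/2);
average precision as the step-wise sum Σ (R_k − R_{k−1}) P_k with no
interpolation. AP is the headline number at 1:10 imbalance. Classical
baselines (naive Bayes, logistic regression, KNN, SVM, random forest,
gradient-boosted trees) run on flattened one-hot windows.

## Interpretation

Integrated Gradients with an all-zero baseline (the all-N window; a
uniform baseline is selectable) and midpoint-rule integration, whose
completeness gap |Σ attributions − (f(x) − f(baseline))| decays
quadratically in the step count (50 steps default). The attribution
target is the positive-class probability of the target classifier in
mode 2 and of the source classifier in mode 1.

Motif aggregation is a deliberately simple stand-in for the full
TF-MoDISco pipeline: per attribution map the per-position weight is the
attribution at the realized base; sliding k-windows (k = 6) above the
map's mean k-window weight are emitted, overlapping candidates keep the
maximum; seqlets link when their best-offset cross-correlation exceeds
0.7 k, connected components are aligned at best offsets against their
highest-weight member, and column counts with pseudocount 0.25 become
position frequency matrices, reported by descending mean seqlet weight.
Maps are taken from positively predicted windows (score ≥ 0.5) only.

The reference interpretation study attributes the mode-2 model on the
`easy` preset: its validation pool contains target positives, which
makes restart selection reliable, and the recovered top consensus can
be compared directly against the planting log. The claim that the
*shared* representation carries cross-domain rather than private
features is checked separately on the `confounded` preset with mode-1
models, where the top recovered motif must be the shared 6-mer and not
either planted confounder.

## Numerical and design choices

* Gradients computed by a small reverse-mode engine on float64 numpy
  arrays; the LSTM and convolution use hand-written fused backward
  passes verified against central finite differences.
* Glorot-uniform initialisation from an explicit generator; forget-gate
  bias 1; model construction is a pure function of (config, mode, seed).
* MMD needs ≥ 2 samples per domain and raises otherwise; a NaN in any
  loss term aborts training with the offending breakdown.
* Ties in checkpoint selection resolve to the earliest epoch; an empty
  or single-class validation pool falls back to the last epoch with a
  warning.
* Delta (the target-classifier weight) defaults to 1 and is
  configurable.
* Reference study sizes: five seeds, ~2000 windows per domain, a 50%
  per-class target test split; chosen so the full study runs on a
  single CPU in minutes while keeping ~90 positive target test windows
  per seed.

## Known limitations

* The similarity pressure uses a bandwidth frozen at the first batch;
  as representations drift the kernels can saturate, and with gamma =
  0.25 the orthogonality split is only soft — under strong confounding
  an occasional seed still transfers poorly, which is why stochastic
  claims are stated as five-seed averages.
* Attribution on the conv-LSTM architecture leaks weight toward window
  edges; the above-mean seqlet emission rule then admits noise
  seqlets, so overlap-with-ground-truth fractions sit well below 1 even
  for near-perfect classifiers.
* Single-linkage seqlet clustering chains aggressively at the default
  0.7 k threshold; with many noise seqlets most of the pool lands in
  one cluster whose consensus is still dominated by the true signal.
* No homology-aware split: transcripts are treated as independent, as
  in the original cross-validation design.
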