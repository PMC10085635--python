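# Methods

## Model

The classifier operates on gene pairs. Expression vectors of the two genes
over *k* ordered cells (column order of the input matrix; for pseudo-time or
time-course data the caller supplies pre-sorted columns) are cut into
contiguous windows of *s* cells and concatenated window-wise into a sequence
of L = ⌈k/s⌉ sub-vectors of width d_model = 2s. The trailing partial window
is zero-padded rather than truncated, so no cell's measurement is discarded;
the cost is one extra, partially padded position. The first half of every
sub-vector always holds the regulator-slot gene, making the encoding of
(a, b) and (b, a) distinct — a requirement for learning regulation
direction.

The network is deliberately small:

1. **Positional encoding.** PE(m, 2n) = sin(m / 10000^(2n/d)) and
   PE(m, 2n+1) = cos(m / 10000^((2n+1)/d)), added element-wise. The default
   exponent divisor is d = d_model; a `literal_pe` switch uses the window
   size s instead (both variants are exercised in the tests, including the
   gradient check). Note the sin/cos channels here use *consecutive*
   exponents (2n and 2n+1) rather than the paired-frequency convention of
   the common transformer encoding.
2. **One encoder layer.** Two-head scaled dot-product self-attention over
   the L positions. Per head, Q/K/V are learned linear projections of the
   input (d_head = d_model / 2); head outputs are concatenated with no
   output projection. Attention logits are scaled by √d_head by default
   (`literal_scale` divides by s instead). Residual connection and layer
   normalization follow. The feed-forward network is two linear layers with
   ReLU (width d_ff = 2·d_model); a second residual + layer norm after it is
   applied by default and omitted under `literal_no_post_ln`.
3. **Classification.** Average pooling over the L positions, then a
   two-layer ReLU head (hidden width d_model/2) with sigmoid output.

Training minimizes binary cross-entropy with Adam (sigmoid output and Adam
are fixed; BCE is the canonical pairing for them). Everything — forward
pass, analytic gradients, Adam — is written in NumPy; the gradients are
validated against central finite differences in all three architecture
modes. Initialization is Glorot-uniform, fully determined by the config
seed; dropout (default 0.1) is applied after the attention and feed-forward
blocks at training time only. Defaults: lr 1e-3, batch 32, 50 epochs,
window s = 100. The model kept is the epoch checkpoint with the best
validation AUROC, not the last epoch.

## Sample construction and splits

All samples are anchored on TFs and carry a `tf_group` (the regulator):

* `gene_gene` (reconstruction, unbalanced): every resolvable edge is a
  positive; every other (known-TF, gene) pair is a negative. No
  subsampling — the natural imbalance is preserved. Pairs whose source is
  not a known regulator are not generated.
* `interaction` (balanced): per edge (a, b), one negative (a, c) with c
  drawn uniformly *without replacement per TF* from the genes a does not
  regulate, maximizing negative diversity at equal balance.
* `causality` (balanced): per edge (a, b), (a, b) labelled 1 and (b, a)
  labelled 0, both in a's group so the pair is never split across folds.
  Bidirectional edges are contradictory and must be dropped explicitly.

Reconstruction uses a stratified 3:1:1 split (per class: 1/5 validation,
1/5 test, rest training — the class ratio of every part matches the global
ratio to within one sample). TF–gene prediction uses 3-fold
cross-validation with whole TF groups assigned to folds greedily (largest
group first, into the currently smallest fold — deterministic and
size-balancing); 20% of each fold's complement is carved out as validation
at the sample level, not the TF level, so validation TFs overlap training
TFs while test TFs never do.

Gene identifiers are matched case-insensitively between matrix and network
(public benchmarks commonly disagree in case). Genes expressed in fewer
than 10% of cells are filtered ("fewer than" strict: a gene nonzero in
exactly ⌈0.1k⌉ cells stays). Highly variable genes are scored by variance
of log1p expression, ties broken lexicographically. Expression is log1p
transformed before encoding by default (flag-controlled; the transform
stabilizes the scale on which span synchrony is expressed).

## Evaluation

AUROC is the trapezoidal area under the ROC curve and AUPRC the step-wise
(non-interpolated) average precision — the estimator that avoids the
optimism of linear PR interpolation; tied scores enter the confusion table
together. Both are computed via scikit-learn and cross-checked in the test
suite against a Mann–Whitney rank-statistic oracle and hand counts.
Per-TF summaries report group-wise AUROC/AUPRC with class counts;
single-class groups are reported as undefined rather than silently skipped.

## Interpretation probe

The trained classification head is applied to each position's encoder
output individually (bypassing the pooling), yielding a per-window
classification probability; the argmax (ties to the earliest position) is
the pair's most important window, and the per-TF histogram of argmax
positions shows which span of the trajectory drives that TF's calls. The
pooled-trained head is reused, not re-trained per position.

## Synthetic data

The generator emulates the phase-synchrony phenomenon: each TF has a smooth
latent profile along the cell axis; targets follow
coupling·TF-latent + (1−coupling)·own-latent inside per-TF synchronization
spans and their own latent elsewhere. Latents are mixed on the log scale —
where co-expression lives — and mapped to expression as
base_mean·exp(amplitude·latent).

* **Latent process.** A mean-reverting (Ornstein–Uhlenbeck) walk with
  correlation time 25 cells, lightly smoothed and standardized. An early
  design used a plain cumulative-sum walk; it was replaced because
  nonstationary walks produce large spurious correlations between
  independent genes (the classic nonsense-correlation effect), which both
  misrepresents expression trajectories — bounded, mean-reverting — and
  breaks the generator's own contract that `coupling` governs within-span
  correlation. For `pulse` profiles a TF's active phase is pinned to its
  synchronization span, so the regulatory program and the TF's expression
  phase coincide.
* **Scale and noise.** amplitude 1.5 (log-sd; ~2 orders of magnitude
  dynamic range, appropriate for highly variable genes), base mean 5,
  log-normal multiplicative noise with sd 0.3, then i.i.d. dropout zeros.
  Defaults: 5 TFs × 20 targets, 100 noise genes, 500 cells, coupling 0.8,
  dropout 0.3, one span per TF covering 40% of the axis at a random
  position.
* **Not modelled:** library-size variation, batch structure,
  expression-dependent dropout, discrete counts, cell-type heterogeneity,
  branching trajectories. Passing tests therefore demonstrate recovery of
  planted phase-synchrony under heavy sparsity, not performance on real
  scRNA-seq.

## Study protocols and measured scales

`grnmotif.protocols` fixes the benchmark conditions (used by the test suite
and `scripts/acceptance.py`; all quantities are 3-seed medians):

* Reconstruction: default fixture, 1,020 pair samples (prevalence 0.098),
  held-out test AUROC/AUPRC; label-permutation null; positional-encoding
  ablation.
* Direction calling: causality fixture with TF expression scale 3× targets
  (emulating the observation that regulated genes sit at lower expression),
  200 samples, TF-disjoint 3-fold CV, pooled AUROC; cross-task control —
  the direction-trained model applied to an interaction fixture, expected
  near chance because both orientations of an interaction sample put the
  TF in the regulator slot.
* Interpretation: balanced interaction task on a fixture with paper-scale
  TF blocks (5 TFs × 40 targets, 150 noise genes) whose single
  synchronization span exactly covers the third encoding window (cells
  200–300, s = 100); the tally of most-important windows across true
  positives is compared with the planted window.

**Known limitation.** On the interpretation protocol the *modal*
most-important window matches the planted span consistently across seeds,
but its concentration is ~0.4–0.5 of true positives rather than the
0.6–0.85 range reported for strongly phase-locked TFs on real data. Probe
inspection shows why: the trained attention maps converge to routing every
position to the span window, so all encoder rows carry the detected signal
and per-position head probabilities saturate near 1 for positives; the
argmax then rests on the residual stream alone, where chance within-window
synchrony of the latent process (~4 independent fluctuations per 100-cell
window) competes with the planted signal. Under these study conditions the
concentration statistic is intrinsically noisier than on data whose
off-span windows are quiescent.
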