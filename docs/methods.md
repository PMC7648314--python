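# Methods

## Problem setting

Enhancer–promoter interactions (EPIs) are cell-line specific, and interaction
labels (from high-resolution chromatin-contact assays) exist only for a
handful of cell lines. The package addresses the cross-cell-line setting:
labeled enhancer–promoter pairs pooled from several cell lines (the *source
domain*) are used to train a sequence-only classifier that is then applied to
a new cell line (the *target domain*) for which only element locations — not
labels — are available. Because sequence composition and the regulatory
grammar around elements differ between cell lines, a classifier trained
naively on the source domain degrades on the target; the package counteracts
this with unsupervised domain-adversarial adaptation.

## Model

Inputs are fixed windows centered on the annotated element midpoint — 3000 nt
for enhancers, 2000 nt for promoters — one-hot encoded over A,C,G,T (columns
in that order; `N` and out-of-chromosome padding encode as all-zero rows).

The feature extractor G_f processes each element in its own branch: a valid
(no padding, stride 1) 1-D convolution with 300 kernels of length 40, ReLU,
and max-pooling of length 20 with stride 20; by default two such conv+pool
blocks are stacked per branch (a config switch selects one). Branch outputs
are concatenated along the position axis, passed through dropout (rate 0.25),
and fused by a unidirectional LSTM whose final hidden state (100 units) is
the shared feature vector.

Two heads consume this identical feature vector:

* the **EPI predictor** G_y: dense 100 → ReLU → dropout 0.5 → sigmoid;
* the **domain discriminator** G_d: a gradient reversal layer, then dense
  50 → ReLU → dropout 0.5 → sigmoid.

The gradient reversal layer (GRL) is the identity in the forward pass and
multiplies the backward gradient by −λ. The training objective is

    E(θ_f, θ_y, θ_d) = Σ_i L_y^i(θ_f, θ_y) − λ Σ_i L_d^i(θ_f, θ_d),

with binary cross-entropy losses L_y (interaction) and L_d (domain),
optimized to a saddle point: θ_y and θ_d descend their losses while the GRL
makes θ_f *ascend* the domain loss, so the learned features predict
interactions but cannot tell the domains apart. λ defaults to 1.0 and is held
constant (no schedule); probabilities are clipped to [1e−7, 1−1e−7] inside
the loss.

Architecture variants (ablations): `source_only` removes the discriminator —
target data is then unusable and training is purely supervised; `base` uses
one conv+pool block per branch with flattened features and no recurrent
fusion; `base_lstm` adds the LSTM to `base`; `base_fc` replaces the LSTM with
a dense fusion layer. A diagnostic control (`reverse_gradient=False`) trains
the discriminator *cooperatively* (gradient scaled +λ), useful as the
contrast case when probing feature invariance.

## Training procedure

The target cell line's pairs are split half/half at random; one half (labels
stripped) joins training as the unlabeled target stream, the other half is
reserved for evaluation. All other cell lines' balanced corpora are pooled
and shuffled as the source. Every mini-batch contains equal numbers of source
(domain 0) and target (domain 1) samples — 32 + 32 at the default batch size
64. Each step performs two updates:

1. interaction loss on the source half updates θ_f and θ_y (target labels
   are never read; the target stream carries none);
2. domain loss on the full batch updates θ_d and, through the GRL, θ_f.

Optimization is plain SGD (no momentum, no decay) at a constant learning
rate, 0.001 for 80 epochs at full scale. An epoch is
ceil(n_source / (batch/2)) steps; the smaller target stream recycles with
reshuffling. Losses are averaged within a batch (the objective's sums scaled
by the batch size), which keeps the learning-rate scale independent of batch
size.

Weights are Glorot-uniform initialized with a dedicated RNG per layer keyed
by (seed, layer name), so variants sharing an extractor start from
bit-identical shared weights under the same seed; the LSTM forget-gate bias
starts at 1. Batch shuffling, the target recycle stream, and per-step,
per-phase dropout masks likewise draw from independent seeded streams. A
consequence used by the test suite: the adversarial model with λ = 0 and the
source-only model follow exactly the same extractor/predictor trajectory.

The networks, automatic differentiation (including the fused
backpropagation-through-time of the LSTM) and SGD are implemented directly
on NumPy within the package; every analytic gradient is verified against
central finite differences in float64, and the GRL's end-to-end effect is
asserted to equal −λ times the identity-path gradient exactly.

## Corpus construction

Pair tables are read as TSV (BED-convention 0-based half-open coordinates);
distances are measured center-to-center, with the center of an odd-length
element the floor of its midpoint. The corpus pipeline:

1. duplicate pairs (exact coordinates of both elements) are dropped;
2. pairs must satisfy 10 kb < distance < 2 Mb, both bounds strict;
   cross-chromosome pairs are removed;
3. positive distances are discretized into 5 quantile bins (edges from the
   positives only; boundary ties fall to the lower bin);
4. negative candidates — all annotated enhancer × promoter pairs passing the
   distance filter and not labeled positive — are assigned to the same bins
   and subsampled uniformly without replacement to exactly the positive count
   per bin, yielding a class-balanced, distance-matched corpus.

Cross-cell-line positive overlap is counted by exact coordinate identity of
both elements.

## Evaluation

Six statistics: accuracy, precision, recall and F1 from the confusion table
at threshold 0.5 (score ≥ threshold counts positive; zero-denominator ratios
report 0 with an explicit flag), AUC by the rank (Mann–Whitney) formulation
with midranks for ties, and AUPR by step-wise non-interpolated integration
(threshold sweep over distinct scores, tied scores entering together).
Inference always runs with dropout disabled.

The *feature domain probe* quantifies residual domain information in the
learned representation: a logistic regression is fit on the extractor's
feature vectors to separate held-out source from target samples (each domain
contributes its first half for training, second half for testing, making the
probe symmetric in domain order); accuracy near 0.5 indicates
domain-invariant features.

## Motif analysis

For interpretation, each first-layer convolution kernel is treated as a motif
scanner: for every input sequence the kernel-length window with the maximal
linear (pre-ReLU) activation is extracted (ties to the leftmost position;
sequences whose maximum activation is ≤ 0, or whose best window contains an
N, are skipped), and the aligned windows form a position frequency matrix
whose column sums equal the number of admitted windows. PFMs are exported in
MEME minimal motif format (background uniform unless supplied) for external
matching against motif databases.

To compare a transfer model against a no-transfer model, motif occurrence
counts are aggregated across repeated trainings (default 5) as
kernels-per-motif-identity, and each motif is scored

    relative importance = (1 − N_wo / N_w) / Rank_w,

where N_w, N_wo are its occurrence counts in the with- and without-transfer
model and Rank_w its descending rank by N_w (ties share the minimum rank).
Scores near 1 mark motifs the transfer model relies on that the plain model
does not. How to count "occurrences" is genuinely underdetermined;
kernels-per-motif was chosen because it is stable under re-extraction and
independent of corpus size. Enhancer- and promoter-branch kernels are
analyzed separately and tagged.

## Synthetic benchmark

The generator produces datasets with the statistical structure the method
assumes, at sizes where every mechanism is testable on one CPU:

* each sample is an (enhancer, promoter) sequence pair; positives carry a
  planted 10-nt consensus in *both* elements, negatives in at most one
  (exactly one with probability 0.5, chosen at random), so the label is
  motif *co-occurrence* — a single-branch detector cannot solve the task;
* planted motifs appear in 3 copies per carrying sequence (regulatory
  elements typically contain several occurrences of a functional site; the
  repetition also makes the task learnable within a short SGD budget);
* backgrounds are i.i.d. with a domain-specific GC content;
* optional per-domain decoy motifs are inserted in both classes of a domain,
  and an optional per-position mutation rate degrades planted copies.

The standard *shifted benchmark* (`shifted_benchmark_config`) combines a
compositional shift — source GC 0.40 vs target GC 0.60 — with a
sequence-patterned shift: the target domain (only) carries a decoy one
substitution away from each true motif, planted in both classes at the same
copy number. The decoy carries no label information, but a source-trained
detector that cannot distinguish decoy from motif mis-ranks target pairs;
producing domain-indistinguishable features requires exactly the sharpened
detectors the adversary rewards. This is the mechanism by which the
adversarial model outperforms source-only training on the target domain at
desk scale. The *null benchmark* uses identical generators for both domains
(GC 0.5, no decoys) and is used to check that the adversary does not
systematically hurt when there is nothing to align. A k-mer-frequency
logistic-regression probe (`domain_shift_probe`) certifies that a configured
shift is detectable before transfer conclusions are drawn.

A second generator writes an on-disk toy genome fixture (FASTA + BED + pair
TSV + JSON manifest, ~2.3 Mb over two chromosomes) whose planted pair
distances straddle both filter bounds (10 kb and 2 Mb exactly, plus interior
and cross-chromosome cases), include a duplicated pair and elements hanging
off chromosome ends, and whose manifest records the expected
surviving-pair count from the planted coordinates — an independent
bookkeeping oracle for the filter.

What the synthetic data does **not** emulate: positional dependence of real
sequence (CpG islands, repeats), degenerate PWM-sampled binding sites (the
default plants exact consensus copies), distance-dependent interaction
probability, chromatin context, or label noise from contact-calling. Passing
the desk-scale tests therefore demonstrates that the machinery — adversarial
optimization, invariance pressure, motif recovery — behaves as designed, not
that the full-scale biological performance figures are reproduced.

## Desk-scale configuration

Full-scale training (300 kernels × 40 nt, two blocks, LSTM 100, 80 epochs on
hundreds of thousands of pairs) is a GPU-days workload. The desk-scale
configuration used by the repeated-seed experiments keeps every mechanism but
shrinks the problem: 2000 pairs per domain, 500/300-nt windows, 32 kernels of
length 12, one conv+pool block per branch (two blocks of pool 20 would
collapse a 500-nt input to zero frames), pool 20/20, LSTM 25, heads 32/16,
10 epochs, batch 64, λ = 1. The learning rate is raised to 0.2 — plain SGD at
the full-scale 0.001 leaves a small network essentially at initialization
within the ~600 steps this budget allows. One adversarial training run takes
roughly 30–40 s on one CPU core; repeated-seed experiments (5 seeds × 3
model variants) complete in minutes.

## Numerical and design choices

* Coordinates 0-based half-open throughout (BED convention).
* Window positions outside the chromosome pad with `N` (all-zero rows)
  rather than rejecting the element; zero rows carry no signal.
* `N` encodes as all-zeros, not 0.25-uniform: the conservative
  no-information choice, and it keeps the row-sum invariant testable.
* Strand is ignored; windows are reported on the forward strand.
* Convolutions are valid with stride 1 (motif-scanner semantics); pooling
  supports stride = pool length only.
* Max-pool argmax ties resolve to the leftmost position; PFM consensus ties
  resolve in A<C<G<T order.
* The quantile-bin edges come from positives only; negatives are binned with
  those same edges. Boundary ties fall to the lower bin.
* Whether phase 2 re-draws its batch is unspecified in the procedure's
  wording; the same mini-batch serves both phases here.
* Enhancer and promoter branches do not share convolution weights.
* The 50/50 target split is purely random (no stratification), since target
  labels are assumed unavailable.
* Checkpoints store all parameters plus the model configuration in a single
  `.npz`; training history is exported as CSV/JSON.

## Known limitations

* The NumPy implementation is CPU-bound and single-threaded apart from BLAS;
  full-scale corpora are out of reach — the package is designed for method
  study, desk-scale benchmarking and small real corpora.
* λ is constant; no adaptation schedule is implemented, and at desk scale
  the adversarial gradient measurably slows label learning when there is no
  shift to remove (the null-benchmark gap is slightly negative but within
  the parity band).
* The motif-importance statistic depends on an external motif-identity
  assignment (e.g. Tomtom against a reference database) for real data; the
  package's internal matching uses exact PFM-consensus identity, which is
  stricter.
* Binary interaction labels only; no probabilistic contact strengths.
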