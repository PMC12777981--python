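# Methods

## The problem

Solid-state nanopores read single molecules as transient dips in ionic
current ("translocation events"). Identifying which analyte produced an event
— which DNA barcode carrier, whether a target protein is bound, which peptide
variant translocated — is a classification problem on short, noisy, 1-D
traces, and labeled nanopore data are scarce. The package implements a
two-stage learning scheme: generative self-supervised pretraining of an
attention autoencoder on unlabeled events, followed by supervised fine-tuning
of the pretrained encoder plus a small classifier.

## Model

**Tokenization.** Each event is brought to a fixed length `F` (linear
interpolation to 500 points for peptide-sequencing-style data; centered
padding into a 700-vector for barcode-carrier-style data) and cut into
`L = ceil(F/w)` non-overlapping subsequences of length `w` (default 12). With
`F = 500, w = 12` this gives `L = 42`, matching the physical picture of one
subsequence per residue of a 42-mer read at constant velocity. The final
subsequence is tail-padded with its own last value (`tail_pad` recorded), so
segmentation is exactly invertible. At `F = 700` the same rule gives
`L = 59`; producing `L = 42` at that length would require `w = 17` — the
library always derives `L` from `(F, w)` rather than fixing it.

**Masked autoencoding.** During pretraining a uniformly random subset of
subsequences is hidden at mask ratio `r` (default 0.6; the mask count is
`round(r·L)` clamped to `[1, L-1]`, so 25 masked / 17 visible at `L = 42`). A
shared affine map projects each `w`-point subsequence to a `d`-dimensional
token (`d = 64` by default) and adds a learned positional embedding (one
table, shared by encoder and decoder). The encoder — `n_layers` (default 8)
post-norm residual blocks of multi-head self-attention (`h = 4` heads,
per-head key/value width `d_k = d_v = 64`) plus a GELU feed-forward sublayer
(width `4d`, dropout `p1 = 0.2`) — processes the visible and the masked
tokens as two separate sequences. The decoder (same depth and widths) sees
all `L` positions: encoder outputs at visible positions, a single learned
mask token plus positional embedding at masked positions. The training signal
is the mean squared error between the decoder's masked-position outputs and
the encoder's masked-branch outputs, averaged over all masked positions and
embedding dimensions. The target branch is gradient-isolated: no gradient
flows into the encoder through the targets, which removes the trivial
solution where both branches agree on a constant by construction.

**Classification.** For fine-tuning the encoder runs over the full sequence,
positions are averaged into one event embedding `z` (global average pooling),
and a two-layer head (`d -> d_c -> M`, GELU, dropout `p2 = 0.2`, default
`d_c = 256`) produces logits; softmax and cross-entropy complete the
pipeline. Pretraining uses Adam (lr 1e-3, batch 128, 300 epochs by default);
fine-tuning uses AdamW (lr 1e-3, weight decay 1e-4, 300 epochs) with cosine
annealing to exactly 1% of the initial learning rate at the final epoch.
`finetune(init=None)` is the supervised-only baseline ("ZeroTrain"):
identical recipe, randomly initialized encoder. A convolutional ablation
replaces each attention sublayer with a kernel-3 residual 1-D convolution of
the same width (feed-forward sublayer kept), behind identical operation
signatures.

Unstated wiring was resolved as follows: post-norm residual blocks with GELU;
masked tokens are encoded as their own sequence (self-attention among masked
positions, original positional embeddings kept) to make the target
well-defined; one positional table shared by both coders; Adam/AdamW betas at
(0.9, 0.999); no early stopping (the final-epoch checkpoint is returned).
Fine-tuning updates the encoder end-to-end by default; a `freeze_encoder`
flag is provided.

## Numerical core

No GPU framework is used: the model runs on a compact reverse-mode autodiff
engine over float64 numpy arrays (`nanossl._autograd`) with hand-written
attention, layer-norm and optimizer steps. Gradients of every composite used
by the model are verified against central finite differences in the test
suite. Forward passes in evaluation mode are bitwise reproducible; training
is exactly reproducible given `TrainConfig.seed` (weight init, dropout,
shuffling and per-epoch mask plans all derive from it). Checkpoints are
`.npz` weight archives with a JSON sidecar carrying the model, classifier and
preprocessing configuration (`F`, `w`) plus class names, so incompatible
fine-tuning or prediction fails loudly.

## Standardization

Three amplitude modes are exposed: `none`, per-event `zscore`, and
dataset-level `zscore_global` (one scalar mean/sd for the whole set — the
analog of calibrating all events against a common open-pore current). The
experiment runners and examples use `zscore_global`: per-event z-scoring
erases the between-event mean-blockade shift that a volume-changing mutation
physically produces, while raw uncentered traces slow optimization badly.
The two calibration scalars are computed on the full dataset before
cross-validation splitting; they are label-free and shared by all classes, so
the induced leakage is negligible, but exact purists can standardize per
training split by hand.

## Synthetic benchmark

The simulator produces the two event families the method targets, with the
statistical structure the learning task needs (localized, class-discriminative
amplitude patterns inside noisy, variable-duration events):

* **Barcode carriers** (`barcode8`, `binding2`): flat carrier blockade with
  rectangular downward spikes at equally spaced sites in the first half of
  the event encoding bits (8 classes at 3 bits), an optional binding spike in
  the latter half (bound/unbound), random event length, i.i.d. Gaussian
  current noise.
* **Peptides** (`peptide`): a 42-residue chain read residue-by-residue;
  residue `i` occupies a gamma-distributed dwell (mean 12 points, shape 200 —
  coefficient of variation ≈ 7%, consistent with the near-constant-velocity
  translocation the tokenization assumes) at depth
  `-depth_per_volume x volume(residue)` (3.0 blockade units per nm³, residue
  volumes from a vendored published table), plus Gaussian noise (default sd
  0.1, "moderate": a nearest-template oracle still resolves classes while
  per-point SNR is low), then linear resampling to 500 points. Volumes can be
  perturbed per position (`volume_deltas`) without changing the sequence —
  the post-translational-modification mechanism; the crystallographic local
  volume deltas of the named variants (E22G 0.0887, G37R 0.1357,
  phosphoserine 0.0565 nm³) ship as constants. An optional random-walk drift
  term (off by default) stresses baseline robustness.

The default 42-mer is the canonical human amyloid-beta 1-42 sequence used as
a surrogate fixture; the named positions (E22, S26, G37) line up with the
variants studied. The `abeta3-default` recipe (3 classes x 200 events, seed
fixed) scores mutants with the volume table (E->G 0.0783 nm³, G->R
0.1133 nm³ — same sign and ordering as the crystallographic deltas).

An independent nearest-template oracle (time-domain L2 against noiseless
class templates; barcode templates rebuilt at each event's observed length)
provides the ceiling: its accuracy is exactly 1.0 at zero noise and decreases
monotonically with `noise_sd`, which is the benchmark's difficulty knob.

**What the simulator does not model:** pore-to-pore gain and baseline
variation, open-pore drift, event-detection artifacts, dwell-time
heavy tails, capture-rate physics, and 1/f noise. Passing tests on this
benchmark therefore demonstrate that the pipeline is implemented correctly
and can learn localized amplitude motifs at realistic SNR — not that the
method's real-data advantages (notably the self-supervised gain under label
scarcity, which the original study attributes to rich unlabeled-data
structure) reproduce on simulated data; see Limitations.

## Desk-scale protocol

The documented examples and the acceptance script use
`ExperimentConfig.scaled_down()`: `d = 32`, 2 layers, 2 heads
(`d_k = d_v = 16`), classifier width 64, 30 pretraining + 30 fine-tuning
epochs, batch 16, fine-tuning lr 3e-3, pretraining lr 1e-3, gradient-norm
clipping at 1.0. The deviations from the reference recipe are deliberate: at
a few hundred events, batch 128 yields too few optimizer steps inside the
fixed epoch budget to converge, so the fine-tuning learning rate is raised
and the batch reduced; pretraining keeps the reference 1e-3 because the
latent-target pretext is stable there (at 3e-3 its representations partially
collapse in rank). Two-fold cross-validation is used instead of the reference
five-fold to keep runs short while leaving 300 events per training split.

## Limitations

* The latent-target pretext with a shared, gradient-isolated encoder can
  still drift toward low-rank representations over long pretraining; at desk
  scale its pooled features are no better than a random encoder's, and on
  the synthetic benchmark the pretrained variant does not beat the
  supervised-only baseline at the smallest label budgets (it is equal within
  noise at full data). Stabilized target schemes (teacher averaging, target
  normalization) were evaluated and did not change this at this scale, so the
  simpler specified design is kept.
* Global average pooling dilutes single-token evidence by `1/L`; tasks whose
  class signal lives in one subsequence lean heavily on fine-tuning to
  re-weight attention.
* The 700-length padded dialect treats padding as ordinary signal during
  masking and loss, matching a plain implementation; an option to exclude
  all-pad subsequences from the masked-loss average is not currently
  provided.
* Everything is single-threaded numpy: fine for hundreds of events and the
  small models documented here, not for the reference-scale model on tens of
  thousands of events.
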