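# Methods

## Problem and model

One 30 s polysomnography epoch is a pair of 3000-sample vectors (EEG
Fpz-Cz and EOG horizontal at 100 Hz) carrying one AASM stage label
(W=0, N1=1, N2=2, N3=3, REM=4). The classifier maps the pair to stage
probabilities through four stages:

**Multi-scale convolution.** Each modality has its own two-branch CNN.
Branch kernels: large 50/stride 20, small 20/stride 5, 64 filters each,
ReLU, max-pool 4; a second convolution (kernel 8, stride 1, 64
filters), ReLU, max-pool 4. From a 3000-sample input the branch
lengths are 148 → 37 → 30 → 7 (large) and 597 → 149 → 142 → 35
(small). Both branches are adaptively max-pooled to the shorter length
(T = 7) and concatenated channel-wise into a (B, 128, 7) sequence.
Design notes:

- The architecture's max-pool is specified as a (4,4) window on
  features that are effectively one-dimensional (height 1); it is
  implemented as a temporal pool of size 4.
- The second convolution layer's shape is a documented default
  (kernel 8 / stride 1 / 64 filters), fully configurable; only the
  first layer's kernels are fixed by the design.
- Alignment happens *after* both convolution stages so the coupling
  module receives a genuine temporal sequence per modality.
- EEG and EOG do not share CNN weights.

**SE channel attention**, applied per modality with separate weights:
squeeze is the temporal mean per channel; excitation is
`s = sigmoid(W₂ relu(W₁ z))` with a bottleneck of C/r, r = 16
(C = 128 must be divisible by r; enforced at construction);
recalibration multiplies each channel by its gate. Gates are strictly
inside (0, 1), so no channel is ever fully silenced or passed
unchanged.

**State-space coupling.** Inputs are the M = 2 modality sequences
(B, T, D = 128). Each modality n holds a hidden state h_n ∈ (−1,1)^H
(H = 64 by default). Per step: the input is layer-normalised (per
modality, learnable affine), then

    h_n(t) = tanh( Σ_m h_m(t−1)·S_n + x̃_n(t)·Bᵀ )
    α_nm(t) = softmax_m( h_n(t)·h_m(t) / √H )
    h_n(t) ← tanh( Σ_m α_nm(t)·h_m(t−1)·S_n + x̃_n(t)·Bᵀ )

with a shared input projection B ∈ R^{H×D} and per-modality
correlation matrices S_n ∈ R^{H×H}. After the last step, Y_n =
h_n(T)·E and Y = (1/M) Σ_n W_n·Y_n with scalar fusion weights W_n.
Open choices resolved here, each switchable in `SSMConfig`:

- The attention score function is the scaled dot product (bounded
  logits, the standard choice).
- Inside the attention-refined update the history term is the
  *cross-modal* h_m(t−1) (each modality attends over the others'
  states). A literal variant that re-uses h_n(t−1) for every term is
  available as `literal_attention_state=True`; both variants are
  verified against a scalar-loop reference.
- An explicit state-transition matrix A (adding h_n(t−1)·Aᵀ inside the
  tanh) exists behind `use_state_matrix` and defaults to off, matching
  the printed update equations in which the correlation matrices carry
  the state dependence.
- The output dimension of E equals D.
- The coupling consumes the T-step CNN feature sequence rather than a
  single pooled vector, preserving within-epoch temporal structure.

**Head.** Fully connected 128 → 64, ReLU, dropout 0.5 (training only),
64 → 5, softmax. Dropout is the package's regularisation default and
can be disabled.

Two ablation variants exist as first-class models: `cnn_se` (coupling
removed; time-pooled CNN+SE features concatenated into the head) and
`ssm_only` (CNN removed; each raw modality epoch reshaped to 30
patches × 100 samples and fed to the coupling module directly — the
patching is a reconstruction, since an SSM-only variant needs *some*
sequence format for a 3000-sample signal).

## Differentiation and training

No deep-learning framework is used: `sleepssm.autograd` is a minimal
tape-based reverse-mode engine over NumPy arrays (broadcast
arithmetic, matmul, activations, strided 1-D convolution,
max-pooling, layer-norm, log-softmax). Its gradients are validated
against central finite differences at 1e-6 relative error on every
primitive and at 1e-4 end-to-end through all three model variants.
Max-pool backward routes gradient by an equality mask, so exact ties
share gradient — a measure-zero event for continuous activations.

Training: Adam (lr 0.001, β = 0.9/0.999, ε = 1e-8), weighted
cross-entropy with inverse-frequency class weights
w_c = N/(K·N_c) normalised to mean 1 over the K classes present
(absent classes get weight 0 with a warning), batch 128, 100 epochs,
5 subject-wise folds — these defaults are the full reference
protocol. No validation split or early stopping is used by default:
training runs the fixed epoch budget. The evaluation protocol never
pools subjects across the train/test boundary; the disjointness of
subject sets is asserted inside `cross_validate`.

A single global seed drives a `SeedSequence` that derives independent
streams for fold splitting, parameter initialisation, shuffling, and
dropout. Everything downstream is plain NumPy, so identical
config + seed reproduces splits, loss histories and metric reports
bitwise.

## Preprocessing of real polysomnography

EDF signal headers are parsed directly to verify channel presence and
the 100 Hz rate (a mismatch is a named error — never a silent
resample); data and EDF+ hypnograms are then read through MNE.
R&K labels map to AASM: 1→N1, 2→N2, 3→N3, 4→N3 (merged), R→REM,
W→W; MOVEMENT and UNKNOWN are excluded. Wake trimming keeps at most
60 epochs (30 min) before the first and after the last sleep epoch;
it runs on the mapped label sequence *before* exclusion-dropping, so
excluded epochs inside the kept range are still removed afterwards.
The 30 s epoch grid is anchored to annotation onsets; partial trailing
windows are dropped. Each epoch is z-scored per channel by default
(configurable): raw µV scale varies across subjects and equipment and
would otherwise dominate; stage information survives in spectral
shape. Whether the half-hour margin is wall-clock or epoch-counted is
ambiguous in the scoring convention; 60 epochs is used.

The package also writes EDF/EDF+ (16-bit quantisation, one annotation
record), which closes the loop for round-trip testing: a synthetic
recording exported and re-read agrees within one quantisation step and
reproduces its label sequence exactly.

## Synthetic data: what it does and does not show

The generator's defaults are the reference study conditions: 10
subjects × 200 epochs, stage proportions (W 19.6%, N1 6.6%, N2 42.1%,
N3 13.5%, REM 18.2%) matching the 20-subject Sleep-EDF cassette
cohort, subject jitter 0.1 (multiplicative perturbation of recipe
amplitudes/frequencies per subject), geometric stage runs with mean
length 10 epochs. Per-stage recipes follow textbook signatures: W =
alpha (8–12 Hz) + blinks; N1 = theta + slow EOG rolls; N2 = theta +
12–14 Hz spindle bursts + K-complexes; N3 = high-amplitude 0.5–2 Hz
delta; REM = low-amplitude mixed EEG + large saccadic EOG
deflections. Band amplitudes were chosen so that per-epoch z-scoring
does not erase class information, and a 1-nearest-neighbour classifier
on canonical band powers separates held-out subjects at ≥95% — the
generator guarantees the task is learnable, with cross-subject
generalisation non-trivial (jitter) but achievable.

What it does not emulate: 1/f background spectra, artifacts, arousals,
scorer disagreement, stage-transition asymmetries, or night-level
non-stationarity. Passing the synthetic end-to-end checks therefore
demonstrates that the architecture, optimisation and evaluation
machinery are correct and that the model can exploit spectrally coded
stage structure across subjects — not that it reaches any particular
accuracy on real polysomnography.

## Evaluation scales and numerical conventions

All metrics are percentages in [0, 100]; kappa is scaled to
[−100, 100]. Overall sensitivity/specificity/precision are unweighted
macro-averages over the five one-vs-rest decompositions (micro
variants behind a flag); macro-F1 averages per-class F1 with
zero-denominator classes contributing 0. Ratios with zero denominators
report 0 with a warning. Fold aggregation defaults to pooling all test
epochs' confusion matrices; per-fold means are reported alongside.

Problem sizes used by the automated end-to-end checks are the
package's scaled study: the 10 × 200 synthetic dataset with a 20-epoch
batch-64 training budget for cross-validation, and three training
seeds × one held-out fold for the ablation comparison. The ablation
uses single hold-out folds rather than three full cross-validations;
the leakage guarantees are identical and the comparison is paired
(same data, same split, same seed per variant).

## Known limitations

- CPU-only, single-threaded by design; a full 100-epoch, 5-fold run on
  real Sleep-EDF-scale data is feasible but slow (hours, not minutes).
- The EDF writer covers the subset of EDF+ needed here (one annotation
  record, uniform record duration); it is not a general-purpose
  exporter.
- No artifact rejection beyond the MOVEMENT/UNKNOWN exclusions; no
  support for the sleep-telemetry (ST*) recordings or Pz-Oz-based
  channel variants beyond passing a different `channel_names`.
- Class weights are recomputed per training fold; with very small
  synthetic runs a class can be absent from a fold's training labels,
  in which case it is unlearnable in that fold (weight 0, warned).
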