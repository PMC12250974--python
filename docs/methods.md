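# Methods

## Problem

An operator's mental workload is classified into three levels (low /
moderate / high) from one-second windows of simultaneously recorded
multichannel EEG and surface EMG. The two modalities are complementary —
EEG carries low-frequency cortical rhythms in microvolts, EMG carries
higher-frequency muscle activity in millivolts — but their feature
distributions differ systematically, and naive feature concatenation lets a
classifier latch onto modality idiosyncrasies instead of workload structure.
The network here (TRM-MAAN: temporal relation modeling with multimodal
adversarial alignment) addresses both problems: Transformer self-attention
models within-window temporal structure, and an adversarially trained
modality classifier drives the shared fusion trunk toward modality-invariant
features.

## Preprocessing

Continuous recordings are bandpass filtered (EEG 0.1–30 Hz, EMG 75–500 Hz),
cut into non-overlapping 1-s windows, and paired. EEG is recorded at twice
the EMG rate; each EEG window is split into its two interleaved half-rate
streams (samples 1, 3, 5, … and 2, 4, 6, … in 1-based counting), and each
stream is paired with the simultaneous EMG window, doubling the sample
count. Implementation choices:

- **Filter realization.** 4th-order Butterworth, zero-phase
  (forward–backward). The band is realized as a lowpass at the upper edge
  followed by a highpass at the lower edge: a single bandpass section set
  with a 0.1 Hz lower edge is numerically fragile under forward–backward
  filtering (the near-unity pole turns edge effects into seconds-long
  transients). The lowpass runs first so the highpass is excited only by
  band-limited content, and both stages use Gustafsson's initial-condition
  method. Measured attenuation matches the analytic squared magnitude
  response of the cascade to within 2%.
- **Nyquist collision.** The EMG band's upper edge (500 Hz) equals Nyquist
  at the 1 kHz EMG rate and is unrealizable; it is clipped to 0.45 × rate
  (450 Hz) with a warning.
- **Order of operations.** Filtering precedes windowing so edge transients
  hit only recording ends, and window alignment across modalities is
  preserved by the zero-phase filters.
- **Indexing.** The interleaved "odd" stream is 0-based indices 0, 2, 4, …

Workload labels (questionnaire-derived, three levels) are taken as given,
one per labeled segment; windows outside labeled segments are dropped.

## Augmentation

Training folds (never test folds) are augmented to 3× size: the originals,
a time-reversed copy of each sample, and a copy with added i.i.d. Gaussian
noise. The noise SD defaults to 0.05 × the per-modality training-set SD —
relative rather than absolute because EEG and EMG amplitudes differ by
orders of magnitude. Flipping defaults to deterministic copy-and-flip along
time; a `flip_prob` option flips stochastically instead. Both modalities of
a copy receive the same kind of transform; labels and window identity are
preserved, and augmented samples carry a provenance flag that the
cross-validation code uses to reject augmented input.

## Architecture

Per modality branch (separate weights per branch):

1. **Temporal conv projection** — Conv1D over the channel axis, kernel
   `k_eeg`/`k_emg` (default 3), same padding, projecting `C` channels to a
   common feature dimension `D` at every time step; an optional stride
   shortens the sequence for budget-limited studies (default 1).
2. **Sinusoidal positional encoding** added elementwise:
   `PE[pos, 2k] = sin(pos / 10000^(2k/D))`, `PE[pos, 2k+1] = cos(...)`,
   0-based `pos` and `k`. The written definition indexes from 1 and leaves
   the first two columns undefined; the standard 0-based convention covers
   all `D` columns and is what "traditional sine and cosine functions"
   denotes in practice.
3. **Self-attention blocks** (`n_layers`, default 2) — per head,
   `softmax(QK^T / sqrt(D_K)) V` with per-head `D_Q = D_K = D_V = D /
   n_heads`; heads are concatenated (no output projection). The block
   output is `LayerNorm(A + FFN(A))` with `A` the attention output — a
   single residual wrapped around the feed-forward sublayer, following the
   method's written definition literally. A `standard_transformer_block`
   switch restores the conventional two-residual post-norm block; the
   default stays with the literal form. The encoder-only reading is used
   throughout: the task offers no target sequence for a decoder, so the
   "Encoder and Decoder" phrasing is interpreted as the encoder stack.

Shared across branches:

4. **Fusion trunk F** — the `L × D` sequence is treated as a one-channel
   2-D map: conv (3×3) to `trunk_channels`, batch norm, ReLU; 2×2 stride-2
   max pool; then three ConvNeXt-style blocks (depthwise 7×7 conv, layer
   norm over channels, GELU); flattened to a fixed-length vector. Both
   modalities pass through the trunk as one joint batch, so batch-norm
   statistics couple the modalities; per-modality trunk calls would let
   train-mode batch norm remove each modality's mean separately — silently
   aligning features during training while eval-mode running statistics
   reintroduce the shift. A `pool_1d` alternative pools time only.
5. **Workload classifier C** — two FC layers with softmax over the three
   classes, on the concatenation `[F(Z_eeg); F(Z_emg)]` (order fixed).
6. **Modality classifier M** — two FC layers with softmax over the two
   modality IDs, fed one branch's fused feature at a time through a
   gradient-reversal layer; used only during training.

Sizes not fixed by the method description (defaults: `D = 40`, kernels 3,
4 heads, 2 layers, 64 trunk channels, 128 FC hidden) were chosen as the
smallest values satisfying the divisibility constraints that train on a CPU
in minutes; all are configurable.

## Training

The total objective is `L = L_cls + L_adv`: mean cross-entropy of the
workload classifier plus an adversarial term, optimized with Adam at the
prescribed learning rate 1e-3, gradients clipped **elementwise** to
|g| ≤ 10 (the prescription speaks of absolute values of gradients, not of a
norm). Epochs and batch size default to 100 and 32 with early stopping on a
training-loss plateau (patience 15).

Two adversarial modes are implemented:

- **`grl`** — the literal single-loss min-max:
  `L_adv = CE(M(GRL(f)), y_modal)`, averaged over the two per-sample
  modality passes, with the gradient-reversal layer multiplying upstream
  gradients by −λ (default λ = 1, no schedule). Forward is the identity.
- **`non_saturating`** (default) — measured on the synthetic studies below,
  the plain reversed objective stalls: once the modality classifier is
  confident, `∂CE/∂logits = p − y → 0`, so the reversed gradient vanishes
  and the fused features remain fully linearly separable regardless of λ
  (Adam's per-parameter normalization also makes λ nearly inert). This is
  the classic saturating-adversarial-loss failure. The default mode
  therefore (a) refits M to near-optimality at the start of each epoch on
  cached inference-mode fused features (M is a small MLP, so this is cheap),
  and (b) trains the feature path against the *frozen* critic with a
  uniform-target confusion loss — cross-entropy of `M(f)` against the
  uniform distribution, which drives features onto the decision boundary
  and merges the modality clusters. (A flipped-label variant was tried
  first and pushes each cluster *across* the boundary instead of onto it —
  the clusters swap rather than merge, and a refit critic separates them
  again.) Both formulations share the desired fixed point — modality
  indistinguishability — and λ scales the confusion term. With λ = 0 the
  trunk receives no adversarial gradient in either mode.

Checkpoint selection differs by mode. Non-adversarial variants restore the
best-training-loss epoch as usual. For adversarially trained models the
total loss is smallest early in training when the critic is still weak, so
best-total-loss restoring would return a nearly unaligned model; and the
adversarial equilibrium oscillates appreciably from epoch to epoch, so the
final epoch is an arbitrary sample from that oscillation.
`fit` therefore checkpoints at the epoch of *minimum critic-refit
accuracy* — each epoch begins by refitting M on the previous epoch's
features, and that refit accuracy is a training-internal measure of how
separable the features still are; the state where even a freshly refit
critic fails most is the best-aligned state. The first third of the run is
burn-in. Early stopping monitors the classification loss in the
adversarial case.

## Evaluation

Decision rule: argmax of the workload probabilities, ties to the lowest
index. Accuracy is trace/total of the 3×3 confusion matrix; F1 is the
unweighted (macro) mean of per-class one-vs-rest F1, with an absent class
contributing 0 (warned). Evaluation is subject-dependent: per subject, a
stratified five-fold cross-validation at 8:2 train:test, where the two
interleaved-phase samples of one EEG window always share a fold (splitting
them would leak near-duplicate signals), folds are stratified by class, and
augmentation is applied after splitting to training folds only. Reports
carry per-fold accuracy/F1/confusion plus mean ± SD over the five folds.

Ablation variants are config switches on the same code path: `trm` (no
adversary, plain concatenation fusion), `maan` (no Transformer — conv
features straight into the trunk), `uni_eeg`/`uni_emg` (one branch, no
adversary).

## Synthetic data

No real EEG/EMG workload recording is bundled (such data is rarely openly
deposited), so the package ships a generator that emulates the *structure*
the pipeline depends on, not the physiology: per class, windows contain band-limited oscillations (defaults
4–8, 8–13, 13–30 Hz, loosely evoking theta/alpha/beta) in all channels plus
white noise at a configurable SNR (default 10 dB); the EEG-like stream is
generated at twice the post-pairing rate so the interleaved-downsampling
path is exercised; the EMG-like stream carries the same class-band
structure pushed through a modality shift — additive offset (2.0),
multiplicative scale (1.5), and a nuisance oscillation band (45–55 Hz) —
which changes no labels. Band-limited class signals have unit RMS per
channel; noise SD is `10^(−SNR/20)`.

A learning-free band-energy classifier verifies the task is solvable before
any training (>90% at SNR ≥ 20 dB). The modality shift is quantified by a
linear probe (`shift_probe`): held-out accuracy of an L2-regularized
logistic regression separating EEG-derived from EMG-derived features —
near 1.0 under the raw shift, near 0.5 when aligned. On *model* features
the probe is applied to the fused vectors of both branches
(`model_shift_probe`).

The generator's signals are already band-limited, so the synthetic dataset
builder skips the per-modality bandpass by default — the 75–450 Hz EMG
filter would remove the low-frequency class signal the generator plants in
both modalities. The bandpass remains the default for real recordings.

What passing on this generator shows: the pipeline can learn
band-discriminated classes, and the adversarial mechanism can remove a
linear-plus-spectral modality shift. What it does not show: robustness to
artifacts, electrode drift, inter-subject variability, or any physiological
validity of the class signatures.

## Study problem sizes

The default study configuration used by the acceptance script and the
heavier tests is scaled to a single CPU: 8 channels at a 125 Hz
post-pairing rate (1-s windows of 125 samples; EEG-like stream at 250 Hz),
20 windows per class per subject, and a small model (D = 8, 2 heads,
1 layer, 4 trunk channels, FC hidden 16, projection stride 2). The shift
magnitudes, SNR, class bands, seed counts and all pass thresholds are kept
as stated above; only the problem size is reduced. At these sizes one
adversarial training run takes on the order of 1–2 minutes; the engine also
offers a float32 mode (`trm_maan.autodiff.default_dtype`) that roughly
halves runtime and is used by the study code (`trm_maan.studies`). The
stride-2 projection halves the attention sequence; its implicit decimation
can alias part of the 45–55 Hz nuisance band into the class bands, which
makes the alignment task somewhat harder but keeps the fused feature
dimension — and with it both runtime and the linear probe's attack
surface — at half size; the trade was measured and the strided
configuration aligned better overall.

## Numerical choices and degenerate inputs

- Probabilities inside the scalar cross-entropy are floored at 1e-12.
- Stable log-softmax (max-shifted) is used for all training losses.
- Softmax rows are checked row-stochastic to 1e-6 in tests.
- Argmax ties break to the lowest index everywhere.
- Recordings containing NaN/Inf are rejected on construction; NaN losses
  abort training with batch diagnostics.
- Empty recordings, odd-length interleave inputs, out-of-range labels,
  mismatched window lengths and sub-Nyquist-violating bands raise
  `ValueError` with specific messages.
- The engine computes in float64 by default; all oracle comparisons
  (positional encoding 1e-9, attention 1e-6, full forward 1e-5) run in
  float64.

## Known limitations

- The adversarial game is solved in its non-saturating form by default;
  the literal single-loss gradient-reversal mode is provided and testable
  but stalls on blatantly shifted data (documented above).
- Alignment quality varies with initialization seed; the studies report
  across-seed behavior rather than single runs.
- The synthetic generator makes no claim of physiological realism; class
  bands are a testing device.
- Subject-pooled (cross-subject) evaluation is available but outside the
  subject-dependent protocol the method prescribes.
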