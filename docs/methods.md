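# Methods

`chirpff` classifies sub-soil insect stridulations — the two scarab larvae
*Melolontha hippocastani* (MH, label 0) and *M. melolontha* (MM, label 1) —
from long, mostly silent soil recordings. The pipeline is: signal
conditioning → short-time-energy (STE) activity segmentation → MFCC features
with an in-input label code → a forward-forward (FF) network with an RMS
goodness function → goodness-accumulation inference. This note records the
model, its assumptions, and every numerically consequential choice.

## Signal conditioning

Input is mono WAV at 44.1 kHz (other rates are polyphase-resampled on
read). Conditioning is DC removal, a 4th-order Butterworth band-pass over
200–5000 Hz — the band carrying scarab stridulation energy — applied
forward–backward so it is zero-phase and does not smear pulse onsets, then
peak normalisation to −1.0 dBFS (max |x| = 10^(−1/20) ≈ 0.8913). All-zero
input is passed through unchanged with a warning, since peak normalisation
is undefined for silence. The filter family and order are a package choice;
any reasonable band-pass shifts STE values slightly but not the selected
windows, because selection is scale-free (below).

## STE segmentation

Activity detection uses the mean square of the waveform over rectangular
10-s windows with 0 % overlap (half-open, 0-based, trailing partial window
discarded; a 5-min file yields 30 candidates). Each recording's window
energies are normalised by that recording's maximum, and windows with
normalised STE ≥ 0.2 are retained as 10-s segments. Normalising per
recording makes the dimensionless 0.2 threshold meaningful regardless of
recorder gain; consequently the selected set is invariant to any positive
gain on the recording. Ties at the threshold are selected. The segmentation
ratio S_g = (retained duration)/(total duration) feeds the complexity index
below. The coarse 10-s rectangular windows are deliberately distinct from
the 25-ms Hamming frames used for features: one detects activity, the other
analyses it.

## Features and label encoding

Each segment is framed at 25 ms (1102 samples) with 50 % overlap and a
symmetric Hamming taper, giving 799 frames for a 10-s segment. MFCCs use a
2048-point FFT (zero-padded frames), 26 triangular mel filters spanning
200–5000 Hz on the HTK mel scale (matching the conditioning band so no
filter sits in the stop-band), log filterbank energies floored at 1e-10,
and an orthonormal DCT-II keeping coefficients 0–12 (c0 included). The
799×13 matrix is flattened frame-major into a 10 387-vector.

The FF network receives the class claim inside the input: entries 0–9 are
overwritten with a block one-hot code — class 0 is `1111100000`, class 1 is
`0000011111`. A *positive* sample carries the true class's code, a
*negative* sample the complement (equivalently the wrong class's code); the
audio features are identical in both, so the network can only separate them
by learning feature–code interactions.

Feature scaling is per-position min–max to [0, 1], fitted on the training
partition only (held-out values are clipped), followed by a single
*block gain* on the feature positions that equates the feature block's mean
squared norm to the code block's (‖code‖² = 5; the gain is ≈ 0.037 for
10 377 feature positions and is capped at 1). Without this gain the two
encodings of a segment differ by √10 out of an input norm of ≈ 60 — under
0.2 % in squared norm — and the layers after the first receive no usable
positive/negative signal at the configured schedule. The relative scale of
the code slots against the features is a genuinely free design axis of
label-in-input encodings, and energy balancing is the neutral choice on it.
Slots remain exactly {0, 1} and scaled features remain in [0, 1].

## The forward-forward network

Three fully connected ReLU layers of 500, 1000 and 1000 units. Each layer h
is trained greedily and locally: for activity vector O the layer's
*goodness* is

    g = sqrt((1/n) Σ_j O_j²)        (RMS, the default)

with `sum_sq` (Hinton's Σ O²), `mean_sq` and `mean_abs` available. The
squashed score p = σ(g − θ) with threshold θ = 3.5 is the layer's local
probability that the input is positive. The per-layer loss on a batch is

    L = (L⁺ + L⁻)²,
    L⁺ = mean_i softplus(−(g_i⁺ − θ)),   L⁻ = mean_i softplus(+(g_i⁻ − θ)),

i.e. positives are pushed above θ and negatives below it, with an outer
square that sharpens the penalty when both terms are large. Per-sample
terms are averaged, not summed, so the loss scale is batch-size invariant;
the summed form combined with the outer square makes the gradient grow
quadratically with batch size and diverges at the default step size
(verified — all ReLUs die within a few steps).

After a layer is trained, only the orientation of its activity vector
(division by the L2 norm, ε = 1e-8 guard) is passed to the next layer, so
magnitude — the very thing goodness measures — cannot leak downstream and
each layer must learn new structure. Layer 1 consumes the encoded input
as-is.

### Optimisation

Plain SGD per ΔW = −η ∂L/∂W at η = 0.1 for 500 epochs, seed 1234, biases
included. Two choices here were forced by measurement rather than taste:

* **Minibatches (size 4) by default.** Full-batch descent on the
  batch-mean squared loss moves the deeper layers' loss by ~3×10⁻⁴ over the
  whole 500-epoch schedule and preferentially shrinks the goodness variance
  instead of separating the classes; seeded size-4 minibatches take N/4
  steps per epoch with 4× larger per-sample coefficients and separate every
  layer. Full batch remains available (`batch_size=None`) and is what the
  monotone-descent property test uses.
* **Goodness-calibrated initialisation.** Weights start uniform
  ±1/√n_in from the seeded generator, then are rescaled by one scalar so
  the mean goodness of the training inputs equals θ (exact, by positive
  homogeneity of ReLU with zero bias; for quadratic goodness kinds the
  scalar enters as its square root). Without this, layers 2–3 start at
  g ≈ 0.2 and the RMS gradient's 1/n factor means they cannot reach θ = 3.5
  within the schedule. Toggleable via `calibrate_init`.

Training is bit-reproducible for a given seed. When the input dimension
exceeds the number of training samples (always true for layer 1: 10 387 vs
a few hundred), descent provably stays in the affine span of the inputs, so
the update loop runs in an orthonormal basis of that span and maps back at
the end — an exact algebraic shortcut (validated against direct descent to
1e-8), cutting layer-1 training cost by ~30×. Training arithmetic is
float32 by default (`precision="float64"` for gradient checks).

The sum-of-squares goodness has gradients larger than RMS by roughly
2·n·g; at η = 0.1 it diverges, which is consistent with RMS being the more
numerically stable choice. The ablation therefore runs `sum_sq` at η = 1e-3,
where it trains cleanly.

### Inference

The true label being unknown, the sample is encoded with each candidate
label's positive code and forwarded through the network; the pre-squash
goodness of all layers except the first is accumulated per candidate, and
the larger accumulated goodness wins. Layer 1 is excluded because it can
read the code directly; ties break toward label 0. The margin
accum(1) − accum(0) is the ranking score used for AUC.

## Noise tooling

`mix_at_snr` loops/truncates a noise signal to the clean length and scales
it by (RMS_clean/RMS_noise)·10^(−SNR/20); the realised RMS-ratio SNR is
exact to well under 0.01 dB. `spectral_subtract` estimates a noise
magnitude spectrum (mean over frames of an explicit reference, or of the
leading 250 ms assumed signal-free), subtracts α·|N̂| from each 25-ms/50 %
frame magnitude with a spectral floor β·|N̂| (α = 1, β = 0.01 defaults;
the floor limits musical noise), keeps the noisy phase, and overlap-adds.
The periodic Hamming at 50 % hop satisfies COLA, so an unmodified spectrum
reconstructs to < 1e-6 RMS.

## Evaluation

MH (label 0) is the positive class: T₊ = MH→MH, T₋ = MM→MM, F₊ = MM→MH,
F₋ = MH→MM; accuracy, precision, recall and F1 follow the usual ratios,
with zero-denominator cases reported as 0 with a warning. AUC is the
rank-based Mann–Whitney statistic with half credit for ties, computed on
the inference margin. Cross-validation is stratified k = 5: per-class
shuffled round-robin assignment, deterministic per seed, per-class fold
counts within one. The feature scaler is refitted on each fold's training
partition.

The complexity index CCP = (T_P · S_g / T_D) · 100, where T_P is processing
time, T_D the total dataset duration, and S_g the segmentation ratio;
CCP < 1 means faster than real time. T_P here covers feature extraction
plus inference over the evaluated segments (training excluded) — the
quantity is hardware-dependent and the timing scope is a documented
convention of this package.

## Synthetic data

The generator emulates the *structure* of the real recordings — long files,
sparse activity, broadband background — not Melolontha acoustics. Two
synthetic species differ in carrier and pulse rate (class 0: 900 Hz,
12 pulses/s; class 1: 2200 Hz, 30 pulses/s; both well inside the analysis
band), each pulse an exponentially decaying sinusoid (5-ms decay) with
per-pulse amplitude jitter (uniform 0.8–1.0 of peak). Activity occupies
whole 10-s windows — a seeded choice of ceil(duty · n_windows) windows,
duty 0.5 by default — so segmentation ground truth is unambiguous;
Gaussian background noise at 0.05 of pulse peak runs throughout.
Background noise for robustness studies is "forest" noise: equal-power pink
(1/f wind/rumble) plus white (foliage hiss).

What passing tests show, and what they do not: the synthetic classes are
strongly separable by spectro-temporal structure, so perfect synthetic
accuracy demonstrates that the pipeline's mechanics (segmentation recall,
encoding, layer-wise separation, inference rule) are correct — not that
real Melolontha species are this separable. Likewise, at 0 dB the synthetic
task does not measurably degrade, so the spectral-subtraction comparison
there is a non-inferiority check (enhancement must not hurt), not a
demonstration of the rescue effect seen on hard real noise.

## Problem sizes

The test suite and acceptance script use desk-scale sizes chosen as this
package's own evaluation design: 20 one-minute recordings for segmentation
ground truth, 100 segments/class for 5-fold CV (each fold trains three
layers for 500 epochs on 160 segments), 40 segments/class for the 0 dB
noise comparison, and 10/class toys for dynamics checks.

## Known limitations

* Two-class only; multi-class would need a wider code block and is untested.
* The STE threshold interpretation is per-recording relative; an absolute
  calibrated threshold would behave differently across gain settings.
* Spectral subtraction assumes stationary noise and a usable noise
  reference (leading signal-free stretch or explicit profile).
* CCP depends on wall-clock timing and hardware; only its formula and
  scale behaviour are contract-tested.
* The accumulated inference goodness uses the raw g (not p); with a shared
  θ across layers this is a monotone relabelling per layer but the choice
  matters if layers ever get different θ.
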