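# Methods

## The model

`vtsnn` implements image denoising with a *fully spiking* network over a
*virtual* temporal axis. A static 8-bit grayscale image x ∈ [0, 255]^{H×W}
is turned into a sequence of T = 8 binary planes by bit-plane
decomposition (UWE, undistorted weighted-encoding): plane t carries bit
(T−1−t) of each pixel, most-significant plane first, mirroring the
conversion order of a successive-approximation ADC. The planes are fed
one per time step into a spiking U-net; the network's T binary output
planes are decoded back to an image by the weighted sum

    ŷ = Σ_t 2^(T−1−t) · ô_t     (UWD, undistorted weighted-decoding),

expressed internally as the mode-0 tensor product of the output stack
with the row A = [2^(T−1), …, 2^0]. The codec is exactly lossless: for
every integer image, decode(encode(x)) = x. Two comparison codecs are
included — time-to-first-spike (TTFS), a latency code that is lossy once
latencies are quantised to T bins, and membrane-potential decoding
(MPD), a real-valued readout tanh(Σ_t θ^(T−1−s_t)·ô_t) with θ = 0.8,
where s_t is the plane's significance, so the most significant plane is
weighted θ^0 = 1.

### Neurons

Units are discrete-time integrate-and-fire neurons with soft reset:

    IF :  u ← u + x            LIF:  u ← u + (x − u)/τ,  τ = 1.1
    o  =  h(u − V_th),  h(0) = 1
    u  ←  u − V_th · o

V_th = 1.0 in the body, 0.077 in the final 1×1 readout convolution.
Soft reset (subtract V_th, keep residual charge) is the reading of
"no reset potential" used throughout; firing at exactly u = V_th counts
as a spike, a tie-break relied on by the identity initialisation below.
Training backpropagates through the firing rule with the surrogate
derivative 1/(1 + (π·(u − V_th))²), which peaks at 1 on the firing
boundary. A literal multiplicative leak (u·τ for IF), which amplifies
the potential for τ > 1 and is not usable as a neuron model, is kept
behind `NeuronConfig.literal_gate` for study only.

### Network

The U-net is fully spiking and bias-free: every nonlinearity is a
spiking neuron, every convolution has zero bias, so zero input yields
zero output (quiescence) and every inter-layer signal is strictly
binary. Downsampling is a stride-2 convolution + neuron; upsampling is
nearest-neighbour (binarity-preserving) followed by convolution +
neuron; skip connections concatenate spike planes — spike maps are
never added outside a neuron's synaptic current. Per encoder level the
channel width doubles. The default architecture (depth 2, base 16
channels) carries ≈0.115 M weights, calibrated near the 0.12 M
parameter budget of the reference configuration; the "tiny" variant
used in the scaled-down experiments is depth 1, base 8 (≈5.8 k
weights). Spatial sizes must be divisible by 2^depth.

### Training regimes

Both regimes use Adam (lr 0.001, β = 0.9/0.999) on mini-batches, and
differ in where the loss lives and how far gradients travel:

* **ITBP** (independent-temporal backpropagation): the clean label is
  *encoded* with UWE and the loss is the significance-weighted squared
  plane error L = (1/N)·Σ_t 2^t‖o_t − ô_t‖_F², t the significance of
  the plane. The membrane state carried between time steps is severed
  from the gradient graph (values unchanged), so credit is assigned
  within each step's spatial path only. The defining identity — joint
  gradients with detached carry equal the sum of per-step gradients
  computed from stored entry states — is asserted in the tests to 1e-6
  relative error.
* **STBP** (spatio-temporal backpropagation): the output planes are
  *decoded* by the differentiable UWD weighted sum and the loss is the
  plain squared error (1/N)‖y − ŷ‖_F² against the clean image, with
  gradients flowing through both the spatial path and the carried
  membrane state (including the soft-reset term).

At test time both regimes share one deployment path: encode → forward →
decode → PSNR (peak 255; identical images are reported as capped +∞).

### Initialisation

Weights are fan-in-scaled Gaussians, plus — by default — an exact
identity path: stem channel c takes a single centre tap of weight
1.1·V_th on input channel c, the last skip-fusion layer copies that
channel from the stem skip, and the 1×1 head reads it with weight
1.1·V_th of its own threshold. Because h(0) = 1 and the soft-reset
residual accumulates only 0.1·V_th per spike (< V_th over T = 8 steps),
the untrained network reproduces its input stack bit-for-bit, and the
10% tap margin keeps the copy intact under early optimiser updates.
This matters at short training budgets: from random init the network
must first *discover* the copy behaviour before it can denoise, which
surrogate-gradient descent does only slowly (observed: no net gain over
the noisy input within the scaled-down budget); from the identity the
starting PSNR equals the noisy input's and every improvement is genuine
noise suppression. Identity init requires base_channels ≥ in_channels;
`init="he"` disables it.

## Synthetic data and noise

The generator emulates small digit-style benchmarks: 28×28 8-bit images
with 2–4 bright strokes (line segments, arcs, filled rectangles) on a
black background, Gaussian-smoothed (σ = 0.7) and peak-normalised to
255; the bright-pixel fraction sits in roughly 0.05–0.40. Noise is
additive i.i.d. Gaussian per pixel with standard deviation η on the
[0, 1] scale — η is read as a standard deviation, not a variance, since
η up to 0.8 as a variance would leave essentially no signal — then
clipped to [0, 1] and re-quantised to 8 bits (the encoder requires
integers). What the generator does *not* emulate: the stroke topology
of real handwriting, dataset-level class structure, and correlated or
signal-dependent noise; a passing scaled-down study therefore shows the
training machinery works end to end at these statistics, not that
full-benchmark PSNR values are reproduced.

## Scaled-down denoising study

The study trained and evaluated by the tests and by
`scripts/acceptance.py`: 500 training and 100 test images at η = 0.2,
the tiny network, IF neurons, T = 8, 5 epochs, Adam lr 0.001,
mini-batches of 10. The batch size is scaled with the dataset: the
full-scale protocol (batch 50 against 60 k images) performs ~1200
optimiser steps per epoch, and batch 50 against 500 images would
perform 10, which is not a training run in any useful sense; batch 10
restores a sane step count (50/epoch) at identical sample throughput.
Under these conditions the bit-plane-loss regime (ITBP) clears the
noisy input by about +5 dB mean test PSNR and stays at or above the
decoded-MSE regime (STBP); the ordering margin is small (a few tenths
of a dB) and seed-dependent, consistent with its "non-binding trend"
status. Problem sizes were chosen so the whole study runs in minutes on
one CPU core.

## Energy model

Event-driven accounting in the 45 nm CMOS convention: a conventional
activation operation costs 4.6 pJ, a spike 0.9 pJ, and a silent spiking
slot costs nothing; convolution MACs are excluded on both sides.
#OP_SNN counts neuron-step *slots* (units × time steps) so that

    E_SNN = #OP_SNN · spike_rate · 0.9 pJ,

the only reading that reproduces the reference table's 3.09×10⁻⁷ J from
2.51 M slots at rate 0.1366; E_ANN = #OP_ANN · 4.6 pJ. Energies are
reported in 10⁻⁷ J rounded to two decimals, and the ANN/SNN ratio is
formed from the rounded energies (giving 273.77 where the unrounded
inputs give ≈274.1), matching how such tables are printed. A ratio over
a zero-rounding SNN energy is reported as NaN. Measured spike rates of
freshly trained models are properties of those models and will differ
from any published instrumentation.

## Numerical choices and degenerate inputs

* All arithmetic is float64; forward spike values are exactly 0.0/1.0
  and codecs validate strict binarity rather than thresholding.
* Out-of-range pixels raise; they are never clipped silently.
* TTFS: latency t = ((max−x)/max)·T is floored by default (configurable
  to nearest); t ≥ T emits no spike; an all-zero image emits no spikes
  and warns. The all-zero case is the one input with no well-defined
  maximum.
* The autodiff core rebuilds im2col patch matrices during the backward
  pass instead of retaining them, keeping memory proportional to the
  activations; convolutions are channels-last so patch extraction is a
  set of contiguous slice copies.
* Checkpoints are `.npz` archives of per-layer weights with the
  architecture spec embedded as JSON; loading validates shapes.

## Known limitations

* ITBP's plane loss is an upper bound on decoded error that ignores
  sign cancellation across planes; at very short budgets its value
  correlates only loosely with PSNR. The identity start largely
  sidesteps this.
* A time-invariant spiking network cannot weight input planes by
  significance explicitly — temporal context enters only through the
  carried membrane state — so very deep significance interactions are
  out of reach of the tiny configuration.
* Multi-channel images are encoded per channel (C·T planes, C channels
  per step, losslessness preserved per channel); this path is exercised
  by construction but the study conditions are grayscale.
* Training at the 0.12 M-parameter default is supported but slow on one
  CPU core; the scaled-down study uses the tiny variant by design.
* The training loop always pairs the lossless codec with the loss (UWE
  on the label path, the UWD weighted sum inside the STBP loss). TTFS
  and MPD are full library citizens for encoding/decoding studies but
  are not wired into `train_step`: they exist here to characterise
  codec distortion, and training through a lossy code would need its
  own protocol and evaluation design.
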