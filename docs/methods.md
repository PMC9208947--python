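# Methods

## Model

The classifier maps a fixed-length window of IMU samples to an activity
class in three stages.

**Spatial extraction.** The window is a single-channel image with height =
time (K samples) and width = sensor axes (D).  Four parallel convolution
branches process it: (1) 1×1 → 1×1; (2) 1×1 → 1×3 → 3×1; (3) 1×1 → 1×5 →
5×1; (4) 3×3 max pool → 1×1.  The asymmetric 1×k kernels mix *across sensor
axes* (e.g. between accelerometer and gyroscope columns) while the k×1
kernels mix *across adjacent time steps*; the 1×1 convolutions act as
per-pixel channel mixers and keep the parameter count low.  All convolutions
use "same" zero padding and stride 1, and the pool uses stride 1 with the
same padding — this is forced by the design: the four branch outputs must
share spatial dimensions to be concatenated, and the recurrent head needs
all K time rows intact.  ReLU follows every convolution; 1×1 kernels with
ReLU are the conventional choice for this block style.  No batch
normalization is used.

**Channel attention.** For a W × H × C feature map, global average pooling
produces one scalar per channel; a single shared k-tap 1-D convolution
(bias-free, zero padding (k−1)/2) mixes each channel with its k neighbours,
and a logistic sigmoid maps the result to a weight ω_i ∈ (0, 1).  The kernel
size adapts to the channel count, k = nearest odd integer of
log₂(C)/γ + b/γ with γ = 2, b = 1 (so C = 384 → k = 5, C = 48 → k = 3).
Channels are then ranked by |ω_i| descending and the top
N = nearest even integer of k + log₂(C)/2 weighted channels are extracted
(C = 384 → N = 10).  `n_override` fixes N explicitly; the full-scale
`ModelConfig.table_reference()` preset uses `n_override=9`.  With N = C the
module reduces to plain channel re-weighting (original ECA) up to channel
order, which the tests verify.

**Temporal head.** The filtered W × H × N map is read row by row, one LSTM
step per time row.  Each row is reduced to the step input by averaging over
the N channels (`lstm_input="channel_mean"`, default), so the LSTM input
size equals the sensor-axis count H; `"flatten"` keeps all H·N values
instead.  The channel-mean default keeps the recurrent parameter count
independent of N and ties the input dimension to the physical sensor layout.
A single unidirectional layer is used and the final hidden state — not a
pool over time — feeds the fully connected softmax classifier.

## Training

Mini-batch Adam on categorical cross-entropy; learning rate 0.001 (the
reference setting for this architecture family), default batch size 64
(16 in the reduced preset).  Parameter initialization: He-scaled normal for
convolutions, uniform ±1/√fan for LSTM and dense weights, zero biases except
the forget-gate bias at 1.0 (so early training does not erase the cell
state).  All randomness flows from one integer seed through
`numpy.random.default_rng`; two runs with the same seed produce bit-identical
weights.  A non-finite loss aborts training with a diagnostic rather than
continuing silently.

All layers, including backpropagation, are implemented directly in NumPy
(im2col convolutions, argmax-scatter pooling, BPTT for the LSTM).  The
backward passes are validated against central finite differences, and each
forward kernel against an independent brute-force loop implementation.  The
top-N selection indices are treated as constants in the backward pass
(straight-through); gradients flow through the channel weights and the
selected activations.

## Preprocessing

Missing readings (NaN) are filled by per-channel linear interpolation
between the nearest valid neighbours, using real timestamps as abscissae.
There is no extrapolation rule, so a gap touching a recording boundary is an
error.  Windows of K samples are cut at a configurable stride (default
stride = K, i.e. non-overlapping, since overlap is an experimental choice
rather than part of the base procedure); a window takes the majority label
of its samples and is discarded when no label reaches half the window or the
top count is tied.  The train/test split is a seeded uniform shuffle of
pooled windows at ratio 0.7 (split at `round(0.7·n)`); subject-wise
splitting is not the default because windows are pooled before splitting.
No normalization is applied by default — the network consumes raw sensor
units — but a per-channel z-scoring helper exists for experiments.

## Numerical conventions

- Nearest-odd rounding (attention kernel size) resolves exact half-ties
  *downward* (t = 3.5 → 3); nearest-even rounding (selection count) resolves
  them *upward* (t = 9 → 10).  Both rules live in one module
  (`harnet._rounding`) since the formulas themselves do not define the ties.
- Attention weights are clamped to the largest representable open interval
  (tiny, 1 − ulp) so the documented range 0 < ω < 1 survives float
  saturation of the sigmoid at |z| ≳ 37.
- |ω| ranking uses a stable sort; ties keep the lower channel index first.
- The channel reduction from C to N is implemented two ways behind
  `channel_reduce`: `"gather"` (default) extracts the top-N ranked channels
  and has only the k attention taps as parameters; `"conv1x1"` applies a
  learned 1×1 convolution over the weighted map (N·C + N parameters, 3465
  for 384 → 9) and is used by the full-scale reference preset.
- CSV recordings are written with 17-significant-digit floats and read with
  pandas' round-trip float parser, making write∘read bit-exact.

## Synthetic data

The generator emulates per-class quasi-periodic IMU signatures: each channel
is offset + amplitude·sin(2πft + φ) + Gaussian noise, with class-specific
frequency and offsets, a fixed per-channel phase spread plus seeded jitter,
and frequencies validated against Nyquist.  The default 3-class set uses
1/2/4 Hz with distinct offsets (noise s.d. 0.1, amplitude 1), which is
linearly separable after windowing in both the mean and spectral sense —
deliberately, so the end-to-end training check has a well-posed target.
Missing-value injection replaces an exact fraction of interior cells with
NaN, never at a channel's first or last sample, so interpolation is always
defined.

What this does *not* show: real IMU data has non-stationary waveforms,
inter-subject variability, gravity orientation changes and label noise, none
of which the sinusoid model reproduces.  Passing the end-to-end check
demonstrates that the architecture, gradients, training loop and metrics are
correct and that the model can learn separable temporal/spectral structure —
not that it attains any particular accuracy on real recordings.

## Problem sizes

The test suite and examples run a reduced-width configuration (branch widths
8/16/16/8 → 48 channels, LSTM hidden 32, K = 32, stride 16) on 40 s per
class at 25 Hz (~3000 samples, ~186 windows), chosen so a full train/test
cycle completes in seconds on one CPU core while exercising every code path
at realistic shape ratios.  The full-scale preset (384 channels, K = 100,
LSTM hidden 64, 12 classes) is assembled and its per-layer parameter census
checked, but not trained in the tests.

## Attention saliency

Attention weights live in feature-channel space; to display them over named
sensor axes, the saliency proxy is the absolute value of the weighted,
extracted feature map summed over retained channels, giving a time × axis
map normalized to peak 1, and a per-axis vector (mean over time).  This is a
defined proxy, not the only possible mapping (gradient-based attributions
are an alternative); lateral convolutions smear saliency onto neighbouring
axes, so single-window rankings can be off by one axis and averaging over
windows is recommended.  Saliency from an untrained model is permitted but
flagged in the result metadata.

## Known limitations

- Pure-NumPy training is practical for the reduced configuration and small
  datasets; the full-scale configuration trains orders of magnitude slower
  than a GPU framework would.
- The 7:3 pooled window split can leak temporally adjacent (overlapping-
  stride) windows across the split; subject- or segment-wise splitting
  should be used for generalization claims on real data.
- Macro-averaged metrics treat all classes equally regardless of support;
  weighted averages are reported alongside.
- The PAMAP2-dialect reader keeps only the wide-range accelerometer and the
  gyroscope of each IMU; magnetometer, temperature, orientation and
  heart-rate columns are out of scope.
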