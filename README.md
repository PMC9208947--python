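# harnet

Human activity recognition (HAR) from body-worn inertial measurement units
(IMUs), for researchers and engineers working with multi-sensor
accelerometer/gyroscope streams.  The package implements a hybrid deep
architecture — an Inception-style parallel-convolution spatial extractor, an
improved efficient-channel-attention (ECA) module with top-N channel
extraction, and an LSTM temporal head — entirely in NumPy, with training,
evaluation, attention visualization, recording I/O and a synthetic IMU
generator for download-free experiments.

## The model

A window of K consecutive samples over D sensor axes is treated as a
single-channel K × D image and passes through three stages:

**1. Inception spatial extractor.** Four parallel branches with "same" zero
padding: two stacked 1×1 convolutions; 1×1 → 1×3 (lateral, across sensor
axes) → 3×1 (longitudinal, across time); 1×1 → 1×5 → 5×1; and 3×3 max
pooling → 1×1.  Each convolution computes
`s(i,j) = ReLU(Σ_m Σ_n w_{m,n} x_{i+m,j+n} + b)`.  Branch outputs are
concatenated channel-wise; with the reference widths 64/128/128/64 the result
is a K × D × 384 feature map.

**2. Improved ECA channel attention.** Global average pooling gives one
scalar per channel; a shared k-tap 1-D convolution plus sigmoid gives
per-channel weights ω_i ∈ (0, 1), with the adaptive kernel size

    k = nearest_odd( log₂(C)/γ + b/γ ),   γ = 2, b = 1   (C = 384 → k = 5).

The improvement ranks channels by |ω_i| descending and extracts only the top

    N = nearest_even( k + log₂(C)/2 )

weighted channels, so the temporal head sees a compact W × H × N map.

**3. LSTM head.** The filtered map is read row by row (one time step per
row; each row's H × N values are reduced to length H by averaging over
channels), through the standard gate equations
f_t = σ(W_f·[h,x]+b_f), i_t = σ(W_i·[h,x]+b_i), c̃_t = tanh(W_c·[h,x]+b_c),
c_t = f_t⊙c_{t−1} + i_t⊙c̃_t, o_t = σ(W_o·[h,x]+b_o), h_t = o_t⊙tanh(c_t).
The final hidden state feeds a fully connected softmax classifier trained
with cross-entropy and Adam (lr 0.001).

Forward *and backward* passes of every layer are hand-written NumPy and are
validated against brute-force oracles and finite differences in the test
suite.

## Worked example

Train the reduced-width classifier on the built-in 3-class synthetic preset
(two IMUs, 12 channels at 25 Hz; classes are quasi-periodic signatures at
1/2/4 Hz with distinct offsets and Gaussian noise):

```python
from harnet import InceptionLSTMClassifier, eval_report
from harnet.datasets import make_split
from harnet.preprocessing import windows_to_arrays

split = make_split(stride=16, seed=0)          # windows of K=32, 7:3 split
Xtr, ytr = windows_to_arrays(split.train)
Xte, yte = windows_to_arrays(split.test)

clf = InceptionLSTMClassifier(epochs=20, seed=0).fit(Xtr, ytr, eval_set=(Xte, yte))
rep = eval_report(yte, clf.predict(Xte), n_classes=3)
print(rep.accuracy, rep.precision, rep.recall, rep.f1)
print(rep.confusion)
```

This prints (deterministically, for seed 0):

```
held-out accuracy: 0.9818
macro precision / recall / F1: 0.9833 0.9833 0.9829
confusion matrix (rows = true):
[[19  0  0]
 [ 1 19  0]
 [ 0  0 16]]
```

i.e. 54 of 55 held-out windows are classified correctly after 20 epochs; the
single error confuses the 1 Hz and 2 Hz classes.  For this 48-channel
concatenated map the adaptive attention kernel is k = 3 and N = 6 channels
are retained.

The same pipeline is available from the shell:

```bash
har synth --preset selfbuilt-like --out rec.csv --seed 0
har train --data rec.csv --out model.pkl
har eval  --model model.pkl --data rec.csv --report report.json
har viz   --model model.pkl --data rec.csv --window 0 --out saliency.csv
```

`har viz` exports the attention saliency of one window as a
time × sensor-axis table (or a PNG heat map), labeling axes by body site,
modality and axis so the dominant sensors for each motion are visible.

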