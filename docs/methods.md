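# Methods

## Problem and approach

Portable single-lead ECG monitors produce long 360 Hz, 11-bit records that
must be stored or transmitted over narrow links. `becg` implements a
near-lossless beat-wise compression codec: each heartbeat — a fixed
320-sample window around the R peak — is mapped by a convolutional
auto-encoder with a *binary* bottleneck to 20 bits, packaged with a 10-bit
inter-beat interval code into a 30-bit pack. The compression ratio is a
structural constant, CR = 320·11 / 30 = 117.33, independent of signal
content; reconstruction quality is what training buys.

## Preprocessing

1. **Band-pass 0.5–150 Hz.** Fourth-order Butterworth sections applied
   forward–backward (`sosfiltfilt`). Zero phase is not cosmetic: segmentation
   anchors on R-peak sample indices, and a causal filter's group delay would
   shift them.
2. **Max–min normalization to [0, 1], per record.** One pair of constants per
   record suffices for amplitude recovery, so the codec carries them once in
   the stream header rather than per beat (the 30-bit pack has no room for
   amplitude). Per-record rather than per-beat scope keeps all beats of a
   record on one amplitude scale.
3. **R detection (Pan–Tompkins, zero-phase variant).** 5–15 Hz band-pass,
   symmetric derivative, squaring, *centered* 150 ms moving-window
   integration, adaptive signal/noise thresholds with a 200 ms refractory
   period, then refinement of each fiducial to the dominant deflection (max
   absolute deviation from the local median) of the input. Centering all
   stages keeps the integrator peak time-aligned with the QRS, which is what
   makes sample-exact refinement against ground truth meaningful.
4. **Segmentation.** 127 samples left of R, 192 right, ends inclusive
   (127 + 192 + 1 = 320). Beats whose window would cross a record boundary
   are skipped (counted via logging). Indices are 0-based throughout.

## Interval code

The gap between consecutive 320-sample beat windows, `gap = RR − 320`, is
stored as a flag bit (0 = delay, 1 = overlap) and a 9-bit magnitude, so any
|gap| ≤ 511 samples (~1.4 s at 360 Hz) is encodable; larger gaps raise. The
first beat of a record, having no predecessor, carries (0, 0) and anchors
the stitched record's origin. At reconstruction, positive gaps are filled by
linear interpolation between the flanking samples; overlaps are replaced by
the element-wise mean of the two overlapping segments (symmetric by
construction).

## Auto-encoder

Channels-last 1-D stacks validated symbolically at build time against the
fixed reference trace (a mismatched spec fails naming the first offending
layer).

* Encoder: 9 tanh convolutions (filters×kernel 4×8, 8×32, 16×64, 32×96,
  64×64, 64×32, 32×16, 16×8, 1×8) with four non-overlapping 2:1 max poolings
  interleaved, then the binary encoding layer.
* Binary encoding layer: hard step (1 for x ≥ 0). Backward pass is a
  straight-through surrogate — downstream gradient masked by the indicator
  of the pre-activation lying in [−0.5, 0.5). The step is applied to the
  tanh output of the last encoder convolution; since tanh is monotone with
  sign at 0, this equals thresholding the pre-activation's sign.
* Decoder: mirrored transposed convolutions (kernels spatially reversed)
  with four zero-padding up-samplings (value in the first slot of each
  window, zeros elsewhere), closed by an affine 320→320 head with no
  activation so reconstructed amplitudes can leave the tanh range.
* Batch norm (momentum 0.9, ε = 1e−5; inference uses running statistics) on
  every convolution except the first of each stack; dropout (rate 0.25,
  configurable) only at the two designated decoder sites. Within a block
  the order is conv → batch norm → activation.
* "Same" padding: total `kernel − 1` zeros, left side getting the floor
  (transposed convolutions get the ceiling on the left so a symmetric kernel
  makes the two operators coincide).
* Initialization: Glorot-uniform scaled by kernel fan-in/out, seeded; the
  RECN's ReLU layers use He-normal initialization.

## Residual error compensation network

An MLP 20 → 80 → 140 → 200 → 260 → 320 → 320 (ReLU hidden layers, linear
head, biases only) mapping the binary code to the reconstruction residual
*magnified tenfold*. Residuals of a trained auto-encoder are small, so raw
labels make updates vanishingly slow; scaling the label by 10 and dividing
the prediction by 10 at compensation time (`refined = bcae + recn/10`)
conditions training without changing the fixed point. The RECN is trained
after the auto-encoder is frozen, on the train split's codes and residuals.

## Training

* Loss: Pseudo-Huber, mean over elements, δ = 0.9 — quadratic near zero,
  linear in the tails, robust to in-band noise that filtering cannot remove.
  Mean (not sum) reduction keeps δ's meaning independent of batch size.
* Optimizer: Adagrad, initial learning rate 0.1, initial accumulator 0.1,
  batch size 256, 400 epochs at full scale (all configurable via
  `TrainConfig`).
* Split: stratified by record — per record up to 1000 beats sampled, 50 to
  the test set, 80 % of the record's beats to training, the rest to
  validation (48 records × 1000 beats → 38,400 / 7,200 / 2,400).
* Validation loss is computed every epoch in inference mode; the
  best-validation parameters are restored at the end. Early stopping exists
  but is off by default. A NaN loss aborts with the epoch named. A run is a
  pure function of (data, seed).

## Synthetic data

The generator emulates what the codec assumes about its input, not clinical
reality: 360 Hz, 11-bit records of beats with P-QRS-T morphology (five
Gaussian bumps; R strictly dominant), RR intervals drawn from a truncated
normal confined to the interval-encodable range [320−511, 320+511] samples,
sinusoidal baseline wander (default 0.33 Hz, amplitude 0.08 of the unit R)
and white noise (default σ = 0.02). Quantization maps the record's min/max
affinely onto [0, 2047] with round-half-to-even. Ground-truth R positions
ride on the record for validating detection (±2 samples on clean records).

Three presets pair distinct morphologies (typical; tall broad T; wide QRS
with flattened T) with the three reference rhythms of the classic
variable-rhythm benchmark records — mean RR 286.05, 422.85 and 327.02
samples. What passing tests on this corpus does *not* show: robustness to
ectopy, conduction abnormalities, electrode artifacts, or morphology change
within a record; the generator has none of these.

## Demonstration scale

The numpy implementation runs everything on one CPU core. The demonstration
protocol (`becg.corpus.reduced_protocol`, also behind
`scripts/acceptance.py` and the shared test fixture) uses: 3 presets × 1
record × ~420 beats (~1,250 after segmentation), split 80/15/5 with 50 test
beats per record, auto-encoder trained 12 epochs at batch 64, RECN 40
epochs, and the RECN ablation repeated from 5 seeds against the single
frozen auto-encoder. These sizes are the package's own demonstration
choice: large enough that both losses fall decisively, the auto-encoder
beats a per-beat mean-value baseline on PRD, and RECN refinement lowers PRD
in ≥ 4/5 seeds — the qualitative properties of the full-scale study — while
the whole protocol completes in minutes. Absolute PRD at this scale remains
well above what hundreds of epochs on tens of thousands of real beats
achieve; the demonstration shows ordering properties, not headline figures.

## Numerical and degenerate-input choices

* Max pooling ties break to the first occurrence; its gradient routes to the
  argmax only.
* `snr` returns +inf for a perfect reconstruction (documented sentinel);
  `prd`/`prdn`/`snr` raise on all-zero or constant originals; `evaluate`
  NaN-guards QS at PRD = 0.
* Aggregate rows average per-record metric values — including QS, so the
  aggregate QS deliberately differs from CR divided by aggregate PRD.
* Interval encoding rejects |gap| > 511 rather than saturating; record
  compression surfaces the offending beat.
* The stream header is byte-aligned; packs are bit-contiguous with zero
  padding only at the very end of the stream.
* An all-zero record yields no detected R peaks (empty result, not an
  error); records shorter than 2 s are rejected by detection.

## Known limitations

* Single lead only; no entropy coding on top of the packs; no streaming
  (whole-record) operation.
* Amplitude recovery relies on the stream header's normalization constants;
  the 30-bit pack alone reconstructs shape, not absolute voltage.
* The detector is tuned for morphologies in the generator's range; extreme
  low-amplitude QRS or pathological rhythms are untested.
* Dropout sites and rate beyond the two designated decoder layers, and
  whether the RECN hidden layers should carry normalization, are design
  choices where the architecture description is silent; we use biases only
  in the RECN and rate 0.25 at the two sites.
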