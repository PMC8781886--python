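# Methods

## Problem and model

Remote photoplethysmography (rPPG) recovers the blood-volume pulse from
facial video: each heartbeat perfuses the skin and shifts its color by a
fraction of an intensity level, strongest in the green channel.  This
package implements a lightweight spatiotemporal network that maps a clip
of stitched skin crops to the pulse waveform, plus everything around it:
ROI geometry, training, spectral heart-rate (HR) readout, and a synthetic
scene generator so the whole pipeline is testable without recorded
datasets.

### ROI geometry

The pipeline consumes a standard 68-point facial landmark set per frame
(0-based indexing; an external detector such as OpenFace produces these —
landmark detection is out of scope).  Two skin boxes are built per frame,
image coordinates y-down:

* **cheek**: left/right edges at jaw points 3 and 13; top at the lowest
  of the lower-eyelid points {40, 41, 46, 47}; bottom at the higher of
  the upper-lip points {50, 52};
* **forehead**: spans brow points 19–24 horizontally and extends upward
  from the higher brow by half the cheek height.

The cheek crop is resized to the top two thirds of the stitched image and
the forehead to the bottom third (64×96 over 32×96 at the default 96×96).
Resizing is bilinear and fractional box edges round to nearest — neither
choice is externally prescribed, so both are recorded in the run config.
A forehead box that extends above row 0 is clipped to the frame with a
warning rather than rejected, preserving pipeline continuity; boxes with
non-positive area raise a degenerate-ROI error naming the frame.

### Temporal central-difference convolution (3DCDC-T)

For kernel taps split into the current time step R′ (temporal offset 0)
and adjacent time steps R″, the operator computes the plain windowed sum
plus a gradient-level term `-θ · x(p₀) · Σ_{R″} ω(p_n)`, θ ∈ [0, 1].
Because that correction is linear in the weights, the layer is evaluated
as a single convolution with an *effective kernel* (the raw kernel with
`-θ·Σ_{R″}ω` added at its center); a nested-loop evaluation of the
defining sum is kept as the correctness oracle and the two agree to
< 1e-5 on randomized instances.  θ defaults to 0.6 — the conventional
value in the central-difference-convolution literature; the architecture
this re-implements does not report its θ — and is configurable per run.
Bias, when present, is added once after the combined sum, which makes the
θ=0 case exactly a conventional convolution.

### 3D attention block

Channel attention: global average- and max-pooled descriptors pass
through one shared biasless two-layer perceptron (C → C/r → C, ReLU
inside); the two outputs are summed, squashed by a sigmoid and multiplied
into the feature map.  One published formulation of this block shows the
sigmoid distributing over the two branches; we follow the standard
formulation σ(MLP(avg)+MLP(max)), which matches the block diagram.
Spatial attention: channel-wise average and maximum maps are stacked (2
channels), convolved with a 7×7×7 kernel ("same" padding) and squashed;
the result reweights every voxel.  The reduction ratio defaults to r=16
and the perceptron and spatial kernels carry no biases (the conventional
choices; unreported in the source architecture).  Under these defaults
the assembled network counts 655,865 ≈ 0.66 M trainable parameters,
matching the published census.

### Architecture

stem 1×5×5 conv (3→16) → spatial 2×2 average pool → four blocks
(two 3DCDC-T convs, the first changing channels 16→32→64→64→64, then the
attention block), with a spatial pool between blocks → adaptive average
pool to 1×1 → linear 1×1×1 head (64→1).  ReLU follows every convolution
except the head, which stays linear so the trace can be zero-centered.
No pooling ever touches the temporal axis, so a T-frame clip yields a
T-sample trace.  Batch normalization is omitted entirely: the reference
design does not use it and the parameter census only matches without it.
Paddings (stem (0,2,2), blocks (1,1,1), attention (3,3,3)) are the unique
choices that preserve the published shape chain.  Inputs are scaled to
[0, 1] by dividing by 255; weights are He-normal.

### Training

Loss is `1 − r` (negative Pearson correlation) between predicted and
reference traces — scale- and offset-free, range [0, 2].  Zero-variance
traces contribute loss 1 with no gradient (logged), so a pathological
batch cannot produce NaNs.  Reference PPG (60 Hz) is z-scored, linearly
interpolated at the frame timestamps (30 fps), and sliced to each clip's
frame range.  Optimization: Adam, learning rate 2e-4, batch 8, 30 epochs
by default, left-right flip augmentation (doubles the corpus; labels
unchanged), everything seeded, best-by-validation-loss state retained
when a validation set is supplied.  Splits are by scene identity.

### Heart-rate readout

Traces are band-passed to 0.7–2.5 Hz (42–150 bpm) with a sixth-order
Butterworth filter built as a 3-section band-pass (a band-pass doubles
the prototype order) and applied forward–backward, so the output is
zero-phase and window timings stay aligned.  HR per 10 s window (2 s
step) is 60× the in-band argmax of the power spectrum of the
mean-removed, Hann-windowed, zero-padded segment (grid ≤ 0.01 Hz; the
same estimator is applied to predictions and references).  Welch
averaging with a single segment degenerates to this periodogram; at 10 s
windows there is nothing to average.  Agreement metrics are MAE, RMSE and
Pearson R over pooled windows, plus a Bland–Altman table with bias and
1.96·SD limits.

## Synthetic scenes

`rppgnet.synthetic` renders a stylized face — an elliptical skin region
with a full 68-landmark layout whose cheek/forehead boxes provably land
on skin — and modulates the skin additively with a quasi-periodic pulse
(fundamental + 0.3× second harmonic; instantaneous frequency follows a
configurable bpm trajectory).  Defaults emulate the recording conditions
the method targets: 30 fps video, 60 Hz reference PPG, pulse amplitude 2
intensity units (on 0–255) with a green-dominant color vector (green 2×
red/blue), per-pixel Gaussian noise (σ = 1), slow sinusoidal illumination
drift (amplitude 1, period 20 s), landmark jitter (σ = 0.5 px), and a
static skin texture (σ = 2) that dithers the uint8 quantization so the
spatial-mean pulse survives rounding.  All outputs are pure functions of
(config, seed).

What the generator does *not* emulate: head motion, specular highlights,
shadows, compression artifacts, non-Gaussian sensor noise, or
subject-to-subject appearance variation.  Passing tests therefore
demonstrate that the implementation is correct and that the architecture
can learn a sub-quantization-level color oscillation against noise and
drift — not that it reaches any particular accuracy on recorded
benchmark data.

Generator validity is checked independently of the network: on a scene at
default noise, the classical baseline (mean green over the true skin
mask → band-pass → windowed PSD) recovers the configured HR within 2 bpm
in every window.

## Scaled-down recovery experiment

Training the full 0.66 M-parameter model on recorded datasets is outside
desk scale, so the end-to-end check is a parameter-recovery experiment on
synthetic scenes, sized for a single CPU with the NumPy engine:

* 20 scenes (14 train / 3 validation / 3 test, split by identity), HR
  drawn uniformly from 60–110 bpm per scene; train/validation scenes
  6 s, test scenes 16 s so 10 s HR windows exist;
* reduced network: 36×36 stitched ROI (24-row cheek over 12-row
  forehead), 64-frame clips (stride 48), stem 8 channels, two blocks
  (16, 24) with attention reduction 8 (24 is not divisible by the default
  16), θ = 0.6 — ~39 k parameters;
* training: Adam, lr 1e-3 (a tiny network and few steps; the full-size
  default stays 2e-4), batch 8, 10 epochs, flip augmentation, seeded.

Success criteria: mean per-scene Pearson r between the stitched held-out
prediction and the frame-aligned reference > 0.8, and pooled windowed-HR
MAE < 3 bpm.  `scripts/acceptance.py` re-runs this experiment from
scratch along with the operator oracles and reports the measured numbers.

## Numerical notes

* The convolution engine is NumPy: small kernels run as one GEMM per
  kernel tap; kernels with ≥ 100 taps (the 7×7×7 attention kernel) go
  through an FFT circular correlation.  Both paths share one gradient
  implementation validated against central differences through the full
  layer stack (float64, rel. tol 1e-4).
* Training math is float32; oracles and tests run float64.
* Spectral ties: `argmax` takes the lowest-frequency bin on exact ties.
* Degenerate inputs: constant reference signals normalize to all-zeros
  with a warning; all-zero windows raise an undefined-HR error; traces
  shorter than the filter warm-up raise a signal-too-short error; clip
  sequences shorter than one clip yield an empty list with a warning.
* Overlapping clip predictions are combined by per-frame averaging of
  z-scored clip traces (output scale is arbitrary under the correlation
  loss); disjoint clip layouts are bridged by linear interpolation with a
  warning.

## Known limitations

* No face detection or landmark estimation; landmark files must follow
  the `frame,x_0..x_67,y_0..y_67` dialect.
* No head-motion compensation or skin segmentation; the ROI model
  assumes the landmark boxes contain skin.
* The NumPy engine is single-threaded BLAS-bound; full-size training at
  128×96×96 is possible but slow, and the package targets the reduced
  configurations for experimentation.
* Only the temporal central-difference variant is implemented (the
  architecture uses no spatial variant).
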