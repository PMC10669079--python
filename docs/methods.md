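# Methods

`emgeca` implements a complete surface-EMG (sEMG) gesture-recognition
pipeline for myoelectric prosthetic-hand control: a synthetic multi-channel
sEMG generator, envelope preprocessing, overlapped window segmentation, a
convolutional network with efficient channel attention (CNN-ECA), evaluation
surfaces, and an online decoder with rest gating and majority-vote
smoothing. This note records the models, the parameters that matter, and
the design decisions taken where the design was genuinely open.

## Synthetic sEMG generator (`emgeca.synth`)

Real gesture datasets of this kind are typically private, so the package
ships a generator that emulates the structure of an 8-electrode forearm
armband protocol: one labelled recording per gesture (default 8 gestures,
60 s each at 1000 Hz), during which the subject repeats the gesture 15–20
times.

The generative model per channel is

```
x_c(t) = n_c(t) + carrier_c(t) · A · g_c · [ τ + (1 − τ) · trap(t) ]
```

* `n_c` — unit-variance white Gaussian baseline (instrumentation noise).
  Amplitude units are arbitrary throughout; everything downstream that needs
  an absolute level (the rest threshold T) is calibrated against this
  baseline rather than expressed in volts.
* `carrier_c` — independent unit-RMS band-limited noise, Butterworth
  band-passed to 20–480 Hz (the informative sEMG band, kept just below the
  Nyquist frequency at fs = 1000 Hz).
* `trap(t)` — a train of trapezoidal activation envelopes: 100 ms linear
  ramps, plateau 0.8–1.6 s, bursts separated by ≥ 300 ms of rest, with the
  residual slack of the recording distributed randomly over lead-in, gaps
  and tail. The burst count k is uniform on `reps_range`.
* `g_c` — the per-gesture channel gain vector ("activation topography"),
  drawn uniformly on [0,1] per channel and rejection-sampled so that gesture
  rows are pairwise > 0.1 apart in Euclidean distance. This is what makes
  gestures distinguishable, mimicking distinct muscle-activation patterns.
* `A = 10^(snr_db/20)` — burst amplitude relative to the baseline noise.
* `τ` (`tonic_level`, default 0.15) — a small sustained component of the
  same channel topography, present between bursts. It emulates the residual
  co-contraction of a subject holding the arm posture between repetitions
  of a gesture. Without it, windows falling entirely between bursts would
  carry no class information at all — a property real recordings do not
  have, and one that would impose an artificial ceiling on window-level
  accuracy far below what is reported for real data.

What the generator does **not** emulate: motor-unit action potentials,
electrode shift, skin-impedance drift, fatigue, inter-subject anatomy.
Passing tests therefore demonstrate that the pipeline recovers the structure
this model encodes (amplitude topographies modulated in time), not that it
would reach the same numbers on physiological recordings.

Desk-scale profile (`desk_protocol`): 10 s per gesture with 4–5 repetitions
(the 60 s protocol's repetition rate, feasible burst packing) and SNR 20 dB
as the "clean acquisition" condition. These are the conditions under which
the package's own experiments and tests run; they were chosen once, from
the geometry above, and are not tuned.

## Envelope preprocessing (`emgeca.preprocess`)

The envelope is the magnitude of the analytic signal computed by the
FFT-based Hilbert transform, then smoothed with a Butterworth low-pass and
clamped at zero (tiny negative filter ripple only). Choices:

* **Magnitude, not imaginary part.** The analytic-signal magnitude is the
  mathematically correct instantaneous envelope; descriptions that identify
  the envelope with the imaginary part of the transform are treated as
  imprecise wording.
* **Hilbert first, smoothing second.** The rectified magnitude is the
  noisy estimate; the low-pass is its smoother. Cutoff 6 Hz, order 4 —
  a conventional sEMG linear-envelope smoother. Both are configurable.
* **Zero-phase offline, causal online.** Offline processing uses
  forward–backward filtering (zero lag, squared magnitude response). The
  streaming decoder must be causal, so it uses a single pass whose state is
  initialised to the step steady state of the first sample
  (`scipy.signal.sosfilt_zi`); this gives exact unit DC gain from the first
  sample and avoids start-up transients dominating 300 ms windows.
* **Edges.** The FFT assumes circularity; accuracy guarantees exclude 5% of
  samples at each end (`edge_policy`).

## Windowing and splits (`emgeca.windows`)

Windows are 300 ms with a 100 ms step (overlapped sliding windows), 0-based
half-open sample ranges; trailing samples are dropped. A 60 s recording at
1000 Hz yields floor((60000 − 300)/100) + 1 = 598 windows.

The train/validation/test split (80/10/10) is stratified per class with
largest-remainder rounding and a single documented seed; ties in the
rounding go to the earlier split. Splitting is done **at the window level**,
which is the faithful default for this kind of study but lets overlapping
windows straddle splits — test accuracy is therefore optimistic relative to
a split by recording or repetition block. Classes with fewer than 10
windows are rejected (a 10% slice would be empty).

## CNN-ECA classifier (`emgeca.model`, `emgeca.nn`)

Architecture: three stacked 2-D convolutions with kernels (3,3), (4,3),
(5,3) over the (time × electrode) plane — growing temporal receptive
fields — each followed by batch normalisation and ReLU; an ECA module after
the first convolution; flatten; one fully connected ReLU layer; a second
ECA module on the FC features; dropout; softmax over the gesture classes.
Training is Adam on categorical cross-entropy with per-epoch validation:
parameters are checkpointed whenever validation accuracy strictly improves
and the checkpoint (not the final state) is returned.

The ECA module computes a channel descriptor by spatial averaging, convolves
it across the channel axis with a 1-D kernel of adaptive size

```
K = | log2(C)/γ + b/γ |_odd      (γ = 2, b = 1, minimum 1)
```

(nearest odd integer; equidistant cases round up by default, widening the
receptive field), and gates each channel with the sigmoid of its logit.
The kernel is initialised to a uniform moving average (1/K), so initial
attention tracks activation magnitude; zero-padded ends mean the two edge
channels see a truncated neighbourhood.

Open design points, resolved as follows:

* **Which "channels" each ECA sees.** The first ECA attends over the
  *electrode axis* of the conv-1 feature map (the width axis, preserved by
  same padding; C = 8 electrodes → K = 3). This is the reading under which
  channel attention means cross-electrode interaction, and it makes the
  attention profile directly interpretable (and testable) against which
  electrodes carry signal. The second ECA treats the FC feature vector as
  C channels on a 1×1 map (C = 64 compact / 128 full → K = 3 / 5),
  gating the decision layer feature-wise.
* **Unstated capacity knobs.** Filters (32, 64, 128), stride 1, same
  padding, no pooling, one FC layer of 128, dropout 0.5, Glorot-uniform
  initialisation. All exposed on `ModelSpec` so the ablation varies only
  the studied factors.
* **Desk-scale capacity** (`compact_spec`): filters (8, 16, 32), temporal
  strides (3, 2, 2), FC 64. A pure-NumPy network (this package implements
  forward and backward passes itself; layers: conv via im2col/tensordot,
  BN, ReLU, dropout, dense, ECA, Adam) trains this on ~780 windows in under
  a minute per seed on one core. The desk training profile
  (`desk_train_config`) is Adam 1e-3, batch 64, 30 epochs — a conventional
  small-network setting for runs of ~300 updates; the library defaults
  remain the full-study values (1e-4, batch 128, 300 epochs).
* **Determinism.** All randomness (init, shuffling, dropout) derives from
  explicit seeds through `numpy.random.SeedSequence`; repeated runs are
  bit-identical.

Ablation variants (`variant_spec`): `conv1d` collapses electrodes into
input feature planes with 1-D kernels of the same temporal extents, no
attention; `conv2d` is the 2-D stack without attention; `conv2d_eca` adds
both ECA modules; `full` is `conv2d_eca` consuming envelope windows instead
of raw windows. All variants share kernel temporal sizes, filter counts,
strides, and the identical window split; each run starts from a fresh
initialisation.

## Evaluation (`emgeca.evaluation`)

Confusion matrices, per-class precision/recall/F1 with macro averages
(macro chosen because classes are balanced by construction; per-class
values are always reported), accuracy, test-split cross-entropy, and
one-vs-rest ROC/AUC per class plus macro AUC (threshold sweep; ties behave
as rank averaging, so AUC equals the Mann–Whitney concordance probability).
Zero-support classes score 0 with a warning; classes lacking positives or
negatives are skipped in ROC with a warning.

## Online decoder (`emgeca.stream`)

A ring buffer holds the latest 300 ms window; every 100 ms step the causal
envelope of the buffered window is computed and its mean compared with an
absolute threshold `T × (mean rest envelope level)`, where the rest level
comes from an explicit calibration step on ≥ 2 s of relaxed-muscle signal
(default T = 3). Below threshold the step emits rest and leaves the vote
buffer untouched. Above threshold the window is classified, the prediction
enters a bounded vote buffer (W most recent predictions, default 100), and
the modal class is the voted output. The window is strictly causal
(trailing), since a real-time system cannot see future predictions. Tie
rule: keep the previously voted class if it is among the tied classes, else
the most recently predicted tied class (`most_recent` alternative
available). Commands are emitted on change of the voted class
(edge-triggered, as a prosthesis is driven); `continuous=True` emits every
active step. A vote window of W removes any error run shorter than ⌈W/2⌉
embedded in a constant stream, and voted transition counts are
non-increasing in W on a fixed trace — both asserted in tests.

Command sinks are plug-in callables; bundled: a CSV logger and a serial
frame formatter (0xAA, class id, XOR checksum — the byte payload only, no
I/O; the physical link of a hand controller is out of scope).

## Pipeline and configuration (`emgeca.config`, `emgeca.pipeline`, CLI)

`run_pipeline` chains synth → preprocess → segment → train → evaluate →
stream replay, writing per-stage artifacts, the effective config, derived
per-stage seeds (SeedSequence of the one global seed) and a log into a run
directory; `resume=True` skips stages whose artifacts exist, so deleting an
intermediate artifact regenerates only downstream stages. The `emgeca` CLI
exposes each stage plus `ablate` and `run`; YAML/JSON configs are validated
strictly (unknown keys rejected with their path, defaults filled).

## Numerical notes and limitations

* Sessions round-trip bit-exactly through CSV (17 significant digits);
  window sets round-trip through HDF5.
* The ECA gate is strictly inside (0, 1); a zero kernel scales features by
  exactly one half (σ(0) = 1/2).
* Batch statistics use biased variance; BN running statistics (momentum
  0.9) are part of the checkpoint, so restored models reproduce recorded
  validation accuracy exactly.
* Problem sizes for the package's own experiments: 8 gestures × 10 s
  (≈ 784 windows), compact capacity, 30 epochs × 3 seeds for learnability;
  12 epochs × 3 seeds × 4 variants at 3 dB SNR for the ablation; 15 epochs
  × 3 seeds for the attention study. These sizes make the whole study
  reproducible in minutes on a single core.
* Window-level splitting (see above) and the synthetic generator's
  simplifications mean absolute accuracies here do not transfer to
  physiological data; the package's claims are structural (ordering of
  ablation variants, attention selectivity, smoothing behaviour), not
  absolute.
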