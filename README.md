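# emgeca

Surface-EMG gesture recognition for myoelectric prosthetic-hand control:
a convolutional network with **e**fficient **c**hannel **a**ttention
(CNN-ECA), Hilbert-transform envelope preprocessing, overlapped window
segmentation, and an online decoder with rest-threshold gating and
majority-vote smoothing.

The package is aimed at researchers prototyping sEMG classification and
real-time myocontrol pipelines. Because gesture datasets of this kind are
usually private, it ships a first-class synthetic generator that emulates an
8-electrode forearm armband (1000 Hz, 8 gesture classes, 15–20 activation
bursts per one-minute recording), so every stage is runnable and testable
end to end without any download.

## The method

1. **Envelope extraction.** Each raw channel x(t) is mapped to its analytic
   signal by the FFT-based Hilbert transform; the envelope is
   |x(t) + i·H[x](t)|, smoothed by an order-4 Butterworth low-pass (6 Hz),
   zero-phase offline and causal in streaming.
2. **Segmentation.** Overlapped sliding windows, w = 300 ms, step
   s = 100 ms; stratified 80/10/10 train/validation/test split.
3. **CNN-ECA.** Conv(3,3)–BN–ReLU → ECA → Conv(4,3)–BN–ReLU →
   Conv(5,3)–BN–ReLU → flatten → FC–ReLU → ECA → dropout → softmax, trained
   with Adam on categorical cross-entropy, checkpointing on validation
   accuracy. The ECA module gates channels with σ(w ∗ d), where d is the
   per-channel spatial mean and the 1-D kernel size adapts to the channel
   count: K = |log₂(C)/γ + b/γ|_odd (γ = 2, b = 1).
4. **Online control.** A 300 ms ring buffer is classified every 100 ms;
   windows whose mean causal envelope falls below T × (calibrated rest
   level) emit rest; active predictions enter a sliding majority-vote
   window (W ∈ {10, 50, 100}) and the voted gesture is emitted on change.

The neural network (convolution, batch norm, ECA, dense, dropout, Adam,
backpropagation) is implemented in NumPy inside the package — see
`docs/methods.md` for the model details and design rationale.

## Worked example

```python
import emgeca as eg

# an 8-gesture desk-scale session: 10 s per gesture at 1000 Hz, SNR 20 dB
protocol = eg.desk_protocol(subject_seed=1)
recordings = eg.synth_session(protocol)                 # 8 labelled trials
envelopes = [eg.extract_envelope(r) for r in recordings]

ws = eg.split_windows(eg.segment_session(envelopes))    # 784 windows, 300x8
spec = eg.compact_spec(ws.window_len, ws.n_channels, 8)
tm = eg.train_model(spec, ws, eg.desk_train_config(seed=1, epochs=30))
report = eg.evaluate_model(tm, ws, "test")
print("test acc", report.accuracy, "loss", round(report.loss, 3),
      "macro AUC", report.roc["macro_auc"], "best epoch", tm.best_epoch)
```

prints

```
test acc 1.0 loss 0.215 macro AUC 1.0 best epoch 3
```

i.e. on clean synthetic sessions the desk-scale CNN-ECA separates all eight
gestures perfectly on held-out windows (the validation optimum was already
reached at epoch 3); the loss is the test-split cross-entropy. Streaming
the same session through the online decoder emits a single edge-triggered
gesture command and stays silent on a relaxed-muscle recording:

```python
causal = eg.EnvelopeConfig(zero_phase=False)
baseline = eg.calibrate_baseline(eg.rest_recording(protocol, 999), causal)
cmds, trace = eg.replay_session(recordings[1], tm,
                                eg.StreamConfig(vote_window_W=10),
                                causal, baseline)
print(len(cmds), "commands over", len(trace), "steps")   # -> 1 commands over 100 steps
```

The same stages are available from the shell:

```sh
emgeca synth --subjects 1 --seed 1 --out data --duration 10 --reps 4 5
emgeca preprocess --in data --out env
emgeca segment --in env --out windows.h5
emgeca train --data windows.h5 --out model --epochs 30 --lr 1e-3 --batch 64
emgeca evaluate --model model --data windows.h5 --out report
emgeca ablate --data data --seeds 1,2,3 --out ablation
emgeca run --seed 7 --out run1          # full pipeline in one go
```

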