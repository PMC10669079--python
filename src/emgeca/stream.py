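"""Online inference: ring-buffered causal envelopes, rest-threshold gating,
sliding majority-vote smoothing, and edge-triggered command emission.

The rest/activity threshold T is unit-free: it multiplies the mean envelope
level of a calibration recording of relaxed muscle, so the absolute
threshold adapts to whatever amplitude scale the armband delivers.  Commands
are emitted on change of the voted gesture (edge-triggered), matching how a
prosthetic hand is driven; set ``continuous=True`` to emit every active step.
"""

from __future__ import annotations

import csv
from collections import Counter, deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import TrainedModel, predict_proba
from .preprocess import EnvelopeConfig, extract_envelope, hilbert_envelope, \
    butterworth_lowpass
from .synth import EmgRecording

REST = -1


@dataclass(frozen=True)
class StreamConfig:
    threshold_T: float = 3.0       # multiple of the calibrated rest envelope mean
    vote_window_W: int = 100       # studied values: 10 / 50 / 100
    step_ms: float = 100.0         # prediction cadence = window step
    tie_rule: str = "keep_previous"
    continuous: bool = False

    def validate(self) -> None:
        if self.threshold_T <= 0:
            raise ValidationError("threshold_T must be positive")
        if self.vote_window_W < 1:
            raise ValidationError("vote_window_W must be >= 1")
        if self.step_ms <= 0:
            raise ValidationError("step_ms must be positive")
        if self.tie_rule not in ("keep_previous", "most_recent"):
            raise ValidationError("tie_rule must be 'keep_previous' or 'most_recent'")


@dataclass
class BaselineStats:
    channel_mean: np.ndarray
    channel_sd: np.ndarray

    @property
    def level(self) -> float:
        """Rest envelope level averaged over channels."""
        return float(self.channel_mean.mean())

    def absolute_threshold(self, threshold_T: float) -> float:
        return threshold_T * self.level


@dataclass
class GestureCommand:
    class_id: int
    timestamp: float
    vote_fraction: float


@dataclass
class StreamState:
    ring: np.ndarray               # [window_len, n_channels], latest samples
    filled: int
    votes: deque                   # bounded queue of recent class predictions
    last_voted: int | None
    last_emitted: int | None
    baseline: BaselineStats
    t: float = 0.0                 # seconds of signal consumed
    steps: int = 0


def majority_vote(votes, tie_rule: str = "keep_previous",
                  previous: int | None = None) -> int:
    """Modal class of ``votes``; ties resolved by the configured rule."""
    votes = list(votes)
    if not votes:
        raise ValidationError("votes must be non-empty")
    counts = Counter(votes)
    top = max(counts.values())
    tied = [c for c, n in counts.items() if n == top]
    if len(tied) == 1:
        return tied[0]
    if tie_rule == "keep_previous" and previous in tied:
        return previous
    # most recent occurrence among the tied classes
    for v in reversed(votes):
        if v in tied:
            return v
    raise AssertionError("unreachable")


def calibrate_baseline(rest_signal: EmgRecording,
                       env_cfg: EnvelopeConfig | None = None) -> BaselineStats:
    """Mean and sd of the rest envelope per channel (>= 2 s of relaxed muscle)."""
    env_cfg = env_cfg or EnvelopeConfig()
    if rest_signal.n_samples < 2 * rest_signal.fs:
        raise ValidationError("rest recording must be at least 2 s long")
    env = extract_envelope(rest_signal, env_cfg).envelope
    return BaselineStats(env.mean(axis=0), env.std(axis=0))


def init_stream(window_len: int, n_channels: int,
                baseline: BaselineStats) -> StreamState:
    return StreamState(
        ring=np.zeros((window_len, n_channels)), filled=0,
        votes=deque(), last_voted=None, last_emitted=None, baseline=baseline)


def _causal_window_envelope(window: np.ndarray, fs: float,
                            env_cfg: EnvelopeConfig) -> np.ndarray:
    env = np.empty_like(window)
    for c in range(window.shape[1]):
        e = hilbert_envelope(window[:, c])
        env[:, c] = butterworth_lowpass(e, fs, env_cfg)
    return np.clip(env, 0.0, None)


def stream_step(state: StreamState, new_samples: np.ndarray, model: TrainedModel,
                cfg: StreamConfig, env_cfg: EnvelopeConfig, fs: float):
    """Consume one block of samples; returns (command | None, raw, voted).

    raw/voted are the per-step labels (REST = -1) for tracing.  No prediction
    is made until the ring buffer is warm; below-threshold windows emit rest
    and leave the vote buffer untouched.
    """
    cfg.validate()
    if env_cfg.zero_phase:
        raise ValidationError("streaming requires a causal envelope config "
                              "(zero_phase=False)")
    new_samples = np.atleast_2d(np.asarray(new_samples, dtype=float))
    if new_samples.shape[1] != state.ring.shape[1]:
        raise ValidationError("block channel count does not match the stream")
    n = new_samples.shape[0]
    wl = state.ring.shape[0]
    if n >= wl:
        state.ring = new_samples[-wl:].copy()
    else:
        state.ring = np.vstack([state.ring[n:], new_samples])
    state.filled = min(state.filled + n, wl)
    state.t += n / fs
    state.steps += 1
    if state.filled < wl:
        return None, REST, REST

    env = _causal_window_envelope(state.ring, fs, env_cfg)
    if env.mean() < state.baseline.absolute_threshold(cfg.threshold_T):
        return None, REST, REST

    probs = predict_proba(model, env[None])
    raw = int(probs[0].argmax())
    state.votes.append(raw)
    while len(state.votes) > cfg.vote_window_W:
        state.votes.popleft()
    voted = majority_vote(state.votes, cfg.tie_rule, previous=state.last_voted)
    state.last_voted = voted
    command = None
    if cfg.continuous or voted != state.last_emitted:
        frac = Counter(state.votes)[voted] / len(state.votes)
        command = GestureCommand(voted, state.t, frac)
        state.last_emitted = voted
    return command, raw, voted


def replay_session(rec: EmgRecording, model: TrainedModel, cfg: StreamConfig,
                   env_cfg: EnvelopeConfig, baseline: BaselineStats,
                   sink=None, window_ms: float = 300.0):
    """Feed a recording block-by-block through the online decoder.

    Returns (commands, trace): the command log and a per-step DataFrame with
    raw and voted labels suitable for raw-vs-voted comparisons.
    """
    cfg.validate()
    wl = int(round(window_ms * rec.fs / 1000.0))
    step = int(round(cfg.step_ms * rec.fs / 1000.0))
    state = init_stream(wl, rec.n_channels, baseline)
    commands, rows = [], []
    for start in range(0, rec.n_samples - step + 1, step):
        block = rec.samples[start:start + step]
        command, raw, voted = stream_step(state, block, model, cfg, env_cfg, rec.fs)
        rows.append({"step": state.steps - 1, "time_s": state.t,
                     "raw": raw, "voted": voted,
                     "emitted": command is not None})
        if command is not None:
            commands.append(command)
            if sink is not None:
                sink(command)
    return commands, pd.DataFrame(rows)


def transition_count(labels) -> int:
    """Number of changes between consecutive entries of a label sequence."""
    labels = np.asarray(list(labels))
    if labels.size < 2:
        return 0
    return int(np.sum(labels[1:] != labels[:-1]))


# -- command sinks ----------------------------------------------------------

class CsvCommandLog:
    """Append each command to a CSV file."""

    def __init__(self, path):
        self.path = Path(path)
        with open(self.path, "w", newline="") as f:
            csv.writer(f).writerow(["timestamp_s", "class_id", "vote_fraction"])

    def __call__(self, cmd: GestureCommand) -> None:
        with open(self.path, "a", newline="") as f:
            csv.writer(f).writerow([f"{cmd.timestamp:.3f}", cmd.class_id,
                                    f"{cmd.vote_fraction:.4f}"])


class SerialFrameFormatter:
    """Format commands as the byte frames a serial hand link would carry.

    Frame: 0xAA, class id, XOR checksum.  No I/O happens here; frames are
    collected on ``frames`` for inspection or forwarding.
    """

    HEADER = 0xAA

    def __init__(self):
        self.frames: list[bytes] = []

    def __call__(self, cmd: GestureCommand) -> bytes:
        cid = cmd.class_id & 0xFF
        frame = bytes([self.HEADER, cid, self.HEADER ^ cid])
        self.frames.append(frame)
        return frame
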