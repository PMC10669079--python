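"""Synthetic multi-channel surface-EMG session generator.

Emulates an 8-electrode forearm armband recording one labelled one-minute
trial per gesture: each trial is a train of muscle-activation bursts
(band-limited 20-500 Hz noise carrier under a trapezoidal envelope) riding on
baseline instrumentation noise, with a per-gesture pattern of channel gains
playing the role of the gesture's muscle-activation topography.  A small
gesture-specific tonic component persists between bursts, emulating the
residual co-contraction of a subject holding the arm posture between
repetitions.

Amplitude units are arbitrary; the baseline noise has unit standard deviation
and burst amplitude is set from ``snr_db``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.spatial.distance import pdist

from .errors import ValidationError, ConfigurationError

RAMP_S = 0.1            # burst onset/offset ramp
HOLD_RANGE_S = (0.8, 1.6)  # plateau duration of one repetition
MIN_GAP_S = 0.3         # minimum rest between repetitions
CARRIER_BAND_HZ = (20.0, 480.0)  # broadband sEMG carrier (clipped below Nyquist)
MANIFEST_NAME = "session.json"


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Recording protocol of one synthetic subject session."""

    n_channels: int = 8
    fs: float = 1000.0
    n_gestures: int = 8
    duration_s: float = 60.0
    reps_range: tuple[int, int] = (15, 20)
    snr_db: float = 20.0
    subject_seed: int = 0
    tonic_level: float = 0.15  # sustained activation, as a fraction of burst amplitude

    def validate(self) -> None:
        if self.n_channels < 1:
            raise ValidationError("n_channels must be >= 1")
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        if self.n_gestures < 1:
            raise ValidationError("n_gestures must be >= 1")
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be positive")
        lo, hi = self.reps_range
        if not (1 <= lo <= hi):
            raise ValidationError("reps_range must satisfy 1 <= low <= high")
        if not 0.0 <= self.tonic_level < 1.0:
            raise ValidationError("tonic_level must be in [0, 1)")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


def desk_protocol(**overrides) -> AcquisitionProtocol:
    """Scaled-down protocol used for desk-size experiments and tests.

    10 s per gesture with 4-5 repetitions keeps the repetition rate of the
    full one-minute protocol (15-20 reps) while fitting the burst geometry.
    """
    kw = dict(duration_s=10.0, reps_range=(4, 5), snr_db=20.0)
    kw.update(overrides)
    return AcquisitionProtocol(**kw)


@dataclass
class EmgRecording:
    """One labelled multi-channel raw sEMG trial."""

    samples: np.ndarray  # [n_samples, n_channels]
    fs: float
    gesture_label: int
    subject_id: str = "S0"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a 2-D [n_samples, n_channels] array")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


@dataclass
class SynthTruth:
    """Ground truth injected by the generator (for oracles, never persisted)."""

    trapezoid: np.ndarray          # [n_samples] burst envelope train in [0, 1]
    modulator: np.ndarray          # [n_samples, n_channels] amplitude modulation
    burst_intervals: list[tuple[float, float]]  # (start_s, end_s) incl. ramps
    k: int
    activation: np.ndarray


def gesture_activation_matrix(protocol: AcquisitionProtocol, seed: int) -> np.ndarray:
    """Per-gesture, per-channel activation gains in [0, 1].

    Rows are kept pairwise distinct (minimum Euclidean distance > 0.1) by
    rejection sampling, so every gesture has its own channel topography.
    """
    protocol.validate()
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        m = rng.uniform(0.0, 1.0, size=(protocol.n_gestures, protocol.n_channels))
        if protocol.n_gestures == 1 or pdist(m).min() > 0.1:
            return m
    raise ConfigurationError(
        "could not draw pairwise-distinct activation rows; "
        "n_channels too small for n_gestures"
    )


def _place_bursts(rng: np.random.Generator, duration_s: float,
                  reps_range: tuple[int, int]) -> list[tuple[float, float]]:
    """Place k bursts (start, hold) with >= MIN_GAP_S rest between them."""
    lo, hi = reps_range
    k = int(rng.integers(lo, hi + 1))
    holds = None
    for _ in range(200):
        cand = rng.uniform(*HOLD_RANGE_S, size=k)
        if cand.sum() + 2 * RAMP_S * k + max(k - 1, 0) * MIN_GAP_S <= duration_s:
            holds = cand
            break
    if holds is None:
        raise ConfigurationError(
            f"cannot place {k} bursts without overlap in {duration_s} s"
        )
    spans = holds + 2 * RAMP_S
    slack = duration_s - spans.sum() - max(k - 1, 0) * MIN_GAP_S
    w = rng.random(k + 1)
    extra = slack * w / w.sum()  # lead, k-1 gap extensions, tail
    bursts = []
    t = extra[0]
    for i in range(k):
        bursts.append((t, float(holds[i])))
        t += spans[i]
        if i < k - 1:
            t += MIN_GAP_S + extra[i + 1]
    return bursts


def _trapezoid_train(n: int, fs: float,
                     bursts: list[tuple[float, float]]) -> np.ndarray:
    t = np.arange(n) / fs
    trap = np.zeros(n)
    for start, hold in bursts:
        xp = [start, start + RAMP_S, start + RAMP_S + hold, start + 2 * RAMP_S + hold]
        np.maximum(trap, np.interp(t, xp, [0.0, 1.0, 1.0, 0.0], left=0.0, right=0.0),
                   out=trap)
    return trap


def _carrier(rng: np.random.Generator, n: int, n_channels: int, fs: float) -> np.ndarray:
    """Unit-RMS band-limited (20-500 Hz) noise carrier, one per channel."""
    lo, hi = CARRIER_BAND_HZ
    hi = min(hi, 0.48 * fs)
    if hi <= lo:
        raise ConfigurationError(f"fs={fs} too low for the {lo}-Hz carrier band")
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    white = rng.standard_normal((n, n_channels))
    carrier = sps.sosfiltfilt(sos, white, axis=0)
    carrier /= np.sqrt(np.mean(carrier**2, axis=0, keepdims=True))
    return carrier


def synth_recording(protocol: AcquisitionProtocol, gesture: int,
                    activation: np.ndarray, seed: int,
                    with_truth: bool = False):
    """Generate one labelled trial: baseline noise + tonic + burst train.

    ``activation`` is the per-channel gain row for this gesture.  Burst
    amplitude A satisfies A / sigma_baseline = 10^(snr_db/20); ``snr_db = -inf``
    yields pure baseline noise.
    """
    protocol.validate()
    if not 0 <= gesture < protocol.n_gestures:
        raise ValidationError(f"gesture {gesture} out of range")
    activation = np.asarray(activation, dtype=float)
    if activation.shape != (protocol.n_channels,):
        raise ValidationError("activation length must equal n_channels")
    rng = np.random.default_rng(seed)
    n = protocol.n_samples

    bursts = _place_bursts(rng, protocol.duration_s, protocol.reps_range)
    trap = _trapezoid_train(n, protocol.fs, bursts)
    amp = 0.0 if np.isneginf(protocol.snr_db) else 10.0 ** (protocol.snr_db / 20.0)
    tl = protocol.tonic_level
    modulator = amp * activation[None, :] * (tl + (1.0 - tl) * trap[:, None])

    carrier = _carrier(rng, n, protocol.n_channels, protocol.fs)
    noise = rng.standard_normal((n, protocol.n_channels))
    rec = EmgRecording(noise + carrier * modulator, protocol.fs, gesture,
                       subject_id=f"S{protocol.subject_seed}")
    if not with_truth:
        return rec
    intervals = [(s, s + 2 * RAMP_S + h) for s, h in bursts]
    truth = SynthTruth(trap, modulator, intervals, len(bursts), activation)
    return rec, truth


def _session_seeds(protocol: AcquisitionProtocol) -> tuple[int, np.ndarray]:
    state = np.random.SeedSequence(protocol.subject_seed).generate_state(
        protocol.n_gestures + 1, dtype=np.uint32)
    seeds = (state % np.uint32(2**31)).astype(np.int64)
    return int(seeds[0]), seeds[1:]


def synth_session(protocol: AcquisitionProtocol,
                  activation: np.ndarray | None = None) -> list[EmgRecording]:
    """One recording per gesture, all seeded from ``protocol.subject_seed``."""
    protocol.validate()
    act_seed, rec_seeds = _session_seeds(protocol)
    if activation is None:
        activation = gesture_activation_matrix(protocol, act_seed)
    activation = np.asarray(activation, dtype=float)
    if activation.shape != (protocol.n_gestures, protocol.n_channels):
        raise ValidationError("activation matrix shape must be [n_gestures, n_channels]")
    return [synth_recording(protocol, g, activation[g], int(rec_seeds[g]))
            for g in range(protocol.n_gestures)]


def rest_recording(protocol: AcquisitionProtocol, seed: int) -> EmgRecording:
    """A relaxed-muscle trial: every channel gain zero (baseline noise only)."""
    rec = synth_recording(protocol, 0, np.zeros(protocol.n_channels), seed)
    rec.gesture_label = -1
    return rec


# ---------------------------------------------------------------------------
# Session on-disk format: one CSV per recording + a JSON manifest.
# ---------------------------------------------------------------------------

def write_session(recordings: list[EmgRecording], out_dir: str | Path,
                  protocol: AcquisitionProtocol | None = None,
                  envelope: bool = False) -> Path:
    """Write recordings as ``gNN.csv`` (columns ch1..chN) plus ``session.json``.

    Values are printed with 17 significant digits so the round trip is
    bit-exact for float64.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for i, rec in enumerate(recordings):
        name = f"g{i:02d}.csv"
        header = ",".join(f"ch{c + 1}" for c in range(rec.n_channels))
        np.savetxt(out_dir / name, rec.samples, fmt="%.17g", delimiter=",",
                   header=header, comments="")
        files.append({"file": name, "gesture_label": int(rec.gesture_label)})
    manifest = {
        "subject_id": recordings[0].subject_id,
        "fs": float(recordings[0].fs),
        "envelope": bool(envelope),
        "files": files,
        "protocol": _protocol_to_json(protocol) if protocol is not None else None,
    }
    (out_dir / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2))
    return out_dir


def _protocol_to_json(p: AcquisitionProtocol) -> dict:
    d = asdict(p)
    d["reps_range"] = list(d["reps_range"])
    return d


def read_session(in_dir: str | Path) -> tuple[list[EmgRecording], dict]:
    """Read a session directory back into recordings + its manifest."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / MANIFEST_NAME).read_text())
    recs = []
    for entry in manifest["files"]:
        data = np.loadtxt(in_dir / entry["file"], delimiter=",", skiprows=1, ndmin=2)
        recs.append(EmgRecording(data, manifest["fs"], entry["gesture_label"],
                                 subject_id=manifest["subject_id"]))
    return recs, manifest


def find_sessions(root: str | Path) -> list[Path]:
    """All session directories at or below ``root`` (detected by manifest)."""
    root = Path(root)
    if (root / MANIFEST_NAME).exists():
        return [root]
    return sorted(p.parent for p in root.glob(f"*/{MANIFEST_NAME}"))
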