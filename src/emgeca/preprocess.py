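"""Envelope extraction: FFT-based Hilbert transform + Butterworth smoothing.

The envelope of a raw sEMG channel is taken as the magnitude of its analytic
signal (forward FFT, zero the negative frequencies / double the positive
ones, inverse FFT), then low-pass filtered to the slow "linear envelope"
band that reflects muscle activation intensity.  The FFT route assumes
circularity, so accuracy guarantees exclude a small fraction at each end
(``edge_policy``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .errors import ValidationError
from .synth import EmgRecording, read_session, write_session


@dataclass(frozen=True)
class EnvelopeConfig:
    """Smoothing stage of the envelope extractor.

    6 Hz / order 4 is a typical sEMG linear-envelope smoother.  Offline
    processing uses a zero-phase forward-backward pass; streaming uses a
    single causal pass (initialised at the step steady state of the first
    sample so there is no startup transient and DC gain is exactly 1).
    """

    lowpass_cutoff_hz: float = 6.0
    lowpass_order: int = 4
    zero_phase: bool = True
    edge_policy: float = 0.05

    def validate(self, fs: float | None = None) -> None:
        if self.lowpass_cutoff_hz <= 0:
            raise ValidationError("lowpass_cutoff_hz must be positive")
        if self.lowpass_order < 1:
            raise ValidationError("lowpass_order must be >= 1")
        if not 0.0 <= self.edge_policy < 0.5:
            raise ValidationError("edge_policy must be in [0, 0.5)")
        if fs is not None and self.lowpass_cutoff_hz >= fs / 2:
            raise ValidationError(
                f"cutoff {self.lowpass_cutoff_hz} Hz must be below fs/2 = {fs / 2}"
            )


@dataclass
class EnvelopeRecording:
    """An EmgRecording after envelope extraction (non-negative samples)."""

    envelope: np.ndarray  # [n_samples, n_channels]
    fs: float
    gesture_label: int
    subject_id: str = "S0"

    @property
    def n_samples(self) -> int:
        return self.envelope.shape[0]

    @property
    def n_channels(self) -> int:
        return self.envelope.shape[1]


def hilbert_envelope(x: np.ndarray, fs: float | None = None) -> np.ndarray:
    """Magnitude of the analytic signal, via the FFT-based Hilbert transform.

    ``fs`` is accepted for interface symmetry with the filtering stage; the
    transform itself is sample-rate free.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.shape[0] < 2:
        raise ValidationError("signal must be a 1-D vector of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValidationError("signal contains non-finite values")
    return np.abs(sps.hilbert(x))


def butterworth_lowpass(x: np.ndarray, fs: float, cfg: EnvelopeConfig) -> np.ndarray:
    """Low-pass an evenly sampled vector (zero-phase or single causal pass)."""
    cfg.validate(fs)
    x = np.asarray(x, dtype=float)
    sos = sps.butter(cfg.lowpass_order, cfg.lowpass_cutoff_hz, fs=fs, output="sos")
    if cfg.zero_phase:
        return sps.sosfiltfilt(sos, x)
    zi = sps.sosfilt_zi(sos) * x[..., 0]
    y, _ = sps.sosfilt(sos, x, zi=zi)
    return y


def extract_envelope(rec: EmgRecording, cfg: EnvelopeConfig | None = None) -> EnvelopeRecording:
    """Per-channel Hilbert magnitude then Butterworth smoothing (clamped >= 0)."""
    cfg = cfg or EnvelopeConfig()
    cfg.validate(rec.fs)
    env = np.empty_like(rec.samples)
    for c in range(rec.n_channels):
        e = hilbert_envelope(rec.samples[:, c])
        env[:, c] = butterworth_lowpass(e, rec.fs, cfg)
    np.clip(env, 0.0, None, out=env)
    return EnvelopeRecording(env, rec.fs, rec.gesture_label, rec.subject_id)


def causal_config(cfg: EnvelopeConfig) -> EnvelopeConfig:
    return replace(cfg, zero_phase=False)


# -- session-level IO -------------------------------------------------------

def preprocess_session(in_dir: str | Path, out_dir: str | Path,
                       cfg: EnvelopeConfig | None = None) -> Path:
    """Envelope-extract every recording of a stored session."""
    recs, manifest = read_session(in_dir)
    envs = [extract_envelope(r, cfg) for r in recs]
    as_recs = [EmgRecording(e.envelope, e.fs, e.gesture_label, e.subject_id)
               for e in envs]
    return write_session(as_recs, out_dir, envelope=True)


def read_envelope_session(in_dir: str | Path) -> list[EnvelopeRecording]:
    recs, manifest = read_session(in_dir)
    if not manifest.get("envelope", False):
        raise ValidationError(f"{in_dir} is not an envelope session")
    return [EnvelopeRecording(r.samples, r.fs, r.gesture_label, r.subject_id)
            for r in recs]
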