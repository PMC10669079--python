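"""Overlapped sliding-window segmentation and stratified splitting.

Windows are half-open sample ranges [i*step, i*step + window_len); trailing
samples that do not fill a whole window are dropped.  The split is assigned
at the window level (the faithful default, although overlapping windows can
then straddle splits and optimistically bias test accuracy; split by
recording instead if that bias matters for your use).
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .errors import ValidationError
from .preprocess import EnvelopeRecording
from .synth import EmgRecording

SPLIT_NAMES = ("train", "val", "test")
UNSPLIT = -1


@dataclass(frozen=True)
class WindowConfig:
    w_ms: float = 300.0
    s_ms: float = 100.0
    split_fracs: tuple[float, float, float] = (0.8, 0.1, 0.1)
    split_seed: int = 0

    def validate(self) -> None:
        if not 0 < self.s_ms <= self.w_ms:
            raise ValidationError("step must satisfy 0 < s_ms <= w_ms")
        if len(self.split_fracs) != 3 or any(f <= 0 for f in self.split_fracs):
            raise ValidationError("split_fracs must be three positive fractions")
        if abs(sum(self.split_fracs) - 1.0) > 1e-9:
            raise ValidationError("split_fracs must sum to 1")

    def window_len(self, fs: float) -> int:
        return int(round(self.w_ms * fs / 1000.0))

    def step_len(self, fs: float) -> int:
        return int(round(self.s_ms * fs / 1000.0))


@dataclass
class WindowSet:
    windows: np.ndarray   # [n_windows, window_len, n_channels]
    labels: np.ndarray    # [n_windows]
    split: np.ndarray     # [n_windows] in {-1 unsplit, 0 train, 1 val, 2 test}
    fs: float
    rec_ids: np.ndarray   # provenance: source recording id per window
    starts: np.ndarray    # provenance: start sample offset per window

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def window_len(self) -> int:
        return self.windows.shape[1]

    @property
    def n_channels(self) -> int:
        return self.windows.shape[2]

    def indices(self, split: str) -> np.ndarray:
        return np.flatnonzero(self.split == SPLIT_NAMES.index(split))

    def subset(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        idx = self.indices(split)
        return self.windows[idx], self.labels[idx]


def _samples_of(rec) -> np.ndarray:
    if isinstance(rec, EnvelopeRecording):
        return rec.envelope
    if isinstance(rec, EmgRecording):
        return rec.samples
    raise ValidationError(f"cannot segment object of type {type(rec).__name__}")


def segment(rec, cfg: WindowConfig | None = None, rec_id: str | None = None) -> WindowSet:
    """Cut one recording into overlapped windows (labels inherited, unsplit)."""
    cfg = cfg or WindowConfig()
    cfg.validate()
    data = _samples_of(rec)
    n, n_ch = data.shape
    wl, sl = cfg.window_len(rec.fs), cfg.step_len(rec.fs)
    if n < wl:
        raise ValidationError(
            f"recording of {n} samples is shorter than one {wl}-sample window; "
            "no windows can be produced"
        )
    count = (n - wl) // sl + 1
    starts = np.arange(count) * sl
    view = np.lib.stride_tricks.sliding_window_view(data, wl, axis=0)
    wins = np.ascontiguousarray(view[::sl][:count].transpose(0, 2, 1))
    rec_id = rec_id if rec_id is not None else f"{rec.subject_id}/g{rec.gesture_label}"
    return WindowSet(
        windows=wins,
        labels=np.full(count, rec.gesture_label, dtype=np.int64),
        split=np.full(count, UNSPLIT, dtype=np.int8),
        fs=rec.fs,
        rec_ids=np.array([rec_id] * count, dtype=object),
        starts=starts.astype(np.int64),
    )


def segment_session(recs, cfg: WindowConfig | None = None) -> WindowSet:
    """Segment a list of recordings and concatenate into one WindowSet."""
    sets = [segment(r, cfg, rec_id=f"{r.subject_id}/g{r.gesture_label}/{i}")
            for i, r in enumerate(recs)]
    return concat_window_sets(sets)


def concat_window_sets(sets: list[WindowSet]) -> WindowSet:
    if not sets:
        raise ValidationError("no window sets to concatenate")
    fs = sets[0].fs
    wl = sets[0].window_len
    if any(s.fs != fs or s.window_len != wl for s in sets):
        raise ValidationError("window sets disagree on fs or window length")
    return WindowSet(
        windows=np.concatenate([s.windows for s in sets]),
        labels=np.concatenate([s.labels for s in sets]),
        split=np.concatenate([s.split for s in sets]),
        fs=fs,
        rec_ids=np.concatenate([s.rec_ids for s in sets]),
        starts=np.concatenate([s.starts for s in sets]),
    )


def _largest_remainder(n: int, fracs) -> np.ndarray:
    quota = np.asarray(fracs, dtype=float) * n
    base = np.floor(quota).astype(int)
    rem = n - base.sum()
    # ties on the fractional part go to the earlier split (train, val, test)
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:rem]] += 1
    return base


def split_windows(ws: WindowSet, cfg: WindowConfig | None = None) -> WindowSet:
    """Stratified train/val/test assignment, shuffled per class with split_seed."""
    cfg = cfg or WindowConfig()
    cfg.validate()
    if np.any(ws.split != UNSPLIT):
        raise ValidationError("window set is already split")
    rng = np.random.default_rng(cfg.split_seed)
    split = np.full(ws.n_windows, UNSPLIT, dtype=np.int8)
    for cls in np.unique(ws.labels):
        idx = np.flatnonzero(ws.labels == cls)
        if idx.size < 10:
            raise ValidationError(
                f"class {cls} has only {idx.size} windows; at least 10 are "
                "required to honour 10% validation/test slices"
            )
        idx = rng.permutation(idx)
        counts = _largest_remainder(idx.size, cfg.split_fracs)
        bounds = np.cumsum(counts)
        split[idx[: bounds[0]]] = 0
        split[idx[bounds[0]: bounds[1]]] = 1
        split[idx[bounds[1]: bounds[2]]] = 2
    return WindowSet(ws.windows, ws.labels, split, ws.fs, ws.rec_ids, ws.starts)


# -- HDF5 persistence -------------------------------------------------------

def save_window_set(ws: WindowSet, path, cfg: WindowConfig | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("windows", data=ws.windows)
        f.create_dataset("labels", data=ws.labels)
        f.create_dataset("split", data=ws.split)
        f.create_dataset("rec_ids", data=ws.rec_ids.astype("S"))
        f.create_dataset("starts", data=ws.starts)
        f.attrs["fs"] = ws.fs
        if cfg is not None:
            f.attrs["w_ms"] = cfg.w_ms
            f.attrs["s_ms"] = cfg.s_ms
            f.attrs["split_seed"] = cfg.split_seed


def load_window_set(path) -> WindowSet:
    with h5py.File(path, "r") as f:
        return WindowSet(
            windows=f["windows"][...],
            labels=f["labels"][...],
            split=f["split"][...],
            fs=float(f.attrs["fs"]),
            rec_ids=np.array([s.decode() for s in f["rec_ids"][...]], dtype=object),
            starts=f["starts"][...],
        )
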