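"""Sliding-window dataset construction with soft labels.

Training windows hold 50 consecutive samples of all 6 channels.  Two slicing
regimes are used for training (step 50: non-overlapping; step 25: half
overlap) and streaming inference slides with step 1.  A window's soft label
is the fraction of its samples carrying each class; because every break in
the corpus is at least 63 samples long, a 50-sample window can straddle at
most one exercise and breaks, never two exercises.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import h5py
import numpy as np

from .signals import N_CLASSES, ActivityLabel, DataError, Protocol, SignalMatrix

WINDOW_SIZE = 50


@dataclass
class ChannelStats:
    """Per-channel mean/sd used for z-score normalization."""

    mean: np.ndarray
    sd: np.ndarray


@dataclass
class WindowedDataset:
    windows: np.ndarray      # (n, size, 6)
    soft_labels: np.ndarray  # (n, 4)
    starts: np.ndarray       # (n,)
    regime: str              # "nonoverlap" | "overlap" | "stream" | "custom"
    normalization: str = "raw"
    channel_stats: ChannelStats | None = None

    def __post_init__(self) -> None:
        if len(self.windows) != len(self.soft_labels):
            raise ValueError("windows and labels must align")

    def __len__(self) -> int:
        return len(self.windows)

    def subset(self, idx: np.ndarray) -> "WindowedDataset":
        return replace(self, windows=self.windows[idx],
                       soft_labels=self.soft_labels[idx],
                       starts=self.starts[idx])


def _regime_for_step(size: int, step: int) -> str:
    if step == size:
        return "nonoverlap"
    if step == size // 2:
        return "overlap"
    if step == 1:
        return "stream"
    return "custom"


def soft_label(sample_labels: np.ndarray) -> np.ndarray:
    """Class-fraction 4-vector of a window's per-sample labels."""
    counts = np.bincount(np.asarray(sample_labels, dtype=np.int64),
                         minlength=N_CLASSES)
    return counts / counts.sum()


#: Exercise mass below this does not count as "present" when hard-labelling.
#: Half the smallest nonzero class fraction a 50-sample window can carry —
#: exact for class-fraction targets, and the natural floor for softmax
#: outputs, which are never exactly zero.
PRESENCE_THRESHOLD = 0.5 / WINDOW_SIZE


def hard_label(soft: np.ndarray,
               presence_threshold: float = PRESENCE_THRESHOLD
               ) -> ActivityLabel:
    """Collapse a soft label to one class.

    Windows that mix an exercise with break samples count as the exercise —
    exercise mass above ``presence_threshold`` beats the break class even
    when break holds the majority; among exercises the largest mass wins,
    ties broken by class-index order.
    """
    soft = np.asarray(soft, dtype=np.float64)
    if soft[1:].max() > presence_threshold:
        return ActivityLabel(1 + int(np.argmax(soft[1:])))
    return ActivityLabel.BREAK


def hard_labels(soft: np.ndarray,
                presence_threshold: float = PRESENCE_THRESHOLD) -> np.ndarray:
    """Vectorized :func:`hard_label` over an (n, 4) soft-label matrix."""
    soft = np.asarray(soft, dtype=np.float64)
    ex = soft[:, 1:]
    has_ex = ex.max(axis=1) > presence_threshold
    return np.where(has_ex, 1 + ex.argmax(axis=1), 0)


def slice_windows(sig: SignalMatrix, truth: Protocol | None,
                  size: int = WINDOW_SIZE, step: int = 25) -> WindowedDataset:
    """Slice a recording into windows at starts 0, step, 2*step, ...

    Ground truth is optional (streaming inference has none); when present,
    each window gets the class-fraction soft label of its samples.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    n = sig.n_samples
    if n < size:
        raise DataError(f"recording shorter ({n}) than window size ({size})")
    starts = np.arange(0, n - size + 1, step)
    view = np.lib.stride_tricks.sliding_window_view(sig.values, size, axis=0)
    windows = np.ascontiguousarray(
        view[starts].transpose(0, 2, 1))  # (n_win, size, channels)
    if truth is not None:
        labels = truth.sample_labels()
        lab_view = np.lib.stride_tricks.sliding_window_view(labels, size)
        onehot = np.eye(N_CLASSES)[lab_view[starts]]
        soft = onehot.mean(axis=1)
    else:
        soft = np.zeros((len(starts), N_CLASSES))
    return WindowedDataset(windows, soft, starts,
                           regime=_regime_for_step(size, step))


def concat_datasets(parts: list[WindowedDataset]) -> WindowedDataset:
    if not parts:
        raise ValueError("nothing to concatenate")
    regime = parts[0].regime if len({p.regime for p in parts}) == 1 else "custom"
    return WindowedDataset(
        np.concatenate([p.windows for p in parts]),
        np.concatenate([p.soft_labels for p in parts]),
        np.concatenate([p.starts for p in parts]),
        regime=regime,
        normalization=parts[0].normalization,
        channel_stats=parts[0].channel_stats)


def fit_normalizer(train_windows: np.ndarray,
                   sd_floor: float = 1e-8) -> ChannelStats:
    """Per-channel mean and sd over every sample of the training windows."""
    w = np.asarray(train_windows, dtype=np.float64)
    if w.size == 0:
        raise ValueError("cannot fit a normalizer on an empty set")
    flat = w.reshape(-1, w.shape[-1])
    return ChannelStats(mean=flat.mean(axis=0),
                        sd=np.maximum(flat.std(axis=0), sd_floor))


def apply_normalizer(windows: np.ndarray, stats: ChannelStats) -> np.ndarray:
    return (windows - stats.mean) / stats.sd


def normalize_dataset(ds: WindowedDataset,
                      stats: ChannelStats) -> WindowedDataset:
    return replace(ds, windows=apply_normalizer(ds.windows, stats),
                   normalization="zscore", channel_stats=stats)


def split_dataset(ds: WindowedDataset,
                  ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
                  seed: int | np.random.SeedSequence = 0
                  ) -> tuple[WindowedDataset, WindowedDataset, WindowedDataset]:
    """Random disjoint train/validation/test partition at window level."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    n = len(ds)
    if n < 3:
        raise DataError("need at least 3 windows to split")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(round(ratios[0] * n))
    n_val = int(round(ratios[1] * n))
    n_val = min(n_val, n - n_train)
    return (ds.subset(perm[:n_train]),
            ds.subset(perm[n_train:n_train + n_val]),
            ds.subset(perm[n_train + n_val:]))


def save_dataset(ds: WindowedDataset, path: str | Path) -> None:
    """Persist a windowed dataset as a single HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("windows", data=ds.windows)
        f.create_dataset("soft_labels", data=ds.soft_labels)
        f.create_dataset("starts", data=ds.starts)
        f.attrs["regime"] = ds.regime
        f.attrs["normalization"] = ds.normalization
        if ds.channel_stats is not None:
            f.create_dataset("channel_mean", data=ds.channel_stats.mean)
            f.create_dataset("channel_sd", data=ds.channel_stats.sd)


def load_dataset(path: str | Path) -> WindowedDataset:
    with h5py.File(path, "r") as f:
        stats = None
        if "channel_mean" in f:
            stats = ChannelStats(f["channel_mean"][()], f["channel_sd"][()])
        return WindowedDataset(f["windows"][()], f["soft_labels"][()],
                               f["starts"][()], regime=str(f.attrs["regime"]),
                               normalization=str(f.attrs["normalization"]),
                               channel_stats=stats)
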