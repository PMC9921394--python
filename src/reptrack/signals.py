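"""Data model and I/O for multichannel accelerometer time series.

The pipeline works on a fixed set of six acceleration channels — three axes
from a chest-worn sensor and three from a hand-worn sensor — sampled on a
uniform 30 Hz grid.  Recordings are stored as plain CSV (one ``t`` column in
seconds plus one column per channel) with a small JSON sidecar carrying the
sampling rate.  Ground-truth annotations are stored as CSV segment tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_RATE = 30.0


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class DataError(ValueError):
    """Input data violate a precondition (ordering, support, size)."""


@dataclass(frozen=True, order=True)
class ChannelId:
    """One acceleration channel: body location plus axis."""

    location: str  # "chest" | "hand"
    axis: str      # "x" | "y" | "z"
    quantity: str = "acceleration"

    def __post_init__(self) -> None:
        if self.location not in ("chest", "hand"):
            raise ValueError(f"unknown location {self.location!r}")
        if self.axis not in ("x", "y", "z"):
            raise ValueError(f"unknown axis {self.axis!r}")

    @property
    def column(self) -> str:
        return f"{self.location}_a{self.axis}"


#: Canonical channel order: chest x,y,z then hand x,y,z.
CHANNELS: tuple[ChannelId, ...] = tuple(
    ChannelId(loc, ax) for loc in ("chest", "hand") for ax in ("x", "y", "z")
)

CHEST_X, CHEST_Y, CHEST_Z, HAND_X, HAND_Y, HAND_Z = CHANNELS


class ActivityLabel(IntEnum):
    """The four stream classes; BREAK is the non-exercise class."""

    BREAK = 0
    DIP = 1
    PULLUP = 2
    SQUAT = 3


N_CLASSES = len(ActivityLabel)
EXERCISES: tuple[ActivityLabel, ...] = (
    ActivityLabel.DIP,
    ActivityLabel.PULLUP,
    ActivityLabel.SQUAT,
)


@dataclass(frozen=True)
class Segment:
    """Half-open labelled interval [start, end) in sample indices."""

    label: ActivityLabel
    start: int
    end: int
    repetitions: int | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty segment [{self.start}, {self.end})")
        if self.label == ActivityLabel.BREAK:
            if self.repetitions is not None:
                raise ValueError("break segments carry no repetition count")
        elif self.repetitions is not None and self.repetitions < 0:
            raise ValueError("repetitions must be nonnegative")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Protocol:
    """Ground truth for one recording: segments tiling [0, n_samples)."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        segs = self.segments
        if not segs:
            raise ValueError("protocol must contain at least one segment")
        if segs[0].start != 0:
            raise ValueError("first segment must start at 0")
        for a, b in zip(segs, segs[1:]):
            if a.end != b.start:
                raise ValueError("segments must tile without gaps or overlap")
            if a.label == b.label:
                raise ValueError("consecutive segments must differ in label")
            if (a.label != ActivityLabel.BREAK
                    and b.label != ActivityLabel.BREAK):
                raise ValueError("exercises must be separated by a break")
        for s in segs:
            if s.label != ActivityLabel.BREAK and s.repetitions is None:
                raise ValueError("ground-truth exercise segments need counts")

    @property
    def n_samples(self) -> int:
        return self.segments[-1].end

    @property
    def scenario(self) -> tuple[ActivityLabel, ...]:
        """Ordered non-break activity sequence."""
        return tuple(s.label for s in self.segments
                     if s.label != ActivityLabel.BREAK)

    def sample_labels(self) -> np.ndarray:
        """Per-sample integer label array of length n_samples."""
        out = np.empty(self.n_samples, dtype=np.int64)
        for s in self.segments:
            out[s.start:s.end] = int(s.label)
        return out

    def exercise_segments(self) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments
                     if s.label != ActivityLabel.BREAK)


@dataclass
class SignalMatrix:
    """N samples x M channels on a uniform grid at ``rate`` Hz (m/s^2)."""

    values: np.ndarray
    rate: float = DEFAULT_RATE
    channels: tuple[ChannelId, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (time x channel) array")
        if self.values.shape[0] < 1:
            raise ValueError("need at least one sample")
        if self.values.shape[1] != len(self.channels):
            raise ValueError("column count must match channel list")
        if self.values.shape[1] < 1:
            raise ValueError("need at least one channel")
        if not np.isfinite(self.values).all():
            raise DataError("signal contains non-finite values")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        self.channels = tuple(self.channels)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def timestamps(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate


@dataclass
class TimestampedStream:
    """Irregularly sampled multichannel stream (pre-resampling)."""

    timestamps: np.ndarray
    values: np.ndarray
    channels: tuple[ChannelId, ...]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.shape[0] != self.timestamps.shape[0]:
            self.values = self.values.T
        if self.values.shape[0] != self.timestamps.shape[0]:
            raise ValueError("values and timestamps disagree in length")
        if np.any(np.diff(self.timestamps) <= 0):
            raise DataError("timestamps must be strictly increasing")
        self.channels = tuple(self.channels)


# ---------------------------------------------------------------------------
# resampling / synchronization

def resample_to_rate(stream: TimestampedStream,
                     target_rate: float = DEFAULT_RATE,
                     t_start: float | None = None,
                     t_end: float | None = None) -> SignalMatrix:
    """Linearly interpolate an irregular stream onto a uniform grid.

    The grid spans ``[t_start, t_end]`` (defaults: the observed support) at
    ``target_rate``; no extrapolation beyond the observed support is allowed.
    """
    t = stream.timestamps
    if t.size < 2:
        raise DataError("need at least 2 samples to resample")
    t0 = t[0] if t_start is None else float(t_start)
    t1 = t[-1] if t_end is None else float(t_end)
    if t0 < t[0] - 1e-12 or t1 > t[-1] + 1e-12:
        raise DataError("grid would extrapolate beyond observed support")
    n = int(np.floor((t1 - t0) * target_rate + 1e-9)) + 1
    grid = t0 + np.arange(n) / target_rate
    out = np.column_stack(
        [np.interp(grid, t, stream.values[:, j])
         for j in range(stream.values.shape[1])])
    return SignalMatrix(out, rate=target_rate, channels=stream.channels)


def synchronize_streams(streams: Sequence[TimestampedStream],
                        target_rate: float = DEFAULT_RATE) -> SignalMatrix:
    """Resample streams onto a shared grid over the intersection of supports
    and concatenate their columns in canonical channel order."""
    if not streams:
        raise ValueError("need at least one stream")
    t0 = max(s.timestamps[0] for s in streams)
    t1 = min(s.timestamps[-1] for s in streams)
    if t1 <= t0:
        raise DataError("streams have empty common time support")
    parts = [resample_to_rate(s, target_rate, t0, t1) for s in streams]
    values = np.hstack([p.values for p in parts])
    channels = tuple(c for s in streams for c in s.channels)
    sig = SignalMatrix(values, rate=target_rate, channels=channels)
    canon = [c for c in CHANNELS if c in channels]
    return select_channels(sig, canon) if tuple(canon) != channels else sig


def select_channels(sig: SignalMatrix,
                    wanted: Iterable[ChannelId]) -> SignalMatrix:
    """Column subset in ``wanted`` order; sample count unchanged."""
    wanted = tuple(wanted)
    idx = []
    for c in wanted:
        try:
            idx.append(sig.channels.index(c))
        except ValueError:
            raise KeyError(f"channel {c} not present") from None
    return SignalMatrix(sig.values[:, idx], rate=sig.rate, channels=wanted)


# ---------------------------------------------------------------------------
# file I/O

def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_recording(sig: SignalMatrix, path: str | Path) -> None:
    """Write a recording as CSV plus a JSON metadata sidecar.

    Float values are written with ``repr`` precision so that a read-back
    reproduces the matrix bit for bit.
    """
    path = Path(path)
    if sig.n_channels == 0:
        raise FormatError("cannot write a recording with no channels")
    df = pd.DataFrame(sig.values, columns=[c.column for c in sig.channels])
    df.insert(0, "t", np.arange(sig.n_samples) / sig.rate)
    df.to_csv(path, index=False, float_format="%.17g")
    _meta_path(path).write_text(json.dumps(
        {"rate": sig.rate, "channels": [c.column for c in sig.channels]}))


def read_recording(path: str | Path) -> SignalMatrix:
    """Read a CSV recording; columns are reordered to canonical order."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "t" not in df.columns:
        raise FormatError("recording is missing the 't' column")
    t = df["t"].to_numpy(dtype=np.float64)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise DataError("non-monotone timestamps")
    missing = [c.column for c in CHANNELS if c.column not in df.columns]
    if missing:
        raise FormatError(f"missing channel columns: {missing}")
    rate = DEFAULT_RATE
    mp = _meta_path(path)
    if mp.exists():
        rate = float(json.loads(mp.read_text()).get("rate", DEFAULT_RATE))
    values = df[[c.column for c in CHANNELS]].to_numpy(dtype=np.float64)
    return SignalMatrix(values, rate=rate, channels=CHANNELS)


_LABEL_NAMES = {lab.name.lower(): lab for lab in ActivityLabel}


def write_annotation(protocol: Protocol, path: str | Path) -> None:
    rows = [{"label": s.label.name.lower(), "start": s.start, "end": s.end,
             "repetitions": "" if s.repetitions is None else s.repetitions}
            for s in protocol.segments]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_annotation(path: str | Path) -> Protocol:
    df = pd.read_csv(path)
    segs = []
    for _, row in df.iterrows():
        name = str(row["label"]).strip().lower()
        if name not in _LABEL_NAMES:
            raise FormatError(f"unknown activity label {name!r}")
        reps = row.get("repetitions")
        reps = None if pd.isna(reps) or reps == "" else int(reps)
        segs.append(Segment(_LABEL_NAMES[name], int(row["start"]),
                            int(row["end"]), reps))
    return Protocol(tuple(segs))
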