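"""Repetition counting per recognized exercise segment.

For each exercise the informative channels are sliced over the segment,
low-pass filtered with a zero-phase (forward-backward) Butterworth filter
whose cutoff reflects the slowest plausible repetition tempo, and counted by
minimum-distance peak detection; the per-channel counts are averaged and
rounded.  Filter order, normalized cutoff Wn (fraction of Nyquist) and
minimum peak distance are per-activity parameters derived from the corpus
repetition-duration statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signals import (
    ActivityLabel, ChannelId, DataError, Protocol, Segment, SignalMatrix,
)
from .simulate import INFORMATIVE_CHANNELS

DIP, PULLUP, SQUAT = (ActivityLabel.DIP, ActivityLabel.PULLUP,
                      ActivityLabel.SQUAT)


@dataclass(frozen=True)
class ActivityCounterConfig:
    channels: tuple[ChannelId, ...]
    filter_order: int = 2
    wn: float = 0.05          # cutoff as fraction of Nyquist
    min_distance: int = 40    # samples between counted peaks
    prominence_frac: float = 0.1  # fraction of segment signal range
    polarity: str = "auto"    # "auto" | "peaks" | "troughs"

    def __post_init__(self) -> None:
        if not 0 < self.wn < 1:
            raise ValueError("wn must lie in (0, 1)")
        if self.min_distance < 1:
            raise ValueError("min_distance must be >= 1")
        if not self.channels:
            raise ValueError("at least one channel per activity")


def default_config() -> dict[ActivityLabel, ActivityCounterConfig]:
    """Per-activity defaults tuned to the corpus repetition statistics."""
    return {
        DIP: ActivityCounterConfig(INFORMATIVE_CHANNELS[DIP],
                                   wn=0.05, min_distance=40),
        PULLUP: ActivityCounterConfig(INFORMATIVE_CHANNELS[PULLUP],
                                      wn=0.04, min_distance=50),
        SQUAT: ActivityCounterConfig(INFORMATIVE_CHANNELS[SQUAT],
                                     wn=0.06, min_distance=30),
    }


RCMConfig = dict  # per-activity map ActivityLabel -> ActivityCounterConfig


def lowpass(x: np.ndarray, order: int = 2, wn: float = 0.05) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward-backward filtering)."""
    x = np.asarray(x, dtype=np.float64)
    if not 0 < wn < 1:
        raise ValueError("wn must lie in (0, 1)")
    if x.size <= 3 * (order + 1):
        raise DataError("series too short for the requested filter order")
    b, a = sps.butter(order, wn, btype="low")
    return sps.filtfilt(b, a, x)


def count_peaks(x: np.ndarray, min_distance: int,
                prominence_frac: float = 0.1) -> int:
    """Count local maxima at least ``min_distance`` samples apart whose
    prominence reaches ``prominence_frac`` of the series range."""
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("series must be nonempty")
    rng = float(x.max() - x.min())
    if rng == 0.0:
        return 0
    prominence = prominence_frac * rng if prominence_frac > 0 else None
    peaks, _ = sps.find_peaks(x, distance=min_distance, prominence=prominence)
    return int(peaks.size)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def count_repetitions(sig: SignalMatrix, seg: Segment,
                      cfg: dict[ActivityLabel, ActivityCounterConfig]
                      | None = None,
                      return_channel_counts: bool = False):
    """Count repetitions in one exercise segment.

    Each configured channel is sliced over [seg.start, seg.end), low-pass
    filtered and peak-counted; the averaged count is rounded half-up.  With
    automatic polarity each channel contributes max(peaks, troughs), so both
    downward and upward repetition excursions are counted.
    """
    if seg.label == ActivityLabel.BREAK:
        raise ValueError("repetitions are undefined for break segments")
    if seg.start < 0 or seg.end > sig.n_samples:
        raise ValueError("segment exceeds the recording")
    cfg = cfg or default_config()
    acfg = cfg[seg.label]
    counts = []
    for ch in acfg.channels:
        j = sig.channels.index(ch)
        x = sig.values[seg.start:seg.end, j]
        y = lowpass(x, acfg.filter_order, acfg.wn)
        n_peaks = count_peaks(y, acfg.min_distance, acfg.prominence_frac)
        if acfg.polarity == "peaks":
            counts.append(n_peaks)
        else:
            n_troughs = count_peaks(-y, acfg.min_distance,
                                    acfg.prominence_frac)
            counts.append(n_troughs if acfg.polarity == "troughs"
                          else max(n_peaks, n_troughs))
    predicted = _round_half_up(float(np.mean(counts)))
    return (predicted, counts) if return_channel_counts else predicted


@dataclass
class SegmentCount:
    """Counting outcome for one exercise segment."""

    label: ActivityLabel
    start: int
    end: int
    predicted: int
    channel_counts: tuple[int, ...]
    truth: int | None = None

    @property
    def error(self) -> int | None:
        return None if self.truth is None else abs(self.predicted - self.truth)


@dataclass
class RepetitionReport:
    """Per-segment counts plus protocol-level totals."""

    segments: tuple[SegmentCount, ...]

    @property
    def total_predicted(self) -> int:
        return sum(s.predicted for s in self.segments)

    @property
    def total_truth(self) -> int | None:
        if any(s.truth is None for s in self.segments):
            return None
        return sum(s.truth for s in self.segments)

    @property
    def total_miscount(self) -> int | None:
        if any(s.truth is None for s in self.segments):
            return None
        return sum(s.error for s in self.segments)


def count_protocol(sig: SignalMatrix, segments: tuple[Segment, ...],
                   cfg: dict[ActivityLabel, ActivityCounterConfig]
                   | None = None,
                   truth: Protocol | None = None) -> RepetitionReport:
    """Apply repetition counting to every exercise segment of a segmentation.

    ``segments`` may come from the recognition pipeline or from ground-truth
    annotations.  When ``truth`` is given, each counted segment is matched to
    the same-label ground-truth segment with maximal overlap and its true
    count is attached (None when no such segment overlaps).
    """
    cfg = cfg or default_config()
    out = []
    truth_ex = truth.exercise_segments() if truth is not None else ()
    for seg in segments:
        if seg.label == ActivityLabel.BREAK:
            continue
        pred, counts = count_repetitions(sig, seg, cfg,
                                         return_channel_counts=True)
        true_count = None
        if truth is not None:
            match = _best_overlap(seg, truth_ex)
            true_count = match.repetitions if match is not None else None
        out.append(SegmentCount(seg.label, seg.start, seg.end, pred,
                                tuple(counts), true_count))
    return RepetitionReport(tuple(out))


def _best_overlap(seg: Segment, candidates: tuple[Segment, ...]
                  ) -> Segment | None:
    best, best_ov = None, 0
    for cand in candidates:
        if cand.label != seg.label:
            continue
        ov = min(seg.end, cand.end) - max(seg.start, cand.start)
        if ov > best_ov:
            best, best_ov = cand, ov
    return best
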