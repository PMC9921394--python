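"""Post-processing block: from raw per-sample class probabilities to a
labelled segmentation and the recognized scenario.

Pipeline per class stream: forward moving-average smoothing, binarization at
a probability threshold, removal of short 1-runs (spurious activity peaks)
and filling of short 0-runs (dropout gaps).  Default run-length thresholds
(keep 1-runs longer than 90 samples, keep 0-runs longer than 60) sit just
under the shortest activity occurrence and break of the protocol corpus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import ActivityLabel, N_CLASSES, Segment
from .cnn import ProbabilityStream


@dataclass
class PPBConfig:
    w: int = 50                   # moving-average window, samples
    delta1: int = 90              # min 1-run length kept, samples
    delta0: int = 60              # min 0-run length kept, samples
    binarize_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.w < 1 or self.delta1 < 1 or self.delta0 < 1:
            raise ValueError("w, delta1, delta0 must all be >= 1")


def moving_average(y: np.ndarray, w: int) -> np.ndarray:
    """Forward moving average: out[i] = mean(y[i : i+w]), truncated tail.

    The last w-1 entries average over the remaining samples only; output
    length equals input length.
    """
    y = np.asarray(y, dtype=np.float64)
    if y.size == 0:
        raise ValueError("series must be nonempty")
    if w < 1:
        raise ValueError("w must be >= 1")
    n = y.size
    csum = np.concatenate([[0.0], np.cumsum(y)])
    hi = np.minimum(np.arange(n) + w, n)
    lo = np.arange(n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def binarize(p: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """1 where probability >= threshold, else 0 (per entry)."""
    return (np.asarray(p, dtype=np.float64) >= threshold).astype(np.int8)


def _run_lengths(b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Maximal-run decomposition: (values, lengths)."""
    b = np.asarray(b)
    change = np.flatnonzero(np.diff(b)) + 1
    bounds = np.concatenate([[0], change, [b.size]])
    return b[bounds[:-1]], np.diff(bounds)


def _apply_runs(values: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    return np.repeat(values, lengths)


def eliminate_peaks(b: np.ndarray, delta1: int) -> np.ndarray:
    """Zero out maximal 1-runs unless their length strictly exceeds delta1."""
    b = np.asarray(b, dtype=np.int8)
    if b.size == 0:
        return b
    vals, lens = _run_lengths(b)
    vals = vals.copy()
    vals[(vals == 1) & (lens <= delta1)] = 0
    return _apply_runs(vals, lens)


def fill_gaps(b: np.ndarray, delta0: int) -> np.ndarray:
    """Set to one maximal 0-runs unless their length strictly exceeds delta0."""
    b = np.asarray(b, dtype=np.int8)
    if b.size == 0:
        return b
    vals, lens = _run_lengths(b)
    vals = vals.copy()
    vals[(vals == 0) & (lens <= delta0)] = 1
    return _apply_runs(vals, lens)


def postprocess(stream: ProbabilityStream | np.ndarray,
                cfg: PPBConfig | None = None) -> np.ndarray:
    """Smooth, binarize and run-length-clean each class stream.

    Accepts a ProbabilityStream (expanded to its per-sample view) or an
    (n_samples, 4) probability matrix; returns an (n_samples, 4) binary
    matrix, one cleaned stream per class.
    """
    cfg = cfg or PPBConfig()
    probs = (stream.per_sample() if isinstance(stream, ProbabilityStream)
             else np.asarray(stream, dtype=np.float64))
    out = np.empty(probs.shape, dtype=np.int8)
    for k in range(probs.shape[1]):
        smoothed = moving_average(probs[:, k], cfg.w)
        b = binarize(smoothed, cfg.binarize_threshold)
        b = eliminate_peaks(b, cfg.delta1)
        b = fill_gaps(b, cfg.delta0)
        out[:, k] = b
    return out


def streams_to_segments(binaries: np.ndarray) -> tuple[Segment, ...]:
    """Collapse per-class binary streams into a labelled segmentation.

    Per-sample winner: the single active exercise class if exactly one is
    active; break if none is; if several exercise streams are simultaneously
    active, the one active for the longest contiguous stretch up to that
    sample wins (ties by class-index order).  Winners are compressed into
    maximal runs.
    """
    binaries = np.asarray(binaries)
    if binaries.ndim != 2 or binaries.shape[1] != N_CLASSES:
        raise ValueError("expected an (n_samples, 4) binary matrix")
    n = binaries.shape[0]
    ex = binaries[:, 1:].astype(bool)            # exercise streams only
    # contiguous run length of 1s ending at each sample, per class
    idx = np.arange(n)[:, None]
    last_zero = np.maximum.accumulate(np.where(~ex, idx, -1), axis=0)
    runlen = np.where(ex, idx - last_zero, 0)
    # winner: longest current run among active classes, ties -> lowest index
    masked = np.where(ex, runlen, -1)
    winner = np.where(ex.any(axis=1), 1 + masked.argmax(axis=1), 0)

    vals, lens = _run_lengths(winner)
    segs = []
    pos = 0
    for v, ln in zip(vals, lens):
        segs.append(Segment(ActivityLabel(int(v)), pos, pos + int(ln)))
        pos += int(ln)
    return tuple(segs)


def extract_scenario(segments: tuple[Segment, ...]
                     ) -> tuple[ActivityLabel, ...]:
    """Ordered non-break labels of a segmentation."""
    return tuple(s.label for s in segments if s.label != ActivityLabel.BREAK)


def recognize(stream: ProbabilityStream,
              cfg: PPBConfig | None = None
              ) -> tuple[tuple[Segment, ...], tuple[ActivityLabel, ...]]:
    """Full post-processing: probabilities -> segments + scenario."""
    segs = streams_to_segments(postprocess(stream, cfg))
    return segs, extract_scenario(segs)
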