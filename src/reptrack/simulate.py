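"""Synthetic protocol and accelerometer-signal generator.

The study corpus (78 recorded protocols, 488 activity occurrences) is not
public, so this module generates surrogate data with the same statistical
skeleton: the 15-scenario mix and its protocol counts, per-activity
repetition-count and per-repetition duration ranges, per-occurrence duration
ranges, the minimum 63-sample break, and the per-activity informative-channel
pattern used downstream for repetition counting.

Each repetition contributes one half-cosine excursion-and-return cycle on the
activity's informative channels (one countable extremum per repetition);
breaks are baseline plus noise plus sparse low-amplitude transients from
incidental movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signals import (
    CHANNELS, CHEST_Y, CHEST_Z, HAND_X, HAND_Z,
    ActivityLabel, ChannelId, Protocol, Segment, SignalMatrix,
)

DIP, PULLUP, SQUAT = (ActivityLabel.DIP, ActivityLabel.PULLUP,
                      ActivityLabel.SQUAT)

#: Scenario mix of the study protocol corpus: scenario -> number of protocols.
SCENARIO_PROTOCOL_COUNTS: dict[tuple[ActivityLabel, ...], int] = {
    (DIP,): 1,
    (PULLUP,): 2,
    (SQUAT,): 7,
    (DIP, SQUAT): 3,
    (PULLUP, SQUAT): 1,
    (SQUAT, DIP): 1,
    (SQUAT, SQUAT): 5,
    (DIP, PULLUP, SQUAT): 5,
    (DIP, SQUAT, PULLUP): 4,
    (PULLUP, DIP, SQUAT): 28,
    (PULLUP, SQUAT, DIP): 1,
    (SQUAT, DIP, PULLUP): 4,
    (SQUAT, PULLUP, DIP): 2,
    (SQUAT, SQUAT, SQUAT): 13,
    (PULLUP, DIP, SQUAT, SQUAT): 1,
}

#: Occurrence statistics of the study corpus: counts and duration (samples).
OCCURRENCE_STATS: dict[ActivityLabel, dict[str, int]] = {
    ActivityLabel.BREAK: {"count": 283, "min": 63, "avg": 382, "max": 1844},
    DIP: {"count": 50, "min": 135, "avg": 297, "max": 768},
    PULLUP: {"count": 48, "min": 91, "avg": 249, "max": 765},
    SQUAT: {"count": 107, "min": 157, "avg": 474, "max": 956},
}

#: Per-repetition statistics: count range and duration range (samples).
REPETITION_STATS: dict[ActivityLabel, dict[str, int]] = {
    DIP: {"count_min": 2, "count_max": 12, "dur_min": 48, "dur_max": 171},
    PULLUP: {"count_min": 1, "count_max": 14, "dur_min": 55, "dur_max": 220},
    SQUAT: {"count_min": 2, "count_max": 15, "dur_min": 33, "dur_max": 130},
}

#: Channels carrying the repetition movement, per activity.
INFORMATIVE_CHANNELS: dict[ActivityLabel, tuple[ChannelId, ...]] = {
    DIP: (CHEST_Z, HAND_X, HAND_Z),
    PULLUP: (CHEST_Y, CHEST_Z, HAND_Z),
    SQUAT: (CHEST_Z,),
}

#: Excursion direction on informative channels (body drops on dips/squats,
#: rises on pull-ups; the counting stage is polarity-agnostic).
_EXCURSION_SIGN: dict[tuple[ActivityLabel, ChannelId], float] = {
    (DIP, CHEST_Z): -1.0, (DIP, HAND_X): +1.0, (DIP, HAND_Z): -1.0,
    (PULLUP, CHEST_Y): +1.0, (PULLUP, CHEST_Z): +1.0, (PULLUP, HAND_Z): +1.0,
    (SQUAT, CHEST_Z): -1.0,
}


def _default_baseline() -> np.ndarray:
    # gravity projects onto the z axis of both sensors at rest
    base = np.zeros(len(CHANNELS))
    base[CHANNELS.index(CHEST_Z)] = 9.81
    base[CHANNELS.index(HAND_Z)] = 9.81
    return base


@dataclass
class GeneratorConfig:
    """Knobs of the surrogate-data generator.

    Defaults reproduce the study-protocol statistics; amplitudes and noise
    are stated modelling assumptions (the study published no signal model).
    """

    rate: float = 30.0
    scenario_weights: dict[tuple[ActivityLabel, ...], float] = field(
        default_factory=lambda: dict(SCENARIO_PROTOCOL_COUNTS))
    rep_count_range: dict[ActivityLabel, tuple[int, int]] = field(
        default_factory=lambda: {
            a: (REPETITION_STATS[a]["count_min"],
                REPETITION_STATS[a]["count_max"])
            for a in REPETITION_STATS})
    rep_duration_range: dict[ActivityLabel, tuple[int, int]] = field(
        default_factory=lambda: {
            a: (REPETITION_STATS[a]["dur_min"],
                REPETITION_STATS[a]["dur_max"])
            for a in REPETITION_STATS})
    occurrence_duration_range: dict[ActivityLabel, tuple[int, int]] = field(
        default_factory=lambda: {
            a: (OCCURRENCE_STATS[a]["min"], OCCURRENCE_STATS[a]["max"])
            for a in (DIP, PULLUP, SQUAT)})
    break_duration_range: tuple[int, int] = (
        OCCURRENCE_STATS[ActivityLabel.BREAK]["min"],
        OCCURRENCE_STATS[ActivityLabel.BREAK]["max"])
    informative_amplitude: float = 3.0   # m/s^2 on informative channels
    residual_amplitude: float = 1.0      # m/s^2 on other channels
    noise_sd: float = 0.3                # m/s^2 white noise, all channels
    baseline: np.ndarray = field(default_factory=_default_baseline)
    transient_rate: float = 0.05         # break transients per second
    transient_amplitude: float = 1.0     # m/s^2
    transient_duration: int = 20         # samples

    def __post_init__(self) -> None:
        if not self.scenario_weights:
            raise ValueError("scenario_weights must be nonempty")
        if any(w < 0 for w in self.scenario_weights.values()):
            raise ValueError("scenario weights must be nonnegative")
        if not any(self.scenario_weights.values()):
            raise ValueError("scenario weights must not all be zero")
        for rng_map in (self.rep_count_range, self.rep_duration_range,
                        self.occurrence_duration_range):
            for lo, hi in rng_map.values():
                if not (0 < lo <= hi):
                    raise ValueError("ranges must satisfy 0 < min <= max")
        lo, hi = self.break_duration_range
        if not (0 < lo <= hi):
            raise ValueError("break range must satisfy 0 < min <= max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        self.baseline = np.asarray(self.baseline, dtype=np.float64)

    def amplitude(self, activity: ActivityLabel, channel: ChannelId) -> float:
        if channel in INFORMATIVE_CHANNELS[activity]:
            return self.informative_amplitude
        return self.residual_amplitude

    def excursion_sign(self, activity: ActivityLabel,
                       channel: ChannelId) -> float:
        return _EXCURSION_SIGN.get((activity, channel), 1.0)


@dataclass(frozen=True)
class ProtocolSpec:
    """A sampled protocol: scenario plus every duration, before synthesis."""

    scenario: tuple[ActivityLabel, ...]
    rep_durations: tuple[tuple[int, ...], ...]  # one tuple per activity series
    break_durations: tuple[int, ...]            # len(scenario) + 1

    @property
    def rep_counts(self) -> tuple[int, ...]:
        return tuple(len(d) for d in self.rep_durations)


def _fit_durations(n_reps: int, rep_range: tuple[int, int],
                   occ_range: tuple[int, int],
                   rng: np.random.Generator) -> np.ndarray:
    """Draw per-repetition durations uniformly in ``rep_range``, then nudge
    the series total into the occurrence-duration range where feasible.

    Per-repetition bounds are the hard constraint; the occurrence maximum is
    relaxed when ``n_reps`` times the repetition minimum already exceeds it.
    """
    rep_lo, rep_hi = rep_range
    lo = max(occ_range[0], n_reps * rep_lo)
    hi = max(lo, min(occ_range[1], n_reps * rep_hi))
    d = rng.uniform(rep_lo, rep_hi, size=n_reps)
    for _ in range(3):
        total = d.sum()
        if lo <= total <= hi:
            break
        target = lo if total < lo else hi
        d = np.clip(d * (target / total), rep_lo, rep_hi)
    out = np.clip(np.round(d).astype(int), rep_lo, rep_hi)
    # rounding can nudge the total just below the occurrence minimum
    while out.sum() < lo and (out < rep_hi).any():
        out[int(np.argmin(out))] += 1
    return out


def sample_protocol(cfg: GeneratorConfig,
                    rng: np.random.Generator) -> ProtocolSpec:
    """Draw one protocol: scenario by configured weights, then counts and
    durations for every activity series and break."""
    scenarios = list(cfg.scenario_weights)
    w = np.array([cfg.scenario_weights[s] for s in scenarios], dtype=float)
    scenario = scenarios[rng.choice(len(scenarios), p=w / w.sum())]

    rep_durations = []
    for act in scenario:
        c_lo, c_hi = cfg.rep_count_range[act]
        n_reps = int(rng.integers(c_lo, c_hi + 1))
        d = _fit_durations(n_reps, cfg.rep_duration_range[act],
                           cfg.occurrence_duration_range[act], rng)
        rep_durations.append(tuple(int(x) for x in d))

    b_lo, b_hi = cfg.break_duration_range
    breaks = tuple(int(rng.integers(b_lo, b_hi + 1))
                   for _ in range(len(scenario) + 1))
    return ProtocolSpec(tuple(scenario), tuple(rep_durations), breaks)


def _rep_waveform(duration: int) -> np.ndarray:
    """Half-cosine excursion-and-return: 0 -> 1 -> 0 over ``duration``."""
    t = np.arange(duration)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * (t + 0.5) / duration))


def synthesize_protocol(spec: ProtocolSpec, cfg: GeneratorConfig,
                        rng: np.random.Generator
                        ) -> tuple[SignalMatrix, Protocol]:
    """Render a sampled protocol into a 6-channel signal plus ground truth."""
    segments: list[Segment] = []
    pieces: list[np.ndarray] = []
    cursor = 0
    m = len(CHANNELS)

    def add_break(duration: int) -> None:
        nonlocal cursor
        block = np.tile(cfg.baseline, (duration, 1))
        n_events = rng.poisson(cfg.transient_rate * duration / cfg.rate)
        for _ in range(n_events):
            dur = min(cfg.transient_duration, duration)
            start = int(rng.integers(0, max(duration - dur, 0) + 1))
            ch = int(rng.integers(0, m))
            amp = cfg.transient_amplitude * rng.uniform(0.5, 1.0)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            block[start:start + dur, ch] += sign * amp * _rep_waveform(dur)
        pieces.append(block)
        segments.append(Segment(ActivityLabel.BREAK, cursor, cursor + duration))
        cursor += duration

    def add_series(act: ActivityLabel, durations: tuple[int, ...]) -> None:
        nonlocal cursor
        length = sum(durations)
        block = np.tile(cfg.baseline, (length, 1))
        offset = 0
        for d in durations:
            wave = _rep_waveform(d)
            for j, ch in enumerate(CHANNELS):
                amp = cfg.amplitude(act, ch) * cfg.excursion_sign(act, ch)
                block[offset:offset + d, j] += amp * wave
            offset += d
        pieces.append(block)
        segments.append(Segment(act, cursor, cursor + length,
                                repetitions=len(durations)))
        cursor += length

    add_break(spec.break_durations[0])
    for act, durs, brk in zip(spec.scenario, spec.rep_durations,
                              spec.break_durations[1:]):
        add_series(act, durs)
        add_break(brk)

    values = np.vstack(pieces)
    if cfg.noise_sd > 0:
        values = values + rng.normal(0.0, cfg.noise_sd, size=values.shape)
    return (SignalMatrix(values, rate=cfg.rate, channels=CHANNELS),
            Protocol(tuple(segments)))


def generate_dataset(cfg: GeneratorConfig, n_protocols: int,
                     seed: int | np.random.SeedSequence
                     ) -> list[tuple[SignalMatrix, Protocol]]:
    """Draw ``n_protocols`` independent (signal, ground-truth) pairs."""
    if n_protocols < 1:
        raise ValueError("n_protocols must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_protocols):
        spec = sample_protocol(cfg, rng)
        out.append(synthesize_protocol(spec, cfg, rng))
    return out
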