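"""Stimulus schedules for the four-test rhythm battery.

The battery comprises two beat-tapping tests (metronome tapping, tempo
adaptation) and two memory/sequencing tests (drumming along to repeating
rhythmic sequences, reproducing a sequence from memory).  Every downstream
stage — scoring, simulation, extraction bookkeeping — works from the
schedules built here, so the planned onset timeline is the single source
of truth for each trial.

Timing conventions: all times are milliseconds from the start of the
trial's recording segment; each trial begins with a silent lead-in
(default 1000 ms) before its first scheduled onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GRID_RESOLUTION_MS = 200
CYCLE_MS = 3200
GRID_LENGTH = CYCLE_MS // GRID_RESOLUTION_MS
#: IOI multiset of every rhythmic sequence: five 200 ms, two 400 ms,
#: one 600 ms, one 800 ms (sums to one 3.2-s cycle, nine onsets).
SEQUENCE_IOI_MULTISET = (200, 200, 200, 200, 200, 400, 400, 600, 800)
#: Grid slots that fall on the implied beat (800-ms period).
BEAT_POSITIONS = (0, 4, 8, 12)

METRONOME_IOIS_MS = (667, 667, 500, 500, 333, 333)
METRONOME_N_BEATS = 40
ADAPTATION_BASE_IOI_MS = 500
ADAPTATION_POST_IOIS_MS = tuple(range(450, 551, 10))
ADAPTATION_N_POST = 5
DEFAULT_LEAD_IN_MS = 1000.0


class InvalidSequenceError(ValueError):
    """Raised when an IOI ordering is not a permutation of the protocol multiset."""


@dataclass(frozen=True)
class MetronomeTrial:
    """An isochronous pacing trial: ``n_beats`` onsets separated by ``ioi_ms``."""

    ioi_ms: float
    n_beats: int = METRONOME_N_BEATS
    lead_in_ms: float = DEFAULT_LEAD_IN_MS

    def __post_init__(self) -> None:
        if self.ioi_ms <= 0 or self.n_beats < 2:
            raise ValueError("ioi_ms must be positive and n_beats >= 2")

    @property
    def rate_hz(self) -> float:
        return 1000.0 / self.ioi_ms

    @property
    def onset_times_ms(self) -> np.ndarray:
        return self.lead_in_ms + self.ioi_ms * np.arange(self.n_beats)

    @property
    def duration_ms(self) -> float:
        return float(self.onset_times_ms[-1] + self.ioi_ms)


@dataclass(frozen=True)
class TempoShiftTrial:
    """A tempo-adaptation trial: 6-10 base-IOI onsets, then five at the post IOI.

    The gap bridging the base and post segments already carries the post IOI,
    so a shifted trial changes tempo at the first of the final five sounds.
    """

    n_base: int
    post_ioi_ms: float
    base_ioi_ms: float = ADAPTATION_BASE_IOI_MS
    n_post: int = ADAPTATION_N_POST
    lead_in_ms: float = DEFAULT_LEAD_IN_MS

    def __post_init__(self) -> None:
        if not 6 <= self.n_base <= 10:
            raise ValueError("n_base must lie in [6, 10]")
        if self.post_ioi_ms not in ADAPTATION_POST_IOIS_MS:
            raise ValueError(f"post_ioi_ms must be one of {ADAPTATION_POST_IOIS_MS}")

    @property
    def shifted(self) -> bool:
        return self.post_ioi_ms != self.base_ioi_ms

    @property
    def onset_times_ms(self) -> np.ndarray:
        gaps = np.concatenate([
            np.full(self.n_base - 1, self.base_ioi_ms),
            np.full(self.n_post, self.post_ioi_ms),
        ])
        return self.lead_in_ms + np.concatenate([[0.0], np.cumsum(gaps)])

    @property
    def duration_ms(self) -> float:
        return float(self.onset_times_ms[-1] + self.post_ioi_ms)


@dataclass(frozen=True)
class RhythmSequence:
    """One 3.2-s four-measure rhythmic cycle with nine onsets.

    ``metricality`` labels whether onsets align with the implied 800-ms beat
    ("strong": every beat-level grid slot carries an onset) or are maximally
    syncopated ("weak": only the downbeat does).
    """

    ioi_order_ms: tuple[int, ...]
    metricality: str

    def __post_init__(self) -> None:
        if tuple(sorted(self.ioi_order_ms)) != tuple(sorted(SEQUENCE_IOI_MULTISET)):
            raise InvalidSequenceError(
                f"IOI ordering {self.ioi_order_ms} is not a permutation of "
                f"{SEQUENCE_IOI_MULTISET}"
            )
        if self.metricality not in ("strong", "weak"):
            raise ValueError("metricality must be 'strong' or 'weak'")

    @property
    def cycle_ms(self) -> int:
        return CYCLE_MS

    @property
    def onset_offsets_ms(self) -> np.ndarray:
        """Onset times within one cycle (first onset at 0)."""
        return np.concatenate([[0], np.cumsum(self.ioi_order_ms[:-1])])

    @property
    def grid(self) -> np.ndarray:
        return grid_from_sequence(self)


def grid_from_sequence(seq: RhythmSequence) -> np.ndarray:
    """Binary hit/rest grid of the cycle at 200-ms resolution (length 16).

    Slot ``p`` is 1 iff an onset falls at ``200*p`` within the cycle; the
    cycle always starts with an onset so slot 0 is 1.
    """
    grid = np.zeros(GRID_LENGTH, dtype=int)
    grid[(seq.onset_offsets_ms // GRID_RESOLUTION_MS).astype(int)] = 1
    return grid


def sequence_from_grid(grid: Sequence[int], metricality: str = "strong") -> RhythmSequence:
    """Inverse of :func:`grid_from_sequence` for valid 9-hit grids."""
    grid = np.asarray(grid, dtype=int)
    if grid.shape != (GRID_LENGTH,) or grid[0] != 1:
        raise InvalidSequenceError("grid must have length 16 and start with a hit")
    onsets = np.flatnonzero(grid) * GRID_RESOLUTION_MS
    iois = np.diff(np.concatenate([onsets, [CYCLE_MS]]))
    return make_sequence(iois, metricality)


def make_sequence(ioi_order_ms: Iterable[int], metricality: str) -> RhythmSequence:
    """Validate an IOI ordering against the protocol multiset and wrap it."""
    return RhythmSequence(tuple(int(x) for x in ioi_order_ms), metricality)


def _beat_slot_count(order: tuple[int, ...]) -> int:
    onsets = np.concatenate([[0], np.cumsum(order[:-1])]) // GRID_RESOLUTION_MS
    return int(np.isin(BEAT_POSITIONS, onsets).sum())


def protocol_sequences(metricality: str, n: int) -> list[RhythmSequence]:
    """Deterministically enumerate ``n`` sequences of the requested metricality.

    The published protocol drew its sequences from a standard catalogue whose
    exact identities are not recorded here, so the battery enumerates all
    distinct permutations of the IOI multiset in lexicographic order and keeps
    those whose hit/rest grid has all four beat-level slots occupied (strong)
    or only the downbeat occupied (weak).  264 strong and 126 weak orderings
    exist, far more than any battery needs.
    """
    want = 4 if metricality == "strong" else 1
    out: list[RhythmSequence] = []
    for order in sorted(set(permutations(SEQUENCE_IOI_MULTISET))):
        if _beat_slot_count(order) == want:
            out.append(RhythmSequence(order, metricality))
            if len(out) == n:
                return out
    raise ValueError(f"only {len(out)} {metricality} sequences available")


def make_metronome_trials(lead_in_ms: float = DEFAULT_LEAD_IN_MS) -> list[MetronomeTrial]:
    """Six 40-beat metronome trials in the fixed order 667, 667, 500, 500, 333, 333 ms."""
    return [MetronomeTrial(ioi, lead_in_ms=lead_in_ms) for ioi in METRONOME_IOIS_MS]


def make_adaptation_trials(
    seed: int, lead_in_ms: float = DEFAULT_LEAD_IN_MS
) -> list[TempoShiftTrial]:
    """Fifty-five tempo-adaptation trials: five per post-shift IOI in 450..550 ms.

    Five trials keep the 500-ms base IOI (unshifted catch trials); the other
    fifty shift to a faster or slower tempo.  The number of base-tempo sounds
    per trial (6-10) and the trial order are drawn from ``seed``.
    """
    rng = np.random.default_rng(seed)
    post_iois = np.repeat(ADAPTATION_POST_IOIS_MS, 5).astype(float)
    rng.shuffle(post_iois)
    n_bases = rng.integers(6, 11, size=post_iois.size)
    return [
        TempoShiftTrial(int(nb), float(pi), lead_in_ms=lead_in_ms)
        for nb, pi in zip(n_bases, post_iois)
    ]


@dataclass(frozen=True)
class SequenceTrial:
    """A scheduled presentation of one rhythmic sequence.

    Drumming-along trials repeat the cycle ``n_repetitions`` = 10 times and
    are scored on repetitions 2-10.  Memory trials present it 3 times and
    append a silent pause of one cycle during which the participant reproduces
    the sequence; scoring happens on that virtual fourth repetition.
    """

    sequence: RhythmSequence
    n_repetitions: int
    pause_cycles: int = 0
    lead_in_ms: float = DEFAULT_LEAD_IN_MS

    @property
    def onset_times_ms(self) -> np.ndarray:
        reps = [
            self.lead_in_ms + k * CYCLE_MS + self.sequence.onset_offsets_ms
            for k in range(self.n_repetitions)
        ]
        return np.concatenate(reps)

    def repetition_grid_times_ms(self, repetition: int) -> np.ndarray:
        """Grid-slot times for repetition ``repetition`` (0-based).

        Valid also for the virtual repetition just past the presented ones
        (the reproduction window of a memory trial).
        """
        if not 0 <= repetition <= self.n_repetitions + self.pause_cycles - 1:
            raise ValueError("repetition outside trial timeline")
        start = self.lead_in_ms + repetition * CYCLE_MS
        return start + GRID_RESOLUTION_MS * np.arange(GRID_LENGTH)

    @property
    def duration_ms(self) -> float:
        return self.lead_in_ms + (self.n_repetitions + self.pause_cycles) * CYCLE_MS


def make_drumalong_trials(lead_in_ms: float = DEFAULT_LEAD_IN_MS) -> list[SequenceTrial]:
    """Four drumming-along trials: 2 strong + 2 weak sequences, 10 repetitions each."""
    seqs = protocol_sequences("strong", 2) + protocol_sequences("weak", 2)
    return [SequenceTrial(s, n_repetitions=10, lead_in_ms=lead_in_ms) for s in seqs]


def make_memory_trials(lead_in_ms: float = DEFAULT_LEAD_IN_MS) -> list[SequenceTrial]:
    """Thirty memory trials: 15 strong then 15 weak, 3 repetitions + 1-cycle pause."""
    seqs = protocol_sequences("strong", 15) + protocol_sequences("weak", 15)
    return [
        SequenceTrial(s, n_repetitions=3, pause_cycles=1, lead_in_ms=lead_in_ms)
        for s in seqs
    ]


@dataclass(frozen=True)
class BatteryPlan:
    """The full stimulus plan of one administration of the battery."""

    metronome_trials: tuple[MetronomeTrial, ...]
    adaptation_trials: tuple[TempoShiftTrial, ...]
    drumalong_trials: tuple[SequenceTrial, ...]
    memory_trials: tuple[SequenceTrial, ...]

    def iter_trials(self):
        for i, t in enumerate(self.metronome_trials):
            yield f"met_{i + 1:02d}", "metronome", t
        for i, t in enumerate(self.adaptation_trials):
            yield f"adp_{i + 1:02d}", "adaptation", t
        for i, t in enumerate(self.drumalong_trials):
            yield f"dal_{i + 1:02d}", "drumalong", t
        for i, t in enumerate(self.memory_trials):
            yield f"mem_{i + 1:02d}", "memory", t

    def trial(self, trial_id: str):
        for tid, _, t in self.iter_trials():
            if tid == trial_id:
                return t
        raise KeyError(trial_id)


def make_battery(seed: int, lead_in_ms: float = DEFAULT_LEAD_IN_MS) -> BatteryPlan:
    return BatteryPlan(
        metronome_trials=tuple(make_metronome_trials(lead_in_ms)),
        adaptation_trials=tuple(make_adaptation_trials(seed, lead_in_ms)),
        drumalong_trials=tuple(make_drumalong_trials(lead_in_ms)),
        memory_trials=tuple(make_memory_trials(lead_in_ms)),
    )


def schedule_frame(plan: BatteryPlan) -> pd.DataFrame:
    """Flatten a plan to a tidy table: trial_id, test, condition, onset_time_ms."""
    rows = []
    for trial_id, test, trial in plan.iter_trials():
        if test == "metronome":
            condition = f"ioi={trial.ioi_ms:g}"
        elif test == "adaptation":
            condition = f"post={trial.post_ioi_ms:g},n_base={trial.n_base}"
        else:
            condition = trial.sequence.metricality
        for t in trial.onset_times_ms:
            rows.append((trial_id, test, condition, round(float(t), 3)))
    return pd.DataFrame(rows, columns=["trial_id", "test", "condition", "onset_time_ms"])
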