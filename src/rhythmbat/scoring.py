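"""Scoring of the four rhythm tests from per-trial onset data.

Outcome measures, one per test:

* ``metronome_variability`` — SD of produced inter-tap intervals over the
  last twenty beats of each trial, divided by the stimulus IOI, averaged
  over the six trials (dimensionless; lower is better).
* ``adaptation_error_ms`` — mean over the fifty shifted trials of the mean
  absolute difference between the post-shift target IOI and the last two
  produced intervals (ms; lower is better).
* ``drumalong_pct`` — positional hit/rest agreement between the drummed and
  stimulus grids over repetitions 2-10 of each sequence, averaged over the
  four trials (%; higher is better).
* ``memory_pct`` — the same agreement computed on the virtual fourth
  repetition of each memory trial, averaged over thirty trials (%).

Missing-data policy: a trial with too few usable taps yields NaN and is
dropped from the participant mean; per-test completeness counts are kept
alongside the scores.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .battery import (
    GRID_RESOLUTION_MS,
    BatteryPlan,
    MetronomeTrial,
    SequenceTrial,
    TempoShiftTrial,
)
from .onsets import OnsetSeries

#: Half-width of the hit/rest window around each grid-slot onset time.
WINDOW_HALF_MS = GRID_RESOLUTION_MS / 2
#: Number of final beats analyzed per metronome trial.
METRONOME_ANALYZED_BEATS = 20

SCORE_COLUMNS = [
    "metronome_variability",
    "adaptation_error_ms",
    "drumalong_pct",
    "memory_pct",
    "awm",
    "digits_reversed",
]


def _match_taps_to_beats(
    tap_times: np.ndarray, beat_times: np.ndarray, ioi_ms: float
) -> np.ndarray:
    """Assign each beat its nearest tap within half an IOI; NaN where none.

    Extra taps (no beat within the tolerance, or beaten to a beat by a
    closer tap) are dropped.
    """
    matched = np.full(beat_times.size, np.nan)
    if tap_times.size == 0:
        return matched
    for b, bt in enumerate(beat_times):
        d = np.abs(tap_times - bt)
        j = int(np.argmin(d))
        if d[j] <= 0.5 * ioi_ms:
            # keep only if this beat is also the tap's nearest beat
            if int(np.argmin(np.abs(beat_times - tap_times[j]))) == b:
                matched[b] = tap_times[j]
    return matched


def metronome_trial_variability(
    drum: OnsetSeries,
    trial: MetronomeTrial,
    n_analyzed: int = METRONOME_ANALYZED_BEATS,
) -> float:
    """SD of produced intervals among taps on the last ``n_analyzed`` beats, / IOI.

    Returns NaN (missing-trial marker) when fewer than three taps land on
    analyzed beats, since at least two intervals are needed for a sample SD.
    """
    beats = trial.onset_times_ms[-n_analyzed:]
    matched = _match_taps_to_beats(drum.times_ms, beats, trial.ioi_ms)
    taps = matched[~np.isnan(matched)]
    if taps.size < 3:
        return math.nan
    return float(np.std(np.diff(np.sort(taps)), ddof=1) / trial.ioi_ms)


def metronome_tempo_deviation(
    drum: OnsetSeries,
    trial: MetronomeTrial,
    n_analyzed: int = METRONOME_ANALYZED_BEATS,
) -> float:
    """|mean produced interval - stimulus IOI| over the analyzed beats, in ms."""
    beats = trial.onset_times_ms[-n_analyzed:]
    matched = _match_taps_to_beats(drum.times_ms, beats, trial.ioi_ms)
    taps = matched[~np.isnan(matched)]
    if taps.size < 3:
        return math.nan
    return float(abs(np.mean(np.diff(np.sort(taps))) - trial.ioi_ms))


def mean_of_available(values) -> tuple[float, int]:
    """Participant-level mean over non-missing trials, with missing count."""
    arr = np.asarray(values, dtype=float)
    missing = int(np.isnan(arr).sum())
    if missing == arr.size:
        return math.nan, missing
    return float(np.nanmean(arr)), missing


def metronome_score(trial_values) -> tuple[float, int]:
    """Average the six per-trial variability values; report missing-trial count."""
    return mean_of_available(trial_values)


def adaptation_trial_error(drum: OnsetSeries, trial: TempoShiftTrial) -> float:
    """Mean |target IOI - produced IOI| over the last two produced intervals.

    Only shifted trials are scored.  "Produced" intervals are the final two
    inter-tap intervals among taps up to one post-shift IOI past the last
    scheduled sound; at least three post-shift taps are required, else the
    trial is marked missing (NaN).
    """
    if not trial.shifted:
        raise ValueError("adaptation error is defined only for shifted trials")
    onsets = trial.onset_times_ms
    shift_time = onsets[trial.n_base]  # first sound at the new tempo
    cutoff = onsets[-1] + trial.post_ioi_ms
    taps = drum.times_ms[drum.times_ms <= cutoff]
    if (taps > shift_time - 0.5 * trial.post_ioi_ms).sum() < 3:
        return math.nan
    intervals = np.diff(taps)[-2:]
    return float(np.mean(np.abs(trial.post_ioi_ms - intervals)))


def adaptation_score(trial_errors) -> tuple[float, int]:
    """Average the fifty shifted-trial errors; report missing-trial count."""
    return mean_of_available(trial_errors)


def drum_grid(drum: OnsetSeries, grid_times_ms: np.ndarray) -> np.ndarray:
    """Hit/rest grid of the drummed response over the given grid-slot times.

    Slot p is 1 iff at least one drum onset lies in [t_p - 100, t_p + 100).
    The half-open window makes adjacent slots tile time exactly: an onset
    exactly 100 ms before a slot's time belongs to that slot, not the
    previous one.
    """
    t = np.asarray(grid_times_ms, dtype=float)
    lo = np.searchsorted(drum.times_ms, t - WINDOW_HALF_MS, side="left")
    hi = np.searchsorted(drum.times_ms, t + WINDOW_HALF_MS, side="left")
    return (hi > lo).astype(int)


def grid_agreement(stim_grid, drum_grid_bits) -> float:
    """Percentage of grid positions where the two hit/rest grids agree."""
    a = np.asarray(stim_grid, dtype=int)
    b = np.asarray(drum_grid_bits, dtype=int)
    if a.shape != b.shape:
        raise ValueError("grids must have equal length")
    return float(100.0 * np.mean(a == b))


def drumalong_trial_score(
    drum: OnsetSeries, trial: SequenceTrial, first_scored_repetition: int = 1
) -> float:
    """Agreement over repetitions 2-10 of one drumming-along trial.

    ``first_scored_repetition`` is 0-based; the default skips the first
    repetition, during which the participant is still learning the pattern.
    """
    stim_grid = trial.sequence.grid
    scored = range(first_scored_repetition, trial.n_repetitions)
    grid_times = np.concatenate([trial.repetition_grid_times_ms(r) for r in scored])
    produced = drum_grid(drum, grid_times)
    expected = np.tile(stim_grid, len(scored))
    return grid_agreement(expected, produced)


def memory_trial_score(drum: OnsetSeries, trial: SequenceTrial) -> float:
    """Agreement on the virtual repetition following the presented ones.

    Grid windows are centered on the slot times the stimulus would have had,
    had it repeated once more; the participant reproduces the sequence from
    memory during this silent cycle.
    """
    virtual = trial.n_repetitions  # 0-based index of the pause cycle
    grid_times = trial.repetition_grid_times_ms(virtual)
    produced = drum_grid(drum, grid_times)
    return grid_agreement(trial.sequence.grid, produced)


def drumalong_score(trial_scores) -> tuple[float, int]:
    return mean_of_available(trial_scores)


def memory_score(trial_scores) -> tuple[float, int]:
    return mean_of_available(trial_scores)


def score_participant(
    plan: BatteryPlan, per_trial: dict[str, tuple[OnsetSeries, OnsetSeries]]
) -> dict[str, float]:
    """Compute all four rhythm scores for one participant's battery.

    ``per_trial`` maps trial_id -> (stimulus OnsetSeries, drum OnsetSeries),
    with trial-local times; the stimulus series is ignored here because the
    plan carries the authoritative schedule.
    """

    def drum_of(trial_id: str) -> OnsetSeries:
        if trial_id not in per_trial:
            return OnsetSeries(np.empty(0))
        return per_trial[trial_id][1]

    met_vals, dev_vals = [], []
    adp_vals, dal_vals, mem_vals = [], [], []
    for trial_id, test, trial in plan.iter_trials():
        drum = drum_of(trial_id)
        if test == "metronome":
            met_vals.append(metronome_trial_variability(drum, trial))
            dev_vals.append(metronome_tempo_deviation(drum, trial))
        elif test == "adaptation":
            if trial.shifted:
                adp_vals.append(adaptation_trial_error(drum, trial))
        elif test == "drumalong":
            dal_vals.append(drumalong_trial_score(drum, trial))
        else:
            mem_vals.append(memory_trial_score(drum, trial))

    met, met_miss = metronome_score(met_vals)
    dev, _ = mean_of_available(dev_vals)
    adp, adp_miss = adaptation_score(adp_vals)
    dal, dal_miss = drumalong_score(dal_vals)
    mem, mem_miss = memory_score(mem_vals)
    return {
        "metronome_variability": met,
        "adaptation_error_ms": adp,
        "drumalong_pct": dal,
        "memory_pct": mem,
        "tempo_deviation_ms": dev,
        "missing_trials": met_miss + adp_miss + dal_miss + mem_miss,
    }


def score_table(
    plan: BatteryPlan,
    cohort_onsets: dict[str, dict[str, tuple[OnsetSeries, OnsetSeries]]],
    verbal_scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score a whole cohort into one row per participant.

    ``verbal_scores`` (optional) is indexed by participant id with columns
    ``awm`` and ``digits_reversed``; these subtests are administered
    separately and merge into the table unchanged.
    """
    rows = []
    for pid, per_trial in cohort_onsets.items():
        row = {"participant_id": pid}
        row.update(score_participant(plan, per_trial))
        rows.append(row)
    table = pd.DataFrame(rows).set_index("participant_id")
    if verbal_scores is not None:
        table = table.join(verbal_scores[["awm", "digits_reversed"]])
    else:
        table["awm"] = np.nan
        table["digits_reversed"] = np.nan
    ordered = SCORE_COLUMNS + ["tempo_deviation_ms", "missing_trials"]
    return table[ordered]
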