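"""Onset extraction from continuous two-channel drum-trigger recordings.

Sessions are recorded as stereo audio: channel 1 carries a copy of the
stimulus playback, channel 2 the output of a vibration-sensitive drum
trigger.  Onsets are marked by a threshold-plus-refractory rule: a sample
is an onset iff its rectified amplitude strictly exceeds the amplitude
threshold and no sample in the preceding refractory window did.  The
refractory period keeps the many adjacent high-amplitude samples of a
single drum hit from being marked as several hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import wavfile


class DataError(ValueError):
    """Raised for malformed signals or onset files."""


@dataclass(frozen=True)
class ExtractionParams:
    """Marking parameters.

    amp_threshold
        Absolute amplitude above which a sample counts as loud, in the
        channel's own units.  ``None`` selects an adaptive default of 5x
        the channel's median absolute amplitude, emulating a per-recording
        manual threshold set just above the noise floor.
    refractory_ms
        Minimum silence (no supra-threshold sample) required before a new
        onset may be marked.  Default 50 ms, well below any protocol IOI.
    """

    amp_threshold: float | None = None
    refractory_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.amp_threshold is not None and self.amp_threshold <= 0:
            raise ValueError("amp_threshold must be positive")
        if self.refractory_ms <= 0:
            raise ValueError("refractory_ms must be positive")

    def resolve_threshold(self, channel: np.ndarray) -> float:
        if self.amp_threshold is not None:
            return self.amp_threshold
        mad = float(np.median(np.abs(channel)))
        return 5.0 * mad if mad > 0 else np.finfo(float).tiny


@dataclass(frozen=True)
class OnsetSeries:
    """Strictly increasing onset times (ms) with the peak amplitude at each."""

    times_ms: np.ndarray
    amplitudes: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        times = np.asarray(self.times_ms, dtype=float)
        object.__setattr__(self, "times_ms", times)
        if self.amplitudes is None:
            object.__setattr__(self, "amplitudes", np.full_like(times, np.nan))
        else:
            object.__setattr__(self, "amplitudes", np.asarray(self.amplitudes, dtype=float))
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("onset times must be strictly increasing")

    def __len__(self) -> int:
        return self.times_ms.size

    def shift(self, offset_ms: float) -> "OnsetSeries":
        return OnsetSeries(self.times_ms + offset_ms, self.amplitudes)


@dataclass(frozen=True)
class ContinuousRecording:
    """A two-channel session recording (stimulus playback + drum trigger)."""

    sample_rate_hz: float
    stimulus_channel: np.ndarray
    drum_channel: np.ndarray

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if len(self.stimulus_channel) != len(self.drum_channel):
            raise DataError("channels must have equal length")


def mark_onsets(
    channel: np.ndarray, sample_rate_hz: float, params: ExtractionParams
) -> OnsetSeries:
    """Mark onsets in one channel by the threshold-plus-refractory rule.

    A sample at time t is marked iff |x(t)| > threshold and no sample in the
    open interval (t - refractory_ms, t) exceeded the threshold.  The marked
    time is the crossing sample (no sub-sample interpolation); the recorded
    amplitude is the rectified peak within the refractory window that follows.
    """
    x = np.asarray(channel, dtype=float)
    if x.size == 0:
        return OnsetSeries(np.empty(0), np.empty(0))
    if not np.all(np.isfinite(x)):
        raise DataError("signal contains non-finite samples")
    thr = params.resolve_threshold(x)
    rect = np.abs(x)
    loud = np.flatnonzero(rect > thr)
    refractory_samples = params.refractory_ms * sample_rate_hz / 1000.0

    onset_idx: list[int] = []
    last = -np.inf
    for i in loud:  # loud samples only; a drum hit spans a handful of them
        if i - last >= refractory_samples:
            onset_idx.append(int(i))
        last = i
    idx = np.asarray(onset_idx, dtype=int)
    win = max(int(np.ceil(refractory_samples)), 1)
    amps = np.array([rect[i : i + win].max() for i in idx])
    return OnsetSeries(idx * 1000.0 / sample_rate_hz, amps)


def extract_recording(
    rec: ContinuousRecording,
    stim_params: ExtractionParams | None = None,
    drum_params: ExtractionParams | None = None,
) -> tuple[OnsetSeries, OnsetSeries]:
    """Mark onsets on both channels of a session recording."""
    stim_params = stim_params or ExtractionParams()
    drum_params = drum_params or ExtractionParams()
    stim = mark_onsets(rec.stimulus_channel, rec.sample_rate_hz, stim_params)
    drum = mark_onsets(rec.drum_channel, rec.sample_rate_hz, drum_params)
    return stim, drum


def split_by_trial(
    stim: OnsetSeries,
    drum: OnsetSeries,
    trial_windows: dict[str, tuple[float, float]],
    scheduled_counts: dict[str, int] | None = None,
) -> tuple[dict[str, tuple[OnsetSeries, OnsetSeries]], list[str]]:
    """Assign session-level onsets to trials by their recording windows.

    ``trial_windows`` maps trial_id -> (start_ms, end_ms), half-open on the
    right.  Returned per-trial series are re-referenced to the trial start.
    If ``scheduled_counts`` is given, a trial whose stimulus-onset count
    disagrees with the schedule is flagged for manual review (the session
    analogue of visually checking marked onsets against the raw trace).
    """
    out: dict[str, tuple[OnsetSeries, OnsetSeries]] = {}
    flags: list[str] = []
    for trial_id, (start, end) in trial_windows.items():
        if end <= start:
            raise ValueError(f"empty window for {trial_id}")
        s_mask = (stim.times_ms >= start) & (stim.times_ms < end)
        d_mask = (drum.times_ms >= start) & (drum.times_ms < end)
        s = OnsetSeries(stim.times_ms[s_mask] - start, stim.amplitudes[s_mask])
        d = OnsetSeries(drum.times_ms[d_mask] - start, drum.amplitudes[d_mask])
        out[trial_id] = (s, d)
        if scheduled_counts is not None and len(s) != scheduled_counts.get(trial_id, len(s)):
            flags.append(trial_id)
    return out, flags


# ---------------------------------------------------------------------------
# File I/O


def read_wav(path) -> ContinuousRecording:
    """Read a stereo WAV (PCM or float) as a session recording."""
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # corrupt header, truncated file, ...
        raise DataError(f"cannot read WAV file {path}: {exc}") from exc
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise DataError("expected a two-channel recording")
    return ContinuousRecording(float(rate), data[:, 0], data[:, 1])


def write_wav(path, rec: ContinuousRecording) -> None:
    data = np.stack([rec.stimulus_channel, rec.drum_channel], axis=1).astype(np.float32)
    wavfile.write(path, int(rec.sample_rate_hz), data)


def onsets_to_frame(
    per_trial: dict[str, tuple[OnsetSeries, OnsetSeries]]
) -> pd.DataFrame:
    """Tidy onset table: trial_id, channel (stimulus|drum), time_ms, amplitude."""
    rows = []
    for trial_id, (stim, drum) in per_trial.items():
        for name, series in (("stimulus", stim), ("drum", drum)):
            for t, a in zip(series.times_ms, series.amplitudes):
                rows.append((trial_id, name, round(float(t), 3), float(a)))
    return pd.DataFrame(rows, columns=["trial_id", "channel", "time_ms", "amplitude"])


def frame_to_onsets(df: pd.DataFrame) -> dict[str, tuple[OnsetSeries, OnsetSeries]]:
    """Inverse of :func:`onsets_to_frame`; tolerates missing amplitude column."""
    required = {"trial_id", "channel", "time_ms"}
    if not required.issubset(df.columns):
        raise DataError(f"onset table must have columns {sorted(required)}")
    out: dict[str, tuple[OnsetSeries, OnsetSeries]] = {}
    for trial_id, g in df.groupby("trial_id", sort=False):
        series = {}
        for name in ("stimulus", "drum"):
            sub = g[g["channel"] == name].sort_values("time_ms")
            amps = sub["amplitude"].to_numpy() if "amplitude" in sub else None
            series[name] = OnsetSeries(sub["time_ms"].to_numpy(), amps)
        out[str(trial_id)] = (series["stimulus"], series["drum"])
    return out
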