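"""Synthetic cohorts with dissociable beat-tapping and rhythm-memory skills.

Each simulated participant is generated from two independent standard-normal
latent abilities — ``beat_ability`` (sensorimotor synchronization) and
``memory_ability`` (rhythm sequence memory) — plus a verbal component shared
between the verbal-memory scores and ``memory_ability``.  Raw tapping onsets
for the full battery are produced trial by trial, so the complete pipeline
(onsets -> scoring -> statistics) can be exercised end to end and the
two-cluster dissociation becomes a parameter-recovery experiment.

Beat-tapping trials use a first-order linear phase-correction model with
two-source (timekeeper + motor) noise: writing a_k for the asynchrony of tap
k relative to stimulus onset k,

    a_{k+1} = (1 - alpha) a_k + (heard IOI - next IOI) + T_k + (M_{k+1} - M_k)

with phase-correction gain alpha, central timekeeper noise T ~ N(0, s_T^2)
and peripheral motor noise M ~ N(0, s_M^2).  The "heard" IOI is the most
recent stimulus interval, so a tempo shift injects a one-interval transient
that phase correction absorbs geometrically — the simulated participant
cannot anticipate the new tempo.  For an isochronous stimulus the asynchrony
is an AR(1)/ARMA(1,1) process with stationary variance s_T^2/(1-(1-alpha)^2)
when motor noise is zero.

Sequence trials use a probabilistic reproduction model: each stimulus hit is
reproduced with probability ``recall_fidelity`` at its grid time plus
Gaussian jitter, and each rest slot spawns a spurious tap with probability
``false_tap_rate``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .battery import (
    BatteryPlan,
    MetronomeTrial,
    SequenceTrial,
    TempoShiftTrial,
    make_battery,
)
from .onsets import OnsetSeries
from .scoring import score_table


@dataclass(frozen=True)
class LatentProfile:
    """Generative abilities of one simulated participant (z-scored)."""

    beat_ability: float
    memory_ability: float
    verbal_loading: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 <= self.verbal_loading <= 1.0:
            raise ValueError("verbal_loading must lie in [0, 1]")


@dataclass(frozen=True)
class TappingModelParams:
    """Linear phase-correction parameters for beat-tapping trials."""

    alpha: float
    timekeeper_sd_ms: float
    motor_sd_ms: float
    mean_asynchrony_ms: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 2.0:
            raise ValueError("alpha must lie in (0, 2) for stationarity")
        if self.timekeeper_sd_ms < 0 or self.motor_sd_ms < 0:
            raise ValueError("noise SDs must be non-negative")


@dataclass(frozen=True)
class MemoryModelParams:
    """Probabilistic sequence-reproduction parameters."""

    recall_fidelity: float
    jitter_sd_ms: float
    false_tap_rate: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.recall_fidelity <= 1.0:
            raise ValueError("recall_fidelity must lie in [0, 1]")
        if not 0.0 <= self.false_tap_rate <= 1.0:
            raise ValueError("false_tap_rate must lie in [0, 1]")
        if self.jitter_sd_ms < 0:
            raise ValueError("jitter_sd_ms must be non-negative")


@dataclass(frozen=True)
class SimulatorConfig:
    """Latent-to-parameter map constants and cohort-level settings.

    The map midpoints and slopes were calibrated once so that the default
    cohort's score distributions resemble the magnitudes typical of young
    adults drumming along to these tests (median normalized metronome
    variability near 0.04, tempo-adaptation errors of roughly 15-40 ms,
    sequence scores of roughly 60-95%).  Logistic/exponential squashings
    keep every parameter in its valid range for any latent value.
    """

    n_participants: int = 65
    latent_correlation: float = 0.0  # between beat and memory abilities
    verbal_loading: float = 0.4
    lead_in_ms: float = 1000.0
    # how strongly each test loads on its cluster's latent; the remainder is
    # test-specific ability variance, so that the two within-cluster score
    # correlations land near the characteristic 0.5 (beat) and 0.7 (memory)
    beat_commonality: float = 0.78
    memory_commonality: float = 0.88
    # beat_ability -> tapping params
    alpha_lo: float = 0.5
    alpha_hi: float = 0.95
    alpha_slope: float = 1.0
    timekeeper_mid_ms: float = 15.0
    timekeeper_slope: float = 0.35
    motor_mid_ms: float = 6.0
    motor_slope: float = 0.35
    mean_asynchrony_ms: float = -15.0
    # memory_ability -> sequence params
    fidelity_intercept: float = 1.2
    fidelity_slope: float = 0.9
    jitter_mid_ms: float = 35.0
    jitter_slope: float = 0.3
    false_rate_intercept: float = -2.2
    false_rate_slope: float = 0.4
    memory_difficulty: float = 0.85  # fidelity multiplier in memory mode
    # verbal standard scores (mean 100, SD 15)
    verbal_mean: float = 100.0
    verbal_sd: float = 15.0


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def params_from_profile(
    profile: LatentProfile, config: SimulatorConfig | None = None, rng=None
) -> tuple[TappingModelParams, MemoryModelParams, dict[str, float]]:
    """Map latent abilities to generative parameters and verbal scores.

    Higher ``beat_ability`` gives less timekeeper/motor noise and a
    phase-correction gain nearer 1; higher ``memory_ability`` gives higher
    recall fidelity, less jitter and fewer false taps.  Verbal scores load
    on ``memory_ability`` with weight ``verbal_loading`` plus independent
    noise (deterministic midpoints when no ``rng`` is supplied).
    """
    cfg = config or SimulatorConfig()
    b, m = profile.beat_ability, profile.memory_ability
    tapping = TappingModelParams(
        alpha=cfg.alpha_lo + (cfg.alpha_hi - cfg.alpha_lo) * _sigmoid(cfg.alpha_slope * b),
        timekeeper_sd_ms=cfg.timekeeper_mid_ms * np.exp(-cfg.timekeeper_slope * b),
        motor_sd_ms=cfg.motor_mid_ms * np.exp(-cfg.motor_slope * b),
        mean_asynchrony_ms=cfg.mean_asynchrony_ms,
    )
    memory = MemoryModelParams(
        recall_fidelity=_sigmoid(cfg.fidelity_intercept + cfg.fidelity_slope * m),
        jitter_sd_ms=cfg.jitter_mid_ms * np.exp(-cfg.jitter_slope * m),
        false_tap_rate=_sigmoid(cfg.false_rate_intercept - cfg.false_rate_slope * m),
    )
    vl = profile.verbal_loading
    resid = np.sqrt(1.0 - vl**2)
    noise = rng.normal(size=2) if rng is not None else np.zeros(2)
    verbal = {
        "awm": cfg.verbal_mean + cfg.verbal_sd * (vl * m + resid * noise[0]),
        "digits_reversed": cfg.verbal_mean + cfg.verbal_sd * (vl * m + resid * noise[1]),
    }
    return tapping, memory, verbal


def simulate_metronome_taps(
    trial: MetronomeTrial | TempoShiftTrial,
    params: TappingModelParams,
    seed=None,
) -> OnsetSeries:
    """Simulate phase-corrected tapping to a pacing trial.

    The first tap lands at the first stimulus onset plus
    ``mean_asynchrony_ms`` (the initial asynchrony); each later tap advances
    by the most recently heard stimulus IOI, corrected by ``alpha`` times
    the current asynchrony, plus timekeeper noise and the motor-delay
    difference.
    """
    rng = np.random.default_rng(seed)
    onsets = trial.onset_times_ms
    n = onsets.size
    rho = 1.0 - params.alpha
    heard = np.empty(n - 1)
    heard[0] = onsets[1] - onsets[0]
    heard[1:] = np.diff(onsets)[:-1]
    drive = heard - np.diff(onsets)  # nonzero only across a tempo shift
    t_noise = rng.normal(0.0, params.timekeeper_sd_ms, size=n - 1)
    motor = rng.normal(0.0, params.motor_sd_ms, size=n)
    u = drive + t_noise + np.diff(motor)

    a = np.empty(n)
    a[0] = params.mean_asynchrony_ms
    # a[k+1] = rho * a[k] + u[k], run as an IIR filter for speed
    a[1:], _ = lfilter([1.0], [1.0, -rho], u, zi=np.array([rho * a[0]]))
    return OnsetSeries(onsets + a)


def simulate_sequence_taps(
    trial: SequenceTrial,
    mparams: MemoryModelParams,
    mode: str,
    seed=None,
) -> OnsetSeries:
    """Simulate drummed responses to a rhythmic-sequence trial.

    In ``drumalong`` mode the participant listens to the first repetition and
    drums along with repetitions 2 onward; in ``memory`` mode taps are
    emitted only during the silent cycle where the virtual next repetition
    would fall.  Hits are reproduced with probability ``recall_fidelity`` at
    the slot time plus Gaussian jitter; rest slots spawn false taps with
    probability ``false_tap_rate``.
    """
    if mode not in ("drumalong", "memory"):
        raise ValueError("mode must be 'drumalong' or 'memory'")
    rng = np.random.default_rng(seed)
    grid = trial.sequence.grid.astype(bool)
    if mode == "drumalong":
        reps = range(1, trial.n_repetitions)
    else:
        reps = range(trial.n_repetitions, trial.n_repetitions + 1)
    times: list[np.ndarray] = []
    for r in reps:
        slot_times = trial.repetition_grid_times_ms(r)
        emit_p = np.where(grid, mparams.recall_fidelity, mparams.false_tap_rate)
        emit = rng.random(grid.size) < emit_p
        jitter = rng.normal(0.0, mparams.jitter_sd_ms, size=grid.size)
        times.append(slot_times[emit] + jitter[emit])
    t = np.sort(np.concatenate(times)) if times else np.empty(0)
    if t.size:  # enforce strict monotonicity after jitter
        t = t[np.concatenate([[True], np.diff(t) > 1e-9])]
    return OnsetSeries(t)


@dataclass(frozen=True)
class SimulatedCohort:
    """Raw battery onsets plus the generative truth table for one cohort."""

    plan: BatteryPlan
    onsets: dict  # participant_id -> trial_id -> (stimulus, drum) OnsetSeries
    truth: pd.DataFrame  # latent profiles, model params, verbal scores
    config: SimulatorConfig
    seed: int

    def score(self) -> pd.DataFrame:
        verbal = self.truth[["awm", "digits_reversed"]]
        return score_table(self.plan, self.onsets, verbal_scores=verbal)


def draw_profiles(n: int, config: SimulatorConfig, rng) -> list[LatentProfile]:
    """Draw latent abilities, optionally correlated across the two clusters."""
    r = config.latent_correlation
    z = rng.normal(size=(n, 2))
    beat = z[:, 0]
    memory = r * z[:, 0] + np.sqrt(1.0 - r**2) * z[:, 1]
    return [
        LatentProfile(float(b), float(m), config.verbal_loading)
        for b, m in zip(beat, memory)
    ]


def simulate_participant(
    plan: BatteryPlan,
    profile: LatentProfile,
    config: SimulatorConfig,
    seed_key: tuple[int, ...],
    verbal_rng,
) -> tuple[dict, dict[str, float]]:
    """Full-battery raw onsets for one participant, trial-addressable seeds.

    Each test loads on its cluster's latent ability with weight
    ``beat_commonality`` / ``memory_commonality``; the remainder is
    test-specific ability, so the four tests are imperfect indicators of
    the two latents rather than exact replicates of each other.
    """
    _, _, verbal = params_from_profile(profile, config, rng=verbal_rng)
    spec_rng = np.random.default_rng([*seed_key, 10_000])
    lb, lm = config.beat_commonality, config.memory_commonality
    eps = spec_rng.normal(size=4)
    effective = {
        "metronome": lb * profile.beat_ability + np.sqrt(1 - lb**2) * eps[0],
        "adaptation": lb * profile.beat_ability + np.sqrt(1 - lb**2) * eps[1],
        "drumalong": lm * profile.memory_ability + np.sqrt(1 - lm**2) * eps[2],
        "memory": lm * profile.memory_ability + np.sqrt(1 - lm**2) * eps[3],
    }
    test_params = {}
    for test, ability in effective.items():
        prof = LatentProfile(ability, ability, profile.verbal_loading)
        tp, mp, _ = params_from_profile(prof, config)
        test_params[test] = tp if test in ("metronome", "adaptation") else mp
    per_trial = {}
    for t_index, (trial_id, test, trial) in enumerate(plan.iter_trials()):
        trial_seed = (*seed_key, t_index)
        if test in ("metronome", "adaptation"):
            tapping = test_params[test]
            # scalar timing: central (timekeeper) noise grows with the
            # produced interval, referenced to the 500-ms base tempo
            ioi = trial.ioi_ms if test == "metronome" else trial.base_ioi_ms
            trial_tapping = dataclasses.replace(
                tapping, timekeeper_sd_ms=tapping.timekeeper_sd_ms * ioi / 500.0
            )
            drum = simulate_metronome_taps(trial, trial_tapping, seed=trial_seed)
        elif test == "drumalong":
            drum = simulate_sequence_taps(
                trial, test_params["drumalong"], "drumalong", seed=trial_seed
            )
        else:
            mp = test_params["memory"]
            mem_params = dataclasses.replace(
                mp, recall_fidelity=mp.recall_fidelity * config.memory_difficulty
            )
            drum = simulate_sequence_taps(trial, mem_params, "memory", seed=trial_seed)
        stim = OnsetSeries(trial.onset_times_ms)
        per_trial[trial_id] = (stim, drum)
    truth = {
        "beat_ability": profile.beat_ability,
        "memory_ability": profile.memory_ability,
        "alpha_metronome": test_params["metronome"].alpha,
        "timekeeper_sd_ms": test_params["metronome"].timekeeper_sd_ms,
        "motor_sd_ms": test_params["metronome"].motor_sd_ms,
        "recall_fidelity": test_params["memory"].recall_fidelity,
        "jitter_sd_ms": test_params["memory"].jitter_sd_ms,
        "false_tap_rate": test_params["memory"].false_tap_rate,
        **verbal,
    }
    return per_trial, truth


def simulate_cohort(
    n: int | None = None,
    seed: int = 0,
    config: SimulatorConfig | None = None,
) -> SimulatedCohort:
    """Simulate raw battery onsets for a cohort of ``n`` participants.

    All randomness flows from ``seed`` through named substreams
    (seed, participant, trial), so any single trial can be regenerated in
    isolation.  The battery plan (including the adaptation schedule) is
    shared by the whole cohort, as in a fixed test administration.
    """
    cfg = config or SimulatorConfig()
    n = cfg.n_participants if n is None else n
    if n < 4:
        raise ValueError("need at least 4 participants")
    plan = make_battery(seed, lead_in_ms=cfg.lead_in_ms)
    profile_rng = np.random.default_rng([seed, 0])
    profiles = draw_profiles(n, cfg, profile_rng)
    onsets, truth_rows = {}, []
    for p_index, profile in enumerate(profiles):
        pid = f"p{p_index + 1:04d}"
        verbal_rng = np.random.default_rng([seed, 1, p_index])
        per_trial, truth = simulate_participant(
            plan, profile, cfg, (seed, 2, p_index), verbal_rng
        )
        onsets[pid] = per_trial
        truth_rows.append({"participant_id": pid, **truth})
    truth_df = pd.DataFrame(truth_rows).set_index("participant_id")
    return SimulatedCohort(plan, onsets, truth_df, cfg, seed)


def simulate_scores(
    n: int | None = None, seed: int = 0, config: SimulatorConfig | None = None
) -> pd.DataFrame:
    """Convenience wrapper: simulate a cohort and score it in one call."""
    return simulate_cohort(n, seed, config).score()


def render_trial_wav(
    trial, drum: OnsetSeries, sample_rate_hz: float = 11025.0, click_ms: float = 3.0
):
    """Render one trial as a synthetic two-channel impulse-train recording.

    Each onset becomes a short rectangular click of amplitude 1.0 (stimulus
    channel) or 0.8 (drum channel) over a near-silent noise floor, giving
    the onset-extraction stage a faithful end-to-end exercise without any
    recorded audio.
    """
    from .onsets import ContinuousRecording

    duration_ms = trial.duration_ms
    n = int(np.ceil(duration_ms * sample_rate_hz / 1000.0)) + 1
    click = max(int(click_ms * sample_rate_hz / 1000.0), 1)
    stim = np.zeros(n)
    drum_sig = np.zeros(n)
    for t in trial.onset_times_ms:
        i = int(round(t * sample_rate_hz / 1000.0))
        stim[i : i + click] = 1.0
    for t in drum.times_ms:
        i = int(round(t * sample_rate_hz / 1000.0))
        if 0 <= i < n:
            drum_sig[i : i + click] = 0.8
    return ContinuousRecording(sample_rate_hz, stim, drum_sig)
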