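# Methods note

Modeling assumptions, parameter conventions and numerical choices behind
`rhythmbat`. The README gives the overview; this note records the
decisions a reader would otherwise have to reverse-engineer from code.

## Timing conventions

* All times are milliseconds from the start of a trial's recording
  segment; every trial begins with a silent lead-in (default 1000 ms).
* Rhythmic sequences live on a 16-slot grid at 200-ms resolution
  (3.2-s cycle). A slot is "hit" iff an onset falls exactly on it; the
  protocol multiset {200 × 5, 400 × 2, 600, 800} guarantees nine hits per
  cycle, always including slot 0.
* Grid windows are **half-open**: a drum onset belongs to slot *p* iff it
  lies in `[t_p − 100, t_p + 100)`. Adjacent windows therefore tile time
  exactly; an onset precisely 100 ms before a slot time belongs to that
  slot, never to two slots or none.
* Sequence identities are enumerated deterministically: all 1512 distinct
  permutations of the multiset in lexicographic order, filtered by
  metricality. "Strong" sequences carry onsets on all four 800-ms beat
  slots (0, 4, 8, 12; 264 exist); "weak" sequences only on slot 0
  (maximal syncopation under this operationalization; 126 exist). No
  fixture files are shipped — the catalogue is pure code.

## Onset extraction

A sample is an onset iff its rectified amplitude strictly exceeds the
threshold and no supra-threshold sample occurred within the preceding
refractory window (default 50 ms, well below every protocol IOI). The
marked time is the crossing sample, with no sub-sample interpolation; the
stored amplitude is the rectified peak over the following refractory
window. The default threshold is adaptive — 5× the channel's median
absolute amplitude — emulating a per-recording manual threshold set just
above the noise floor. Scale-invariance of the adaptive rule and
equivalence with a brute-force per-sample scan are tested properties.

## Scoring

* Metronome trials analyze only the last 20 of 40 beats (the entrained
  steady state). Taps are matched to beats mutual-nearest within half an
  IOI; a trial with fewer than three matched taps is missing (NaN) and
  drops out of the participant mean. A companion `tempo_deviation_ms`
  (|mean produced interval − IOI|) feeds the exclusion rules.
* Adaptation trials score only the 50 shifted trials: the mean absolute
  difference between the post-shift target IOI and the **last two**
  produced intervals, using taps up to one post-IOI past the final sound.
* Sequence scores are percent positional agreement between the stimulus
  hit/rest grid and the drummed grid — repetitions 2–10 for drumming
  along (repetition 1 is learning), the silent virtual repetition for
  memory trials. A silent participant scores 43.75% (the 7 rest slots of
  16 agree), which is the floor of the measure, not zero.

## Simulator

### Tapping model

First-order linear phase correction with two-source noise:

```
a_{k+1} = (1 − α) a_k + (heard IOI − next IOI) + T_k + (M_{k+1} − M_k)
```

* `α` ∈ (0, 2) is the phase-correction gain; `T ~ N(0, σ_T²)` is central
  timekeeper noise, `M ~ N(0, σ_M²)` peripheral motor delay noise.
* The **heard** IOI is the most recent stimulus interval. At a tempo
  shift the participant's period estimate is therefore one interval
  stale, producing a genuine transient (first post-shift tap off by the
  full shift) that phase correction absorbs geometrically. Using the
  upcoming IOI instead would make the simulated participant clairvoyant
  and the adaptation test trivial.
* Closed forms used as oracles: with zero noise on an isochronous
  stimulus, `a_k = a_0 (1 − α)^k`; with zero motor noise the asynchrony
  is AR(1) with stationary variance `σ_T² / (1 − (1 − α)²)`.
* Timekeeper noise scales linearly with the trial's base interval
  (σ_T · IOI/500), the standard scalar-timing (Weber) property, so the
  IOI-normalized variability measure is comparable across the three tempi.
* The recursion is executed with `scipy.signal.lfilter` (an IIR filter in
  the asynchrony), so 10⁵-tap trials used by the variance check run in
  milliseconds.

### Sequence model

Each hit slot is reproduced with probability `recall_fidelity` at its
grid time plus Gaussian jitter; each rest slot spawns a false tap with
probability `false_tap_rate`. Memory mode multiplies fidelity by a
difficulty factor (default 0.85) — reproducing from silence is harder
than drumming along. With fidelity 0.5 and no jitter/false taps the
expected memory score is 100 × (7 + 4.5)/16 = 71.875%, a tested
Monte-Carlo oracle.

### Latent structure

Two standard-normal latent abilities (optionally correlated) map to model
parameters through logistic/exponential squashings, keeping every
parameter in range for any latent value. Each test loads on its cluster's
latent with a commonality weight (0.78 beat, 0.88 memory); the remainder
is test-specific ability, so the four tests are imperfect indicators
rather than replicates — without this the within-cluster correlations
would approach the trial-sampling ceiling (~0.9) instead of realistic
values (~0.5–0.7). Verbal scores are standard scores (mean 100, SD 15)
loading 0.4 on the memory latent plus independent noise.

Map midpoints and slopes were calibrated **once**, before any acceptance
test existed, to land the default cohort near plausible young-adult
magnitudes (median normalized variability ≈ 0.05, adaptation errors
≈ 15–40 ms, sequence scores ≈ 60–95%); they are exposed on
`SimulatorConfig` and not tuned thereafter.

All randomness flows from one master seed through named substreams
(`[seed, stream, participant, trial]`), so any single trial can be
regenerated in isolation; derived seeds stay within 32-bit range.

## Statistics

* **Exclusions** (computed once on the full table, not iterated): any
  rhythm measure > 3 SD from the cohort mean, or a mean produced
  metronome tempo deviating > 5 ms from the stimulus tempo.
* **Transforms**: log for metronome variability (positive,
  right-skewed), rationalized arcsine `rau(p) = (146/π)·2·asin(√p) − 23`
  for the drumming-along proportion; normality checked by Jarque–Bera
  before and after.
* **Factor analysis** is generalized least squares:
  minimize `½·tr[(I − S⁻¹Σ)²]` for `Σ = ΛΛ' + Ψ`, profiled over the
  uniquenesses with the conditionally optimal loadings taken analytically
  from the eigenstructure of `Ψ^{1/2} S⁻¹ Ψ^{1/2}` (Jöreskog–Goldberger),
  started from squared multiple correlations, uniquenesses bounded below
  at 0.005 with solutions on that bound flagged as Heywood cases, then
  varimax-rotated (statsmodels), factors ordered by explained variance
  and sign-fixed so each column's largest loading is positive.

  **Degrees of freedom caveat**: with p = 4 measures and k = 2 factors,
  df = ((p − k)² − p − k)/2 = **−1**. The two-factor model of the
  four-test battery is under-identified; the optimum is an exact-fit
  region and the GLS global optimum genuinely sits at a near-Heywood
  corner (verified against unconstrained 12-parameter optimization).
  This is a property of the design, not of the implementation — published
  four-indicator/two-factor solutions show the same over-reproduction
  signature, with implied within-cluster correlations well above the
  observed ones. The rotated simple-structure *pattern* (which measure
  loads where), the quantity the dissociation argument rests on, is
  stable; the `heywood` flag and the unrotated loadings are exposed so
  users can see when the caveat applies. Exact recovery is instead tested
  on an identified 6-variable case (df = 4).
* **Hierarchical regressions** compare nested OLS models by the
  R² increment, `F = (ΔR²/q)/((1 − R²_full)/(n − k − 1))`: verbal scores
  then drumming-along predicting sequence memory (rhythm memory overlaps
  but exceeds verbal memory), and rhythm scores then `awm` predicting
  digit span (verbal memory exceeds rhythm memory).
* The dissociation verdict requires both within-cluster correlations to
  exceed every cross-cluster |r|. For the inversion control (latents
  correlated 0.9) the collapse is asserted on the first **unrotated**
  factor, because varimax by construction redistributes a general factor
  across rotated factors; error-type measures load with opposite sign to
  accuracy-type measures, hence magnitudes are compared.

## What the simulator does and does not emulate

Emulated: trial-by-trial tap timing, tempo-shift transients, scalar
timing, imperfect sequence recall with false taps, two-latent cohort
structure, verbal–memory overlap, recording-level audio (impulse trains)
for the extraction stage.

Not emulated: tempo drift / period correction as distinct from phase
correction, metricality-dependent memory difficulty, learning across
repetitions, motor constraints on very fast tapping, realistic drum
acoustics. Cohort-level calibration is approximate by necessity: no
population means/SDs for the four measures are available, only
illustrative magnitudes.

## Limitations

* The −1-df factor model is reported for fidelity to the analysis it
  mirrors, with the caveats above; the correlation pattern is the primary
  evidence.
* Problem sizes (n = 65 default, n = 1000 for the large-sample check) are
  this package's own choices, sized so the full pipeline runs in seconds
  to tens of seconds on one CPU.
* Onset extraction assumes trigger-like recordings (sparse, sharp
  transients); it is not a general music onset detector.
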