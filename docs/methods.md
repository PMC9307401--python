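# Methods

This note documents the models and estimators implemented in `prestim`,
the choices made where the design was genuinely open, and what the
synthetic-data validation does and does not demonstrate.

## The task and its two statistics

One session is a block of `n_trials` three-second trials. The subject
chooses the left square (large bet, value *X*) or the right square (small
bet, value 5); the reward parameter **E = X / 5** indexes the block's risk
level. One second after the choice the outcome (gain or loss, each with
probability ½) is revealed. Two quantities are computed at a frontal
midline channel (Fz by default):

**Prestimulus time (PT).** With d(t) the difference of the decision-locked
condition averages (left − right) on a window ending at the decision
marker, the crossing time t\* is the latest time at which d changes sign —
equivalently, the opening of the final run of constant-sign samples
reaching t = 0 — and PT = −t\*. A *separation tolerance* generalises "sign"
to "sign where |d| > tol": samples inside the ±tol band count as
not-yet-separated, and the crossing becomes the moment d last left the band
for good. With tol = 0 this reduces exactly to the last adjacent-sample
sign change (the oracle the tests compare against); crossings are linearly
interpolated between samples. Degenerate inputs: a difference that never
leaves the tolerance band raises a "no separation" error; a single-signed
difference returns the window length with `persistence_ok=False`; a
difference inside the band at t = 0 reports the latest crossing with
`persistence_ok=False`.

*Tolerance default in the pipeline:* 3 × the noise SD of d, estimated over
the signal-free baseline segment (−500…−400 ms) and pooled across all EEG
channels. Pooling matters: one channel's 100 ms baseline offers only ~5
independent samples after 30 Hz filtering, and an underestimated tolerance
lets slow background fluctuations masquerade as early separation. Even with
a stable tolerance, single-subject PT occasionally lands tens of ms early
when a slow noise excursion of the signal's sign abuts the true onset —
this is why group PT comparisons use a rank permutation statistic (below)
and why per-subject PT values and persistence flags are all reported.

**Feedback negativity (MFN) and Δ.** The latency is the argmax of
|loss − gain| inside 150–350 ms post-feedback (sample resolution, earliest
tie wins, boundary hits flagged). Δ = |gain − loss| at that latency. For
cohort analyses the pipeline models the component as a Gaussian peak
(the standard unimodal morphology of an averaged ERP): its width and centre
are fitted (with a linear nuisance) to the grand-average difference pooled
across blocks — the component's shape does not depend on the stake — and
every subject's loss/gain amplitude is the least-squares coefficient of the
resulting unit-peak template (constant + linear trend as nuisances). This
matched-filter score is unbiased when the subject waveform shares the
template shape and substantially less noisy than a single-sample read-out;
re-fitting only the centre per block gives the reported per-block latencies.
A GLS variant weighted by a single-trial noise covariance is available
(`gls_scored_amplitude`); it is not the pipeline default because, for this
noise process, the unweighted score was verified to sit within a few
percent of the exact-covariance GLS bound, so an *estimated* covariance
only adds noise.

**Group inference.** Means ± SD per block; between-block differences tested
by two-sided label-shuffling permutation (10,000 shuffles, add-one p-value,
seeded), loss vs gain within block by paired sign-flip permutation. The PT
between-block tests use a rank (permutation Mann–Whitney) statistic because
single-subject crossing estimates are heavy-tailed; Δ tests use the mean
statistic.

## Preprocessing chain

Stage order actually run (recorded in every report): continuous DC removal
(the "constant method" applied to the recording) → ocular handling →
epoch extraction → per-epoch baseline correction → amplitude rejection →
per-condition averaging → zero-phase low-pass → common average reference.

* **Windows.** Decision-locked epochs −500…0 ms with baseline −500…−400 ms;
  feedback-locked epochs −100…500 ms with baseline −100…0 ms. Windows are
  closed intervals on the sample grid (a −500…0 ms window at 500 Hz has 251
  samples including t = 0).
* **Ocular handling.** Two paths. *Labelling* (default): intervals where
  |VEOG| > 100 µV are blinks; any trial whose epoch overlaps one (±50 ms
  padding) is dropped with reason `"ocular"`. *ICA*: FastICA with as many
  components as EEG channels (fitted on a strided subset for long
  recordings), zeroing every component whose |Pearson r| with VEOG exceeds
  0.7. Labelling is the default because blink propagation to the scalp is
  only ~0.5–0.6 of the VEOG amplitude at frontopolar sites, so the plain
  ±100 µV EEG rejection misses many blinks, while ICA on a full 64-channel
  session is far more expensive than the rest of the chain combined.
* **Rejection.** Trials with any EEG sample beyond ±100 µV are dropped. The
  classical scan window is −200…500 ms; the pipeline scans each epoch's full
  extent (a blink at −400 ms corrupts the decision baseline just as surely).
* **Filter.** 4th-order Butterworth, 30 Hz, applied forward–backward
  (zero phase — PT is a latency statistic and phase distortion would bias
  it): DC gain 1, ≥48 dB down at 60 Hz. Applied to the evoked averages.
* **Reference.** Instantaneous mean of all EEG channels subtracted (EOG
  excluded); idempotent; EEG channels sum to zero at every sample.

## The simulator

`prestim.synth` emulates the study's recordings: a 64-channel 10-20/10-10
montage plus VEOG at 500 Hz, `n_trials` three-second trials, the decision
marker 1.5 s into each trial and feedback 1 s later, sides and outcomes
Bernoulli(½).

* **Pre-decision divergence** (left-choice trials only): zero until
  `divergence_onset_ms` before the decision, quadratic ease-out to the peak
  at −50 ms (where |left − right| is maximal), relaxation to 60% of peak at
  t = 0, release to zero by +100 ms. Default Fz peak −6 µV — the published
  waveform axes do not constrain it, so it is a free parameter set to a
  readiness-potential-like amplitude; the SNR consequence is that a
  300-trial session separates the conditions at ~10× the averaged noise.
* **Feedback component**: Gaussian, FWHM 60 ms, centred at
  `mfn_latency_ms` (default 232), per-condition Fz amplitudes from the
  block configuration.
* **Scalp maps** are zero-mean across EEG channels (i.e. expressed in
  average-reference space) and scaled to unit gain at Fz, so the configured
  amplitudes are exactly what a correct chain reads off at Fz: the
  pre-decision map is frontal-focal, the gain map anterior, the loss map
  carries an additional posterior lobe.
* **Noise**: independent per-channel 1/f (exponent 1, spectrum flattened
  below 0.1 Hz), normalised to RMS 5 µV per channel — a deliberately harsh
  but plausible single-trial SNR for a ~1 µV feedback effect.
* **Artifacts**: biphasic 150 ms blinks at 8/min, VEOG amplitude uniform
  150–400 µV, propagated to the scalp with weights decaying with distance
  from the frontopolar midline; occasional 1–3 s high-amplitude "bad
  blocks" (0.2/min) across all EEG channels.
* **Cohorts** jitter the divergence onset (SD 9 ms) and the two feedback
  amplitudes (SD 0.07 µV) per subject; subject *i* runs with seed
  `base + i`, so cohorts are reproducible and subject 0 with zero spread
  equals the single-session generator.

What the simulator does *not* model — and what recovery tests therefore do
not demonstrate about real data: spatially correlated background noise
(channel noise here is independent, which flatters any multichannel
pooling), line noise and muscle artifact, trial-to-trial latency jitter of
the components, volume-conduction-accurate topographies, and any
dependence of behaviour on outcomes (sides and outcomes are i.i.d.).

## Validation scales and expected precision

The recovery checks in `tests/test_acceptance.py` run three 12-subject,
300-trial cohorts (the package's scaled standard for a laptop-class
machine; ≈2 min total). Under these conditions the information floor for
the group-mean Δ is ≈0.10 µV (the matched filter was verified against the
exact-covariance GLS bound), so the ±0.15 µV recovery check operates at
about 1.5 standard errors per block; at the full 36-subject scale the same
check sits at ≈2.6 standard errors. Group-mean PT recovers the configured
onsets to within ≈10 ms (a small negative bias — the divergence must clear
the separation tolerance — plus ≈3–4 ms standard error).

## Formats

EDF+C with events as annotations (`blk:E=<v>`, `dec:<side>`,
`fb:<valence>`), 16-bit quantisation over per-channel symmetric ranges;
a TSV sidecar (`sample`, `label`) as fallback; an own archive for
epochs/evoked (8-byte magic, JSON header, little-endian float32 payload)
with CSV export. Reading validates the EDF structure first and reports
truncation with byte offsets, then delegates parsing to MNE.

## Known limitations

* Per-subject PT on low-SNR averages is heavy-tailed; with fewer than
  ~100 trials per condition the group mean should be treated with caution
  (the per-subject values are always reported).
* The Gaussian template is a morphology assumption; real feedback
  negativities are asymmetric, and the matched-filter score inherits any
  shape mismatch as a proportional bias.
* The EDF writer pads the final data record with edge values when the
  recording length is not a whole number of record durations.
* ICA-based ocular removal assumes stationary blink topography and
  full-rank data; rank-deficient recordings are rejected with a diagnosis.
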