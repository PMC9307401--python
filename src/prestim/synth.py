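"""Synthetic gambling-task EEG sessions with known ground truth.

The generator emulates the recordings of a loss-gain gambling experiment:
a 64-channel 10-20 montage plus a vertical EOG channel, 3-second trials in
which the subject picks the left (large bet) or right (small bet) square,
and feedback (gain or loss, equal probability) one second after the choice.

Injected structure, all of it recorded as ground truth:

* a pre-decision frontal negativity on left-choice (large-bet) trials whose
  departure from zero starts ``divergence_onset_ms`` before the decision
  marker and peaks 50 ms before it -- the substrate of the prestimulus-time
  (PT) statistic;
* a feedback-locked medial-frontal component peaking at ``mfn_latency_ms``
  (default 232 ms) whose Fz amplitude differs between loss and gain trials;
* 1/f background noise, blink transients exceeding 100 uV on VEOG that
  propagate to frontal scalp sites, and occasional high-amplitude "bad
  block" artifacts.

Component scalp maps are zero-mean across the EEG channels (i.e. expressed
against an average reference) and scaled to unit gain at Fz, so the
configured amplitudes are what a correctly implemented analysis chain
should read off at Fz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from . import montage
from .containers import Event, EventList, RawRecording

__all__ = [
    "ExperimentConfig",
    "EffectSpec",
    "CohortSpread",
    "SyntheticTruth",
    "generate_session",
    "generate_cohort",
    "iter_cohort",
    "trials_in_block",
]


def trials_in_block(block_duration_s: float = 900.0, trial_duration_s: float = 3.0) -> int:
    """Number of choices that fit in one experimental block.

    A 15-minute block of 3-second trials yields 300 choices.
    """
    if trial_duration_s <= 0:
        raise ValueError("trial_duration_s must be positive")
    return int(round(block_duration_s / trial_duration_s))


@dataclass(frozen=True)
class ExperimentConfig:
    """Design of one recording session (one experimental block).

    ``left_value`` and ``right_value`` are the two bet sizes in currency
    units; their ratio is the reward parameter E that indexes the block's
    risk level.
    """

    left_value: float
    right_value: float = 5.0
    n_trials: int = 300
    trial_duration: float = 3.0  # seconds per choice
    sampling_rate: float = 500.0  # Hz
    channel_names: tuple[str, ...] = field(
        default_factory=montage.default_channel_names
    )
    seed: int = 0
    veog_channel: str = montage.VEOG
    decision_offset_s: float = 1.5  # decision marker position within a trial

    def __post_init__(self) -> None:
        if self.right_value <= 0:
            raise ValueError("right_value must be positive")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")
        # The analysis chain low-passes at 30 Hz; leave generous headroom.
        if self.sampling_rate <= 60.0:
            raise ValueError("sampling_rate must exceed twice the 30 Hz cutoff")
        if "Fz" not in self.channel_names:
            raise ValueError("montage must include Fz")
        if self.veog_channel not in self.channel_names:
            raise ValueError(f"montage must include the {self.veog_channel} channel")
        if not (0 < self.decision_offset_s < self.trial_duration - 0.6):
            raise ValueError(
                "decision marker must leave >= 0.6 s for feedback analysis "
                "before the trial ends"
            )

    @property
    def E(self) -> float:
        """Reward parameter: left bet divided by right bet."""
        return self.left_value / self.right_value


@dataclass(frozen=True)
class EffectSpec:
    """Requested effect structure of a session (the generator's dials).

    Template amplitudes refer to Fz in average-reference space.
    """

    divergence_onset_ms: float = 107.0  # before the decision marker
    divergence_amplitude_uv: float = -6.0  # left-minus-right Fz peak
    divergence_peak_ms: float = 50.0  # |difference| maximal this long before 0
    divergence_end_fraction: float = 0.6  # fraction of peak remaining at t=0
    mfn_latency_ms: float = 232.0  # after the feedback marker
    mfn_width_ms: float = 60.0  # FWHM of the feedback component
    loss_amplitude_uv: float = -0.34  # Fz amplitude at the component peak
    gain_amplitude_uv: float = +0.37
    noise_rms_uv: float = 5.0  # per-channel 1/f noise RMS
    blink_rate_per_min: float = 8.0
    bad_block_rate_per_min: float = 0.2

    def __post_init__(self) -> None:
        if self.divergence_onset_ms <= 0:
            raise ValueError("divergence_onset_ms must be positive")
        if self.divergence_peak_ms <= 0:
            raise ValueError("divergence_peak_ms must be positive")
        if self.divergence_onset_ms <= self.divergence_peak_ms:
            raise ValueError("divergence onset must precede its peak")
        if self.mfn_width_ms <= 0:
            raise ValueError("mfn_width_ms must be positive")
        if self.noise_rms_uv < 0 or self.blink_rate_per_min < 0:
            raise ValueError("noise RMS and blink rate must be non-negative")
        if self.bad_block_rate_per_min < 0:
            raise ValueError("bad_block_rate_per_min must be non-negative")


@dataclass(frozen=True)
class CohortSpread:
    """Between-subject normal perturbations applied by :func:`generate_cohort`."""

    onset_sd_ms: float = 9.0  # SD of the divergence onset across subjects
    amplitude_sd_uv: float = 0.07  # SD of loss/gain component amplitudes

    def __post_init__(self) -> None:
        if self.onset_sd_ms < 0 or self.amplitude_sd_uv < 0:
            raise ValueError("between-subject SDs must be non-negative")


@dataclass
class SyntheticTruth:
    """Ground truth actually realised in one generated session."""

    divergence_onset: float  # ms before the decision marker
    mfn_latency: float  # ms after the feedback marker
    loss_amplitude: float  # uV at Fz at the component peak
    gain_amplitude: float  # uV
    blink_times: np.ndarray  # blink peak times, seconds
    bad_block_intervals: list[tuple[float, float]]  # seconds

    @property
    def delta(self) -> float:
        """|gain - loss| amplitude difference, the Δ the analysis recovers."""
        return abs(self.gain_amplitude - self.loss_amplitude)


# ---------------------------------------------------------------------------
# signal building blocks


def _pink_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    sampling_rate: float,
    rms: float,
    exponent: float = 1.0,
    f_min: float = 0.1,
) -> np.ndarray:
    """Independent 1/f^exponent noise per channel, normalised to a target RMS.

    The spectrum is flattened below ``f_min`` so the variance stays finite;
    the DC bin is zero.
    """
    if rms == 0 or n_samples == 0:
        return np.zeros((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = np.maximum(freqs[nz], f_min) ** (-exponent / 2.0)
    spec = (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    ) * shape
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    current = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    current[current == 0] = 1.0
    return x * (rms / current)


def _zero_mean_fz_map(
    raw_weights: np.ndarray, eeg_idx: np.ndarray, fz_idx: int
) -> np.ndarray:
    """Centre a scalp weight map across EEG channels and set unit gain at Fz."""
    w = raw_weights.astype(float).copy()
    w -= w[eeg_idx].mean()
    if abs(w[fz_idx]) < 1e-6:
        raise ValueError("scalp map degenerate at Fz after centring")
    w /= w[fz_idx]
    return w


def _gaussian_blob(
    positions: np.ndarray, centre: np.ndarray, width: float
) -> np.ndarray:
    d2 = np.sum((positions - centre[None, :]) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * width**2))


def _component_maps(
    channel_names: tuple[str, ...], positions: np.ndarray
) -> dict[str, np.ndarray]:
    """Scalp maps for the injected components (zero-mean, unit gain at Fz).

    The pre-decision negativity is frontal-midline focal; the loss component
    carries an additional same-sign posterior lobe and the gain component is
    anterior-focal, echoing the qualitative loss/gain scalp distributions
    this task elicits.
    """
    names = list(channel_names)
    eeg_idx = np.array(
        [i for i, n in enumerate(names) if not montage.is_eog(n)], dtype=int
    )
    fz = names.index("Fz")

    # blob centres in head-circle coordinates (y is anterior), so the maps
    # do not depend on which optional 10-10 sites the montage carries
    frontal = _gaussian_blob(positions, positions[fz], 0.45)
    gain = _gaussian_blob(positions, np.array([0.0, 0.65]), 0.45)
    loss = 0.7 * _gaussian_blob(positions, np.array([0.0, 0.25]), 0.5) + (
        0.8 * _gaussian_blob(positions, np.array([0.0, -0.75]), 0.5)
    )
    maps = {}
    for name, w in (("divergence", frontal), ("gain", gain), ("loss", loss)):
        w = w.copy()
        w[[i for i in range(len(names)) if montage.is_eog(names[i])]] = 0.0
        maps[name] = _zero_mean_fz_map(w, eeg_idx, fz)
        maps[name][
            [i for i in range(len(names)) if montage.is_eog(names[i])]
        ] = 0.0
    return maps


def _divergence_profile(
    sampling_rate: float,
    onset_ms: float,
    peak_ms: float,
    end_fraction: float,
    release_ms: float = 100.0,
) -> tuple[np.ndarray, int]:
    """Unit-amplitude time course of the pre-decision divergence.

    Quadratic ease-out from zero at ``-onset_ms`` to 1 at ``-peak_ms`` (a
    steep initial departure, matching the abrupt late separation of the
    condition averages), linear relaxation to ``end_fraction`` at the
    decision marker, then linear release to zero ``release_ms`` after it.

    Returns the profile and the sample offset of its first sample relative
    to the decision marker (negative).
    """
    step_ms = 1000.0 / sampling_rate
    first = -int(np.ceil(onset_ms / step_ms))
    last = int(np.ceil(release_ms / step_ms))
    t = np.arange(first, last + 1) * step_ms  # ms relative to decision
    p = np.zeros_like(t)
    rise = (t >= -onset_ms) & (t <= -peak_ms)
    u = (t[rise] + onset_ms) / (onset_ms - peak_ms)
    p[rise] = 1.0 - (1.0 - u) ** 2
    plateau = (t > -peak_ms) & (t <= 0)
    p[plateau] = 1.0 + (end_fraction - 1.0) * (t[plateau] + peak_ms) / peak_ms
    release = (t > 0) & (t <= release_ms)
    p[release] = end_fraction * (1.0 - t[release] / release_ms)
    return p, first


def _mfn_profile(
    sampling_rate: float, latency_ms: float, fwhm_ms: float
) -> tuple[np.ndarray, int]:
    """Unit-amplitude Gaussian feedback component, peak at ``latency_ms``."""
    sigma_ms = fwhm_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    step_ms = 1000.0 / sampling_rate
    half = int(np.ceil(4.0 * sigma_ms / step_ms))
    centre = int(round(latency_ms / step_ms))
    t = np.arange(centre - half, centre + half + 1) * step_ms
    p = np.exp(-((t - latency_ms) ** 2) / (2.0 * sigma_ms**2))
    return p, centre - half


def _blink_shape(sampling_rate: float) -> np.ndarray:
    """Biphasic 150 ms blink transient, unit positive peak."""
    n_pos = int(round(0.100 * sampling_rate))
    n_neg = int(round(0.050 * sampling_rate))
    pos = np.sin(np.linspace(0.0, np.pi, n_pos, endpoint=False))
    neg = -0.25 * np.sin(np.linspace(0.0, np.pi, n_neg, endpoint=False))
    return np.concatenate([pos, neg])


def _add_at(target: np.ndarray, start: int, segment: np.ndarray) -> None:
    """Add ``segment`` (channels x L or L) into ``target`` clipped at edges."""
    n = target.shape[-1]
    length = segment.shape[-1]
    lo = max(start, 0)
    hi = min(start + length, n)
    if hi <= lo:
        return
    target[..., lo:hi] += segment[..., lo - start : hi - start]


# ---------------------------------------------------------------------------
# session / cohort generation


def generate_session(
    config: ExperimentConfig, effects: EffectSpec | None = None
) -> tuple[RawRecording, EventList, SyntheticTruth]:
    """Generate one continuous gambling-task session with ground truth.

    Deterministic for a given ``config.seed``: running twice returns
    byte-identical recordings.
    """
    effects = effects if effects is not None else EffectSpec()
    if effects.divergence_onset_ms / 1000.0 >= config.decision_offset_s:
        raise ValueError(
            "divergence onset reaches past the start of the trial: "
            f"{effects.divergence_onset_ms} ms before a decision marker placed "
            f"{config.decision_offset_s * 1000:.0f} ms into the trial"
        )
    if effects.divergence_onset_ms >= config.trial_duration * 1000.0:
        raise ValueError("divergence onset must be shorter than the trial")

    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n_ch = len(config.channel_names)
    n_samples = int(round(config.n_trials * config.trial_duration * fs))
    positions = montage.positions_2d(config.channel_names)
    names = list(config.channel_names)
    veog_idx = names.index(config.veog_channel)
    maps = _component_maps(config.channel_names, positions)

    # trial schedule -------------------------------------------------------
    decision_samples = (
        np.round(
            (np.arange(config.n_trials) * config.trial_duration
             + config.decision_offset_s) * fs
        ).astype(int)
    )
    feedback_delay = int(round(1.0 * fs))
    sides = np.where(rng.random(config.n_trials) < 0.5, "left", "right")
    outcomes = np.where(rng.random(config.n_trials) < 0.5, "gain", "loss")

    data = np.zeros((n_ch, n_samples))

    # deterministic ERP templates -----------------------------------------
    div_profile, div_first = _divergence_profile(
        fs,
        effects.divergence_onset_ms,
        effects.divergence_peak_ms,
        effects.divergence_end_fraction,
    )
    div_seg = (
        effects.divergence_amplitude_uv * maps["divergence"][:, None] * div_profile
    )
    mfn_profile, mfn_first = _mfn_profile(
        fs, effects.mfn_latency_ms, effects.mfn_width_ms
    )
    loss_seg = effects.loss_amplitude_uv * maps["loss"][:, None] * mfn_profile
    gain_seg = effects.gain_amplitude_uv * maps["gain"][:, None] * mfn_profile

    for i in range(config.n_trials):
        dec = decision_samples[i]
        if sides[i] == "left":
            _add_at(data, dec + div_first, div_seg)
        fb = dec + feedback_delay
        seg = gain_seg if outcomes[i] == "gain" else loss_seg
        _add_at(data, fb + mfn_first, seg)

    # noise ---------------------------------------------------------------
    if effects.noise_rms_uv > 0:
        data += _pink_noise(rng, n_ch, n_samples, fs, effects.noise_rms_uv)

    # blinks --------------------------------------------------------------
    duration_s = n_samples / fs
    n_blinks = rng.poisson(effects.blink_rate_per_min * duration_s / 60.0)
    blink_times = np.sort(rng.uniform(0.0, duration_s, size=n_blinks))
    if n_blinks:
        shape = _blink_shape(fs)
        # Propagation from the eyes: full amplitude at VEOG, decaying with
        # distance from the frontopolar midline over the scalp.
        fpz_pos = positions[names.index("Fpz")]
        dist = np.linalg.norm(positions - fpz_pos[None, :], axis=1)
        weights = np.exp(-dist / 0.3)
        weights[veog_idx] = 1.0
        for t0 in blink_times:
            amp = rng.uniform(150.0, 400.0)
            start = int(round(t0 * fs)) - shape.size // 2
            _add_at(data, start, amp * weights[:, None] * shape[None, :])

    # bad blocks ----------------------------------------------------------
    n_bad = rng.poisson(effects.bad_block_rate_per_min * duration_s / 60.0)
    bad_intervals: list[tuple[float, float]] = []
    if n_bad:
        eeg_idx = np.array(
            [i for i, n in enumerate(names) if not montage.is_eog(n)], dtype=int
        )
        for _ in range(n_bad):
            t0 = rng.uniform(0.0, max(duration_s - 3.0, 0.0))
            length = rng.uniform(1.0, 3.0)
            bad_intervals.append((t0, t0 + length))
            n_seg = int(round(length * fs))
            lump = rng.uniform(150.0, 300.0) * np.sin(
                np.linspace(0.0, np.pi, n_seg)
            )
            ch_w = rng.uniform(0.5, 1.0, size=eeg_idx.size) * rng.choice(
                [-1.0, 1.0], size=eeg_idx.size
            )
            seg = ch_w[:, None] * lump[None, :]
            full = np.zeros((n_ch, n_seg))
            full[eeg_idx] = seg
            _add_at(data, int(round(t0 * fs)), full)

    raw = RawRecording(
        data=data,
        sampling_rate=fs,
        channel_names=config.channel_names,
        montage_positions=positions,
        reference_label="average",
    )
    events = EventList(
        events=[
            Event(
                sample=int(decision_samples[i]),
                decision_side=str(sides[i]),
                feedback=str(outcomes[i]),
                block_E=config.E,
            )
            for i in range(config.n_trials)
        ],
        sampling_rate=fs,
        feedback_delay_s=1.0,
    )
    truth = SyntheticTruth(
        divergence_onset=effects.divergence_onset_ms,
        mfn_latency=effects.mfn_latency_ms,
        loss_amplitude=effects.loss_amplitude_uv,
        gain_amplitude=effects.gain_amplitude_uv,
        blink_times=blink_times,
        bad_block_intervals=bad_intervals,
    )
    return raw, events, truth


def _subject_effects(
    base: EffectSpec, spread: CohortSpread, rng: np.random.Generator
) -> EffectSpec:
    onset = base.divergence_onset_ms + spread.onset_sd_ms * rng.standard_normal()
    onset = max(onset, base.divergence_peak_ms + 10.0)
    loss = base.loss_amplitude_uv + spread.amplitude_sd_uv * rng.standard_normal()
    gain = base.gain_amplitude_uv + spread.amplitude_sd_uv * rng.standard_normal()
    return replace(
        base,
        divergence_onset_ms=onset,
        loss_amplitude_uv=loss,
        gain_amplitude_uv=gain,
    )


def iter_cohort(
    n_subjects: int,
    config: ExperimentConfig,
    effects: EffectSpec | None = None,
    spread: CohortSpread | None = None,
) -> Iterator[tuple[RawRecording, EventList, SyntheticTruth]]:
    """Lazily generate a cohort, one session at a time.

    Subject ``i`` runs with seed ``config.seed + i``; subject 0 with zero
    spread therefore reproduces :func:`generate_session` exactly.  Effect
    parameters are jittered per subject with the normal perturbations in
    ``spread`` (drawn from a dedicated stream so the per-session noise is
    unaffected by the cohort size).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    effects = effects if effects is not None else EffectSpec()
    spread = spread if spread is not None else CohortSpread()
    jitter_rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed) % 2**31, 0x5C0DE])
    )
    for i in range(n_subjects):
        subject_effects = _subject_effects(effects, spread, jitter_rng)
        subject_config = replace(config, seed=(config.seed + i) % 2**31)
        yield generate_session(subject_config, subject_effects)


def generate_cohort(
    n_subjects: int,
    config: ExperimentConfig,
    effects: EffectSpec | None = None,
    spread: CohortSpread | None = None,
) -> list[tuple[RawRecording, EventList, SyntheticTruth]]:
    """Materialised cohort (see :func:`iter_cohort` for the lazy variant)."""
    return list(iter_cohort(n_subjects, config, effects, spread))
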