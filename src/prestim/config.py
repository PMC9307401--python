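"""Validated JSON run configuration for the end-to-end pipeline."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, Field, model_validator

from . import montage

__all__ = [
    "BlockSpec",
    "SynthParams",
    "PreprocessParams",
    "AnalysisParams",
    "RunConfig",
]


class BlockSpec(BaseModel):
    """One experimental block: bet values plus the effects to inject."""

    left_value: float
    right_value: float = 5.0
    divergence_onset_ms: float = 107.0
    loss_amplitude_uv: float = -0.34
    gain_amplitude_uv: float = 0.37

    @property
    def E(self) -> float:
        return self.left_value / self.right_value

    @model_validator(mode="after")
    def _check(self):
        if self.right_value <= 0:
            raise ValueError("right_value must be positive")
        return self


class SynthParams(BaseModel):
    """Simulator settings shared across blocks."""

    n_trials: int = 300
    trial_duration_s: float = 3.0
    sampling_rate_hz: float = 500.0
    noise_rms_uv: float = 5.0
    blink_rate_per_min: float = 8.0
    bad_block_rate_per_min: float = 0.2
    divergence_amplitude_uv: float = -6.0
    mfn_latency_ms: float = 232.0
    onset_sd_ms: float = 9.0  # between-subject spread
    amplitude_sd_uv: float = 0.07
    channel_names: list[str] | None = None  # None -> full 64-channel montage

    def resolved_channels(self) -> tuple[str, ...]:
        if self.channel_names is None:
            return montage.default_channel_names()
        return tuple(self.channel_names)


class PreprocessParams(BaseModel):
    """Settings of the preprocessing chain."""

    amplitude_threshold_uv: float = 100.0
    scan_window_ms: tuple[float, float] | None = None  # None -> whole epoch
    lowpass_cutoff_hz: float = 30.0
    decision_window_ms: tuple[float, float] = (-500.0, 0.0)
    decision_baseline_ms: tuple[float, float] = (-500.0, -400.0)
    feedback_window_ms: tuple[float, float] = (-100.0, 500.0)
    feedback_baseline_ms: tuple[float, float] = (-100.0, 0.0)
    # ocular handling: "reject" drops trials overlapping VEOG-labelled
    # blinks, "ica" removes VEOG-correlated independent components,
    # "none" disables the stage
    ocular: str = "reject"
    ica_corr_threshold: float = 0.7
    blink_threshold_uv: float = 100.0


class AnalysisParams(BaseModel):
    """Settings of the statistical stage."""

    channel: str = "Fz"
    pt_window_ms: tuple[float, float] = (-500.0, 0.0)
    # separation tolerance = k x SD of the difference waveform over the
    # (signal-free) decision baseline window; 0 disables the tolerance
    pt_tolerance_k: float = 3.0
    mfn_window_ms: tuple[float, float] = (150.0, 350.0)
    # extra Gaussian smoothing (FWHM, ms) applied only for latency detection
    latency_smooth_fwhm_ms: float = 25.0
    # "pooled": Gaussian peak fitted to the cross-block pooled grand
    # difference, subjects scored against the fitted unit-peak template;
    # "shape": matched-filter projection on this block's grand-average
    # shape; "point": single-sample read-out at the detected latency
    amplitude_scoring: str = "pooled"
    n_permutations: int = 10_000
    decision_map_ms: float = -50.0  # latency of the pre-decision scalp map


class RunConfig(BaseModel):
    """Everything needed to rerun a full simulate-preprocess-analyze pass."""

    blocks: list[BlockSpec] = Field(min_length=1)
    n_subjects: int = Field(default=12, ge=1)
    seed: int
    synth: SynthParams = Field(default_factory=SynthParams)
    preprocess: PreprocessParams = Field(default_factory=PreprocessParams)
    analysis: AnalysisParams = Field(default_factory=AnalysisParams)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(self.canonical_json())

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), sort_keys=True, indent=2)

    def config_hash(self) -> str:
        """Short digest identifying the configuration (for provenance)."""
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]
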