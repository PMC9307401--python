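"""In-memory containers: continuous recordings, event markers, epochs, averages.

All voltages are in microvolts, all time axes in milliseconds relative to the
time-locking marker, and all continuous positions in samples, mirroring the
conventions of mainstream ERP toolboxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .montage import is_eog

DECISION_SIDES = ("left", "right")
FEEDBACK_VALENCES = ("gain", "loss")


@dataclass
class RawRecording:
    """Continuous multichannel EEG in microvolts.

    data : (n_channels, n_samples) array, microvolts
    montage_positions : (n_channels, 2) flat head-circle coordinates
    """

    data: np.ndarray
    sampling_rate: float
    channel_names: tuple[str, ...]
    montage_positions: np.ndarray
    reference_label: str = "average"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = tuple(self.channel_names)
        self.montage_positions = np.asarray(self.montage_positions, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        n_ch = self.data.shape[0]
        if len(self.channel_names) != n_ch:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {n_ch} data rows"
            )
        if self.montage_positions.shape != (n_ch, 2):
            raise ValueError("montage_positions must be (n_channels, 2)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None

    def get_channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_index(name)]

    def eeg_indices(self) -> np.ndarray:
        """Indices of scalp EEG channels (EOG excluded)."""
        return np.array(
            [i for i, n in enumerate(self.channel_names) if not is_eog(n)],
            dtype=int,
        )

    def copy(self) -> "RawRecording":
        return replace(self, data=self.data.copy())


@dataclass(frozen=True)
class Event:
    """One trial: a decision marker plus its feedback outcome one second on."""

    sample: int  # decision-marker sample index
    decision_side: str  # "left" | "right"
    feedback: str  # "gain" | "loss"
    block_E: float  # reward parameter of the block the trial belongs to

    def __post_init__(self) -> None:
        if self.decision_side not in DECISION_SIDES:
            raise ValueError(f"decision_side must be one of {DECISION_SIDES}")
        if self.feedback not in FEEDBACK_VALENCES:
            raise ValueError(f"feedback must be one of {FEEDBACK_VALENCES}")


@dataclass
class EventList:
    """Time-stamped trial markers.

    The feedback marker of every trial follows the decision marker by a fixed
    delay (one second in the task this package models).
    """

    events: list[Event]
    sampling_rate: float
    feedback_delay_s: float = 1.0

    def __post_init__(self) -> None:
        samples = [e.sample for e in self.events]
        if any(b <= a for a, b in zip(samples, samples[1:])):
            raise ValueError("event samples must be strictly increasing")
        if samples and samples[0] < 0:
            raise ValueError("event samples must be non-negative")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __getitem__(self, i: int) -> Event:
        return self.events[i]

    @property
    def feedback_delay_samples(self) -> int:
        return int(round(self.feedback_delay_s * self.sampling_rate))

    def feedback_sample(self, event: Event) -> int:
        return event.sample + self.feedback_delay_samples

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": [e.sample for e in self.events],
                "decision_side": [e.decision_side for e in self.events],
                "feedback": [e.feedback for e in self.events],
                "block_E": [e.block_E for e in self.events],
            }
        )


@dataclass
class Epochs:
    """Trials x channels x time tensor time-locked to one marker type."""

    data: np.ndarray  # (n_trials, n_channels, n_times), microvolts
    times: np.ndarray  # milliseconds relative to the marker; includes 0
    channel_names: tuple[str, ...]
    labels: np.ndarray  # condition per trial
    sampling_rate: float
    lock: str = "decision"  # which marker t=0 refers to
    rejected: np.ndarray = field(default=None)  # type: ignore[assignment]
    reject_reason: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.channel_names = tuple(self.channel_names)
        self.labels = np.asarray(self.labels)
        n_trials = self.data.shape[0] if self.data.ndim == 3 else 0
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x times)")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis does not match times")
        if self.labels.shape != (n_trials,):
            raise ValueError("labels must have one entry per trial")
        if self.rejected is None:
            self.rejected = np.zeros(n_trials, dtype=bool)
        else:
            self.rejected = np.asarray(self.rejected, dtype=bool)
        if self.reject_reason is None:
            self.reject_reason = np.array([""] * n_trials, dtype=object)
        else:
            self.reject_reason = np.asarray(self.reject_reason, dtype=object)
        if self.times.size:
            step = 1000.0 / self.sampling_rate
            diffs = np.diff(self.times)
            if diffs.size and not np.allclose(diffs, step, atol=1e-6):
                raise ValueError(
                    "time axis must be uniform with step 1000/sampling_rate"
                )
            if np.abs(self.times).min() > 1e-9:
                raise ValueError("time axis must include the marker sample t=0")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_kept(self) -> int:
        return int((~self.rejected).sum())

    def kept_mask(self, condition: str | None = None) -> np.ndarray:
        mask = ~self.rejected
        if condition is not None:
            mask = mask & (self.labels == condition)
        return mask

    def eeg_indices(self) -> np.ndarray:
        return np.array(
            [i for i, n in enumerate(self.channel_names) if not is_eog(n)],
            dtype=int,
        )

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in epochs") from None

    def copy(self) -> "Epochs":
        return replace(
            self,
            data=self.data.copy(),
            times=self.times.copy(),
            labels=self.labels.copy(),
            rejected=self.rejected.copy(),
            reject_reason=self.reject_reason.copy(),
        )


@dataclass
class EvokedWaveform:
    """Per-condition average (channels x time) with the trial count behind it."""

    data: np.ndarray  # (n_channels, n_times), microvolts
    times: np.ndarray  # milliseconds relative to the marker
    channel_names: tuple[str, ...]
    n: int  # number of trials averaged
    condition: str
    lock: str = "decision"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.data.shape != (len(self.channel_names), self.times.size):
            raise ValueError("data must be (n_channels, n_times)")
        if self.n < 1:
            raise ValueError("an average must come from at least one trial")

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in waveform") from None

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_index(name)]

    def eeg_indices(self) -> np.ndarray:
        return np.array(
            [i for i, n in enumerate(self.channel_names) if not is_eog(n)],
            dtype=int,
        )

    def copy(self) -> "EvokedWaveform":
        return replace(self, data=self.data.copy(), times=self.times.copy())
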