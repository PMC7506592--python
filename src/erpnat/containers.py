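"""In-memory containers shared across the pipeline stages.

Voltages are microvolts throughout; sample indices are 0-based; epoch windows
are half-open ``[tmin, tmax)`` in milliseconds relative to the offset-corrected
target onset (t = 0 at epoch sample ``round(-tmin * rate / 1000)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ContractError

HUMAN_NATURAL = "human-natural"
AI_UNNATURAL = "AI-unnatural"
CONDITIONS = (HUMAN_NATURAL, AI_UNNATURAL)

RESPONSE_NATURAL = 1
RESPONSE_UNNATURAL = 2

EVENT_COLUMNS = ["onset_sample", "identity", "response", "rt_ms"]


def ms_to_samples(ms: float, rate_hz: float) -> int:
    return int(round(ms * rate_hz / 1000.0))


@dataclass
class ContinuousEEG:
    """Continuous multichannel recording, referenced to a single electrode."""

    data: np.ndarray                 # (n_channels, n_samples), μV
    sampling_rate_hz: float
    channel_labels: list[str]
    reference: str = "Cz"
    filtered: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ConfigurationError("EEG data must be 2-D (channels × samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ConfigurationError("data row count must equal label count")
        if not self.sampling_rate_hz > 0:
            raise ConfigurationError("sampling rate must be positive")
        if not np.isfinite(self.data).all():
            raise ConfigurationError("EEG data contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / self.sampling_rate_hz

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise ConfigurationError(f"channel {label!r} not in recording") from None

    def copy(self) -> "ContinuousEEG":
        return replace(self, data=self.data.copy(),
                       channel_labels=list(self.channel_labels))


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Validate an event table (onset_sample, identity, response, rt_ms)."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ConfigurationError(f"event table missing columns {missing}")
    onsets = events["onset_sample"].to_numpy()
    if len(onsets) > 1 and not (np.diff(onsets) > 0).all():
        raise ConfigurationError("event onsets must be strictly increasing")
    if not events["identity"].isin(["human", "AI"]).all():
        raise ConfigurationError("identity must be 'human' or 'AI'")
    ok = events["response"].isin([RESPONSE_NATURAL, RESPONSE_UNNATURAL])
    if not (ok | events["response"].isna()).all():
        raise ConfigurationError("response codes must be 1 (natural) or 2 (unnatural)")
    return events


@dataclass(frozen=True)
class ArtifactCriteria:
    """Threshold-based artifact rules (all voltages μV, window in ms)."""

    segment_channel_bad_uv: float = 200.0
    blink_uv: float = 140.0
    eye_move_uv: float = 55.0
    moving_avg_ms: float = 80.0
    max_bad_channels_per_segment: int = 10
    global_bad_channel_fraction: float = 0.20
    # 'smooth_then_range': boxcar-smooth the trace, then take its max−min.
    # 'windowed_range': max over sliding windows of the within-window range.
    method: str = "smooth_then_range"

    def __post_init__(self) -> None:
        for name in ("segment_channel_bad_uv", "blink_uv", "eye_move_uv",
                     "moving_avg_ms"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0 < self.global_bad_channel_fraction < 1:
            raise ConfigurationError("global_bad_channel_fraction must be in (0,1)")
        if self.method not in ("smooth_then_range", "windowed_range"):
            raise ConfigurationError(f"unknown artifact method {self.method!r}")


# Processing stages, in their mandatory order.
STAGE_ORDER = ("segmented", "detected", "interpolated", "baselined", "rereferenced")


@dataclass
class Epochs:
    """Condition-labelled fixed-window epochs with artifact annotations."""

    data: np.ndarray                      # (n_epochs, n_channels, n_samples), μV
    conditions: np.ndarray                # (n_epochs,) of CONDITIONS
    sampling_rate_hz: float
    channel_labels: list[str]
    window_ms: tuple[float, float] = (-200.0, 1000.0)
    epoch_flags: list[str] = field(default_factory=list)       # 'clean' | 'rejected:<why>'
    channel_global_bad: np.ndarray | None = None               # (n_channels,) bool
    interpolated: np.ndarray | None = None                     # (n_epochs, n_channels) bool
    stage: str = "segmented"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ConfigurationError("epoch data must be 3-D")
        n_ep, n_ch, n_samp = self.data.shape
        if n_ch != len(self.channel_labels):
            raise ConfigurationError("channel count mismatch")
        expected = ms_to_samples(self.window_ms[1] - self.window_ms[0],
                                 self.sampling_rate_hz)
        if n_samp != expected:
            raise ConfigurationError(
                f"window {self.window_ms} implies {expected} samples, got {n_samp}")
        if not self.epoch_flags:
            self.epoch_flags = ["clean"] * n_ep
        if self.channel_global_bad is None:
            self.channel_global_bad = np.zeros(n_ch, dtype=bool)
        if self.interpolated is None:
            self.interpolated = np.zeros((n_ep, n_ch), dtype=bool)
        bad = set(np.unique(self.conditions)) - set(CONDITIONS)
        if bad:
            raise ConfigurationError(f"unknown conditions {bad}")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        step = 1000.0 / self.sampling_rate_hz
        return self.window_ms[0] + step * np.arange(self.n_samples)

    @property
    def clean_mask(self) -> np.ndarray:
        return np.array([f == "clean" for f in self.epoch_flags])

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise ConfigurationError(f"channel {label!r} not in epochs") from None

    def require_stage(self, *allowed: str) -> None:
        if self.stage not in allowed:
            raise ContractError(
                f"operation requires stage in {allowed}, epochs are at "
                f"{self.stage!r}; the pipeline order is "
                "filter → segment → detect → replace → baseline → re-reference")

    def copy(self) -> "Epochs":
        return replace(
            self,
            data=self.data.copy(),
            conditions=self.conditions.copy(),
            channel_labels=list(self.channel_labels),
            epoch_flags=list(self.epoch_flags),
            channel_global_bad=self.channel_global_bad.copy(),
            interpolated=self.interpolated.copy(),
            meta=dict(self.meta),
        )


@dataclass
class ArtifactReport:
    """Outcome of threshold-based artifact screening."""

    bad_matrix: np.ndarray          # (n_epochs, n_channels) final indicators
    raw_bad_matrix: np.ndarray      # before the >20% global rule
    epoch_reasons: list[list[str]]  # rejection rules tripped per epoch
    global_bad_channels: list[str]
    channel_labels: list[str]
    counts: dict = field(default_factory=dict)

    @property
    def rejected_mask(self) -> np.ndarray:
        return np.array([len(r) > 0 for r in self.epoch_reasons])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e, reasons in enumerate(self.epoch_reasons):
            n_bad = int(self.bad_matrix[e].sum())
            rows.append({
                "epoch": e,
                "n_bad_channels": n_bad,
                "rejected": len(reasons) > 0,
                "reasons": ";".join(reasons),
                "bad_channels": ";".join(
                    lab for lab, b in zip(self.channel_labels, self.bad_matrix[e]) if b
                ),
            })
        return pd.DataFrame(rows)
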