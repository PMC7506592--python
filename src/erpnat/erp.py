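"""Subject/grand averaging and adaptive-mean component amplitude extraction.

The two components of interest are the P1 (positive, search window 70–130 ms)
and the N170 (negative, 150–200 ms), measured at the text-specific left
parieto-occipital site P7 and the face-specific right site P8. The *adaptive
mean* of a component is the mean voltage over a short interval centred on the
within-window peak of the stated polarity — robust to latency differences
between subjects, less noisy than the raw peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AI_UNNATURAL, CONDITIONS, HUMAN_NATURAL, Epochs
from .exceptions import ConfigurationError
from .montage import Montage

logger = logging.getLogger(__name__)

CONDITION_TO_IDENTITY = {HUMAN_NATURAL: "human", AI_UNNATURAL: "AI"}
SITES = ("P7", "P8")


@dataclass(frozen=True)
class ComponentWindow:
    """Search window and polarity for one ERP component."""

    name: str
    window_ms: tuple[float, float]
    polarity: str                      # 'positive' | 'negative'
    halfwidth_ms: float = 10.0

    def __post_init__(self) -> None:
        if not self.window_ms[0] < self.window_ms[1]:
            raise ConfigurationError("component window start must precede end")
        if self.polarity not in ("positive", "negative"):
            raise ConfigurationError(f"bad polarity {self.polarity!r}")
        expected = {"P1": "positive", "N170": "negative"}.get(self.name)
        if expected is not None and self.polarity != expected:
            raise ConfigurationError(
                f"{self.name} must be {expected}, got {self.polarity}")
        if not self.halfwidth_ms > 0:
            raise ConfigurationError("halfwidth must be positive")


P1_WINDOW = ComponentWindow("P1", (70.0, 130.0), "positive")
N170_WINDOW = ComponentWindow("N170", (150.0, 200.0), "negative")
DEFAULT_WINDOWS = (P1_WINDOW, N170_WINDOW)


@dataclass
class SubjectAverage:
    """Per-condition mean waveforms for one subject (or the grand average)."""

    subject: str
    data: dict[str, np.ndarray]        # condition → (n_channels, n_samples) μV
    n_epochs: dict[str, int]
    sampling_rate_hz: float
    channel_labels: list[str]
    window_ms: tuple[float, float] = (-200.0, 1000.0)
    meta: dict = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return all(c in self.data for c in CONDITIONS)

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise ConfigurationError(f"channel {label!r} not in average") from None


def subject_average(epochs: Epochs, subject: str = "subject") -> SubjectAverage:
    """Arithmetic mean of the retained epochs, per condition and channel.

    A condition with zero retained epochs is simply absent from the result;
    the subject is then *incomplete* and excluded from the amplitude table.
    """
    epochs.require_stage("rereferenced")
    clean = epochs.clean_mask
    data, counts = {}, {}
    for cond in CONDITIONS:
        sel = clean & (epochs.conditions == cond)
        n = int(sel.sum())
        if n == 0:
            logger.warning("subject %s: no retained epochs for %s", subject, cond)
            continue
        data[cond] = epochs.data[sel].mean(axis=0)
        counts[cond] = n
    return SubjectAverage(
        subject=subject, data=data, n_epochs=counts,
        sampling_rate_hz=epochs.sampling_rate_hz,
        channel_labels=list(epochs.channel_labels),
        window_ms=epochs.window_ms,
    )


def grand_average(subject_averages: list[SubjectAverage]) -> SubjectAverage:
    """Unweighted mean across subjects per condition/channel/sample."""
    if not subject_averages:
        raise ConfigurationError("grand_average requires at least one subject")
    complete = [s for s in subject_averages if s.complete]
    if not complete:
        raise ConfigurationError("no complete subject averages")
    first = complete[0]
    data = {
        cond: np.mean([s.data[cond] for s in complete], axis=0)
        for cond in CONDITIONS
    }
    return SubjectAverage(
        subject="grand",
        data=data,
        n_epochs={cond: len(complete) for cond in CONDITIONS},
        sampling_rate_hz=first.sampling_rate_hz,
        channel_labels=list(first.channel_labels),
        window_ms=first.window_ms,
        meta={"n_subjects": len(complete)},
    )


def adaptive_mean(waveform: np.ndarray, window: ComponentWindow,
                  rate_hz: float, tmin_ms: float = 0.0) -> float:
    """Adaptive-mean amplitude of one component on a single-channel trace.

    Finds the extremum of the component's polarity inside its search window
    (earliest sample wins ties), then averages the trace over
    ``peak ± halfwidth`` clipped to the search window. ``tmin_ms`` is the
    time of the first sample (−200 for standard epochs).
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.ndim != 1:
        raise ConfigurationError("adaptive_mean expects a single-channel trace")
    step = 1000.0 / rate_hz
    times = tmin_ms + step * np.arange(waveform.size)
    lo, hi = window.window_ms
    in_win = np.flatnonzero((times >= lo) & (times <= hi))
    if in_win.size == 0:
        raise ConfigurationError(
            f"window {window.window_ms} outside trace span "
            f"[{times[0]:.1f}, {times[-1]:.1f}] ms")
    seg = waveform[in_win]
    local = int(np.argmax(seg) if window.polarity == "positive" else np.argmin(seg))
    peak_idx = in_win[local]
    if local in (0, seg.size - 1):
        logger.debug("%s peak on window edge at %.1f ms", window.name,
                     times[peak_idx])
    t_peak = times[peak_idx]
    sel = (np.abs(times - t_peak) <= window.halfwidth_ms + 1e-9) & \
          (times >= lo) & (times <= hi)
    return float(waveform[sel].mean())


def adaptive_attenuation(width_ms: float, halfwidth_ms: float,
                         rate_hz: float) -> float:
    """Ratio (adaptive mean)/(peak) for an on-grid Gaussian bump.

    The generator uses this to express ground-truth amplitudes on the same
    scale the extraction reports: a bump of SD ``width_ms/4`` averaged over
    ``±halfwidth_ms`` around its peak keeps this fraction of its peak value.
    """
    sd = width_ms / 4.0
    step = 1000.0 / rate_hz
    k = int(round(halfwidth_ms / step))
    offsets = step * np.arange(-k, k + 1)
    return float(np.mean(np.exp(-0.5 * (offsets / sd) ** 2)))


def component_table(subject_averages: list[SubjectAverage],
                    windows: tuple[ComponentWindow, ...] = DEFAULT_WINDOWS,
                    montage: Montage | None = None,
                    sites: tuple[str, str] = SITES) -> pd.DataFrame:
    """Long-format amplitude table: subject × component × identity × site.

    Incomplete subjects (a condition with no retained epochs) are omitted
    with a log entry. When a montage is given, the site labels are resolved
    through it (they must exist there and in the averages).
    """
    if montage is not None:
        for site in sites:
            if site not in montage.channel_labels:
                raise ConfigurationError(f"site {site} missing from montage")
    rows = []
    for sa in subject_averages:
        if not sa.complete:
            logger.info("omitting incomplete subject %s from amplitude table",
                        sa.subject)
            continue
        for win in windows:
            for cond, identity in CONDITION_TO_IDENTITY.items():
                for site in sites:
                    trace = sa.data[cond][sa.channel_index(site)]
                    amp = adaptive_mean(trace, win, sa.sampling_rate_hz,
                                        tmin_ms=sa.window_ms[0])
                    rows.append({
                        "subject": sa.subject, "component": win.name,
                        "identity": identity, "site": site,
                        "amplitude_uv": amp,
                    })
    return pd.DataFrame(rows,
                        columns=["subject", "component", "identity", "site",
                                 "amplitude_uv"])
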