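"""Continuous EEG → clean epochs: filter, segment, artifact screening,
bad-channel interpolation, baseline correction, average re-reference.

The stage order is fixed and enforced through the containers' ``stage``
attribute: filter → segment → detect → replace → baseline → re-reference.
Artifact screening is threshold-based (reject, don't correct): a channel is
bad within a segment if its smoothed max−min range exceeds 200 μV; a segment
is rejected for >10 bad channels, a vertical-ocular range >140 μV (blink) or
a horizontal-ocular range >55 μV (eye movement); a channel bad in >20% of
segments is bad everywhere.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .containers import (AI_UNNATURAL, ArtifactCriteria, ArtifactReport,
                         ContinuousEEG, Epochs, HUMAN_NATURAL,
                         RESPONSE_NATURAL, RESPONSE_UNNATURAL, ms_to_samples,
                         validate_events)
from .exceptions import ConfigurationError, ContractError
from .montage import Montage

logger = logging.getLogger(__name__)

REASON_BAD_CHANNELS = "bad_channels"
REASON_BLINK = "blink"
REASON_EYE_MOVE = "eye_movement"
REASON_UNINTERPOLATABLE = "uninterpolatable"


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def bandpass_filter(eeg: ContinuousEEG, low_hz: float = 0.3,
                    high_hz: float = 30.0) -> ContinuousEEG:
    """Zero-phase FIR band-pass (windowed-sinc, symmetric kernel).

    The kernel length follows the low cut-off (≈3.3/low_hz seconds), capped
    at a third of the record so short traces remain filterable; channels are
    reflect-padded so edge transients stay mild. Phase is exactly zero by
    kernel symmetry.
    """
    nyquist = eeg.sampling_rate_hz / 2.0
    if not 0 < low_hz < high_hz < nyquist:
        raise ConfigurationError(
            f"band ({low_hz}, {high_hz}) must satisfy 0 < low < high < "
            f"Nyquist ({nyquist})")
    numtaps = int(round(3.3 * eeg.sampling_rate_hz / low_hz))
    numtaps = min(numtaps, max(eeg.n_samples // 3, 3))
    if numtaps % 2 == 0:
        numtaps -= 1
    if numtaps < 3:
        raise ConfigurationError("record too short to filter")
    kernel = sps.firwin(numtaps, [low_hz, high_hz], pass_zero=False,
                        fs=eeg.sampling_rate_hz)
    half = (numtaps - 1) // 2
    padded = np.pad(eeg.data, ((0, 0), (half, half)), mode="reflect")
    filtered = sps.fftconvolve(padded, kernel[None, :], mode="valid", axes=1)
    out = eeg.copy()
    out.data = filtered
    out.filtered = True
    return out


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment(eeg: ContinuousEEG, events: pd.DataFrame,
            window_ms: tuple[float, float] = (-200.0, 1000.0),
            offset_ms: float = 11.0) -> Epochs:
    """Cut condition-concordant epochs around offset-corrected target onsets.

    Only events where the behavioural response matches the analysis
    conditions are kept: (human, response 1) → human-natural and
    (AI, response 2) → AI-unnatural; all other events are dropped with a
    logged count. t = 0 is ``onset_sample`` plus the stimulus-presentation
    offset. Epochs whose window leaves the record are dropped with a
    warning, not an error.
    """
    if not eeg.filtered:
        raise ContractError("segment must run on band-pass-filtered data "
                            "(pipeline order: filter → segment → …)")
    validate_events(events)
    rate = eeg.sampling_rate_hz
    shift = ms_to_samples(offset_ms, rate)
    start_rel = ms_to_samples(window_ms[0], rate)
    n_samp = ms_to_samples(window_ms[1] - window_ms[0], rate)

    slices, conditions = [], []
    n_discordant = n_oob = 0
    for row in events.itertuples(index=False):
        if row.identity == "human" and row.response == RESPONSE_NATURAL:
            cond = HUMAN_NATURAL
        elif row.identity == "AI" and row.response == RESPONSE_UNNATURAL:
            cond = AI_UNNATURAL
        else:
            n_discordant += 1
            continue
        start = int(row.onset_sample) + shift + start_rel
        if start < 0 or start + n_samp > eeg.n_samples:
            n_oob += 1
            logger.warning("epoch at onset %d outside record; dropped",
                           row.onset_sample)
            continue
        slices.append(eeg.data[:, start:start + n_samp])
        conditions.append(cond)
    logger.info("segment: kept %d epochs, dropped %d discordant, %d out of "
                "bounds", len(slices), n_discordant, n_oob)
    data = (np.stack(slices) if slices
            else np.empty((0, eeg.n_channels, n_samp)))
    return Epochs(
        data=data, conditions=np.array(conditions, dtype=object),
        sampling_rate_hz=rate, channel_labels=list(eeg.channel_labels),
        window_ms=tuple(window_ms), stage="segmented",
        meta={"offset_ms": offset_ms, "n_discordant": n_discordant,
              "n_out_of_bounds": n_oob},
    )


# ---------------------------------------------------------------------------
# Artifact screening
# ---------------------------------------------------------------------------

def _boxcar_smooth(x: np.ndarray, half: int) -> np.ndarray:
    """Centered boxcar mean along the last axis, shrinking at the edges."""
    n = x.shape[-1]
    cs = np.concatenate(
        [np.zeros(x.shape[:-1] + (1,)), np.cumsum(x, axis=-1)], axis=-1)
    i = np.arange(n)
    lo = np.maximum(i - half, 0)
    hi = np.minimum(i + half + 1, n)
    return (cs[..., hi] - cs[..., lo]) / (hi - lo)


def _range_after_screening(x: np.ndarray, window_ms: float, rate_hz: float,
                           method: str) -> np.ndarray:
    """max−min screening statistic along the last axis (vectorised)."""
    w = ms_to_samples(window_ms, rate_hz)
    half = max(w // 2, 1)
    if method == "smooth_then_range":
        sm = _boxcar_smooth(x, half)
        return sm.max(axis=-1) - sm.min(axis=-1)
    size = 2 * half + 1
    local = (maximum_filter1d(x, size=size, axis=-1, mode="nearest")
             - minimum_filter1d(x, size=size, axis=-1, mode="nearest"))
    return local.max(axis=-1)


def moving_range(trace: np.ndarray, window_ms: float, rate_hz: float,
                 method: str = "smooth_then_range") -> float:
    """Max−min of a single trace after 80 ms-style moving-average screening.

    ``smooth_then_range`` (default): boxcar-smooth, then global max−min.
    ``windowed_range``: largest within-window range over sliding windows.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ConfigurationError("empty trace")
    if trace.size < 2:
        return 0.0
    return float(_range_after_screening(trace[None, :], window_ms, rate_hz,
                                        method)[0])


def _ocular_derivation(epochs: Epochs, labels: list[str]) -> np.ndarray:
    idx = [epochs.channel_index(lab) for lab in labels if
           lab in epochs.channel_labels]
    if not idx:
        raise ConfigurationError("montage defines no usable ocular channels")
    if len(idx) >= 2:
        return epochs.data[:, idx[0], :] - epochs.data[:, idx[1], :]
    return epochs.data[:, idx[0], :]


def detect_artifacts(epochs: Epochs, criteria: ArtifactCriteria,
                     montage: Montage) -> ArtifactReport:
    """Threshold screening. Pure: epochs are not modified.

    Per epoch each scalp channel is bad if its screened range exceeds the
    200 μV rule; channels bad in more than the global fraction of segments
    are marked bad in every segment; an epoch is rejected for more than the
    allowed count of (final) bad channels, a blink on the vertical-ocular
    derivation, or an eye movement on the horizontal-ocular derivation.
    """
    epochs.require_stage("segmented")
    if epochs.n_epochs == 0:
        raise ConfigurationError("no epochs to screen")
    voc = montage.ocular_channels("vertical-ocular")
    hoc = montage.ocular_channels("horizontal-ocular")
    if not voc or not hoc:
        raise ConfigurationError("montage must define vertical- and "
                                 "horizontal-ocular channels")
    scalp = [lab for lab in montage.scalp_channels()
             if lab in epochs.channel_labels]
    scalp_idx = np.array([epochs.channel_index(lab) for lab in scalp])

    rng_mat = _range_after_screening(epochs.data[:, scalp_idx, :],
                                     criteria.moving_avg_ms,
                                     epochs.sampling_rate_hz, criteria.method)
    raw_bad_scalp = rng_mat > criteria.segment_channel_bad_uv
    globally_bad = (raw_bad_scalp.mean(axis=0)
                    > criteria.global_bad_channel_fraction)
    final_bad_scalp = raw_bad_scalp | globally_bad[None, :]

    n_ch = len(epochs.channel_labels)
    raw_bad = np.zeros((epochs.n_epochs, n_ch), dtype=bool)
    final_bad = np.zeros_like(raw_bad)
    raw_bad[:, scalp_idx] = raw_bad_scalp
    final_bad[:, scalp_idx] = final_bad_scalp

    blink_rng = _range_after_screening(_ocular_derivation(epochs, voc),
                                       criteria.moving_avg_ms,
                                       epochs.sampling_rate_hz, criteria.method)
    eye_rng = _range_after_screening(_ocular_derivation(epochs, hoc),
                                     criteria.moving_avg_ms,
                                     epochs.sampling_rate_hz, criteria.method)

    reasons: list[list[str]] = []
    for e in range(epochs.n_epochs):
        why = []
        if final_bad[e].sum() > criteria.max_bad_channels_per_segment:
            why.append(REASON_BAD_CHANNELS)
        if blink_rng[e] > criteria.blink_uv:
            why.append(REASON_BLINK)
        if eye_rng[e] > criteria.eye_move_uv:
            why.append(REASON_EYE_MOVE)
        reasons.append(why)

    global_labels = [scalp[i] for i in np.flatnonzero(globally_bad)]
    n_rejected = sum(1 for r in reasons if r)
    counts = {
        "n_epochs": epochs.n_epochs,
        "n_rejected": n_rejected,
        "n_bad_channel_flags": int(final_bad.sum()),
        "n_global_bad_channels": len(global_labels),
        "by_reason": {
            REASON_BAD_CHANNELS: sum(REASON_BAD_CHANNELS in r for r in reasons),
            REASON_BLINK: sum(REASON_BLINK in r for r in reasons),
            REASON_EYE_MOVE: sum(REASON_EYE_MOVE in r for r in reasons),
        },
    }
    logger.info("detect_artifacts: %d/%d epochs rejected, %d globally bad "
                "channels", n_rejected, epochs.n_epochs, len(global_labels))
    return ArtifactReport(
        bad_matrix=final_bad, raw_bad_matrix=raw_bad, epoch_reasons=reasons,
        global_bad_channels=global_labels,
        channel_labels=list(epochs.channel_labels), counts=counts,
    )


# ---------------------------------------------------------------------------
# Interpolation, baseline, re-reference
# ---------------------------------------------------------------------------

def replace_bad_channels(epochs: Epochs, report: ArtifactReport,
                         montage: Montage) -> Epochs:
    """Apply the artifact report and interpolate bad channels.

    Rejected epochs get their rejection reason; in retained epochs every bad
    channel is replaced by the inverse-distance-weighted mean of its good
    neighbours. A bad channel with no good neighbour rejects the epoch
    (``uninterpolatable``). Good channels are bit-unchanged.
    """
    epochs.require_stage("segmented")
    if report.bad_matrix.shape != (epochs.n_epochs, len(epochs.channel_labels)):
        raise ConfigurationError("report inconsistent with epochs")
    out = epochs.copy()
    out.stage = "interpolated"
    out.meta["scalp_channels"] = [lab for lab in montage.scalp_channels()
                                  if lab in epochs.channel_labels]
    out.meta["global_bad_channels"] = list(report.global_bad_channels)
    label_idx = {lab: i for i, lab in enumerate(epochs.channel_labels)}
    for e in range(epochs.n_epochs):
        if report.epoch_reasons[e]:
            out.epoch_flags[e] = "rejected:" + ",".join(report.epoch_reasons[e])
            continue
        for ci in np.flatnonzero(report.bad_matrix[e]):
            lab = epochs.channel_labels[ci]
            neighbors = [
                nb for nb in montage.neighbor_map.get(lab, ())
                if nb in label_idx and not report.bad_matrix[e, label_idx[nb]]
            ]
            if not neighbors:
                out.epoch_flags[e] = f"rejected:{REASON_UNINTERPOLATABLE}"
                logger.warning("epoch %d: bad channel %s has no good "
                               "neighbours; epoch rejected", e, lab)
                break
            dists = np.array([montage.distance(lab, nb) for nb in neighbors])
            weights = 1.0 / dists
            weights /= weights.sum()
            nb_idx = [label_idx[nb] for nb in neighbors]
            out.data[e, ci] = weights @ epochs.data[e, nb_idx]
            out.interpolated[e, ci] = True
    return out


def baseline_correct(epochs: Epochs,
                     baseline_ms: tuple[float, float] = (-200.0, 0.0)) -> Epochs:
    """Subtract the mean over the pre-stimulus interval, per epoch & channel."""
    epochs.require_stage("interpolated")
    t = epochs.times_ms
    if baseline_ms[0] < epochs.window_ms[0] - 1e-9 or \
            baseline_ms[1] > epochs.window_ms[1] + 1e-9:
        raise ConfigurationError("baseline outside epoch window")
    sel = (t >= baseline_ms[0]) & (t < baseline_ms[1])
    if not sel.any():
        raise ConfigurationError("baseline interval contains no samples")
    out = epochs.copy()
    out.data = epochs.data - epochs.data[:, :, sel].mean(axis=2, keepdims=True)
    out.stage = "baselined"
    return out


def rereference_average(epochs: Epochs,
                        scalp_labels: list[str] | None = None) -> Epochs:
    """Subtract the instantaneous mean across scalp channels at every sample.

    Must follow bad-channel replacement (no bad channels may remain in
    retained epochs). Ocular channels keep their original reference; the
    scalp channels sum to zero at every sample afterwards.
    """
    epochs.require_stage("baselined")
    if scalp_labels is None:
        scalp_labels = epochs.meta.get("scalp_channels",
                                       list(epochs.channel_labels))
    scalp_idx = np.array([epochs.channel_index(lab) for lab in scalp_labels])
    out = epochs.copy()
    mean = epochs.data[:, scalp_idx, :].mean(axis=1, keepdims=True)
    nonocular = sorted(set(scalp_idx) | {
        i for i, lab in enumerate(epochs.channel_labels)
        if epochs.meta.get("reference_label") == lab})
    out.data[:, nonocular, :] = epochs.data[:, nonocular, :] - mean
    out.stage = "rereferenced"
    return out
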