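"""Synthetic EEG, behaviour and rating generator with known ground truth.

Emulates a 1000 Hz Cz-referenced multichannel recording of a prime–target
paradigm (60 target trials: 30 with a human-framed agent, 30 AI-framed), in
which each target evokes a positive ~100 ms (P1) and a negative ~170 ms
(N170) deflection at the parieto-occipital sites P7/P8, with per-cell
(identity × site) ground-truth amplitudes, ocular artifacts and optional bad
channels. Rating tables carry a 7-point human < AI negativity gap on two
instruments (attitude, perceived unnaturalness).

Ground-truth convention: a profile cell amplitude is the *adaptive-mean*
amplitude the downstream extraction should report. Bumps are peak-scaled by
the inverse adaptive-mean attenuation and injected as average-reference-
neutral source patterns (counterweighted over the other scalp channels), so
with vanishing noise the pipeline recovers the profile values exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (ContinuousEEG, RESPONSE_NATURAL, RESPONSE_UNNATURAL,
                         ms_to_samples, validate_events)
from .erp import adaptive_attenuation
from .exceptions import ConfigurationError
from .montage import Montage, build_montage  # noqa: F401  (re-exported)

IDENTITIES = ("human", "AI")

# Component shapes used for injection: (latency ms, width ms). The Gaussian
# SD is width/4, so the support (±4 SD) equals ±width.
P1_SHAPE = (100.0, 60.0)
N170_SHAPE = (170.0, 50.0)


@dataclass(frozen=True)
class ParadigmSpec:
    """Timing of the prime–target trial structure."""

    n_trials_per_identity: int = 30
    prime_durations_ms: tuple[float, ...] = (200.0, 300.0, 200.0, 200.0, 300.0)
    target_duration_ms: float = 2000.0
    post_target_blank_ms: float = 3000.0
    response_deadline_ms: float = 5000.0
    onset_offset_ms: float = 11.0
    sampling_rate_hz: float = 1000.0

    def __post_init__(self) -> None:
        durations = (*self.prime_durations_ms, self.target_duration_ms,
                     self.post_target_blank_ms)
        if not all(d > 0 for d in durations):
            raise ConfigurationError("all durations must be positive")
        if self.response_deadline_ms < self.target_duration_ms:
            raise ConfigurationError("deadline must be ≥ target duration")

    @property
    def pre_target_ms(self) -> float:
        return float(sum(self.prime_durations_ms))

    @property
    def trial_ms(self) -> float:
        return (self.pre_target_ms + self.target_duration_ms
                + self.post_target_blank_ms)


@dataclass(frozen=True)
class SubjectProfile:
    """Ground truth for one simulated subject.

    Amplitudes are μV on the adaptive-mean scale (see module docstring);
    N170 cells are negative. Rating means are 7-point scale positions, with
    higher = more negative attitude / more perceived unnaturalness.
    """

    p1_amp_by_cell: dict = field(default_factory=lambda: {
        ("human", "P7"): 4.41, ("human", "P8"): 5.76,
        ("AI", "P7"): 4.41, ("AI", "P8"): 5.76,
    })
    n170_amp_by_cell: dict = field(default_factory=lambda: {
        ("human", "P7"): -0.83, ("human", "P8"): -2.09,
        ("AI", "P7"): -2.27, ("AI", "P8"): -1.90,
    })
    component_latency_jitter_sd: float = 5.0   # ms
    noise_sd: float = 5.0                      # μV per sample, white
    colored_noise: bool = False                # 1/f-shaped instead of white
    blink_rate: float = 4.0                    # events/min
    eye_move_rate: float = 2.0                 # events/min
    bad_channel_ids: frozenset = frozenset()
    p_natural_given_human: float = 0.85
    p_natural_given_AI: float = 0.20
    rating_means: dict = field(default_factory=lambda: {
        ("attitude", "human"): 3.05, ("attitude", "AI"): 3.83,
        ("naturalness", "human"): 2.91, ("naturalness", "AI"): 3.57,
    })

    def __post_init__(self) -> None:
        for p in (self.p_natural_given_human, self.p_natural_given_AI):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("response probabilities must be in [0,1]")
        if not self.noise_sd > 0:
            raise ConfigurationError("noise_sd must be positive")
        for mean in self.rating_means.values():
            if not 1.0 <= mean <= 7.0:
                raise ConfigurationError("rating means must be in [1,7]")

    def amplitude(self, component: str, identity: str, site: str) -> float:
        table = self.p1_amp_by_cell if component == "P1" else self.n170_amp_by_cell
        return float(table[(identity, site)])


# ---------------------------------------------------------------------------
# Signal primitives
# ---------------------------------------------------------------------------

def _gaussian_bump(n_samples: int, onset_ms: float, latency_ms: float,
                   amplitude: float, width_ms: float,
                   rate_hz: float) -> tuple[slice, np.ndarray]:
    """Sample slice and values of a Gaussian bump peaking at onset+latency."""
    if width_ms <= 0:
        raise ConfigurationError("width must be positive")
    sd_ms = width_ms / 4.0
    peak = (onset_ms + latency_ms) * rate_hz / 1000.0
    if not 0 <= peak < n_samples:
        raise ConfigurationError("bump peak outside trace")
    half = int(round(4 * sd_ms * rate_hz / 1000.0))
    lo, hi = int(round(peak)) - half, int(round(peak)) + half + 1
    if lo < 0 or hi > n_samples:
        raise ConfigurationError("bump support extends past trace bounds")
    idx = np.arange(lo, hi)
    t_ms = idx * 1000.0 / rate_hz
    values = amplitude * np.exp(-0.5 * ((t_ms - onset_ms - latency_ms) / sd_ms) ** 2)
    return slice(lo, hi), values


def inject_component(signal: np.ndarray, onset_ms: float, latency_ms: float,
                     amplitude: float, width_ms: float,
                     rate_hz: float = 1000.0) -> np.ndarray:
    """Add a smooth unimodal (Gaussian, SD = width/4) bump to a trace.

    The peak value added at ``onset + latency`` is exactly ``amplitude``;
    the trace is unchanged outside the bump's ±4 SD support.
    """
    signal = np.asarray(signal, dtype=float)
    out = signal.copy()
    if amplitude == 0.0:
        # still validate geometry
        _gaussian_bump(signal.size, onset_ms, latency_ms, 0.0, width_ms, rate_hz)
        return out
    sl, values = _gaussian_bump(signal.size, onset_ms, latency_ms,
                                amplitude, width_ms, rate_hz)
    out[sl] += values
    return out


def _half_sine(duration_ms: float, rate_hz: float) -> np.ndarray:
    n = ms_to_samples(duration_ms, rate_hz)
    return np.sin(np.pi * np.arange(n) / n)


def _trapezoid(rise_ms: float, plateau_ms: float, rate_hz: float) -> np.ndarray:
    r = ms_to_samples(rise_ms, rate_hz)
    p = ms_to_samples(plateau_ms, rate_hz)
    return np.concatenate([np.linspace(0, 1, r, endpoint=False),
                           np.ones(p),
                           np.linspace(1, 0, r, endpoint=False)])


def _add_at(row: np.ndarray, start: int, template: np.ndarray,
            scale: float) -> None:
    """Add ``scale * template`` to ``row`` starting at ``start``, clipped."""
    lo = max(start, 0)
    hi = min(start + template.size, row.size)
    if hi > lo:
        row[lo:hi] += scale * template[lo - start:hi - start]


def _apply_artifact(data: np.ndarray, montage: Montage, labels: list[str],
                    kind: str, onset_ms: float, magnitude: float,
                    rate_hz: float, channel: str | None = None) -> None:
    """In-place artifact injection shared by inject_artifact and the simulator."""
    if magnitude == 0.0:
        return
    idx = {lab: i for i, lab in enumerate(labels)}
    start = ms_to_samples(onset_ms, rate_hz)
    if kind == "blink":
        if not 0 <= start < data.shape[1]:
            raise ConfigurationError("blink onset outside record")
        tpl = _half_sine(300.0, rate_hz)
        voc = montage.ocular_channels("vertical-ocular")
        if not voc:
            raise ConfigurationError("montage has no vertical-ocular channels")
        if len(voc) >= 2:   # bipolar swing = magnitude
            _add_at(data[idx[voc[0]]], start, tpl, +magnitude / 2.0)
            _add_at(data[idx[voc[1]]], start, tpl, -magnitude / 2.0)
        else:
            _add_at(data[idx[voc[0]]], start, tpl, magnitude)
        for lab in montage.frontal_scalp_channels():
            _add_at(data[idx[lab]], start, tpl, 0.4 * magnitude)
    elif kind == "eye_move":
        if not 0 <= start < data.shape[1]:
            raise ConfigurationError("eye movement onset outside record")
        tpl = _trapezoid(50.0, 400.0, rate_hz)
        hoc = montage.ocular_channels("horizontal-ocular")
        if not hoc:
            raise ConfigurationError("montage has no horizontal-ocular channels")
        if len(hoc) >= 2:
            _add_at(data[idx[hoc[0]]], start, tpl, +magnitude / 2.0)
            _add_at(data[idx[hoc[1]]], start, tpl, -magnitude / 2.0)
        else:
            _add_at(data[idx[hoc[0]]], start, tpl, magnitude)
    elif kind == "bad_channel":
        if channel is None:
            candidates = [c for c in montage.scalp_channels()
                          if c not in ("P7", "P8")]
            channel = candidates[0]
        # 5 Hz square wave, peak-to-peak = magnitude: its 100 ms plateaus
        # survive the 80 ms moving-average screening in every segment.
        n = data.shape[1]
        phase = (np.arange(n) * 5.0 / rate_hz) % 1.0
        data[idx[channel]] += np.where(phase < 0.5, magnitude / 2.0,
                                       -magnitude / 2.0)
    else:
        raise ConfigurationError(f"unknown artifact kind {kind!r}")


def inject_artifact(eeg: ContinuousEEG, montage: Montage, kind: str,
                    onset_ms: float, magnitude: float,
                    channel: str | None = None) -> ContinuousEEG:
    """Return a copy of ``eeg`` with one artifact added.

    ``blink``: 300 ms half-sine on the vertical-ocular pair (bipolar swing =
    magnitude) with a 40% copy on frontal scalp channels. ``eye_move``:
    50/400/50 ms trapezoid on the horizontal-ocular pair. ``bad_channel``:
    sustained 5 Hz square wave (peak-to-peak = magnitude) on one channel for
    the whole record.
    """
    out = eeg.copy()
    _apply_artifact(out.data, montage, out.channel_labels, kind, onset_ms,
                    magnitude, eeg.sampling_rate_hz, channel)
    return out


def _background_noise(rng: np.random.Generator, n_ch: int, n_samp: int,
                      sd: float, colored: bool) -> np.ndarray:
    noise = rng.normal(0.0, sd, size=(n_ch, n_samp))
    if colored:
        spec = np.fft.rfft(noise, axis=1)
        freqs = np.fft.rfftfreq(n_samp, d=1.0)
        shape = 1.0 / np.sqrt(np.maximum(freqs, freqs[1]))
        spec *= shape
        noise = np.fft.irfft(spec, n=n_samp, axis=1)
        noise *= sd / noise.std(axis=1, keepdims=True)
    return noise


# ---------------------------------------------------------------------------
# Recording simulation
# ---------------------------------------------------------------------------

def simulate_recording(profile: SubjectProfile, paradigm: ParadigmSpec,
                       montage: Montage, seed: int,
                       adaptive_halfwidth_ms: float = 10.0,
                       lead_ms: float = 2500.0,
                       ) -> tuple[ContinuousEEG, pd.DataFrame]:
    """Simulate one subject's continuous recording and event table.

    Trials alternate through a permuted sequence of 30 human / 30 AI targets;
    behavioural responses are Bernoulli draws from the profile's
    naturalness probabilities and reaction times log-normal, truncated at
    the response deadline. P1/N170 bumps are injected at P7/P8 (11 ms after
    the logged event onset, matching the stimulus-presentation offset the
    epoching later corrects), ocular artifacts at the profile's rates.
    Bit-identical for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    rate = paradigm.sampling_rate_hz
    labels = montage.channel_labels
    n_trials = 2 * paradigm.n_trials_per_identity
    n_samples = ms_to_samples(2 * lead_ms + n_trials * paradigm.trial_ms, rate)

    data = _background_noise(rng, len(labels), n_samples, profile.noise_sd,
                             profile.colored_noise)
    ref_idx = [i for i, lab in enumerate(labels)
               if montage.role(lab) == "reference"]
    data[ref_idx] = 0.0               # a Cz-referenced record has Cz ≡ 0

    identities = np.array(["human"] * paradigm.n_trials_per_identity
                          + ["AI"] * paradigm.n_trials_per_identity)
    identities = rng.permutation(identities)

    scalp = montage.scalp_channels()
    counterweights = [lab for lab in scalp if lab not in ("P7", "P8")]
    idx = {lab: i for i, lab in enumerate(labels)}
    offset_samples = ms_to_samples(paradigm.onset_offset_ms, rate)

    records = []
    for t, identity in enumerate(identities):
        onset_ms = lead_ms + t * paradigm.trial_ms + paradigm.pre_target_ms
        onset_sample = ms_to_samples(onset_ms, rate)
        stim_ms = (onset_sample + offset_samples) * 1000.0 / rate

        p_nat = (profile.p_natural_given_human if identity == "human"
                 else profile.p_natural_given_AI)
        natural = rng.random() < p_nat
        response = RESPONSE_NATURAL if natural else RESPONSE_UNNATURAL
        rt = float(np.clip(rng.lognormal(np.log(800.0), 0.35), 200.0,
                           paradigm.response_deadline_ms - 1.0))

        for component, (latency, width) in (("P1", P1_SHAPE),
                                            ("N170", N170_SHAPE)):
            atten = adaptive_attenuation(width, adaptive_halfwidth_ms, rate)
            jitter = rng.normal(0.0, profile.component_latency_jitter_sd)
            for site in ("P7", "P8"):
                amp = profile.amplitude(component, identity, site) / atten
                sl, values = _gaussian_bump(n_samples, stim_ms,
                                            latency + jitter, amp, width, rate)
                data[idx[site], sl] += values
                for cw in counterweights:
                    data[idx[cw], sl] -= values / len(counterweights)

        records.append({"onset_sample": onset_sample, "identity": identity,
                        "response": response, "rt_ms": rt})

    minutes = n_samples / rate / 60.0
    for kind, rate_per_min, loc, spread, floor in (
            ("blink", profile.blink_rate, 220.0, 25.0, 160.0),
            ("eye_move", profile.eye_move_rate, 80.0, 15.0, 60.0)):
        n_events = rng.poisson(rate_per_min * minutes)
        for _ in range(n_events):
            onset = rng.uniform(100.0, n_samples / rate * 1000.0 - 600.0)
            magnitude = max(float(rng.normal(loc, spread)), floor)
            _apply_artifact(data, montage, labels, kind, onset, magnitude, rate)

    for channel in sorted(profile.bad_channel_ids):
        _apply_artifact(data, montage, labels, "bad_channel", 0.0, 300.0,
                        rate, channel=channel)

    eeg = ContinuousEEG(data=data, sampling_rate_hz=rate,
                        channel_labels=list(labels), reference="Cz")
    events = validate_events(pd.DataFrame.from_records(records))
    return eeg, events


# ---------------------------------------------------------------------------
# Rating simulation
# ---------------------------------------------------------------------------

def simulate_ratings(profile: SubjectProfile, n_subjects: int, seed: int,
                     item_sd: float = 0.8, subject_sd: float = 0.5,
                     n_items: int = 3) -> pd.DataFrame:
    """Simulate 7-point rating items for both instruments and agents.

    Each item is ``clip(round(mean + subject shift + item noise), 1, 7)``;
    the subject shift is shared across agents and instruments, so it cancels
    in within-subject contrasts, as trait response styles do.
    """
    if n_subjects < 2:
        raise ConfigurationError("need at least two subjects")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(1, n_subjects + 1):
        shift = rng.normal(0.0, subject_sd) if subject_sd > 0 else 0.0
        for (instrument, agent), mean in sorted(profile.rating_means.items()):
            for item in range(1, n_items + 1):
                noise = rng.normal(0.0, item_sd) if item_sd > 0 else 0.0
                score = int(np.clip(round(mean + shift + noise), 1, 7))
                rows.append({"subject": f"sub-{s:02d}", "agent": agent,
                             "instrument": instrument, "item": item,
                             "score": score})
    return pd.DataFrame(rows)


def rating_means_table(ratings: pd.DataFrame) -> pd.DataFrame:
    """Per-subject per-agent instrument means (the analysed quantities)."""
    return (ratings.groupby(["subject", "instrument", "agent"])["score"]
            .mean().rename("mean_score").reset_index())


# ---------------------------------------------------------------------------
# Cohort model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortModel:
    """Population distribution the per-subject profiles are drawn from.

    Cell means follow the study-scale pattern: P1 larger at the
    face-specific P8 than the text-specific P7 regardless of identity; N170
    more negative for human/face than human/text, and more negative for
    AI/text than human/text. A per-subject offset shared across a
    component's four cells models stable individual amplitude differences;
    the cell-specific deviation is what limits within-subject contrasts.
    """

    p1_means: dict = field(default_factory=lambda: {
        ("human", "P7"): 4.41, ("human", "P8"): 5.76,
        ("AI", "P7"): 4.41, ("AI", "P8"): 5.76,
    })
    n170_means: dict = field(default_factory=lambda: {
        ("human", "P7"): -0.83, ("human", "P8"): -2.09,
        ("AI", "P7"): -2.27, ("AI", "P8"): -1.90,
    })
    subject_offset_sd: float = 2.0     # μV, shared within a component
    cell_sd: float = 0.8               # μV, independent per cell
    min_abs_amp: float = 0.2           # μV, polarity floor for drawn truths
    bad_channel_prob: float = 0.15
    base: SubjectProfile = field(default_factory=SubjectProfile)

    def sample_profile(self, rng: np.random.Generator) -> SubjectProfile:
        # Draws are clipped at the component's polarity: a P1 is positive and
        # an N170 negative by definition, and a fixed-polarity adaptive-mean
        # measure could not recover a sign-flipped "component" anyway.
        p1_off = rng.normal(0.0, self.subject_offset_sd)
        n170_off = rng.normal(0.0, self.subject_offset_sd)
        p1 = {cell: max(mean + p1_off + rng.normal(0.0, self.cell_sd),
                        self.min_abs_amp)
              for cell, mean in sorted(self.p1_means.items())}
        n170 = {cell: min(mean + n170_off + rng.normal(0.0, self.cell_sd),
                          -self.min_abs_amp)
                for cell, mean in sorted(self.n170_means.items())}
        bad: frozenset = frozenset()
        if rng.random() < self.bad_channel_prob:
            candidates = ["O1", "O2", "F3", "F4", "Pz"]
            bad = frozenset({candidates[rng.integers(len(candidates))]})
        return replace(self.base, p1_amp_by_cell=p1, n170_amp_by_cell=n170,
                       bad_channel_ids=bad)


def simulate_cohort(n_subjects: int, seed: int,
                    paradigm: ParadigmSpec | None = None,
                    montage: Montage | None = None,
                    model: CohortModel | None = None,
                    ) -> tuple[list[dict], pd.DataFrame]:
    """Simulate a full cohort: per-subject (profile, eeg, events) + ratings.

    Returns a list of dicts with keys ``subject``, ``profile``, ``eeg``,
    ``events`` and the pooled long-format rating table.
    """
    paradigm = paradigm or ParadigmSpec()
    montage = montage or build_montage()
    model = model or CohortModel()
    root = np.random.SeedSequence(seed)
    profile_rng = np.random.default_rng(root.spawn(1)[0])
    subject_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                     for s in root.spawn(n_subjects + 1)[1:]]
    records = []
    for s in range(n_subjects):
        profile = model.sample_profile(profile_rng)
        eeg, events = simulate_recording(profile, paradigm, montage,
                                         seed=subject_seeds[s])
        records.append({"subject": f"sub-{s + 1:02d}", "profile": profile,
                        "eeg": eeg, "events": events})
    ratings = simulate_ratings(model.base, n_subjects,
                               seed=int(root.generate_state(1)[0] % (2 ** 31)))
    return records, ratings


def simulate_amplitude_table(model: CohortModel, n_subjects: int,
                             rng: np.random.Generator,
                             measurement_sd: float = 0.7) -> pd.DataFrame:
    """Draw an amplitude table directly from the cohort amplitude model.

    Used by power/type-I studies where full-signal simulation is not needed:
    per subject, true cell amplitudes from :meth:`CohortModel.sample_profile`
    plus independent measurement noise per cell (``measurement_sd``,
    calibrated against the full pipeline's extraction residual).
    """
    rows = []
    for s in range(1, n_subjects + 1):
        profile = model.sample_profile(rng)
        for component in ("P1", "N170"):
            for identity in IDENTITIES:
                for site in ("P7", "P8"):
                    amp = (profile.amplitude(component, identity, site)
                           + rng.normal(0.0, measurement_sd))
                    rows.append({"subject": f"sub-{s:02d}",
                                 "component": component,
                                 "identity": identity, "site": site,
                                 "amplitude_uv": amp})
    return pd.DataFrame(rows)
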