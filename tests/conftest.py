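import numpy as np
import pandas as pd
import pytest

from erpnat.containers import Epochs
from erpnat.montage import build_montage
from erpnat.synth import ParadigmSpec, SubjectProfile


@pytest.fixture(scope="session")
def montage16():
    return build_montage(16)


@pytest.fixture(scope="session")
def quiet_profile():
    """Essentially noise- and artifact-free subject with deterministic behaviour."""
    return SubjectProfile(
        noise_sd=1e-9, blink_rate=0.0, eye_move_rate=0.0,
        component_latency_jitter_sd=0.0,
        p_natural_given_human=1.0, p_natural_given_AI=0.0,
    )


@pytest.fixture(scope="session")
def short_paradigm():
    return ParadigmSpec(n_trials_per_identity=5)


def make_epochs(montage, n_epochs=4, fill=0.0, rate=1000.0,
                window=(-200.0, 1000.0), stage="segmented"):
    """Blank segmented epochs on a montage, ready for artifact screening."""
    labels = montage.channel_labels
    n_samp = int(round((window[1] - window[0]) * rate / 1000.0))
    data = np.full((n_epochs, len(labels), n_samp), float(fill))
    conditions = np.array(
        ["human-natural" if i % 2 == 0 else "AI-unnatural"
         for i in range(n_epochs)], dtype=object)
    return Epochs(data=data, conditions=conditions, sampling_rate_hz=rate,
                  channel_labels=list(labels), window_ms=window, stage=stage)


@pytest.fixture
def blank_epochs(montage16):
    return make_epochs(montage16)


def square_pulse(n_samples, start, width, amplitude):
    """A sustained plateau whose smoothed range stays ≈ amplitude."""
    trace = np.zeros(n_samples)
    trace[start:start + width] = amplitude
    return trace


def rand_amplitude_table(rng, n_subjects=12, effects=(0.0, 0.0, 0.0), sd=1.0):
    """Random 2×2 within-subject amplitude table with optional true effects."""
    a_eff, b_eff, ab_eff = effects
    rows = []
    for s in range(n_subjects):
        base = rng.normal(0, 1)
        for i, identity in enumerate(("human", "AI")):
            for j, site in enumerate(("P7", "P8")):
                mu = a_eff * i + b_eff * j + ab_eff * i * j
                rows.append({
                    "subject": f"s{s}", "component": "P1",
                    "identity": identity, "site": site,
                    "amplitude_uv": base + mu + rng.normal(0, sd),
                })
    return pd.DataFrame(rows)
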