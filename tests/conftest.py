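"""Shared fixtures: small sessions for mechanics, full-size sessions for
recovery properties (session-scoped; the EEG chain is the expensive part)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from coupledraw import behaviour, coherence, spectral
from coupledraw.core import BAND_PRESETS, MOTOR_CHANNELS
from coupledraw.synthetic import SessionConfig, generate_session

CHANNELS = list(MOTOR_CHANNELS)
BANDS = BAND_PRESETS["default"]


def run_eeg_chain(eeg):
    """Filter, epoch and time-frequency transform a session."""
    epochs = spectral.epoch_trials(spectral.bandpass_filter(eeg))
    maps = spectral.session_tf_maps(epochs, CHANNELS)
    return epochs, maps


@pytest.fixture(scope="session")
def small_session():
    """20-trial session, default encoding; for mechanics, not recovery."""
    cfg = SessionConfig(n_trials=20, trials_per_condition=5, seed=7)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def nonlinear_chain():
    """Full 240-trial distributed_nonlinear session with derived tables.

    Session-scoped: shared by the recovery-contrast checks and by feature
    shape/consistency tests so the EEG chain runs once.
    """
    cfg = SessionConfig(seed=11, encoding_mode="distributed_nonlinear")
    trials, eeg, truth = generate_session(cfg)
    curv = behaviour.curvature_table(trials)
    ci = curv.set_index("trial_id")["ci"]
    epochs, maps = run_eeg_chain(eeg)
    erd = spectral.erd_table(maps, BANDS, CHANNELS)
    coh = coherence.coherence_table(epochs, CHANNELS, BANDS)
    features = spectral.feature_matrix(maps, BANDS, CHANNELS)
    return {
        "trials": trials, "truth": truth, "curv": curv, "ci": ci,
        "epochs": epochs, "maps": maps, "erd": erd, "coh": coh,
        "features": features, "seed": 11,
    }


@pytest.fixture(scope="session")
def univariate_chain():
    """Full 240-trial univariate-encoding session with its ERD table."""
    cfg = SessionConfig(seed=12, encoding_mode="univariate")
    trials, eeg, truth = generate_session(cfg)
    ci = behaviour.curvature_table(trials).set_index("trial_id")["ci"]
    _, maps = run_eeg_chain(eeg)
    erd = spectral.erd_table(maps, BANDS, CHANNELS)
    return {"trials": trials, "truth": truth, "ci": ci, "erd": erd}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def circle_trajectory(radius: float = 50.0, cx: float = 0.0, cy: float = 0.0,
                      n: int = 500) -> np.ndarray:
    t = np.linspace(0.0, 5.0, n)
    th = 2 * np.pi * t / 5.0
    return np.column_stack([t, cx + radius * np.cos(th), cy + radius * np.sin(th)])
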