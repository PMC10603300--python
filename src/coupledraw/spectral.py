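"""EEG preprocessing and time-frequency features.

The chain mirrors a conventional movement-EEG analysis: zero-phase
Butterworth band-pass (0.5-35 Hz), optional mastoid re-referencing,
variable-length epochs from 2 s before trial onset to trial offset, a
continuous Morlet wavelet transform on a 50-point 1-35 Hz grid, log10 power
relative to the mean power in the -2000..-500 ms pre-onset baseline, and
linear resampling of the trial window onto 200 normalised time points so
every trial yields a 200 x 50 log-ratio matrix per channel.  Negative
log-ratio values indicate suppression relative to baseline
(event-related desynchronisation, ERD); positive values enhancement.

From the maps come the two feature families:

* ERD values — the in-band, all-time mean of a trial/channel map
  (9 channels x 2 bands = 18 scalars per trial);
* the multivariate feature vector — the in-band mean at each of the 200
  time points, keeping temporal dynamics, concatenated channel-major then
  band-major into 3600 values per trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from mne.time_frequency import tfr_array_morlet
from scipy import signal

from .core import MOTOR_CHANNELS, BandSpec, EEGSession

logger = logging.getLogger(__name__)

N_TIME_POINTS = 200
N_FREQS = 50
FREQ_GRID = np.linspace(1.0, 35.0, N_FREQS)
PRE_ONSET_S = 2.0
BASELINE_WINDOW_S = (-2.0, -0.5)

#: Morlet cycles per frequency: scale with frequency, floored at 3 so the
#: longest wavelet (~4.8 s at 1 Hz) still fits the shortest admissible
#: epoch, capped at 7.
MORLET_CYCLES = np.clip(FREQ_GRID / 2.0, 3.0, 7.0)


@dataclass
class TimeFrequencyMap:
    """One trial/channel 200 x 50 log-ratio matrix on a normalised time grid."""

    trial_id: int
    channel: str
    values: np.ndarray            # (N_TIME_POINTS, N_FREQS)
    freqs: np.ndarray = None      # Hz grid, length N_FREQS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.freqs is None:
            self.freqs = FREQ_GRID.copy()
        if self.values.shape != (N_TIME_POINTS, N_FREQS):
            raise ValueError(
                f"map must be {N_TIME_POINTS} x {N_FREQS}, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map contains non-finite values")


@dataclass
class Epoch:
    """Variable-length epoch: -PRE_ONSET_S..offset relative to trial onset."""

    trial_id: int
    condition: str
    data: np.ndarray      # (n_channels, n_samples)
    sfreq: float
    pre_s: float          # seconds of pre-onset context included

    @property
    def n_trial_samples(self) -> int:
        return self.data.shape[1] - int(round(self.pre_s * self.sfreq))


# ---------------------------------------------------------------------------
# preprocessing


def bandpass_filter(session: EEGSession, lo: float = 0.5, hi: float = 35.0) -> EEGSession:
    """Zero-phase 4th-order Butterworth band-pass, per channel.

    Forward-backward application doubles the effective roll-off
    (24 dB/octave) and cancels phase distortion; the pass band removes DC.
    """
    nyq = session.sfreq / 2
    if not 0 < lo < hi < nyq:
        raise ValueError(f"need 0 < lo < hi < {nyq} Hz, got ({lo}, {hi})")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=session.sfreq, output="sos")
    data = signal.sosfiltfilt(sos, session.data, axis=1)
    return EEGSession(data=data, channels=list(session.channels),
                      sfreq=session.sfreq, events=session.events)


def rereference(session: EEGSession, reference_channels: list[str]) -> EEGSession:
    """Subtract the mean of the reference channels from every channel.

    With an empty reference list this is a pass-through (the synthetic
    generator emits already-referenced data).
    """
    if not reference_channels:
        return session
    missing = [c for c in reference_channels if c not in session.channels]
    if missing:
        raise ValueError(f"reference channels not in session: {missing}")
    ref = np.mean([session.pick(c) for c in reference_channels], axis=0)
    return EEGSession(data=session.data - ref, channels=list(session.channels),
                      sfreq=session.sfreq, events=session.events)


def epoch_trials(session: EEGSession, pre_s: float = PRE_ONSET_S) -> list[Epoch]:
    """Cut one variable-length epoch per trial, -pre_s..offset.

    Trials without ``pre_s`` seconds of recording before onset are excluded
    with a log entry rather than zero-padded.
    """
    fs = session.sfreq
    epochs: list[Epoch] = []
    for ev in session.events.itertuples():
        i0 = int(round((ev.onset_s - pre_s) * fs))
        i1 = int(round(ev.offset_s * fs))
        if i0 < 0:
            logger.warning(
                "trial %s excluded: needs %.1f s pre-onset, has %.2f s",
                ev.trial_id, pre_s, ev.onset_s,
            )
            continue
        epochs.append(
            Epoch(trial_id=int(ev.trial_id), condition=ev.condition,
                  data=session.data[:, i0:i1], sfreq=fs, pre_s=pre_s)
        )
    return epochs


# ---------------------------------------------------------------------------
# time-frequency


def morlet_tf(epoch_data: np.ndarray, sfreq: float,
              freqs: np.ndarray = FREQ_GRID,
              n_cycles: np.ndarray = MORLET_CYCLES) -> np.ndarray:
    """Morlet wavelet power of one epoch.

    epoch_data is (n_channels, n_times); returns power of shape
    (n_channels, n_times, n_freqs), non-negative, at native time
    resolution.
    """
    epoch_data = np.atleast_2d(np.asarray(epoch_data, dtype=float))
    longest = np.max(5.0 * (n_cycles / (2 * np.pi * np.asarray(freqs))) * 2)
    if epoch_data.shape[1] / sfreq <= longest:
        raise ValueError(
            f"epoch ({epoch_data.shape[1] / sfreq:.2f} s) shorter than the "
            f"longest wavelet ({longest:.2f} s)"
        )
    power = tfr_array_morlet(
        epoch_data[np.newaxis], sfreq=sfreq, freqs=freqs, n_cycles=n_cycles,
        output="power", verbose="error",
    )[0]
    return np.transpose(power, (0, 2, 1))  # -> (channels, times, freqs)


def baseline_logratio(power: np.ndarray, baseline_power: np.ndarray) -> np.ndarray:
    """log10(power / per-frequency baseline mean), elementwise.

    power is (..., n_times, n_freqs); baseline_power is the per-frequency
    mean power over the pre-onset baseline window.  Negative output means
    suppression relative to baseline, positive enhancement.
    """
    baseline_power = np.asarray(baseline_power, dtype=float)
    if np.any(baseline_power <= 0) or not np.all(np.isfinite(baseline_power)):
        bad = np.where(~(baseline_power > 0))[0]
        raise ValueError(f"non-positive baseline power at frequency indices {bad}")
    return np.log10(power / baseline_power)


def resample_time(matrix: np.ndarray, n_out: int = N_TIME_POINTS) -> np.ndarray:
    """Linear interpolation of each frequency column onto ``n_out`` equally
    spaced points spanning the input's time extent."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("matrix must be (n_times >= 2, n_freqs)")
    n_in = matrix.shape[0]
    t_in = np.linspace(0.0, 1.0, n_in)
    t_out = np.linspace(0.0, 1.0, n_out)
    out = np.empty((n_out, matrix.shape[1]))
    for j in range(matrix.shape[1]):
        out[:, j] = np.interp(t_out, t_in, matrix[:, j])
    return out


def epoch_tf_maps(epoch: Epoch, channels: list[str] | None = None) -> list[TimeFrequencyMap]:
    """Full per-epoch chain: Morlet power -> baseline log-ratio over the
    -2000..-500 ms window (per-frequency geometric-mean power) ->
    200-point trial-window resampling.

    Returns one 200 x 50 map per channel, covering onset..offset on a
    normalised time grid.
    """
    fs = epoch.sfreq
    power = morlet_tf(epoch.data, fs)  # (ch, times, freqs)
    i_pre = int(round(epoch.pre_s * fs))
    b0 = i_pre + int(round(BASELINE_WINDOW_S[0] * fs))
    b1 = i_pre + int(round(BASELINE_WINDOW_S[1] * fs))
    if b0 < 0 or b1 <= b0:
        raise ValueError("baseline window does not fit in the pre-onset span")
    maps = []
    labels = channels if channels is not None else list(MOTOR_CHANNELS)
    for c in range(power.shape[0]):
        # per-frequency geometric mean: with single-trial wavelet power the
        # arithmetic baseline mean sits ~0.25 log10 units above the mean of
        # the log, so an arithmetic baseline would report spurious
        # suppression even for stationary noise
        baseline = 10.0 ** np.log10(power[c, b0:b1]).mean(axis=0)
        lr = baseline_logratio(power[c], baseline)
        trial_lr = lr[i_pre:]
        maps.append(
            TimeFrequencyMap(
                trial_id=epoch.trial_id,
                channel=labels[c],
                values=resample_time(trial_lr),
            )
        )
    return maps


def session_tf_maps(epochs: list[Epoch], channels: list[str]) -> dict[int, dict[str, TimeFrequencyMap]]:
    """TF maps for all epochs, keyed [trial_id][channel]."""
    return {
        ep.trial_id: {m.channel: m for m in epoch_tf_maps(ep, channels)}
        for ep in epochs
    }


# ---------------------------------------------------------------------------
# features


def compute_erd(tf: TimeFrequencyMap, band: BandSpec) -> float:
    """Mean log-ratio over all 200 time points and the in-band frequencies."""
    mask = band.mask(tf.freqs)
    if not mask.any():
        raise ValueError(f"band {band.name} covers no grid frequencies")
    return float(tf.values[:, mask].mean())


def erd_table(tf_maps: dict[int, dict[str, TimeFrequencyMap]],
              bands: tuple[BandSpec, BandSpec],
              channels: list[str] = list(MOTOR_CHANNELS)) -> pd.DataFrame:
    """Per-trial ERD for every channel x band, columns ``"{ch}_{band}"``."""
    rows = []
    for trial_id in sorted(tf_maps):
        row = {"trial_id": trial_id}
        for ch in channels:
            for band in bands:
                row[f"{ch}_{band.name}"] = compute_erd(tf_maps[trial_id][ch], band)
        rows.append(row)
    return pd.DataFrame(rows)


def build_feature_vector(tfs: dict[str, TimeFrequencyMap],
                         bands: tuple[BandSpec, BandSpec],
                         channels: list[str] = list(MOTOR_CHANNELS)) -> np.ndarray:
    """3600-value multivariate representation of one trial.

    For each channel and band, average the map across in-band frequencies
    at each of the 200 time points (temporal dynamics preserved), then
    concatenate channel-major, band-minor: [ch0-band0 (200), ch0-band1
    (200), ch1-band0, ...].
    """
    missing = [c for c in channels if c not in tfs]
    if missing:
        raise ValueError(f"missing channels: {missing}")
    parts = []
    for ch in channels:
        tf = tfs[ch]
        for band in bands:
            mask = band.mask(tf.freqs)
            if not mask.any():
                raise ValueError(f"band {band.name} covers no grid frequencies")
            parts.append(tf.values[:, mask].mean(axis=1))
    return np.concatenate(parts)


def feature_matrix(tf_maps: dict[int, dict[str, TimeFrequencyMap]],
                   bands: tuple[BandSpec, BandSpec],
                   channels: list[str] = list(MOTOR_CHANNELS)) -> pd.DataFrame:
    """Trials x 3600 feature matrix indexed by trial_id."""
    ids = sorted(tf_maps)
    X = np.vstack([build_feature_vector(tf_maps[i], bands, channels) for i in ids])
    return pd.DataFrame(X, index=pd.Index(ids, name="trial_id"))
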