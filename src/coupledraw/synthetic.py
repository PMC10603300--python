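"""Synthetic circle-line drawing sessions with known ground-truth coupling.

The generator emulates one participant's session of the bimanual circle-line
task: 240 trials (60 per condition, pseudo-random order with no condition
repeated more than 4 times in a row), variable trial durations around
7.26 +/- 1.91 s, pen trajectories for both hands, and continuous 9-channel
motor-strip EEG at 256 Hz whose alpha/beta envelopes can carry a
configurable encoding of each trial's coupling index (CI).

Interference model
------------------
Each hand's nominal shape (a vertical line, or a circle of radius 190 px)
is morphed toward the *other* hand's nominal shape by a convex blend with
weight equal to the trial's coupling strength.  In incongruent trials this
reproduces the classic phenomenology: lines bulge horizontally and circles
flatten.  In congruent trials the blend is a no-op, so the two curvatures
differ only through motor variability and the coupling index stays high.

EEG forward model
-----------------
Each channel is pink (1/f) background noise — an independent component plus
a component shared across channels, which keeps cross-channel coherence
non-degenerate — plus alpha (8-13 Hz) and beta (13-30 Hz) band-limited
oscillations.  During each trial every band envelope drops by a generic
movement-related desynchronisation factor; on top of that, encoding_mode
decides how the trial's latent coupling drive modulates the envelopes:

``none``
    no dependence on the drive anywhere;
``univariate``
    only the C3 alpha envelope carries the drive, linearly;
``distributed_linear``
    a fixed linear mixture over six channel-band envelopes carries it;
``distributed_nonlinear``
    eight channel-band carriers show a desynchronisation dip of fixed depth
    whose within-trial *timing* moves with the drive, with independent
    per-carrier timing jitter.  Trial-mean band power is then
    drive-independent (so ERD and coherence carry nothing), and recovery
    requires estimating dip latency — a nonlinear functional of the
    envelope time-course — and pooling it across several channel-bands
    (see :func:`nonlinear_oracle_readout`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.stats import truncnorm

from .behaviour import compute_ci, compute_curvature
from .core import (
    CONDITIONS,
    MOTOR_CHANNELS,
    EEGSession,
    TrialRecord,
    substream,
)

ENCODING_MODES = ("none", "univariate", "distributed_linear", "distributed_nonlinear")

#: Channel-band carriers of the distributed_nonlinear latency code.  Each
#: carrier's within-trial desynchronisation dip is centred at a normalised
#: time set by the trial's drive plus independent per-carrier jitter, so the
#: drive can only be read out by estimating and pooling dip latencies across
#: several carriers — a nonlinear function of the envelope time-courses.
NONLINEAR_CARRIERS: tuple[tuple[str, str], ...] = tuple(
    (ch, band)
    for ch in ("FC3", "FCz", "FC4", "C3", "Cz", "C4", "CP3", "CPz", "CP4")
    for band in ("alpha", "beta")
)

#: Fixed mixture for distributed_linear (channel, band, weight).
LINEAR_MIXTURE: tuple[tuple[str, str, float], ...] = (
    ("C3", "alpha", 1.0),
    ("C4", "alpha", 1.0),
    ("FCz", "alpha", 0.5),
    ("C3", "beta", -0.5),
    ("C4", "beta", -0.5),
    ("CPz", "beta", 0.5),
)


@dataclass(frozen=True)
class SessionConfig:
    """Study-condition parameters of one simulated session."""

    n_trials: int = 240
    trials_per_condition: int = 60
    sampling_rate_hz: float = 256.0
    channels: tuple[str, ...] = MOTOR_CHANNELS
    trial_duration_mean_s: float = 7.26
    trial_duration_sd_s: float = 1.91
    trial_duration_min_s: float = 3.0
    rest_s: float = 5.0
    encoding_mode: str = "distributed_nonlinear"
    snr: float = 1.0
    coupling_strength: float = 0.3
    seed: int = 0
    # trajectory nuisance parameters (pixels unless noted)
    pen_rate_hz: float = 60.0
    circle_radius_px: float = 190.0
    shape_iterations: int = 6
    jitter_px: float = 2.0
    amplitude_sd: float = 0.03          # common per-trial scale variability
    hand_asymmetry: float = 0.05        # right hand draws slightly larger
    hand_scale_sd: float = 0.006        # residual per-hand scale noise
    line_bow_px: float = 50.0           # mean horizontal half-extent of a drawn "line"
    line_bow_sd: float = 0.02           # relative per-hand bow variability
    line_bow_asymmetry: float = 0.12    # right-hand lines bow systematically more
    # EEG nuisance parameters
    erd_gain: float = 0.8               # generic movement-related envelope drop
    encoding_depth: float = 0.7         # max fractional envelope modulation
    bump_width: float = 0.12            # dip width, normalised trial time (sd)
    latency_span: float = 0.25          # dip-centre swing per unit drive
    latency_jitter: float = 0.15        # per-carrier dip-centre jitter (sd)
    shared_noise_frac: float = 0.4      # amplitude fraction of shared pink noise
    output_scale_uv: float = 10.0

    def __post_init__(self) -> None:
        if self.n_trials != 4 * self.trials_per_condition:
            raise ValueError("n_trials must equal 4 * trials_per_condition")
        if not self.channels or len(set(self.channels)) != len(self.channels):
            raise ValueError("channel list must be non-empty with unique labels")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if not 0 <= self.coupling_strength <= 1:
            raise ValueError("coupling_strength must lie in [0, 1]")
        if self.encoding_mode not in ENCODING_MODES:
            raise ValueError(
                f"encoding_mode must be one of {ENCODING_MODES}, got {self.encoding_mode!r}"
            )


@dataclass
class GroundTruth:
    """Per-trial generative targets: true CI and the latent coupling drive."""

    true_ci: np.ndarray
    drive: np.ndarray
    encoding_mode: str
    carrier_latency: np.ndarray | None = None  # (n_trials, n_carriers), nonlinear mode

    def __post_init__(self) -> None:
        self.true_ci = np.asarray(self.true_ci, dtype=float)
        self.drive = np.asarray(self.drive, dtype=float)
        if self.true_ci.shape != self.drive.shape:
            raise ValueError("true_ci and drive must be aligned")
        if not np.all(np.isfinite(self.true_ci)) or np.any(self.true_ci <= 0):
            raise ValueError("true CI must be finite and positive")

    def frame(self, trials: list[TrialRecord]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_id": [t.trial_id for t in trials],
                "true_ci": self.true_ci,
                "condition": [t.condition for t in trials],
            }
        )


# ---------------------------------------------------------------------------
# trajectories


def _nominal_xy(shape: str, theta: np.ndarray, radius: float
                ) -> tuple[np.ndarray, np.ndarray]:
    if shape == "line":
        return np.zeros_like(theta), radius * np.sin(theta)
    if shape == "circle":
        return radius * np.cos(theta), radius * np.sin(theta)
    raise ValueError(f"unknown shape {shape!r}")


def generate_trajectory(
    condition: str,
    coupling_strength: float,
    duration_s: float,
    rng: np.random.Generator,
    *,
    pen_rate_hz: float = 60.0,
    circle_radius_px: float = 190.0,
    shape_iterations: int = 6,
    jitter_px: float = 2.0,
    amplitude_sd: float = 0.03,
    hand_asymmetry: float = 0.05,
    hand_scale_sd: float = 0.006,
    line_bow_px: float = 50.0,
    line_bow_sd: float = 0.02,
    line_bow_asymmetry: float = 0.12,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate both hands' pen trajectories for one trial.

    Returns (left, right), each an (n, 3) array of (t_s, x_px, y_px)
    covering ``shape_iterations`` repetitions of the instructed shape at a
    fixed pen sampling rate.  The coupling morph is a convex blend of each
    hand's nominal shape with the other hand's nominal shape, with weight
    ``coupling_strength``; horizontal bulge/flattening is therefore
    monotone in the coupling strength.
    """
    if condition not in CONDITIONS:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        )
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    w = float(coupling_strength)
    if not 0 <= w <= 1:
        raise ValueError("coupling_strength must lie in [0, 1]")

    shape_left, shape_right = condition.split("-")
    n = max(int(round(duration_s * pen_rate_hz)), 2)
    t = np.arange(n) / pen_rate_hz
    theta = 2 * np.pi * shape_iterations * t / duration_s

    # common trial scale and per-hand residuals; the right hand draws
    # slightly larger (handedness), which keeps congruent curvature
    # differences away from zero, as in real participants
    common = 1.0 + amplitude_sd * rng.standard_normal()
    scale = {
        "left": common * (1.0 + hand_scale_sd * rng.standard_normal()),
        "right": common * (1.0 + hand_asymmetry + hand_scale_sd * rng.standard_normal()),
    }

    # horizontal postural sway ("bow"): the motor variability that gives
    # real drawn lines their non-zero horizontal extent; additive, outside
    # the coupling blend, so the morph is strictly monotone in coupling
    bow = {
        "left": line_bow_px * (1.0 + line_bow_sd * rng.standard_normal()),
        "right": line_bow_px * (1.0 + line_bow_asymmetry
                                + line_bow_sd * rng.standard_normal()),
    }
    out = {}
    for hand, own, other in (("left", shape_left, shape_right), ("right", shape_right, shape_left)):
        x_own, y_own = _nominal_xy(own, theta, circle_radius_px)
        x_oth, y_oth = _nominal_xy(other, theta, circle_radius_px)
        x = ((1 - w) * x_own + w * x_oth) * scale[hand] + bow[hand] * np.sin(theta)
        y = ((1 - w) * y_own + w * y_oth) * scale[hand]
        if jitter_px > 0:
            x = x + jitter_px * rng.standard_normal(n)
            y = y + jitter_px * rng.standard_normal(n)
        out[hand] = np.column_stack([t, x, y])
    return out["left"], out["right"]


# ---------------------------------------------------------------------------
# trial schedule


def _condition_order(trials_per_condition: int, rng: np.random.Generator,
                     max_run: int = 4, retries: int = 1000) -> list[str]:
    """Shuffled condition sequence with no run longer than ``max_run``."""
    base = [c for c in CONDITIONS for _ in range(trials_per_condition)]
    for _ in range(retries):
        order = list(rng.permutation(base))
        run, longest = 1, 1
        for a, b in zip(order, order[1:]):
            run = run + 1 if a == b else 1
            longest = max(longest, run)
        if longest <= max_run:
            return order
    raise RuntimeError(
        f"no condition order with runs <= {max_run} found in {retries} shuffles"
    )


def _trial_durations(cfg: SessionConfig, rng: np.random.Generator) -> np.ndarray:
    a = (cfg.trial_duration_min_s - cfg.trial_duration_mean_s) / cfg.trial_duration_sd_s
    return truncnorm.rvs(
        a, np.inf, loc=cfg.trial_duration_mean_s, scale=cfg.trial_duration_sd_s,
        size=cfg.n_trials, random_state=rng,
    )


# ---------------------------------------------------------------------------
# EEG


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-amplitude Gaussian noise via spectral shaping."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # keep DC finite; removed below
    spectrum /= np.sqrt(f)
    x = np.fft.irfft(spectrum, n)
    x -= x.mean()
    return x / x.std()


def _band_noise(n: int, sfreq: float, lo: float, hi: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise (4th-order Butterworth)."""
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=sfreq, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _envelope(n: int, sfreq: float, events: pd.DataFrame,
              trial_gains: list[float | np.ndarray],
              erd_gain: float, ramp_s: float = 0.25) -> np.ndarray:
    """Band-amplitude envelope over the whole recording.

    1 at rest; inside each trial, erd_gain times that trial's encoding gain
    (a scalar, or an array over the trial's samples for time-varying
    codes); raised-cosine ramps join the rest level to the trial level.
    """
    env = np.ones(n)
    nramp = int(round(ramp_s * sfreq))
    ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, nramp)))
    for (_, ev), g in zip(events.iterrows(), trial_gains):
        i0 = int(round(ev.onset_s * sfreq))
        i1 = int(round(ev.offset_s * sfreq))
        level = erd_gain * np.asarray(g, dtype=float)
        if level.ndim == 0:
            level = np.full(i1 - i0, float(level))
        env[i0:i1] = level
        lo = max(i0 - nramp, 0)
        env[lo:i0] = 1 + (level[0] - 1) * ramp[-(i0 - lo):]
        hi = min(i1 + nramp, n)
        env[i1:hi] = level[-1] + (1 - level[-1]) * ramp[: hi - i1]
    return env


def _dip_profile(n_samples: int, mu: float, depth: float, width: float) -> np.ndarray:
    """Gaussian desynchronisation dip over normalised trial time."""
    t = np.linspace(0.0, 1.0, n_samples)
    return 1.0 - depth * np.exp(-((t - mu) ** 2) / (2.0 * width**2))


def _encoding_gains(cfg: SessionConfig, truth: GroundTruth,
                    rng: np.random.Generator,
                    trial_samples: list[int],
                    ) -> dict[tuple[str, str], list[float | np.ndarray]]:
    """Per-(channel, band) multiplicative envelope gains, one entry per trial.

    Entries are scalars for the constant-gain modes and per-sample arrays
    for the time-varying distributed_nonlinear latency code.
    """
    n = len(truth.drive)
    gains: dict[tuple[str, str], list[float | np.ndarray]] = {
        (ch, band): [1.0] * n for ch in cfg.channels for band in ("alpha", "beta")
    }
    a, z = cfg.encoding_depth, truth.drive
    mode = cfg.encoding_mode
    if mode == "none":
        return gains
    if mode == "univariate":
        _require(cfg.channels, ["C3"], mode)
        gains[("C3", "alpha")] = list(1 + a * z)
        return gains
    if mode == "distributed_linear":
        chans = sorted({ch for ch, _, _ in LINEAR_MIXTURE})
        _require(cfg.channels, chans, mode)
        wmax = max(abs(w) for _, _, w in LINEAR_MIXTURE)
        for ch, band, w in LINEAR_MIXTURE:
            gains[(ch, band)] = list(1 + a * (w / wmax) * z)
        return gains
    # distributed_nonlinear: every carrier shows a desynchronisation dip of
    # fixed depth and area whose *timing* within the trial moves with the
    # drive, plus independent per-carrier timing jitter.  Trial-mean band
    # power is therefore drive-independent (ERD sees nothing), and reliable
    # recovery requires estimating dip latency — a nonlinear functional of
    # the envelope — and pooling it over several channel-bands.
    chans = sorted({ch for ch, _ in NONLINEAR_CARRIERS})
    _require(cfg.channels, chans, mode)
    centre = 0.5 + cfg.latency_span * z
    lat = centre[:, None] + cfg.latency_jitter * rng.standard_normal(
        (n, len(NONLINEAR_CARRIERS)))
    lat = np.clip(lat, 0.12, 0.88)
    truth.carrier_latency = lat
    for k, (ch, band) in enumerate(NONLINEAR_CARRIERS):
        gains[(ch, band)] = [
            _dip_profile(trial_samples[i], lat[i, k], a, cfg.bump_width)
            for i in range(n)
        ]
    return gains


def _require(channels: tuple[str, ...], needed: list[str], mode: str) -> None:
    missing = [c for c in needed if c not in channels]
    if missing:
        raise ValueError(
            f"encoding_mode {mode!r} needs channels {missing} not in the montage"
        )


def generate_eeg(
    trials: list[TrialRecord],
    truth: GroundTruth,
    cfg: SessionConfig,
    rng: np.random.Generator,
) -> EEGSession:
    """Forward-model continuous EEG for a scheduled session.

    snr is the RMS amplitude of each band oscillation (at rest) relative to
    the in-band RMS of that channel's background noise.
    """
    events = pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in trials],
            "onset_s": [t.onset_s for t in trials],
            "offset_s": [t.offset_s for t in trials],
            "condition": [t.condition for t in trials],
        }
    )
    if (events.onset_s.values[1:] - events.offset_s.values[:-1] < cfg.rest_s - 1e-9).any():
        raise ValueError(f"trial windows must be separated by >= rest_s={cfg.rest_s}")

    fs = cfg.sampling_rate_hz
    n = int(round((events.offset_s.iloc[-1] + cfg.rest_s) * fs))
    trial_samples = [
        int(round(ev.offset_s * fs)) - int(round(ev.onset_s * fs))
        for ev in events.itertuples()
    ]
    gains = _encoding_gains(cfg, truth, rng, trial_samples)

    bands = {"alpha": (8.0, 13.0), "beta": (13.0, 30.0)}
    shared = _pink_noise(n, rng) * cfg.shared_noise_frac
    data = np.empty((len(cfg.channels), n))
    for i, ch in enumerate(cfg.channels):
        noise = shared + _pink_noise(n, rng) * np.sqrt(1 - cfg.shared_noise_frac**2)
        x = noise.copy()
        for band, (lo, hi) in bands.items():
            sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
            inband_rms = signal.sosfiltfilt(sos, noise).std()
            osc = _band_noise(n, fs, lo, hi, rng) * cfg.snr * inband_rms
            env = _envelope(n, fs, events, gains[(ch, band)], cfg.erd_gain)
            x = x + osc * env
        data[i] = x * cfg.output_scale_uv
    return EEGSession(data=data, channels=list(cfg.channels), sfreq=fs, events=events)


# ---------------------------------------------------------------------------
# full session


def generate_session(
    cfg: SessionConfig,
) -> tuple[list[TrialRecord], EEGSession, GroundTruth]:
    """Generate one complete simulated session.

    Draws the pseudo-random condition schedule and trial durations, renders
    both hands' trajectories per trial, computes each trial's true CI from
    those trajectories, converts log CI to a bounded latent drive
    (tanh of the session-standardised log10 CI), and forward-models EEG
    whose band envelopes encode that drive according to
    ``cfg.encoding_mode``.  Fully reproducible from ``cfg.seed``.
    """
    rng_sched = substream(cfg.seed, "schedule")
    rng_traj = substream(cfg.seed, "trajectories")
    rng_eeg = substream(cfg.seed, "eeg")

    order = _condition_order(cfg.trials_per_condition, rng_sched)
    durations = _trial_durations(cfg, rng_sched)

    trials: list[TrialRecord] = []
    t0 = cfg.rest_s
    ci = np.empty(cfg.n_trials)
    for i, (cond, dur) in enumerate(zip(order, durations)):
        left, right = generate_trajectory(
            cond, cfg.coupling_strength, float(dur), rng_traj,
            pen_rate_hz=cfg.pen_rate_hz,
            circle_radius_px=cfg.circle_radius_px,
            shape_iterations=cfg.shape_iterations,
            jitter_px=cfg.jitter_px,
            amplitude_sd=cfg.amplitude_sd,
            hand_asymmetry=cfg.hand_asymmetry,
            hand_scale_sd=cfg.hand_scale_sd,
            line_bow_px=cfg.line_bow_px,
            line_bow_sd=cfg.line_bow_sd,
            line_bow_asymmetry=cfg.line_bow_asymmetry,
        )
        trials.append(
            TrialRecord(
                trial_id=i, condition=cond,
                onset_s=t0, offset_s=t0 + float(dur),
                left_traj=left, right_traj=right,
            )
        )
        ci[i] = compute_ci(
            compute_curvature(left), compute_curvature(right)
        )
        t0 += float(dur) + cfg.rest_s

    logci = np.log10(ci)
    drive = np.tanh((logci - logci.mean()) / logci.std())
    truth = GroundTruth(true_ci=ci, drive=drive, encoding_mode=cfg.encoding_mode)
    eeg = generate_eeg(trials, truth, cfg, rng_eeg)
    return trials, eeg, truth


# ---------------------------------------------------------------------------
# oracle readout of the nonlinear code (used by recovery tests)


def nonlinear_oracle_readout(features: pd.DataFrame,
                             channels: tuple[str, ...] = MOTOR_CHANNELS,
                             bump_width: float = 0.12) -> np.ndarray:
    """Decode the latent drive from the 200-point band time-courses,
    knowing the generating mechanism but not the per-trial jitters.

    ``features`` is the trials x 3600 matrix (channel-major, band-minor
    blocks of 200 normalised time points).  For each carrier channel-band
    the dip latency is estimated by matched filtering the mean-centred
    time-course against Gaussian dip templates; latencies are averaged
    over carriers, which suppresses the per-carrier timing jitter.
    Returns an estimate proportional to the drive (latency re-centred at
    mid-trial).
    """
    X = features.to_numpy(float)
    n = len(X)
    t = np.linspace(0.0, 1.0, 200)
    centres = np.linspace(0.12, 0.88, 77)
    templates = -np.exp(-((t[None, :] - centres[:, None]) ** 2)
                        / (2.0 * bump_width**2))
    templates -= templates.mean(axis=1, keepdims=True)
    bands = ("alpha", "beta")
    col = {(ch, b): (i * 2 + j) for i, ch in enumerate(channels)
           for j, b in enumerate(bands)}
    est = np.zeros(n)
    for ch, band in NONLINEAR_CARRIERS:
        k = col[(ch, band)]
        block = X[:, k * 200:(k + 1) * 200]
        block = block - block.mean(axis=1, keepdims=True)
        score = block @ templates.T          # (trials, centres)
        est += centres[np.argmax(score, axis=1)]
    est /= len(NONLINEAR_CARRIERS)
    return est - 0.5  # dip occurs later in the trial for higher drive
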