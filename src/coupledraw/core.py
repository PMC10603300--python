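"""Shared domain types and constants for the circle-line drawing pipeline.

The analysis operates on nine motor-related 10-20 channels arranged in three
rows (frontal-central, central, central-parietal), two movement-related
frequency bands (alpha, beta), and trials of a four-condition bimanual
drawing task.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Motor-strip montage used throughout (fixed order: feature vectors,
#: coherence groups and reports all follow this ordering).
MOTOR_CHANNELS: tuple[str, ...] = (
    "FC3", "FCz", "FC4", "C3", "Cz", "C4", "CP3", "CPz", "CP4",
)

#: Drawing conditions.  The first two are congruent (both hands draw the
#: same shape), the last two incongruent.
CONDITIONS: tuple[str, ...] = (
    "line-line", "circle-circle", "line-circle", "circle-line",
)
CONGRUENT: frozenset[str] = frozenset({"line-line", "circle-circle"})
INCONGRUENT: frozenset[str] = frozenset({"line-circle", "circle-line"})


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [lo, hi) in Hz.

    Membership of a grid frequency is half-open on the right so that a point
    exactly at a shared band edge (13 Hz) belongs to the lower band only;
    the highest band of a preset is closed on the right.
    """

    name: str
    lo: float
    hi: float
    closed_right: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi <= 35):
            raise ValueError(
                f"band {self.name}: need 0 < lo < hi <= 35, got [{self.lo}, {self.hi}]"
            )

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        """Boolean membership mask over a frequency grid."""
        freqs = np.asarray(freqs, dtype=float)
        if self.closed_right:
            m = (freqs >= self.lo) & (freqs <= self.hi)
        else:
            m = (freqs >= self.lo) & (freqs < self.hi)
        return m


#: Band presets.  "default" follows the Methods definition (alpha 8-13,
#: beta 13-30); "results-variant" follows the alternative definition that
#: appears in the Results text (alpha 8-12, beta 15-30).
BAND_PRESETS: dict[str, tuple[BandSpec, BandSpec]] = {
    "default": (
        BandSpec("alpha", 8.0, 13.0),
        BandSpec("beta", 13.0, 30.0, closed_right=True),
    ),
    "results-variant": (
        BandSpec("alpha", 8.0, 12.0),
        BandSpec("beta", 15.0, 30.0, closed_right=True),
    ),
}

#: Channel-pair groups over which coherence is averaged.
CHANNEL_GROUPS: dict[str, tuple[tuple[str, str], ...]] = {
    "frontal-central": (("FC3", "FC4"), ("FC3", "FCz"), ("FCz", "FC4")),
    "central": (("C3", "C4"), ("C3", "Cz"), ("C4", "Cz")),
    "central-parietal": (("CP3", "CP4"), ("CP3", "CPz"), ("CP4", "CPz")),
}


@dataclass
class TrialRecord:
    """One trial: condition label, timing, and the two pen trajectories.

    Trajectories are float arrays of shape (n, 3) with columns
    (t_s, x_px, y_px); t_s is seconds from trial onset, strictly increasing.
    """

    trial_id: int
    condition: str
    onset_s: float
    offset_s: float
    left_traj: np.ndarray
    right_traj: np.ndarray

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if not self.offset_s > self.onset_s:
            raise ValueError("offset_s must exceed onset_s")
        for name, traj in (("left", self.left_traj), ("right", self.right_traj)):
            traj = np.asarray(traj, dtype=float)
            if traj.ndim != 2 or traj.shape[1] != 3 or traj.shape[0] < 2:
                raise ValueError(f"{name} trajectory must be (n>=2, 3)")
            if not np.all(np.diff(traj[:, 0]) > 0):
                raise ValueError(f"{name} trajectory times must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class EEGSession:
    """Continuous multichannel EEG plus the trial event table.

    data is (n_channels, n_samples) in microvolts; events is a DataFrame
    with columns trial_id, onset_s, offset_s, condition.
    """

    data: np.ndarray
    channels: list[str]
    sfreq: float
    events: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be (n_channels, n_samples)")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if len(self.events):
            needed = {"trial_id", "onset_s", "offset_s", "condition"}
            if not needed.issubset(self.events.columns):
                raise ValueError(f"events table needs columns {sorted(needed)}")
            last = self.data.shape[1] / self.sfreq
            if (self.events["offset_s"] > last).any():
                raise ValueError("event extends beyond recording")

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[1])

    def pick(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(label)]
        except ValueError as err:
            raise KeyError(f"channel {label!r} not in session") from err


def substream(seed: int, *names: object) -> np.random.Generator:
    """Named reproducible child generator of one master seed.

    Every source of randomness in the package draws from a substream keyed
    by (master seed, stage name, ...), so a whole pipeline run is
    bit-reproducible from the single master seed while stages stay
    statistically independent.
    """
    key = [zlib.crc32(str(n).encode()) % (2**31) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *key]))
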