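"""Per-trial band-limited cross-channel coherence (distributed-univariate features).

Magnitude-squared coherence |S_xy|^2 / (S_xx S_yy) is estimated per trial
from Welch-averaged cross- and auto-spectra (1 s Hann windows, 50 %
overlap) over the trial window, then averaged across in-band frequency
bins.  Pair coherences are averaged within three electrode triplets of the
motor strip (frontal-central, central, central-parietal), yielding
3 groups x 2 bands = 6 values per trial.

Trials shorter than two estimation windows are excluded (single-window
coherence is identically 1) and logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import signal

from .core import CHANNEL_GROUPS, BandSpec
from .spectral import Epoch

logger = logging.getLogger(__name__)

WINDOW_S = 1.0
OVERLAP = 0.5


def pair_coherence(x: np.ndarray, y: np.ndarray, sfreq: float, band: BandSpec,
                   window_s: float = WINDOW_S, overlap: float = OVERLAP) -> float:
    """Band-mean magnitude-squared coherence of two equal-length signals."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D signals")
    nperseg = int(round(window_s * sfreq))
    noverlap = int(round(nperseg * overlap))
    step = nperseg - noverlap
    n_windows = (len(x) - noverlap) // step
    if n_windows < 2:
        raise ValueError(
            f"epoch too short for >= 2 estimation windows of {window_s} s "
            "(coherence from one window is identically 1)"
        )
    freqs, coh = signal.coherence(
        x, y, fs=sfreq, window="hann", nperseg=nperseg, noverlap=noverlap,
    )
    mask = band.mask(freqs)
    if not mask.any():
        raise ValueError(f"band {band.name} covers no spectral bins")
    return float(coh[mask].mean())


def group_coherence(epoch: Epoch, channels: list[str],
                    bands: tuple[BandSpec, BandSpec],
                    groups: dict[str, tuple[tuple[str, str], ...]] = CHANNEL_GROUPS,
                    ) -> dict[tuple[str, str], float]:
    """6 coherence values for one trial, keyed (group, band).

    Each value is the arithmetic mean of the three pair coherences of the
    group, computed over the trial window (onset..offset) only.
    """
    i_pre = int(round(epoch.pre_s * epoch.sfreq))
    data = {ch: epoch.data[i, i_pre:] for i, ch in enumerate(channels)}
    out: dict[tuple[str, str], float] = {}
    for gname, pairs in groups.items():
        for a, b in pairs:
            if a not in data or b not in data:
                missing = [c for c in (a, b) if c not in data]
                raise ValueError(f"group {gname!r} needs missing channels {missing}")
        for band in bands:
            vals = [pair_coherence(data[a], data[b], epoch.sfreq, band) for a, b in pairs]
            out[(gname, band.name)] = float(np.mean(vals))
    return out


def coherence_table(epochs: list[Epoch], channels: list[str],
                    bands: tuple[BandSpec, BandSpec]) -> pd.DataFrame:
    """Per-trial coherence features, columns ``"{group}_{band}"``.

    Trials too short for two Welch windows are skipped with a log entry.
    """
    rows = []
    for ep in epochs:
        try:
            vals = group_coherence(ep, channels, bands)
        except ValueError as err:
            if "too short" in str(err):
                logger.warning("trial %s excluded from coherence: %s", ep.trial_id, err)
                continue
            raise
        row = {"trial_id": ep.trial_id}
        row.update({f"{g}_{b}": v for (g, b), v in vals.items()})
        rows.append(row)
    return pd.DataFrame(rows)
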