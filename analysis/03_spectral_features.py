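#!/usr/bin/env python
"""ERD values and multivariate feature vectors from the session EEG.

Band-pass filters the recording (0.5-35 Hz zero-phase Butterworth), cuts
variable-length epochs (-2 s to trial offset), computes Morlet log-ratio
maps (200 normalised time points x 50 frequencies per trial and channel),
and derives both feature families: the 18 trial-mean ERD values and the
3600-long per-trial vector that keeps the temporal dynamics.
"""

import argparse
import time
from pathlib import Path

from coupledraw import io, spectral
from coupledraw.core import BAND_PRESETS, MOTOR_CHANNELS


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--session", type=Path, default=Path("results/session"))
    ap.add_argument("--out", type=Path, default=Path("results/features"))
    ap.add_argument("--bands", choices=list(BAND_PRESETS), default="default")
    args = ap.parse_args()

    bands = BAND_PRESETS[args.bands]
    channels = list(MOTOR_CHANNELS)
    eeg = io.read_eeg(args.session / "eeg", dialect="archive")

    t0 = time.time()
    epochs = spectral.epoch_trials(spectral.bandpass_filter(eeg))
    maps = spectral.session_tf_maps(epochs, channels)
    erd = spectral.erd_table(maps, bands, channels)
    features = spectral.feature_matrix(maps, bands, channels)

    args.out.mkdir(parents=True, exist_ok=True)
    erd.to_csv(args.out / "erd.csv", index=False)
    io.write_features(features, args.out / "features",
                      meta={"channels": channels,
                            "bands": [b.name for b in bands],
                            "freq_grid": spectral.FREQ_GRID.tolist()})

    print(f"time-frequency chain over {len(epochs)} trials x "
          f"{len(channels)} channels in {time.time() - t0:.0f} s")
    print(f"ERD table: {erd.shape[0]} trials x {erd.shape[1] - 1} channel-bands; "
          f"feature matrix: {features.shape[0]} x {features.shape[1]}")
    print(f"wrote erd.csv and the feature archive to {args.out}/")


if __name__ == "__main__":
    main()
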