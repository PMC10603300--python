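#!/usr/bin/env python
"""Cross-channel coherence features (the distributed-univariate approach).

Per trial, magnitude-squared coherence from Welch cross-spectra (1 s Hann
windows, 50 % overlap) averaged over the three pairs of each electrode
triplet (frontal-central, central, central-parietal) and over in-band
frequencies, giving 3 groups x 2 bands = 6 values per trial.
"""

import argparse
from pathlib import Path

from coupledraw import coherence, io, spectral
from coupledraw.core import BAND_PRESETS, MOTOR_CHANNELS


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--session", type=Path, default=Path("results/session"))
    ap.add_argument("--out", type=Path, default=Path("results/features"))
    ap.add_argument("--bands", choices=list(BAND_PRESETS), default="default")
    args = ap.parse_args()

    eeg = io.read_eeg(args.session / "eeg", dialect="archive")
    epochs = spectral.epoch_trials(spectral.bandpass_filter(eeg))
    table = coherence.coherence_table(epochs, list(MOTOR_CHANNELS),
                                      BAND_PRESETS[args.bands])

    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "coherence.csv", index=False)
    cols = [c for c in table.columns if c != "trial_id"]
    print(f"coherence for {len(table)} trials, 6 group-band values each")
    print("session means:")
    print(table[cols].mean().round(3).to_string())
    print(f"wrote coherence.csv to {args.out}/")


if __name__ == "__main__":
    main()
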