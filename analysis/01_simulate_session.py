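#!/usr/bin/env python
"""Simulate one circle-line drawing session with known ground truth.

Generates the study-condition session — 240 trials (60 per condition in
pseudo-random order), pen trajectories for both hands, and 9-channel
motor-strip EEG at 256 Hz whose band envelopes carry the trial coupling
drive through the distributed nonlinear (latency) code — and writes the raw
artifacts under results/session/.
"""

import argparse
from pathlib import Path

from coupledraw import io
from coupledraw.synthetic import SessionConfig, generate_session


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--encoding", default="distributed_nonlinear")
    ap.add_argument("--out", type=Path, default=Path("results/session"))
    args = ap.parse_args()

    cfg = SessionConfig(seed=args.seed, encoding_mode=args.encoding)
    trials, eeg, truth = generate_session(cfg)

    args.out.mkdir(parents=True, exist_ok=True)
    io.write_trajectories(trials, args.out / "trajectories.csv")
    io.write_events(eeg.events, args.out / "events.csv")
    io.write_eeg_archive(eeg, args.out / "eeg")
    truth.frame(trials).to_csv(args.out / "ground_truth.csv", index=False)

    minutes = eeg.n_samples / eeg.sfreq / 60
    print(f"simulated {len(trials)} trials ({args.encoding}, seed {args.seed}): "
          f"{minutes:.1f} min of EEG on {len(eeg.channels)} channels")
    print(f"wrote trajectories, events, EEG archive and ground truth to {args.out}/")


if __name__ == "__main__":
    main()
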