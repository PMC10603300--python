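"""File formats: trajectory/feature CSVs, EEG archives, and EDF.

Two EEG dialects are supported.  The ``archive`` dialect (NumPy .npz with a
JSON sidecar carrying labels, rate and the event table) is bit-exact and is
the default interchange format between pipeline stages.  EDF is provided
for interoperability with standard EEG tooling: a minimal EDF writer
(16-bit, 1 s data records, physical units microvolts) plus a reader backed
by MNE's EDF parser.  EDF quantises to 16 bits, so round-trips through it
are exact only to quantisation; events travel in a CSV sidecar since the
plain EDF container has no annotation channel.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EEGSession, TrialRecord

EXPECTED_SFREQ = 256.0

# ---------------------------------------------------------------------------
# CSV tables


def write_trajectories(trials: list[TrialRecord], path: str | Path) -> None:
    """Long-format CSV: trial_id, hand, t_s, x_px, y_px."""
    frames = []
    for tr in trials:
        for hand, traj in (("left", tr.left_traj), ("right", tr.right_traj)):
            frames.append(
                pd.DataFrame(
                    {"trial_id": tr.trial_id, "hand": hand,
                     "t_s": traj[:, 0], "x_px": traj[:, 1], "y_px": traj[:, 2]}
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories(path: str | Path, events: pd.DataFrame) -> list[TrialRecord]:
    """Rebuild TrialRecords from a trajectory CSV plus the event table."""
    df = pd.read_csv(path)
    ev = events.set_index("trial_id")
    trials = []
    for tid, g in df.groupby("trial_id", sort=True):
        trajs = {
            hand: gh[["t_s", "x_px", "y_px"]].to_numpy(float)
            for hand, gh in g.groupby("hand")
        }
        row = ev.loc[tid]
        trials.append(
            TrialRecord(
                trial_id=int(tid), condition=row.condition,
                onset_s=float(row.onset_s), offset_s=float(row.offset_s),
                left_traj=trajs["left"], right_traj=trajs["right"],
            )
        )
    return trials


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# EEG: archive dialect


def write_eeg_archive(session: EEGSession, path: str | Path) -> None:
    """Bit-exact EEG container: .npz signal + .json sidecar."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), data=session.data)
    sidecar = {
        "channels": list(session.channels),
        "sfreq": session.sfreq,
        "events": session.events.to_dict(orient="list"),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_eeg_archive(path: str | Path) -> EEGSession:
    path = Path(path)
    data = np.load(path.with_suffix(".npz"))["data"]
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return EEGSession(
        data=data, channels=sidecar["channels"], sfreq=sidecar["sfreq"],
        events=pd.DataFrame(sidecar["events"]),
    )


# ---------------------------------------------------------------------------
# EEG: EDF dialect


def write_edf(session: EEGSession, path: str | Path) -> None:
    """Write a minimal EDF file (1 s records, int16, physical unit uV).

    The last partial record is zero-padded; the true sample count is
    recoverable from the sidecar event table or by trimming trailing rest.
    """
    path = Path(path)
    fs = session.sfreq
    if fs != int(fs):
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(fs)  # samples per 1 s record per signal
    nsig = len(session.channels)
    nrec = int(np.ceil(session.n_samples / spr))
    padded = np.zeros((nsig, nrec * spr))
    padded[:, : session.n_samples] = session.data

    pmax = float(np.max(np.abs(padded))) * 1.01 + 1e-9
    dmin, dmax = -32768, 32767
    scale = dmax / pmax
    digital = np.clip(np.round(padded * scale), dmin, dmax).astype("<i2")

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")
        if len(b) > n:
            raise ValueError(f"EDF field too long: {s!r}")
        return b.ljust(n)

    header = b"".join([
        pad("0", 8),                       # version
        pad("X X X X", 80),                # patient id (anonymous)
        pad("Startdate X X X X", 80),      # recording id
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (nsig + 1)), 8),     # header bytes
        pad("", 44),
        pad(str(nrec), 8),
        pad("1", 8),                       # record duration, s
        pad(str(nsig), 4),
    ])
    fields = [
        (16, lambda ch: ch),                             # label
        (80, lambda ch: "SimulatedEEG"),                 # transducer
        (8, lambda ch: "uV"),                            # physical dimension
        (8, lambda ch: f"{-pmax:.6g}"[:8]),              # physical min
        (8, lambda ch: f"{pmax:.6g}"[:8]),               # physical max
        (8, lambda ch: str(dmin)),                       # digital min
        (8, lambda ch: str(dmax)),                       # digital max
        (80, lambda ch: ""),                             # prefiltering
        (8, lambda ch: str(spr)),                        # samples per record
        (32, lambda ch: ""),                             # reserved
    ]
    sig_header = b"".join(
        b"".join(pad(fn(ch), width) for ch in session.channels)
        for width, fn in fields
    )
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(nrec):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())


def read_edf(path: str | Path, events: pd.DataFrame | None = None) -> EEGSession:
    """Read an EDF file via MNE; events come from a sidecar table."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE returns volts
    # note: the last EDF record may carry <1 s of zero padding at the end
    return EEGSession(
        data=data, channels=list(raw.ch_names),
        sfreq=float(raw.info["sfreq"]),
        events=events if events is not None else pd.DataFrame(),
    )


def read_eeg(path: str | Path, dialect: str = "archive",
             events_path: str | Path | None = None,
             expected_sfreq: float | None = EXPECTED_SFREQ) -> EEGSession:
    """Load an EEG session in either dialect, with a rate contract check."""
    if dialect == "archive":
        session = read_eeg_archive(path)
    elif dialect == "edf":
        events = read_events(events_path) if events_path else None
        session = read_edf(path, events)
    else:
        raise ValueError(f"unknown EEG dialect {dialect!r}")
    if expected_sfreq is not None and session.sfreq != expected_sfreq:
        raise ValueError(
            f"sampling rate {session.sfreq} Hz differs from the expected "
            f"{expected_sfreq} Hz; pass expected_sfreq=None to override"
        )
    return session


# ---------------------------------------------------------------------------
# feature archives


def write_features(features: pd.DataFrame, path: str | Path,
                   meta: dict | None = None) -> None:
    """Trials x features matrix as .npz with a JSON sidecar."""
    path = Path(path)
    np.savez_compressed(
        path.with_suffix(".npz"),
        X=features.to_numpy(float),
        trial_id=features.index.to_numpy(),
    )
    path.with_suffix(".json").write_text(json.dumps(meta or {}, indent=1))


def read_features(path: str | Path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    z = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    df = pd.DataFrame(z["X"], index=pd.Index(z["trial_id"], name="trial_id"))
    return df, meta
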