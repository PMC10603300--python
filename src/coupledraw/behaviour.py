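"""Per-trial curvature and the bimanual coupling index (CI).

Curvature of a drawn shape is its horizontal extent: the distance between
the right-most and left-most sample on the x axis, in pixels.  An ideal
vertical line scores 0, an ideal circle its diameter; interference between
the hands moves both toward each other.  The coupling index of a trial is
the reciprocal of the absolute difference between the two hands'
curvatures — the more similar the two shapes, the larger the CI.  Because
the raw reciprocal is singular when the curvatures coincide, the difference
is floored at one pixel (the quantisation limit of the tablet) by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import CONGRUENT, TrialRecord

DEFAULT_FLOOR_PX = 1.0


def compute_curvature(traj: np.ndarray) -> float:
    """Horizontal extent |max(x) - min(x)| of a (n, 3) trajectory, px."""
    traj = np.asarray(traj, dtype=float)
    if traj.size == 0:
        raise ValueError("empty trajectory")
    if traj.ndim != 2 or traj.shape[1] != 3:
        raise ValueError("trajectory must be (n, 3) of (t, x, y)")
    x = traj[:, 1]
    return float(np.max(x) - np.min(x))


def compute_ci(c_left: float, c_right: float, floor_px: float = DEFAULT_FLOOR_PX) -> float:
    """CI = 1 / max(|c_left - c_right|, floor_px).

    Strictly decreasing in the curvature difference above the floor and
    bounded above by 1/floor_px; symmetric in its two arguments.
    """
    if c_left < 0 or c_right < 0:
        raise ValueError("curvatures must be non-negative")
    if floor_px <= 0:
        raise ValueError("floor_px must be positive")
    return 1.0 / max(abs(c_left - c_right), floor_px)


def curvature_table(
    trials: list[TrialRecord], floor_px: float = DEFAULT_FLOOR_PX
) -> pd.DataFrame:
    """Per-trial curvature and CI for a whole session.

    Returns columns trial_id, condition, c_left_px, c_right_px, ci.
    """
    rows = []
    for tr in trials:
        cl = compute_curvature(tr.left_traj)
        cr = compute_curvature(tr.right_traj)
        rows.append(
            {
                "trial_id": tr.trial_id,
                "condition": tr.condition,
                "c_left_px": cl,
                "c_right_px": cr,
                "ci": compute_ci(cl, cr, floor_px),
            }
        )
    return pd.DataFrame(rows, columns=["trial_id", "condition", "c_left_px", "c_right_px", "ci"])


def summarise_conditions(results: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean and sd of both curvatures and the CI.

    ``results`` is a curvature table (see :func:`curvature_table`); an
    unknown trial set simply yields an empty summary.
    """
    if results.empty:
        return pd.DataFrame(
            columns=["condition", "c_left_mean", "c_left_sd", "c_right_mean",
                     "c_right_sd", "ci_mean", "ci_sd", "n"]
        )
    g = results.groupby("condition", sort=False)
    out = pd.DataFrame(
        {
            "c_left_mean": g["c_left_px"].mean(),
            "c_left_sd": g["c_left_px"].std(ddof=1),
            "c_right_mean": g["c_right_px"].mean(),
            "c_right_sd": g["c_right_px"].std(ddof=1),
            "ci_mean": g["ci"].mean(),
            "ci_sd": g["ci"].std(ddof=1),
            "n": g.size(),
        }
    ).reset_index()
    return out


def check_extent_ordering(summary: pd.DataFrame) -> bool:
    """Whether mean curvatures follow line-line < incongruent < circle-circle
    for both hands (the canonical interference ordering)."""
    s = summary.set_index("condition")
    needed = {"line-line", "circle-circle", "line-circle", "circle-line"}
    if not needed.issubset(s.index):
        raise ValueError(f"summary must cover conditions {sorted(needed)}")
    ok = True
    for col in ("c_left_mean", "c_right_mean"):
        ll, cc = s.loc["line-line", col], s.loc["circle-circle", col]
        for inc in ("line-circle", "circle-line"):
            ok &= bool(ll < s.loc[inc, col] < cc)
    return ok


def ci_condition_contrast(results: pd.DataFrame) -> tuple[float, float]:
    """(mean CI over congruent trials, mean CI over incongruent trials)."""
    cong = results.condition.isin(CONGRUENT)
    return float(results.ci[cong].mean()), float(results.ci[~cong].mean())
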