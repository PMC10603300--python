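"""Correlation analyses linking neural features to the coupling index.

Each approach yields a correlation report across trials: 18 rows for the
ERD features (9 channels x 2 bands), 6 for coherence (3 groups x 2 bands),
and a single row for the ANN's averaged test-set predictions.  p values are
reported uncorrected (alpha = 0.01), with a Bonferroni-adjusted column for
the multi-feature families.  Zero-variance features are reported as
undefined rather than silently dropped.  A permutation null of the
max-|r| statistic over a feature family provides the familywise 95 % bound
used by the cross-approach comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.01


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Sample Pearson r with two-sided p from the t transform at n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length 1-D series of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), len(x)


def _feature_report(table: pd.DataFrame, ci: pd.Series, approach: str) -> pd.DataFrame:
    """One row per feature column of ``table`` (indexed by trial_id)."""
    merged = table.join(ci.rename("_ci"), how="inner")
    dropped = len(table) - len(merged)
    y = merged["_ci"].to_numpy()
    rows = []
    n_feat = table.shape[1]
    for col in table.columns:
        x = merged[col].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"approach": approach, "feature": col, "r": np.nan,
                         "p": np.nan, "n": len(y), "defined": False})
            continue
        r, p, n = pearson(x, y)
        rows.append({"approach": approach, "feature": col, "r": r, "p": p,
                     "n": n, "defined": True})
    rep = pd.DataFrame(rows)
    rep["p_bonferroni"] = np.minimum(rep["p"] * n_feat, 1.0)
    rep["significant"] = rep["p"] < ALPHA
    rep.attrs["n_trials_dropped"] = dropped
    return rep


def correlate_erd(erd: pd.DataFrame, ci: pd.Series) -> pd.DataFrame:
    """18-row report: each channel-band ERD vs CI across trials."""
    table = erd.set_index("trial_id") if "trial_id" in erd.columns else erd
    if table.shape[1] != 18:
        raise ValueError(f"expected 18 ERD features, got {table.shape[1]}")
    return _feature_report(table, ci, "erd")


def correlate_coherence(coh: pd.DataFrame, ci: pd.Series) -> pd.DataFrame:
    """6-row report: each group-band coherence vs CI across trials."""
    table = coh.set_index("trial_id") if "trial_id" in coh.columns else coh
    if table.shape[1] != 6:
        raise ValueError(f"expected 6 coherence features, got {table.shape[1]}")
    return _feature_report(table, ci, "coherence")


def evaluate_ann(predictions: pd.DataFrame, ci: pd.Series,
                 scatter_path: str | None = None) -> pd.DataFrame:
    """Single-row report: averaged ANN predictions vs actual CI.

    Optionally renders the prediction-vs-actual scatter with the least
    squares regression line to ``scatter_path``.
    """
    pred = predictions.set_index("trial_id")["mean_predicted_ci"]
    missing = ci.index.difference(pred.index).tolist()
    missing += pred.index[pred.isna()].tolist()
    if missing:
        raise ValueError(f"missing ANN predictions for trials {sorted(missing)}")
    pred = pred.loc[ci.index]
    r, p, n = pearson(pred.to_numpy(), ci.to_numpy())
    if scatter_path is not None:
        _render_scatter(ci.to_numpy(), pred.to_numpy(), r, scatter_path)
    return pd.DataFrame(
        [{"approach": "ann", "feature": "mean_prediction", "r": r, "p": p,
          "n": n, "defined": True, "p_bonferroni": p, "significant": p < ALPHA}]
    )


def _render_scatter(actual: np.ndarray, predicted: np.ndarray, r: float,
                    path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(actual, predicted, s=12, alpha=0.6)
    slope, intercept = np.polyfit(actual, predicted, 1)
    xs = np.array([actual.min(), actual.max()])
    ax.plot(xs, slope * xs + intercept, "k-", lw=1)
    ax.set_xlabel("actual CI")
    ax.set_ylabel("predicted CI (mean over test appearances)")
    ax.set_title(f"ANN prediction, r = {r:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def permutation_null_bound(features: pd.DataFrame, ci: pd.Series,
                           rng: np.random.Generator, n_perm: int = 1000,
                           quantile: float = 0.95) -> float:
    """Familywise null bound: the ``quantile`` of max |r| over the feature
    family under joint permutation of the CI labels.

    Permuting CI jointly against all columns preserves the between-feature
    correlation structure, so the bound controls the probability that *any*
    feature of a CI-independent family exceeds it.
    """
    table = features.set_index("trial_id") if "trial_id" in features.columns else features
    merged = table.join(ci.rename("_ci"), how="inner")
    X = merged[table.columns].to_numpy(float)
    y = merged["_ci"].to_numpy(float)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    maxima = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y)
        ys = (yp - yp.mean()) / yp.std()
        maxima[i] = np.max(np.abs(Xs.T @ ys)) / len(y)
    return float(np.quantile(maxima, quantile))


def single_feature_null_bound(n: int, quantile: float = 0.95) -> float:
    """Analytic two-sided null bound on |r| for one feature at sample size n."""
    t = stats.t.ppf(0.5 + quantile / 2, df=n - 2)
    return float(t / np.sqrt(n - 2 + t**2))


def compare_approaches(reports: list[pd.DataFrame]) -> pd.DataFrame:
    """Cross-approach summary: max |r|, number of significant features, and
    whether the ANN's r exceeds the best univariate/distributed |r|."""
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    rows = []
    for rep in reports:
        defined = rep[rep["defined"]]
        rows.append(
            {
                "approach": rep["approach"].iloc[0],
                "max_abs_r": float(defined["r"].abs().max()) if len(defined) else np.nan,
                "n_significant": int(rep["significant"].sum()),
                "n_features": len(rep),
            }
        )
    summary = pd.DataFrame(rows)
    ann = summary[summary.approach == "ann"]
    others = summary[summary.approach != "ann"]
    flag = bool(len(ann) and len(others)
                and ann.max_abs_r.iloc[0] > others.max_abs_r.max())
    summary.attrs["ann_beats_univariate"] = flag
    summary["ann_beats_univariate"] = flag
    return summary
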