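"""ROC / AUC and rejection-rate summaries for simulation benchmarks.

A simulation benchmark yields two p-value collections — replicates
generated without a group difference (null) and with one (difference).
Treating difference replicates as positives and ranking by ascending
p-value, the AUC of the induced ROC measures how well the test separates
the regimes; the rejection rate of the null collection at a threshold is
the false positive rate and that of the difference collection the true
positive rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import SimStudyResult

__all__ = ["roc_auc", "rejection_rate", "summarize", "roc_points"]


def roc_auc(null_p: np.ndarray, diff_p: np.ndarray) -> float:
    """AUC of the classifier that ranks difference replicates as positives
    by ascending p-value.

    Computed by the rank (Mann-Whitney) formulation: the proportion of
    (difference, null) pairs with p_diff < p_null, ties counting 1/2.
    Equals the trapezoid area under the empirical ROC exactly.
    """
    null_p = np.asarray(null_p, float)
    diff_p = np.asarray(diff_p, float)
    if null_p.size == 0 or diff_p.size == 0:
        raise ValueError("both p-value collections must be non-empty")
    # rank by -p so that larger rank = more positive (smaller p)
    ranks = stats.rankdata(np.concatenate([-diff_p, -null_p]))
    r_pos = ranks[: diff_p.size].sum()
    n_d, n_n = diff_p.size, null_p.size
    return float((r_pos - n_d * (n_d + 1) / 2) / (n_d * n_n))


def rejection_rate(p: np.ndarray, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Proportion of p-values strictly below ``alpha``, with its exact
    (Clopper–Pearson) binomial 95% interval."""
    p = np.asarray(p, float)
    if p.size == 0:
        raise ValueError("empty p-value collection")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    k = int((p < alpha).sum())
    n = p.size
    lo = stats.beta.ppf(0.025, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(0.975, k + 1, n - k) if k < n else 1.0
    return k / n, (float(lo), float(hi))


def roc_points(null_p: np.ndarray, diff_p: np.ndarray) -> pd.DataFrame:
    """Empirical ROC curve (FPR, TPR) over all observed thresholds."""
    thresholds = np.unique(np.concatenate([[0.0], null_p, diff_p, [1.0 + 1e-12]]))
    rows = [
        {"threshold": t,
         "fpr": float((np.asarray(null_p) < t).mean()),
         "tpr": float((np.asarray(diff_p) < t).mean())}
        for t in thresholds
    ]
    return pd.DataFrame(rows)


def summarize(result: SimStudyResult, alpha: float = 0.05) -> pd.DataFrame:
    """One row per analysis mode: AUC, FPR and TPR at ``alpha`` with exact
    binomial intervals, replicate counts and failures."""
    rows = []
    for mode in result.null_p:
        null_p = result.null_p[mode]
        diff_p = result.diff_p[mode]
        fpr, fpr_ci = rejection_rate(null_p, alpha)
        tpr, tpr_ci = rejection_rate(diff_p, alpha)
        rows.append({
            "mode": mode,
            "auc": roc_auc(null_p, diff_p),
            f"fpr@{alpha}": fpr, "fpr_lo": fpr_ci[0], "fpr_hi": fpr_ci[1],
            f"tpr@{alpha}": tpr, "tpr_lo": tpr_ci[0], "tpr_hi": tpr_ci[1],
            "n_null": null_p.size, "n_diff": diff_p.size,
            "failures": result.failures,
        })
    return pd.DataFrame(rows)


def plot_roc(result: SimStudyResult, path: str | Path) -> None:
    """ROC curves per mode, with AUC in the legend."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for mode in result.null_p:
        pts = roc_points(result.null_p[mode], result.diff_p[mode])
        auc = roc_auc(result.null_p[mode], result.diff_p[mode])
        label = {"fitted": "weights", "none": "no weights"}.get(mode, mode)
        ax.plot(pts["fpr"], pts["tpr"], label=f"{label} (AUC = {auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_rejection_bars(result: SimStudyResult, path: str | Path,
                        alpha: float = 0.05) -> None:
    """Bar chart of FPR and TPR at ``alpha`` per mode."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = summarize(result, alpha)
    x = np.arange(len(summary))
    width = 0.35
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(x - width / 2, summary[f"fpr@{alpha}"], width, label="FPR (null)")
    ax.bar(x + width / 2, summary[f"tpr@{alpha}"], width, label="TPR (difference)")
    ax.axhline(alpha, color="k", ls=":", lw=0.8)
    labels = [{"fitted": "weights", "none": "no weights"}.get(m, m)
              for m in summary["mode"]]
    ax.set_xticks(x, labels)
    ax.set_ylabel(f"rejection rate at p < {alpha}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
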