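"""Model discrimination and goodness-of-fit comparison.

The c-statistic is the Mann-Whitney concordance probability (ties count one
half).  Correlated c-statistics from two models scored on the same patients
are compared with the DeLong test, which estimates the variance of the AUC
difference from the empirical covariance of placement values.  Nested models
are compared with the likelihood-ratio test, 2*(LL_ext - LL_basic) ~ chi2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .errors import (
    DegenerateCovarianceError,
    NestingError,
    UndefinedAUCError,
)
from .models import LogisticFit


@dataclass
class ROCResult:
    """A ROC curve with its area and DeLong standard error."""

    auc: float
    se: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    @property
    def n_points(self) -> int:
        return len(self.fpr)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: int | None = None
    method: str = ""


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=float)
    if not set(np.unique(labels)) <= {0.0, 1.0}:
        raise ValueError("labels must be coded 0/1")
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise UndefinedAUCError("both outcome classes must be present")
    return labels


def _placements(scores: np.ndarray, labels: np.ndarray):
    """AUC and DeLong placement values (events first, then non-events)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tz = stats.rankdata(np.concatenate([pos, neg]))  # midranks on pooled sample
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    v10 = (tz[:m] - tx) / n          # per-event placement among non-events
    v01 = 1.0 - (tz[m:] - ty) / m    # per-non-event placement among events
    auc = float((tz[:m].sum() / m - (m + 1) / 2.0) / n)
    return auc, v10, v01


def c_statistic(scores, labels) -> ROCResult:
    """Concordance c-statistic with DeLong SE and the full ROC point set."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(np.asarray(labels))
    auc, v10, v01 = _placements(scores, labels)
    m, n = len(v10), len(v01)
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    return ROCResult(auc=auc, se=se, fpr=fpr, tpr=tpr, thresholds=thr)


def delong_test(scores_a, scores_b, labels) -> TestResult:
    """DeLong test for the difference of two correlated AUCs.

    Both score vectors must be computed on the same patients with the same
    labels.  Two-sided normal p value on the AUC difference over its
    placement-value covariance estimate.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = _check_labels(np.asarray(labels))
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("scores_a, scores_b and labels must have identical shape")

    auc_a, v10_a, v01_a = _placements(scores_a, labels)
    auc_b, v10_b, v01_b = _placements(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 0:
        if np.isclose(diff, 0.0):
            return TestResult(statistic=0.0, p_value=1.0, method="delong")
        raise DegenerateCovarianceError(
            f"zero variance of the AUC difference with unequal AUCs ({auc_a:.3f} vs {auc_b:.3f})"
        )
    z = float(diff / np.sqrt(var))
    return TestResult(statistic=z, p_value=float(2.0 * stats.norm.sf(abs(z))), method="delong")


def likelihood_ratio_test(fit_basic: LogisticFit, fit_extended: LogisticFit) -> TestResult:
    """Nested-model likelihood-ratio test: 2*(LL_ext - LL_basic) ~ chi2(df).

    Identical predictor sets are the degenerate nesting (df = 0, p = 1).
    """
    basic = set(fit_basic.predictors)
    extended = set(fit_extended.predictors)
    if not basic <= extended:
        raise NestingError("basic model predictors must be a subset of the extended model's")
    if fit_basic.n != fit_extended.n:
        raise NestingError("fits must use the same rows")
    stat = 2.0 * (fit_extended.loglike - fit_basic.loglike)
    if stat < -1e-6:
        raise DegenerateCovarianceError(
            f"negative LRT statistic ({stat:.3g}); extended fit is worse than nested fit"
        )
    stat = max(stat, 0.0)
    df = len(extended) - len(basic)
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return TestResult(statistic=float(stat), p_value=p, df=df, method="likelihood-ratio")


def export_roc(results: dict, out_dir, plot: bool = True) -> list[Path]:
    """Write ROC coordinates (CSV per model), AUC metadata (JSON) and a plot.

    ``results`` maps model names to :class:`ROCResult`.  Output is
    deterministic given the inputs.
    """
    if not results:
        raise ValueError("no ROC results to export")
    for name, roc in results.items():
        if roc.n_points == 0:
            raise ValueError(f"ROC for {name!r} has no points")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    meta = {}
    for name in sorted(results):
        roc = results[name]
        df = pd.DataFrame(
            {"threshold": roc.thresholds, "fpr": roc.fpr, "tpr": roc.tpr}
        )
        path = out_dir / f"{name}_roc.csv"
        df.to_csv(path, index=False)
        written.append(path)
        meta[name] = {"auc": roc.auc, "se": roc.se, "n_points": roc.n_points}
    meta_path = out_dir / "roc_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    written.append(meta_path)
    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        for name in sorted(results):
            roc = results[name]
            ax.plot(roc.fpr, roc.tpr, label=f"{name} (AUC {roc.auc:.2f})")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right")
        fig.tight_layout()
        plot_path = out_dir / "roc.png"
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
        written.append(plot_path)
    return written
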