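"""Classifier evaluation statistics.

Rank-based AUC, the DeLong test for paired AUCs, percentile bootstrap
confidence intervals (1000 resamples, stratified by class), Wilson score
intervals for binomial proportions, stage-stratified sensitivity, and the
Z-score-versus-control matrix used for feature heatmaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)

__all__ = [
    "auc",
    "delong_test",
    "bootstrap_ci",
    "wilson_ci",
    "zscore_vs_control",
    "stage_stratified_sensitivity",
    "sensitivity",
    "specificity",
    "accuracy",
    "MetricReport",
    "metric_report",
]


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    return labels


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    order = np.argsort(neg, kind="mergesort")
    sneg = neg[order]
    # for each positive: fraction of negatives strictly below + half of ties
    below = np.searchsorted(sneg, pos, side="left")
    upto = np.searchsorted(sneg, pos, side="right")
    v10 = (below + 0.5 * (upto - below)) / len(neg)
    spos = np.sort(pos)
    below = np.searchsorted(spos, neg, side="left")
    upto = np.searchsorted(spos, neg, side="right")
    v01 = 1.0 - (below + 0.5 * (upto - below)) / len(pos)
    return v10, v01


def delong_test(scores_a, scores_b, labels):
    """DeLong comparison of two correlated AUCs on the same samples.

    Returns ``(auc_a, auc_b, z, p)`` with a two-sided normal p-value.  When
    the variance of the AUC difference is degenerate (e.g. identical score
    vectors) the difference carries no evidence and p is 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = _check_labels(labels)
    if len(scores_a) != len(labels) or len(scores_b) != len(labels):
        raise ValueError("scores and labels must be paired (same length)")
    v10a, v01a = _placements(scores_a, labels)
    v10b, v01b = _placements(scores_b, labels)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0 or not np.isfinite(var):
        logger.info("delong_test: degenerate variance of the AUC difference; p set to 1")
        return auc_a, auc_b, 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return auc_a, auc_b, float(z), float(p)


def bootstrap_ci(
    metric,
    scores,
    labels,
    n_boot: int = 1000,
    seed: int | None = None,
    confidence: float = 0.95,
    stratified: bool = True,
    max_redraws: int = 100,
):
    """Percentile bootstrap CI of ``metric(scores, labels)``.

    Resampling is stratified by class by default so every resample contains
    both classes.  A resample on which the metric is undefined (raises) is
    redrawn; redraws are counted and logged.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(labels == 1)
    idx_neg = np.flatnonzero(labels == 0)
    values = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        for _ in range(max_redraws + 1):
            if stratified:
                take = np.concatenate([
                    rng.choice(idx_pos, size=len(idx_pos), replace=True),
                    rng.choice(idx_neg, size=len(idx_neg), replace=True),
                ])
            else:
                take = rng.choice(len(labels), size=len(labels), replace=True)
            try:
                values[b] = metric(scores[take], labels[take])
                break
            except ValueError:
                redraws += 1
        else:
            raise RuntimeError("bootstrap_ci: metric undefined on every redraw")
    if redraws:
        logger.info("bootstrap_ci: %d resamples redrawn (metric undefined)", redraws)
    alpha = 1 - confidence
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def wilson_ci(successes: int, trials: int, confidence: float = 0.95):
    """Wilson score interval for a binomial proportion."""
    if trials <= 0:
        raise ValueError("wilson_ci: trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError("wilson_ci: successes out of range")
    lo, hi = proportion_confint(successes, trials, alpha=1 - confidence, method="wilson")
    return float(lo), float(hi)


def sensitivity(calls, labels) -> float:
    calls, labels = np.asarray(calls).astype(int), np.asarray(labels).astype(int)
    pos = labels == 1
    if not pos.any():
        raise ValueError("sensitivity undefined without positive samples")
    return float(calls[pos].mean())


def specificity(calls, labels) -> float:
    calls, labels = np.asarray(calls).astype(int), np.asarray(labels).astype(int)
    neg = labels == 0
    if not neg.any():
        raise ValueError("specificity undefined without negative samples")
    return float(1 - calls[neg].mean())


def accuracy(calls, labels) -> float:
    calls, labels = np.asarray(calls).astype(int), np.asarray(labels).astype(int)
    return float((calls == labels).mean())


@dataclass
class MetricReport:
    """Point metrics at a fixed threshold, with bootstrap 95% CIs."""

    threshold: float
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    youden: float
    ci: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "youden": self.youden,
            "ci": {k: list(v) for k, v in self.ci.items()},
        }


def metric_report(
    scores,
    labels,
    threshold: float,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MetricReport:
    """AUC/sensitivity/specificity/accuracy/Youden at ``threshold``, each
    with a percentile-bootstrap 95% CI.

    A score exactly at the threshold is a positive call (>= semantics).
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    calls = (scores >= threshold).astype(int)
    report = MetricReport(
        threshold=float(threshold),
        auc=auc(scores, labels),
        sensitivity=sensitivity(calls, labels),
        specificity=specificity(calls, labels),
        accuracy=accuracy(calls, labels),
        youden=sensitivity(calls, labels) + specificity(calls, labels) - 1,
    )
    metrics = {
        "auc": lambda s, y: auc(s, y),
        "sensitivity": lambda s, y: sensitivity((s >= threshold).astype(int), y),
        "specificity": lambda s, y: specificity((s >= threshold).astype(int), y),
        "accuracy": lambda s, y: accuracy((s >= threshold).astype(int), y),
    }
    rng = np.random.default_rng(seed)
    for name, fn in metrics.items():
        sub_seed = int(rng.integers(0, 2**31 - 1))
        report.ci[name] = bootstrap_ci(fn, scores, labels, n_boot=n_boot, seed=sub_seed)
    return report


def zscore_vs_control(table: pd.DataFrame, control_ids: list[str]) -> pd.DataFrame:
    """Standardize every sample's features against the control group.

    ``Z = (X - mean_control) / sd_control`` column-wise, applied to cases
    and controls alike; zero-variance control features yield NaN columns
    and are logged.
    """
    ctrl = table.loc[[s for s in table.index if s in set(control_ids)]]
    if len(ctrl) < 2:
        raise ValueError("zscore_vs_control needs >= 2 control samples")
    mu = ctrl.mean(axis=0)
    sd = ctrl.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning("zscore_vs_control: %d zero-variance control features", int(degenerate.sum()))
        sd = sd.replace(0, np.nan)
    return (table - mu) / sd


def stage_stratified_sensitivity(
    calls,
    labels,
    stages,
    early=("I", "II"),
    late=("III", "IV"),
) -> dict:
    """Sensitivity with Wilson 95% CI in early- and late-stage case strata.

    Strata without cases are reported as not-applicable (None), not errors.
    """
    calls = np.asarray(calls).astype(int)
    labels = np.asarray(labels).astype(int)
    stages = np.asarray(stages, dtype=object)
    out = {}
    for name, members in (("early", set(early)), ("late", set(late))):
        mask = (labels == 1) & np.isin(stages, list(members))
        n = int(mask.sum())
        if n == 0:
            out[name] = {"n": 0, "sensitivity": None, "ci": None}
            continue
        hits = int(calls[mask].sum())
        out[name] = {"n": n, "sensitivity": hits / n, "ci": wilson_ci(hits, n)}
    return out
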