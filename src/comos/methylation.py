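"""Differentially methylated region (DMR) calling and the DMR feature matrix.

DMRs are identified on the training set only: candidate regions are runs of
at least ``min_cpg`` consecutive CpG sites (inter-site gap at most
``max_cpg_gap`` bp) whose per-site group-mean methylation differences share
one sign; each candidate is then tested by a two-sided Mann-Whitney U on
per-sample region methylation levels, q-values come from Benjamini-Hochberg
over all candidates, and survivors additionally need an absolute group-mean
level difference of at least ``diff_threshold`` percentage points (20 for
control-vs-case, 15 for the treatment-response task).  This caller is a
transparent behavioural stand-in for segmentation-based DMR tools, wired to
the same thresholds (minimum 4 CpGs, q <= 0.05).

Methylation levels are percentages (0-100) throughout, so the 20/15
difference thresholds apply literally as percentage points.

The per-sample feature matrix evaluates every sample (train and validation)
on the train-defined DMRs; samples missing more than 20% of DMRs are
excluded outright, and remaining missing entries are imputed with the mean
methylation level of the DMR itself.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "region_methylation_level",
    "call_dmrs",
    "build_dmr_matrix",
]


def region_methylation_level(calls: pd.DataFrame, chrom: str, start: int, end: int) -> float:
    """Pooled-count methylation percentage of one sample over a region.

    ``100 * sum(meth) / sum(meth + unmeth)`` over covered CpGs inside
    ``[start, end)``; NaN when no covered CpG falls in the region.
    """
    sel = calls[(calls["chrom"] == chrom) & (calls["pos"] >= start) & (calls["pos"] < end)]
    cov = (sel["meth"] + sel["unmeth"]).to_numpy()
    total = cov.sum()
    if total == 0:
        return float("nan")
    return 100.0 * sel["meth"].sum() / total


def _site_matrices(calls_by_sample: dict[str, pd.DataFrame]):
    """Align per-sample calls onto the union of (chrom, pos) sites.

    Returns (site index DataFrame sorted by chrom/pos, meth matrix, coverage
    matrix) with one row per sample in input order.
    """
    keys = sorted(
        {(c, int(p)) for df in calls_by_sample.values() for c, p in zip(df["chrom"], df["pos"])}
    )
    site_index = {key: i for i, key in enumerate(keys)}
    n_sites = len(keys)
    sample_ids = list(calls_by_sample)
    meth = np.zeros((len(sample_ids), n_sites))
    cov = np.zeros((len(sample_ids), n_sites))
    for row, sid in enumerate(sample_ids):
        df = calls_by_sample[sid]
        idx = np.fromiter((site_index[(c, int(p))] for c, p in zip(df["chrom"], df["pos"])),
                          dtype=np.int64, count=len(df))
        np.add.at(meth[row], idx, df["meth"].to_numpy(dtype=float))
        np.add.at(cov[row], idx, (df["meth"] + df["unmeth"]).to_numpy(dtype=float))
    sites = pd.DataFrame(keys, columns=["chrom", "pos"])
    return sites, meth, cov


def _candidate_regions(sites: pd.DataFrame, diff: np.ndarray, min_cpg: int, max_cpg_gap: int):
    """Maximal sign-consistent runs of informative CpGs with bounded gaps."""
    candidates = []
    chroms = sites["chrom"].to_numpy()
    positions = sites["pos"].to_numpy()
    run: list[int] = []
    run_sign = 0

    def flush():
        if len(run) >= min_cpg:
            candidates.append(list(run))

    for i in range(len(sites)):
        d = diff[i]
        sign = 0 if (np.isnan(d) or d == 0) else (1 if d > 0 else -1)
        if sign == 0:
            flush()
            run, run_sign = [], 0
            continue
        if run and (chroms[i] != chroms[run[-1]]
                    or positions[i] - positions[run[-1]] > max_cpg_gap
                    or sign != run_sign):
            flush()
            run = []
        run.append(i)
        run_sign = sign
    flush()
    return candidates


def call_dmrs(
    case_calls: dict[str, pd.DataFrame],
    control_calls: dict[str, pd.DataFrame],
    min_cpg: int = 4,
    q_threshold: float = 0.05,
    diff_threshold: float = 20.0,
    max_cpg_gap: int = 300,
) -> pd.DataFrame:
    """Call DMRs (case relative to control) on training samples.

    Returns a DataFrame with chrom, start, end, n_cpgs, mean_diff
    (percentage points, case minus control) and BH q_value, sorted by
    position.  ``diff_threshold`` is in percentage points.
    """
    if len(case_calls) < 2 or len(control_calls) < 2:
        raise ValueError("call_dmrs needs at least 2 samples per group")
    merged = {**{f"case::{s}": df for s, df in case_calls.items()},
              **{f"ctrl::{s}": df for s, df in control_calls.items()}}
    sites, meth, cov = _site_matrices(merged)
    is_case = np.array([sid.startswith("case::") for sid in merged])
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(cov > 0, meth / np.maximum(cov, 1), np.nan)
    case_covered = (cov[is_case] > 0).any(axis=0)
    ctrl_covered = (cov[~is_case] > 0).any(axis=0)
    diff = np.full(len(sites), np.nan)
    informative = case_covered & ctrl_covered
    if informative.any():
        with np.errstate(invalid="ignore"):
            diff[informative] = (
                np.nanmean(rates[is_case][:, informative], axis=0)
                - np.nanmean(rates[~is_case][:, informative], axis=0)
            )
    candidates = _candidate_regions(sites, diff, min_cpg, max_cpg_gap)
    if not candidates:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_cpgs", "mean_diff", "q_value"])

    records = []
    pvals = []
    positions = sites["pos"].to_numpy()
    for idx in candidates:
        idx = np.asarray(idx)
        chrom = sites["chrom"].iloc[idx[0]]
        start, end = int(positions[idx[0]]), int(positions[idx[-1]]) + 1
        # per-sample pooled region level, percent
        region_cov = cov[:, idx].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            levels = np.where(region_cov > 0,
                              100.0 * meth[:, idx].sum(axis=1) / np.maximum(region_cov, 1),
                              np.nan)
        case_lv = levels[is_case & ~np.isnan(levels)]
        ctrl_lv = levels[~is_case & ~np.isnan(levels)]
        if len(case_lv) < 2 or len(ctrl_lv) < 2:
            continue
        try:
            p = stats.mannwhitneyu(case_lv, ctrl_lv, alternative="two-sided").pvalue
        except ValueError:  # all-identical values
            p = 1.0
        records.append((chrom, start, end, len(idx), case_lv.mean() - ctrl_lv.mean()))
        pvals.append(p)
    if not records:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_cpgs", "mean_diff", "q_value"])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    out = pd.DataFrame(records, columns=["chrom", "start", "end", "n_cpgs", "mean_diff"])
    out["q_value"] = qvals
    keep = (out["q_value"] <= q_threshold) & (out["mean_diff"].abs() >= diff_threshold)
    out = out[keep].sort_values(["chrom", "start"]).reset_index(drop=True)
    logger.info("call_dmrs: %d candidates, %d DMRs at q<=%.3g, |diff|>=%g",
                len(records), len(out), q_threshold, diff_threshold)
    return out


def build_dmr_matrix(
    calls_by_sample: dict[str, pd.DataFrame],
    dmrs: pd.DataFrame,
    max_missing: float = 0.2,
    impute_with: str = "all",
    train_samples: list[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample methylation levels on train-defined DMRs, with exclusion
    and imputation.

    Samples whose proportion of missing DMR levels exceeds ``max_missing``
    are excluded (train and validation alike).  Remaining missing entries
    are imputed with the per-DMR mean level over the non-missing retained
    samples (``impute_with="all"``) or over retained training samples only
    (``impute_with="train"``, leakage-averse mode; needs ``train_samples``).

    Returns (imputed matrix, excluded sample ids).
    """
    if impute_with not in {"all", "train"}:
        raise ValueError("impute_with must be 'all' or 'train'")
    if impute_with == "train" and train_samples is None:
        raise ValueError("impute_with='train' requires train_samples")
    cols = [f"dmr_{r.chrom}_{r.start}_{r.end}" for r in dmrs.itertuples()]
    data = {}
    for sid, calls in calls_by_sample.items():
        data[sid] = [
            region_methylation_level(calls, r.chrom, r.start, r.end) for r in dmrs.itertuples()
        ]
    matrix = pd.DataFrame.from_dict(data, orient="index", columns=cols)
    missing_frac = matrix.isna().mean(axis=1)
    excluded = sorted(matrix.index[missing_frac > max_missing])
    if excluded:
        logger.info("build_dmr_matrix: excluded %d samples with >%d%% missing DMRs: %s",
                    len(excluded), int(100 * max_missing), excluded)
    matrix = matrix.drop(index=excluded)
    if impute_with == "train":
        basis = matrix.loc[[s for s in matrix.index if s in set(train_samples)]]
    else:
        basis = matrix
    means = basis.mean(axis=0)
    if means.isna().any():
        bad = list(means.index[means.isna()])
        raise ValueError(f"no imputation basis (all-missing) for DMRs: {bad}")
    return matrix.fillna(means), excluded
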