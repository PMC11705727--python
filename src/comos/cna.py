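"""Shallow copy-number profiles from binned fragment counts.

Per sample: fragments are counted into 1-Mb bins by midpoint, counts are
corrected for GC content and mappability with a local (lowess) regression,
normalized by the sample median, outlier-smoothed by winsorizing against
neighbouring bins, and log2-transformed.  This reproduces the standard
fixed-bin read-depth pipeline (filter, estimate/correct, normalize, smooth)
as a self-contained behavioural equivalent.

Group-level gain/loss calling follows the raw-rule convention: per bin a
two-sided Wilcoxon rank-sum test between groups; a bin is a Gain when
p < 0.05 and the case/control log2 ratio of group means is positive, a
Loss when negative, otherwise NoChange.  No multiple-testing correction is
applied to these calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import GenomicBin

logger = logging.getLogger(__name__)

__all__ = ["CnaProfile", "bin_counts", "correct_and_normalize", "call_gain_loss", "build_cna_table"]


@dataclass
class CnaProfile:
    """Normalized log2 copy-number profile of one sample.

    ``log2_ratio`` is NaN for filtered bins; ``filtered`` marks them (bins
    are flagged, never silently dropped).
    """

    sample_id: str
    log2_ratio: np.ndarray
    filtered: np.ndarray

    @property
    def retained(self) -> np.ndarray:
        return ~self.filtered

    def to_series(self) -> pd.Series:
        return pd.Series(self.log2_ratio, index=[f"cna_bin{i}" for i in range(len(self.log2_ratio))])


def bin_counts(fragments: pd.DataFrame, bins: list[GenomicBin]) -> np.ndarray:
    """Count each fragment once, in the bin holding its midpoint."""
    width = max(b.width for b in bins)
    first_index = {}
    n_bins_per_chrom = {}
    for b in bins:
        if b.chrom not in first_index or b.index < first_index[b.chrom]:
            first_index[b.chrom] = b.index
        n_bins_per_chrom[b.chrom] = n_bins_per_chrom.get(b.chrom, 0) + 1
    counts = np.zeros(len(bins), dtype=np.int64)
    mid = ((fragments["start"] + fragments["end"]) // 2).to_numpy(dtype=np.int64)
    chroms = fragments["chrom"].to_numpy()
    for chrom, fi in first_index.items():
        mask = chroms == chrom
        if not mask.any():
            continue
        k = mid[mask] // width
        k = k[(k >= 0) & (k < n_bins_per_chrom[chrom])]
        counts[fi:fi + n_bins_per_chrom[chrom]] += np.bincount(k, minlength=n_bins_per_chrom[chrom])
    return counts


def _lowess_correct(values: np.ndarray, covariate: np.ndarray, span: float) -> np.ndarray:
    """Divide values by a lowess fit of values vs covariate (ratio residuals)."""
    if np.ptp(covariate) == 0:
        return values / max(values.mean(), np.finfo(float).tiny)
    fitted = lowess(values, covariate, frac=span, return_sorted=False)
    fitted = np.maximum(fitted, np.finfo(float).tiny)
    return values / fitted


def correct_and_normalize(
    counts: np.ndarray,
    gc: np.ndarray,
    mappability: np.ndarray,
    min_mappability: float = 0.5,
    span: float = 0.3,
    reference_zero_fraction: np.ndarray | None = None,
    max_zero_fraction: float = 0.1,
    winsor_mads: float = 4.0,
    sample_id: str = "",
) -> CnaProfile:
    """GC/mappability-corrected, median-normalized, outlier-smoothed log2
    profile.

    Parameters
    ----------
    counts, gc, mappability
        Per-bin fragment counts and covariates, aligned with the tiling.
    reference_zero_fraction
        Optional per-bin fraction of reference-panel samples with zero
        count; bins above ``max_zero_fraction`` are filtered.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.sum() == 0:
        raise ValueError(f"correct_and_normalize({sample_id}): all-zero counts")
    filtered = np.asarray(mappability, dtype=float) < min_mappability
    if reference_zero_fraction is not None:
        filtered |= np.asarray(reference_zero_fraction, dtype=float) > max_zero_fraction
    retained = ~filtered
    corrected = counts[retained]
    corrected = _lowess_correct(corrected, np.asarray(gc, dtype=float)[retained], span)
    corrected = _lowess_correct(corrected, np.asarray(mappability, dtype=float)[retained], span)
    med = np.median(corrected)
    if med <= 0:
        raise ValueError(f"correct_and_normalize({sample_id}): non-positive median after correction")
    normalized = corrected / med
    smoothed = _winsorize_neighbors(normalized, winsor_mads)
    log2_ratio = np.full(len(counts), np.nan)
    with np.errstate(divide="ignore"):
        log2_ratio[retained] = np.log2(np.maximum(smoothed, np.finfo(float).tiny))
    return CnaProfile(sample_id, log2_ratio, filtered)


def _winsorize_neighbors(values: np.ndarray, n_mads: float, reach: int = 2) -> np.ndarray:
    """Clip each bin to median +/- n_mads * MAD of its +/-reach neighbours."""
    out = values.copy()
    n = len(values)
    for i in range(n):
        lo, hi = max(0, i - reach), min(n, i + reach + 1)
        neighbors = np.delete(values[lo:hi], i - lo)
        if neighbors.size < 2:
            continue
        med = np.median(neighbors)
        mad = stats.median_abs_deviation(neighbors, scale="normal")
        if mad == 0:
            continue
        out[i] = np.clip(values[i], med - n_mads * mad, med + n_mads * mad)
    return out


def call_gain_loss(
    case_profiles: list[CnaProfile],
    control_profiles: list[CnaProfile],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-bin Gain/Loss/NoChange calls between two groups.

    Two-sided Wilcoxon rank-sum on per-bin log2 values; the group log2
    ratio is ``log2(mean case linear / mean control linear)``.  Raw
    p-values are compared against ``alpha`` (no FDR correction).
    """
    if len(case_profiles) < 2 or len(control_profiles) < 2:
        raise ValueError("call_gain_loss needs at least 2 samples per group")
    case = np.vstack([p.log2_ratio for p in case_profiles])
    ctrl = np.vstack([p.log2_ratio for p in control_profiles])
    n_bins = case.shape[1]
    records = []
    for b in range(n_bins):
        cv, nv = case[:, b], ctrl[:, b]
        cv, nv = cv[~np.isnan(cv)], nv[~np.isnan(nv)]
        if len(cv) < 2 or len(nv) < 2:
            records.append((b, "NoChange", np.nan, np.nan))
            continue
        p = stats.ranksums(cv, nv).pvalue
        log2_ratio = float(np.log2(np.mean(2.0 ** cv) / np.mean(2.0 ** nv)))
        if p < alpha and log2_ratio > 0:
            label = "Gain"
        elif p < alpha and log2_ratio < 0:
            label = "Loss"
        else:
            label = "NoChange"
        records.append((b, label, p, log2_ratio))
    return pd.DataFrame(records, columns=["bin", "label", "p_value", "log2_ratio"])


def build_cna_table(
    fragments_by_sample: dict[str, pd.DataFrame],
    bins: list[GenomicBin],
    gc: np.ndarray,
    mappability: np.ndarray,
    train_samples: list[str],
    min_mappability: float = 0.5,
    span: float = 0.3,
    max_zero_fraction: float = 0.1,
) -> pd.DataFrame:
    """Cohort CNA feature table (per-bin log2 ratios on retained bins).

    The zero-count reference panel used for bin filtering is the training
    split, so the retained-bin set is a train-only artifact.
    """
    counts = {sid: bin_counts(frags, bins) for sid, frags in fragments_by_sample.items()}
    train = [s for s in counts if s in set(train_samples)]
    if not train:
        raise ValueError("build_cna_table: no training samples in cohort")
    zero_frac = np.mean([counts[s] == 0 for s in train], axis=0)
    rows = {}
    for sid, c in counts.items():
        profile = correct_and_normalize(
            c, gc, mappability,
            min_mappability=min_mappability, span=span,
            reference_zero_fraction=zero_frac, max_zero_fraction=max_zero_fraction,
            sample_id=sid,
        )
        rows[sid] = profile.to_series()
    table = pd.DataFrame(rows).T
    return table.dropna(axis=1)
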