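"""Fragment size ratio (FSR) and breakpoint-score profiles.

FSR: cfDNA fragments of length 100-220 bp are assigned to 5-Mb genome bins
(by >= 50% overlap); per bin, the ratio of short (100-150 bp) to long
(151-220 bp) fragment counts.  Tumour-derived cfDNA is enriched for short
fragments, so the per-bin ratio carries case/control signal genome-wide.

Breakpoint score: for each class of chromatin annotation (nucleosome
centers, CpG islands, DNase clusters, enhancers), the distribution of
fragment 5'-end positions (breakage start sites) over offsets within a
fixed window around the region centers.  Counts are pooled over all regions
of the class and normalized to proportions, so profiles are comparable
across samples with different sequencing depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomicBin, assign_intervals

logger = logging.getLogger(__name__)

#: default half-window (bp) around each annotation class center
DEFAULT_HALF_WINDOWS = {
    "nucleosome": 200,
    "cpg_island": 300,
    "dnase_cluster": 150,
    "enhancer": 500,
}

SHORT_RANGE = (100, 150)
LONG_RANGE = (151, 220)

__all__ = [
    "FsrVector",
    "BreakpointProfile",
    "DEFAULT_HALF_WINDOWS",
    "compute_fsr",
    "compute_breakpoint_profile",
    "profile_feature_vector",
    "build_fsr_table",
    "build_breakpoint_table",
]


@dataclass
class FsrVector:
    """Per-bin short/long fragment count ratio for one sample.

    Bins whose long-fragment count is zero have an undefined ratio and are
    NaN — explicitly missing, never zero.
    """

    sample_id: str
    values: np.ndarray
    bin_indices: np.ndarray

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=[f"fsr_bin{i}" for i in self.bin_indices])


@dataclass
class BreakpointProfile:
    """Per-offset proportion of breakpoints around one annotation class."""

    sample_id: str
    class_label: str
    half_window: int
    scores: np.ndarray
    n_breakpoints: int = 0
    empty: bool = False

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.half_window, self.half_window + 1)

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=[f"{self.class_label}@{o:+d}" for o in self.offsets])


def compute_fsr(
    fragments: pd.DataFrame,
    bins: list[GenomicBin],
    short_range: tuple[int, int] = SHORT_RANGE,
    long_range: tuple[int, int] = LONG_RANGE,
    min_overlap_fraction: float = 0.5,
    sample_id: str = "",
) -> FsrVector:
    """Short/long fragment count ratio per bin.

    Fragments outside ``[short_range[0], long_range[1]]`` are discarded
    before assignment (both bounds inclusive).
    """
    n_bins = len(bins)
    if fragments.empty:
        logger.warning("compute_fsr(%s): empty fragment set, all bins missing", sample_id)
        return FsrVector(sample_id, np.full(n_bins, np.nan), np.arange(n_bins))
    lengths = (fragments["end"] - fragments["start"]).to_numpy()
    keep = (lengths >= short_range[0]) & (lengths <= long_range[1])
    frag = fragments.loc[keep]
    lengths = lengths[keep]
    assigned = assign_intervals(frag, bins, min_overlap_fraction)
    in_bin = assigned >= 0
    is_short = (lengths >= short_range[0]) & (lengths <= short_range[1])
    short_counts = np.bincount(assigned[in_bin & is_short], minlength=n_bins)
    long_counts = np.bincount(assigned[in_bin & ~is_short], minlength=n_bins)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(long_counts > 0, short_counts / np.maximum(long_counts, 1), np.nan)
    return FsrVector(sample_id, values, np.arange(n_bins))


def compute_breakpoint_profile(
    fragments: pd.DataFrame,
    regions: pd.DataFrame,
    half_window: int,
    sample_id: str = "",
) -> BreakpointProfile:
    """Distribution of fragment start sites over offsets around region centers.

    A breakpoint is the fragment 5'-most coordinate (interval start) only.
    For every (fragment, region) pair on the same chromosome with
    ``|start - center| <= half_window`` the count at offset
    ``start - center`` is incremented; counts are then normalized to
    proportions over the window.  If no breakpoint falls in any window the
    profile is all zeros and flagged ``empty``.
    """
    if regions.empty:
        raise ValueError("compute_breakpoint_profile: empty region set")
    class_label = str(regions["class_label"].iloc[0]) if "class_label" in regions else ""
    width = 2 * half_window + 1
    counts = np.zeros(width, dtype=np.int64)
    for chrom, chrom_regions in regions.groupby("chrom", sort=False):
        starts = np.sort(
            fragments.loc[fragments["chrom"] == chrom, "start"].to_numpy(dtype=np.int64)
        )
        if starts.size == 0:
            continue
        for center in chrom_regions["center"].to_numpy(dtype=np.int64):
            lo = np.searchsorted(starts, center - half_window, side="left")
            hi = np.searchsorted(starts, center + half_window, side="right")
            if hi > lo:
                counts += np.bincount(starts[lo:hi] - center + half_window, minlength=width)
    total = int(counts.sum())
    if total == 0:
        return BreakpointProfile(sample_id, class_label, half_window, np.zeros(width), 0, empty=True)
    return BreakpointProfile(sample_id, class_label, half_window, counts / total, total)


def profile_feature_vector(profile: BreakpointProfile, smoothing_bin: int = 1) -> np.ndarray:
    """Per-offset scores, optionally averaged in consecutive windows.

    ``smoothing_bin`` offsets are averaged per output feature; a trailing
    remainder shorter than one window is dropped.  1 is the identity.
    """
    if smoothing_bin < 1:
        raise ValueError(f"smoothing_bin must be >= 1, got {smoothing_bin}")
    scores = profile.scores
    if smoothing_bin == 1:
        return scores.copy()
    n = (len(scores) // smoothing_bin) * smoothing_bin
    return scores[:n].reshape(-1, smoothing_bin).mean(axis=1)


def build_fsr_table(
    fragments_by_sample: dict[str, pd.DataFrame],
    bins: list[GenomicBin],
    train_samples: list[str],
    max_missing_bin_fraction: float = 0.2,
    **fsr_kwargs,
) -> pd.DataFrame:
    """Cohort FSR feature table with train-defined bin retention/imputation.

    Bins missing (zero long-fragment count) in more than
    ``max_missing_bin_fraction`` of *training* samples are dropped from the
    feature set; remaining missing values are imputed with the training-set
    bin mean.  Both the retained-bin set and the imputation means depend on
    training samples only.
    """
    rows = {
        sid: compute_fsr(frags, bins, sample_id=sid, **fsr_kwargs).to_series()
        for sid, frags in fragments_by_sample.items()
    }
    table = pd.DataFrame(rows).T
    train = table.loc[[s for s in table.index if s in set(train_samples)]]
    if train.empty:
        raise ValueError("build_fsr_table: no training samples in cohort")
    missing_frac = train.isna().mean(axis=0)
    retained = table.columns[missing_frac <= max_missing_bin_fraction]
    dropped = table.shape[1] - len(retained)
    if dropped:
        logger.info("build_fsr_table: dropped %d of %d bins (missing in >%d%% of train)",
                    dropped, table.shape[1], int(100 * max_missing_bin_fraction))
    table = table[retained]
    train_means = table.loc[train.index].mean(axis=0)
    return table.fillna(train_means)


def build_breakpoint_table(
    fragments_by_sample: dict[str, pd.DataFrame],
    regions: pd.DataFrame,
    half_window: int,
    smoothing_bin: int = 1,
) -> pd.DataFrame:
    """Cohort breakpoint-score feature table for one annotation class."""
    class_label = str(regions["class_label"].iloc[0]) if "class_label" in regions else "bp"
    rows = {}
    for sid, frags in fragments_by_sample.items():
        profile = compute_breakpoint_profile(frags, regions, half_window, sample_id=sid)
        vec = profile_feature_vector(profile, smoothing_bin)
        rows[sid] = pd.Series(vec, index=[f"{class_label}_w{smoothing_bin}_{j}" for j in range(len(vec))])
    return pd.DataFrame(rows).T
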