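"""Synthetic cfDNA cohort generator.

Emulates the statistical structure the feature extractors are built for,
without any sequence-level simulation:

* fragment lengths from a two-component normal mixture (mono-nucleosomal
  mode ~167 bp and a short mode ~145 bp) truncated to [80, 250] bp, with
  the short-component weight increased in the case group;
* fragment start positions that are either "structured" — drawn around a
  random annotation-region center from a symmetric triangular density
  (with a depleted +/-40 bp core around nucleosome centers) or uniformly
  within the window — or background-uniform over the genome, weighted per
  1-Mb bin by a GC-bias curve and, for cases, by planted copy-number
  multipliers;
* per-CpG methylation calls with Beta-distributed baseline rates,
  Poisson coverage, sample-specific missingness, and planted
  hypomethylated regions shifting the case rates;
* a sample sheet with train/validation splits and case stages.

The ground truth (planted DMRs, CNA segments, group effect parameters) is
written alongside the data as ``truth.json`` and is never read by the
pipeline under test.  Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import sample_io
from .fragmentomics import DEFAULT_HALF_WINDOWS
from .genome import ChromSizes, tile_genome

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "SimulatedCohort", "simulate_cohort", "make_fixture", "PRESETS"]

REGION_WIDTHS = {"nucleosome": 147, "cpg_island": 500, "dnase_cluster": 300, "enhancer": 800}


@dataclass
class SimConfig:
    """All knobs of the cohort generator; fully serializable.

    Group-effect sizes (``delta_*``) are zero for an exchangeable null
    cohort.  ``delta_meth`` is in percentage points (negative = case
    hypomethylation); ``cna_multiplier`` is a linear copy-ratio factor
    applied to case background coverage inside planted segments.
    """

    # genome
    chromosomes: list = field(default_factory=lambda: [["chr1", 50_000_000], ["chr2", 50_000_000]])
    cna_bin_width: int = 1_000_000

    # cohort
    n_train_per_group: int = 20
    n_validation_per_group: int = 10
    group_labels: tuple = ("control", "case")

    # fragments
    fragments_per_sample: int = 20_000
    short_mode: float = 145.0
    short_sd: float = 8.0
    long_mode: float = 167.0
    long_sd: float = 10.0
    w_short: float = 0.2
    delta_w_short: float = 0.0
    length_bounds: tuple = (80, 250)

    # annotations + breakpoint positioning
    n_regions_per_class: int = 150
    f_window: float = 0.3
    p_struct: float = 0.6
    delta_p_struct: float = 0.0
    nucleosome_core: int = 40

    # methylation
    n_cpg_sites: int = 3000
    cpg_depth: float = 30.0
    baseline_beta: tuple = (6.0, 2.0)
    sample_rate_sd: float = 0.03
    missing_rate: float = 0.05
    n_high_missing_samples: int = 0
    high_missing_rate: float = 0.35

    # planted signals
    n_dmrs: int = 8
    dmr_width_cpgs: int = 10
    delta_meth: float = 0.0
    cna_segments: int = 0
    cna_segment_bins: int = 10
    cna_multiplier: float = 1.5

    # technical bias
    gc_bias_strength: float = 0.5
    n_low_mappability_bins: int = 3

    def validate(self) -> None:
        for name in ("w_short", "f_window", "p_struct", "missing_rate", "high_missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0 <= self.w_short + self.delta_w_short <= 1:
            raise ValueError("w_short + delta_w_short outside [0, 1]")
        if not 0 <= self.p_struct + self.delta_p_struct <= 1:
            raise ValueError("p_struct + delta_p_struct outside [0, 1]")
        if self.n_dmrs * self.dmr_width_cpgs > self.n_cpg_sites // 2:
            raise ValueError("planted DMRs cover more than half of the CpG landscape")
        n_bins = sum(int(np.ceil(l / self.cna_bin_width)) for _, l in self.chromosomes)
        if self.cna_segments * self.cna_segment_bins > n_bins // 2:
            raise ValueError("planted CNA segments cover more than half of the genome bins")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass
class SimulatedCohort:
    """In-memory cohort: inputs for the pipeline plus the hidden truth."""

    config: SimConfig
    seed: int
    chrom_sizes: ChromSizes
    samples: pd.DataFrame
    fragments: dict
    cpg_calls: dict
    regions: dict
    cna_covariates: pd.DataFrame
    truth: dict

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        (out / "fragments").mkdir(parents=True, exist_ok=True)
        (out / "methylation").mkdir(exist_ok=True)
        (out / "annotations").mkdir(exist_ok=True)
        with open(out / "genome.chrom.sizes", "w") as fh:
            for name, length in self.chrom_sizes:
                fh.write(f"{name}\t{length}\n")
        sample_io.write_sample_sheet(self.samples, out / "samples.tsv")
        for sid, frags in self.fragments.items():
            sample_io.write_fragments(frags, out / "fragments" / f"{sid}.bed")
        for sid, calls in self.cpg_calls.items():
            sample_io.write_cpg_calls(calls, out / "methylation" / f"{sid}.tsv")
        for label, regions in self.regions.items():
            sample_io.write_regions(regions, out / "annotations" / f"{label}.bed")
        self.cna_covariates.to_csv(out / "cna_covariates.tsv", sep="\t", index=False)
        (out / "truth.json").write_text(json.dumps(self.truth, indent=1))
        (out / "config.yaml").write_text(
            yaml.safe_dump({"seed": self.seed, **self.config.to_dict()})
        )
        return out


def _make_annotations(config: SimConfig, rng: np.random.Generator) -> dict:
    regions = {}
    chroms = config.chromosomes
    for label in sample_io.ANNOTATION_CLASSES:
        width = REGION_WIDTHS[label]
        margin = DEFAULT_HALF_WINDOWS[label] + width
        rows = []
        for _ in range(config.n_regions_per_class):
            ci = int(rng.integers(0, len(chroms)))
            name, length = chroms[ci]
            start = int(rng.integers(margin, length - margin))
            rows.append((name, start, start + width))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
        df["center"] = (df["start"] + df["end"]) // 2
        df["class_label"] = label
        regions[label] = df
    return regions


def _cna_bins(config: SimConfig):
    sizes = ChromSizes([(n, l) for n, l in config.chromosomes])
    return sizes, tile_genome(sizes, config.cna_bin_width)


def _make_covariates(config: SimConfig, n_bins: int, rng: np.random.Generator):
    # smooth, periodic GC landscape with mild noise
    i = np.arange(n_bins)
    gc = 0.45 + 0.08 * np.sin(2 * np.pi * i / 29.0) + rng.normal(0, 0.01, n_bins)
    gc = np.clip(gc, 0.3, 0.65)
    mappability = np.ones(n_bins)
    if config.n_low_mappability_bins:
        low = rng.choice(n_bins, size=config.n_low_mappability_bins, replace=False)
        mappability[low] = 0.3
    return gc, mappability


def _plant_cna_segments(config: SimConfig, n_bins: int, rng: np.random.Generator):
    segments = []
    taken = np.zeros(n_bins, dtype=bool)
    for _ in range(config.cna_segments):
        for _attempt in range(1000):
            start = int(rng.integers(0, n_bins - config.cna_segment_bins))
            span = slice(start, start + config.cna_segment_bins)
            if not taken[span].any():
                taken[span] = True
                segments.append({"start_bin": start, "end_bin": start + config.cna_segment_bins,
                                 "multiplier": config.cna_multiplier})
                break
        else:
            raise ValueError("could not place non-overlapping CNA segments")
    return segments


def _make_cpg_landscape(config: SimConfig, rng: np.random.Generator):
    chroms = config.chromosomes
    per_chrom = config.n_cpg_sites // len(chroms)
    chrom_names, positions = [], []
    for name, length in chroms:
        gaps = rng.integers(80, 220, size=per_chrom)
        pos = 1_000_000 + np.cumsum(gaps)
        pos = pos[pos < length - 1_000_000]
        chrom_names.extend([name] * len(pos))
        positions.extend(pos.tolist())
    sites = pd.DataFrame({"chrom": chrom_names, "pos": positions})
    a, b = config.baseline_beta
    base_rates = rng.beta(a, b, size=len(sites))
    # plant hypo/hyper-methylated runs, non-overlapping, away from chromosome joins
    dmr_sites = np.zeros(len(sites), dtype=bool)
    dmrs = []
    width = config.dmr_width_cpgs
    for _ in range(config.n_dmrs):
        for _attempt in range(1000):
            start = int(rng.integers(0, len(sites) - width))
            span = slice(start, start + width)
            if dmr_sites[span].any():
                continue
            if sites["chrom"].iloc[start] != sites["chrom"].iloc[start + width - 1]:
                continue
            dmr_sites[span] = True
            # keep baseline high enough that the planted drop stays observable
            base_rates[span] = np.clip(base_rates[span], 0.55, 0.95)
            dmrs.append({
                "chrom": str(sites["chrom"].iloc[start]),
                "start": int(sites["pos"].iloc[start]),
                "end": int(sites["pos"].iloc[start + width - 1]) + 1,
                "n_cpgs": width,
                "delta_meth": config.delta_meth,
            })
            break
        else:
            raise ValueError("could not place non-overlapping DMRs")
    case_rates = base_rates.copy()
    case_rates[dmr_sites] = np.clip(case_rates[dmr_sites] + config.delta_meth / 100.0, 0.02, 0.98)
    return sites, base_rates, case_rates, dmrs


def _sample_fragments(
    config: SimConfig,
    rng: np.random.Generator,
    is_case: bool,
    bin_weights: np.ndarray,
    bins,
    all_regions: pd.DataFrame,
) -> pd.DataFrame:
    n = config.fragments_per_sample
    w_short = config.w_short + (config.delta_w_short if is_case else 0.0)
    p_struct = config.p_struct + (config.delta_p_struct if is_case else 0.0)
    lo, hi = config.length_bounds

    is_short = rng.random(n) < w_short
    lengths = np.where(
        is_short,
        rng.normal(config.short_mode, config.short_sd, n),
        rng.normal(config.long_mode, config.long_sd, n),
    )
    lengths = np.clip(np.round(lengths), lo, hi).astype(np.int64)

    structured = rng.random(n) < config.f_window
    starts = np.empty(n, dtype=np.int64)
    chrom_idx = np.empty(n, dtype=np.int64)

    # background: per-1-Mb-bin weighted uniform
    bg = ~structured
    n_bg = int(bg.sum())
    probs = bin_weights / bin_weights.sum()
    chosen = rng.choice(len(bins), size=n_bg, p=probs)
    chrom_order = [name for name, _ in config.chromosomes]
    bin_chrom = np.array([chrom_order.index(b.chrom) for b in bins])
    bin_start = np.array([b.start for b in bins])
    bin_width_eff = np.array([b.width for b in bins])
    starts[bg] = bin_start[chosen] + rng.integers(0, bin_width_eff[chosen])
    chrom_idx[bg] = bin_chrom[chosen]

    # structured: offset from a random annotation center
    n_st = n - n_bg
    if n_st:
        ridx = rng.integers(0, len(all_regions), size=n_st)
        centers = all_regions["center"].to_numpy()[ridx]
        r_chrom = all_regions["chrom_idx"].to_numpy()[ridx]
        half = all_regions["half_window"].to_numpy()[ridx].astype(float)
        is_nuc = all_regions["is_nucleosome"].to_numpy()[ridx]
        peaked = rng.random(n_st) < p_struct
        offsets = np.where(
            peaked,
            rng.triangular(-half, 0, half),
            rng.uniform(-half, half),
        )
        # depleted nucleosome core: push peaked draws out of +/- core
        core = config.nucleosome_core
        redo = peaked & is_nuc & (np.abs(offsets) < core)
        for _ in range(50):
            if not redo.any():
                break
            offsets[redo] = rng.triangular(-half[redo], 0, half[redo])
            redo = redo & (np.abs(offsets) < core)
        starts[structured] = centers + np.round(offsets).astype(np.int64)
        chrom_idx[structured] = r_chrom

    chrom_lengths = np.array([l for _, l in config.chromosomes])
    starts = np.clip(starts, 0, chrom_lengths[chrom_idx] - lengths - 1)
    names = np.array(chrom_order, dtype=object)
    df = pd.DataFrame({"chrom": names[chrom_idx], "start": starts, "end": starts + lengths})
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    df["length"] = df["end"] - df["start"]
    return df


def _sample_methylation(
    config: SimConfig,
    rng: np.random.Generator,
    sites: pd.DataFrame,
    rates: np.ndarray,
    missing_rate: float,
) -> pd.DataFrame:
    n = len(sites)
    cov = rng.poisson(config.cpg_depth, n)
    cov[rng.random(n) < missing_rate] = 0
    jitter = rng.normal(0, config.sample_rate_sd, n)
    p = np.clip(rates + jitter, 0.01, 0.99)
    meth = rng.binomial(cov, p)
    keep = cov > 0
    return pd.DataFrame({
        "chrom": sites["chrom"].to_numpy()[keep],
        "pos": sites["pos"].to_numpy()[keep],
        "meth": meth[keep],
        "unmeth": (cov - meth)[keep],
    })


def simulate_cohort(config: SimConfig, seed: int) -> SimulatedCohort:
    """Generate a full cohort deterministically from (config, seed)."""
    config.validate()
    rng = np.random.default_rng(seed)
    chrom_sizes = ChromSizes([(n, l) for n, l in config.chromosomes])
    regions = _make_annotations(config, rng)
    sizes, bins = _cna_bins(config)
    gc, mappability = _make_covariates(config, len(bins), rng)
    segments = _plant_cna_segments(config, len(bins), rng)
    sites, base_rates, case_rates, dmrs = _make_cpg_landscape(config, rng)

    # pooled annotation lookup used by the structured-fragment sampler
    chrom_order = [n for n, _ in config.chromosomes]
    pooled = []
    for label, df in regions.items():
        d = df[["chrom", "center"]].copy()
        d["chrom_idx"] = d["chrom"].map({c: i for i, c in enumerate(chrom_order)})
        d["half_window"] = DEFAULT_HALF_WINDOWS[label]
        d["is_nucleosome"] = label == "nucleosome"
        pooled.append(d)
    pooled = pd.concat(pooled, ignore_index=True)

    gc_weight = np.exp(config.gc_bias_strength * (gc - gc.mean()) / max(gc.std(), 1e-9))
    control_weights = gc_weight.copy()
    case_weights = gc_weight.copy()
    for seg in segments:
        case_weights[seg["start_bin"]:seg["end_bin"]] *= seg["multiplier"]

    # sample sheet
    rows = []
    control_label, case_label = config.group_labels
    for split, n_per in (("train", config.n_train_per_group),
                         ("validation", config.n_validation_per_group)):
        for g, label in (("ctrl", control_label), ("case", case_label)):
            for i in range(n_per):
                sid = f"{g}_{split[:2]}_{i:02d}"
                stage = rng.choice(["I", "II", "III", "IV"]) if g == "case" else ""
                rows.append((sid, label, split, stage))
    samples = pd.DataFrame(rows, columns=["sample_id", "group", "split", "stage"])

    high_missing = set(
        samples.loc[samples["split"] == "validation", "sample_id"][: config.n_high_missing_samples]
    )

    fragments, cpg_calls = {}, {}
    for row in samples.itertuples():
        is_case = row.group == case_label
        weights = case_weights if is_case else control_weights
        fragments[row.sample_id] = _sample_fragments(config, rng, is_case, weights, bins, pooled)
        rates = case_rates if is_case else base_rates
        miss = config.high_missing_rate if row.sample_id in high_missing else config.missing_rate
        cpg_calls[row.sample_id] = _sample_methylation(config, rng, sites, rates, miss)

    covariates = pd.DataFrame({
        "bin": [b.index for b in bins],
        "chrom": [b.chrom for b in bins],
        "start": [b.start for b in bins],
        "end": [b.end for b in bins],
        "gc": gc,
        "mappability": mappability,
    })
    truth = {
        "seed": seed,
        "dmrs": dmrs,
        "cna_segments": [
            {**seg,
             "chrom": bins[seg["start_bin"]].chrom,
             "start": bins[seg["start_bin"]].start,
             "end": bins[seg["end_bin"] - 1].end}
            for seg in segments
        ],
        "effects": {
            "delta_w_short": config.delta_w_short,
            "delta_p_struct": config.delta_p_struct,
            "delta_meth": config.delta_meth,
            "cna_multiplier": config.cna_multiplier if segments else None,
        },
        "high_missing_samples": sorted(high_missing),
    }
    return SimulatedCohort(config, seed, chrom_sizes, samples, fragments, cpg_calls,
                           regions, covariates, truth)


def _preset_tiny() -> SimConfig:
    return SimConfig(
        chromosomes=[["chr1", 10_000_000], ["chr2", 10_000_000]],
        n_train_per_group=6, n_validation_per_group=2,
        fragments_per_sample=2_000,
        n_regions_per_class=40,
        n_cpg_sites=600,
        n_dmrs=2, dmr_width_cpgs=8, delta_meth=-30.0,
        delta_w_short=0.08, delta_p_struct=0.05,
        cna_segments=1, cna_segment_bins=4,
        n_low_mappability_bins=1,
    )


def _preset_null() -> SimConfig:
    return SimConfig(
        n_dmrs=0, delta_meth=0.0, delta_w_short=0.0, delta_p_struct=0.0, cna_segments=0,
    )


def _preset_signal() -> SimConfig:
    return SimConfig(
        delta_w_short=0.1,
        n_dmrs=8, dmr_width_cpgs=10, delta_meth=-25.0,
        cna_segments=2, cna_segment_bins=10, cna_multiplier=1.5,
        delta_p_struct=0.05,
        n_high_missing_samples=1,
    )


PRESETS = {"tiny": _preset_tiny, "null": _preset_null, "signal": _preset_signal}


def make_fixture(name: str, seed: int = 0, out_dir=None):
    """Materialize a named preset; returns the in-memory cohort.

    With ``out_dir`` the dataset is also written in the standard on-disk
    layout (fragments/, methylation/, annotations/, samples.tsv,
    cna_covariates.tsv, truth.json, config.yaml).
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cohort = simulate_cohort(PRESETS[name](), seed)
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort
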