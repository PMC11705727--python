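"""End-to-end orchestration: data -> seven feature tables -> model -> metrics.

A run is driven by a :class:`PipelineConfig` and writes a manifest with the
config hash, per-stage output paths and artifact checksums; re-running with
an identical config and inputs reproduces identical feature tables and
models.  Stages are resumable: a stage whose outputs already exist is
skipped, and recomputing a stage invalidates everything downstream.

The omics order is fixed and global — DMR, FSR, CNA, BSN, BSC, BSD, BSE —
and is used for stacking columns and all reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import methylation, sample_io
from .cna import build_cna_table
from .fragmentomics import DEFAULT_HALF_WINDOWS, build_breakpoint_table, build_fsr_table
from .genome import ChromSizes, read_chrom_sizes, tile_genome
from .modeling import OMICS_ORDER, ComosModel, ModelConfig, default_grids, fast_grids
from .simulate import PRESETS, SimulatedCohort, make_fixture

logger = logging.getLogger(__name__)

#: omics code -> annotation class for the four breakpoint-score layers
BREAKPOINT_OMICS = {
    "BSN": "nucleosome",
    "BSC": "cpg_island",
    "BSD": "dnase_cluster",
    "BSE": "enhancer",
}

__all__ = ["PipelineConfig", "DataBundle", "load_dataset", "extract_features",
           "run_pipeline", "RunManifest"]


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    Either ``data_dir`` (an existing dataset in the standard layout) or
    ``preset`` (a simulator preset materialized under the output
    directory) must be given.
    """

    out_dir: str = "comos_run"
    data_dir: str | None = None
    preset: str | None = None
    seed: int = 42
    task: str = "early_dx"

    fsr_bin_width: int = 5_000_000
    fsr_max_missing_bin_fraction: float = 0.2
    bs_n_features: int = 20
    half_windows: dict = field(default_factory=lambda: dict(DEFAULT_HALF_WINDOWS))
    cna_bin_width: int = 1_000_000
    dmr_min_cpg: int = 4
    dmr_q_threshold: float = 0.05
    dmr_max_cpg_gap: int = 300
    dmr_max_missing: float = 0.2
    dmr_impute_with: str = "train"
    grids: str = "fast"
    cv_folds: int = 10
    target_specificity: float = 0.99
    rfecv_step: int = 1

    def __post_init__(self):
        if (self.data_dir is None) == (self.preset is None):
            raise ValueError("exactly one of data_dir or preset must be set")
        if self.preset is not None and self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.grids not in {"fast", "full"}:
            raise ValueError("grids must be 'fast' or 'full'")

    @property
    def dmr_diff_threshold(self) -> float:
        # control-vs-case uses 20 percentage points; treatment response 15
        return 20.0 if self.task == "early_dx" else 15.0

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")  # where a run lands does not change what it computes
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def model_config(self) -> ModelConfig:
        grids = fast_grids() if self.grids == "fast" else default_grids()
        return ModelConfig(cv_folds=self.cv_folds, seed=self.seed, grids=grids,
                           target_specificity=self.target_specificity,
                           rfecv_step=self.rfecv_step)


@dataclass
class DataBundle:
    """A dataset in memory, truth excluded by construction."""

    chrom_sizes: ChromSizes
    samples: pd.DataFrame
    fragments: dict
    cpg_calls: dict
    regions: dict
    cna_covariates: pd.DataFrame

    @classmethod
    def from_cohort(cls, cohort: SimulatedCohort) -> "DataBundle":
        return cls(cohort.chrom_sizes, cohort.samples, cohort.fragments,
                   cohort.cpg_calls, cohort.regions, cohort.cna_covariates)


def load_dataset(data_dir) -> DataBundle:
    """Load a dataset directory (never touches truth.json)."""
    data_dir = Path(data_dir)
    chrom_sizes = read_chrom_sizes(data_dir / "genome.chrom.sizes")
    samples = sample_io.read_sample_sheet(data_dir / "samples.tsv")
    fragments = {
        sid: sample_io.read_fragments(data_dir / "fragments" / f"{sid}.bed")
        for sid in samples["sample_id"]
    }
    cpg_calls = {
        sid: sample_io.read_cpg_calls(data_dir / "methylation" / f"{sid}.tsv")
        for sid in samples["sample_id"]
    }
    regions = {
        label: sample_io.read_regions(data_dir / "annotations" / f"{label}.bed", label)
        for label in sample_io.ANNOTATION_CLASSES
    }
    covariates = pd.read_csv(data_dir / "cna_covariates.tsv", sep="\t")
    return DataBundle(chrom_sizes, samples, fragments, cpg_calls, regions, covariates)


def extract_features(data: DataBundle, config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Compute the seven omics feature tables (train-defined artifacts)."""
    samples = data.samples
    train_ids = list(samples.loc[samples["split"] == "train", "sample_id"])
    labels = dict(zip(samples["sample_id"], samples["group"]))
    positive = {"case", "PDSD"}
    train_case = [s for s in train_ids if labels[s] in positive]
    train_ctrl = [s for s in train_ids if labels[s] not in positive]

    tables: dict[str, pd.DataFrame] = {}

    t0 = time.time()
    dmrs = methylation.call_dmrs(
        {s: data.cpg_calls[s] for s in train_case},
        {s: data.cpg_calls[s] for s in train_ctrl},
        min_cpg=config.dmr_min_cpg, q_threshold=config.dmr_q_threshold,
        diff_threshold=config.dmr_diff_threshold, max_cpg_gap=config.dmr_max_cpg_gap,
    )
    if len(dmrs) == 0:
        logger.warning("extract: no DMRs called on the training split; "
                       "DMR omics reduced to a single null feature")
        tables["DMR"] = pd.DataFrame(
            {"dmr_none": 0.0}, index=list(samples["sample_id"])
        )
    else:
        matrix, excluded = methylation.build_dmr_matrix(
            data.cpg_calls, dmrs, max_missing=config.dmr_max_missing,
            impute_with=config.dmr_impute_with, train_samples=train_ids,
        )
        tables["DMR"] = matrix
    logger.info("extract: DMR done (%d regions, %.1fs)", len(dmrs), time.time() - t0)

    t0 = time.time()
    fsr_bins = tile_genome(data.chrom_sizes, config.fsr_bin_width)
    tables["FSR"] = build_fsr_table(
        data.fragments, fsr_bins, train_ids,
        max_missing_bin_fraction=config.fsr_max_missing_bin_fraction,
    )
    logger.info("extract: FSR done (%d bins, %.1fs)", tables["FSR"].shape[1], time.time() - t0)

    t0 = time.time()
    cna_bins = tile_genome(data.chrom_sizes, config.cna_bin_width)
    cov = data.cna_covariates
    tables["CNA"] = build_cna_table(
        data.fragments, cna_bins,
        cov["gc"].to_numpy(), cov["mappability"].to_numpy(), train_ids,
    )
    logger.info("extract: CNA done (%d bins, %.1fs)", tables["CNA"].shape[1], time.time() - t0)

    for omics, label in BREAKPOINT_OMICS.items():
        t0 = time.time()
        half = config.half_windows[label]
        smoothing = max(1, (2 * half + 1) // config.bs_n_features)
        tables[omics] = build_breakpoint_table(data.fragments, data.regions[label],
                                               half, smoothing)
        logger.info("extract: %s done (%d features, %.1fs)", omics,
                    tables[omics].shape[1], time.time() - t0)
    return {o: tables[o] for o in OMICS_ORDER}


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)
    input_checksums: dict = field(default_factory=dict)
    version: str = ""
    started: str = ""
    finished: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _save_model_artifacts(results, model_dir: Path) -> None:
    model_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "task": results.model.task,
        "omics_order": list(results.model.omics_order),
        "stacked_threshold": results.stacked.threshold,
        "omics": {},
    }
    for omics, m in results.omics_models.items():
        meta["omics"][omics] = {
            "family": m.family,
            "hyperparameters": {k: (None if v is None else v) for k, v in m.hyperparameters.items()},
            "cv_auc": m.cv_auc,
            "threshold": m.threshold,
            "features": m.features,
            "scaler_center": m.standardizer.center.to_dict(),
            "scaler_scale": m.standardizer.scale.to_dict(),
        }
    (model_dir / "model.json").write_text(json.dumps(meta, indent=1, default=str))
    import joblib

    joblib.dump(
        {"omics_models": results.omics_models, "stacked": results.stacked},
        model_dir / "classifiers.joblib",
    )


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute (or resume) a full run; returns the written manifest."""
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.config_hash(), config.seed, version=__version__,
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    (out / "config.json").write_text(json.dumps(dataclasses.asdict(config), indent=1))

    # -- stage 1: data ----------------------------------------------------
    recomputed = False
    if config.preset is not None:
        data_dir = out / "data"
        if not (data_dir / "samples.tsv").exists():
            logger.info("stage simulate: preset %s seed %d", config.preset, config.seed)
            make_fixture(config.preset, seed=config.seed, out_dir=data_dir)
            recomputed = True
    else:
        data_dir = Path(config.data_dir)
    manifest.stages["data"] = str(data_dir)
    data = load_dataset(data_dir)
    for f in sorted((data_dir / "fragments").glob("*.bed"))[:3]:
        manifest.input_checksums[f.name] = _sha256(f)

    # -- stage 2: features -------------------------------------------------
    features_dir = out / "features"
    expected = [features_dir / f"{o}.features.tsv" for o in OMICS_ORDER]
    if recomputed or not all(p.exists() for p in expected):
        features_dir.mkdir(exist_ok=True)
        train_ids = list(data.samples.loc[data.samples["split"] == "train", "sample_id"])
        tables = extract_features(data, config)
        for omics, table in tables.items():
            sample_io.write_feature_table(table, features_dir / f"{omics}.features.tsv",
                                          omics=omics, train_samples=train_ids)
        recomputed = True
    else:
        logger.info("stage extract: cached feature tables found, skipping")
        tables = {o: sample_io.read_feature_table(p) for o, p in zip(OMICS_ORDER, expected)}
    manifest.stages["features"] = str(features_dir)

    # -- stage 3: train ----------------------------------------------------
    model_dir = out / "model"
    model = ComosModel(tables, data.samples, task=config.task, config=config.model_config())
    if recomputed or not (model_dir / "model.json").exists():
        logger.info("stage train: task %s, %d train / %d validation samples",
                    config.task, len(model.train_ids), len(model.validation_ids))
        results = model.fit()
        _save_model_artifacts(results, model_dir)
        recomputed = True
    else:
        import joblib

        logger.info("stage train: cached model found, skipping")
        payload = joblib.load(model_dir / "classifiers.joblib")
        from .modeling import ComosResults

        results = ComosResults(model, payload["omics_models"], payload["stacked"],
                               config.model_config())
    manifest.stages["model"] = str(model_dir)

    # -- stage 4: evaluate ---------------------------------------------------
    metrics_path = out / "metrics.json"
    if recomputed or not metrics_path.exists():
        reports = results.evaluate("validation", n_boot=1000, seed=config.seed)
        payload = {name: r.to_dict() for name, r in reports.items()}
        preds = results.predict(model.validation_ids)
        case_mask = model.labels.loc[model.validation_ids] == 1
        stages = data.samples.set_index("sample_id").reindex(model.validation_ids)
        if "stage" in stages.columns and case_mask.any():
            from .evaluation import stage_stratified_sensitivity

            payload["stage_stratified"] = stage_stratified_sensitivity(
                preds["call"].to_numpy(),
                model.labels.loc[model.validation_ids].to_numpy(),
                stages["stage"].fillna("").to_numpy(),
            )
        metrics_path.write_text(json.dumps(payload, indent=1))
    manifest.stages["metrics"] = str(metrics_path)

    for path in [*features_dir.glob("*.features.tsv"), model_dir / "model.json", metrics_path]:
        path = Path(path)
        if path.exists():
            manifest.checksums[path.name] = _sha256(path)
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=1))
    return manifest
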