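"""Per-omics classifier bank and the stacked integrator.

For each omics feature table the training recipe is: z-standardize (scaler
fit on the training split, applied to the whole table), recursive feature
elimination with cross-validation (RFECV, 10-fold, ROC AUC), exhaustive
grid search over three classifier families (logistic regression, random
forest, AdaBoost; 10-fold ROC AUC), selection of the family with the
largest mean cross-validated AUC, and calibration of a decision threshold
by stepping upward from 0.5 in increments of 0.01 until the training-set
specificity reaches a target (99% by default).

The integrator ("stack") is a random forest fit on the seven per-omics
positive-class probability columns in a fixed omics order (DMR, FSR, CNA,
BSN, BSC, BSD, BSE), seed 42; tree count is 100 for the early-diagnosis
task and 5 for the smaller treatment-response task, where a small forest
guards against over-fitting.  Its threshold is calibrated the same way.

The public surface is :class:`ComosModel` (built from feature tables and a
sample sheet) whose :meth:`~ComosModel.fit` returns a
:class:`ComosResults` carrying the trained bank, the stack, per-omics
cross-validation AUCs, calibrated thresholds and a ``summary()`` table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.feature_selection import RFECV
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from . import evaluation

logger = logging.getLogger(__name__)

#: fixed global omics order used for stacking columns and all reports
OMICS_ORDER = ("DMR", "FSR", "CNA", "BSN", "BSC", "BSD", "BSE")

#: family evaluation order; also the tie-break order for best-family choice
FAMILY_ORDER = ("logistic_regression", "random_forest", "adaboost")

POSITIVE_GROUPS = {"case": 1, "control": 0, "PDSD": 1, "PRCR": 0}

__all__ = [
    "OMICS_ORDER",
    "FAMILY_ORDER",
    "ModelConfig",
    "Standardizer",
    "TrainedOmicsModel",
    "StackedModel",
    "ComosModel",
    "ComosResults",
    "default_grids",
    "fast_grids",
    "fit_standardizer",
    "select_features",
    "tune_and_train",
    "pick_best_family",
    "calibrate_threshold",
    "encode_labels",
]


def default_grids() -> dict:
    """The full hyperparameter grids searched per classifier family.

    The random-forest ``max_features`` grid collapses the historical
    ``auto`` alias (identical to ``sqrt`` for classifiers) into ``sqrt``.
    """
    return {
        "adaboost": {"n_estimators": [50, 100, 200], "learning_rate": [0.01, 0.1, 1.0]},
        "logistic_regression": {
            "C": [0.001, 0.01, 0.1, 1, 10, 100],
            "penalty": ["l1", "l2"],
            "max_iter": [100, 500, 1000],
        },
        "random_forest": {
            "n_estimators": [100, 200, 300],
            "max_depth": [None, 10, 20, 30],
            "min_samples_split": [2, 5, 10],
            "min_samples_leaf": [1, 2, 4],
            "max_features": ["sqrt", "log2"],
        },
    }


def fast_grids() -> dict:
    """Reduced grids for desk-scale cohorts and simulation studies."""
    return {
        "adaboost": {"n_estimators": [50], "learning_rate": [0.1, 1.0]},
        "logistic_regression": {"C": [0.01, 1, 100], "penalty": ["l2"], "max_iter": [500]},
        "random_forest": {"n_estimators": [100], "max_depth": [None, 10]},
    }


@dataclass
class ModelConfig:
    """Training-recipe knobs shared by every omics model."""

    cv_folds: int = 10
    seed: int = 42
    grids: dict = field(default_factory=default_grids)
    target_specificity: float = 0.99
    threshold_start: float = 0.5
    threshold_step: float = 0.01
    rfecv_step: int = 1
    min_features: int = 1


def encode_labels(groups) -> np.ndarray:
    """Map group labels to 0/1 (case and PDSD are the positive class)."""
    try:
        return np.array([POSITIVE_GROUPS[g] for g in groups], dtype=int)
    except KeyError as exc:
        raise ValueError(f"unknown group label {exc.args[0]!r}") from exc


# ---------------------------------------------------------------------------
# standardization

@dataclass
class Standardizer:
    """Per-feature z-transform with train-split moments.

    Zero-variance training features are centered and passed through with
    unit scale; their names are kept in ``degenerate``.
    """

    center: pd.Series
    scale: pd.Series
    degenerate: list[str] = field(default_factory=list)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return (table[self.center.index] - self.center) / self.scale


def fit_standardizer(train_table: pd.DataFrame) -> Standardizer:
    center = train_table.mean(axis=0)
    scale = train_table.std(axis=0, ddof=0)
    degenerate = list(scale.index[scale == 0])
    if degenerate:
        logger.warning("fit_standardizer: %d zero-variance features pass through unscaled",
                       len(degenerate))
        scale = scale.replace(0, 1.0)
    return Standardizer(center, scale, degenerate)


# ---------------------------------------------------------------------------
# feature elimination, grid search, family choice

def _folds(y: np.ndarray, cv_folds: int, seed: int) -> StratifiedKFold:
    smallest = int(min(np.bincount(y, minlength=2)))
    k = min(cv_folds, smallest)
    if k < cv_folds:
        logger.warning("reducing CV folds from %d to %d (smallest class has %d samples)",
                       cv_folds, k, smallest)
    if k < 2:
        raise ValueError("need at least 2 samples per class for cross-validation")
    return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)


def select_features(
    train_table: pd.DataFrame,
    y: np.ndarray,
    cv_folds: int = 10,
    seed: int = 42,
    step: int = 1,
    min_features: int = 1,
) -> list[str]:
    """RFECV feature subset (logistic-L2 eliminator, ROC-AUC scored).

    Deterministic under a fixed seed; with a single input feature it is
    returned untouched.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("select_features: training data contains a single class")
    if train_table.shape[1] == 1:
        return list(train_table.columns)
    estimator = LogisticRegression(C=1.0, max_iter=1000, solver="liblinear",
                                   random_state=seed)
    selector = RFECV(
        estimator,
        step=step,
        min_features_to_select=min_features,
        cv=_folds(y, cv_folds, seed),
        scoring="roc_auc",
        n_jobs=1,
    )
    selector.fit(train_table.to_numpy(), y)
    return list(train_table.columns[selector.support_])


def _make_estimator(family: str, seed: int):
    if family == "logistic_regression":
        return LogisticRegression(solver="liblinear", random_state=seed)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if family == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    raise ValueError(f"unknown classifier family {family!r}")


def tune_and_train(
    train_table: pd.DataFrame,
    y: np.ndarray,
    family: str,
    grid: dict,
    cv_folds: int = 10,
    seed: int = 42,
):
    """Exhaustive grid search for one family, scored by mean CV ROC AUC.

    Returns ``(fitted estimator, best hyperparameters, mean CV AUC)``; the
    best configuration is refit on the full training split.
    """
    estimator = _make_estimator(family, seed)
    valid = set(estimator.get_params())
    bad = set(grid) - valid
    if bad:
        raise ValueError(f"invalid grid entries for {family}: {sorted(bad)}")
    search = GridSearchCV(
        estimator,
        grid,
        scoring="roc_auc",
        cv=_folds(y, cv_folds, seed),
        n_jobs=1,
        refit=True,
        error_score=0.0,
    )
    with warnings.catch_warnings():
        # the logistic grid spells the penalty as l1/l2, which
        # newer sklearn releases alias to l1_ratio with a FutureWarning;
        # failed fits (e.g. boosting on signal-free data) score 0
        warnings.simplefilter("ignore", FutureWarning)
        warnings.simplefilter("ignore", UserWarning)
        search.fit(train_table.to_numpy(), y)
    return search.best_estimator_, search.best_params_, float(search.best_score_)


def pick_best_family(candidates: dict[str, tuple]) -> str:
    """Family with the largest mean CV AUC; ties go to the fixed order."""
    if not candidates:
        raise ValueError("pick_best_family: no candidates")
    best = None
    for family in FAMILY_ORDER:
        if family not in candidates:
            continue
        auc = candidates[family][2]
        if best is None or auc > candidates[best][2]:
            best = family
    return best


def calibrate_threshold(
    probabilities: np.ndarray,
    y: np.ndarray,
    target_specificity: float = 0.99,
    start: float = 0.5,
    step: float = 0.01,
) -> float:
    """Smallest threshold on the {0.5, 0.51, ...} grid reaching the target
    training-set specificity.

    A probability exactly at the threshold is a positive call.  If no grid
    point below 1 reaches the target, the largest threshold attaining the
    maximum specificity is returned (logged).
    """
    y = np.asarray(y).astype(int)
    if not (y == 0).any():
        raise ValueError("calibrate_threshold: no negative samples; specificity undefined")
    neg = np.asarray(probabilities, dtype=float)[y == 0]
    grid = np.round(np.arange(start, 1.0, step), 10)
    grid = grid[grid < 1.0]
    specs = np.array([(neg < t).mean() for t in grid])
    reached = np.flatnonzero(specs >= target_specificity)
    if reached.size:
        return float(grid[reached[0]])
    best = specs.max()
    t = float(grid[np.flatnonzero(specs == best)[-1]])
    logger.warning("calibrate_threshold: target specificity %.2f unreachable; "
                   "returning argmax threshold %.2f (specificity %.3f)", target_specificity, t, best)
    return t


# ---------------------------------------------------------------------------
# trained artifacts

@dataclass
class TrainedOmicsModel:
    """Everything needed to score new samples for one omics layer."""

    omics: str
    standardizer: Standardizer
    features: list[str]
    family: str
    hyperparameters: dict
    classifier: object
    cv_auc: float
    threshold: float

    def predict_proba(self, table: pd.DataFrame) -> pd.Series:
        missing = [f for f in self.standardizer.center.index if f not in table.columns]
        if missing:
            raise ValueError(f"{self.omics}: table lacks trained features, e.g. {missing[:5]}")
        z = self.standardizer.transform(table)[self.features]
        probs = self.classifier.predict_proba(z.to_numpy())[:, 1]
        return pd.Series(probs, index=table.index, name=self.omics)

    def predict(self, table: pd.DataFrame) -> pd.DataFrame:
        probs = self.predict_proba(table)
        return pd.DataFrame({"probability": probs, "call": (probs >= self.threshold).astype(int)})


@dataclass
class StackedModel:
    """Random-forest integrator over the per-omics probability columns."""

    omics_order: tuple
    classifier: object
    threshold: float

    def predict_proba(self, prob_table: pd.DataFrame) -> pd.Series:
        x = prob_table[list(self.omics_order)].to_numpy()
        return pd.Series(self.classifier.predict_proba(x)[:, 1], index=prob_table.index,
                         name="stacked")

    def predict(self, prob_table: pd.DataFrame) -> pd.DataFrame:
        probs = self.predict_proba(prob_table)
        return pd.DataFrame({"probability": probs, "call": (probs >= self.threshold).astype(int)})


def train_omics_model(
    omics: str,
    table: pd.DataFrame,
    labels: pd.Series,
    train_ids: list[str],
    config: ModelConfig,
) -> TrainedOmicsModel:
    """Run the full per-omics recipe on one feature table."""
    train_ids = [s for s in train_ids if s in table.index]
    train = table.loc[train_ids]
    y = labels.loc[train_ids].to_numpy()
    standardizer = fit_standardizer(train)
    z_train = standardizer.transform(train)
    features = select_features(z_train, y, cv_folds=config.cv_folds, seed=config.seed,
                               step=config.rfecv_step, min_features=config.min_features)
    candidates = {}
    for family in FAMILY_ORDER:
        if family not in config.grids:
            continue
        try:
            candidates[family] = tune_and_train(
                z_train[features], y, family, config.grids[family],
                cv_folds=config.cv_folds, seed=config.seed,
            )
        except ValueError as exc:
            # a family that cannot be fit at all (e.g. boosting when every
            # weak learner is worse than random) drops out of the contest
            logger.warning("%s: %s family could not be fit (%s); skipped", omics, family, exc)
    if not candidates:
        raise ValueError(f"{omics}: no classifier family could be fit")
    best = pick_best_family(candidates)
    classifier, params, cv_auc = candidates[best]
    train_probs = classifier.predict_proba(z_train[features].to_numpy())[:, 1]
    threshold = calibrate_threshold(train_probs, y, config.target_specificity,
                                    config.threshold_start, config.threshold_step)
    logger.info("%s: %d/%d features, best family %s (CV AUC %.3f), threshold %.2f",
                omics, len(features), table.shape[1], best, cv_auc, threshold)
    return TrainedOmicsModel(omics, standardizer, features, best, params, classifier,
                             cv_auc, threshold)


# ---------------------------------------------------------------------------
# model / results objects

class ComosModel:
    """Multi-omics stacked classifier specification bound to data.

    Parameters
    ----------
    feature_tables
        Mapping omics name -> sample x feature table, in any subset of the
        canonical omics set; tables must share the sample universe.
    samples
        Sample sheet with ``sample_id``, ``group``, ``split`` (and optional
        ``stage``) columns.
    task
        ``early_dx`` (control vs case) or ``treatment`` (PRCR vs PDSD); the
        treatment task uses a 5-tree integrator.
    """

    def __init__(
        self,
        feature_tables: dict[str, pd.DataFrame],
        samples: pd.DataFrame,
        task: str = "early_dx",
        config: ModelConfig | None = None,
    ):
        if task not in {"early_dx", "treatment"}:
            raise ValueError(f"unknown task {task!r}")
        unknown = set(feature_tables) - set(OMICS_ORDER)
        if unknown:
            raise ValueError(f"unknown omics names {sorted(unknown)}")
        self.omics_order = tuple(o for o in OMICS_ORDER if o in feature_tables)
        self.feature_tables = {o: feature_tables[o] for o in self.omics_order}
        self.samples = samples.set_index("sample_id") if "sample_id" in samples.columns else samples
        self.task = task
        self.config = config or ModelConfig()
        # samples present in every omics table (DMR filtering may drop some)
        common = set(self.samples.index)
        for table in self.feature_tables.values():
            common &= set(table.index)
        dropped = sorted(set(self.samples.index) - common)
        if dropped:
            logger.info("ComosModel: %d samples absent from some omics table: %s",
                        len(dropped), dropped)
        self.sample_ids = [s for s in self.samples.index if s in common]
        self.labels = pd.Series(encode_labels(self.samples.loc[self.sample_ids, "group"]),
                                index=self.sample_ids)
        split = self.samples.loc[self.sample_ids, "split"]
        self.train_ids = list(split.index[split == "train"])
        self.validation_ids = list(split.index[split == "validation"])

    @classmethod
    def from_directory(cls, features_dir, samples_path, **kwargs) -> "ComosModel":
        """Build from a directory of ``<omics>.features.tsv`` tables."""
        from pathlib import Path

        from .sample_io import read_feature_table, read_sample_sheet

        features_dir = Path(features_dir)
        tables = {}
        for omics in OMICS_ORDER:
            path = features_dir / f"{omics}.features.tsv"
            if path.exists():
                tables[omics] = read_feature_table(path)
        if not tables:
            raise FileNotFoundError(f"no *.features.tsv tables under {features_dir}")
        return cls(tables, read_sample_sheet(samples_path), **kwargs)

    def fit(self, seed: int | None = None) -> "ComosResults":
        """Train the per-omics bank and the stacked integrator."""
        config = self.config
        if seed is not None:
            config = ModelConfig(**{**config.__dict__, "seed": seed})
        omics_models = {}
        train_probs = {}
        for omics in self.omics_order:
            table = self.feature_tables[omics].loc[self.sample_ids]
            model = train_omics_model(omics, table, self.labels, self.train_ids, config)
            omics_models[omics] = model
            train_probs[omics] = model.predict_proba(table.loc[self.train_ids])
        prob_table = pd.DataFrame(train_probs)[list(self.omics_order)]
        n_trees = 100 if self.task == "early_dx" else 5
        integrator = RandomForestClassifier(n_estimators=n_trees, random_state=config.seed)
        y_train = self.labels.loc[self.train_ids].to_numpy()
        integrator.fit(prob_table.to_numpy(), y_train)
        stack_probs = integrator.predict_proba(prob_table.to_numpy())[:, 1]
        threshold = calibrate_threshold(stack_probs, y_train, config.target_specificity,
                                        config.threshold_start, config.threshold_step)
        stacked = StackedModel(self.omics_order, integrator, threshold)
        return ComosResults(self, omics_models, stacked, config)


class ComosResults:
    """Trained bank + stack, with prediction and evaluation helpers."""

    def __init__(self, model: ComosModel, omics_models: dict, stacked: StackedModel,
                 config: ModelConfig):
        self.model = model
        self.omics_models = omics_models
        self.stacked = stacked
        self.config = config

    # -- prediction -------------------------------------------------------
    def omics_probabilities(self, sample_ids: list[str] | None = None) -> pd.DataFrame:
        """Per-omics positive-class probability columns (stacking input)."""
        ids = sample_ids if sample_ids is not None else self.model.sample_ids
        cols = {
            o: m.predict_proba(self.model.feature_tables[o].loc[ids])
            for o, m in self.omics_models.items()
        }
        return pd.DataFrame(cols)[list(self.model.omics_order)]

    def predict(self, sample_ids: list[str] | None = None) -> pd.DataFrame:
        """Stacked probability and binary call at the calibrated threshold."""
        ids = sample_ids if sample_ids is not None else self.model.sample_ids
        if len(ids) == 0:
            return pd.DataFrame(columns=["probability", "call"])
        return self.stacked.predict(self.omics_probabilities(ids))

    # -- evaluation -------------------------------------------------------
    def evaluate(self, split: str = "validation", n_boot: int = 1000,
                 seed: int | None = None) -> dict:
        """Metric reports for the stack and each omics model on one split."""
        ids = self.model.validation_ids if split == "validation" else self.model.train_ids
        labels = self.model.labels.loc[ids].to_numpy()
        out = {}
        probs = self.omics_probabilities(ids)
        for omics, m in self.omics_models.items():
            out[omics] = evaluation.metric_report(probs[omics].to_numpy(), labels,
                                                  m.threshold, n_boot=n_boot, seed=seed)
        stacked_probs = self.stacked.predict_proba(probs).to_numpy()
        out["stacked"] = evaluation.metric_report(stacked_probs, labels,
                                                  self.stacked.threshold, n_boot=n_boot, seed=seed)
        return out

    def summary(self, split: str = "validation", n_boot: int = 200,
                seed: int = 0) -> pd.DataFrame:
        """One row per omics model plus the stack: family, CV AUC,
        threshold, and split AUC/sensitivity/specificity."""
        reports = self.evaluate(split, n_boot=n_boot, seed=seed)
        rows = []
        for omics in list(self.model.omics_order) + ["stacked"]:
            r = reports[omics]
            if omics == "stacked":
                family, cv_auc, n_feat = "random_forest (integrator)", np.nan, len(self.model.omics_order)
            else:
                m = self.omics_models[omics]
                family, cv_auc, n_feat = m.family, m.cv_auc, len(m.features)
            rows.append({
                "model": omics, "family": family, "n_features": n_feat,
                "cv_auc": cv_auc, "threshold": r.threshold,
                f"{split}_auc": r.auc, f"{split}_sensitivity": r.sensitivity,
                f"{split}_specificity": r.specificity,
            })
        return pd.DataFrame(rows).set_index("model")
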