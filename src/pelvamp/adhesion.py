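"""Per-location adhesion classification from organ shape features.

Adhesions pull and deform pelvic organs, which shows up in their shape
radiomics.  For each of seven inter-organ locations a gradient-boosted
decision-tree (LightGBM) binary classifier is trained on the 56-dimensional
shape vector, and evaluated by patient-grouped stratified 5-fold
cross-validation: all images of a patient stay in one fold, folds
approximately preserve the positive fraction, and recall / precision / F1
are computed from the pooled out-of-fold predictions with percentile
bootstrap confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.model_selection import GroupKFold, StratifiedGroupKFold

from .phantom import ADHESION_LOCATIONS, PhantomSample
from .shape_radiomics import FeatureVector56, feature_vector

__all__ = [
    "ADHESION_LOCATIONS",
    "DEFAULT_HYPERPARAMS",
    "DECISION_THRESHOLD",
    "AdhesionDataset",
    "CVMetrics",
    "build_dataset",
    "grouped_stratified_folds",
    "train_adhesion",
    "evaluate_cv",
    "predict_adhesions",
    "permutation_null_f1",
]

#: Small-data-safe gradient-boosting defaults.
DEFAULT_HYPERPARAMS = dict(
    n_estimators=200,
    max_depth=4,
    learning_rate=0.1,
    min_child_samples=10,
    n_jobs=1,
    verbosity=-1,
    deterministic=True,
)

#: Probability cut for a positive adhesion call.
DECISION_THRESHOLD = 0.5

_FEATURE_COLUMNS = FeatureVector56.column_names()
_LABEL_COLUMNS = [f"adhesion_{loc}" for loc in ADHESION_LOCATIONS]


@dataclass
class AdhesionDataset:
    """Feature rows (one per image), 7 binary labels, and patient grouping."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"patient_id", "image_id", *_FEATURE_COLUMNS, *_LABEL_COLUMNS}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"dataset table lacks columns: {sorted(missing)}")
        if self.table.duplicated(["patient_id", "image_id"]).any():
            raise ValueError("duplicate (patient, image) keys")
        for col in _LABEL_COLUMNS:
            if not self.table[col].isin([0, 1]).all():
                raise ValueError(f"labels in {col} must be binary")

    @property
    def features(self) -> pd.DataFrame:
        x = self.table[_FEATURE_COLUMNS].astype(float).copy()
        if x.isna().any().any():
            # Missing-organ imputation: per-column median, plus the
            # missingness itself is visible through the imputed constancy.
            x = x.fillna(x.median())
        return x

    def labels(self, location: str) -> np.ndarray:
        return self.table[f"adhesion_{location}"].to_numpy(dtype=int)

    @property
    def groups(self) -> np.ndarray:
        return self.table["patient_id"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class CVMetrics:
    location: str
    recall: float
    precision: float
    f1: float
    recall_ci: tuple[float, float]
    precision_ci: tuple[float, float]
    f1_ci: tuple[float, float]
    n_positive: int
    flags: tuple[str, ...] = ()


def build_dataset(cohort: Sequence[PhantomSample]) -> AdhesionDataset:
    """Extract the 56-dim shape vector of every sample into a dataset table."""
    rows = []
    for i, s in enumerate(cohort):
        fv = feature_vector(s.organ_mask)
        row = {"patient_id": s.patient_id, "image_id": f"{s.patient_id}_{i:04d}"}
        row.update(dict(zip(_FEATURE_COLUMNS, fv.values)))
        row.update({f"adhesion_{k}": int(v) for k, v in s.truth.adhesions.items()})
        rows.append(row)
    return AdhesionDataset(pd.DataFrame(rows))


def grouped_stratified_folds(
    ds: AdhesionDataset, k: int = 5, location: str = "uterus_rectum", seed: int = 0
) -> np.ndarray:
    """Fold index per row: patients never split, folds label-stratified.

    When stratification is unsatisfiable (e.g. a single class) the split
    falls back to grouped-only with a warning.
    """
    groups = ds.groups
    if len(np.unique(groups)) < k:
        raise ValueError(f"need at least {k} patients for {k} folds")
    y = ds.labels(location)
    folds = np.full(len(ds), -1, dtype=int)
    try:
        if len(np.unique(y)) < 2:
            raise ValueError("single-class labels")
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        for f, (_, test_idx) in enumerate(splitter.split(np.zeros(len(ds)), y, groups)):
            folds[test_idx] = f
    except ValueError as exc:
        warnings.warn(f"stratification unsatisfiable ({exc}); using grouped-only folds",
                      stacklevel=2)
        splitter = GroupKFold(n_splits=k)
        for f, (_, test_idx) in enumerate(splitter.split(np.zeros(len(ds)), y, groups)):
            folds[test_idx] = f
    assert (folds >= 0).all()
    return folds


def train_adhesion(
    ds: AdhesionDataset,
    location: str,
    hyperparams: dict | None = None,
    seed: int = 0,
    rows: np.ndarray | None = None,
) -> LGBMClassifier:
    """Fit the gradient-boosted classifier for one location (optionally on a row subset)."""
    x = ds.features
    y = ds.labels(location)
    if rows is not None:
        x, y = x.loc[rows], y[rows]
    if len(np.unique(y)) < 2:
        raise ValueError(f"training labels for {location} are single-class")
    params = dict(DEFAULT_HYPERPARAMS, **(hyperparams or {}), random_state=seed)
    clf = LGBMClassifier(**params)
    clf.fit(x, y)
    return clf


def _prf(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float, list[str]]:
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    flags = []
    recall = tp / (tp + fn) if tp + fn else 0.0
    if tp + fn == 0:
        flags.append("recall_undefined_no_positives")
    precision = tp / (tp + fp) if tp + fp else 0.0
    if tp + fp == 0:
        flags.append("precision_undefined_no_predicted_positives")
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return recall, precision, f1, flags


def evaluate_cv(
    ds: AdhesionDataset,
    location: str,
    k: int = 5,
    seed: int = 0,
    hyperparams: dict | None = None,
    n_bootstrap: int = 2000,
) -> CVMetrics:
    """Pooled out-of-fold recall / precision / F1 with bootstrap 95% CIs.

    Predictions are thresholded at 0.5.  Confidence intervals are percentile
    bootstrap over the pooled out-of-fold (truth, prediction) pairs.
    """
    folds = grouped_stratified_folds(ds, k, location, seed)
    y = ds.labels(location)
    oof = np.zeros(len(ds))
    for f in range(k):
        test = folds == f
        clf = train_adhesion(ds, location, hyperparams, seed=seed + f, rows=~test)
        oof[test] = clf.predict_proba(ds.features.loc[test])[:, 1]
    y_pred = (oof >= DECISION_THRESHOLD).astype(int)
    recall, precision, f1, flags = _prf(y, y_pred)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_bootstrap, 3))
    n = len(y)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        boots[b] = _prf(y[idx], y_pred[idx])[:3]
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)

    pos_patients = ds.table.loc[y == 1, "patient_id"].nunique()
    return CVMetrics(
        location=location,
        recall=recall, precision=precision, f1=f1,
        recall_ci=(float(lo[0]), float(hi[0])),
        precision_ci=(float(lo[1]), float(hi[1])),
        f1_ci=(float(lo[2]), float(hi[2])),
        n_positive=int(pos_patients),
        flags=tuple(flags),
    )


def predict_adhesions(
    classifiers: dict[str, LGBMClassifier], fv: FeatureVector56
) -> pd.DataFrame:
    """Probabilities and thresholded calls for all 7 locations, fixed order."""
    missing = [loc for loc in ADHESION_LOCATIONS if loc not in classifiers]
    if missing:
        raise ValueError(f"classifiers missing for locations: {missing}")
    values = np.nan_to_num(np.asarray(fv.values, dtype=float), nan=0.0)
    x = pd.DataFrame([values], columns=_FEATURE_COLUMNS)
    rows = []
    for loc in ADHESION_LOCATIONS:
        prob = float(classifiers[loc].predict_proba(x)[0, 1])
        rows.append({"location": loc, "probability": prob,
                     "call": int(prob >= DECISION_THRESHOLD)})
    return pd.DataFrame(rows)


def permutation_null_f1(
    ds: AdhesionDataset,
    location: str,
    n_permutations: int = 100,
    k: int = 5,
    seed: int = 0,
    hyperparams: dict | None = None,
) -> np.ndarray:
    """Null distribution of CV F1 under patient-level label shuffling.

    Labels are permuted across patients (keeping each patient's images
    consistent), the full grouped CV is re-run, and the pooled F1 recorded.
    """
    rng = np.random.default_rng(seed)
    patients = ds.table["patient_id"].to_numpy()
    uniq = pd.unique(patients)
    patient_label = {
        p: int(ds.table.loc[patients == p, f"adhesion_{location}"].iloc[0]) for p in uniq
    }
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation([patient_label[p] for p in uniq])
        shuffled = dict(zip(uniq, perm))
        tbl = ds.table.copy()
        tbl[f"adhesion_{location}"] = [shuffled[p] for p in patients]
        ds_i = AdhesionDataset(tbl)
        try:
            null[i] = evaluate_cv(ds_i, location, k=k, seed=seed + i,
                                  hyperparams=hyperparams, n_bootstrap=1).f1
        except ValueError:  # a permutation may produce single-class folds
            null[i] = np.nan
    return null
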