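"""Leakage-safe random-forest classification of threatened status.

Features come in three tagged groups: 13 genome-wide summary statistics,
ecological variables (PanTHERIA-style), and per-window genomic metrics.
The evaluation protocol: stratified 75/25 train/test split; imputation
statistics (median for numeric cells) computed on the training rows only
and applied to the held-out set; 5-fold cross-validated grid search over
number of trees, maximum depth, and features-per-split; AUROC on the
untouched test set. Data-deficient (unlabeled) species receive forest
vote fractions as threat probabilities, and are refused — not silently
imputed — when a model's required feature group is wholly missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline

from .errors import InsufficientDataError, InvalidParameterError

MIN_LABELED_SPECIES = 40

DEFAULT_GRID = {
    "rf__n_estimators": [100, 300, 500],
    "rf__max_depth": [3, 5, 10, None],
    "rf__max_features": ["sqrt", 0.3, 0.5],
}

SMALL_GRID = {
    "rf__n_estimators": [100],
    "rf__max_depth": [3, None],
    "rf__max_features": ["sqrt"],
}


@dataclass(frozen=True)
class FeatureMatrix:
    """Species x features with disjoint group tags and optional labels.

    ``labels`` is a boolean Series (True = threatened) with NaN for
    data-deficient species. ``groups`` maps each column to exactly one of
    {"summary", "ecological", "windows"}.
    """

    data: pd.DataFrame
    groups: dict[str, str]
    labels: pd.Series

    def __post_init__(self) -> None:
        missing = set(self.data.columns) - set(self.groups)
        if missing:
            raise InvalidParameterError(f"untagged feature columns: {sorted(missing)}")
        bad = set(self.groups.values()) - {"summary", "ecological", "windows"}
        if bad:
            raise InvalidParameterError(f"unknown group tags: {sorted(bad)}")

    def columns_for(self, group_set: tuple[str, ...] | list[str]) -> list[str]:
        cols = [c for c in self.data.columns if self.groups[c] in set(group_set)]
        if not cols:
            raise InvalidParameterError(f"no feature columns for groups {group_set}")
        return cols

    def labeled(self) -> "FeatureMatrix":
        keep = self.labels.notna()
        return FeatureMatrix(self.data.loc[keep], self.groups, self.labels.loc[keep])


@dataclass(frozen=True)
class EvalReport:
    auroc: float
    importances: pd.Series
    best_params: dict
    split_seed: int
    group_set: tuple[str, ...]
    n_train: int
    n_test: int


@dataclass(frozen=True)
class TrainedModel:
    pipeline: Pipeline
    feature_columns: tuple[str, ...]
    group_set: tuple[str, ...]
    report: EvalReport


def build_feature_matrix(
    summaries: pd.DataFrame,
    labels: pd.Series,
    ecological: pd.DataFrame | None = None,
    windows: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Join tagged feature groups on the species index.

    ``summaries`` is required (index = species); ecological and window
    tables are optional and may cover a subset of species (others keep
    that group missing). A species in an optional table that is absent
    from the summaries is an error; duplicated species are an error.
    """
    for name, df in (("summaries", summaries), ("ecological", ecological), ("windows", windows)):
        if df is not None and df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise InvalidParameterError(f"duplicate species in {name}: {dup}")
    data = summaries.copy()
    groups = {c: "summary" for c in summaries.columns}
    for name, df in (("ecological", ecological), ("windows", windows)):
        if df is None:
            continue
        extra = df.index.difference(summaries.index)
        if len(extra):
            raise InvalidParameterError(
                f"{name} table contains unknown species: {list(extra[:3])}")
        aligned = df.reindex(summaries.index)
        data = pd.concat([data, aligned], axis=1)
        tag = "ecological" if name == "ecological" else "windows"
        groups.update({c: tag for c in df.columns})
    lab = labels.reindex(summaries.index)
    return FeatureMatrix(data=data, groups=groups, labels=lab.astype(object))


def variance_filter(fm: FeatureMatrix, group: str = "windows", top_k: int = 500) -> FeatureMatrix:
    """Keep the ``top_k`` highest-variance columns of a group.

    Guards against numerous weakly informative window features
    overwhelming the forest.
    """
    cols = [c for c in fm.data.columns if fm.groups[c] == group]
    if len(cols) <= top_k:
        return fm
    v = fm.data[cols].var(axis=0)
    drop = v.sort_values(ascending=False).index[top_k:]
    data = fm.data.drop(columns=list(drop))
    groups = {c: g for c, g in fm.groups.items() if c not in set(drop)}
    return FeatureMatrix(data=data, groups=groups, labels=fm.labels)


def _rf_pipeline(seed: int) -> Pipeline:
    return Pipeline([
        ("impute", SimpleImputer(strategy="median")),
        ("rf", RandomForestClassifier(random_state=seed)),
    ])


def train_rf(
    features: FeatureMatrix,
    group_set: tuple[str, ...] = ("summary",),
    seed: int = 0,
    grid: dict | None = None,
    test_size: float = 0.25,
    split: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrainedModel:
    """Train and evaluate the random-forest protocol on one feature-group set.

    Stratified 75/25 split (or a caller-supplied ``split`` of index
    arrays), imputation fitted on training rows only, grid search by
    5-fold CV maximizing AUROC, refit on the full training set, AUROC on
    the untouched test set.
    """
    fm = features.labeled()
    y = fm.labels.astype(bool).to_numpy()
    if len(y) < MIN_LABELED_SPECIES:
        raise InsufficientDataError(
            f"need >= {MIN_LABELED_SPECIES} labeled species, got {len(y)}")
    if len(np.unique(y)) < 2:
        raise InvalidParameterError("labels are single-class; AUROC undefined")
    cols = fm.columns_for(group_set)
    x = fm.data[cols].to_numpy(dtype=float)
    if split is None:
        idx = np.arange(len(y))
        tr, te = train_test_split(idx, test_size=test_size, stratify=y, random_state=seed)
    else:
        tr, te = split
    grid = grid or DEFAULT_GRID
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    search = GridSearchCV(_rf_pipeline(seed), grid, scoring="roc_auc", cv=cv, n_jobs=1)
    search.fit(x[tr], y[tr])
    model = search.best_estimator_  # refit on full training set by GridSearchCV
    proba = model.predict_proba(x[te])[:, list(model.classes_).index(True)]
    auroc = float(roc_auc_score(y[te], proba))
    imps = pd.Series(model.named_steps["rf"].feature_importances_, index=cols)
    report = EvalReport(
        auroc=auroc, importances=imps.sort_values(ascending=False),
        best_params={k.replace("rf__", ""): v for k, v in search.best_params_.items()},
        split_seed=seed, group_set=tuple(group_set),
        n_train=len(tr), n_test=len(te),
    )
    return TrainedModel(pipeline=model, feature_columns=tuple(cols),
                        group_set=tuple(group_set), report=report)


def compare_feature_sets(
    features: FeatureMatrix,
    seed: int = 0,
    group_sets: tuple[tuple[str, ...], ...] | None = None,
    grid: dict | None = None,
) -> pd.DataFrame:
    """AUROC of several feature-group sets on the common species subset.

    Restricted to labeled species with at least one non-missing value in
    every group involved; all models share one stratified split so the
    comparison is apples-to-apples.
    """
    if group_sets is None:
        present = sorted(set(features.groups.values()))
        group_sets = tuple((g,) for g in present)
        if "summary" in present and "ecological" in present:
            group_sets += (("summary", "ecological"),)
    involved = sorted({g for gs in group_sets for g in gs})
    fm = features.labeled()
    keep = pd.Series(True, index=fm.data.index)
    for g in involved:
        cols = [c for c in fm.data.columns if fm.groups[c] == g]
        keep &= fm.data[cols].notna().any(axis=1)
    if not keep.any():
        raise InsufficientDataError("no species carries every requested feature group")
    common = FeatureMatrix(fm.data.loc[keep], fm.groups, fm.labels.loc[keep])
    y = common.labels.astype(bool).to_numpy()
    idx = np.arange(len(y))
    tr, te = train_test_split(idx, test_size=0.25, stratify=y, random_state=seed)
    rows = []
    for gs in group_sets:
        tm = train_rf(common, group_set=gs, seed=seed, grid=grid, split=(tr, te))
        rows.append({"group_set": "+".join(gs), "auroc": tm.report.auroc,
                     "n_species": len(y), "n_features": len(tm.feature_columns)})
    return pd.DataFrame(rows).sort_values("auroc", ascending=False).reset_index(drop=True)


def predict_unlabeled(
    model: TrainedModel,
    features: FeatureMatrix,
) -> tuple[pd.Series, dict[str, str]]:
    """Threat probability (forest vote fraction) for data-deficient species.

    Species for which an entire group required by the model is missing
    are refused with an explanatory message rather than imputed
    wholesale. Returns (probabilities, refusals).
    """
    dd = features.data.loc[features.labels.isna()]
    if dd.empty:
        raise InvalidParameterError("no unlabeled (data-deficient) species present")
    probs = {}
    refusals = {}
    group_cols = {
        g: [c for c in model.feature_columns if features.groups.get(c) == g]
        for g in model.group_set
    }
    for sp, row in dd.iterrows():
        missing_groups = [g for g, cols in group_cols.items()
                          if cols and row[cols].isna().all()]
        if missing_groups:
            refusals[sp] = (
                f"feature group(s) {missing_groups} entirely missing; "
                "prediction refused rather than imputed")
            continue
        x = row[list(model.feature_columns)].to_numpy(dtype=float)[None, :]
        p = model.pipeline.predict_proba(x)[0]
        probs[sp] = float(p[list(model.pipeline.classes_).index(True)])
    return pd.Series(probs, dtype=float), refusals
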