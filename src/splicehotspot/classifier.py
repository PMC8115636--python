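"""Gradient-boosted classification of splice-disrupting variants.

The learner itself is an off-the-shelf gradient-boosting (or random-forest)
implementation; what this module contributes is the seeded 70/30 protocol,
training-median imputation with missingness indicators, the model manifest,
and the feature-group ablation — retraining with one group left out and
with one group kept at a time, on an identical split, to rank the groups'
contributions.

Hyperparameter defaults: 1000 trees, learning rate 0.05, interaction depth
3, bag fraction 0.5, minimum 10 observations per node, 3 cross-validation
folds, 70% of variants for training, score cutoff 0.5 (strict).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .features import FeatureTable

SCORE_CUTOFF = 0.5


@dataclass
class ClassifierConfig:
    n_trees: int = 1000
    learning_rate: float = 0.05
    interaction_depth: int = 3
    bag_fraction: float = 0.5
    min_node_obs: int = 10
    cv_folds: int = 3
    train_fraction: float = 0.70
    score_cutoff: float = SCORE_CUTOFF
    seed: int = 0
    learner: str = "gbm"  # "gbm" | "rf"

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if not 0.0 < self.score_cutoff < 1.0:
            raise ValueError("score_cutoff must be in (0, 1)")

    def make_learner(self):
        if self.learner == "gbm":
            return GradientBoostingClassifier(
                n_estimators=self.n_trees,
                learning_rate=self.learning_rate,
                max_depth=self.interaction_depth,
                subsample=self.bag_fraction,
                min_samples_leaf=self.min_node_obs,
                random_state=self.seed,
            )
        if self.learner == "rf":
            return RandomForestClassifier(
                n_estimators=self.n_trees, random_state=self.seed
            )
        raise ValueError(f"unknown learner {self.learner!r}")


@dataclass
class TrainedModel:
    model: object
    feature_names: list[str]
    manifest: dict
    heldout_auc: float
    cv_auc: float

    def save_manifest(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest, fh, indent=1)


def _impute(frame: pd.DataFrame, medians: pd.Series | None = None,
            add_indicators: bool = True):
    """Training-median imputation with missingness indicator columns."""
    out = frame.copy()
    if medians is None:
        medians = out.median()
    indicator_cols = {}
    if add_indicators:
        for c in frame.columns:
            if frame[c].isna().any():
                indicator_cols[f"{c}_missing"] = frame[c].isna().astype(float)
    out = out.fillna(medians)
    out = out.fillna(0.0)  # all-missing training column: median undefined
    for name, col in indicator_cols.items():
        out[name] = col
    return out, medians


def _split(n: int, labels: np.ndarray, config: ClassifierConfig):
    idx = np.arange(n)
    train, test = train_test_split(
        idx, train_size=config.train_fraction, random_state=config.seed,
        stratify=labels,
    )
    return train, test


def _fit_and_score(frame: pd.DataFrame, labels: np.ndarray,
                   config: ClassifierConfig, train, test,
                   with_cv: bool = True):
    x_train, medians = _impute(frame.iloc[train])
    x_test, _ = _impute(frame.iloc[test], medians)
    x_test = x_test.reindex(columns=x_train.columns, fill_value=0.0)
    model = config.make_learner()
    model.fit(x_train.to_numpy(), labels[train])
    scores = model.predict_proba(x_test.to_numpy())[:, 1]
    heldout = float(roc_auc_score(labels[test], scores))
    cv_auc = float("nan")
    if with_cv:
        aucs = []
        skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                              random_state=config.seed)
        for tr, te in skf.split(x_train, labels[train]):
            m = config.make_learner()
            m.fit(x_train.to_numpy()[tr], labels[train][tr])
            s = m.predict_proba(x_train.to_numpy()[te])[:, 1]
            aucs.append(roc_auc_score(labels[train][te], s))
        cv_auc = float(np.mean(aucs))
    return model, medians, x_train.columns.tolist(), heldout, cv_auc


def train(table: FeatureTable, labels: pd.Series | np.ndarray,
          config: ClassifierConfig | None = None) -> TrainedModel:
    """Seeded 70/30 fit; reports held-out ROC AUC and cross-validated AUC."""
    config = config or ClassifierConfig()
    config.validate()
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present in the labels")
    train_idx, test_idx = _split(len(labels), labels, config)
    model, medians, columns, heldout, cv_auc = _fit_and_score(
        table.frame, labels, config, train_idx, test_idx
    )
    manifest = {
        "learner": config.learner,
        "config": asdict(config),
        "feature_names": columns,
        "feature_groups": {
            c: table.groups.get(c.removesuffix("_missing"), "derived")
            for c in columns
        },
        "imputation_medians": {
            k: (None if pd.isna(v) else float(v))
            for k, v in medians.items()
        },
        "structure_plugin": any(
            g == "mutation" and c.startswith("hyb")
            for c, g in table.groups.items()
        ),
        "heldout_auc": heldout,
        "cv_auc": cv_auc,
        "seed": config.seed,
    }
    return TrainedModel(model, columns, manifest, heldout, cv_auc)


def call_splice_altering(scores, cutoff: float = SCORE_CUTOFF):
    """The variant-call rule: splice-altering iff score strictly above the
    cutoff (a score exactly at the cutoff is a no-effect call)."""
    return np.asarray(scores) > cutoff


def predict(model: TrainedModel, table: FeatureTable,
            cutoff: float = SCORE_CUTOFF) -> pd.DataFrame:
    """Scores in [0, 1]; splice-altering iff score strictly above cutoff."""
    medians = pd.Series(
        {k: (np.nan if v is None else v)
         for k, v in model.manifest["imputation_medians"].items()}
    )
    x, _ = _impute(table.frame, medians)
    x = x.reindex(columns=model.feature_names, fill_value=0.0)
    scores = model.model.predict_proba(x.to_numpy())[:, 1]
    return pd.DataFrame(
        {
            "variant_id": table.frame.index,
            "score": scores,
            "call": call_splice_altering(scores, cutoff),
        }
    ).reset_index(drop=True)


def ablation(table: FeatureTable, labels: pd.Series | np.ndarray,
             config: ClassifierConfig | None = None) -> pd.DataFrame:
    """Leave-one-group-out and single-group AUCs on one identical split.

    Returns a frame with columns variant_set ("full" | "without_<g>" |
    "only_<g>"), group, and heldout_auc.  Groups with no features are
    skipped with a warning.
    """
    config = config or ClassifierConfig()
    config.validate()
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present in the labels")
    train_idx, test_idx = _split(len(labels), labels, config)
    groups = sorted(set(table.groups.values()))
    results = []

    def run(name: str, group: str | None, columns: list[str]) -> None:
        _, _, _, auc, _ = _fit_and_score(
            table.frame[columns], labels, config, train_idx, test_idx,
            with_cv=False,
        )
        results.append((name, group, auc))

    run("full", None, list(table.frame.columns))
    for g in groups:
        cols = table.features_in_group(g)
        if not cols:
            warnings.warn(f"feature group {g!r} has no features; skipped")
            continue
        rest = [c for c in table.frame.columns if c not in cols]
        if rest:
            run(f"without_{g}", g, rest)
        run(f"only_{g}", g, cols)
    return pd.DataFrame(results, columns=["variant_set", "group", "heldout_auc"])
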