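"""Random-Forests meta-classifier over base-classifier scores (stacking).

The merger takes the per-pair scores of the base classifiers as its feature
vector and trains a Random Forest to emit the final interaction
probability. Nine variants are defined by crossing the classifier family
category (GO family only, profile family only, or both combined) with the
training-network subcategory (SC, cross species, all species); each
variant's feature list is the corresponding slice of the canonical grid.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .classifier_grid import (
    CATEGORIES,
    FAMILIES,
    GO_FAMILY,
    PHYLO_FAMILY,
    ScoreTable,
    enumerate_grid,
    filter_category,
)

META_CATEGORIES = (GO_FAMILY, PHYLO_FAMILY, "combined")
MODEL_FORMAT_VERSION = 1


def category_families(category: str) -> tuple[str, ...]:
    if category == "combined":
        return FAMILIES
    if category in (GO_FAMILY, PHYLO_FAMILY):
        return (category,)
    raise ValueError(f"unknown category {category!r}; choose from {META_CATEGORIES}")


def variant_feature_ids(category: str, subcategory: str) -> list[str]:
    """Canonical feature (classifier) ids for one ensemble variant."""
    specs = filter_category(enumerate_grid(category_families(category)), subcategory)
    return [s.id for s in specs]


@dataclass
class PPCMModel:
    """A fitted stacking model for one (category, subcategory) variant."""

    category: str
    subcategory: str
    feature_ids: list[str]
    n_trees: int
    seed: int
    forest: RandomForestClassifier = field(repr=False)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)


def train_ppcm(
    train_table: ScoreTable,
    labels: Sequence[int],
    category: str,
    subcategory: str,
    seed: int = 0,
    n_trees: int = 500,
) -> PPCMModel:
    """Fit the meta-forest on a training score table.

    The feature columns are selected from the table by classifier id in
    canonical grid order, so the table may contain extra columns and its
    column order is irrelevant. Deterministic for a given seed.
    """
    if subcategory not in CATEGORIES:
        raise ValueError(f"unknown subcategory {subcategory!r}")
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(train_table.pairs):
        raise ValueError("labels must align with the table rows")
    if labels.min() == labels.max():
        raise ValueError("training labels contain a single class")
    feature_ids = variant_feature_ids(category, subcategory)
    X = train_table.select_columns(feature_ids)
    use_oob = n_trees >= 50 and len(labels) >= 20
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=use_oob,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, labels)
    return PPCMModel(
        category=category,
        subcategory=subcategory,
        feature_ids=feature_ids,
        n_trees=n_trees,
        seed=seed,
        forest=forest,
    )


def predict_ppcm(model: PPCMModel, table: ScoreTable) -> np.ndarray:
    """Final interaction probability for every pair in the table.

    Columns are matched by classifier id, so any column order (or presence
    of extra columns) yields identical scores.
    """
    X = table.select_columns(model.feature_ids)
    return model.forest.predict_proba(X)[:, 1]


def save_model(model: PPCMModel, path: str | Path) -> None:
    """Persist a fitted model to a versioned pickle archive."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "category": model.category,
        "subcategory": model.subcategory,
        "feature_ids": model.feature_ids,
        "n_trees": model.n_trees,
        "seed": model.seed,
        "forest": model.forest,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path: str | Path) -> PPCMModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model archive version {version!r}")
    return PPCMModel(
        category=payload["category"],
        subcategory=payload["subcategory"],
        feature_ids=payload["feature_ids"],
        n_trees=payload["n_trees"],
        seed=payload["seed"],
        forest=payload["forest"],
    )
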