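"""Enumeration and execution of the base-classifier grid.

The ensemble's feature space is a fixed grid of base classifiers:

* phylogenetic-profile family: 3 scoring methods (pp, mi, hg) x 8
  reference-taxa optimisation strategies x 4 training networks
  (E. coli EC, S. cerevisiae SC, D. melanogaster DM, A. thaliana AT)
  = 96 classifiers;
* GO-annotation family: 2 learners (nb, rf) x 7 aspect combinations x 7
  training networks (HS, MM, SP, SC, AT, EC, DM) = 98 classifiers;

194 in total. Classifiers are further split by training network into the
target-species subcategory (SC), the cross-species subcategory (every
network except SC) and all species. ``build_score_table`` runs each
classifier on a pair list and assembles the pairs x classifiers score
matrix that the meta-learner consumes, with deterministic column order and
zero-imputed, masked entries wherever a pair cannot be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from hashlib import sha256
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import go_features, phylo_profiles
from .go_features import ASPECT_COMBOS, GOAnnotationMap
from .gold_standard import ProteinPair
from .phylo_profiles import TAXA_STRATEGIES, PhyloProfileMatrix

PHYLO_FAMILY = "phyloprof"
GO_FAMILY = "go2ppi"
FAMILIES = (PHYLO_FAMILY, GO_FAMILY)

PHYLO_METHODS = ("pp", "mi", "hg")
PHYLO_TAXA_STRATEGIES = tuple(TAXA_STRATEGIES)  # registry order, 8 entries
PHYLO_NETWORKS = ("EC", "SC", "DM", "AT")

GO_LEARNERS = ("nb", "rf")
GO_NETWORKS = ("HS", "MM", "SP", "SC", "AT", "EC", "DM")

TARGET_NETWORK = "SC"
CATEGORIES = ("SC", "cross", "all")


@dataclass(frozen=True)
class ClassifierSpec:
    """One cell of the classifier grid.

    ``option`` is a taxa-strategy name for the profile family and an aspect
    combo for the GO family; ``network`` is the species whose interaction
    network trains/calibrates the classifier.
    """

    family: str
    method: str
    option: str
    network: str

    def __post_init__(self) -> None:
        if self.family == PHYLO_FAMILY:
            ok = (self.method in PHYLO_METHODS
                  and self.option in PHYLO_TAXA_STRATEGIES
                  and self.network in PHYLO_NETWORKS)
        elif self.family == GO_FAMILY:
            ok = (self.method in GO_LEARNERS
                  and self.option in ASPECT_COMBOS
                  and self.network in GO_NETWORKS)
        else:
            raise ValueError(f"unknown family {self.family!r}")
        if not ok:
            raise ValueError(f"invalid spec fields for family {self.family!r}: "
                             f"{self.method}|{self.option}|{self.network}")

    @property
    def id(self) -> str:
        return f"{self.family}|{self.method}|{self.option}|{self.network}"


def enumerate_grid(families: Sequence[str] = FAMILIES) -> list[ClassifierSpec]:
    """All classifier specs for the requested families, in canonical order.

    Order is family (profile family first), then method, then option, then
    network, each in registry order — fixed so score-table columns are
    reproducible.
    """
    families = tuple(families)
    unknown = set(families) - set(FAMILIES)
    if unknown:
        raise ValueError(f"unknown families {sorted(unknown)}")
    specs: list[ClassifierSpec] = []
    for family in FAMILIES:
        if family not in families:
            continue
        if family == PHYLO_FAMILY:
            methods, options, networks = PHYLO_METHODS, PHYLO_TAXA_STRATEGIES, PHYLO_NETWORKS
        else:
            methods, options, networks = GO_LEARNERS, ASPECT_COMBOS, GO_NETWORKS
        for method in methods:
            for option in options:
                for network in networks:
                    specs.append(ClassifierSpec(family, method, option, network))
    return specs


def filter_category(specs: Sequence[ClassifierSpec], category: str) -> list[ClassifierSpec]:
    """Subset a grid by training-network subcategory: SC, cross or all."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}; choose from {CATEGORIES}")
    if category == "all":
        return list(specs)
    if category == "SC":
        return [s for s in specs if s.network == TARGET_NETWORK]
    return [s for s in specs if s.network != TARGET_NETWORK]


# ---------------------------------------------------------------------------
# score-table construction
# ---------------------------------------------------------------------------

@dataclass
class SpeciesData:
    """Per-species inputs: profiles, annotations and a labelled pair set."""

    species: str
    profiles: PhyloProfileMatrix | None = None
    annotations: GOAnnotationMap | None = None
    training_pairs: list[ProteinPair] = field(default_factory=list)


@dataclass
class DataBundle:
    """All species' data plus the identity of the target species."""

    species: dict[str, SpeciesData]
    target_species: str = TARGET_NETWORK

    @property
    def target(self) -> SpeciesData:
        return self.species[self.target_species]


@dataclass
class ScoreTable:
    """Pairs x classifiers score matrix with a missing-value mask."""

    pairs: list[ProteinPair]
    columns: list[str]
    scores: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        expected = (len(self.pairs), len(self.columns))
        if self.scores.shape != expected or self.mask.shape != expected:
            raise ValueError("score/mask shape mismatch")
        if np.isnan(self.scores).any():
            raise ValueError("score table contains NaN after imputation")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("duplicate column ids")

    def column(self, column_id: str) -> np.ndarray:
        try:
            return self.scores[:, self.columns.index(column_id)]
        except ValueError:
            raise KeyError(f"no column {column_id!r}") from None

    def select_columns(self, column_ids: Sequence[str]) -> np.ndarray:
        idx = []
        for cid in column_ids:
            if cid not in self.columns:
                raise KeyError(f"score table lacks column {cid!r}")
            idx.append(self.columns.index(cid))
        return self.scores[:, idx]

    def subset_rows(self, indices: Sequence[int]) -> "ScoreTable":
        idx = np.asarray(indices, dtype=int)
        return ScoreTable(
            pairs=[self.pairs[i] for i in idx],
            columns=list(self.columns),
            scores=self.scores[idx],
            mask=self.mask[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=self.columns)
        df.insert(0, "pair_id", [f"{p.a}--{p.b}" for p in self.pairs])
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def _spec_seed(base_seed: int, spec_id: str) -> int:
    """Stable per-spec seed: independent of column order, below 2**31."""
    h = int.from_bytes(sha256(spec_id.encode()).digest()[:4], "big")
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(h,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _network_training_pairs(bundle: DataBundle, network: str,
                            target_train: Sequence[ProteinPair] | None):
    if network == bundle.target_species:
        if target_train is not None:
            return list(target_train)
    if network not in bundle.species:
        raise ValueError(f"bundle lacks data for network {network!r}")
    return list(bundle.species[network].training_pairs)


def _phylo_columns_for_group(specs, pairs, bundle, target_train, base_seed):
    """Score all methods of one (taxa strategy, network) group.

    The taxa selection is calibrated once on the source network and shared
    by the pp/mi/hg scorers of the group; scoring uses the target-species
    profile rows restricted to the selected taxa.
    """
    option, network = specs[0].option, specs[0].network
    source = bundle.species.get(network)
    if source is None or source.profiles is None:
        raise ValueError(f"bundle lacks profile data for network {network!r}")
    target_matrix = bundle.target.profiles
    if target_matrix is None:
        raise ValueError("bundle lacks a target-species profile matrix")
    train_pairs = _network_training_pairs(bundle, network, target_train)
    _, supervised = TAXA_STRATEGIES[option]
    selection = phylo_profiles.select_taxa(
        source.profiles, option, seed=_spec_seed(base_seed, f"taxa|{option}|{network}"),
        training_pairs=train_pairs if supervised else None,
    )
    taxa = [t for t in selection.selected if t in target_matrix._taxon_index]
    if not taxa:
        raise ValueError(
            f"no selected taxon of network {network!r} exists in the target matrix"
        )
    scorable = [i for i, p in enumerate(pairs)
                if p.a in target_matrix and p.b in target_matrix]
    scorable_set = set(scorable)
    missing = [i for i in range(len(pairs)) if i not in scorable_set]
    sub = [pairs[i] for i in scorable]
    out = {}
    for spec in specs:
        scores = np.zeros(len(pairs), dtype=float)
        mask = np.zeros(len(pairs), dtype=bool)
        if scorable:
            scores[scorable] = phylo_profiles.score_pairs(
                target_matrix, sub, spec.method, taxa)
        if missing:
            mask[missing] = True
        out[spec.id] = (scores, mask)
    return out


def _go_columns_for_group(specs, pairs, bundle, target_train, base_seed, n_trees):
    """Score all learners of one (combo, network) group; features are shared."""
    combo, network = specs[0].option, specs[0].network
    source = bundle.species.get(network)
    if source is None or source.annotations is None:
        raise ValueError(f"bundle lacks GO annotations for network {network!r}")
    target_ann = bundle.target.annotations
    if target_ann is None:
        raise ValueError("bundle lacks target-species GO annotations")
    train_pairs = _network_training_pairs(bundle, network, target_train)
    if not train_pairs:
        raise ValueError(f"no labelled training pairs for network {network!r}")
    y = np.array([1 if p.label == "positive" else 0 for p in train_pairs])
    X_train = go_features.feature_matrix(source.annotations, train_pairs, combo)
    X_pairs = go_features.feature_matrix(target_ann, pairs, combo)
    is_target = network == bundle.target_species
    train_key = {p.key(): i for i, p in enumerate(train_pairs)} if is_target else {}
    out = {}
    for spec in specs:
        seed = _spec_seed(base_seed, spec.id)
        if is_target:
            model, oof, _ = go_features.fit_with_oof(
                X_train, y, spec.method, seed, n_trees=n_trees)
            scores = model.score(X_pairs)
            # pairs inside the learner's own training set take their
            # out-of-fold score so stacking never sees in-fold leakage
            for i, p in enumerate(pairs):
                j = train_key.get(p.key())
                if j is not None:
                    scores[i] = oof[j]
        else:
            model = go_features.train_base_learner(
                X_train, y, spec.method, seed, n_trees=n_trees)
            scores = model.score(X_pairs)
        out[spec.id] = (scores, np.zeros(len(pairs), dtype=bool))
    return out


def build_score_table(
    specs: Sequence[ClassifierSpec],
    pairs: Sequence[ProteinPair],
    bundle: DataBundle,
    seed: int = 0,
    target_train: Sequence[ProteinPair] | None = None,
    rf_trees: int = go_features.RF_DEFAULT_TREES,
) -> ScoreTable:
    """Run every classifier in ``specs`` over ``pairs``.

    ``target_train`` supplies the labelled pairs used for supervised
    calibration on the target network (taxa selection and GO learners); when
    omitted, the bundle's own target-species training pairs are used. Pairs
    whose proteins are absent from a profile matrix get a zero score with
    the mask bit set for that column. Deterministic for a given seed, with
    per-classifier seeds independent of column order.
    """
    pairs = list(pairs)
    ids = [s.id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate classifier specs")
    scores = np.zeros((len(pairs), len(specs)), dtype=float)
    mask = np.zeros((len(pairs), len(specs)), dtype=bool)
    col_of = {cid: j for j, cid in enumerate(ids)}

    go_groups: dict[tuple[str, str], list[ClassifierSpec]] = {}
    phylo_groups: dict[tuple[str, str], list[ClassifierSpec]] = {}
    for spec in specs:
        groups = go_groups if spec.family == GO_FAMILY else phylo_groups
        groups.setdefault((spec.option, spec.network), []).append(spec)
    results: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for group in phylo_groups.values():
        results.update(_phylo_columns_for_group(group, pairs, bundle, target_train, seed))
    for group in go_groups.values():
        results.update(_go_columns_for_group(group, pairs, bundle, target_train, seed, rf_trees))
    for cid, (col_scores, col_mask) in results.items():
        j = col_of[cid]
        scores[:, j], mask[:, j] = col_scores, col_mask
    return ScoreTable(pairs=pairs, columns=ids, scores=scores, mask=mask)
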