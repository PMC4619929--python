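"""GO-annotation base classifiers.

Each protein carries sets of Gene Ontology terms in the three aspects —
biological process (BP), cellular component (CC), molecular function (MF).
For a candidate pair, simple set-overlap features are computed per aspect
(shared-term count, Jaccard index, union size, overlap ratio), concatenated
over one of the seven admissible aspect combinations (BP, CC, MF, BPCC,
BPMF, CCMF, BPCCMF), and fed to a trainable base learner: Gaussian Naive
Bayes or a Random Forest. Because the GO vocabulary is shared across
organisms, a learner trained on one species' interaction network can score
pairs of another species through the identical feature definitions — the
basis of the cross-species classifiers in the grid.

When the pairs to be scored overlap the learner's own training set, the
training-pair scores are produced out-of-fold (5-fold stratified CV) so that
downstream stacking never sees a leaked in-fold prediction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB

from .gold_standard import ProteinPair

ASPECTS = ("BP", "CC", "MF")
ASPECT_COMBOS = ("BP", "CC", "MF", "BPCC", "BPMF", "CCMF", "BPCCMF")
_GAF_ASPECT = {"P": "BP", "C": "CC", "F": "MF"}
_GO_ID = re.compile(r"^GO:\d{7}$")


def combo_aspects(combo: str) -> tuple[str, ...]:
    """Aspects of a combo name, in fixed BP, CC, MF order."""
    if combo not in ASPECT_COMBOS:
        raise ValueError(f"unknown aspect combo {combo!r}; admissible: {ASPECT_COMBOS}")
    return tuple(a for a in ASPECTS if a in combo)


@dataclass
class GOAnnotationMap:
    """Per-protein GO term sets split by aspect."""

    annotations: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)

    def terms(self, protein: str, aspect: str) -> frozenset[str]:
        if aspect not in ASPECTS:
            raise ValueError(f"unknown aspect {aspect!r}")
        return self.annotations.get(protein, {}).get(aspect, frozenset())

    def proteins(self) -> list[str]:
        return sorted(self.annotations)

    def __len__(self) -> int:
        return len(self.annotations)

    def __eq__(self, other) -> bool:
        return isinstance(other, GOAnnotationMap) and self._norm() == other._norm()

    def _norm(self) -> dict:
        return {
            p: {a: t for a, t in by_aspect.items() if t}
            for p, by_aspect in self.annotations.items()
            if any(by_aspect.values())
        }


def _build_map(triples: Sequence[tuple[str, str, str]]) -> GOAnnotationMap:
    acc: dict[str, dict[str, set[str]]] = {}
    for protein, term, aspect in triples:
        acc.setdefault(protein, {a: set() for a in ASPECTS})[aspect].add(term)
    return GOAnnotationMap(annotations={
        p: {a: frozenset(s) for a, s in by_aspect.items()}
        for p, by_aspect in acc.items()
    })


def load_annotations(
    path: str | Path,
    fmt: str = "auto",
    aspect_map: Mapping[str, str] | None = None,
) -> GOAnnotationMap:
    """Read annotations from a GAF 2.x file or a protein/term TSV.

    GAF mode uses columns 2 (DB object ID), 5 (GO ID) and 9 (aspect P/C/F);
    comment lines starting with ``!`` are skipped and term IDs must match
    ``GO:`` followed by seven digits. TSV mode expects three columns
    (protein, term, aspect with aspect in BP/CC/MF or P/C/F) or two columns
    plus an external ``aspect_map`` from term to aspect.
    """
    path = Path(path)
    if fmt not in ("auto", "gaf", "tsv"):
        raise ValueError(f"unknown format {fmt!r}")
    triples: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("!") or line.startswith("#"):
                continue
            fields = line.split("\t")
            mode = fmt
            if mode == "auto":
                mode = "gaf" if len(fields) >= 9 else "tsv"
            if mode == "gaf":
                if len(fields) < 9:
                    raise ValueError(f"{path}:{lineno}: GAF line with <9 columns")
                protein, term, aspect_code = fields[1], fields[4], fields[8]
                if not _GO_ID.match(term):
                    raise ValueError(f"{path}:{lineno}: malformed GO ID {term!r}")
                if aspect_code not in _GAF_ASPECT:
                    raise ValueError(f"{path}:{lineno}: unknown aspect code {aspect_code!r}")
                aspect = _GAF_ASPECT[aspect_code]
            else:
                if len(fields) >= 3:
                    protein, term, aspect = fields[0], fields[1], fields[2]
                    aspect = _GAF_ASPECT.get(aspect, aspect)
                elif len(fields) == 2:
                    protein, term = fields
                    if aspect_map is None or term not in aspect_map:
                        raise ValueError(
                            f"{path}:{lineno}: two-column TSV needs an aspect_map entry "
                            f"for term {term!r}"
                        )
                    aspect = aspect_map[term]
                else:
                    raise ValueError(f"{path}:{lineno}: expected >=2 columns")
                if aspect not in ASPECTS:
                    raise ValueError(f"{path}:{lineno}: unknown aspect {aspect!r}")
            if not protein.strip() or not term.strip():
                raise ValueError(f"{path}:{lineno}: empty protein or term ID")
            triples.append((protein.strip(), term.strip(), aspect))
    if not triples:
        raise ValueError(f"{path}: no annotations parsed")
    return _build_map(triples)


def write_gaf(annotations: GOAnnotationMap, path: str | Path, db: str = "PPCM") -> None:
    """Write a minimal GAF 2.2 file (columns 2, 5 and 9 populated)."""
    inv_aspect = {v: k for k, v in _GAF_ASPECT.items()}
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for protein in annotations.proteins():
            for aspect in ASPECTS:
                for term in sorted(annotations.terms(protein, aspect)):
                    cols = [""] * 17
                    cols[0] = db
                    cols[1] = protein
                    cols[2] = protein
                    cols[4] = term
                    cols[6] = "IEA"
                    cols[8] = inv_aspect[aspect]
                    fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# pair features
# ---------------------------------------------------------------------------

def feature_names(combo: str) -> list[str]:
    aspects = combo_aspects(combo)
    names = []
    for a in aspects:
        names += [f"{a}_shared", f"{a}_jaccard", f"{a}_union", f"{a}_overlap_ratio"]
    names += [f"{a}_missing" for a in aspects]
    return names


def pair_features(
    annotations: GOAnnotationMap,
    pair: ProteinPair | tuple[str, str],
    combo: str,
) -> np.ndarray:
    """Per-aspect set-overlap feature vector, symmetric in pair order.

    For each aspect in the combo: shared-term count, Jaccard index, union
    size and overlap ratio (shared / min set size); then one missing flag
    per aspect (1 when either protein has no terms in that aspect, in which
    case the four overlap features are zero).
    """
    a, b = pair
    aspects = combo_aspects(combo)
    overlap: list[float] = []
    missing: list[float] = []
    for aspect in aspects:
        ta, tb = annotations.terms(a, aspect), annotations.terms(b, aspect)
        if not ta or not tb:
            overlap += [0.0, 0.0, 0.0, 0.0]
            missing.append(1.0)
            continue
        shared = len(ta & tb)
        union = len(ta | tb)
        overlap += [
            float(shared),
            shared / union,
            float(union),
            shared / min(len(ta), len(tb)),
        ]
        missing.append(0.0)
    return np.array(overlap + missing, dtype=float)


def feature_matrix(
    annotations: GOAnnotationMap,
    pairs: Sequence[ProteinPair],
    combo: str,
) -> np.ndarray:
    return np.array([pair_features(annotations, p, combo) for p in pairs], dtype=float)


# ---------------------------------------------------------------------------
# base learners
# ---------------------------------------------------------------------------

RF_DEFAULT_TREES = 500


@dataclass
class FittedBaseLearner:
    """A fitted pair-probability scorer over a fixed feature definition."""

    learner: str
    model: object
    n_features: int

    def score(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        if features.ndim != 2 or features.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got shape {features.shape}"
            )
        return self.model.predict_proba(features)[:, 1]


def _make_model(learner: str, seed: int, n_trees: int):
    if learner == "nb":
        return GaussianNB()
    if learner == "rf":
        return RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
        )
    raise ValueError(f"unknown learner {learner!r}; choose 'nb' or 'rf'")


def _check_training(features, labels):
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if features.ndim != 2 or len(features) != len(labels):
        raise ValueError("features must be 2-D and aligned with labels")
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    if labels.min() == labels.max():
        raise ValueError("training labels contain a single class")
    return features, labels


def train_base_learner(
    features: np.ndarray,
    labels: Sequence[int],
    learner: str,
    seed: int,
    n_trees: int = RF_DEFAULT_TREES,
) -> FittedBaseLearner:
    """Fit a Naive Bayes ('nb') or Random Forest ('rf') pair classifier.

    Returns a scorer emitting interaction probabilities in [0, 1];
    deterministic for a given seed.
    """
    features, labels = _check_training(features, labels)
    model = _make_model(learner, seed, n_trees)
    model.fit(features, labels)
    return FittedBaseLearner(learner=learner, model=model, n_features=features.shape[1])


def fit_with_oof(
    features: np.ndarray,
    labels: Sequence[int],
    learner: str,
    seed: int,
    n_splits: int = 5,
    n_trees: int = RF_DEFAULT_TREES,
) -> tuple[FittedBaseLearner, np.ndarray, np.ndarray]:
    """Fit on all data and compute out-of-fold training-set scores.

    Returns ``(full_model, oof_scores, fold_assignment)`` where
    ``oof_scores[i]`` is the probability from the fold model whose training
    part excluded sample ``i`` (fold membership in ``fold_assignment``).
    These are the scores a stacking meta-learner should consume for pairs
    that belong to the base learner's own training set.
    """
    features, labels = _check_training(features, labels)
    n_splits = min(n_splits, int(np.bincount(labels).min()))
    if n_splits < 2:
        raise ValueError("minority class too small for out-of-fold scoring")
    oof = np.empty(len(labels), dtype=float)
    fold_of = np.empty(len(labels), dtype=int)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    for fold, (tr, te) in enumerate(skf.split(features, labels)):
        model = _make_model(learner, seed + fold + 1, n_trees)
        model.fit(features[tr], labels[tr])
        oof[te] = model.predict_proba(features[te])[:, 1]
        fold_of[te] = fold
    full = train_base_learner(features, labels, learner, seed, n_trees=n_trees)
    return full, oof, fold_of
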