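"""Phylogenetic-profile base classifiers.

A phylogenetic profile records the presence (1) or absence (0) of a protein's
homolog across a panel of reference taxa. Proteins that co-evolve — and
hence tend to interact or function together — have correlated profiles.
Three classical pair scorers operate on the two binary rows restricted to a
selected taxa subset:

* ``pp`` — normalised Hamming similarity (co-occurrence),
  ``1 - d_H(a, b) / n_taxa``.
* ``mi`` — plug-in mutual information of the two rows in bits.
* ``hg`` — upper-tail hypergeometric enrichment of co-occurrence, reported
  as ``-log10 P(X >= k)`` so that larger is more interaction-like.

Because profile comparison is sensitive to which taxa are included, a
registry of reference-taxa optimisation strategies is provided, from the
trivial identity through unsupervised redundancy filters to supervised
searches (greedy, genetic algorithm, simulated annealing) that maximise the
training AUC of the co-occurrence score on a labelled pair set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .evaluation import ranking_auc
from .gold_standard import ProteinPair


@dataclass
class PhyloProfileMatrix:
    """Binary presence/absence matrix of proteins (rows) across taxa (columns)."""

    proteins: list[str]
    taxa: list[str]
    presence: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)
    _taxon_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=np.uint8)
        if self.presence.shape != (len(self.proteins), len(self.taxa)):
            raise ValueError("presence shape does not match protein/taxon lists")
        if len(set(self.proteins)) != len(self.proteins):
            raise ValueError("duplicate protein IDs")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon IDs")
        if not np.isin(self.presence, (0, 1)).all():
            raise ValueError("profile entries must be 0/1")
        self._index = {p: i for i, p in enumerate(self.proteins)}
        self._taxon_index = {t: j for j, t in enumerate(self.taxa)}

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def __contains__(self, protein: str) -> bool:
        return protein in self._index

    def row(self, protein: str) -> np.ndarray:
        try:
            return self.presence[self._index[protein]]
        except KeyError:
            raise KeyError(f"unknown protein ID {protein!r}") from None

    def taxa_columns(self, taxa: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._taxon_index[t] for t in taxa], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown taxon ID {exc.args[0]!r}") from None

    def all_zero_proteins(self) -> list[str]:
        mask = self.presence.sum(axis=1) == 0
        return [p for p, z in zip(self.proteins, mask) if z]


def load_profiles(path: str | Path) -> PhyloProfileMatrix:
    """Read a profile matrix from TSV: header of taxa, first column protein IDs."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty profile file") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: profile matrix has no rows or no taxa")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate protein ID {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate taxon ID {dup!r}")
    values = np.empty(df.shape, dtype=np.uint8)
    for i, (protein, row) in enumerate(df.iterrows()):
        for j, cell in enumerate(row):
            if isinstance(cell, float) and np.isnan(cell):
                raise ValueError(f"{path}: ragged/missing cell at row {protein!r}")
            cell = str(cell).strip()
            if cell not in ("0", "1"):
                raise ValueError(
                    f"{path}: non-binary cell {cell!r} at protein {protein!r}, "
                    f"taxon {df.columns[j]!r}"
                )
            values[i, j] = int(cell)
    return PhyloProfileMatrix(
        proteins=[str(p) for p in df.index],
        taxa=[str(t) for t in df.columns],
        presence=values,
    )


def write_profiles(matrix: PhyloProfileMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein\t" + "\t".join(matrix.taxa) + "\n")
        for p, row in zip(matrix.proteins, matrix.presence):
            fh.write(p + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# pair scorers
# ---------------------------------------------------------------------------

def _pair_rows(matrix: PhyloProfileMatrix, pair: ProteinPair | tuple[str, str],
               taxa: Sequence[str] | None) -> tuple[np.ndarray, np.ndarray]:
    a, b = pair
    ra, rb = matrix.row(a), matrix.row(b)
    if taxa is not None:
        cols = matrix.taxa_columns(taxa)
        ra, rb = ra[cols], rb[cols]
    return ra.astype(np.int64), rb.astype(np.int64)


def score_pp(matrix: PhyloProfileMatrix, pair, taxa: Sequence[str] | None = None) -> float:
    """Co-occurrence similarity: 1 - HammingDistance / n_taxa, in [0, 1]."""
    ra, rb = _pair_rows(matrix, pair, taxa)
    return float(1.0 - np.mean(ra != rb))


def binary_mutual_information(ra: np.ndarray, rb: np.ndarray) -> float:
    """Plug-in mutual information of two binary vectors, in bits (0*log0 = 0)."""
    n = len(ra)
    counts = np.array([
        [np.sum((ra == 0) & (rb == 0)), np.sum((ra == 0) & (rb == 1))],
        [np.sum((ra == 1) & (rb == 0)), np.sum((ra == 1) & (rb == 1))],
    ], dtype=float)
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / (px * py)), 0.0)
    return float(max(terms.sum(), 0.0))


def score_mi(matrix: PhyloProfileMatrix, pair, taxa: Sequence[str] | None = None) -> float:
    """Mutual information (bits) between the two presence rows."""
    ra, rb = _pair_rows(matrix, pair, taxa)
    if len(ra) < 1:
        raise ValueError("need at least one selected taxon")
    return binary_mutual_information(ra, rb)


def hypergeom_cooccurrence_neglog_p(N: int, K: int, n: int, k: int) -> float:
    """-log10 of the upper-tail hypergeometric p-value P(X >= k).

    ``N`` taxa, protein a present in ``K``, protein b in ``n``, co-present in
    ``k``. ``P(X >= 0) = 1`` so k = 0 maps to 0 exactly.
    """
    if k <= 0:
        return 0.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, 1e-300), 1.0)
    return float(-np.log10(p))


def score_hypergeom(matrix: PhyloProfileMatrix, pair, taxa: Sequence[str] | None = None) -> float:
    """Enrichment of profile co-occurrence under the hypergeometric null."""
    ra, rb = _pair_rows(matrix, pair, taxa)
    N = len(ra)
    K = int(ra.sum())
    n = int(rb.sum())
    k = int(np.sum((ra == 1) & (rb == 1)))
    return hypergeom_cooccurrence_neglog_p(N, K, n, k)


_METHODS: dict[str, Callable] = {"pp": score_pp, "mi": score_mi, "hg": score_hypergeom}


def score_pairs(
    matrix: PhyloProfileMatrix,
    pairs: Sequence[ProteinPair],
    method: str,
    taxa: Sequence[str] | None = None,
) -> np.ndarray:
    """Score a list of pairs with one method; vectorised over the pair list.

    Numerically identical to calling the scalar scorer pair by pair.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_METHODS)}")
    if not pairs:
        return np.zeros(0, dtype=float)
    ia = np.array([matrix._index.get(p.a, -1) for p in pairs])
    ib = np.array([matrix._index.get(p.b, -1) for p in pairs])
    if (ia < 0).any() or (ib < 0).any():
        bad = next(p for p, i, j in zip(pairs, ia, ib) if i < 0 or j < 0)
        raise KeyError(f"unknown protein ID in pair {bad.key()}")
    cols = slice(None) if taxa is None else matrix.taxa_columns(taxa)
    A = matrix.presence[ia][:, cols].astype(np.int64)
    B = matrix.presence[ib][:, cols].astype(np.int64)
    n = A.shape[1]
    if n < 1:
        raise ValueError("need at least one selected taxon")
    if method == "pp":
        return 1.0 - np.mean(A != B, axis=1)
    n11 = np.sum((A == 1) & (B == 1), axis=1)
    if method == "hg":
        K = A.sum(axis=1)
        m = B.sum(axis=1)
        p = stats.hypergeom.sf(n11 - 1, n, K, m)
        p = np.clip(p, 1e-300, 1.0)
        out = -np.log10(p)
        out[n11 <= 0] = 0.0
        return out
    # mi: plug-in MI in bits from the four joint counts
    n10 = np.sum((A == 1) & (B == 0), axis=1)
    n01 = np.sum((A == 0) & (B == 1), axis=1)
    n00 = n - n11 - n10 - n01
    joint = np.stack([n00, n01, n10, n11], axis=1) / n
    pa1 = (n10 + n11) / n
    pb1 = (n01 + n11) / n
    marg = np.stack([(1 - pa1) * (1 - pb1), (1 - pa1) * pb1,
                     pa1 * (1 - pb1), pa1 * pb1], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(joint > 0, joint * np.log2(joint / marg), 0.0)
    return np.maximum(terms.sum(axis=1), 0.0)


# ---------------------------------------------------------------------------
# reference-taxa optimisation strategies
# ---------------------------------------------------------------------------

@dataclass
class TaxaSelection:
    strategy_name: str
    selected: list[str]
    params: dict
    seed: int

    def __post_init__(self) -> None:
        if not self.selected:
            raise ValueError("taxa selection must be non-empty")


def _pair_agreement_matrix(matrix: PhyloProfileMatrix,
                           pairs: Sequence[ProteinPair]) -> np.ndarray:
    """Row i, column t = 1 iff the two proteins of pair i agree at taxon t."""
    ia = np.array([matrix._index[p.a] for p in pairs])
    ib = np.array([matrix._index[p.b] for p in pairs])
    return (matrix.presence[ia] == matrix.presence[ib]).astype(float)


def _mask_auc(agreement: np.ndarray, labels: np.ndarray, mask: np.ndarray) -> float:
    if mask.sum() == 0:
        return 0.5
    scores = agreement[:, mask].mean(axis=1)
    if scores.min() == scores.max():
        return 0.5
    return ranking_auc(scores, labels)


def _training_arrays(matrix, training_pairs):
    pairs = [p for p in training_pairs if p.a in matrix and p.b in matrix]
    if not pairs:
        raise ValueError("no training pair maps onto the profile matrix")
    labels = np.array([1 if p.label == "positive" else 0 for p in pairs])
    if labels.min() == labels.max():
        raise ValueError("training pairs must contain both classes")
    return _pair_agreement_matrix(matrix, pairs), labels


def _strategy_identity(matrix, params, rng, training_pairs):
    return list(matrix.taxa)


def _strategy_random_subset(matrix, params, rng, training_pairs):
    frac = float(params.get("fraction", 0.5))
    m = matrix.n_taxa
    k = max(1, int(round(frac * m)))
    idx = np.sort(rng.choice(m, size=k, replace=False))
    return [matrix.taxa[i] for i in idx]


def _column_correlation(presence: np.ndarray) -> np.ndarray:
    """Absolute Pearson correlation between taxon columns; constant columns
    correlate 1 with identical columns and 0 otherwise."""
    X = presence.astype(float)
    m = X.shape[1]
    sd = X.std(axis=0)
    corr = np.zeros((m, m))
    ok = sd > 0
    if ok.sum() >= 2:
        sub = np.corrcoef(X[:, ok], rowvar=False)
        corr[np.ix_(ok, ok)] = np.abs(sub)
    for j in range(m):
        for k in range(m):
            if not (ok[j] and ok[k]):
                corr[j, k] = 1.0 if np.array_equal(X[:, j], X[:, k]) else 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def _strategy_redundancy_filter(matrix, params, rng, training_pairs):
    threshold = float(params.get("threshold", 0.95))
    corr = _column_correlation(matrix.presence)
    kept: list[int] = []
    for j in range(matrix.n_taxa):
        if all(corr[j, k] < threshold for k in kept):
            kept.append(j)
    return [matrix.taxa[j] for j in kept]


def _strategy_tree_level_filter(matrix, params, rng, training_pairs):
    """Cluster taxa by profile correlation and keep one medoid per cluster."""
    k = int(params.get("n_clusters", min(8, matrix.n_taxa)))
    k = max(1, min(k, matrix.n_taxa))
    if matrix.n_taxa == 1 or k == matrix.n_taxa:
        return list(matrix.taxa)
    corr = _column_correlation(matrix.presence)
    dist = 1.0 - corr
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    assignment = fcluster(Z, t=k, criterion="maxclust")
    selected = []
    for c in np.unique(assignment):
        members = np.nonzero(assignment == c)[0]
        within = dist[np.ix_(members, members)].sum(axis=1)
        selected.append(members[int(np.argmin(within))])
    return [matrix.taxa[j] for j in sorted(selected)]


def _strategy_greedy_forward(matrix, params, rng, training_pairs):
    """Iterative taxon selection: add the column that most improves the
    training AUC of the co-occurrence score; stop at no improvement."""
    agreement, labels = _training_arrays(matrix, training_pairs)
    m = matrix.n_taxa
    max_taxa = int(params.get("max_taxa", min(10, m)))
    mask = np.zeros(m, dtype=bool)
    picked: list[int] = []
    best_auc = -np.inf
    while len(picked) < max_taxa:
        candidate_auc = np.full(m, -np.inf)
        for j in range(m):
            if mask[j]:
                continue
            trial = mask.copy()
            trial[j] = True
            candidate_auc[j] = _mask_auc(agreement, labels, trial)
        j_best = int(np.argmax(candidate_auc))
        if picked and candidate_auc[j_best] <= best_auc + 1e-12:
            break
        best_auc = candidate_auc[j_best]
        mask[j_best] = True
        picked.append(j_best)
    return [matrix.taxa[j] for j in picked]  # in pick order


def _strategy_greedy_backward(matrix, params, rng, training_pairs):
    agreement, labels = _training_arrays(matrix, training_pairs)
    m = matrix.n_taxa
    mask = np.ones(m, dtype=bool)
    best_auc = _mask_auc(agreement, labels, mask)
    while mask.sum() > 1:
        candidate_auc = np.full(m, -np.inf)
        for j in range(m):
            if not mask[j]:
                continue
            trial = mask.copy()
            trial[j] = False
            candidate_auc[j] = _mask_auc(agreement, labels, trial)
        j_best = int(np.argmax(candidate_auc))
        if candidate_auc[j_best] < best_auc - 1e-12:
            break
        best_auc = candidate_auc[j_best]
        mask[j_best] = False
    return [matrix.taxa[j] for j in np.nonzero(mask)[0]]


def _strategy_genetic_algorithm(matrix, params, rng, training_pairs):
    """Bit-mask GA over taxa subsets; fitness = training AUC of the
    co-occurrence score. Small population, fixed generation count."""
    agreement, labels = _training_arrays(matrix, training_pairs)
    m = matrix.n_taxa
    pop_size = int(params.get("population", 16))
    generations = int(params.get("generations", 10))
    p_mut = float(params.get("mutation_rate", 1.0 / m))
    pop = rng.random((pop_size, m)) < 0.5
    pop[pop.sum(axis=1) == 0, 0] = True
    fitness = np.array([_mask_auc(agreement, labels, ind) for ind in pop])
    for _ in range(generations):
        new = [pop[int(np.argmax(fitness))].copy()]  # elitism
        while len(new) < pop_size:
            # tournament selection of two parents, uniform crossover
            c1 = rng.choice(pop_size, size=2, replace=False)
            c2 = rng.choice(pop_size, size=2, replace=False)
            pa = pop[c1[np.argmax(fitness[c1])]]
            pb = pop[c2[np.argmax(fitness[c2])]]
            cross = rng.random(m) < 0.5
            child = np.where(cross, pa, pb)
            child = child ^ (rng.random(m) < p_mut)
            if child.sum() == 0:
                child[rng.integers(m)] = True
            new.append(child)
        pop = np.array(new)
        fitness = np.array([_mask_auc(agreement, labels, ind) for ind in pop])
    best = pop[int(np.argmax(fitness))]
    return [matrix.taxa[j] for j in np.nonzero(best)[0]]


def _strategy_simulated_annealing(matrix, params, rng, training_pairs):
    agreement, labels = _training_arrays(matrix, training_pairs)
    m = matrix.n_taxa
    n_iter = int(params.get("iterations", 150))
    t0 = float(params.get("t0", 0.05))
    current = rng.random(m) < 0.5
    if current.sum() == 0:
        current[rng.integers(m)] = True
    current_fit = _mask_auc(agreement, labels, current)
    best, best_fit = current.copy(), current_fit
    for it in range(n_iter):
        temp = t0 * (1.0 - it / n_iter) + 1e-6
        trial = current.copy()
        j = rng.integers(m)
        trial[j] = ~trial[j]
        if trial.sum() == 0:
            continue
        fit = _mask_auc(agreement, labels, trial)
        if fit >= current_fit or rng.random() < np.exp((fit - current_fit) / temp):
            current, current_fit = trial, fit
            if fit > best_fit:
                best, best_fit = trial.copy(), fit
    return [matrix.taxa[j] for j in np.nonzero(best)[0]]


# name -> (function, requires labelled training pairs)
TAXA_STRATEGIES: dict[str, tuple[Callable, bool]] = {
    "identity": (_strategy_identity, False),
    "random_subset": (_strategy_random_subset, False),
    "redundancy_filter": (_strategy_redundancy_filter, False),
    "tree_level_filter": (_strategy_tree_level_filter, False),
    "greedy_forward": (_strategy_greedy_forward, True),
    "greedy_backward": (_strategy_greedy_backward, True),
    "genetic_algorithm": (_strategy_genetic_algorithm, True),
    "simulated_annealing": (_strategy_simulated_annealing, True),
}


def select_taxa(
    matrix: PhyloProfileMatrix,
    strategy_name: str,
    params: Mapping | None = None,
    seed: int = 0,
    training_pairs: Sequence[ProteinPair] | None = None,
) -> TaxaSelection:
    """Run a registered reference-taxa optimisation strategy.

    Supervised strategies (greedy searches, GA, simulated annealing) require
    ``training_pairs`` labelled positive/negative; they maximise the training
    AUC of the co-occurrence score over taxa subsets. All strategies are
    deterministic for a given seed.
    """
    if strategy_name not in TAXA_STRATEGIES:
        raise ValueError(
            f"unknown taxa strategy {strategy_name!r}; registered: {sorted(TAXA_STRATEGIES)}"
        )
    fn, supervised = TAXA_STRATEGIES[strategy_name]
    if supervised and training_pairs is None:
        raise ValueError(f"strategy {strategy_name!r} requires labelled training pairs")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    selected = fn(matrix, params, rng, training_pairs)
    return TaxaSelection(strategy_name=strategy_name, selected=list(selected),
                         params=params, seed=seed)
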