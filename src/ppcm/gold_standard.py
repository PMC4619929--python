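"""Gold-standard pair dataset construction.

Curated interacting pairs (the positives) are combined with negatives drawn
by randomly pairing proteins and discarding anything already positive, at a
configurable positive:negative ratio (1:100 is the convention for yeast
benchmarks; area under the ROC curve is largely insensitive to the ratio).
All pairs are undirected and stored in canonical lexicographic order, so
(a, b) and (b, a) denote the same pair and self-pairs are rejected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
UNLABELLED = "unlabelled"
_LABELS = (POSITIVE, NEGATIVE, UNLABELLED)


@dataclass(frozen=True)
class ProteinPair:
    """Canonical unordered pair of protein identifiers.

    The constructor swaps ``a`` and ``b`` into lexicographic order, so pair
    identity (equality, hashing) is orientation-free. The label is carried
    along but excluded from identity, which lets positive and negative sets
    be compared as plain sets of pairs.
    """

    a: str
    b: str
    label: str = field(default=UNLABELLED, compare=False)

    def __init__(self, a: str, b: str, label: str = UNLABELLED):
        if not a or not b:
            raise ValueError("protein IDs must be non-empty")
        if a == b:
            raise ValueError(f"self-pair forbidden: {a!r}")
        if label not in _LABELS:
            raise ValueError(f"unknown label {label!r}")
        lo, hi = (a, b) if a < b else (b, a)
        object.__setattr__(self, "a", lo)
        object.__setattr__(self, "b", hi)
        object.__setattr__(self, "label", label)

    def relabel(self, label: str) -> "ProteinPair":
        return ProteinPair(self.a, self.b, label)

    def key(self) -> tuple[str, str]:
        return (self.a, self.b)

    def __iter__(self):
        return iter((self.a, self.b))


@dataclass
class GoldStandardDataset:
    """Labelled pair set: positives plus ``ratio`` times as many negatives."""

    pairs: list[ProteinPair]
    ratio: int
    universe: frozenset[str]
    seed: int

    @property
    def positives(self) -> list[ProteinPair]:
        return [p for p in self.pairs if p.label == POSITIVE]

    @property
    def negatives(self) -> list[ProteinPair]:
        return [p for p in self.pairs if p.label == NEGATIVE]

    @property
    def labels(self) -> np.ndarray:
        return np.array([1 if p.label == POSITIVE else 0 for p in self.pairs], dtype=int)

    def validate(self) -> None:
        pos = {p.key() for p in self.positives}
        neg = {p.key() for p in self.negatives}
        if pos & neg:
            raise ValueError("positive and negative pair sets overlap")
        if len(neg) != self.ratio * len(pos):
            raise ValueError(
                f"negative count {len(neg)} != ratio {self.ratio} x positives {len(pos)}"
            )
        for p in self.pairs:
            if p.a not in self.universe or p.b not in self.universe:
                raise ValueError(f"pair {p.key()} outside universe")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("pair_id\tprotein_a\tprotein_b\tlabel\n")
            for i, p in enumerate(self.pairs):
                fh.write(f"{i}\t{p.a}\t{p.b}\t{p.label}\n")


def _canonicalize(rows: Iterable[tuple[str, str]], label: str) -> tuple[list[ProteinPair], int, int]:
    """De-duplicate and canonicalize raw ID pairs; returns (pairs, n_self, n_dup)."""
    seen: set[tuple[str, str]] = set()
    out: list[ProteinPair] = []
    n_self = 0
    n_dup = 0
    for a, b in rows:
        if a == b:
            n_self += 1
            continue
        pair = ProteinPair(a, b, label)
        if pair.key() in seen:
            n_dup += 1
            continue
        seen.add(pair.key())
        out.append(pair)
    return out, n_self, n_dup


def _strip_mitab_prefix(token: str) -> str:
    # PSI-MI TAB identifiers look like "uniprotkb:P12345"; keep the accession.
    first = token.split("|", 1)[0]
    if ":" in first:
        return first.split(":", 1)[1]
    return first


def load_positive_pairs(path: str | Path, fmt: str = "auto") -> list[ProteinPair]:
    """Read positive interaction pairs from a two-column TSV or PSI-MI TAB file.

    Parameters
    ----------
    path:
        Tab-separated file. Lines starting with ``#`` are skipped. In
        ``mitab`` mode only columns 1-2 (interactor A/B) are used and
        database prefixes (``uniprotkb:``) are stripped.
    fmt:
        ``"tsv"``, ``"mitab"`` or ``"auto"`` (mitab assumed when a data row
        has >= 11 tab-separated fields).
    """
    path = Path(path)
    if fmt not in ("auto", "tsv", "mitab"):
        raise ValueError(f"unknown format {fmt!r}")
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"{path}:{lineno}: expected at least two non-empty columns")
            mode = fmt
            if mode == "auto":
                mode = "mitab" if len(fields) >= 11 else "tsv"
            a, b = fields[0].strip(), fields[1].strip()
            if mode == "mitab":
                a, b = _strip_mitab_prefix(a), _strip_mitab_prefix(b)
                if not a or not b:
                    raise ValueError(f"{path}:{lineno}: empty interactor identifier")
            rows.append((a, b))
    pairs, n_self, n_dup = _canonicalize(rows, POSITIVE)
    if n_self or n_dup:
        logger.info(
            "load_positive_pairs(%s): dropped %d self-pair(s) and %d duplicate(s)",
            path, n_self, n_dup,
        )
    if not pairs:
        raise ValueError(f"{path}: no usable positive pairs")
    return pairs


def sample_negatives(
    universe: Iterable[str],
    positives: Iterable[ProteinPair],
    ratio: int,
    seed: int,
) -> list[ProteinPair]:
    """Draw ``ratio * len(positives)`` distinct random non-positive pairs.

    Random pairing over the protein universe with rejection of self-pairs,
    duplicates and known positives. Deterministic for a given seed. When the
    request is a large fraction of the available pairs the sampler falls back
    to enumerating every eligible pair and choosing without replacement, so
    it always terminates.
    """
    proteins = sorted(set(universe))
    if len(proteins) < 3:
        raise ValueError(f"universe too small ({len(proteins)} proteins); need >= 3")
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    pos_keys = {p.key() for p in positives}
    n = len(proteins)
    capacity = math.comb(n, 2) - len(pos_keys)
    need = ratio * len(pos_keys)
    if capacity < need:
        raise ValueError(
            f"cannot sample {need} negatives: only {capacity} non-positive pairs exist "
            f"in a universe of {n} proteins (short by {need - capacity})"
        )
    rng = np.random.default_rng(seed)
    out: list[ProteinPair] = []
    if need > capacity // 2:
        # dense regime: enumerate all eligible pairs once
        eligible = [
            (proteins[i], proteins[j])
            for i in range(n)
            for j in range(i + 1, n)
            if (proteins[i], proteins[j]) not in pos_keys
        ]
        idx = rng.choice(len(eligible), size=need, replace=False)
        return [ProteinPair(*eligible[i], NEGATIVE) for i in sorted(idx)]
    seen: set[tuple[str, str]] = set()
    while len(out) < need:
        batch = max(64, 2 * (need - len(out)))
        ii = rng.integers(0, n, size=batch)
        jj = rng.integers(0, n, size=batch)
        for i, j in zip(ii, jj):
            if i == j:
                continue
            a, b = proteins[min(i, j)], proteins[max(i, j)]
            key = (a, b)
            if key in pos_keys or key in seen:
                continue
            seen.add(key)
            out.append(ProteinPair(a, b, NEGATIVE))
            if len(out) == need:
                break
    return out


def assemble_gold_standard(
    positives: Sequence[ProteinPair],
    universe: Iterable[str] | None = None,
    ratio: int = 100,
    seed: int = 0,
) -> GoldStandardDataset:
    """Combine positives with sampled negatives into a labelled dataset.

    ``universe`` defaults to the proteins appearing in the positive set.
    """
    positives = [p.relabel(POSITIVE) for p in positives]
    if universe is None:
        universe = {x for p in positives for x in (p.a, p.b)}
    universe = frozenset(universe)
    missing = {x for p in positives for x in (p.a, p.b)} - universe
    if missing:
        raise ValueError(f"{len(missing)} positive-pair protein(s) outside universe")
    negatives = sample_negatives(universe, positives, ratio, seed)
    ds = GoldStandardDataset(pairs=positives + negatives, ratio=ratio, universe=universe, seed=seed)
    ds.validate()
    logger.info(
        "gold standard: %d positives + %d negatives (1:%d), universe %d proteins",
        len(positives), len(negatives), ratio, len(universe),
    )
    return ds


def split_seed(base_seed: int, repeat_index: int) -> int:
    """Derive a per-repeat seed below 2**31, deterministic in both arguments."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(repeat_index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def split_repeat(
    dataset: GoldStandardDataset,
    train_fraction: float,
    repeat_index: int,
    base_seed: int,
) -> tuple[list[ProteinPair], list[ProteinPair]]:
    """Stratified train/test split preserving the class ratio in both parts.

    The split is keyed on ``(base_seed, repeat_index)`` so repeated
    evaluations draw different, reproducible partitions.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(split_seed(base_seed, repeat_index))
    train: list[ProteinPair] = []
    test: list[ProteinPair] = []
    for group in (dataset.positives, dataset.negatives):
        if not group:
            raise ValueError("both classes must be present before splitting")
        k = int(round(train_fraction * len(group)))
        if k == 0 or k == len(group):
            raise ValueError(
                f"train_fraction {train_fraction} leaves an empty class "
                f"(class size {len(group)})"
            )
        order = rng.permutation(len(group))
        train.extend(group[i] for i in order[:k])
        test.extend(group[i] for i in order[k:])
    return train, test
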