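"""Synthetic multi-species benchmark generator.

Produces, for each species, an interaction network (positive pairs plus
randomly sampled negatives), a binary phylogenetic profile matrix over a
shared reference-taxa panel, and flat GO annotations over a shared term
vocabulary — with interaction signal planted in two independent channels:

* co-evolution channel: the profile rows of an interacting pair agree at
  each taxon with probability ``background_agreement +
  coevolution_strength * (1 - background_agreement)``, where the background
  agreement is that of two independent Bernoulli rows;
* GO channel: an interacting pair gains extra terms shared by both
  partners, each vocabulary term being co-assigned with probability
  ``go_sharing_strength * background_term_rate`` on top of the independent
  background assignment.

Non-interacting pairs sit exactly at background in both channels, so with
both strengths at zero every classifier is calibrated at AUC 0.5. The two
channels are deliberately separate so that neither the profile-based nor
the GO-based classifier family alone captures all the signal — the regime
in which a stacking ensemble over both families has something to gain.

Species share the taxa panel and the GO vocabulary but have disjoint
protein ID spaces, mirroring the cross-species transfer setting in which a
classifier calibrated on one organism's network scores pairs of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .classifier_grid import DataBundle, SpeciesData
from .go_features import ASPECTS, GOAnnotationMap, write_gaf
from .gold_standard import POSITIVE, ProteinPair, sample_negatives
from .phylo_profiles import PhyloProfileMatrix, write_profiles

DEFAULT_SPECIES = ("EC", "SC", "DM", "AT", "HS", "MM", "SP")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    Desk-scale defaults: 300 proteins and 50 interacting pairs per species,
    40 reference taxa, negatives at 1:10 (the heavier 1:100 regime is
    exercised separately at reduced size), moderate planted signal in both
    channels so single-classifier AUCs land well clear of both 0.5 and 1.
    """

    n_proteins: int = 300
    n_taxa: int = 40
    n_positive_pairs: int = 50
    ratio: int = 10
    coevolution_strength: float = 0.25
    go_sharing_strength: float = 0.5
    n_terms_per_aspect: int = 60
    background_term_rate: float = 0.05
    profile_presence_rate: float = 0.5
    species: tuple[str, ...] = DEFAULT_SPECIES
    target_species: str = "SC"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("coevolution_strength", "go_sharing_strength",
                     "background_term_rate", "profile_presence_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_proteins", "n_taxa", "n_positive_pairs", "ratio",
                     "n_terms_per_aspect"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_positive_pairs > math.comb(self.n_proteins, 2):
            raise ValueError(
                f"cannot place {self.n_positive_pairs} interacting pairs among "
                f"{self.n_proteins} proteins"
            )
        if self.target_species not in self.species:
            raise ValueError("target_species must be in the species list")

    @property
    def background_agreement(self) -> float:
        q = self.profile_presence_rate
        return q * q + (1 - q) * (1 - q)


@dataclass
class SpeciesBundle:
    """One species' synthetic inputs."""

    species: str
    positives: list[ProteinPair]
    training_pairs: list[ProteinPair]  # positives + sampled negatives
    profiles: PhyloProfileMatrix
    annotations: GOAnnotationMap


@dataclass
class MultiSpeciesBundle:
    species: dict[str, SpeciesBundle]
    taxa: list[str]
    config: SyntheticConfig

    def as_data_bundle(self) -> DataBundle:
        return DataBundle(
            species={
                name: SpeciesData(
                    species=name,
                    profiles=sb.profiles,
                    annotations=sb.annotations,
                    training_pairs=sb.training_pairs,
                )
                for name, sb in self.species.items()
            },
            target_species=self.config.target_species,
        )


def _protein_ids(species: str, n: int) -> list[str]:
    return [f"{species}_P{i:05d}" for i in range(n)]


def _term_vocabulary(n_per_aspect: int) -> dict[str, list[str]]:
    # numeric blocks per aspect keep IDs syntactically valid and disjoint
    vocab = {}
    for a_idx, aspect in enumerate(ASPECTS):
        base = (a_idx + 1) * 1_000_000
        vocab[aspect] = [f"GO:{base + i:07d}" for i in range(n_per_aspect)]
    return vocab


def _sample_positive_pairs(proteins: Sequence[str], n_pairs: int,
                           rng: np.random.Generator) -> list[ProteinPair]:
    n = len(proteins)
    seen: set[tuple[int, int]] = set()
    while len(seen) < n_pairs:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        seen.add(key)
    return [ProteinPair(proteins[i], proteins[j], POSITIVE) for i, j in sorted(seen)]


def _plant_profiles(proteins, positives, config, rng) -> np.ndarray:
    presence = (rng.random((len(proteins), config.n_taxa))
                < config.profile_presence_rate).astype(np.uint8)
    if config.coevolution_strength <= 0:
        return presence
    index = {p: i for i, p in enumerate(proteins)}
    p_agree = (config.background_agreement
               + config.coevolution_strength * (1 - config.background_agreement))
    # copy-with-noise along the positive graph; a protein's row is planted
    # at most once so overlapping pairs stay consistent
    planted: set[int] = set()
    for pair in positives:
        ia, ib = index[pair.a], index[pair.b]
        if ia in planted and ib in planted:
            continue
        if ib in planted and ia not in planted:
            ia, ib = ib, ia
        src, dst = presence[ia], ib
        agree = rng.random(config.n_taxa) < p_agree
        presence[dst] = np.where(agree, src, 1 - src)
        planted.update((ia, dst))
    return presence


def _plant_annotations(proteins, positives, vocab, config, rng) -> GOAnnotationMap:
    annotations: dict[str, dict[str, set[str]]] = {
        p: {a: set() for a in ASPECTS} for p in proteins
    }
    for aspect in ASPECTS:
        terms = vocab[aspect]
        hits = rng.random((len(proteins), len(terms))) < config.background_term_rate
        for i, p in enumerate(proteins):
            annotations[p][aspect].update(t for t, h in zip(terms, hits[i]) if h)
    if config.go_sharing_strength > 0:
        p_share = config.go_sharing_strength * config.background_term_rate
        for pair in positives:
            for aspect in ASPECTS:
                terms = vocab[aspect]
                shared = rng.random(len(terms)) < p_share
                for t, h in zip(terms, shared):
                    if h:
                        annotations[pair.a][aspect].add(t)
                        annotations[pair.b][aspect].add(t)
    return GOAnnotationMap(annotations={
        p: {a: frozenset(s) for a, s in by_aspect.items()}
        for p, by_aspect in annotations.items()
    })


def generate_species_bundle(config: SyntheticConfig, species: str,
                            seed: int) -> SpeciesBundle:
    """Generate one species' synthetic inputs; deterministic for a seed."""
    rng = np.random.default_rng(seed)
    proteins = _protein_ids(species, config.n_proteins)
    positives = _sample_positive_pairs(proteins, config.n_positive_pairs, rng)
    presence = _plant_profiles(proteins, positives, config, rng)
    vocab = _term_vocabulary(config.n_terms_per_aspect)
    annotations = _plant_annotations(proteins, positives, vocab, config, rng)
    negatives = sample_negatives(
        proteins, positives, config.ratio,
        seed=int(rng.integers(0, 2**31)),
    )
    taxa = [f"taxon{j:03d}" for j in range(config.n_taxa)]
    profiles = PhyloProfileMatrix(proteins=list(proteins), taxa=taxa, presence=presence)
    return SpeciesBundle(
        species=species,
        positives=positives,
        training_pairs=positives + negatives,
        profiles=profiles,
        annotations=annotations,
    )


def generate_bundle(config: SyntheticConfig) -> MultiSpeciesBundle:
    """Generate all species' bundles from one config.

    Per-species seeds derive from the config seed, so the whole bundle is
    reproducible and species are statistically independent.
    """
    bundles = {}
    for k, species in enumerate(config.species):
        ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(k,))
        bundles[species] = generate_species_bundle(
            config, species, seed=int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31)))
    taxa = [f"taxon{j:03d}" for j in range(config.n_taxa)]
    return MultiSpeciesBundle(species=bundles, taxa=taxa, config=config)


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    return replace(config, seed=seed)


def write_bundle(bundle: MultiSpeciesBundle, out_dir: str | Path) -> dict[str, dict[str, Path]]:
    """Write every species' inputs in the formats the loaders read.

    Emits ``<species>.positives.tsv`` (two-column pair list),
    ``<species>.profiles.tsv`` (binary matrix) and ``<species>.gaf``
    (GAF 2.2); reading them back reproduces the in-memory bundle.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, dict[str, Path]] = {}
    for name, sb in bundle.species.items():
        paths = {
            "positives": out_dir / f"{name}.positives.tsv",
            "profiles": out_dir / f"{name}.profiles.tsv",
            "gaf": out_dir / f"{name}.gaf",
        }
        with open(paths["positives"], "w") as fh:
            fh.write("# protein_a\tprotein_b\n")
            for p in sb.positives:
                fh.write(f"{p.a}\t{p.b}\n")
        write_profiles(sb.profiles, paths["profiles"])
        write_gaf(sb.annotations, paths["gaf"])
        written[name] = paths
    return written
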