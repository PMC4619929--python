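import itertools
import math

import numpy as np
import pytest
from sklearn.metrics import mutual_info_score

from ppcm.gold_standard import ProteinPair
from ppcm.phylo_profiles import (
    PhyloProfileMatrix,
    TAXA_STRATEGIES,
    binary_mutual_information,
    hypergeom_cooccurrence_neglog_p,
    load_profiles,
    score_hypergeom,
    score_mi,
    score_pairs,
    score_pp,
    select_taxa,
    write_profiles,
)


def _matrix_from_rows(rows: dict[str, list[int]]) -> PhyloProfileMatrix:
    n = len(next(iter(rows.values())))
    return PhyloProfileMatrix(
        proteins=list(rows),
        taxa=[f"t{i}" for i in range(n)],
        presence=np.array(list(rows.values()), dtype=np.uint8),
    )


class TestLoadProfiles:
    def test_round_trip(self, toy_matrix, tmp_path):
        f = tmp_path / "profiles.tsv"
        write_profiles(toy_matrix, f)
        loaded = load_profiles(f)
        assert loaded.proteins == toy_matrix.proteins
        assert loaded.taxa == toy_matrix.taxa
        assert np.array_equal(loaded.presence, toy_matrix.presence)

    def test_non_binary_cell_names_coordinates(self, tmp_path):
        f = tmp_path / "profiles.tsv"
        f.write_text("protein\tt0\tt1\np1\t0\t2\n")
        with pytest.raises(ValueError, match=r"'2'.*'p1'.*'t1'"):
            load_profiles(f)

    def test_empty_file_is_error(self, tmp_path):
        f = tmp_path / "profiles.tsv"
        f.write_text("")
        with pytest.raises(ValueError, match="empty"):
            load_profiles(f)

    def test_ragged_row_is_error(self, tmp_path):
        f = tmp_path / "profiles.tsv"
        f.write_text("protein\tt0\tt1\np1\t0\n")
        with pytest.raises(ValueError):
            load_profiles(f)

    def test_duplicate_protein_is_error(self, tmp_path):
        f = tmp_path / "profiles.tsv"
        f.write_text("protein\tt0\np1\t0\np1\t1\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_profiles(f)


class TestCooccurrenceScore:
    def test_identical_rows_score_one(self, toy_matrix):
        assert score_pp(toy_matrix, ProteinPair("pA", "pC")) == 1.0

    def test_complementary_rows_score_zero(self, toy_matrix):
        assert score_pp(toy_matrix, ProteinPair("pA", "pD")) == 0.0

    def test_hamming_arithmetic(self, toy_matrix, pair_ab):
        # rows 1111100000 and 1010101010 disagree at 4 of 10 taxa
        assert score_pp(toy_matrix, pair_ab) == pytest.approx(0.6)

    def test_unknown_protein_raises(self, toy_matrix):
        with pytest.raises(KeyError, match="pZ"):
            score_pp(toy_matrix, ProteinPair("pA", "pZ"))

    def test_symmetry_and_bounds(self, toy_matrix):
        rng = np.random.default_rng(0)
        names = toy_matrix.proteins
        for a, b in itertools.combinations(names, 2):
            s = score_pp(toy_matrix, ProteinPair(a, b))
            assert 0.0 <= s <= 1.0
            assert s == score_pp(toy_matrix, ProteinPair(b, a))


class TestMutualInformationScore:
    def test_identical_balanced_rows_give_one_bit(self, toy_matrix):
        assert score_mi(toy_matrix, ProteinPair("pA", "pC")) == pytest.approx(1.0)

    def test_constant_row_gives_zero(self, toy_matrix):
        assert score_mi(toy_matrix, ProteinPair("pA", "pE")) == 0.0
        assert score_mi(toy_matrix, ProteinPair("pA", "pF")) == 0.0

    def test_hand_computed_example(self, toy_matrix, pair_ab):
        # joint counts n11=3, n10=2, n01=2, n00=3 over 10 taxa
        expected = (0.3 * math.log2(0.3 / 0.25) * 2
                    + 0.2 * math.log2(0.2 / 0.25) * 2)
        assert expected == pytest.approx(0.029, abs=5e-4)
        assert score_mi(toy_matrix, pair_ab) == pytest.approx(expected, abs=1e-12)

    def test_bounded_by_marginal_entropies_and_symmetric(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            ra, rb = rng.integers(0, 2, size=(2, n))
            mi = binary_mutual_information(ra, rb)
            assert mi == pytest.approx(binary_mutual_information(rb, ra))

            def h(v):
                p = v.mean()
                return 0.0 if p in (0.0, 1.0) else -(p * math.log2(p)
                                                     + (1 - p) * math.log2(1 - p))
            assert mi <= min(h(ra), h(rb)) + 1e-9

    def test_matches_independent_library_estimator(self):
        """Plug-in MI agrees with sklearn's contingency-based estimator."""
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            ra, rb = rng.integers(0, 2, size=(2, n))
            ours = binary_mutual_information(ra, rb)
            theirs = mutual_info_score(ra, rb) / math.log(2)
            assert ours == pytest.approx(theirs, abs=1e-10)


def _exhaustive_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by enumerating all C(N, n) placements of b's ones."""
    hits = 0
    total = 0
    a_positions = set(range(K))
    for combo in itertools.combinations(range(N), n):
        total += 1
        if len(a_positions & set(combo)) >= k:
            hits += 1
    return hits / total if total else 1.0


class TestHypergeometricScore:
    def test_identical_balanced_rows(self, toy_matrix):
        s = score_hypergeom(toy_matrix, ProteinPair("pA", "pC"))
        assert s == pytest.approx(-math.log10(1 / 252), abs=1e-9)

    def test_zero_cooccurrence_scores_zero(self, toy_matrix):
        assert score_hypergeom(toy_matrix, ProteinPair("pA", "pD")) == 0.0

    def test_matches_exhaustive_enumeration_small_vectors(self):
        """All binary-vector pairs up to length 4 against the enumeration oracle."""
        for N in range(1, 5):
            for bits_a in itertools.product((0, 1), repeat=N):
                for bits_b in itertools.product((0, 1), repeat=N):
                    ra, rb = np.array(bits_a), np.array(bits_b)
                    K, n = int(ra.sum()), int(rb.sum())
                    k = int(((ra == 1) & (rb == 1)).sum())
                    expected_p = _exhaustive_upper_tail(N, K, n, k)
                    got = hypergeom_cooccurrence_neglog_p(N, K, n, k)
                    assert got == pytest.approx(
                        0.0 if k == 0 else -math.log10(expected_p), abs=1e-9)

    def test_matches_exhaustive_enumeration_random_longer_vectors(self):
        rng = np.random.default_rng(12)
        for _ in range(150):
            N = int(rng.integers(5, 13))
            ra, rb = rng.integers(0, 2, size=(2, N))
            K, n = int(ra.sum()), int(rb.sum())
            k = int(((ra == 1) & (rb == 1)).sum())
            expected_p = _exhaustive_upper_tail(N, K, n, k)
            got = hypergeom_cooccurrence_neglog_p(N, K, n, k)
            assert got == pytest.approx(0.0 if k == 0 else -math.log10(expected_p),
                                        abs=1e-9)


class TestVectorisedScoring:
    def test_matches_scalar_scorers(self, toy_matrix):
        pairs = [ProteinPair(a, b)
                 for a, b in itertools.combinations(toy_matrix.proteins, 2)]
        for method, scalar in (("pp", score_pp), ("mi", score_mi),
                               ("hg", score_hypergeom)):
            vec = score_pairs(toy_matrix, pairs, method)
            ref = [scalar(toy_matrix, p) for p in pairs]
            assert vec == pytest.approx(ref, abs=1e-12)

    def test_taxa_subset_respected(self, toy_matrix, pair_ab):
        subset = ["t0", "t2", "t4"]  # pA and pB agree on all three
        assert score_pairs(toy_matrix, [pair_ab], "pp", subset)[0] == 1.0


def _labelled_pairs(matrix, positives, negatives):
    return ([ProteinPair(a, b, "positive") for a, b in positives]
            + [ProteinPair(a, b, "negative") for a, b in negatives])


class TestTaxaSelection:
    def test_identity_returns_all_taxa(self, toy_matrix):
        sel = select_taxa(toy_matrix, "identity")
        assert sel.selected == toy_matrix.taxa

    def test_unknown_strategy(self, toy_matrix):
        with pytest.raises(ValueError, match="unknown taxa strategy"):
            select_taxa(toy_matrix, "nope")

    def test_supervised_strategy_requires_labels(self, toy_matrix):
        with pytest.raises(ValueError, match="training pairs"):
            select_taxa(toy_matrix, "greedy_forward")

    def test_redundancy_filter_drops_duplicate_column(self):
        rows = {
            "p1": [1, 1, 0, 1],
            "p2": [0, 0, 1, 0],
            "p3": [1, 1, 0, 0],
        }  # taxa t0 and t1 are identical columns
        m = _matrix_from_rows(rows)
        sel = select_taxa(m, "redundancy_filter")
        assert not {"t0", "t1"} <= set(sel.selected)
        assert sel.selected  # non-empty

    def test_greedy_forward_first_pick_is_exhaustive_argmax(self):
        """The first greedy pick equals a brute-force scan of single taxa."""
        rng = np.random.default_rng(21)
        presence = rng.integers(0, 2, size=(12, 6)).astype(np.uint8)
        # make taxon t3 perfectly separate planted interactors
        presence[:, 3] = 0
        for i in (0, 1, 2, 3):
            presence[i, 3] = 1
        m = PhyloProfileMatrix(
            proteins=[f"p{i}" for i in range(12)],
            taxa=[f"t{i}" for i in range(6)],
            presence=presence,
        )
        pos = [("p0", "p1"), ("p2", "p3")]
        neg = [("p0", "p4"), ("p1", "p5"), ("p2", "p6"), ("p3", "p7"),
               ("p8", "p9"), ("p10", "p11")]
        training = _labelled_pairs(m, pos, neg)

        from ppcm.evaluation import ranking_auc
        y = np.array([1] * len(pos) + [0] * len(neg))

        def single_taxon_auc(j):
            scores = [1.0 - abs(int(m.row(p.a)[j]) - int(m.row(p.b)[j]))
                      for p in training]
            if min(scores) == max(scores):
                return 0.5
            return ranking_auc(scores, y)

        best_single = max(range(6), key=single_taxon_auc)
        sel = select_taxa(m, "greedy_forward", seed=0, training_pairs=training)
        assert sel.selected[0] == f"t{best_single}"

    @pytest.mark.parametrize("strategy", sorted(TAXA_STRATEGIES))
    def test_every_strategy_deterministic_and_nonempty(self, strategy, tiny_bundle):
        sc = tiny_bundle.species["SC"]
        training = sc.training_pairs
        a = select_taxa(sc.profiles, strategy, seed=7, training_pairs=training)
        b = select_taxa(sc.profiles, strategy, seed=7, training_pairs=training)
        assert a.selected == b.selected
        assert len(a.selected) >= 1
        assert set(a.selected) <= set(sc.profiles.taxa)

    def test_unsupervised_strategies_permutation_equivariant(self):
        """Permuting taxon columns permutes the selection accordingly."""
        rng = np.random.default_rng(5)
        presence = rng.integers(0, 2, size=(20, 8)).astype(np.uint8)
        m = PhyloProfileMatrix(
            proteins=[f"p{i}" for i in range(20)],
            taxa=[f"t{i}" for i in range(8)],
            presence=presence,
        )
        perm = rng.permutation(8)
        m_perm = PhyloProfileMatrix(
            proteins=m.proteins,
            taxa=[m.taxa[j] for j in perm],
            presence=presence[:, perm],
        )
        for strategy in ("identity", "redundancy_filter", "tree_level_filter"):
            sel = set(select_taxa(m, strategy).selected)
            sel_perm = set(select_taxa(m_perm, strategy).selected)
            assert sel == sel_perm, strategy
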