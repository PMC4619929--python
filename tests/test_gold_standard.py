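import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppcm.gold_standard import (
    GoldStandardDataset,
    ProteinPair,
    assemble_gold_standard,
    load_positive_pairs,
    sample_negatives,
    split_repeat,
)


class TestProteinPair:
    def test_canonical_order_and_orientation_free_identity(self):
        assert ProteinPair("B", "A").key() == ("A", "B")
        assert ProteinPair("A", "B") == ProteinPair("B", "A")
        assert hash(ProteinPair("A", "B")) == hash(ProteinPair("B", "A"))

    def test_label_excluded_from_identity(self):
        assert ProteinPair("A", "B", "positive") == ProteinPair("A", "B", "negative")

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError, match="self-pair"):
            ProteinPair("P3", "P3")

    @given(st.text(min_size=1, max_size=6), st.text(min_size=1, max_size=6))
    @settings(max_examples=100, derandomize=True)
    def test_canonicalization_is_idempotent(self, a, b):
        if a == b:
            return
        p = ProteinPair(a, b)
        assert p.a < p.b
        assert p == ProteinPair(p.b, p.a)


class TestLoadPositivePairs:
    def test_dedup_and_self_pair_drop(self, tmp_path):
        f = tmp_path / "pairs.tsv"
        f.write_text("P1\tP2\nP2\tP1\nP3\tP3\nP1\tP2\n")
        pairs = load_positive_pairs(f)
        assert pairs == [ProteinPair("P1", "P2")]
        assert pairs[0].label == "positive"

    def test_lexicographic_canonical_order(self, tmp_path):
        f = tmp_path / "pairs.tsv"
        f.write_text("B\tA\nC\tA\n")
        assert [p.key() for p in load_positive_pairs(f)] == [("A", "B"), ("A", "C")]

    def test_comments_skipped_and_malformed_row_reports_line(self, tmp_path):
        f = tmp_path / "pairs.tsv"
        f.write_text("# header\nP1\tP2\nonly_one_column\n")
        with pytest.raises(ValueError, match=":3"):
            load_positive_pairs(f)

    def test_empty_result_is_error(self, tmp_path):
        f = tmp_path / "pairs.tsv"
        f.write_text("P1\tP1\n")
        with pytest.raises(ValueError, match="no usable"):
            load_positive_pairs(f)

    def test_minimal_psimitab_reader_strips_prefixes(self, tmp_path):
        f = tmp_path / "pairs.mitab"
        cols_rest = "\t".join(["-"] * 13)
        f.write_text(
            f"uniprotkb:P1\tuniprotkb:P2\t{cols_rest}\n"
            f"uniprotkb:P2\tuniprotkb:P3\t{cols_rest}\n"
        )
        assert [p.key() for p in load_positive_pairs(f)] == [("P1", "P2"), ("P2", "P3")]


class TestSampleNegatives:
    def test_contract_count_and_exclusion(self):
        positives = [ProteinPair("A", "B", "positive")]
        negs = sample_negatives("ABCDEF", positives, ratio=2, seed=5)
        assert len(negs) == 2
        assert len({n.key() for n in negs}) == 2
        assert all(n.key() != ("A", "B") for n in negs)
        assert all(n.label == "negative" for n in negs)

    def test_exhausted_universe_is_error(self):
        proteins = [f"P{i}" for i in range(10)]
        positives = [ProteinPair(a, b, "positive")
                     for i, a in enumerate(proteins) for b in proteins[i + 1:]]
        assert len(positives) == 45
        with pytest.raises(ValueError, match="short by"):
            sample_negatives(proteins, positives, ratio=1, seed=0)

    def test_three_protein_universe_deficit(self):
        # C(3,2)=3 pairs; two are positive, so two negatives cannot exist
        positives = [ProteinPair("A", "B", "positive"), ProteinPair("A", "C", "positive")]
        with pytest.raises(ValueError, match="short by 1"):
            sample_negatives("ABC", positives, ratio=1, seed=0)

    def test_dense_regime_draws_every_remaining_pair(self):
        # need == capacity forces the enumeration fallback
        positives = [ProteinPair("A", "B", "positive")]
        negs = sample_negatives("ABCD", positives, ratio=5, seed=3)
        assert len(negs) == 5
        assert len({n.key() for n in negs}) == 5

    def test_determinism(self):
        universe = [f"P{i}" for i in range(30)]
        positives = [ProteinPair("P0", "P1", "positive")]
        a = sample_negatives(universe, positives, ratio=10, seed=42)
        b = sample_negatives(universe, positives, ratio=10, seed=42)
        assert [p.key() for p in a] == [p.key() for p in b]

    def test_random_configurations_respect_invariants(self):
        """Sampled negatives never collide with positives and are canonical."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = int(rng.integers(5, 14))
            universe = [f"P{i}" for i in range(n)]
            all_pairs = [(universe[i], universe[j])
                         for i in range(n) for j in range(i + 1, n)]
            k = int(rng.integers(1, max(2, len(all_pairs) // 4)))
            pos_idx = rng.choice(len(all_pairs), size=k, replace=False)
            positives = [ProteinPair(*all_pairs[i], "positive") for i in pos_idx]
            r = int(rng.integers(1, 4))
            if math.comb(n, 2) - k < r * k:
                continue
            negs = sample_negatives(universe, positives, r, seed=int(rng.integers(2**31)))
            keys = {p.key() for p in negs}
            assert len(negs) == r * k
            assert len(keys) == len(negs)
            assert not keys & {p.key() for p in positives}
            assert all(p.a < p.b for p in negs)


class TestAssembleGoldStandard:
    def test_counts_at_ratio_100(self):
        universe = [f"P{i:03d}" for i in range(200)]
        positives = [ProteinPair(universe[2 * i], universe[2 * i + 1], "positive")
                     for i in range(5)]
        ds = assemble_gold_standard(positives, universe, ratio=100, seed=1)
        assert len(ds.pairs) == 505
        ds.validate()

    def test_counts_small_ratio(self):
        positives = [ProteinPair("A", "B", "positive"), ProteinPair("C", "D", "positive"),
                     ProteinPair("E", "F", "positive")]
        ds = assemble_gold_standard(positives, "ABCDEFGH", ratio=2, seed=0)
        assert len(ds.pairs) == 9
        assert len(ds.negatives) == 6

    def test_default_universe_is_positive_proteins(self):
        positives = [ProteinPair("A", "B", "positive"), ProteinPair("C", "D", "positive")]
        ds = assemble_gold_standard(positives, ratio=1, seed=0)
        assert ds.universe == frozenset("ABCD")

    def test_same_seed_identical_dataset(self, tmp_path):
        universe = [f"P{i}" for i in range(40)]
        positives = [ProteinPair("P0", "P1", "positive"), ProteinPair("P2", "P3", "positive")]
        f1, f2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        assemble_gold_standard(positives, universe, 10, seed=9).to_tsv(f1)
        assemble_gold_standard(positives, universe, 10, seed=9).to_tsv(f2)
        assert f1.read_bytes() == f2.read_bytes()


class TestSplitRepeat:
    @pytest.fixture
    def dataset(self):
        universe = [f"P{i:04d}" for i in range(300)]
        positives = [ProteinPair(universe[2 * i], universe[2 * i + 1], "positive")
                     for i in range(10)]
        return assemble_gold_standard(positives, universe, ratio=100, seed=2)

    def test_stratified_arithmetic(self, dataset):
        train, test = split_repeat(dataset, 0.7, repeat_index=0, base_seed=1)
        n_pos = sum(1 for p in train if p.label == "positive")
        n_neg = sum(1 for p in train if p.label == "negative")
        assert (n_pos, n_neg) == (7, 700)
        assert (len(test) - sum(1 for p in test if p.label == "positive")) == 300
        assert not ({p.key() for p in train} & {p.key() for p in test})

    def test_repeats_differ_but_reproduce(self, dataset):
        t0a, _ = split_repeat(dataset, 0.7, 0, base_seed=5)
        t0b, _ = split_repeat(dataset, 0.7, 0, base_seed=5)
        t1, _ = split_repeat(dataset, 0.7, 1, base_seed=5)
        assert [p.key() for p in t0a] == [p.key() for p in t0b]
        assert {p.key() for p in t0a} != {p.key() for p in t1}

    def test_empty_class_is_error(self):
        positives = [ProteinPair("A", "B", "positive"), ProteinPair("C", "D", "positive")]
        ds = assemble_gold_standard(positives, [f"P{i}" for i in range(20)] + list("ABCD"),
                                    ratio=5, seed=0)
        with pytest.raises(ValueError, match="empty class"):
            split_repeat(ds, 0.999, 0, base_seed=0)
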