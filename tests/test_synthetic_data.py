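"""Generator correctness: complementarity, partitioning, labelling, I/O."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chisquare

from comprec import synthetic_data as sd

strands = st.text(alphabet="ACGU", min_size=1, max_size=10)


class TestComplement:
    @pytest.mark.parametrize(
        "base,partner", [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")]
    )
    def test_watson_crick_map(self, base, partner):
        assert sd.complement_base(base) == partner

    def test_rejects_foreign_symbols(self):
        with pytest.raises(sd.InvalidAlphabetError):
            sd.complement_base("T")

    def test_worked_example(self):
        assert sd.exact_complement("AGUCAG") == "CUGACU"

    def test_self_complementary_strand(self):
        # palindromic under reverse-complement: its own exact complement
        assert sd.exact_complement("ACGUACGU") == "ACGUACGU"

    @given(strands)
    @settings(deadline=None, max_examples=200)
    def test_involution_preserves_length(self, s):
        twice = sd.exact_complement(sd.exact_complement(s))
        assert twice == s
        assert len(sd.exact_complement(s)) == len(s)

    def test_pairwise_condition_exhaustive_small_l(self):
        # definition check on the whole space up to L=4
        for L in (1, 2, 3, 4):
            for s in sd.enumerate_strands(L):
                star = sd.exact_complement(s)
                assert all(
                    s[i] == sd.complement_base(star[L - 1 - i])
                    for i in range(L)
                )
                assert sd.is_complementary(s, star)


class TestPartition:
    def test_covers_space_disjointly(self):
        part = sd.partition_sequence_space(8, seed=0)
        assert len(part.train_pool) + len(part.test_pool) == 4**8
        assert not set(part.train_pool) & set(part.test_pool)

    def test_brute_force_l2(self):
        part = sd.partition_sequence_space(2, seed=3, train_fraction=0.5)
        both = set(part.train_pool) | set(part.test_pool)
        assert both == set(sd.enumerate_strands(2))
        assert len(part.train_pool) == 8 and len(part.test_pool) == 8

    def test_deterministic_given_seed(self):
        a = sd.partition_sequence_space(5, seed=42)
        b = sd.partition_sequence_space(5, seed=42)
        assert a.train_pool == b.train_pool and a.test_pool == b.test_pool

    def test_rejects_overlong_strands(self):
        with pytest.raises(ValueError):
            sd.partition_sequence_space(11, seed=0)


class TestMakeExample:
    def test_positive_uses_exact_complement(self):
        rng = np.random.default_rng(0)
        e = sd.make_example("AGUCAG", 4, positive=True, rng=rng)
        assert e.s_bar == "CUGACU" and e.true_label == 1

    def test_negative_l1_never_draws_the_partner(self):
        rng = np.random.default_rng(0)
        seen = {
            sd.make_example("A", 4, positive=False, rng=rng).s_bar
            for _ in range(200)
        }
        assert seen <= {"A", "C", "G"} and "U" not in seen

    def test_negatives_fail_the_pairing_condition(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            e = sd.make_example("ACGUA", 4, positive=False, rng=rng)
            assert e.true_label == 0
            assert not sd.is_complementary(e.s, e.s_bar)

    def test_negative_draws_uniform_over_complement_space(self):
        # 10,000 draws at L=3: uniform over the 63 strands != s*
        rng = np.random.default_rng(5)
        counts: dict[str, int] = {}
        for _ in range(10_000):
            e = sd.make_example("ACG", 4, positive=False, rng=rng)
            counts[e.s_bar] = counts.get(e.s_bar, 0) + 1
        assert len(counts) == 63
        _, p = chisquare(list(counts.values()))
        assert p > 0.01


class TestMislabelling:
    def test_mu_zero_is_identity(self, small_train):
        out = sd.apply_mislabelling(small_train, 0.0, np.random.default_rng(0))
        assert out.observed_labels().tolist() == (
            small_train.observed_labels().tolist()
        )

    def test_flip_fraction_within_three_sigma(self, partition_l4):
        mu, N = 0.2, 10_000
        ds = sd.generate_dataset(
            partition_l4.train_pool, N, 0.5, mu, role="train", seed=2
        )
        flipped = np.mean(
            [e.is_mislabelled for e in ds.examples]
        )
        sigma = np.sqrt(mu * (1 - mu) / N)
        assert abs(flipped - mu) < 3 * sigma

    def test_true_labels_untouched(self, noisy_train):
        for e in noisy_train.examples:
            assert e.true_label == sd.is_complementary(e.s, e.s_bar)
            assert e.is_mislabelled == (e.observed_label != e.true_label)

    def test_mu_half_decouples_labels(self, partition_l4):
        # at mu = 1/2 the observed label is independent of the truth
        ds = sd.generate_dataset(
            partition_l4.train_pool, 10_000, 0.5, 0.5, role="train", seed=3
        )
        t, o = ds.true_labels(), ds.observed_labels()
        corr = np.corrcoef(t, o)[0, 1]
        assert abs(corr) < 0.05

    def test_refuses_test_role(self, small_test):
        with pytest.raises(ValueError):
            sd.apply_mislabelling(small_test, 0.1, np.random.default_rng(0))


class TestGenerateDataset:
    def test_test_role_is_balanced_and_clean(self, partition_l4):
        ds = sd.generate_dataset(
            partition_l4.test_pool, 1000, 0.5, 0.0, role="test", seed=1
        )
        t = ds.true_labels()
        assert t.sum() == 500 and (1 - t).sum() == 500
        assert not any(e.is_mislabelled for e in ds.examples)

    def test_alpha_sets_positive_count(self, partition_l4):
        ds = sd.generate_dataset(
            partition_l4.train_pool, 500, 0.4, 0.0, role="train", seed=1
        )
        assert ds.true_labels().sum() == 200

    def test_pools_keep_roles_disjoint(self, small_train, small_test):
        train_s = {e.s for e in small_train.examples}
        test_s = {e.s for e in small_test.examples}
        assert not train_s & test_s

    def test_identical_seeds_reproduce_identical_datasets(self, partition_l4, tmp_path):
        a = sd.generate_dataset(
            partition_l4.train_pool, 200, 0.5, 0.2, role="train", seed=77
        )
        b = sd.generate_dataset(
            partition_l4.train_pool, 200, 0.5, 0.2, role="train", seed=77
        )
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        sd.to_csv(a, pa)
        sd.to_csv(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_rejects_bad_inputs(self, partition_l4):
        with pytest.raises(ValueError):
            sd.generate_dataset([], 10, 0.5, 0.0, role="train", seed=0)
        with pytest.raises(ValueError):
            sd.generate_dataset(
                partition_l4.train_pool, 10, 1.5, 0.0, role="train", seed=0
            )

    def test_full_balanced_dataset_pairs_every_strand(self):
        pool = sd.enumerate_strands(3)
        ds = sd.full_balanced_dataset(pool, seed=0)
        assert ds.N == 2 * len(pool)
        t = ds.true_labels()
        assert t.sum() == len(pool)


class TestEncoding:
    @pytest.mark.parametrize(
        "L,loop,pad_each_side", [(10, 4, 0), (8, 4, 2), (5, 4, 5)]
    )
    def test_layout(self, L, loop, pad_each_side):
        rng = np.random.default_rng(0)
        e = sd.make_example("A" * L, loop, positive=True, rng=rng)
        tok = sd.encode(e)
        assert tok.shape == (20 + loop,)
        assert (tok[:pad_each_side] == 0).all()
        assert (tok[len(tok) - pad_each_side :] == 0).all()
        assert (tok[pad_each_side : len(tok) - pad_each_side] != 0).all()

    def test_token_ids_fixed(self):
        e = sd.HairpinExample("ACGU", "GAAA", "ACGU", 0, 0)
        mid = sd.encode(e)[6:-6]
        assert mid.tolist() == [1, 2, 3, 4, 3, 1, 1, 1, 1, 2, 3, 4]

    def test_vectorized_encoding_matches_scalar(self, noisy_train):
        tokens, labels = sd.encode_dataset(noisy_train)
        for i in (0, 5, 399):
            assert tokens[i].tolist() == sd.encode(
                noisy_train.examples[i]
            ).tolist()
        assert labels.tolist() == noisy_train.observed_labels().tolist()

    def test_rejects_overlong(self):
        e = sd.HairpinExample("ACGUA", "GAAA", "ACGUA", 0, 0)
        with pytest.raises(ValueError):
            sd.encode(e, max_strand_length=4)


class TestSerialization:
    def test_fasta_round_trip(self, noisy_train, tmp_path):
        path = tmp_path / "ds.fasta"
        sd.export_fasta(noisy_train, path)
        back = sd.import_fasta(path)
        assert back.N == noisy_train.N
        for a, b in zip(noisy_train.examples, back.examples):
            assert (a.s, a.loop, a.s_bar) == (b.s, b.loop, b.s_bar)
            assert a.observed_label == b.observed_label
            assert a.true_label == b.true_label

    def test_fasta_record_is_plain_concatenation(self, tmp_path):
        e = sd.HairpinExample("AGUCAG", "GAAA", "CUGACU", 1, 1)
        ds = sd.Dataset([e], 6, 1.0, 0.0, "train", 4, 0)
        path = tmp_path / "one.fasta"
        sd.export_fasta(ds, path)
        text = path.read_text()
        assert "AGUCAGGAAACUGACU" in text.replace("\n", "")

    def test_csv_round_trip(self, small_train, tmp_path):
        path = tmp_path / "ds.csv"
        sd.to_csv(small_train, path)
        back = sd.from_csv(path)
        assert [e.s for e in back.examples] == [
            e.s for e in small_train.examples
        ]
        assert back.observed_labels().tolist() == (
            small_train.observed_labels().tolist()
        )
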