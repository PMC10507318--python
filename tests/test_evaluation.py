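"""Thresholded accuracy, the exact oracle, simulations and score probes."""

import numpy as np
import pytest

from comprec import (
    GenParams,
    OracleModel,
    accuracy,
    default_probe_triple,
    mismatch_pairs,
    oracle_classifier,
    probe_scores,
    run_simulation,
    summarize_simulations,
)
from comprec.evaluation import build_simulation_data
from comprec.synthetic_data import (
    Dataset,
    HairpinExample,
    generate_dataset,
    make_example,
)


class _ConstantScorer:
    def __init__(self, value: float):
        self.value = value

    def predict_scores(self, tokens, batch_size: int = 0):
        return np.full(tokens.shape[0], self.value)


class TestOracle:
    def test_worked_positive(self):
        e = HairpinExample("AGUCAG", "GAAA", "CUGACU", 1, 1)
        assert oracle_classifier(e) == 1

    def test_single_mismatch_is_negative(self):
        e = HairpinExample("AGUCAG", "GAAA", "CUGACC", 0, 0)
        assert oracle_classifier(e) == 0

    def test_agrees_with_generator_on_100k_examples(self):
        # generator and oracle implement the predicate independently
        rng = np.random.default_rng(0)
        strands = ["ACGUA", "GGGGG", "AUCGU", "CCAUG"]
        n_checked = 0
        for i in range(100_000):
            e = make_example(strands[i % 4], 4, positive=bool(i % 2), rng=rng)
            assert oracle_classifier(e) == e.true_label
            n_checked += 1
        assert n_checked == 100_000

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            HairpinExample("ACG", "GAAA", "AC", 0, 0)


class TestAccuracy:
    def test_oracle_is_perfect_on_clean_data(self, small_test):
        res = accuracy(OracleModel(small_test), small_test)
        assert res.accuracy == 1.0
        assert res.n_correct == small_test.N

    def test_oracle_lands_at_one_minus_mu_on_noisy_labels(self, partition_l4):
        mu, N = 0.2, 10_000
        ds = generate_dataset(
            partition_l4.train_pool, N, 0.5, mu, role="train", seed=13
        )
        res = accuracy(OracleModel(ds), ds)
        sigma = np.sqrt(mu * (1 - mu) / N)
        assert abs(res.accuracy - (1 - mu)) < 3 * sigma

    def test_constant_high_score_scores_half_on_balanced_set(self, small_test):
        assert accuracy(_ConstantScorer(0.99), small_test).accuracy == 0.5

    def test_threshold_tie_counts_as_negative(self, small_test):
        res = accuracy(_ConstantScorer(0.5), small_test, theta=0.5)
        # all predicted negative: exactly the negative half is correct
        assert res.accuracy == 0.5

    def test_complement_scorer_sums_to_one(self, small_test):
        class Flip:
            def __init__(self, inner):
                self.inner = inner

            def predict_scores(self, tokens, batch_size: int = 0):
                return 1.0 - self.inner.predict_scores(tokens)

        scorer = _ConstantScorer(0.73)
        a = accuracy(scorer, small_test).accuracy
        b = accuracy(Flip(scorer), small_test).accuracy
        assert a + b == pytest.approx(1.0)

    def test_empty_dataset_raises(self):
        ds = Dataset([], 4, 0.5, 0.0, "test", 4, 0)
        with pytest.raises(ValueError):
            accuracy(_ConstantScorer(0.5), ds)


class TestSimulation:
    def test_end_to_end_determinism(self):
        gp = GenParams(L_train=4, N=300, alpha=0.5, mu=0.1)
        a = run_simulation("MLP", 2.70, gp, rep_seed=21)
        b = run_simulation("MLP", 2.70, gp, rep_seed=21)
        assert a[0].accuracy == b[0].accuracy
        assert a[1].accuracy == b[1].accuracy

    def test_degenerate_tiny_run_completes(self):
        gp = GenParams(L_train=3, N=8, alpha=0.5, mu=0.0, test_size=16)
        tr, te = run_simulation("MLP", 2.70, gp, rep_seed=2)
        assert 0.0 <= tr.accuracy <= 1.0
        assert 0.0 <= te.accuracy <= 1.0

    def test_train_test_pools_disjoint_within_length(self):
        gp = GenParams(L_train=4, N=200, alpha=0.5, mu=0.0, test_size=100)
        train_ds, test_ds = build_simulation_data(gp, rep_seed=3)
        assert not {e.s for e in train_ds.examples} & {
            e.s for e in test_ds.examples
        }

    def test_extrapolation_evaluates_on_full_balanced_set(self):
        gp = GenParams(L_train=3, N=100, alpha=0.5, mu=0.0, L_test=5)
        _, test_ds = build_simulation_data(gp, rep_seed=4)
        assert test_ds.N == 2 * 4**5
        assert test_ds.true_labels().sum() == 4**5

    def test_summary_statistics_consistent(self):
        gp = GenParams(L_train=4, N=256, alpha=0.5, mu=0.0, test_size=200)
        summary = summarize_simulations(
            "MLP", 2.70, gp, repetitions=3, base_seed=30
        )
        stats = summary.test
        accs = summary.test_accuracies
        assert summary.repetitions == 3
        assert stats["min"] <= stats["mean"] <= stats["max"]
        assert stats["mean"] == pytest.approx(np.mean(accs))
        assert (stats["sd"] == 0) == (len(set(accs)) == 1)


class TestProbes:
    def test_default_triple_matches_canonical_sequences(self):
        pos, upper, lower = default_probe_triple()
        assert pos.sequence == "ACGUACGUGAAAACGUACGU"
        assert pos.true_label == 1
        # the upper-pairs probe is the canonical misclassified sequence
        assert upper.sequence == "ACGUACGUGAAAACGUAGCA"
        assert upper.true_label == 0
        assert lower.sequence == "ACGUACGUGAAAAGCAACGU"
        assert lower.true_label == 0

    def test_mismatch_positions_counted_from_loop(self):
        pos = default_probe_triple()[0]
        broken = mismatch_pairs(pos, [1])
        # pair 1 is s_L . s_bar_1: only the first s_bar base changes
        assert broken.s_bar[0] != pos.s_bar[0]
        assert broken.s_bar[1:] == pos.s_bar[1:]
        assert broken.true_label == 0

    def test_mismatching_always_breaks_the_pair(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            e = make_example("ACGUAC", 4, positive=True, rng=rng)
            p = int(rng.integers(1, 7))
            assert oracle_classifier(mismatch_pairs(e, [p])) == 0

    def test_scores_shape_and_range(self):
        from comprec.models import ArchitectureSpec, build_model

        models = [
            build_model(ArchitectureSpec.from_level("MLP", 2.70), seed=s)
            for s in range(3)
        ]
        for m in models:
            m.eval()
        res = probe_scores(models)
        assert res.scores.shape == (3, 3)
        assert ((res.scores > 0) & (res.scores < 1)).all()
        assert res.mean_scores().shape == (3,)
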