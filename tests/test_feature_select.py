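import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays

from snptrace import (
    GenotypeMatrix,
    compare_rankings,
    dnn_importance,
    garson_importance,
    olden_importance,
    select_snps,
    selection_threshold,
)
from snptrace.feature_select import ImportanceRanking, default_training_config
from snptrace.neuralnet import NetworkWeights, TrainingConfig


def _net(W, V, b1=None, b2=None):
    W, V = np.asarray(W, float), np.asarray(V, float)
    return NetworkWeights(
        [W.shape[0], W.shape[1], V.shape[1]],
        [W, V],
        [np.zeros(W.shape[1]) if b1 is None else b1,
         np.zeros(V.shape[1]) if b2 is None else b2],
    )


class TestDnnImportance:
    def test_max_of_absolutes(self):
        net = _net([[-3.0, 1.0]], [[1.0], [1.0]])
        assert dnn_importance(net)[0] == pytest.approx(3.0)

    def test_all_zero_weights(self):
        net = _net(np.zeros((4, 2)), np.zeros((2, 1)))
        np.testing.assert_array_equal(dnn_importance(net), 0.0)

    def test_brute_force_columnwise_max(self):
        rng = np.random.default_rng(2)
        W = rng.normal(size=(3, 5))
        net = _net(W, rng.normal(size=(5, 2)))
        brute = [max(abs(W[j, h]) for h in range(5)) for j in range(3)]
        np.testing.assert_allclose(dnn_importance(net), brute)

    def test_invariant_to_hidden_permutation(self):
        rng = np.random.default_rng(3)
        W = rng.normal(size=(6, 4))
        perm = rng.permutation(4)
        np.testing.assert_allclose(
            dnn_importance(_net(W, np.ones((4, 1)))),
            dnn_importance(_net(W[:, perm], np.ones((4, 1)))),
        )


class TestSelectionThreshold:
    def test_constant_weights_select_nothing(self):
        c = 0.7
        net = _net(np.full((5, 3), c), np.ones((3, 1)))
        tau = selection_threshold(net)
        assert tau == pytest.approx(c)
        assert not np.any(dnn_importance(net) > tau)  # strict rule

    def test_hand_arithmetic_1_2_3(self):
        """|W| = {1,2,3}: tau = 2 + sqrt(2/3) with population variance."""
        net = _net(np.array([[1.0], [-2.0], [3.0]]), np.ones((1, 1)))
        assert selection_threshold(net) == pytest.approx(2.0 + math.sqrt(2.0 / 3.0))

    def test_per_input_max_statistic(self):
        # per-input maxima {2, 4}: mean 3, population sd 1 -> tau = 4
        W = np.array([[1.0, -2.0], [4.0, 3.0]])
        net = _net(W, np.ones((2, 1)))
        assert selection_threshold(net, statistic="per_input_max") == pytest.approx(4.0)
        with pytest.raises(ValueError, match="statistic"):
            selection_threshold(net, statistic="median")

    @given(
        c=st.floats(min_value=0.1, max_value=50.0),
        W=arrays(float, (4, 3), elements=st.floats(-5, 5, allow_nan=False)),
    )
    def test_positive_scaling_homogeneity(self, c, W):
        net1 = _net(W, np.ones((3, 1)))
        net2 = _net(c * W, np.ones((3, 1)))
        assert selection_threshold(net2) == pytest.approx(
            c * selection_threshold(net1), rel=1e-9, abs=1e-12
        )


class TestGarson:
    def test_single_path_normalizes_to_one(self):
        net = _net([[2.5]], [[-1.0]])
        assert garson_importance(net)[0] == pytest.approx(1.0)

    def test_hand_shares_quarter_three_quarters(self):
        net = _net([[1.0], [3.0]], [[2.0]])
        np.testing.assert_allclose(garson_importance(net), [0.25, 0.75])

    def test_two_hidden_hand_computation(self):
        # inputs x hidden |w|: [[1, 2], [3, 2]]; |v| = [1, 1]
        # shares per hidden: h1 -> (0.25, 0.75); h2 -> (0.5, 0.5)
        # contributions: input1 = 0.75, input2 = 1.25 -> normalized (0.375, 0.625)
        net = _net([[1.0, 2.0], [3.0, -2.0]], [[1.0], [-1.0]])
        np.testing.assert_allclose(garson_importance(net), [0.375, 0.625])

    def test_dead_hidden_unit_contributes_zero(self):
        net = _net([[1.0, 0.0], [3.0, 0.0]], [[1.0], [5.0]])
        imp = garson_importance(net)
        assert np.isfinite(imp).all()
        np.testing.assert_allclose(imp, [0.25, 0.75])

    def test_rejects_two_hidden_layers(self):
        net = NetworkWeights(
            [2, 3, 2, 1],
            [np.ones((2, 3)), np.ones((3, 2)), np.ones((2, 1))],
            [np.zeros(3), np.zeros(2), np.zeros(1)],
        )
        with pytest.raises(ValueError, match="single-hidden-layer"):
            garson_importance(net)

    @given(
        W=arrays(float, (5, 3), elements=st.floats(-4, 4, allow_nan=False)),
        V=arrays(float, (3, 2), elements=st.floats(-4, 4, allow_nan=False)),
    )
    def test_scores_nonnegative_sum_to_one(self, W, V):
        net = _net(W, V)
        imp = garson_importance(net)
        assert np.all(imp >= 0)
        total = imp.sum()
        # degenerate all-zero networks yield an all-zero score vector
        assert total == pytest.approx(1.0, abs=1e-12) or total == 0.0


class TestOlden:
    def test_single_path_signed_product(self):
        net = _net([[2.0]], [[-3.0]])
        assert olden_importance(net)[0] == pytest.approx(-6.0)

    def test_two_hidden_hand_computation(self):
        net = _net([[1.0, -2.0]], [[3.0], [1.0]])
        assert olden_importance(net)[0] == pytest.approx(1.0)

    def test_negating_output_weights_negates_importance(self):
        rng = np.random.default_rng(5)
        W, V = rng.normal(size=(4, 3)), rng.normal(size=(3, 2))
        np.testing.assert_allclose(
            olden_importance(_net(W, -V)), -olden_importance(_net(W, V))
        )

    def test_equals_collapsed_linear_map(self):
        """With multiple outputs, olden averages the per-output products
        W @ V — the input-to-output coefficients of the collapsed linear map."""
        rng = np.random.default_rng(6)
        W, V = rng.normal(size=(6, 4)), rng.normal(size=(4, 3))
        np.testing.assert_allclose(olden_importance(_net(W, V)), (W @ V).mean(axis=1))


class TestSelectSnps:
    def test_determinism(self, sim_study):
        _, _, _, G = sim_study
        sub = G.take_snps(range(100))
        r1 = select_snps(sub, "dnn", chunk_size=100)
        r2 = select_snps(sub, "dnn", chunk_size=100)
        np.testing.assert_array_equal(r1.scores, r2.scores)
        assert r1.selected == r2.selected

    def test_planted_recovery_all_methods(self, sim_study, sim_rankings):
        """Planted discriminant SNPs dominate each method's top-100 far above
        the ~5% chance rate."""
        _, _, planted, G = sim_study
        planted_set = set(planted) & set(G.snp_ids)
        chance = 100 * len(planted_set) / G.n_snps
        for method, rk in sim_rankings.items():
            hits = len(set(rk.top(100)) & planted_set)
            assert hits >= 5 * chance, f"{method}: {hits} planted in top-100"

    @pytest.mark.parametrize("method", ["dnn", "garson", "olden"])
    def test_uninformative_snp_ranks_low(self, sim_study, method):
        """A SNP with identical frequency in all breeds carries no label
        signal; among genuinely discriminant markers its score, averaged
        over retrainings, falls in the lower half of the ranking."""
        _, _, planted, G = sim_study
        sub = G.select_snp_ids([s for s in G.snp_ids if s in set(planted)])
        flat_id = "flat_snp"
        rng = np.random.default_rng(17)
        flat = rng.binomial(2, 0.5, size=(sub.n_samples, 1)).astype(np.int16)
        G2 = GenotypeMatrix(
            list(sub.samples), list(sub.breeds), sub.snp_ids + [flat_id],
            np.hstack([sub.dosages, flat]),
        )
        rk = select_snps(G2, method, chunk_size=G2.n_snps, n_iterations=10)
        pos = rk.top(G2.n_snps).index(flat_id)
        assert pos > G2.n_snps // 2

    def test_causal_inputs_recovered_from_linear_signal(self):
        """Noiseless linear signal through 3 of 20 inputs: every method puts
        the causal inputs in the top 5 in >= 9 of 10 seeded replicates."""
        n, p = 120, 20
        causal = [2, 7, 15]
        wins = {m: 0 for m in ("dnn", "garson", "olden")}
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.integers(0, 3, size=(n, p))
            y = X[:, causal] @ np.array([2.0, -1.5, 1.0])
            labels = np.where(y > np.median(y), "hi", "lo").tolist()
            G = GenotypeMatrix(
                [f"s{i}" for i in range(n)], labels,
                [f"v{j}" for j in range(p)], X.astype(np.int16),
            )
            for method in wins:
                cfg = default_training_config(method, seed=seed, hidden_layers=(8,),
                                              learning_rate=2.0, max_epochs=1500)
                rk = select_snps(G, method, cfg, chunk_size=p)
                top5 = set(rk.top(5))
                if all(f"v{j}" in top5 for j in causal):
                    wins[method] += 1
        for method, w in wins.items():
            assert w >= 9, f"{method}: causal trio in top-5 only {w}/10 times"


class TestCompareRankings:
    def _rk(self, method, ids, scores):
        return ImportanceRanking(method, ids, np.asarray(scores, float))

    def test_self_comparison_is_identity(self):
        ids = [f"s{i}" for i in range(10)]
        scores = np.arange(10)[::-1].astype(float)
        df = compare_rankings([self._rk("dnn", ids, scores), self._rk("garson", ids, scores / 10)], top_n=4)
        row = df.iloc[0]
        assert row["common"] == 4
        assert row["spearman"] == pytest.approx(1.0)

    def test_hand_built_partial_overlap(self):
        ids = ["a", "b", "c", "d"]
        ra = self._rk("dnn", ids, [4.0, 3.0, 2.0, 1.0])    # top-3 {a,b,c}
        rb = self._rk("garson", ids, [0.1, 0.3, 0.4, 0.2])  # top-3 {c,b,d}
        df = compare_rankings([ra, rb], top_n=3)
        row = df.iloc[0]
        assert row["common"] == 2  # {b, c}
        # scores over {b, c}: a-ranking (3, 2) vs b-ranking (0.3, 0.4) -> opposed
        assert row["spearman"] == pytest.approx(-1.0)

    def test_reversed_scores_anticorrelate(self):
        ids = [f"s{i}" for i in range(6)]
        scores = np.arange(6, dtype=float)
        df = compare_rankings(
            [self._rk("dnn", ids, scores), self._rk("garson", ids, scores[::-1] / 10)],
            top_n=6,
        )
        assert df.iloc[0]["spearman"] == pytest.approx(-1.0)

    def test_empty_overlap_is_undefined_not_zero(self):
        ids = ["a", "b", "c", "d"]
        ra = self._rk("dnn", ids, [4.0, 3.0, 1.0, 0.0])
        rb = self._rk("garson", ids, [0.0, 0.1, 0.8, 0.9])
        df = compare_rankings([ra, rb], top_n=2)
        assert math.isnan(df.iloc[0]["spearman"])

    def test_different_universes_rejected(self):
        ra = self._rk("dnn", ["a", "b"], [1.0, 0.0])
        rb = self._rk("garson", ["a", "c"], [1.0, 0.0])
        with pytest.raises(ValueError, match="universe"):
            compare_rankings([ra, rb], top_n=2)


class TestRankingContainer:
    def test_dense_ranks_and_stable_ties(self):
        rk = ImportanceRanking("dnn", ["a", "b", "c", "d"], np.array([2.0, 3.0, 2.0, 1.0]))
        np.testing.assert_array_equal(rk.ranks, [2, 1, 2, 3])
        assert rk.top(3) == ["b", "a", "c"]  # tie a/c broken by panel order

    def test_olden_ranks_by_magnitude(self):
        rk = ImportanceRanking("olden", ["a", "b", "c"], np.array([-5.0, 2.0, 1.0]))
        assert rk.top(2) == ["a", "b"]

    def test_tsv_round_trip(self, tmp_path):
        rk = ImportanceRanking("garson", ["a", "b"], np.array([0.25, 0.75]), selected=["b"])
        path = tmp_path / "rk.tsv"
        rk.to_tsv(path)
        back = ImportanceRanking.from_tsv(path)
        assert back.method == "garson"
        assert back.selected == ["b"]
        np.testing.assert_allclose(back.scores, rk.scores)
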