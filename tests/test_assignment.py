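import math

import numpy as np
import pytest

from snptrace import (
    MISSING,
    GenotypeMatrix,
    PopulationFrequencies,
    assign,
    assign_matrix,
    estimate_frequencies,
    evaluate_success,
    genotype_loglik,
    minimal_marker_counts,
)
from snptrace.assignment import results_to_frame
from snptrace.feature_select import ImportanceRanking


def _freqs(breeds, snp_ids, rows):
    return PopulationFrequencies(breeds, snp_ids, np.asarray(rows, float))


class TestFrequencyEstimation:
    def test_raw_frequency_half(self):
        G2 = GenotypeMatrix(
            ["a", "b", "c", "d"], ["x", "x", "y", "y"], ["s1"],
            np.array([[0], [2], [1], [1]]),
        )
        fr = estimate_frequencies(G2, smooth=False)
        assert fr.freq[0, 0] == pytest.approx(0.5)
        assert fr.freq[1, 0] == pytest.approx(0.5)

    def test_breed_with_one_sample_rejected(self):
        G = GenotypeMatrix(
            ["a", "b", "c"], ["x", "x", "y"], ["s1"], np.array([[0], [2], [1]])
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            estimate_frequencies(G)

    def test_monomorphic_breed_smoothed_off_boundary(self):
        G = GenotypeMatrix(
            ["a", "b", "c", "d"], ["x", "x", "y", "y"], ["s1"],
            np.array([[0], [0], [2], [2]]),
        )
        fr = estimate_frequencies(G, smooth=True)
        # n = 2 samples -> bound 1/(2*2+2) = 1/6
        assert fr.freq[0, 0] == pytest.approx(1.0 / 6.0)
        assert fr.freq[1, 0] == pytest.approx(5.0 / 6.0)

    def test_undefined_cell_is_nan(self):
        G = GenotypeMatrix(
            ["a", "b", "c", "d"], ["x", "x", "y", "y"], ["s1"],
            np.array([[MISSING], [MISSING], [0], [2]]),
        )
        fr = estimate_frequencies(G, smooth=True)
        assert math.isnan(fr.freq[0, 0])
        assert fr.freq[1, 0] == pytest.approx(0.5)

    def test_leave_one_out_recount(self):
        """Removing the focal dosage-2 sample from breed {2, 2, 0} leaves
        counts 2/4 -> frequency 0.5."""
        G = GenotypeMatrix(
            ["a", "b", "c", "d", "e"],
            ["x", "x", "x", "y", "y"],
            ["s1"],
            np.array([[2], [2], [0], [1], [1]]),
        )
        res = assign_matrix(G, G, leave_one_out=True)
        # focal sample 'a' (dosage 2): LOO x-frequency 0.5 -> loglik log10(0.25)
        r = res[0]
        x_idx = r.breeds.index("x")
        assert r.loglik[x_idx] == pytest.approx(math.log10(0.25))


class TestGenotypeLoglik:
    def test_hand_arithmetic_single_locus(self):
        fr = _freqs(["x", "y"], ["s1"], [[0.5], [0.9]])
        ll = genotype_loglik(np.array([2]), fr)
        assert ll[0] == pytest.approx(math.log10(0.25))
        assert ll[1] == pytest.approx(math.log10(0.81))

    def test_symmetric_frequencies_give_equal_logliks(self):
        fr = _freqs(["x", "y", "z"], ["s1", "s2"], [[0.3, 0.7]] * 3)
        ll = genotype_loglik(np.array([1, 2]), fr)
        assert np.allclose(ll, ll[0])

    def test_shared_locus_cancels_in_llr(self):
        fr1 = _freqs(["x", "y"], ["s1"], [[0.8], [0.2]])
        fr2 = _freqs(["x", "y"], ["s1", "s2"], [[0.8, 0.6], [0.2, 0.6]])
        ll1 = genotype_loglik(np.array([2]), fr1)
        ll2 = genotype_loglik(np.array([2, 1]), fr2)
        assert (ll1[0] - ll1[1]) == pytest.approx(ll2[0] - ll2[1])

    def test_missing_locus_skipped(self):
        fr = _freqs(["x", "y"], ["s1", "s2"], [[0.5, 0.9], [0.5, 0.1]])
        ll = genotype_loglik(np.array([2, MISSING]), fr)
        assert ll[0] == pytest.approx(math.log10(0.25))
        assert ll[1] == pytest.approx(math.log10(0.25))

    def test_all_loci_unusable_errors(self):
        fr = _freqs(["x", "y"], ["s1"], [[0.5], [0.5]])
        with pytest.raises(ValueError, match="no usable locus"):
            genotype_loglik(np.array([MISSING]), fr)

    def test_logliks_are_nonpositive(self, sim_study):
        _, _, _, G = sim_study
        fr = estimate_frequencies(G)
        for i in range(0, G.n_samples, 30):
            assert np.all(genotype_loglik(G.dosages[i], fr) <= 0.0)

    def test_brute_force_toy_oracle(self):
        """3 breeds x 5 SNPs: vectorized logliks match an independent
        per-locus hand computation."""
        rng = np.random.default_rng(8)
        freq = rng.uniform(0.1, 0.9, size=(3, 5))
        fr = _freqs(["x", "y", "z"], [f"s{j}" for j in range(5)], freq)
        dosage = np.array([0, 1, 2, 1, 0])
        ll = genotype_loglik(dosage, fr)
        for b in range(3):
            expected = 0.0
            for j, d in enumerate(dosage):
                p = freq[b, j]
                prob = {0: (1 - p) ** 2, 1: 2 * p * (1 - p), 2: p**2}[int(d)]
                expected += math.log10(prob)
            assert ll[b] == pytest.approx(expected, abs=1e-10)


class TestAssign:
    def test_hand_llr_and_stringency(self):
        """dosage 2 at one locus, p = 0.8 vs 0.2: LLR = log10(0.64/0.04)
        ~ 1.204 -> passes level 1, fails level 2."""
        fr = _freqs(["x", "y"], ["s1"], [[0.8], [0.2]])
        r = assign("samp", "x", np.array([2]), fr)
        assert r.assigned_breed == "x"
        assert r.llr == pytest.approx(math.log10(0.64 / 0.04), abs=1e-9)
        assert r.passed[1] and not r.passed[2]

    def test_single_breed_reference_rejected(self):
        fr = _freqs(["x"], ["s1"], [[0.5]])
        with pytest.raises(ValueError, match="at least 2"):
            assign("samp", "x", np.array([2]), fr)

    def test_identical_frequencies_fail_everything(self):
        fr = _freqs(["x", "y"], ["s1", "s2"], [[0.4, 0.6], [0.4, 0.6]])
        r = assign("samp", "x", np.array([1, 1]), fr)
        assert r.llr == pytest.approx(0.0)
        assert r.tie
        assert not any(r.passed.values())
        assert r.assigned_breed == "x"  # deterministic breed-order tie-break

    def test_llr_nonnegative_by_construction(self, sim_study):
        _, _, _, G = sim_study
        res = assign_matrix(G.take_samples(range(0, 150, 10)), G, leave_one_out=False)
        assert all(r.llr >= 0 for r in res)

    def test_llr_true_negative_on_misassignment(self):
        fr = _freqs(["x", "y"], ["s1"], [[0.2], [0.8]])
        r = assign("samp", "x", np.array([2]), fr)
        assert r.assigned_breed == "y"
        assert r.llr_true == pytest.approx(-r.llr)

    def test_leave_one_out_deflates_true_breed_loglik(self, sim_study):
        """On average the LOO log-likelihood of the true breed cannot exceed
        the resubstitution one (no self-inflation)."""
        _, _, _, G = sim_study
        sub = G.take_snps(range(100))
        loo = assign_matrix(sub, sub, leave_one_out=True)
        resub = assign_matrix(sub, sub, leave_one_out=False)
        def true_ll(res):
            return np.array([r.loglik[r.breeds.index(r.true_breed)] for r in res])
        assert true_ll(loo).mean() <= true_ll(resub).mean()


class TestEvaluateSuccess:
    def _ranking(self, G):
        rng = np.random.default_rng(0)
        return ImportanceRanking("dnn", list(G.snp_ids), rng.random(G.n_snps))

    def test_levels_are_nested(self, sim_study):
        _, _, _, G = sim_study
        sub = G.take_samples(range(0, 150, 3))
        rk = self._ranking(sub)
        df = evaluate_success(sub, rk, [20, 60], leave_one_out=True)
        for k, grp in df.groupby("k"):
            pct = grp.sort_values("level")["pct_pass"].to_numpy()
            assert np.all(np.diff(pct) <= 1e-12)

    def test_unsorted_counts_rejected(self, toy_matrix):
        rk = self._ranking(toy_matrix)
        with pytest.raises(ValueError, match="ascending"):
            evaluate_success(toy_matrix, rk, [3, 2])

    def test_count_exceeding_panel_rejected(self, toy_matrix):
        rk = self._ranking(toy_matrix)
        with pytest.raises(ValueError, match="exceeds"):
            evaluate_success(toy_matrix, rk, [5])

    def test_minimal_marker_counts_reads_grid(self):
        import pandas as pd

        success = pd.DataFrame(
            {
                "method": ["dnn"] * 4,
                "k": [10, 20, 10, 20],
                "level": [1, 1, 2, 2],
                "n_pass": [0, 0, 0, 0],
                "pct_pass": [60.0, 95.0, 40.0, 60.0],
                "n_total": [100] * 4,
            }
        )
        mk = minimal_marker_counts(success, target_rates=(70.0, 90.0))
        got = {(r.level, r.target_pct): r.min_k for r in mk.itertuples()}
        assert got[(1, 70.0)] == 20 and got[(1, 90.0)] == 20
        assert math.isnan(got[(2, 70.0)]) and math.isnan(got[(2, 90.0)])

    def test_results_frame_columns(self, sim_study):
        _, _, _, G = sim_study
        sub = G.take_samples(range(10))
        sub = GenotypeMatrix(sub.samples, ["x"] * 5 + ["y"] * 5, sub.snp_ids, sub.dosages)
        df = results_to_frame(assign_matrix(sub, sub, leave_one_out=True))
        assert {"sample_id", "assigned_breed", "llr", "pass_llr_gt_1"} <= set(df.columns)
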