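import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from deducemeth.diffmeth import (
    FragmentTestResult,
    ModerationParams,
    adjust_fdr,
    combine_fragment_pvalues,
    moderated_t_test,
    rank_fragments,
    select_top_fragments,
    evaluate_fragments,
)
from .oracles import bh_adjust, pooled_t_two_sample, worst_of_three_ranking


def _two_group_matrix(data: np.ndarray) -> tuple[pd.DataFrame, dict]:
    n = data.shape[1] // 2
    cols = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
    return pd.DataFrame(data, columns=cols), {
        "g1": cols[:n],
        "g2": cols[n:],
    }


class TestModeratedT:
    def test_identical_group_means_give_t_zero_p_one(self):
        data = np.tile([0.2, 0.4, 0.2, 0.4], (5, 2)).reshape(5, 8)[:, :8]
        data = np.column_stack([data[:, :4], data[:, :4]])
        matrix, groups = _two_group_matrix(data)
        # add variation on other rows so the prior is estimable
        rng = np.random.default_rng(1)
        noise = rng.uniform(0, 1, size=(30, 8))
        matrix = pd.concat([matrix, _two_group_matrix(noise)[0]], ignore_index=True)
        results = moderated_t_test(matrix, groups)
        for r in results[:5]:
            assert r.t_statistic == 0.0
            assert r.p_value == 1.0

    def test_zero_prior_df_equals_textbook_pooled_t(self, rng):
        data = rng.uniform(0, 1, size=(50, 8))
        matrix, groups = _two_group_matrix(data)
        results = moderated_t_test(
            matrix, groups, ModerationParams(prior_df=0.0, prior_variance=1.0)
        )
        for i, r in enumerate(results):
            t_ref, p_ref = pooled_t_two_sample(list(data[i, :4]), list(data[i, 4:]))
            assert r.t_statistic == pytest.approx(t_ref, abs=1e-10)
            assert r.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_matches_limma_ebayes(self, tmp_path):
        """The moderated t and its p-values agree with limma to numerical
        precision on a matrix with heterogeneous variances."""
        rng = np.random.default_rng(11)
        scales = rng.choice([0.05, 0.1, 0.3], size=60)
        data = rng.normal(0.5, 1.0, size=(60, 8)) * scales[:, None]
        matrix, groups = _two_group_matrix(data)
        results = moderated_t_test(matrix, groups)
        in_path = tmp_path / "matrix.tsv"
        matrix.to_csv(in_path, sep="\t", index=False)
        out_path = tmp_path / "limma.tsv"
        script = f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.delim('{in_path}'))
        fit <- eBayes(lmFit(x, cbind(1, c(rep(1,4), rep(0,4)))))
        write.table(data.frame(t=fit$t[,2], p=fit$p.value[,2]),
                    '{out_path}', sep='\\t', row.names=FALSE)
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(out_path, sep="\t")
        t_mine = np.array([r.t_statistic for r in results])
        p_mine = np.array([r.p_value for r in results])
        assert np.allclose(t_mine, ref["t"], atol=1e-8)
        assert np.allclose(p_mine, ref["p"], atol=1e-8)

    def test_insufficient_replication_errors(self):
        matrix = pd.DataFrame(np.ones((5, 3)), columns=["a0", "a1", "b0"])
        with pytest.raises(ValueError, match="insufficient replication"):
            moderated_t_test(matrix, {"g1": ["a0", "a1"], "g2": ["b0"]})

    def test_all_null_type_one_error_calibrated(self, rng):
        """All-null binomial simulation: the fraction of p < 0.05 stays within
        3 binomial SEs of 0.05."""
        n_sites, cov = 1000, 30
        data = rng.binomial(cov, 0.5, size=(n_sites, 8)) / cov
        matrix, groups = _two_group_matrix(data)
        results = moderated_t_test(matrix, groups)
        frac = np.mean([r.p_value < 0.05 for r in results])
        se = np.sqrt(0.05 * 0.95 / n_sites)
        assert abs(frac - 0.05) < 3 * se


class TestFDR:
    def test_hand_computed_example(self):
        assert adjust_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert adjust_fdr([0.3]) == [0.3]

    def test_all_ones_stay_one(self):
        assert adjust_fdr([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, size=rng.integers(1, 200))
            assert np.allclose(adjust_fdr(p), bh_adjust(list(p)), atol=1e-12)

    def test_stable_under_input_order(self, rng):
        p = list(rng.uniform(0, 1, size=50))
        adjusted = adjust_fdr(p)
        perm = rng.permutation(50)
        adjusted_perm = adjust_fdr([p[i] for i in perm])
        for j, i in enumerate(perm):
            assert adjusted_perm[j] == pytest.approx(adjusted[i])


class TestCombination:
    def test_single_site_identity(self):
        for method in ("fisher", "weighted"):
            assert combine_fragment_pvalues([0.07], method=method) == pytest.approx(0.07)

    def test_fisher_worked_example(self):
        # X = -2(ln .05 + ln .05) ~= 11.98, df 4
        p = combine_fragment_pvalues([0.05, 0.05], method="fisher")
        x = -2 * (np.log(0.05) + np.log(0.05))
        assert p == pytest.approx(stats.chi2.sf(x, 4))
        assert p == pytest.approx(0.0175, abs=5e-4)

    def test_weighted_equal_weights_reduces_to_fisher(self, rng):
        for _ in range(50):
            p = rng.uniform(0.001, 1, size=rng.integers(2, 6))
            fisher = combine_fragment_pvalues(p, method="fisher")
            weighted = combine_fragment_pvalues(p, weights=np.ones(len(p)), method="weighted")
            assert weighted == pytest.approx(fisher, rel=1e-9)

    def test_monotone_in_member_pvalues(self, rng):
        p = [0.2, 0.5, 0.8]
        w = [1.0, 2.0, 3.0]
        base = combine_fragment_pvalues(p, w)
        for i in range(3):
            smaller = list(p)
            smaller[i] = p[i] / 2
            assert combine_fragment_pvalues(smaller, w) <= base

    def test_zero_p_clamped_not_fatal(self):
        assert 0.0 <= combine_fragment_pvalues([0.0, 0.5]) < 1e-6


class TestRanking:
    def _frag(self, fid, p, lfc, diff, cov=3.0):
        return FragmentTestResult(fid, p, diff, lfc, cov)

    def test_worst_of_three_rule(self):
        frags = [
            self._frag("a", 0.001, 2.0, 0.1),   # best p, best lfc, worst diff
            self._frag("b", 0.01, 1.0, 0.4),
            self._frag("c", 0.05, 0.5, 0.2),
        ]
        ranked = rank_fragments(frags)
        by_id = {r.fragment_id: r for r in ranked}
        assert by_id["a"].combined_rank == max(
            by_id["a"].rank_p, by_id["a"].rank_lfc, by_id["a"].rank_diff
        )
        assert by_id["a"].rank_p == 1
        assert by_id["a"].rank_diff == 3

    def test_best_in_all_three_is_rank_one(self):
        frags = [
            self._frag("top", 0.001, 3.0, 0.5),
            self._frag("x", 0.01, 1.0, 0.2),
            self._frag("y", 0.5, 0.1, 0.05),
        ]
        ranked = rank_fragments(frags)
        assert ranked[0].fragment_id == "top"
        assert ranked[0].combined_rank == 1

    def test_matches_brute_force_ordering(self, rng):
        for _ in range(10):
            frags = [
                self._frag(f"f{i}", float(rng.uniform(0, 1)), float(rng.uniform(0, 3)),
                           float(rng.uniform(0, 0.6)))
                for i in range(7)
            ]
            ranked = rank_fragments(frags)
            oracle = worst_of_three_ranking(
                [(f.fragment_id, f.combined_p, abs(f.log_fold_change), abs(f.mean_diff))
                 for f in frags]
            )
            assert [r.fragment_id for r in ranked] == oracle

    def test_ties_share_minimum_rank(self):
        frags = [
            self._frag("a", 0.01, 1.0, 0.3),
            self._frag("b", 0.01, 1.0, 0.3),
            self._frag("c", 0.5, 0.2, 0.1),
        ]
        ranked = rank_fragments(frags)
        by_id = {r.fragment_id: r for r in ranked}
        assert by_id["a"].rank_p == by_id["b"].rank_p == 1
        assert by_id["c"].rank_p == 3


class TestSelection:
    def _ranked(self):
        frags = [
            FragmentTestResult("keep", 0.049, 0.3, 1.0, mean_coverage=3.0),
            FragmentTestResult("cov_at_gate", 0.01, 0.3, 1.0, mean_coverage=2.0),
            FragmentTestResult("p_at_gate", 0.05, 0.3, 1.0, mean_coverage=3.0),
            FragmentTestResult("down", 0.001, -0.4, -1.2, mean_coverage=5.0),
        ]
        return rank_fragments(frags)

    def test_gates_are_strict(self):
        seqs = {f: "ACGT" for f in ("keep", "cov_at_gate", "p_at_gate", "down")}
        out = select_top_fragments(self._ranked(), seqs)
        chosen = {fid for recs in out.values() for fid, _ in recs}
        assert "keep" in chosen and "down" in chosen
        assert "cov_at_gate" not in chosen  # coverage must be strictly > 2
        assert "p_at_gate" not in chosen  # p must be strictly < 0.05

    def test_direction_split(self):
        seqs = {f: "ACGT" for f in ("keep", "cov_at_gate", "p_at_gate", "down")}
        out = select_top_fragments(self._ranked(), seqs)
        assert [fid for fid, _ in out["hyper_group1"]] == ["keep"]
        assert [fid for fid, _ in out["hyper_group2"]] == ["down"]

    def test_fewer_than_n_returns_all(self):
        seqs = {f: "ACGT" for f in ("keep", "cov_at_gate", "p_at_gate", "down")}
        out = select_top_fragments(self._ranked(), seqs, n=500)
        assert sum(len(v) for v in out.values()) == 2

    def test_zero_passing_warns_not_errors(self):
        ranked = rank_fragments([FragmentTestResult("x", 0.9, 0.0, 0.0, mean_coverage=1.0)])
        with pytest.warns(UserWarning):
            out = select_top_fragments(ranked, {"x": "ACGT"})
        assert all(not v for v in out.values())


class TestPlantedSignal:
    def test_planted_fragments_recovered_in_top_ranks(self, rng):
        """1000 fragments (3 CpGs each), 50 planted with a 0.4 methylation
        difference at coverage 30: at least 90% of planted fragments reach
        the top-100 combined ranks."""
        n_frag, n_planted, sites_per_frag, cov = 1000, 50, 3, 30
        rows = []
        index = []
        planted = set(range(n_planted))
        for f in range(n_frag):
            base = rng.uniform(0.15, 0.55, size=sites_per_frag)
            delta = 0.4 if f in planted else 0.0
            for s in range(sites_per_frag):
                m1 = rng.binomial(cov, base[s], size=4) / cov
                m2 = rng.binomial(cov, min(1.0, base[s] + delta), size=4) / cov
                rows.append(np.concatenate([m1, m2]))
                index.append((f"frag_{f:04d}", s))
        matrix = pd.DataFrame(
            rows,
            index=pd.MultiIndex.from_tuples(index, names=["fragment_id", "position"]),
            columns=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)],
        )
        groups = {"g1": [f"a{i}" for i in range(4)], "g2": [f"b{i}" for i in range(4)]}
        site_results = moderated_t_test(matrix, groups)
        coverage = {idx: float(cov) for idx in matrix.index}
        frags = evaluate_fragments(site_results, coverage)
        ranked = rank_fragments(frags)
        top100 = {r.fragment_id for r in ranked[:100]}
        recovered = sum(1 for f in planted if f"frag_{f:04d}" in top100)
        assert recovered >= 0.9 * n_planted
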