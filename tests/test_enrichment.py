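import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ipac import (Enricher, GeneSetCollection, bonferroni_filter, call_ipac,
                  cross_cohort_consistency, empirical_null, enrich_pivot,
                  hypergeometric_tail, mhg_pvalue, mhg_score, residual_matrix,
                  trans_ranking)
from ipac.enrichment import NullScoreStore, _hgt_table

from conftest import make_gene_table


# ---------------------------------------------------------------------------
# Exact rational oracle, independent of the implementation
# ---------------------------------------------------------------------------

def exact_hgt(b, n, B, N):
    """P(X >= b) as a Fraction, by direct pmf summation."""
    total = Fraction(0)
    for k in range(b, min(n, B) + 1):
        if n - k <= N - B:
            total += Fraction(comb(B, k) * comb(N - B, n - k), comb(N, n))
    return total


def exact_mhg_score(labels):
    N = len(labels)
    B = sum(labels)
    if B == 0:
        return Fraction(1)
    best = Fraction(1)
    b = 0
    for n in range(1, N):
        b += labels[n - 1]
        best = min(best, exact_hgt(b, n, B, N))
    return best


def exact_mhg_pvalue(s, N, B):
    """Fraction of all C(N, B) arrangements with score <= s (exact)."""
    count = 0
    for ones in itertools.combinations(range(N), B):
        labels = [0] * N
        for i in ones:
            labels[i] = 1
        if exact_mhg_score(labels) <= s:
            count += 1
    return Fraction(count, comb(N, B))


class TestHypergeometricTail:
    def test_b_zero_is_one(self):
        assert hypergeometric_tail(0, 3, 5, 10) == 1.0

    def test_symmetric_half(self):
        assert hypergeometric_tail(1, 1, 1, 2) == pytest.approx(0.5)

    def test_enumerated_small_case(self):
        # draws of 2 from {2 marked, 2 unmarked}: P(both marked) = 1/6
        assert hypergeometric_tail(2, 2, 2, 4) == pytest.approx(1 / 6)

    def test_matches_scipy_sf(self, rng):
        for _ in range(200):
            N = int(rng.integers(2, 60))
            B = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            b = int(rng.integers(0, min(n, B) + 1))
            ours = hypergeometric_tail(b, n, B, N)
            ref = stats.hypergeom.sf(b - 1, N, B, n)
            assert ours == pytest.approx(ref, rel=1e-10, abs=1e-14)

    def test_tail_minus_next_tail_is_pmf(self, rng):
        for _ in range(50):
            N = int(rng.integers(4, 40))
            B = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            b = int(rng.integers(0, min(n, B)))
            diff = (hypergeometric_tail(b, n, B, N)
                    - hypergeometric_tail(b + 1, n, B, N))
            pmf = stats.hypergeom.pmf(b, N, B, n)
            assert diff == pytest.approx(pmf, rel=1e-9, abs=1e-12)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            hypergeometric_tail(3, 2, 5, 10)


class TestMhgScore:
    def test_top_heavy_example(self):
        r = mhg_score([1, 1, 0, 0])
        assert r.score == pytest.approx(1 / 6)
        assert (r.n_star, r.b_star) == (2, 2)
        assert r.fold == pytest.approx(2.0)

    def test_empty_set_scores_one(self):
        assert mhg_score([0, 0, 0, 0]).score == 1.0

    def test_bottom_heavy_scores_one(self):
        # every prefix tail equals 1 when members sit at the end
        assert mhg_score([0, 0, 1, 1]).score == pytest.approx(1.0)

    def test_matches_exact_oracle(self, rng):
        for _ in range(150):
            N = int(rng.integers(2, 13))
            B = int(rng.integers(0, N + 1))
            labels = np.zeros(N, dtype=int)
            labels[rng.choice(N, size=B, replace=False)] = 1
            ours = mhg_score(labels).score
            assert ours == pytest.approx(float(exact_mhg_score(list(labels))),
                                         rel=1e-9)

    def test_prefix_restriction_equals_full_scan(self, rng):
        """Evaluating only member-ending prefixes equals scanning all
        prefixes (tail is increasing in n at fixed b)."""
        for _ in range(50):
            N = int(rng.integers(3, 30))
            B = int(rng.integers(1, N))
            labels = np.zeros(N, dtype=int)
            labels[rng.choice(N, size=B, replace=False)] = 1
            table = _hgt_table(N, B)
            b = np.cumsum(labels)[:-1]
            full = min(table[n, b[n - 1]] for n in range(1, N))
            assert mhg_score(labels).score == pytest.approx(full, rel=1e-12)


class TestMhgPvalue:
    def test_empty_set(self):
        assert mhg_pvalue(1.0, 6, 0) == 1.0

    def test_single_extreme_arrangement(self):
        # only (1,1,0,0) attains score <= 1/6 among the 6 arrangements
        assert mhg_pvalue(1 / 6, 4, 2) == pytest.approx(1 / 6)

    def test_matches_bruteforce_enumeration(self, rng):
        for _ in range(80):
            N = int(rng.integers(2, 11))
            B = int(rng.integers(1, N + 1))
            labels = np.zeros(N, dtype=int)
            labels[rng.choice(N, size=B, replace=False)] = 1
            s = mhg_score(labels).score
            ours = mhg_pvalue(s, N, B)
            ref = exact_mhg_pvalue(Fraction(s).limit_denominator(10**12), N, B)
            assert ours == pytest.approx(float(ref), rel=1e-9, abs=1e-12)

    def test_bounds_s_le_p_le_Ns(self, rng):
        for _ in range(60):
            N = int(rng.integers(4, 40))
            B = int(rng.integers(1, N))
            labels = np.zeros(N, dtype=int)
            labels[rng.choice(N, size=B, replace=False)] = 1
            s = mhg_score(labels).score
            p = mhg_pvalue(s, N, B)
            assert s <= p <= min(1.0, N * s) + 1e-12


def build_enrichment_inputs(rng, n_genes=60, n_samples=25, module_size=8,
                            coupling=0.9):
    """Small cohort with one planted module tracking gene G00."""
    genes = [f"G{i:02d}" for i in range(n_genes)]
    expr = rng.normal(size=(n_genes, n_samples))
    pivot_dev = expr[0] - expr[0].mean()
    members = genes[10:10 + module_size]
    for g in members:
        i = genes.index(g)
        expr[i] = coupling * pivot_dev + rng.normal(0, 0.3, n_samples)
    gt = make_gene_table(np.zeros_like(expr), expr, genes=genes)
    sets = GeneSetCollection()
    sets.add("MOD", "planted", members)
    for k in range(10):
        decoy = rng.choice(genes[10 + module_size:], size=module_size,
                           replace=False)
        sets.add(f"D{k}", "decoy", decoy)
    return gt, sets, members


class TestEnrichPivot:
    def test_absent_set_skipped(self, rng):
        gt, sets, _ = build_enrichment_inputs(rng)
        sets.add("ABSENT", "not in universe", {"ZZZ1", "ZZZ2", "ZZZ3"})
        fit = residual_matrix(gt, min_pairs=5)
        ranking = trans_ranking("G00", gt.expr, fit.residuals, min_pairs=5)
        rec = enrich_pivot(ranking, sets, "top")
        assert "ABSENT" not in set(rec["set_id"])

    def test_planted_module_is_extreme_top(self, rng):
        gt, sets, _ = build_enrichment_inputs(rng)
        fit = residual_matrix(gt, min_pairs=5)
        ranking = trans_ranking("G00", gt.expr, fit.residuals, min_pairs=5)
        rec = enrich_pivot(ranking, sets, "top").set_index("set_id")
        assert rec.loc["MOD", "p_exact"] == rec["p_exact"].min()
        assert rec.loc["MOD", "p_exact"] < 1e-6

    def test_top_k_set_attains_minimal_score(self):
        residuals = pd.DataFrame(np.diag(np.arange(10, 0, -1.0)),
                                 index=[f"G{i}" for i in range(10)],
                                 columns=[f"S{j}" for j in range(10)])
        # build a ranking directly: ranking order is G0..G9 by construction
        expr = pd.DataFrame([np.eye(10)[0] * 5], index=["G0"],
                            columns=residuals.columns)
        ranking = trans_ranking("G0", expr, residuals, min_pairs=3)
        top3 = ranking.genes[:3]
        sets = GeneSetCollection()
        sets.add("TOP", "top 3", top3)
        rec = enrich_pivot(ranking, sets, "top").iloc[0]
        table = _hgt_table(10, 3)
        assert rec["mhg_score"] == pytest.approx(table[3, 3])

    def test_score_depends_only_on_membership_pattern(self, rng):
        gt, sets, members = build_enrichment_inputs(rng)
        fit = residual_matrix(gt, min_pairs=5)
        ranking = trans_ranking("G00", gt.expr, fit.residuals, min_pairs=5)
        rec1 = enrich_pivot(ranking, sets, "top").set_index("set_id")
        # relabel all non-member genes: scores must not change
        mapping = {g: (g if g in members else f"X{g}") for g in ranking.genes}
        gt2 = make_gene_table(gt.cn.to_numpy(), gt.expr.to_numpy(),
                              genes=[mapping[g] for g in gt.cn.index])
        fit2 = residual_matrix(gt2, min_pairs=5)
        ranking2 = trans_ranking("XG00", gt2.expr, fit2.residuals, min_pairs=5)
        rec2 = enrich_pivot(ranking2, sets, "top").set_index("set_id")
        assert rec2.loc["MOD", "mhg_score"] == \
            pytest.approx(rec1.loc["MOD", "mhg_score"], rel=1e-12)

    def test_bottom_direction_reverses(self, rng):
        gt, sets, members = build_enrichment_inputs(rng)
        fit = residual_matrix(gt, min_pairs=5)
        ranking = trans_ranking("G00", gt.expr, fit.residuals, min_pairs=5)
        top = enrich_pivot(ranking, sets, "top").set_index("set_id")
        bottom = enrich_pivot(ranking, sets, "bottom").set_index("set_id")
        assert bottom.loc["MOD", "mhg_score"] > top.loc["MOD", "mhg_score"]


class TestBonferroni:
    def _records(self, ps):
        return pd.DataFrame({"pivot": "G", "set_id": [f"S{i}" for i, _ in
                                                      enumerate(ps)],
                             "direction": "top", "p_exact": ps})

    def test_exact_boundary_fails(self):
        rec = bonferroni_filter(self._records([0.05 / 10]), alpha=0.05,
                                n_tests=10)
        assert not rec["bonferroni_pass"].iloc[0]

    def test_single_test_reduces_to_alpha(self):
        rec = bonferroni_filter(self._records([0.049, 0.051]), alpha=0.05,
                                n_tests=1)
        assert rec["bonferroni_pass"].tolist() == [True, False]

    def test_doubling_tests_never_converts_fail_to_pass(self, rng):
        ps = rng.random(50) * 0.01
        r1 = bonferroni_filter(self._records(ps), 0.05, n_tests=100)
        r2 = bonferroni_filter(self._records(ps), 0.05, n_tests=200)
        assert not (r2["bonferroni_pass"] & ~r1["bonferroni_pass"]).any()


class TestEmpiricalNull:
    def test_identity_permutation_reproduces_observed_minima(self, rng):
        gt, sets, _ = build_enrichment_inputs(rng)
        fit = residual_matrix(gt, min_pairs=5)
        pivots = ["G00", "G01"]
        store = empirical_null(fit.residuals, pivots, gt.expr, sets,
                               n_sims=1, seed=0, identity_permutation=True)
        observed = {}
        for pivot in pivots:
            ranking = trans_ranking(pivot, gt.expr, fit.residuals, min_pairs=5)
            rec = enrich_pivot(ranking, sets, "top")
            for _, row in rec.iterrows():
                observed[row["set_id"]] = min(
                    observed.get(row["set_id"], np.inf), row["mhg_score"])
        for set_id, s in observed.items():
            assert store.min_score["top"][set_id] == pytest.approx(s, rel=1e-12)

    def test_minima_non_increasing_in_n_sims(self, rng):
        gt, sets, _ = build_enrichment_inputs(rng)
        fit = residual_matrix(gt, min_pairs=5)
        s1 = empirical_null(fit.residuals, ["G00"], gt.expr, sets,
                            n_sims=2, seed=7)
        s2 = empirical_null(fit.residuals, ["G00"], gt.expr, sets,
                            n_sims=6, seed=7)
        for set_id in s1.min_score["top"]:
            assert s2.min_score["top"][set_id] <= s1.min_score["top"][set_id]

    def test_null_data_rarely_beats_null_minima(self):
        """With residuals independent of every pivot, observed scores come
        from the null distribution and essentially never beat the minimum of
        many null draws."""
        n_calls = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            genes = [f"G{i:02d}" for i in range(40)]
            expr = rng.normal(size=(40, 20))
            gt = make_gene_table(np.zeros_like(expr), expr, genes=genes)
            sets = GeneSetCollection()
            for k in range(8):
                sets.add(f"D{k}", "decoy",
                         rng.choice(genes[1:], size=6, replace=False))
            fit = residual_matrix(gt, min_pairs=5)
            # independent residuals: re-draw them
            fit.residuals.iloc[:, :] = rng.normal(size=(40, 20))
            ranking = trans_ranking("G00", gt.expr, fit.residuals, min_pairs=5)
            rec = pd.concat([enrich_pivot(ranking, sets, d)
                             for d in ("top", "bottom")], ignore_index=True)
            rec = bonferroni_filter(rec, alpha=1.0)  # no screening here
            store = empirical_null(fit.residuals, ["G00"], gt.expr, sets,
                                   n_sims=25, seed=seed)
            called, _ = call_ipac(rec, store)
            n_calls += int(called["empirical_significant"].sum())
        assert n_calls <= 2


class TestCallIpac:
    def _records(self, scores, ps, bonf):
        return pd.DataFrame({
            "pivot": "G00", "set_id": [f"S{i}" for i in range(len(scores))],
            "direction": "top", "mhg_score": scores, "p_exact": ps,
            "bonferroni_pass": bonf})

    def _store(self, minima):
        return NullScoreStore(
            min_score={"top": minima, "bottom": {}},
            p_star={"top": {k: v for k, v in minima.items()}, "bottom": {}},
            n_sims=1)

    def test_tie_with_null_minimum_not_significant(self):
        rec = self._records([1e-4], [1e-3], [True])
        called, genes = call_ipac(rec, self._store({"S0": 1e-4}))
        assert not called["empirical_significant"].iloc[0]
        assert genes == []

    def test_below_every_null_score_is_significant(self):
        rec = self._records([1e-6], [1e-5], [True])
        called, genes = call_ipac(rec, self._store({"S0": 1e-4}))
        assert called["empirical_significant"].iloc[0]
        assert genes == ["G00"]

    def test_requires_bonferroni(self):
        rec = self._records([1e-6], [1e-5], [False])
        called, genes = call_ipac(rec, self._store({"S0": 1e-4}))
        assert not called["empirical_significant"].iloc[0]

    def test_signed_log_score_convention(self):
        rec = self._records([1e-6], [1e-4], [True])
        rec.loc[1] = ["G00", "S1", "bottom", 1e-6, 1e-4, True]
        called, _ = call_ipac(rec, self._store({"S0": 1, "S1": 1}))
        assert called["signed_log_score"].iloc[0] == pytest.approx(4.0)
        assert called["signed_log_score"].iloc[1] == pytest.approx(-4.0)


class TestCrossCohort:
    def test_absent_gene_skipped_and_z_large_for_true_pair(self, rng):
        gt, sets, _ = build_enrichment_inputs(rng, n_genes=200, n_samples=40,
                                              module_size=10)
        pairs = pd.DataFrame({"pivot": ["G00", "NOT_THERE"],
                              "set_id": ["MOD", "MOD"],
                              "direction": ["top", "top"]})
        out = cross_cohort_consistency(pairs, gt, sets, n_random=25, seed=3,
                                       min_pairs=5)
        assert list(out["pivot"]) == ["G00"]
        assert out["z"].iloc[0] > 2
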