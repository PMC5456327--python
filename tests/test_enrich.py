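import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fabrymeta.enrich import (EnrichmentConfig, enrich, group_terms,
                              holm_adjust, hypergeom_two_sided,
                              pathway_zscore, term_direction, term_kappa)
from fabrymeta.errors import ConfigError, ValidationError
from fabrymeta.io_formats import GeneSet

from oracles import holm_stepdown, kappa_2x2


class TestHypergeomTwoSided:
    def test_perfect_overlap_doubles_single_tail(self):
        # N=20, K=5, n=5, k=5: upper tail = 1/C(20,5) = 1/15504
        p = hypergeom_two_sided(5, 5, 5, 20)
        assert p == pytest.approx(2 / 15504, rel=1e-9)

    def test_empty_term_is_degenerate(self):
        assert hypergeom_two_sided(0, 5, 0, 20) == 1.0

    def test_out_of_support_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_two_sided(6, 5, 5, 20)
        with pytest.raises(ValidationError):
            hypergeom_two_sided(0, 5, 18, 20)  # k below max(0, n+K-N)

    @given(st.integers(2, 80), st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bounded_by_twice_smaller_tail_and_one(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(max(0, n + K - N), min(n, K)))
        p = hypergeom_two_sided(k, n, K, N)
        dist = stats.hypergeom(N, K, n)
        smaller = min(dist.sf(k - 1), dist.cdf(k))
        assert 0 < p <= 1
        assert p <= 2 * smaller + 1e-12

    def test_min_likelihood_policy_sums_unlikely_outcomes(self):
        # N=10, K=4, n=5: pmf over k=0..4, sum outcomes with
        # pmf <= pmf(0) = C(6,5)/C(10,5) = 6/252
        p = hypergeom_two_sided(0, 5, 4, 10, policy="min_likelihood")
        dist = stats.hypergeom(10, 4, 5)
        expected = sum(dist.pmf(k) for k in range(5)
                       if dist.pmf(k) <= dist.pmf(0) * (1 + 1e-10))
        assert p == pytest.approx(expected, rel=1e-9)


class TestHolm:
    def test_hand_computed_triple(self):
        out = holm_adjust([0.01, 0.04, 0.03])
        assert np.allclose(out, [0.03, 0.06, 0.06])

    def test_single_value_unchanged(self):
        assert holm_adjust([0.2]) == pytest.approx([0.2])

    def test_tied_pair_doubles_both(self):
        assert np.allclose(holm_adjust([0.05, 0.05]), [0.10, 0.10])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            holm_adjust([0.1, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=25))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_stepdown_definition_and_dominates_raw(self, pvals):
        out = holm_adjust(pvals)
        assert np.allclose(out, holm_stepdown(pvals))
        assert (out >= np.asarray(pvals) - 1e-12).all()
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(out[order]) >= -1e-12).all()  # ranking preserved

    @given(st.lists(st.floats(0.0, 0.9), min_size=1, max_size=15),
           st.integers(0, 14), st.floats(1.01, 1.5))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_raising_any_raw_never_lowers_any_adjusted(
            self, pvals, idx, factor):
        idx = idx % len(pvals)
        bumped = list(pvals)
        bumped[idx] = min(1.0, bumped[idx] * factor + 1e-6)
        assert (holm_adjust(bumped) >= holm_adjust(pvals) - 1e-12).all()


class TestTermKappa:
    def test_identical_sets_give_one(self):
        uni = [f"g{i}" for i in range(10)]
        assert term_kappa(uni[:5], uni[:5], uni) == 1.0

    def test_complementary_halves_give_minus_one(self):
        uni = [f"g{i}" for i in range(10)]
        assert term_kappa(uni[:5], uni[5:], uni) == pytest.approx(-1.0)

    def test_four_of_five_shared(self):
        uni = [f"g{i}" for i in range(10)]
        a = uni[:5]
        b = uni[:4] + [uni[5]]
        assert term_kappa(a, b, uni) == pytest.approx(0.6)

    def test_degenerate_marginals(self):
        uni = ["a", "b"]
        assert term_kappa(uni, uni, uni) == 1.0

    def test_member_outside_universe_rejected(self):
        with pytest.raises(ValidationError, match="zz"):
            term_kappa(["a", "zz"], ["a"], ["a", "b"])

    def test_agrees_with_brute_force_tables_on_random_pairs(self):
        rng = np.random.default_rng(11)
        uni = [f"g{i}" for i in range(30)]
        for _ in range(1000):
            a = set(rng.choice(uni, size=rng.integers(0, 31), replace=False))
            b = set(rng.choice(uni, size=rng.integers(0, 31), replace=False))
            assert term_kappa(a, b, uni) == pytest.approx(
                kappa_2x2(a, b, uni), abs=1e-12)

    def test_agrees_with_sklearn_on_membership_vectors(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(5)
        uni = [f"g{i}" for i in range(25)]
        for _ in range(50):
            a = set(rng.choice(uni, size=rng.integers(1, 24), replace=False))
            b = set(rng.choice(uni, size=rng.integers(1, 24), replace=False))
            va = [int(g in a) for g in uni]
            vb = [int(g in b) for g in uni]
            if len(set(va)) == 1 and len(set(vb)) == 1:
                continue
            assert term_kappa(a, b, uni) == pytest.approx(
                sklearn_metrics.cohen_kappa_score(va, vb), abs=1e-12)


class TestTermDirection:
    def test_all_up_inflammatory_fixture(self):
        genes = ["DEFB1", "IL1RN", "ITIH4", "ORM1", "ORM2", "SERPINA3",
                 "VCAM1", "VTN"]
        directions = {g: "up" for g in genes}
        assert term_direction(genes, directions) == "up"

    def test_equal_split_is_mixed(self):
        directions = {"a": "up", "b": "up", "c": "down", "d": "down"}
        assert term_direction(list(directions), directions) == "mixed"

    def test_majority_down(self):
        directions = {"a": "up", "b": "down", "c": "down"}
        assert term_direction(list(directions), directions) == "down"

    def test_zero_hits_is_an_error(self):
        with pytest.raises(ValidationError):
            term_direction([], {})


class TestGroupTerms:
    def _results(self, rows):
        cols = ["term_id", "N", "K", "n", "k", "p_two_sided", "p_adjusted",
                "hit_genes", "n_up", "n_down", "regulation_label"]
        return pd.DataFrame(rows, columns=cols)

    def test_similar_terms_group_and_isolate(self):
        # T1/T2 share 4 of 5 hits over a 10-gene hit universe (kappa 0.6),
        # T3 is disjoint from both
        uni = [f"g{i}" for i in range(10)]
        res = self._results([
            ("T1", 50, 5, 10, 5, 1e-4, 1e-3, ",".join(uni[:5]), 5, 0, "up"),
            ("T2", 50, 5, 10, 5, 2e-4, 2e-3,
             ",".join(uni[:4] + [uni[5]]), 5, 0, "up"),
            ("T3", 50, 4, 10, 4, 3e-4, 3e-3, ",".join(uni[6:]), 4, 0, "up"),
        ])
        gene_sets = [GeneSet(t, "", tuple(uni)) for t in ("T1", "T2", "T3")]
        groups = group_terms(res, gene_sets, EnrichmentConfig())
        assert [g.members for g in groups] == [("T1", "T2"), ("T3",)]
        assert groups[0].representative == "T1"
        assert groups[0].mean_kappa == pytest.approx(0.6)
        assert groups[1].mean_kappa == 1.0

    def test_single_significant_term_is_singleton_group(self):
        res = self._results([("T1", 50, 5, 10, 5, 1e-4, 1e-3, "a,b", 2, 0,
                              "up")])
        groups = group_terms(res, [GeneSet("T1", "", ("a", "b"))],
                             EnrichmentConfig())
        assert len(groups) == 1 and groups[0].members == ("T1",)

    def test_nonsignificant_terms_excluded(self):
        res = self._results([("T1", 50, 5, 10, 5, 0.5, 0.9, "a,b", 2, 0,
                              "up")])
        assert group_terms(res, [], EnrichmentConfig()) == []


class TestPathwayZscore:
    def test_centered_case_is_zero(self):
        # r = nR/N exactly: N=10, R=5, n=2, r=1
        assert pathway_zscore(1, 2, 5, 10).z == pytest.approx(0.0)

    def test_worked_example(self):
        res = pathway_zscore(3, 10, 10, 100)
        assert res.z == pytest.approx(2.2111, abs=1e-4)
        assert res.significant

    def test_significance_cutoff_is_one_sided_normal_5pct(self):
        res = pathway_zscore(3, 10, 10, 100)
        assert res.significant == (res.z >= 1.6449)
        under = pathway_zscore(0, 10, 10, 100)
        assert not under.significant  # strongly negative z, one-sided

    def test_degenerate_variance_yields_zero_with_warning(self, caplog):
        res = pathway_zscore(0, 5, 0, 10)
        assert res.z == 0.0 and not res.significant

    def test_parameter_validation(self):
        with pytest.raises(ValidationError):
            pathway_zscore(5, 4, 6, 10)  # r > n
        with pytest.raises(ValidationError):
            pathway_zscore(2, 3, 1, 10)  # R < r
        with pytest.raises(ValidationError):
            pathway_zscore(0, 1, 0, 1)  # N < 2

    @pytest.mark.parametrize("seed", range(5))
    def test_standardizes_hypergeometric_draws(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(20, 200))
        R = int(rng.integers(1, N))
        n = int(rng.integers(1, N))
        draws = stats.hypergeom(N, R, n).rvs(size=100_000, random_state=rng)
        z = np.array([pathway_zscore(int(r), n, R, N).z for r in
                      np.unique(draws)])
        weights = np.array([(draws == r).mean() for r in np.unique(draws)])
        mean = float((z * weights).sum())
        var = float(((z - mean) ** 2 * weights).sum())
        assert mean == pytest.approx(0.0, abs=0.02)
        assert var == pytest.approx(1.0, abs=0.05)


class TestEnrich:
    def _sets(self):
        uni = [f"g{i}" for i in range(30)]
        return [GeneSet("T1", "", tuple(uni[:10])),
                GeneSet("T2", "", tuple(uni[10:20])),
                GeneSet("T3", "", tuple(uni))]

    def test_counts_and_invariants(self):
        query = [f"g{i}" for i in range(8)] + ["absent_gene"]
        directions = {f"g{i}": "up" if i % 2 else "down" for i in range(30)}
        res = enrich(query, self._sets(), directions=directions)
        assert (res["n_up"] + res["n_down"] == res["k"]).all()
        assert (res["p_adjusted"] >= res["p_two_sided"] - 1e-12).all()
        t1 = res.set_index("term_id").loc["T1"]
        assert t1["N"] == 30 and t1["n"] == 8 and t1["k"] == 8
        t2 = res.set_index("term_id").loc["T2"]
        assert t2["k"] == 0 and t2["regulation_label"] == ""

    def test_explicit_universe_policy(self):
        cfg = EnrichmentConfig(universe_policy="explicit_list")
        with pytest.raises(ConfigError):
            enrich(["g1"], self._sets(), config=cfg)
        res = enrich(["g1"], self._sets(), config=cfg,
                     universe=[f"g{i}" for i in range(50)])
        assert (res["N"] == 50).all()

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            EnrichmentConfig(alpha=1.5)
        with pytest.raises(ConfigError):
            EnrichmentConfig(kappa_threshold=2.0)
        with pytest.raises(ConfigError):
            EnrichmentConfig(z_cutoff=-1.0)


@given(st.integers(2, 120))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_internal_pmf_sums_to_one_over_support(N):
    rng = np.random.default_rng(N)
    for K, n in [(0, N), (N, N // 2), (int(rng.integers(0, N + 1)),
                                       int(rng.integers(0, N + 1)))]:
        lo, hi = max(0, n + K - N), min(n, K)
        total = stats.hypergeom(N, K, n).pmf(np.arange(lo, hi + 1)).sum()
        assert total == pytest.approx(1.0, abs=1e-12)
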