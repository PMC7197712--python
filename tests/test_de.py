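"""Overestimated-variance DE test, BH correction, GO enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from heartregen import de
from conftest import lognorm_from_dense


def ttest_overestim_oracle(x, y):
    """Hand-coded formula: rest variance divided by the group size, same
    substitution in the Welch-Satterthwaite degrees of freedom."""
    n = len(x)
    m1, m2 = np.mean(x), np.mean(y)
    v1, v2 = np.var(x, ddof=1), np.var(y, ddof=1)
    denom = np.sqrt(v1 / n + v2 / n)
    t = (m1 - m2) / denom
    df = (v1 / n + v2 / n) ** 2 / (
        (v1 / n) ** 2 / (n - 1) + (v2 / n) ** 2 / (n - 1)
    )
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


class TestOverestimatedVarTTest:
    def test_identical_groups_give_t_zero_p_one(self):
        vals = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        ln = lognorm_from_dense(vals)
        res = de.rank_genes(ln, np.array(["a", "a", "b", "b"]), "a")
        assert (res["t"] == 0).all()
        assert (res["p"] == 1).all()

    def test_six_cell_fixture_matches_hand_coded_oracle(self):
        x = np.array([1.3, 0.2, 2.1])
        y = np.array([0.1, 0.0, 0.4])
        t_oracle, p_oracle = ttest_overestim_oracle(x, y)
        mean_x, var_x = x.mean(), x.var(ddof=1)
        t, p = de.overestimated_var_ttest(
            np.array([mean_x]), np.array([var_x]), 3,
            np.array([y.mean()]), np.array([y.var(ddof=1)]),
        )
        assert t[0] == pytest.approx(t_oracle, abs=1e-12)
        assert p[0] == pytest.approx(p_oracle, abs=1e-12)

    def test_overestimation_shrinks_t_versus_welch(self):
        # when n_group <= n_rest, s2_rest/n_group >= s2_rest/n_rest, so the
        # inflated denominator can only shrink |t|
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(n1, 12))
            x = rng.normal(size=n1)
            y = rng.normal(loc=rng.normal(), size=n2)
            if np.var(x, ddof=1) == 0 or np.var(y, ddof=1) == 0:
                continue
            t_over, _ = ttest_overestim_oracle(x, y)
            t_welch = stats.ttest_ind(x, y, equal_var=False).statistic
            assert abs(t_over) <= abs(t_welch) + 1e-12

    def test_matches_scanpy_reference(self):
        scanpy = pytest.importorskip("scanpy")
        import anndata as ad

        rng = np.random.default_rng(1)
        dense = np.log1p(rng.poisson(2.0, size=(50, 25)).astype(float))
        labels = np.array(["a"] * 20 + ["b"] * 30)
        mine = de.rank_genes(lognorm_from_dense(dense), labels, "a").set_index("gene")
        adata = ad.AnnData(X=dense.copy())
        adata.var_names = [f"g{i}" for i in range(25)]
        adata.obs["grp"] = pd.Categorical(labels)
        scanpy.tl.rank_genes_groups(
            adata, "grp", groups=["a"], reference="rest",
            method="t-test_overestim_var",
        )
        ref = scanpy.get.rank_genes_groups_df(adata, group="a").set_index("names")
        joined = mine.join(ref[["scores", "pvals"]])
        # scanpy computes group stats in float32
        np.testing.assert_allclose(joined["t"], joined["scores"], atol=1e-4)
        np.testing.assert_allclose(joined["p"], joined["pvals"], atol=1e-6)

    def test_degenerate_group_sizes_rejected(self):
        ln = lognorm_from_dense(np.random.default_rng(2).random((4, 3)))
        with pytest.raises(ValueError, match=">=2 cells"):
            de.rank_genes(ln, np.array(["a", "b", "b", "b"]), "a")

    def test_null_calibration_is_conservative(self):
        # permuted labels: raw p<0.05 rate should be at most nominal
        rng = np.random.default_rng(3)
        dense = np.log1p(rng.poisson(2.0, size=(60, 400)).astype(float))
        ln = lognorm_from_dense(dense)
        labels = rng.permutation(np.array(["a"] * 25 + ["b"] * 35))
        res = de.rank_genes(ln, labels, "a")
        assert (res["p"] < 0.05).mean() <= 0.06


class TestBhAdjust:
    def test_single_and_tied_p_unchanged(self):
        assert de.bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)
        np.testing.assert_allclose(de.bh_adjust(np.full(7, 0.2)), np.full(7, 0.2))

    def test_matches_brute_force_step_up(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 40)))
            adj = de.bh_adjust(p)
            m = len(p)
            order = np.argsort(p, kind="stable")
            brute = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                brute[i] = running
            np.testing.assert_allclose(adj, brute, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.bh_adjust(np.array([0.5, 1.2]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        p=st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=2,
            max_size=30,
        )
    )
    def test_monotone_and_dominates_raw(self, p):
        p = np.asarray(p)
        adj = de.bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestGoEnrichment:
    def hypergeom_enumeration(self, N, K, n, k):
        """P(X >= k) by exhaustive enumeration over all C(N, n) draws."""
        universe = list(range(N))
        annotated = set(range(K))
        hits = sum(
            1
            for draw in itertools.combinations(universe, n)
            if len(annotated & set(draw)) >= k
        )
        from math import comb

        return hits / comb(N, n)

    def test_p_matches_exhaustive_enumeration(self):
        # N=10, K=4, n=3, k=2 against all C(10,3) draws
        universe = [f"g{i}" for i in range(10)]
        annotations = {"GO:x": set(universe[:4])}
        ranked = universe[:3]  # overlap k=2 requires 2 annotated in top 3
        res = de.go_enrichment(
            ranked, annotations, universe, n_top=3, min_size=1, max_size=10
        )
        assert res.loc[0, "overlap"] == 3
        for k in (2, 3):
            p_enum = self.hypergeom_enumeration(10, 4, 3, k)
            from scipy.stats import hypergeom

            assert hypergeom.sf(k - 1, 10, 4, 3) == pytest.approx(p_enum, abs=1e-12)
        assert res.loc[0, "p"] == pytest.approx(
            self.hypergeom_enumeration(10, 4, 3, 3), abs=1e-12
        )

    def test_zero_overlap_gives_p_exactly_one(self):
        universe = [f"g{i}" for i in range(20)]
        annotations = {"GO:y": set(universe[10:17])}
        res = de.go_enrichment(
            universe[:5], annotations, universe, n_top=5, min_size=1, max_size=20
        )
        assert res.loc[0, "p"] == 1.0

    def test_term_size_bounds_strict(self):
        universe = [f"g{i}" for i in range(600)]
        annotations = {
            "K5": set(universe[:5]),
            "K6": set(universe[:6]),
            "K499": set(universe[:499]),
            "K500": set(universe[:500]),
        }
        res = de.go_enrichment(universe[:50], annotations, universe, n_top=50)
        assert set(res["term"]) == {"K6", "K499"}

    def test_hypergeometric_tail_is_a_distribution(self):
        from scipy.stats import hypergeom

        N, K, n = 12, 5, 4
        pmf_total = sum(hypergeom.pmf(k, N, K, n) for k in range(min(K, n) + 1))
        assert pmf_total == pytest.approx(1.0, abs=1e-12)

    def test_n_top_larger_than_universe_rejected(self):
        with pytest.raises(ValueError):
            de.go_enrichment(["g1"], {}, {"g1", "g2"}, n_top=3)

    def test_enrichment_detects_planted_term(self):
        from heartregen import sim

        terms, names = sim.simulate_go_universe(500, [20, 30, 40], seed=5)
        universe = [f"g{i:05d}".replace("g", "gene", 1) for i in range(500)]
        universe = [f"gene{i:05d}" for i in range(500)]
        # rank the genes of the first term at the top
        planted = sorted(terms["GO:0000001"])
        rest = [g for g in universe if g not in terms["GO:0000001"]]
        res = de.go_enrichment(planted + rest, terms, universe, n_top=20)
        res = res.set_index("term")
        assert res.loc["GO:0000001", "overlap"] == 20
        assert res.loc["GO:0000001", "p_adj"] < 1e-10
        assert res.loc["GO:0000001", "p"] <= res["p"].min() + 1e-15
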