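"""Permutation enrichment vs its hypergeometric and brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from orgrowth import enrichment as en
from orgrowth.errors import DegenerateNullError, SchemaError


def _deg(genes, l2fc, padj):
    return pd.DataFrame(
        {"gene_id": genes, "log2fc": l2fc, "pvalue": padj, "padj": padj}
    )


class TestSignificantGenes:
    def test_strict_threshold(self):
        t = _deg(list("abcde"), [1] * 5, [0.01, 0.049, 0.05, 0.2, 1.0])
        assert en.significant_genes(t).ids == {"a", "b"}

    def test_internal_bh_matches_step_up_oracle(self):
        rng = np.random.default_rng(0)
        p = np.concatenate([10.0 ** rng.uniform(-6, -3, 20), rng.uniform(0, 1, 180)])
        genes = [f"g{i}" for i in range(len(p))]
        t = pd.DataFrame({"gene_id": genes, "log2fc": 1.0, "pvalue": p})
        got = en.significant_genes(t, adjust=True).ids

        # brute-force BH step-up: largest k with p_(k) <= k/m * alpha
        m = len(p)
        order = np.argsort(p)
        ranked = p[order]
        k = np.max(np.nonzero(ranked <= (np.arange(1, m + 1) / m) * 0.05)[0]) + 1
        expected = {genes[i] for i in order[:k]}
        assert got == expected

    def test_empty_table_warns(self):
        with pytest.warns(UserWarning):
            s = en.significant_genes(_deg([], [], []))
        assert len(s) == 0

    def test_missing_column_schema_error(self):
        with pytest.raises(SchemaError):
            en.significant_genes(pd.DataFrame({"gene_id": ["a"], "pvalue": [0.1]}))


class TestOverlapCount:
    def test_identity_and_disjoint(self):
        a = en.GeneSet("a", ["x", "y", "z"])
        assert en.overlap_count(a, a) == 3
        assert en.overlap_count(a, en.GeneSet("b", ["q"])) == 0

    def test_case_folding(self):
        a = en.GeneSet("a", ["A", "B", "C"])
        b = en.GeneSet("b", [" b", "C ", "D"])
        assert en.overlap_count(a, b) == 2


class TestHypergeometricMoments:
    def test_bernoulli_case(self):
        mu, sd = en.hypergeometric_moments(1, 30, 100)
        assert mu == pytest.approx(0.3)
        assert sd**2 == pytest.approx(0.3 * 0.7)

    def test_exhaustive_draw(self):
        mu, sd = en.hypergeometric_moments(100, 30, 100)
        assert mu == pytest.approx(30.0)
        assert sd == 0.0

    def test_matches_scipy(self):
        mu, sd = en.hypergeometric_moments(339, 980, 20000)
        smu, svar = sps.hypergeom.stats(20000, 980, 339)
        assert mu == pytest.approx(float(smu))
        assert sd == pytest.approx(float(np.sqrt(svar)))

    def test_matches_exhaustive_enumeration(self):
        # all C(12, 4) subsets of a 12-gene universe, 5-gene target
        N, K, n = 12, 5, 4
        target = set(range(K))
        overlaps = [len(target & set(c)) for c in itertools.combinations(range(N), n)]
        mu, sd = en.hypergeometric_moments(n, K, N)
        assert mu == pytest.approx(np.mean(overlaps))
        assert sd == pytest.approx(np.std(overlaps, ddof=0))

    @settings(derandomize=True, max_examples=30)
    @given(data=st.data())
    def test_matches_scipy_everywhere(self, data):
        N = data.draw(st.integers(2, 500))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        mu, sd = en.hypergeometric_moments(n, K, N)
        smu, svar = sps.hypergeom.stats(N, K, n)
        assert mu == pytest.approx(float(smu), abs=1e-12)
        assert sd**2 == pytest.approx(float(svar), abs=1e-9)


class TestPermutationEnrichment:
    def test_agrees_with_hypergeometric_oracle(self):
        universe = [f"g{i:05d}" for i in range(5000)]
        query = en.GeneSet("q", universe[:200])
        target = en.GeneSet("t", universe[150:500])
        res = en.permutation_enrichment(query, target, universe, n_perm=4000, seed=1)
        mu, sd = en.hypergeometric_moments(200, 350, 5000)
        z_hg = (res.observed_overlap - mu) / sd
        assert res.null_mean == pytest.approx(mu, abs=4 * sd / np.sqrt(4000) * 3)
        assert abs(res.z - z_hg) < 0.15

    def test_self_enrichment_large_positive_z(self):
        universe = [f"g{i}" for i in range(500)]
        q = en.GeneSet("q", universe[:40])
        res = en.permutation_enrichment(q, q, universe, n_perm=500, seed=0)
        assert res.observed_overlap == 40
        assert res.z > 5

    def test_monotone_in_observed_overlap(self):
        """With sizes fixed, z strictly increases with the overlap."""
        universe = [f"g{i:03d}" for i in range(100)]
        target = en.GeneSet("t", universe[:30])
        zs = []
        for x in (0, 10, 20, 30):
            query = en.GeneSet("q", universe[30 - x:60 - x])
            res = en.permutation_enrichment(query, target, universe, n_perm=500, seed=7)
            assert res.observed_overlap == x
            zs.append(res.z)
        assert all(a < b for a, b in zip(zs, zs[1:]))

    def test_reproducible_under_seed(self):
        universe = [f"g{i}" for i in range(300)]
        q = en.GeneSet("q", universe[:25])
        t = en.GeneSet("t", universe[20:80])
        r1 = en.permutation_enrichment(q, t, universe, n_perm=300, seed=9)
        r2 = en.permutation_enrichment(q, t, universe, n_perm=300, seed=9)
        assert r1 == r2

    def test_degenerate_universe_errors(self):
        universe = [f"g{i}" for i in range(50)]
        q = en.GeneSet("q", universe[:10])
        whole = en.GeneSet("t", universe)
        with pytest.raises(DegenerateNullError):
            en.permutation_enrichment(q, whole, universe, n_perm=200, seed=0)

    def test_query_outside_universe_errors(self):
        with pytest.raises(ValueError):
            en.permutation_enrichment(
                en.GeneSet("q", ["zz"]), en.GeneSet("t", ["g1"]),
                [f"g{i}" for i in range(100)], n_perm=100,
            )


class TestDirectionReversal:
    def test_full_negation_reverses_all_significant(self, small_expr):
        deg = small_expr.deg_patient
        negated = deg.assign(log2fc=-deg["log2fc"])
        rev, _ = en.direction_reversal(deg, negated, n_perm=200, seed=0)
        assert rev.ids == en.significant_genes(deg).ids

    def test_identical_tables_reverse_nothing(self, small_expr):
        deg = small_expr.deg_patient
        rev, res = en.direction_reversal(deg, deg.copy(), n_perm=200, seed=0)
        assert len(rev) == 0
        assert res.z < 0  # fewer reversals than chance

    def test_planted_reversal_fraction_recovered(self, small_expr):
        rev, res = en.direction_reversal(
            small_expr.deg_patient, small_expr.deg_rescue, n_perm=500, seed=1
        )
        truth = small_expr.truth
        assert len(rev) == int(truth["is_reversed"].sum())
        assert res.z > 3

    def test_zero_log2fc_excluded_with_warning(self):
        deg = _deg(["a", "b", "c"], [0.0, 1.0, -1.0], [0.01, 0.01, 0.01])
        with pytest.warns(UserWarning):
            rev, _ = en.direction_reversal(
                deg, deg.assign(log2fc=-deg["log2fc"]), n_perm=100, seed=0
            )
        assert "a" not in rev.ids


class TestTopLoadingGenes:
    def test_k_equals_n_returns_all(self):
        s = pd.Series([0.1, -0.5, 0.3], index=["a", "b", "c"])
        assert en.top_loading_genes(s, 3).ids == {"a", "b", "c"}

    def test_absolute_value_convention(self):
        s = pd.Series([3.0, -5.0, 1.0], index=["a", "b", "c"])
        assert en.top_loading_genes(s, 1).ids == {"b"}

    def test_tie_break_lexicographic(self):
        s = pd.Series([1.0, -1.0, 0.5], index=["zz", "aa", "mm"])
        assert en.top_loading_genes(s, 1).ids == {"aa"}

    def test_invalid_k(self):
        s = pd.Series([1.0], index=["a"])
        with pytest.raises(ValueError):
            en.top_loading_genes(s, 0)
        with pytest.raises(ValueError):
            en.top_loading_genes(s, 2)

    def test_pc1_tracks_batch_genes_not_de(self):
        from orgrowth import simulate

        sim = simulate.gen_expression(simulate.ExprSimConfig(seed=3))
        loadings, evr = en.pc_loadings(sim.counts, n_components=2)
        top = en.top_loading_genes(loadings["PC1"], 100)
        de = en.GeneSet("de", sim.truth.loc[sim.truth["is_de"], "gene_id"])
        batch_hits = en.overlap_count(top, sim.batch_genes)
        de_hits = en.overlap_count(top, de)
        # chance expectation: 100 * |set| / 20000 -> ~5 batch, ~2 DE
        assert batch_hits > 50
        assert de_hits <= 10


class TestPFromZ:
    def test_reference_points(self):
        assert en.p_from_z(0.0) == pytest.approx(1.0)
        assert en.p_from_z(1.95996) == pytest.approx(0.05, abs=1e-4)
        assert en.p_from_z(-2.0) == en.p_from_z(2.0)
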