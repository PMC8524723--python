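import anndata as ad
import itertools

import numpy as np
import pandas as pd
import pytest

from clonodyn import signatures


def make_adata(X, genes=None, barcodes=None):
    X = np.asarray(X, dtype=float)
    genes = genes or [f"g{i:02d}" for i in range(X.shape[1])]
    barcodes = barcodes or [f"c{i}" for i in range(X.shape[0])]
    adata = ad.AnnData(
        X=X, obs=pd.DataFrame(index=barcodes), var=pd.DataFrame(index=genes)
    )
    return adata


def mannwhitney_enumeration(a, b):
    """Independent oracle: exact two-sided p by enumerating every
    assignment of the pooled (tie-free) values to the two groups."""
    pooled = sorted(list(a) + list(b))
    na = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    n1n2 = na * len(b)
    u_min = min(u_obs, n1n2 - u_obs)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), na):
        grp_a = [pooled[i] for i in comb]
        grp_b = [pooled[i] for i in range(len(pooled)) if i not in comb]
        u = sum(1 for x in grp_a for y in grp_b if x > y)
        if min(u, n1n2 - u) <= u_min:
            hits += 1
        total += 1
    return hits / total


class TestSsgsea:
    def test_top_block_scores_one(self):
        # 10 genes; the set is exactly the 3 highest-expressed genes of the
        # cell; unweighted running sum peaks at +1 after rank 3
        x = np.arange(10, 0, -1)[None, :]
        adata = make_adata(x)
        scores = signatures.score_cells(
            adata, {"TOP": ["g00", "g01", "g02"]}, tau=0.0
        )
        assert scores.loc["c0", "TOP"] == pytest.approx(1.0)

    def test_bottom_block_scores_minus_one(self):
        x = np.arange(10, 0, -1)[None, :]
        adata = make_adata(x)
        scores = signatures.score_cells(
            adata, {"BOT": ["g07", "g08", "g09"]}, tau=0.0
        )
        assert scores.loc["c0", "BOT"] == pytest.approx(-1.0)

    def test_hand_enumerated_interior_set(self):
        # genes ranked g00 > ... > g09; set = {g01, g03} at tau=0:
        # deviations after each rank: -1/8, 1/2-1/8, 1/2-2/8, 1-2/8, ...
        # maximum deviation = 1 - 2/8 = 0.75 at rank 4
        x = np.arange(10, 0, -1)[None, :]
        adata = make_adata(x)
        scores = signatures.score_cells(adata, {"S": ["g01", "g03"]}, tau=0.0)
        assert scores.loc["c0", "S"] == pytest.approx(0.75)

    def test_complement_antisymmetry_on_block_sets(self):
        x = np.arange(10, 0, -1)[None, :]
        adata = make_adata(x)
        top = ["g00", "g01", "g02"]
        rest = [f"g{i:02d}" for i in range(3, 10)]
        s = signatures.score_cells(adata, {"A": top, "B": rest}, tau=0.0)
        assert s.loc["c0", "A"] == pytest.approx(-s.loc["c0", "B"])

    def test_cell_duplication_leaves_scores_unchanged(self, rng):
        X = rng.random((5, 12))
        a1 = make_adata(X)
        a2 = make_adata(np.vstack([X, X]),
                        barcodes=[f"c{i}" for i in range(10)])
        sets = {"S": ["g01", "g04", "g07"]}
        s1 = signatures.score_cells(a1, sets)
        s2 = signatures.score_cells(a2, sets)
        np.testing.assert_allclose(s1.values, s2.values[:5], atol=1e-12)

    def test_gene_order_permutation_invariance(self, rng):
        X = rng.random((4, 12))
        genes = [f"g{i:02d}" for i in range(12)]
        perm = rng.permutation(12)
        a1 = make_adata(X, genes=genes)
        a2 = make_adata(X[:, perm], genes=[genes[i] for i in perm])
        sets = {"S": ["g02", "g05", "g09"]}
        np.testing.assert_allclose(
            signatures.score_cells(a1, sets).values,
            signatures.score_cells(a2, sets).values, atol=1e-12,
        )

    def test_absent_genes_warned_small_sets_dropped(self):
        adata = make_adata(np.random.default_rng(0).random((3, 6)))
        with pytest.warns(UserWarning):
            scores = signatures.score_cells(
                adata, {"S": ["g00", "NOPE1", "NOPE2"]}
            )
        assert scores.empty or "S" not in scores.columns

    def test_gsva_gaussian_variant_separates_shifted_cells(self, rng):
        X = rng.normal(0, 1, (40, 20))
        X[:20, :5] += 2.0  # first 20 cells up-shifted on the set genes
        adata = make_adata(X)
        sets = {"S": [f"g{i:02d}" for i in range(5)]}
        s = signatures.score_cells(adata, sets, method="gsva_gaussian")
        assert s.iloc[:20]["S"].mean() > s.iloc[20:]["S"].mean()


class TestCompareScores:
    def test_separated_groups_exact(self):
        p, effect = signatures.compare_scores([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)
        assert effect == pytest.approx(-1.0)

    def test_identical_groups(self):
        p, _ = signatures.compare_scores([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_label_swap_symmetry(self, rng):
        a, b = rng.random(8), rng.random(9)
        pa, ea = signatures.compare_scores(a, b)
        pb, eb = signatures.compare_scores(b, a)
        assert pa == pytest.approx(pb)
        assert ea == pytest.approx(-eb)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            signatures.compare_scores([], [1.0])

    def test_matches_permutation_enumeration(self, rng):
        for na, nb in [(3, 4), (5, 5), (4, 6)]:
            vals = rng.permutation(np.arange(1.0, na + nb + 1.0))
            a, b = vals[:na], vals[na:]
            p, _ = signatures.compare_scores(a, b)
            assert p == pytest.approx(mannwhitney_enumeration(a, b), abs=1e-12)

    def test_planted_shift_separates_groups(self, rng):
        """An additive shift of 0.5 on the set genes of 100 'exhausted'
        cells yields a strong Mann-Whitney separation."""
        X = rng.normal(1.0, 0.5, (200, 30)).clip(min=0)
        X[:100, :5] += 0.5
        adata = make_adata(X)
        s = signatures.score_cells(adata, {"EXH": [f"g{i:02d}" for i in range(5)]})
        p, _ = signatures.compare_scores(s.iloc[:100]["EXH"], s.iloc[100:]["EXH"])
        assert p < 0.01


class TestGeneCorrelations:
    def test_identity_and_sign(self, rng):
        x = rng.random(30)
        X = np.column_stack([x, -x, 2 * x + 1])
        adata = make_adata(X, genes=["anchor", "neg", "lin"])
        r = signatures.gene_correlations(adata, "anchor", ["anchor", "neg", "lin"])
        assert r["anchor"] == pytest.approx(1.0)
        assert r["neg"] == pytest.approx(-1.0)
        assert r["lin"] == pytest.approx(1.0)

    def test_zero_variance_target_missing(self, rng):
        X = np.column_stack([rng.random(10), np.full(10, 3.0)])
        adata = make_adata(X, genes=["anchor", "flat"])
        with pytest.warns(UserWarning):
            r = signatures.gene_correlations(adata, "anchor", ["flat"])
        assert np.isnan(r["flat"])

    def test_too_few_cells_rejected(self, rng):
        adata = make_adata(rng.random((2, 3)))
        with pytest.raises(ValueError):
            signatures.gene_correlations(adata, "g00", ["g01"])
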