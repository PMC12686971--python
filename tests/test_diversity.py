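import numpy as np
import pytest
from scipy.special import comb
from scipy.stats import hypergeom

from invpopgen.diversity import (
    diversity_table,
    fst_bootstrap_ci,
    heterozygosity,
    kruskal_wallis_bh,
    overall_fst,
    pairwise_fst,
    private_alleles,
    rarefied_allelic_richness,
)

from conftest import make_gm, make_meta

N = np.nan


class TestHeterozygosity:
    def test_all_heterozygotes_hand_values(self):
        # two individuals, both 0/1 at both loci: Ho = 1, p = 0.5,
        # unbiased He = (2n/(2n-1)) 2pq = 4/3 * 0.5 = 2/3, Fis = 1 - 1/(2/3) = -0.5
        gm = make_gm([[1, 1], [1, 1]])
        meta = make_meta(["p", "p"])
        het = heterozygosity(gm, meta)
        assert het.loc["p", "Ho"] == pytest.approx(1.0)
        assert het.loc["p", "He"] == pytest.approx(2 / 3)
        assert het.loc["p", "Fis"] == pytest.approx(-0.5)

    def test_monomorphic_population_nan_fis(self):
        gm = make_gm([[0, 2], [0, 2]])
        meta = make_meta(["p", "p"])
        het = heterozygosity(gm, meta)
        assert het.loc["p", "He"] == 0.0
        assert np.isnan(het.loc["p", "Fis"])

    def test_missing_calls_ignored_per_locus(self):
        gm = make_gm([[1, N], [1, 2], [N, 2]])
        meta = make_meta(["p", "p", "p"])
        het = heterozygosity(gm, meta)
        # locus 1: n=2 hets only -> Ho=1, He=2/3; locus 2: monomorphic He=0, Ho=0
        assert het.loc["p", "Ho"] == pytest.approx(0.5)
        assert het.loc["p", "He"] == pytest.approx(1 / 3)


class TestRarefaction:
    def test_matches_hypergeometric_enumeration(self):
        # one population, N = 20 copies with allele counts (18, 2), g = 12
        dosages = np.array([[2]] * 8 + [[1]] * 2 + [[0]] * 0, dtype=float)
        # 8 hom alt (16) + 2 het (2) = alt 18 of 20
        gm = make_gm(dosages)
        meta = make_meta(["p"] * 10)
        ar = rarefied_allelic_richness(gm, meta, g=12)
        expected = 2 - comb(20 - 18, 12) / comb(20, 12) - comb(20 - 2, 12) / comb(20, 12)
        assert ar["p"] == pytest.approx(expected)
        # independent oracle: P(allele present in subsample) via hypergeom
        oracle = sum(
            1.0 - hypergeom(20, n_i, 12).pmf(0) for n_i in (18, 2)
        )
        assert ar["p"] == pytest.approx(oracle)

    def test_locus_dropped_when_any_pop_below_g(self):
        gm = make_gm(
            np.array([[1, 1], [1, N], [1, N], [1, 1], [1, 1], [1, 1]], dtype=float)
        )
        meta = make_meta(["a", "a", "a", "b", "b", "b"])
        # locus 2 has only 2 copies in pop a -> dropped for both pops at g=4
        ar = rarefied_allelic_richness(gm, meta, g=4)
        expected = 2 - 2 * comb(3, 4) / comb(6, 4)  # counts (3,3), C(3,4)=0
        assert ar["a"] == pytest.approx(2.0)
        assert ar["b"] == pytest.approx(2.0)
        assert expected == 2.0

    def test_no_usable_locus_raises(self):
        gm = make_gm([[1], [1]])
        meta = make_meta(["a", "b"])
        with pytest.raises(ValueError, match="gene copies"):
            rarefied_allelic_richness(gm, meta, g=12)

    def test_g_floor(self):
        gm = make_gm([[1], [1]])
        meta = make_meta(["a", "b"])
        with pytest.raises(ValueError, match=">= 2"):
            rarefied_allelic_richness(gm, meta, g=1)


class TestPrivateAlleles:
    def test_hand_case(self):
        # locus 1: pop a has alt (private), both have ref
        # locus 2: both polymorphic -> nothing private
        # locus 3: a fixed ref, b fixed alt -> ref private to a, alt private to b
        gm = make_gm(
            np.array([[1, 1, 0], [0, 1, 0], [0, 1, 2], [0, 1, 2]], dtype=float)
        )
        meta = make_meta(["a", "a", "b", "b"])
        ap = private_alleles(gm, meta)
        assert ap["a"] == 2  # alt at locus 1 + ref at locus 3
        assert ap["b"] == 1  # alt at locus 3


class TestPairwiseFst:
    def test_numeric_fixture(self):
        # pop1: 10 individuals, p1 = 0.9; pop2: 10 individuals, p2 = 0.5
        pop1 = [[2]] * 8 + [[1]] * 2
        pop2 = [[2]] * 5 + [[0]] * 5
        gm = make_gm(np.array(pop1 + pop2, dtype=float))
        meta = make_meta(["a"] * 10 + ["b"] * 10)
        fst = pairwise_fst(gm, meta)
        he1 = 20 / 19 * 2 * 0.9 * 0.1
        he2 = 20 / 19 * 2 * 0.5 * 0.5
        hs = (he1 + he2) / 2
        ht = 2 * 0.7 * 0.3 + hs / (2 * 10 * 2)
        assert fst.get("a", "b") == pytest.approx((ht - hs) / ht)

    def test_wahlund_fixed_difference(self):
        gm = make_gm(np.array([[0]] * 4 + [[2]] * 4, dtype=float))
        meta = make_meta(["a"] * 4 + ["b"] * 4)
        fst = pairwise_fst(gm, meta)
        # Hs = 0, Ht = 2*0.25 + 0 = 0.5 -> F_ST = 1
        assert fst.get("a", "b") == pytest.approx(1.0)

    def test_negative_estimates_not_truncated(self):
        # identical small samples: sampling correction drives the estimate < 0
        gm = make_gm(np.array([[1], [1], [1], [1]], dtype=float))
        meta = make_meta(["a", "a", "b", "b"])
        fst = pairwise_fst(gm, meta)
        hs = 2 / 3
        ht = 0.5 + hs / 8
        assert fst.get("a", "b") == pytest.approx((ht - hs) / ht)
        assert fst.get("a", "b") < 0

    def test_monomorphic_pair_nan(self):
        gm = make_gm(np.zeros((4, 2)))
        meta = make_meta(["a", "a", "b", "b"])
        fst = pairwise_fst(gm, meta)
        assert np.isnan(fst.get("a", "b"))

    def test_single_individual_pop_rejected(self):
        gm = make_gm(np.ones((3, 2)))
        meta = make_meta(["a", "a", "b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            pairwise_fst(gm, meta)

    def test_overall_equals_pairwise_for_two_pops(self):
        rng = np.random.default_rng(5)
        gm = make_gm(rng.integers(0, 3, size=(12, 40)).astype(float))
        meta = make_meta(["a"] * 6 + ["b"] * 6)
        pw = pairwise_fst(gm, meta).get("a", "b")
        ov = overall_fst(gm, meta)
        assert ov == pytest.approx(pw)

    def test_overall_needs_two_pops(self):
        gm = make_gm(np.ones((2, 2)))
        meta = make_meta(["a", "a"])
        with pytest.raises(ValueError, match="two populations"):
            overall_fst(gm, meta)


class TestBootstrapCI:
    def test_ci_brackets_point_estimate(self, structured_dataset):
        gm, meta, _ = structured_dataset
        res = fst_bootstrap_ci(gm, meta, n_boot=200, seed=1)
        iu = np.triu_indices(res.n, k=1)
        assert (res.ci_low[iu] <= res.values[iu] + 1e-12).all()
        assert (res.ci_high[iu] >= res.values[iu] - 1e-12).all()
        assert (res.ci_high[iu] > res.ci_low[iu]).all()

    def test_single_locus_degenerate_ci(self):
        pop1 = [[2]] * 5
        pop2 = [[0]] * 5
        gm = make_gm(np.array(pop1 + pop2, dtype=float))
        meta = make_meta(["a"] * 5 + ["b"] * 5)
        res = fst_bootstrap_ci(gm, meta, n_boot=50, seed=0)
        assert res.ci_low[0, 1] == pytest.approx(res.values[0, 1])
        assert res.ci_high[0, 1] == pytest.approx(res.values[0, 1])

    def test_invalid_n_boot(self, structured_dataset):
        gm, meta, _ = structured_dataset
        with pytest.raises(ValueError, match="n_boot"):
            fst_bootstrap_ci(gm, meta, n_boot=0)


class TestKruskalWallis:
    def test_hand_ranks(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        out = kruskal_wallis_bh(values, groups)
        # mean ranks 2 and 5: H = 12/(6*7) * 3((2-3.5)^2 + (5-3.5)^2) = 27/7
        assert out["H"] == pytest.approx(27 / 7)
        row = out["pairwise"].iloc[0]
        se = np.sqrt((6 * 7 / 12) * (1 / 3 + 1 / 3))
        assert row["z"] == pytest.approx((2 - 5) / se)
        assert row["p_adj"] >= row["p"] - 1e-12

    def test_identical_values_guard(self):
        out = kruskal_wallis_bh(np.ones(6), np.array(["a"] * 3 + ["b"] * 3))
        assert out["H"] == 0.0
        assert out["p"] == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            kruskal_wallis_bh(np.arange(3.0), np.array(["a"] * 3))

    def test_bh_adjustment_monotone(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.normal(0, 1, 10), rng.normal(3, 1, 10), rng.normal(0, 1, 10)])
        groups = np.array(["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        out = kruskal_wallis_bh(values, groups)
        tab = out["pairwise"]
        assert (tab["p_adj"] >= tab["p"] - 1e-12).all()
        assert (tab["p_adj"] <= 1.0 + 1e-12).all()


def test_diversity_table_shape(structured_dataset):
    gm, meta, _ = structured_dataset
    table = diversity_table(gm, meta, g=12)
    assert list(table.columns) == ["n", "Ar", "Ap", "Ho", "He", "Fis"]
    assert len(table) == 6
    assert (table["n"] == 12).all()
    assert table["He"].between(0, 1).all()
    assert (table["Ar"] <= 2.0).all() and (table["Ar"] >= 1.0).all()
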