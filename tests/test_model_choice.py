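import numpy as np
import pandas as pd
import pytest

from invpopgen.coalescent import GROUPS, NATIVE, build_model, default_priors, simulate_snps, sim_metadata
from invpopgen.diversity import heterozygosity, overall_fst, pairwise_fst, private_alleles
from invpopgen.model_choice import (
    ModelPosterior,
    ReferenceTable,
    abc_mnlogistic,
    abc_neuralnet,
    abc_random_forest,
    abc_reject,
    build_reference_table,
    cross_validate,
    estimate_params,
    fit_random_forest,
    summarize,
    summary_stat_names,
)


def synthetic_table(n_per_model=40, n_models=3, n_stats=6, seed=0, shift=3.0):
    """Hand-built reference table whose models differ by a mean shift."""
    rng = np.random.default_rng(seed)
    names = [f"m{k}" for k in range(n_models)]
    models, stats, params = [], [], []
    for k, name in enumerate(names):
        x = rng.normal(k * shift, 1.0, size=(n_per_model, n_stats))
        stats.append(x)
        models += [name] * n_per_model
        params.append(
            pd.DataFrame({"theta": rng.uniform(0, 1, n_per_model)})
        )
    return ReferenceTable(
        models=np.asarray(models),
        params=pd.concat(params, ignore_index=True),
        stats=np.vstack(stats),
        stat_names=[f"s{j}" for j in range(n_stats)],
        n_per_model=n_per_model,
    )


class TestSummarize:
    def test_names_and_order(self):
        names = summary_stat_names(["A", "B"])
        assert names == ["He_A", "Ho_A", "S_A", "Ap_A", "He_B", "Ho_B", "S_B", "Ap_B", "fst_A_B", "fst_overall"]

    def test_consistent_with_direct_statistics(self):
        sizes = {NATIVE: 5, **{g: 5 for g in GROUPS}}
        gm = simulate_snps(build_model("Grp2_bridge"), sizes, 30, seed=4)
        meta = sim_metadata(sizes)
        s = summarize(gm, meta, level="group")
        het = heterozygosity(gm, meta, level="group")
        ap = private_alleles(gm, meta, level="group")
        fst = pairwise_fst(gm, meta, level="group")
        assert s["He_Grp2"] == pytest.approx(het.loc["Grp2", "He"])
        assert s["Ap_Grp4"] == float(ap["Grp4"])
        assert s["fst_Grp1_Grp2"] == pytest.approx(fst.get("Grp1", "Grp2"))
        assert s["fst_overall"] == pytest.approx(overall_fst(gm, meta, level="group"))
        assert list(s.index) == summary_stat_names(sorted({NATIVE, *GROUPS}))
        assert not s.isna().any()


class TestReferenceTable:
    def test_unbalanced_rejected(self):
        t = synthetic_table()
        with pytest.raises(ValueError, match="balanced"):
            ReferenceTable(
                models=t.models[1:],
                params=t.params.iloc[1:].reset_index(drop=True),
                stats=t.stats[1:],
                stat_names=t.stat_names,
                n_per_model=t.n_per_model,
            )

    def test_nan_stats_rejected(self):
        t = synthetic_table()
        bad = t.stats.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing statistics"):
            ReferenceTable(t.models, t.params, bad, t.stat_names, t.n_per_model)

    def test_standardization_uses_table_constants_only(self):
        t = synthetic_table()
        obs = np.full(t.stats.shape[1], 1e6)  # wild observed vector
        z = t.standardized(obs)
        np.testing.assert_allclose(z, (obs - t.location) / t.scale)
        # table constants unchanged by standardising an observation
        np.testing.assert_allclose(t.location, np.median(t.stats, axis=0))

    def test_mad_floor(self):
        t = synthetic_table()
        stats = t.stats.copy()
        stats[:, 0] = 7.0  # constant statistic -> MAD 0 -> floor 1
        t2 = ReferenceTable(t.models, t.params, stats, t.stat_names, t.n_per_model)
        assert t2.scale[0] == 1.0


class TestRejection:
    def test_tolerance_one_returns_prior_exactly(self):
        t = synthetic_table()
        obs = np.zeros(t.stats.shape[1])
        post = abc_reject(obs, t, tolerance=1.0)
        np.testing.assert_allclose(post.probs.to_numpy(), 1 / 3)
        assert post.accepted == t.n

    def test_matches_exhaustive_sort_oracle(self):
        rng = np.random.default_rng(17)
        t = synthetic_table(n_per_model=100, n_models=5, seed=17)  # 500 rows
        for tol in (0.01, 0.05, 0.2):
            obs = rng.normal(5.0, 3.0, size=t.stats.shape[1])
            post = abc_reject(obs, t, tolerance=tol)
            # independent oracle: full sort on re-derived distances
            loc = np.median(t.stats, axis=0)
            mad = np.median(np.abs(t.stats - loc), axis=0)
            mad = np.where(mad > 0, mad, 1.0)
            z = (t.stats - loc) / mad
            zo = (obs - loc) / mad
            d = np.sqrt(((z - zo) ** 2).sum(axis=1))
            n_accept = int(np.ceil(tol * t.n))
            idx = np.argsort(d, kind="stable")[:n_accept]
            expected = pd.Series(t.models[idx]).value_counts(normalize=True)
            for m in post.probs.index:
                assert post.probs[m] == pytest.approx(expected.get(m, 0.0))
            assert post.accepted == n_accept

    def test_tolerance_bounds(self):
        t = synthetic_table()
        with pytest.raises(ValueError, match="tolerance"):
            abc_reject(np.zeros(6), t, tolerance=0.0)
        with pytest.raises(ValueError, match="tolerance"):
            abc_reject(np.zeros(6), t, tolerance=1.5)


class TestClassifiers:
    def test_all_algorithms_valid_simplex(self):
        t = synthetic_table()
        obs = t.stats[5] + 0.1  # near model m0
        for post in (
            abc_reject(obs, t, 0.2),
            abc_mnlogistic(obs, t, 0.5),
            abc_neuralnet(obs, t, 0.5, seed=0, n_restarts=2),
            abc_random_forest(obs, t, n_trees=100, seed=0),
        ):
            assert isinstance(post, ModelPosterior)
            p = post.probs.to_numpy()
            assert p.sum() == pytest.approx(1.0)
            assert (p >= 0).all()
            assert set(post.probs.index) == {"m0", "m1", "m2"}

    def test_well_separated_models_identified(self):
        t = synthetic_table(shift=8.0)
        obs = t.stats[t.models == "m1"].mean(axis=0)
        assert abc_reject(obs, t, 0.1).best_model() == "m1"
        assert abc_mnlogistic(obs, t, 0.5).best_model() == "m1"
        assert abc_random_forest(obs, t, n_trees=200, seed=1).best_model() == "m1"

    def test_single_model_accepted_set(self):
        t = synthetic_table(shift=50.0)
        obs = t.stats[t.models == "m2"].mean(axis=0)
        tol = 0.05  # ceil(0.05 * 120) = 6 rows, all m2
        for fn in (abc_mnlogistic, abc_neuralnet):
            post = fn(obs, t, tol)
            assert post.probs["m2"] == pytest.approx(1.0)

    def test_rf_votes_sum_to_trees(self):
        t = synthetic_table()
        post = abc_random_forest(t.stats[0], t, n_trees=50, seed=2)
        assert int(post.votes.sum()) == 50

    def test_rf_prefit_reuse_identical(self):
        t = synthetic_table()
        forest = fit_random_forest(t, n_trees=60, seed=5)
        for obs in (t.stats[0], t.stats[50], t.stats[-1]):
            one_shot = abc_random_forest(obs, t, n_trees=60, seed=5)
            reused = abc_random_forest(obs, fitted=forest)
            pd.testing.assert_series_equal(one_shot.probs, reused.probs)
            pd.testing.assert_series_equal(one_shot.votes, reused.votes)

    def test_rf_requires_table_or_fit(self):
        with pytest.raises(ValueError, match="reference table or a fitted"):
            abc_random_forest(np.zeros(6))


class TestEstimateParams:
    def _regression_table(self, n=400, seed=3):
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0, 1, n)
        stats = np.column_stack([theta + rng.normal(0, 0.05, n), rng.normal(0, 1, n)])
        return ReferenceTable(
            models=np.asarray(["m"] * n),
            params=pd.DataFrame({"theta": theta}),
            stats=stats,
            stat_names=["s0", "s1"],
            n_per_model=n,
        )

    def test_unadjusted_returns_accepted_draws(self):
        t = self._regression_table()
        obs = np.array([0.8, 0.0])
        out = estimate_params(obs, t, "m", tolerance=0.1, adjust=False)
        assert len(out) == int(np.ceil(0.1 * t.n))
        assert out["theta"].between(0, 1).all()

    def test_adjusted_recovers_truth(self):
        t = self._regression_table()
        obs = np.array([0.8, 0.0])
        post = estimate_params(
            obs, t, "m", tolerance=0.2, bounds={"theta": (0.0, 1.0)}
        )
        assert post["theta"].mean() == pytest.approx(0.8, abs=0.05)
        assert post["theta"].between(0, 1).all()
        # the adjustment tightens the posterior relative to plain rejection
        plain = estimate_params(obs, t, "m", tolerance=0.2, adjust=False)
        assert post["theta"].std() < plain["theta"].std()

    def test_bounds_respected_at_edges(self):
        t = self._regression_table()
        obs = np.array([0.01, 0.0])
        post = estimate_params(obs, t, "m", 0.2, bounds={"theta": (0.0, 1.0)})
        assert post["theta"].between(0, 1).all()


class TestCrossValidate:
    def test_rejection_contract(self):
        t = synthetic_table(shift=8.0)
        cm = cross_validate(t, 4, "rejection", tolerance=0.1, seed=0)
        assert 0.0 <= cm.accuracy <= 1.0
        assert cm.counts.to_numpy().sum() == 12
        assert cm.accuracy > 0.8  # well separated models
        assert cm.oob_error is None

    def test_random_forest_oob(self):
        t = synthetic_table(shift=8.0)
        cm = cross_validate(t, 4, "randomforest", seed=0, n_trees=100)
        assert cm.oob_error == pytest.approx(1.0 - cm.accuracy)
        assert cm.accuracy > 0.8

    def test_unknown_algorithm(self):
        t = synthetic_table()
        with pytest.raises(ValueError, match="unknown algorithm"):
            cross_validate(t, 2, "magic")


def test_build_reference_table_end_to_end():
    sizes = {NATIVE: 4, **{g: 4 for g in GROUPS}}
    t = build_reference_table(
        ["Grp2_bridge", "W2E_step"],
        default_priors(),
        4,
        sizes,
        n_loci=25,
        seed=1,
    )
    assert t.n == 8
    assert t.stats.shape == (8, len(t.stat_names))
    assert t.stat_names == summary_stat_names(sorted({NATIVE, *GROUPS}))
    assert set(t.params.columns) >= {"ne_native", "m_weak", "founder_Grp1"}
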