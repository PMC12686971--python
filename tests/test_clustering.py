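import numpy as np
import pytest

from invpopgen.clustering import (
    bootstrap_supports,
    dapc,
    find_clusters,
    kmeans_bic,
    nj_tree,
    optimal_n_pcs,
    pca,
)
from invpopgen.core import PairwiseMatrix

from conftest import make_gm, make_meta


def blob_data(n_per=10, n_groups=3, n_loci=60, seed=0):
    """Strongly separated groups: each group fixed for its own block of loci."""
    rng = np.random.default_rng(seed)
    block = n_loci // n_groups
    dosages = np.zeros((n_per * n_groups, n_loci))
    for g in range(n_groups):
        rows = slice(g * n_per, (g + 1) * n_per)
        dosages[rows, g * block : (g + 1) * block] = 2.0
    flip = rng.random(dosages.shape) < 0.02
    dosages[flip] = 1.0
    labels = np.repeat([f"g{g}" for g in range(n_groups)], n_per)
    return make_gm(dosages), labels


class TestPCA:
    def test_matches_eigendecomposition(self):
        rng = np.random.default_rng(3)
        gm = make_gm(rng.integers(0, 3, size=(15, 30)).astype(float))
        res = pca(gm)
        xc = gm.dosages - gm.dosages.mean(axis=0)
        evals = np.linalg.eigvalsh(xc @ xc.T)[::-1]
        var = res.explained_variance_ratio * evals.sum()
        np.testing.assert_allclose(var, evals[: len(var)], atol=1e-8)
        # scores reproduce the centred matrix through the loadings
        np.testing.assert_allclose(res.scores @ res.components, xc, atol=1e-8)

    def test_missing_mean_imputed(self):
        gm = make_gm([[0, np.nan], [2, 1], [1, 1]])
        res = pca(gm)
        assert np.isfinite(res.scores).all()

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(4)
        gm = make_gm(rng.integers(0, 3, size=(10, 20)).astype(float))
        a = pca(gm)
        b = pca(gm)
        np.testing.assert_array_equal(a.scores, b.scores)
        for row in a.components:
            assert row[np.argmax(np.abs(row))] > 0

    def test_needs_two_individuals(self):
        with pytest.raises(ValueError, match="at least 2"):
            pca(make_gm(np.ones((1, 3))))


class TestFindClusters:
    def test_recovers_three_blobs(self):
        gm, labels = blob_data()
        res = find_clusters(gm, k_max=8, seed=0)
        assert res.K == 3
        # hard labels define the same partition as the truth
        for g in np.unique(labels):
            assert len(set(res.hard_labels[labels == g])) == 1
        assert len(set(res.hard_labels)) == 3
        np.testing.assert_allclose(res.memberships.sum(axis=1), 1.0)

    def test_bic_curve_complete(self):
        gm, _ = blob_data()
        res = find_clusters(gm, k_max=5, seed=0)
        assert sorted(res.bic_curve) == [1, 2, 3, 4, 5]

    def test_k_max_too_large(self):
        gm, _ = blob_data(n_per=2)
        with pytest.raises(ValueError, match="k_max"):
            find_clusters(gm, k_max=6)

    def test_bic_formula(self):
        assert kmeans_bic(10, 5.0, 2) == pytest.approx(
            10 * np.log(0.5) + 2 * np.log(10)
        )


class TestDAPC:
    def test_perfect_separation(self):
        gm, labels = blob_data()
        res = dapc(gm, labels, n_pcs=5)
        assert res.self_assignment == 1.0
        np.testing.assert_allclose(res.memberships.sum(axis=1), 1.0)
        assert res.scores.shape == (30, 2)  # 3 groups -> 2 discriminant axes

    def test_overfit_warning_when_all_pcs(self, caplog):
        gm, labels = blob_data(n_per=4)
        with caplog.at_level("WARNING"):
            dapc(gm, labels, n_pcs=10_000)
        assert any("overfitting" in r.message for r in caplog.records)

    def test_a_score_selection(self):
        gm, labels = blob_data()
        best, scores = optimal_n_pcs(gm, labels, seed=0)
        assert best in scores
        assert all(-1.0 <= v <= 1.0 for v in scores.values())
        # separable data: the winning a-score is clearly positive
        assert scores[best] > 0.3


def _random_additive_tree(rng, n_taxa):
    """Random unrooted binary tree; returns (distance matrix, bipartitions)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n_taxa)}
    nxt = n_taxa

    def connect(a, b, ln):
        adj.setdefault(a, []).append((b, ln))
        adj.setdefault(b, []).append((a, ln))

    active = list(range(n_taxa))
    while len(active) > 3:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[i], active[j]
        new = nxt
        nxt += 1
        connect(a, new, rng.uniform(0.5, 2.0))
        connect(b, new, rng.uniform(0.5, 2.0))
        active = [x for x in active if x not in (a, b)] + [new]
    hub = nxt
    for a in active:
        connect(a, hub, rng.uniform(0.5, 2.0))

    # pairwise leaf distances by BFS
    d = np.zeros((n_taxa, n_taxa))
    for s in range(n_taxa):
        dist = {s: 0.0}
        stack = [s]
        while stack:
            u = stack.pop()
            for v, ln in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + ln
                    stack.append(v)
        for t in range(n_taxa):
            d[s, t] = dist[t]
    d = (d + d.T) / 2  # exact symmetry for downstream consumers

    # true bipartitions from internal edges
    all_set = frozenset(labels)
    bips = set()
    for u in adj:
        for v, _ in adj[u]:
            if u < n_taxa or v < n_taxa or u > v:
                continue
            # leaves on u's side when edge (u, v) removed
            seen = {u}
            stack = [u]
            while stack:
                w = stack.pop()
                for x, _ in adj[w]:
                    if x != v and x not in seen and not (w == u and x == v):
                        if x not in seen:
                            seen.add(x)
                            stack.append(x)
            side = frozenset(labels[x] for x in seen if x < n_taxa)
            if 1 < len(side) < n_taxa - 1:
                bips.add(frozenset([side, all_set - side]))
    return PairwiseMatrix(labels, d), bips


class TestNJ:
    def test_recovers_random_additive_trees(self):
        rng = np.random.default_rng(12)
        for rep in range(50):
            n_taxa = int(rng.integers(5, 13))
            d, true_bips = _random_additive_tree(rng, n_taxa)
            tree = nj_tree(d)
            assert tree.bipartitions() == true_bips
            assert not tree.negative_clamped

    def test_patristic_distances_exact_for_additive(self):
        rng = np.random.default_rng(7)
        d, _ = _random_additive_tree(rng, 6)
        tree = nj_tree(d)
        tt = tree.tree.tip_tip_distances()
        for a in d.labels:
            for b in d.labels:
                if a != b:
                    assert tt[a, b] == pytest.approx(d.get(a, b), abs=1e-9)

    def test_too_few_taxa(self):
        d = PairwiseMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(d)

    def test_nonfinite_rejected(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            nj_tree(PairwiseMatrix(["a", "b", "c"], vals))

    def test_negative_branch_clamped_and_flagged(self):
        # strongly non-additive matrix forces a negative NJ branch
        vals = np.array(
            [
                [0.0, 1.0, 8.0, 8.0],
                [1.0, 0.0, 8.0, 8.0],
                [8.0, 8.0, 0.0, 0.1],
                [8.0, 8.0, 0.1, 0.0],
            ]
        )
        tree = nj_tree(PairwiseMatrix(["a", "b", "c", "d"], vals))
        for node in tree.tree.traverse():
            assert node.length is None or node.length >= 0


def test_bootstrap_supports_on_structured_data(structured_dataset):
    gm, meta, _ = structured_dataset
    tree = bootstrap_supports(gm, meta, n_boot=30, seed=2)
    assert tree.leaf_names() == {f"deme{d:02d}" for d in range(6)}
    assert tree.supports
    assert all(0.0 <= v <= 100.0 for v in tree.supports.values())
    assert "deme00" in tree.newick()
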