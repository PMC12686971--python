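"""Ordination, cluster-number selection, DAPC and neighbour-joining trees.

The clustering workflow mirrors the adegenet approach: k-means on
retained principal-component scores with an SSE-based BIC across
candidate K, followed by linear discriminant analysis on the PC scores
(DAPC) with an a-score criterion guarding against retaining too many
axes.  Population trees are neighbour-joining on the pairwise F_ST
matrix with locus-bootstrap bipartition supports.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np

from .core import GenotypeMatrix, PairwiseMatrix, SampleMetadata

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    scores: np.ndarray  # (n_individuals, n_components)
    explained_variance_ratio: np.ndarray
    components: np.ndarray  # (n_components, n_loci)
    mean: np.ndarray


def _imputed_centered(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    x = gm.dosages.copy()
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    nan_r, nan_c = np.nonzero(np.isnan(x))
    x[nan_r, nan_c] = col_mean[nan_c]
    return x - col_mean, col_mean


def pca(gm: GenotypeMatrix, n_components: int | None = None) -> PCAResult:
    """SVD principal components of the mean-imputed, centred dosage matrix.

    Missing calls are imputed with the per-locus mean dosage.  Component
    signs are fixed so the loading of largest magnitude is positive,
    making scores deterministic.
    """
    if gm.n_individuals < 2:
        raise ValueError("PCA needs at least 2 individuals")
    xc, col_mean = _imputed_centered(gm)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    max_rank = min(gm.n_individuals - 1, gm.n_loci)
    if n_components is None:
        n_components = max_rank
    n_components = min(n_components, max_rank)
    # deterministic sign: largest-|loading| entry of each axis positive
    for k in range(n_components):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    var = s**2
    evr = var / var.sum() if var.sum() > 0 else var
    scores = u[:, :n_components] * s[:n_components]
    return PCAResult(scores, evr[:n_components], vt[:n_components], col_mean)


# ---------------------------------------------------------------------------
# find.clusters-style K selection


@dataclass
class ClusterAssignment:
    K: int
    bic_curve: dict[int, float]
    memberships: np.ndarray  # (n_individuals, K) rows sum to 1
    hard_labels: np.ndarray


def kmeans_bic(n: int, sse: float, k: int) -> float:
    """SSE-based BIC, n*ln(SSE/n) + K*ln(n), with an SSE floor guard."""
    sse = max(sse, 1e-12)
    return n * np.log(sse / n) + k * np.log(n)


def find_clusters(
    gm: GenotypeMatrix,
    k_max: int = 10,
    n_pcs: int | None = None,
    seed: int | None = None,
    n_restarts: int = 10,
) -> ClusterAssignment:
    """Unsupervised k-means over K = 1..k_max on retained PC scores.

    The reported K minimises the SSE-based BIC; when the BIC curve has a
    plateau the whole curve should be inspected rather than trusting the
    argmin alone, so the curve is always returned.
    """
    from sklearn.cluster import KMeans

    n = gm.n_individuals
    if k_max >= n:
        raise ValueError("k_max must be smaller than the number of individuals")
    p = pca(gm, n_components=n_pcs)
    x = p.scores
    rng = np.random.default_rng(seed)
    bic_curve: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in range(1, k_max + 1):
        if k == 1:
            centre = x.mean(axis=0)
            sse = float(((x - centre) ** 2).sum())
            labels_by_k[1] = np.zeros(n, dtype=int)
        else:
            km = KMeans(
                n_clusters=k,
                n_init=n_restarts,
                random_state=int(rng.integers(0, 2**31 - 1)),
            ).fit(x)
            sse = float(km.inertia_)
            labels_by_k[k] = km.labels_
        bic_curve[k] = kmeans_bic(n, sse, k)
    best_k = min(bic_curve, key=bic_curve.get)
    hard = labels_by_k[best_k]
    memberships = np.zeros((n, best_k))
    memberships[np.arange(n), hard] = 1.0
    return ClusterAssignment(best_k, bic_curve, memberships, hard)


# ---------------------------------------------------------------------------
# DAPC


@dataclass
class DAPCResult:
    scores: np.ndarray  # discriminant-space coordinates
    memberships: np.ndarray  # posterior group membership
    group_labels: list
    n_pcs: int
    self_assignment: float


def dapc(
    gm: GenotypeMatrix,
    labels: np.ndarray,
    n_pcs: int,
    n_da: int | None = None,
) -> DAPCResult:
    """Linear discriminant analysis on retained PC scores.

    Membership posteriors come from the Gaussian class model in
    discriminant space (scikit-learn's LDA ``predict_proba``).
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    labels = np.asarray(labels)
    p = pca(gm)
    if n_pcs >= p.scores.shape[1]:
        logger.warning(
            "retaining all %d PC axes risks overfitting the discriminant analysis",
            p.scores.shape[1],
        )
        n_pcs = p.scores.shape[1]
    x = p.scores[:, :n_pcs]
    groups = list(dict.fromkeys(labels.tolist()))
    if n_da is None:
        n_da = min(len(groups) - 1, n_pcs)
    lda = LinearDiscriminantAnalysis(n_components=n_da)
    lda.fit(x, labels)
    scores = lda.transform(x)
    memberships = lda.predict_proba(x)
    self_assign = float((lda.predict(x) == labels).mean())
    return DAPCResult(scores, memberships, list(lda.classes_), n_pcs, self_assign)


def _reassignment_by_group(pred: np.ndarray, labels: np.ndarray) -> float:
    groups = np.unique(labels)
    return float(np.mean([np.mean(pred[labels == g] == g) for g in groups]))


def optimal_n_pcs(
    gm: GenotypeMatrix,
    labels: np.ndarray,
    seed: int | None = None,
    candidates: list[int] | None = None,
    n_perm: int = 10,
) -> tuple[int, dict[int, float]]:
    """a-score selection of the number of PC axes to retain for DAPC.

    a-score(n) = mean over groups of (observed reassignment proportion -
    mean reassignment under label permutation); the candidate with the
    highest a-score wins.  Returns (best_n, a-score per candidate).
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    labels = np.asarray(labels)
    p = pca(gm)
    max_pcs = p.scores.shape[1]
    if candidates is None:
        candidates = sorted({max(1, max_pcs * k // 10) for k in range(1, 10)})
    candidates = [c for c in candidates if 1 <= c <= max_pcs]
    if not candidates:
        raise ValueError("no valid PC-count candidates")
    if len(candidates) == 1:
        return candidates[0], {candidates[0]: np.nan}
    rng = np.random.default_rng(seed)
    scores: dict[int, float] = {}
    for n_pcs in candidates:
        x = p.scores[:, :n_pcs]
        lda = LinearDiscriminantAnalysis()
        lda.fit(x, labels)
        obs = _reassignment_by_group(lda.predict(x), labels)
        null = []
        for _ in range(n_perm):
            shuffled = rng.permutation(labels)
            lda_p = LinearDiscriminantAnalysis()
            lda_p.fit(x, shuffled)
            null.append(_reassignment_by_group(lda_p.predict(x), shuffled))
        scores[n_pcs] = obs - float(np.mean(null))
    best = max(scores, key=scores.get)
    return best, scores


# ---------------------------------------------------------------------------
# neighbour-joining trees with bootstrap


@dataclass
class Tree:
    """Unrooted population tree with optional bipartition supports."""

    tree: object  # skbio.TreeNode
    negative_clamped: bool = False
    supports: dict[frozenset, float] = field(default_factory=dict)

    def newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()

    def leaf_names(self) -> set[str]:
        return {t.name for t in self.tree.tips()}

    def bipartitions(self) -> set[frozenset]:
        return _bipartitions(self.tree)


def _bipartitions(tree) -> set[frozenset]:
    """Internal-edge bipartitions as orientation-free frozensets."""
    all_leaves = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(frozenset([side, all_leaves - side]))
    return out


def nj_tree(d: PairwiseMatrix) -> Tree:
    """Neighbour-joining on a population distance matrix.

    Negative branch lengths (possible for non-additive inputs) are
    clamped to zero and the clamping is flagged on the result.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    if d.n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    if not np.isfinite(d.values).all():
        raise ValueError("distance matrix contains non-finite entries")
    dm = DistanceMatrix(d.values, ids=d.labels)
    raw = skbio_nj(dm, neg_as_zero=False)
    clamped = False
    for node in raw.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped = True
    return Tree(raw, negative_clamped=clamped)


def bootstrap_supports(
    gm: GenotypeMatrix,
    meta: SampleMetadata,
    n_boot: int = 100,
    seed: int | None = None,
    level: str = "waterbody",
) -> Tree:
    """NJ tree on pairwise F_ST with locus-bootstrap bipartition supports.

    Supports are the percentage of trees built from locus resamples that
    contain each internal bipartition of the point-estimate tree; they
    are attached as internal node labels for newick export.
    """
    from .diversity import pairwise_fst

    rng = np.random.default_rng(seed)
    point = nj_tree(pairwise_fst(gm, meta, level=level))
    target = {bp: 0 for bp in point.bipartitions()}
    done = 0
    for _ in range(n_boot):
        idx = rng.integers(0, gm.n_loci, size=gm.n_loci)
        boot_d = _fst_on_locus_subset(gm, meta, idx, level)
        try:
            t = nj_tree(boot_d)
        except ValueError:
            continue
        done += 1
        for bp in t.bipartitions():
            if bp in target:
                target[bp] += 1
    supports = {bp: 100.0 * c / max(done, 1) for bp, c in target.items()}
    _attach_supports(point, supports)
    point.supports = supports
    return point


def _fst_on_locus_subset(
    gm: GenotypeMatrix, meta: SampleMetadata, idx: np.ndarray, level: str
) -> PairwiseMatrix:
    from .core import GenotypeMatrix as GM
    import pandas as pd

    lm = gm.locus_meta.iloc[idx].reset_index(drop=True).copy()
    lm["pos"] = np.arange(1, len(idx) + 1)  # re-key to dodge duplicate guard
    lm["chrom"] = "boot"
    sub = GM(gm.dosages[:, idx], lm, list(gm.ind_ids))
    from .diversity import pairwise_fst

    return pairwise_fst(sub, meta, level=level)


def _attach_supports(tree: Tree, supports: dict[frozenset, float]) -> None:
    all_leaves = frozenset(tree.leaf_names())
    for node in tree.tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        key = frozenset([side, all_leaves - side])
        if key in supports:
            node.name = f"{supports[key]:.0f}"
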