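"""Per-population diversity and pairwise divergence statistics.

Heterozygosity uses Nei's unbiased gene diversity, allelic richness is
rarefied by hypergeometric subsampling, and divergence is Nei's
(Ht - Hs)/Ht with small-sample corrections (the estimator family behind
hierfstat's ``pairwise.neifst``).  All statistics ignore missing calls
locus-by-locus; a population with no data at a locus simply contributes
nothing for that locus, and undefined summaries are reported as NaN
rather than silently as zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .core import GenotypeMatrix, PairwiseMatrix, SampleMetadata


# ---------------------------------------------------------------------------
# per-population allele counts


def _pop_counts(gm: GenotypeMatrix, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(n_genotyped_diploids, alt_allele_count) per locus for one population."""
    d = gm.dosages[idx, :]
    n = np.sum(~np.isnan(d), axis=0).astype(float)
    alt = np.nansum(d, axis=0)
    return n, alt


def _unbiased_he(n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Nei's unbiased gene diversity 2n/(2n-1) * 2p(1-p); NaN where n == 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        he = (2 * n) / (2 * n - 1) * 2 * p * (1 - p)
    he = np.where(n >= 1, he, np.nan)
    return np.where(n == 0.5, np.nan, he)  # unreachable guard; n is integral


def heterozygosity(
    gm: GenotypeMatrix,
    meta: SampleMetadata,
    level: str = "waterbody",
    pops: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Observed/expected heterozygosity and F_IS per population.

    Ho per locus is the heterozygote fraction among non-missing calls; He
    is Nei's unbiased gene diversity.  The population values are means
    over loci with data, and F_IS = 1 - mean(Ho)/mean(He) (ratio of
    means).  A population whose loci are all monomorphic has He = 0 and an
    undefined (NaN) F_IS.
    """
    if pops is None:
        pops = meta.populations(gm, level=level)
    rows = []
    for label, idx in pops.items():
        d = gm.dosages[idx, :]
        n, alt = _pop_counts(gm, idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / (2 * n)
            ho = np.nansum(d == 1, axis=0) / n
        he = _unbiased_he(n, p)
        has_data = n >= 1
        if not has_data.any():
            rows.append(
                {"pop": label, "n": len(idx), "Ho": np.nan, "He": np.nan, "Fis": np.nan}
            )
            continue
        mean_ho = float(np.nanmean(np.where(has_data, ho, np.nan)))
        mean_he = float(np.nanmean(np.where(has_data, he, np.nan)))
        fis = 1.0 - mean_ho / mean_he if mean_he > 0 else np.nan
        rows.append(
            {"pop": label, "n": len(idx), "Ho": mean_ho, "He": mean_he, "Fis": fis}
        )
    return pd.DataFrame(rows).set_index("pop")


# ---------------------------------------------------------------------------
# rarefied allelic richness and private alleles


def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefied_allelic_richness(
    gm: GenotypeMatrix,
    meta: SampleMetadata,
    g: int = 12,
    level: str = "waterbody",
) -> pd.Series:
    """Allelic richness rarefied to ``g`` gene copies.

    Per locus and population with N observed gene copies of which N_i are
    allele i, Ar = sum_i [1 - C(N - N_i, g) / C(N, g)], the expected
    number of distinct alleles in a hypergeometric subsample of ``g``
    copies.  Loci where any population has fewer than ``g`` copies are
    dropped from all populations so values stay comparable; the
    population value is the mean over retained loci.
    """
    if g < 2:
        raise ValueError("rarefaction size g must be >= 2")
    pops = meta.populations(gm, level=level)
    labels = list(pops)
    counts = {lab: _pop_counts(gm, idx) for lab, idx in pops.items()}
    valid = np.ones(gm.n_loci, dtype=bool)
    for lab in labels:
        n, _ = counts[lab]
        valid &= 2 * n >= g
    if not valid.any():
        raise ValueError(f"no locus has >= {g} gene copies in every population")
    out = {}
    for lab in labels:
        n, alt = counts[lab]
        ncopies = (2 * n)[valid]
        alt_v = alt[valid]
        ref_v = ncopies - alt_v
        ar = np.zeros(valid.sum())
        denom = _log_comb(ncopies, g)
        for allele_count in (ref_v, alt_v):
            rem = ncopies - allele_count
            term = np.where(
                rem >= g, np.exp(_log_comb(np.maximum(rem, g), g) - denom), 0.0
            )
            ar += 1.0 - term
        out[lab] = float(ar.mean())
    return pd.Series(out, name="Ar")


def private_alleles(
    gm: GenotypeMatrix,
    meta: SampleMetadata,
    level: str = "waterbody",
    pops: dict[str, np.ndarray] | None = None,
) -> pd.Series:
    """Count of alleles observed in exactly one population.

    An allele is private to population p when p carries at least one
    non-missing copy and every other population carries zero non-missing
    copies of it.
    """
    if pops is None:
        pops = meta.populations(gm, level=level)
    labels = list(pops)
    present = {}
    for lab, idx in pops.items():
        n, alt = _pop_counts(gm, idx)
        ref = 2 * n - alt
        present[lab] = np.stack([ref > 0, alt > 0])  # (2 alleles, n_loci)
    stacked = np.stack([present[lab] for lab in labels])  # (pops, 2, loci)
    n_pops_with = stacked.sum(axis=0)
    out = {}
    for k, lab in enumerate(labels):
        is_private = stacked[k] & (n_pops_with == 1)
        out[lab] = int(is_private.sum())
    return pd.Series(out, name="Ap")


def diversity_table(
    gm: GenotypeMatrix, meta: SampleMetadata, g: int = 12, level: str = "waterbody"
) -> pd.DataFrame:
    """Combined per-population table: n, Ar, Ap, Ho, He, Fis."""
    het = heterozygosity(gm, meta, level=level)
    ar = rarefied_allelic_richness(gm, meta, g=g, level=level)
    ap = private_alleles(gm, meta, level=level)
    out = het.join(ar).join(ap)
    return out[["n", "Ar", "Ap", "Ho", "He", "Fis"]]


# ---------------------------------------------------------------------------
# Nei F_ST


def _pair_locus_components(
    n1: np.ndarray, p1: np.ndarray, n2: np.ndarray, p2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus (Ht - Hs, Ht, usable) for one population pair.

    Hs is the mean of the two unbiased within-population gene
    diversities; Ht is the pooled-pair gene diversity from the unweighted
    mean allele frequency plus Nei's sample-size correction
    Hs / (2 * n_harmonic * 2).  Loci with data in only one population or
    monomorphic across the pair are unusable.
    """
    usable = (n1 >= 1) & (n2 >= 1)
    pbar = (p1 + p2) / 2.0
    poly = usable & (pbar > 0) & (pbar < 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        hs = (_unbiased_he(n1, p1) + _unbiased_he(n2, p2)) / 2.0
        nh = 2.0 / (1.0 / n1 + 1.0 / n2)
        ht = 2 * pbar * (1 - pbar) + hs / (2 * nh * 2)
    return ht - hs, ht, poly


def pairwise_fst(
    gm: GenotypeMatrix,
    meta: SampleMetadata,
    level: str = "waterbody",
    pops: dict[str, np.ndarray] | None = None,
) -> PairwiseMatrix:
    """Nei pairwise F_ST = (Ht - Hs)/Ht, ratio of sums over usable loci.

    Negative estimates are reported as computed (no truncation at zero).
    """
    if pops is None:
        pops = meta.populations(gm, level=level)
    labels = list(pops)
    for lab, idx in pops.items():
        if len(idx) < 2:
            raise ValueError(f"population {lab!r} has fewer than 2 individuals")
    counts = {}
    for lab, idx in pops.items():
        n, alt = _pop_counts(gm, idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            counts[lab] = (n, alt / (2 * n))
    vals = np.zeros((len(labels), len(labels)))
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            n1, p1 = counts[labels[i]]
            n2, p2 = counts[labels[j]]
            num, den, poly = _pair_locus_components(n1, p1, n2, p2)
            if not poly.any():
                vals[i, j] = vals[j, i] = np.nan
                continue
            fst = np.nansum(num[poly]) / np.nansum(den[poly])
            vals[i, j] = vals[j, i] = fst
    return PairwiseMatrix(labels, vals)


def overall_fst(
    gm: GenotypeMatrix,
    meta: SampleMetadata,
    level: str = "waterbody",
    pops: dict[str, np.ndarray] | None = None,
) -> float:
    """Multi-population Nei F_ST over all populations (ratio of sums)."""
    if pops is None:
        pops = meta.populations(gm, level=level)
    labels = list(pops)
    r = len(labels)
    if r < 2:
        raise ValueError("need at least two populations")
    ns, ps, hes = [], [], []
    for lab, idx in pops.items():
        n, alt = _pop_counts(gm, idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / (2 * n)
        ns.append(n)
        ps.append(p)
        hes.append(_unbiased_he(n, p))
    ns_a = np.stack(ns)
    ps_a = np.stack(ps)
    hes_a = np.stack(hes)
    usable = (ns_a >= 1).all(axis=0)
    pbar = ps_a.mean(axis=0)
    poly = usable & (pbar > 0) & (pbar < 1)
    hs = hes_a.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        nh = r / (1.0 / ns_a).sum(axis=0)
        ht = 2 * pbar * (1 - pbar) + hs / (2 * nh * r)
    return float(np.nansum((ht - hs)[poly]) / np.nansum(ht[poly]))


def fst_bootstrap_ci(
    gm: GenotypeMatrix,
    meta: SampleMetadata,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    level: str = "waterbody",
) -> PairwiseMatrix:
    """Percentile bootstrap CIs for pairwise F_ST, resampling loci.

    A pair is conventionally called significantly differentiated when its
    CI excludes zero.
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    rng = np.random.default_rng(seed)
    pops = meta.populations(gm, level=level)
    labels = list(pops)
    point = pairwise_fst(gm, meta, level=level)
    counts = {}
    for lab, idx in pops.items():
        n, alt = _pop_counts(gm, idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            counts[lab] = (n, alt / (2 * n))
    npop = len(labels)
    low = np.zeros((npop, npop))
    high = np.zeros((npop, npop))
    for i in range(npop):
        for j in range(i + 1, npop):
            n1, p1 = counts[labels[i]]
            n2, p2 = counts[labels[j]]
            num, den, poly = _pair_locus_components(n1, p1, n2, p2)
            idx = np.flatnonzero(poly)
            if idx.size == 0:
                low[i, j] = low[j, i] = np.nan
                high[i, j] = high[j, i] = np.nan
                continue
            picks = rng.integers(0, idx.size, size=(n_boot, idx.size))
            num_p = num[idx][picks]
            den_p = den[idx][picks]
            reps = np.nansum(num_p, axis=1) / np.nansum(den_p, axis=1)
            lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
            low[i, j] = low[j, i] = lo
            high[i, j] = high[j, i] = hi
    return PairwiseMatrix(labels, point.values, ci_low=low, ci_high=high)


# ---------------------------------------------------------------------------
# group-level hypothesis tests


def kruskal_wallis_bh(
    values: pd.Series | np.ndarray, groups: pd.Series | np.ndarray
) -> dict:
    """Kruskal-Wallis H over groups plus Dunn pairwise z-tests with
    Benjamini-Hochberg correction.

    Returns a dict with keys ``H``, ``p`` and ``pairwise`` (DataFrame of
    group1, group2, z, p, p_adj).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in labels]
    if np.ptp(values) == 0:  # scipy rejects all-identical data
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*samples)
    # Dunn's test: rank all values jointly, compare mean ranks
    n = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (n - 1)) if n > 1 else 0.0
    var_unit = n * (n + 1) / 12.0 - tie_term
    rows = []
    pvals = []
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            ra = ranks[groups == labels[a]]
            rb = ranks[groups == labels[b]]
            se = np.sqrt(var_unit * (1 / len(ra) + 1 / len(rb)))
            z = (ra.mean() - rb.mean()) / se if se > 0 else 0.0
            pz = 2 * stats.norm.sf(abs(z))
            rows.append({"group1": labels[a], "group2": labels[b], "z": z, "p": pz})
            pvals.append(pz)
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    table = pd.DataFrame(rows)
    table["p_adj"] = p_adj
    return {"H": float(h), "p": float(p), "pairwise": table}
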