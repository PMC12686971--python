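"""Isolation-by-distance and directionality-of-expansion statistics.

The Mantel test regresses linearised differentiation F_ST/(1 - F_ST) on
the natural log of great-circle distance and assesses significance by
permuting population labels of one matrix (one-sided, positive
association).  The directionality index psi compares derived- (or
minor-) allele frequencies between population pairs at loci polymorphic
in both; under a range expansion the downstream population carries, on
average, the higher conditional frequency, so the sign of psi points
away from the origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeMatrix, PairwiseMatrix, SampleMetadata

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088  # WGS84 mean radius


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km on a sphere of WGS84 mean radius."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def great_circle_km(meta: SampleMetadata, level: str = "waterbody") -> PairwiseMatrix:
    """Pairwise great-circle distances (km) between population centroids."""
    coords = meta.coords_by(level)
    labels = [str(l) for l in coords.index]
    lat = coords["lat"].to_numpy()
    lon = coords["lon"].to_numpy()
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        vals[i, :] = haversine_km(lat[i], lon[i], lat, lon)
    np.fill_diagonal(vals, 0.0)
    vals = (vals + vals.T) / 2  # guard tiny asymmetries from rounding
    return PairwiseMatrix(labels, vals)


@dataclass
class MantelResult:
    """Mantel correlation plus the paired linearised-F_ST regression."""

    r: float
    p: float
    n_perm: int
    slope: float
    intercept: float
    r2: float
    n_pops: int
    low_power: bool = False


def mantel_ibd(
    fst: PairwiseMatrix,
    dist_km: PairwiseMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """One-sided Mantel test of linearised F_ST against ln(distance).

    x = ln(km), y = F/(1-F) over unordered pairs; r is their Pearson
    correlation and p = (1 + #{permuted r >= observed}) / (n_perm + 1)
    under joint row/column permutation of the genetic matrix.  Pairs at
    zero distance or with F_ST exactly 1 are excluded with a warning.
    """
    if set(fst.labels) != set(dist_km.labels):
        raise ValueError("matrices must share labels")
    dist = dist_km.reordered(fst.labels)
    n = fst.n
    if n < 3:
        raise ValueError("need at least 3 populations")
    f = fst.values.copy()
    d = dist.values.copy()
    iu = np.triu_indices(n, k=1)
    bad = (d[iu] <= 0) | (f[iu] >= 1) | ~np.isfinite(f[iu])
    if bad.any():
        logger.warning(
            "excluding %d pairs with zero distance or undefined linearised F_ST",
            int(bad.sum()),
        )
    good = ~bad

    def stat(perm: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        fp = f[np.ix_(perm, perm)]
        y = fp[iu]
        y = y / (1.0 - y)
        x = np.log(d[iu])
        xg, yg = x[good], y[good]
        if xg.std() == 0 or yg.std() == 0:
            return 0.0, xg, yg
        return float(np.corrcoef(xg, yg)[0, 1]), xg, yg

    identity = np.arange(n)
    r_obs, x_obs, y_obs = stat(identity)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm, _, _ = stat(perm)
        if r_perm >= r_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    res = stats.linregress(x_obs, y_obs)
    return MantelResult(
        r=r_obs,
        p=p,
        n_perm=n_perm,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n_pops=n,
        low_power=n < 5,
    )


# ---------------------------------------------------------------------------
# directionality index


def _pop_freqs(gm: GenotypeMatrix, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = gm.dosages[idx, :]
    n = np.sum(~np.isnan(d), axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(d, axis=0) / (2 * n)
    return n, p


def directionality_index(
    gm: GenotypeMatrix,
    meta: SampleMetadata,
    level: str = "waterbody",
    outgroup: str | None = None,
    outgroup_max_freq: float = 0.10,
    n_boot: int = 1000,
    min_pop_n: int = 5,
    seed: int | None = None,
) -> tuple[PairwiseMatrix, PairwiseMatrix]:
    """Pairwise directionality index psi and its bootstrap z-scores.

    For each pair (i, j), loci polymorphic in both populations are kept
    and psi_ij = mean(f_j - f_i) over those loci, where f is the
    oriented-allele sample frequency.  Orientation uses the outgroup
    population when given (derived = allele absent or at frequency below
    ``outgroup_max_freq`` there); otherwise the pooled minor allele.
    z-scores come from a bootstrap over loci.  psi_ij > 0 indicates
    population j lies farther from the expansion origin than i.
    """
    pops = {
        lab: idx
        for lab, idx in meta.populations(gm, level=level).items()
        if lab != outgroup
    }
    pops = {lab: idx for lab, idx in pops.items() if len(idx) >= min_pop_n}
    labels = list(pops)
    if len(labels) < 2:
        raise ValueError("need at least two populations of sufficient size")
    rng = np.random.default_rng(seed)
    freqs = {lab: _pop_freqs(gm, idx) for lab, idx in pops.items()}

    # allele orientation: +1 keeps the ALT allele, -1 flips to REF
    if outgroup is not None:
        out_idx = meta.populations(gm, level=level).get(outgroup)
        if out_idx is None:
            raise ValueError(f"outgroup {outgroup!r} not present")
        n_out, p_out = _pop_freqs(gm, out_idx)
        flip = np.where((n_out >= 1) & (p_out > 1 - outgroup_max_freq), -1.0, 1.0)
        usable_orient = (n_out >= 1) & (
            (p_out <= outgroup_max_freq) | (p_out >= 1 - outgroup_max_freq)
        )
    else:
        all_n, all_p = _pop_freqs(gm, np.arange(gm.n_individuals))
        flip = np.where(all_p > 0.5, -1.0, 1.0)
        usable_orient = all_n >= 1

    npop = len(labels)
    psi = np.zeros((npop, npop))
    z = np.zeros((npop, npop))
    for a in range(npop):
        for b in range(a + 1, npop):
            n1, p1 = freqs[labels[a]]
            n2, p2 = freqs[labels[b]]
            shared = (
                usable_orient
                & (n1 >= 1)
                & (n2 >= 1)
                & (p1 > 0)
                & (p1 < 1)
                & (p2 > 0)
                & (p2 < 1)
            )
            idx = np.flatnonzero(shared)
            if idx.size == 0:
                psi[a, b] = psi[b, a] = np.nan
                z[a, b] = z[b, a] = np.nan
                logger.warning(
                    "no shared polymorphic loci for pair (%s, %s)",
                    labels[a],
                    labels[b],
                )
                continue
            f1 = np.where(flip[idx] > 0, p1[idx], 1 - p1[idx])
            f2 = np.where(flip[idx] > 0, p2[idx], 1 - p2[idx])
            diff = f2 - f1
            val = float(diff.mean())
            boots = diff[rng.integers(0, idx.size, size=(n_boot, idx.size))].mean(
                axis=1
            )
            se = float(boots.std(ddof=1))
            psi[a, b] = val
            psi[b, a] = -val
            zval = val / se if se > 0 else 0.0
            z[a, b] = zval
            z[b, a] = -zval
    return (
        PairwiseMatrix(labels, psi, antisymmetric=True),
        PairwiseMatrix(labels, z, antisymmetric=True),
    )
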