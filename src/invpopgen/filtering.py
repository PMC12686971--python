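"""Iterative SNP and sample filtering.

The filter chain mirrors a conventional RAD-seq VCFtools workflow:
site quality, minor allele count, per-locus missingness, read depth,
per-individual missingness, and distance thinning to one SNP per
window.  Because removing individuals changes allele counts and
missingness, the locus- and individual-level steps are repeated until a
fixed point is reached, which also makes the whole filter idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .core import GenotypeMatrix, SampleMetadata


@dataclass
class FilterConfig:
    """Thresholds for the filter chain.

    ``min_depth=None`` skips the depth filter (it is only used for the
    demographic-track dataset).  ``strict_locus_missing`` is the extra
    trim applied to the diversity-track dataset and is not part of
    :func:`filter_dataset` itself.
    """

    min_qual: float = 20.0
    min_mac: int = 3
    max_locus_missing: float = 0.55
    max_ind_missing: float = 0.70
    min_depth: float | None = None
    thin_spacing: int = 100_000
    strict_locus_missing: float = 0.20
    min_pop_n: int = 5

    def __post_init__(self) -> None:
        for name in ("max_locus_missing", "max_ind_missing", "strict_locus_missing"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.thin_spacing < 0:
            raise ValueError("thin_spacing must be >= 0")


@dataclass
class FilterReport:
    """Loci/individuals removed at each step (accumulated over iterations)."""

    loci_removed_qual: int = 0
    loci_removed_mac: int = 0
    loci_removed_missing: int = 0
    loci_removed_depth: int = 0
    inds_removed_missing: int = 0
    loci_removed_thin: int = 0
    n_iterations: int = 0
    loci_in: int = 0
    inds_in: int = 0
    loci_out: int = 0
    inds_out: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def minor_allele_counts(gm: GenotypeMatrix) -> np.ndarray:
    """MAC per locus, counted over non-missing alleles only."""
    d = gm.dosages
    alt = np.nansum(d, axis=0)
    total = 2 * np.sum(~np.isnan(d), axis=0)
    return np.minimum(alt, total - alt)


def thin_keep_mask(gm: GenotypeMatrix, spacing: int) -> np.ndarray:
    """Greedy thinning: scan each chromosome by position, keep the lowest-
    position SNP then skip any SNP closer than ``spacing`` bp to the last
    one kept."""
    keep = np.zeros(gm.n_loci, dtype=bool)
    meta = gm.locus_meta
    for chrom in meta["chrom"].unique():
        idx = meta.index[meta["chrom"] == chrom].to_numpy()
        order = idx[np.argsort(meta.loc[idx, "pos"].to_numpy(), kind="stable")]
        last = None
        for j in order:
            p = meta.at[j, "pos"]
            if last is None or p - last >= spacing:
                keep[j] = True
                last = p
    return keep


def filter_dataset(
    gm: GenotypeMatrix, cfg: FilterConfig
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the full filter chain and return the retained matrix + report.

    Steps within one iteration: quality, MAC, locus missingness, depth,
    individual missingness.  Iterates to a fixed point, then thins to one
    SNP per ``thin_spacing`` window per chromosome.
    """
    if gm.n_loci == 0:
        raise ValueError("empty panel: no loci to filter")
    report = FilterReport(loci_in=gm.n_loci, inds_in=gm.n_individuals)
    cur = gm
    while True:
        report.n_iterations += 1
        n_loci0, n_ind0 = cur.n_loci, cur.n_individuals

        qual = cur.locus_meta["qual"].to_numpy(dtype=float)
        keep = ~(qual < cfg.min_qual)  # loci with unknown quality are kept
        report.loci_removed_qual += int((~keep).sum())
        cur = cur.take_loci(np.flatnonzero(keep))
        _require_nonempty(cur)

        keep = minor_allele_counts(cur) >= cfg.min_mac
        report.loci_removed_mac += int((~keep).sum())
        cur = cur.take_loci(np.flatnonzero(keep))
        _require_nonempty(cur)

        keep = cur.locus_missingness() <= cfg.max_locus_missing
        report.loci_removed_missing += int((~keep).sum())
        cur = cur.take_loci(np.flatnonzero(keep))
        _require_nonempty(cur)

        if cfg.min_depth is not None:
            depth = cur.locus_meta["depth"].to_numpy(dtype=float)
            keep = ~(depth < cfg.min_depth)
            report.loci_removed_depth += int((~keep).sum())
            cur = cur.take_loci(np.flatnonzero(keep))
            _require_nonempty(cur)

        keep_ind = cur.individual_missingness() <= cfg.max_ind_missing
        report.inds_removed_missing += int((~keep_ind).sum())
        cur = cur.take_individuals(np.flatnonzero(keep_ind))
        if cur.n_individuals == 0:
            raise ValueError("empty after filtering: all individuals removed")

        if cur.n_loci == n_loci0 and cur.n_individuals == n_ind0:
            break

    if cfg.thin_spacing > 0:
        keep = thin_keep_mask(cur, cfg.thin_spacing)
        report.loci_removed_thin = int((~keep).sum())
        cur = cur.take_loci(np.flatnonzero(keep))
        _require_nonempty(cur)

    report.loci_out = cur.n_loci
    report.inds_out = cur.n_individuals
    return cur, report


def strict_missing_trim(
    gm: GenotypeMatrix, max_missing: float = 0.20
) -> GenotypeMatrix:
    """Diversity-track trim: drop loci then individuals above ``max_missing``."""
    keep = gm.locus_missingness() <= max_missing
    out = gm.take_loci(np.flatnonzero(keep))
    _require_nonempty(out)
    keep_ind = out.individual_missingness() <= max_missing
    out = out.take_individuals(np.flatnonzero(keep_ind))
    if out.n_individuals == 0:
        raise ValueError("empty after filtering: all individuals removed")
    return out


def drop_small_pops(
    gm: GenotypeMatrix,
    meta: SampleMetadata,
    min_pop_n: int = 5,
    level: str = "waterbody",
) -> tuple[GenotypeMatrix, SampleMetadata]:
    """Remove populations sampled with fewer than ``min_pop_n`` individuals."""
    pops = meta.populations(gm, level=level)
    keep_rows: list[int] = []
    for label, idx in pops.items():
        if len(idx) >= min_pop_n:
            keep_rows.extend(idx.tolist())
    if not keep_rows:
        raise ValueError("no populations remain after minimum-size filter")
    keep_rows = sorted(keep_rows)
    out = gm.take_individuals(np.asarray(keep_rows))
    return out, meta.subset_ids(out.ind_ids)


def _require_nonempty(gm: GenotypeMatrix) -> None:
    if gm.n_loci == 0:
        raise ValueError("empty after filtering: all loci removed")
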