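"""Reading and writing diploid biallelic SNP genotypes as VCF v4.2.

Parsing goes through :mod:`cyvcf2`; only the GT field is consumed and
``./.`` marks a missing genotype.  Multiallelic records are rejected —
every downstream statistic assumes a biallelic dosage encoding.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

from .core import GenotypeMatrix

logger = logging.getLogger(__name__)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=invpopgen
##INFO=<ID=DP,Number=1,Type=Float,Description="Mean read depth across samples">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_GT_STRINGS = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a genotype matrix as an uncompressed VCF v4.2 with GT only."""
    meta = gm.locus_meta
    contigs = pd.unique(meta["chrom"]) if gm.n_loci else []
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + list(gm.ind_ids)) + "\n")
        for j in range(gm.n_loci):
            row = meta.iloc[j]
            qual = "." if not np.isfinite(row["qual"]) else f"{row['qual']:g}"
            info = "." if not np.isfinite(row["depth"]) else f"DP={row['depth']:g}"
            gts = [
                _GT_STRINGS.get(gm.dosages[i, j], "./.")
                for i in range(gm.n_individuals)
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t.\tA\tT\t{qual}\tPASS\t{info}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a VCF into a dosage matrix (count of ALT alleles, ``nan`` missing).

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        On a malformed header or a multiallelic record (the offending
        record is named).
    """
    import cyvcf2

    if not os.path.exists(path):
        raise FileNotFoundError(str(path))
    try:
        vcf = cyvcf2.VCF(str(path))
        samples = list(vcf.samples)
    except Exception as exc:  # cyvcf2 raises bare Exceptions on bad headers
        raise ValueError(f"malformed VCF header in {path}: {exc}") from exc

    dosage_cols: list[np.ndarray] = []
    chroms: list[str] = []
    pos: list[int] = []
    quals: list[float] = []
    depths: list[float] = []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {v.CHROM}:{v.POS} (ALT={','.join(v.ALT)})"
            )
        col = np.full(len(samples), np.nan)
        for i, gt in enumerate(v.genotypes):
            a, b = gt[0], gt[1]
            if a >= 0 and b >= 0:
                col[i] = a + b
        dosage_cols.append(col)
        chroms.append(v.CHROM)
        pos.append(v.POS)
        quals.append(v.QUAL if v.QUAL is not None else np.nan)
        dp = v.INFO.get("DP")
        depths.append(float(dp) if dp is not None else np.nan)
    vcf.close()

    if not dosage_cols:
        logger.warning("VCF %s has no variant records; returning 0-locus matrix", path)
        dosages = np.empty((len(samples), 0))
    else:
        dosages = np.column_stack(dosage_cols)
    locus_meta = pd.DataFrame(
        {"chrom": chroms, "pos": pos, "qual": quals, "depth": depths}
    )
    return GenotypeMatrix(dosages, locus_meta, samples)
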