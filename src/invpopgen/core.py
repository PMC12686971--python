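"""Core in-memory containers shared by every analysis stage.

Genotypes are stored as alternate-allele dosages (0, 1, 2) in a float
matrix with ``numpy.nan`` marking missing calls, alongside a pandas
locus-metadata table and unique individual identifiers.  Pairwise
statistics (F_ST, geographic distance, resistance, the directionality
index) share a single labelled-matrix container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = np.nan

LOCUS_META_COLUMNS = ("chrom", "pos", "qual", "depth")


@dataclass
class GenotypeMatrix:
    """Individuals x loci alternate-allele dosage matrix.

    Parameters
    ----------
    dosages:
        ``(n_individuals, n_loci)`` float array with entries in
        ``{0, 1, 2, nan}`` where ``nan`` is a missing genotype.
    locus_meta:
        Per-locus table with columns ``chrom`` (label), ``pos``
        (1-based bp), ``qual`` (phred-like score) and ``depth``
        (mean read depth; may be ``nan`` when unknown).
    ind_ids:
        Unique individual labels, one per matrix row.
    """

    dosages: np.ndarray
    locus_meta: pd.DataFrame
    ind_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        n_ind, n_loci = self.dosages.shape
        if len(self.ind_ids) != n_ind:
            raise ValueError("ind_ids length does not match dosage rows")
        if len(set(self.ind_ids)) != n_ind:
            raise ValueError("duplicate individual ids")
        if len(self.locus_meta) != n_loci:
            raise ValueError("locus_meta length does not match dosage columns")
        for col in LOCUS_META_COLUMNS:
            if col not in self.locus_meta.columns:
                raise ValueError(f"locus_meta missing column {col!r}")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        if n_loci and (self.locus_meta["pos"].to_numpy() < 1).any():
            raise ValueError("positions are 1-based and must be >= 1")
        if n_loci:
            dup = self.locus_meta.duplicated(subset=["chrom", "pos"])
            if dup.any():
                raise ValueError("duplicate (chrom, pos) locus")
        self.locus_meta = self.locus_meta.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def locus_missingness(self) -> np.ndarray:
        """Fraction of missing calls per locus."""
        return np.isnan(self.dosages).mean(axis=0)

    def individual_missingness(self) -> np.ndarray:
        """Fraction of missing calls per individual."""
        return np.isnan(self.dosages).mean(axis=1)

    def take_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[:, idx],
            self.locus_meta.iloc[np.asarray(idx)].reset_index(drop=True),
            list(self.ind_ids),
        )

    def take_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosages[idx, :],
            self.locus_meta.copy(),
            [self.ind_ids[i] for i in idx],
        )

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per locus over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0


@dataclass
class SampleMetadata:
    """Per-individual sampling metadata.

    Backed by a DataFrame with columns ``id``, ``waterbody``, ``group``,
    ``sex`` (F/M/unknown), ``lat`` and ``lon`` (decimal degrees, WGS84).
    """

    table: pd.DataFrame

    REQUIRED = ("id", "waterbody", "group", "sex", "lat", "lon")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"metadata missing column {col!r}")
        if self.table["id"].duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        lat = self.table["lat"].to_numpy(dtype=float)
        lon = self.table["lon"].to_numpy(dtype=float)
        if ((lat < -90) | (lat > 90)).any():
            raise ValueError("latitude out of [-90, 90]")
        if ((lon < -180) | (lon > 180)).any():
            raise ValueError("longitude out of [-180, 180]")
        self.table = self.table.reset_index(drop=True)

    def aligned_to(self, gm: GenotypeMatrix) -> "SampleMetadata":
        """Rows reordered to match ``gm.ind_ids``; errors on absent ids."""
        indexed = self.table.set_index("id")
        missing = [i for i in gm.ind_ids if i not in indexed.index]
        if missing:
            raise ValueError(f"metadata missing ids: {missing[:5]}")
        out = indexed.loc[gm.ind_ids].reset_index()
        return SampleMetadata(out)

    def populations(self, gm: GenotypeMatrix, level: str = "waterbody") -> dict[str, np.ndarray]:
        """Mapping population label -> row indices into ``gm``."""
        aligned = self.aligned_to(gm).table
        groups: dict[str, list[int]] = {}
        for i, label in enumerate(aligned[level]):
            groups.setdefault(str(label), []).append(i)
        return {k: np.asarray(v, dtype=int) for k, v in groups.items()}

    def coords_by(self, level: str = "waterbody") -> pd.DataFrame:
        """Mean lat/lon per population label."""
        return self.table.groupby(level)[["lat", "lon"]].mean()

    def subset_ids(self, ids: Sequence[str]) -> "SampleMetadata":
        keep = self.table["id"].isin(list(ids))
        return SampleMetadata(self.table.loc[keep].reset_index(drop=True))


@dataclass
class PairwiseMatrix:
    """Labelled symmetric (or antisymmetric) pairwise matrix with zero diagonal.

    Optional ``ci_low``/``ci_high`` carry bootstrap confidence bounds.
    """

    labels: list[str]
    values: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    antisymmetric: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values shape does not match labels")
        if not np.allclose(np.diag(self.values), 0.0, equal_nan=True):
            raise ValueError("diagonal must be zero")
        sign = -1.0 if self.antisymmetric else 1.0
        finite = np.isfinite(self.values) & np.isfinite(self.values.T)
        if not np.allclose(
            self.values[finite], sign * self.values.T[finite], atol=1e-10
        ):
            kind = "antisymmetric" if self.antisymmetric else "symmetric"
            raise ValueError(f"matrix is not {kind}")

    @property
    def n(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def pairs(self) -> list[tuple[str, str]]:
        return [
            (self.labels[i], self.labels[j])
            for i in range(self.n)
            for j in range(i + 1, self.n)
        ]

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in row-major pair order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_long(self, value_name: str = "value") -> pd.DataFrame:
        rows = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                row = {
                    "pop1": self.labels[i],
                    "pop2": self.labels[j],
                    value_name: self.values[i, j],
                }
                if self.ci_low is not None:
                    row["ci_low"] = self.ci_low[i, j]
                if self.ci_high is not None:
                    row["ci_high"] = self.ci_high[i, j]
                rows.append(row)
        return pd.DataFrame(rows)

    def reordered(self, labels: Sequence[str]) -> "PairwiseMatrix":
        idx = [self.labels.index(l) for l in labels]
        sub = self.values[np.ix_(idx, idx)]
        return PairwiseMatrix(list(labels), sub, antisymmetric=self.antisymmetric)


def pairwise_from_condensed(
    labels: Sequence[str], condensed: np.ndarray, antisymmetric: bool = False
) -> PairwiseMatrix:
    n = len(labels)
    vals = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    vals[iu] = condensed
    sign = -1.0 if antisymmetric else 1.0
    vals[(iu[1], iu[0])] = sign * np.asarray(condensed)
    return PairwiseMatrix(list(labels), vals, antisymmetric=antisymmetric)
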