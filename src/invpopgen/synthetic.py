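"""Synthetic genotype, coordinate, and raster generation with known truth.

Genotypes follow a hierarchical Balding-Nichols drift model: an
ancestral allele frequency per locus, cluster frequencies drawn from a
Beta distribution around it, and deme frequencies drawn around the
cluster frequency.  Because Nei's pairwise F_ST has a closed-form
expectation under this model, the drift parameters can be calibrated so
the realised estimates match a requested target, which makes every
downstream estimator quantitatively testable.

Isolation-by-distance datasets use a one-dimensional Brownian drift
chain of demes on a transect, with the per-step drift calibrated so the
expected regression slope of linearised F_ST on ln(distance) equals the
requested value for the generated geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, SampleMetadata
from .resistance import ConductanceRaster

# Anchor of the synthetic study area (decimal degrees, WGS84); deme
# spacing keeps the maximum extent well under 200 km.
_BASE_LAT = 42.40
_BASE_LON = -83.30
_KM_PER_DEG_LAT = 110.574


@dataclass
class SyntheticScenario:
    """Ground-truth description of a simulated sampling design."""

    n_demes: int = 20
    deme_sizes: list[int] | None = None
    cluster_map: list[int] | None = None
    target_fst_between: float = 0.3
    target_fst_within: float = 0.05
    n_loci: int = 2000
    missing_locus_rate: float = 0.0
    missing_ind_rate: float = 0.0
    ibd_slope: float = 0.0
    seed: int = 0
    coords: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.deme_sizes is None:
            self.deme_sizes = [20] * self.n_demes
        if self.cluster_map is None:
            n_clusters = min(5, self.n_demes)
            self.cluster_map = [d % n_clusters for d in range(self.n_demes)]
        if len(self.deme_sizes) != self.n_demes:
            raise ValueError("deme_sizes must cover all demes")
        if len(self.cluster_map) != self.n_demes:
            raise ValueError("cluster_map must cover all demes")
        if any(s < 1 for s in self.deme_sizes):
            raise ValueError("deme sizes must be >= 1")
        for name in (
            "target_fst_between",
            "target_fst_within",
            "missing_locus_rate",
            "missing_ind_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _nei_target_to_drift(target: float) -> float:
    """Invert the pairwise Nei F_ST expectation under Balding-Nichols drift.

    Two demes drawn independently around an ancestral frequency with
    drift parameter F have expected Nei pairwise F_ST = F / (2 - F), so a
    requested pairwise target T needs F = 2T / (1 + T).
    """
    return 2.0 * target / (1.0 + target)


def _beta_around(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Balding-Nichols draw: Beta(p(1-F)/F, (1-p)(1-F)/F) around p."""
    if f <= 0.0:
        return p.copy()
    a = p * (1 - f) / f
    b = (1 - p) * (1 - f) / f
    return np.clip(rng.beta(a, b), 1e-9, 1 - 1e-9)


def generate_structured_genotypes(
    scenario: SyntheticScenario,
) -> tuple[GenotypeMatrix, SampleMetadata]:
    """Simulate a hierarchically structured biallelic SNP matrix.

    Drift parameters are calibrated so realised pairwise Nei F_ST matches
    ``target_fst_between`` for demes in different clusters and
    ``target_fst_within`` for demes sharing a cluster.  Loci monomorphic
    over the whole sample are redrawn so the panel is fully polymorphic
    before missing calls are injected (missingness is completely at
    random at the requested rates).
    """
    if scenario.n_loci == 0:
        raise ValueError("empty panel: n_loci must be positive")
    rng = np.random.default_rng(scenario.seed)
    f_within = _nei_target_to_drift(scenario.target_fst_within)
    f_total = _nei_target_to_drift(scenario.target_fst_between)
    if f_total < f_within:
        raise ValueError("target_fst_between must be >= target_fst_within")
    f_between = (f_total - f_within) / (1.0 - f_within) if f_within < 1 else 0.0

    n_demes = scenario.n_demes
    clusters = np.asarray(scenario.cluster_map)
    cluster_ids = np.unique(clusters)
    sizes = list(scenario.deme_sizes)
    n_ind = sum(sizes)

    dosages = np.empty((n_ind, scenario.n_loci))
    deme_of_ind = np.repeat(np.arange(n_demes), sizes)
    remaining = np.arange(scenario.n_loci)
    for _attempt in range(60):
        m = remaining.size
        if m == 0:
            break
        p_anc = rng.uniform(0.1, 0.9, size=m)
        p_cluster = {
            int(c): _beta_around(rng, p_anc, f_between) for c in cluster_ids
        }
        p_deme = np.stack(
            [
                _beta_around(rng, p_cluster[int(clusters[d])], f_within)
                for d in range(n_demes)
            ]
        )  # (n_demes, m)
        draws = rng.binomial(2, p_deme[deme_of_ind, :]).astype(float)
        dosages[:, remaining] = draws
        poly = (draws.min(axis=0) < 2) & (draws.max(axis=0) > 0)
        remaining = remaining[~poly]
    if remaining.size:
        raise RuntimeError("could not generate a fully polymorphic panel")

    # missing completely at random: per-call locus-level rate combined
    # with an extra per-individual rate
    miss_p = 1.0 - (1.0 - scenario.missing_locus_rate) * (
        1.0 - scenario.missing_ind_rate
    )
    if miss_p > 0:
        mask = rng.random(dosages.shape) < miss_p
        dosages[mask] = np.nan

    meta = _metadata_for(scenario, sizes, clusters)
    locus_meta = _default_locus_meta(scenario.n_loci, rng)
    gm = GenotypeMatrix(dosages, locus_meta, list(meta.table["id"]))
    return gm, meta


def _default_locus_meta(n_loci: int, rng: np.random.Generator) -> pd.DataFrame:
    """Plausible locus metadata: one chromosome block per 500 loci,
    positions spaced > 100 kb so default thinning keeps everything."""
    chroms = [f"chr{1 + j // 500}" for j in range(n_loci)]
    pos = [100_001 * (1 + j % 500) for j in range(n_loci)]
    qual = np.round(rng.uniform(30, 60, size=n_loci), 1)
    depth = np.round(rng.uniform(10, 40, size=n_loci), 1)
    return pd.DataFrame({"chrom": chroms, "pos": pos, "qual": qual, "depth": depth})


def _metadata_for(
    scenario: SyntheticScenario, sizes: list[int], clusters: np.ndarray
) -> SampleMetadata:
    if scenario.coords is not None:
        coords = list(scenario.coords)
        if len(coords) != scenario.n_demes:
            raise ValueError("coords must cover all demes")
    else:
        # clusters spread on a coarse grid, demes jittered within cluster
        rng = np.random.default_rng(scenario.seed + 1)
        coords = []
        for d in range(scenario.n_demes):
            c = int(clusters[d])
            lat = _BASE_LAT + 0.25 * (c % 3) + rng.uniform(-0.04, 0.04)
            lon = _BASE_LON + 0.35 * (c // 3) + rng.uniform(-0.05, 0.05)
            coords.append((lat, lon))
    rows = []
    rng2 = np.random.default_rng(scenario.seed + 2)
    i = 0
    for d in range(scenario.n_demes):
        lat, lon = coords[d]
        for _ in range(sizes[d]):
            rows.append(
                {
                    "id": f"ind{i:04d}",
                    "waterbody": f"deme{d:02d}",
                    "group": str(int(clusters[d]) + 1),
                    "sex": rng2.choice(["F", "M"]),
                    "lat": lat,
                    "lon": lon,
                }
            )
            i += 1
    return SampleMetadata(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# isolation-by-distance transect


def ibd_transect_coords(scenario: SyntheticScenario, spacing_km: float = 5.0):
    """Deme coordinates on an east-west transect with constant spacing."""
    if scenario.n_demes < 3:
        raise ValueError("isolation-by-distance transect needs >= 3 demes")
    lat = _BASE_LAT
    km_per_deg_lon = _KM_PER_DEG_LAT * np.cos(np.radians(lat))
    return [
        (lat, _BASE_LON + d * spacing_km / km_per_deg_lon)
        for d in range(scenario.n_demes)
    ]


def generate_ibd_coordinates(
    scenario: SyntheticScenario, spacing_km: float = 5.0
) -> SampleMetadata:
    """Metadata with demes laid on a transect (see :func:`ibd_transect_coords`)."""
    coords = ibd_transect_coords(scenario, spacing_km)
    on_transect = SyntheticScenario(
        n_demes=scenario.n_demes,
        deme_sizes=list(scenario.deme_sizes),
        cluster_map=list(scenario.cluster_map),
        seed=scenario.seed,
        coords=coords,
    )
    return _metadata_for(
        on_transect, list(scenario.deme_sizes), np.asarray(scenario.cluster_map)
    )


def _expected_slope_unit(n_demes: int, spacing_km: float) -> float:
    """Regression slope of (|i-j|/4) on ln(distance) over all deme pairs.

    Under the sequential drift chain the expected linearised F_ST of a
    pair separated by s steps is (f/4)*s for per-step drift f (each step
    adds f*p(1-p) of frequency variance and Nei's pairwise estimator maps
    variance D onto D / (2 Ht)), so the expected fitted slope is f times
    this geometric constant.
    """
    steps, lnd = [], []
    for i in range(n_demes):
        for j in range(i + 1, n_demes):
            steps.append((j - i) / 4.0)
            lnd.append(np.log((j - i) * spacing_km))
    steps_a, lnd_a = np.asarray(steps), np.asarray(lnd)
    lnd_c = lnd_a - lnd_a.mean()
    return float((lnd_c @ (steps_a - steps_a.mean())) / (lnd_c @ lnd_c))


def generate_ibd_dataset(
    scenario: SyntheticScenario, spacing_km: float = 5.0
) -> tuple[GenotypeMatrix, SampleMetadata]:
    """Genotypes whose linearised pairwise F_ST regresses on ln(distance)
    with expected slope ``scenario.ibd_slope``.

    Deme allele frequencies follow sequential Balding-Nichols drift steps
    along the transect with per-step drift f chosen from the generated
    geometry so the expected regression slope equals the target.
    """
    if scenario.n_demes < 3:
        raise ValueError("isolation-by-distance transect needs >= 3 demes")
    if scenario.n_loci == 0:
        raise ValueError("empty panel: n_loci must be positive")
    unit = _expected_slope_unit(scenario.n_demes, spacing_km)
    f_step = scenario.ibd_slope / unit
    if not (0.0 <= f_step < 0.5):
        raise ValueError("ibd_slope too steep for this transect geometry")
    rng = np.random.default_rng(scenario.seed)
    sizes = list(scenario.deme_sizes)
    n_ind = sum(sizes)
    deme_of_ind = np.repeat(np.arange(scenario.n_demes), sizes)

    dosages = np.empty((n_ind, scenario.n_loci))
    remaining = np.arange(scenario.n_loci)
    for _attempt in range(60):
        m = remaining.size
        if m == 0:
            break
        p = rng.uniform(0.2, 0.8, size=m)
        p_deme = np.empty((scenario.n_demes, m))
        p_deme[0] = p
        for d in range(1, scenario.n_demes):
            p_deme[d] = _beta_around(rng, p_deme[d - 1], f_step)
        draws = rng.binomial(2, p_deme[deme_of_ind, :]).astype(float)
        dosages[:, remaining] = draws
        poly = (draws.min(axis=0) < 2) & (draws.max(axis=0) > 0)
        remaining = remaining[~poly]
    if remaining.size:
        raise RuntimeError("could not generate a fully polymorphic panel")

    miss_p = 1.0 - (1.0 - scenario.missing_locus_rate) * (
        1.0 - scenario.missing_ind_rate
    )
    if miss_p > 0:
        mask = rng.random(dosages.shape) < miss_p
        dosages[mask] = np.nan

    coords = ibd_transect_coords(scenario, spacing_km)
    meta = _metadata_for(
        SyntheticScenario(
            n_demes=scenario.n_demes,
            deme_sizes=sizes,
            cluster_map=list(scenario.cluster_map),
            seed=scenario.seed,
            coords=coords,
        ),
        sizes,
        np.asarray(scenario.cluster_map),
    )
    locus_meta = _default_locus_meta(scenario.n_loci, rng)
    gm = GenotypeMatrix(dosages, locus_meta, list(meta.table["id"]))
    return gm, meta


# ---------------------------------------------------------------------------
# rasters


def generate_resistance_raster(
    n_rows: int,
    n_cols: int,
    barrier_spec: dict | None = None,
    seed: int | None = None,
    cell_size: float = 30.0,
    background: float = 1.0,
    noise_sd: float = 0.0,
) -> ConductanceRaster:
    """Conductance raster with an optional low-conductance barrier band.

    ``barrier_spec`` keys: ``orientation`` ("row" or "col"), ``index``
    (centre line of the band), ``width`` (cells, default 1) and
    ``conductance`` (default 0.01).
    """
    if n_rows < 2 or n_cols < 2:
        raise ValueError("raster must be at least 2x2")
    rng = np.random.default_rng(seed)
    grid = np.full((n_rows, n_cols), background, dtype=float)
    if noise_sd > 0:
        grid *= np.exp(rng.normal(0.0, noise_sd, size=grid.shape))
    if barrier_spec:
        orient = barrier_spec.get("orientation", "col")
        idx = int(barrier_spec["index"])
        width = int(barrier_spec.get("width", 1))
        cond = float(barrier_spec.get("conductance", 0.01))
        if cond <= 0:
            raise ValueError("barrier conductance must be positive")
        sl = slice(idx, idx + width)
        if orient == "col":
            grid[:, sl] = cond
        elif orient == "row":
            grid[sl, :] = cond
        else:
            raise ValueError("orientation must be 'row' or 'col'")
    return ConductanceRaster(grid, cell_size=cell_size)


# ---------------------------------------------------------------------------
# file export


def write_scenario_bundle(
    gm: GenotypeMatrix,
    meta: SampleMetadata,
    scenario: SyntheticScenario,
    out_dir: str,
) -> dict[str, str]:
    """Write VCF + metadata CSV + JSON sidecar; returns written paths."""
    import os

    from .vcfio import write_vcf

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "genotypes.vcf"),
        "metadata": os.path.join(out_dir, "metadata.csv"),
        "scenario": os.path.join(out_dir, "scenario.json"),
    }
    write_vcf(gm, paths["vcf"])
    meta.table.to_csv(paths["metadata"], index=False)
    with open(paths["scenario"], "w") as fh:
        fh.write(scenario.to_json())
    return paths
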