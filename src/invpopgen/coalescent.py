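"""Backward-time structured coalescent simulator of invasion histories.

Each demographic model describes a native-range source population and
five invaded regions connected by colonisation events (a time in
generations before present, the source population, and a founder size
acting as a bottleneck epoch immediately after founding) plus continuous
symmetric migration between coexisting populations.  Per locus one
genealogy is simulated under the standard n-coalescent with population
structure: pairwise coalescence at rate k(k-1)/(4N) within each
population, lineage migration as a Poisson process, and, looking
backward, all lineages of a derived population merging into its source
at the colonisation time.  Mutations fall on branches as a Poisson
process with infinite sites within the locus.

Lineages carry their descendant sample sets as integer bitmasks, so a
mutation on a branch directly yields the derived-allele carriers.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, SampleMetadata

NATIVE = "LA_native"
GROUPS = ("Grp1", "Grp2", "Grp3", "Grp4", "Grp5")

MODEL_NAMES = (
    "5cols_step",
    "Grp3_bridge",
    "Grp3_bridge_indGrp1_5",
    "Grp3_step",
    "Grp3_step_indGrp1_5",
    "Grp2_bridge",
    "Grp2_bridge_indGrp1_5",
    "Grp2_step",
    "Grp2_step_indGrp1_5",
    "W2E_step",
)

# Synthetic coordinates for simulated samples (decimal degrees): the five
# invaded regions on a ~40 km west-east arc plus the native-range source.
GROUP_COORDS = {
    "Grp1": (42.52, -83.55),
    "Grp2": (42.45, -83.35),
    "Grp3": (42.42, -83.15),
    "Grp4": (42.38, -82.98),
    "Grp5": (42.60, -83.10),
    NATIVE: (30.45, -91.15),
}


@dataclass
class ColonizationEvent:
    """Founding of ``derived`` from ``source`` ``time`` generations ago.

    The founder-size bottleneck is modelled as an epoch of
    ``bottleneck_duration`` generations at size ``founder_size``
    immediately after founding (forward in time), after which the
    population is at its contemporary size.
    """

    time: float
    derived: str
    source: str
    founder_size: float
    bottleneck_duration: float = 5.0

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"event time must be positive ({self.derived})")
        if self.founder_size < 2:
            raise ValueError(f"founder size must be >= 2 ({self.derived})")


@dataclass
class DemographicModel:
    """Populations, sizes, colonisation events and migration rates."""

    name: str
    pops: list[str]
    sizes: dict[str, float]
    events: list[ColonizationEvent]
    migration: dict[tuple[str, str], float] = field(default_factory=dict)
    mu: float = 3.6e-9
    seq_len: int = 150
    gen_time: float = 1.0

    def __post_init__(self) -> None:
        founded: dict[str, float] = {}
        for e in sorted(self.events, key=lambda e: e.time):
            if e.derived in founded:
                raise ValueError(f"population {e.derived} founded twice")
            if e.derived not in self.pops or e.source not in self.pops:
                raise ValueError(f"unknown population in event for {e.derived}")
            founded[e.derived] = e.time
        for e in self.events:
            src_t = founded.get(e.source, math.inf)
            if e.time >= src_t:
                raise ValueError(
                    f"event founding {e.derived} at t={e.time} predates its "
                    f"source {e.source} (founded at t={src_t})"
                )
        for p, n in self.sizes.items():
            if n < 2:
                raise ValueError(f"population size of {p} must be >= 2")
        for rate in self.migration.values():
            if rate < 0:
                raise ValueError("migration rates must be >= 0")

    def founding_time(self, pop: str) -> float:
        for e in self.events:
            if e.derived == pop:
                return e.time
        return math.inf


# ---------------------------------------------------------------------------
# the ten invasion-history models


def _sym(migration: dict, a: str, b: str, rate: float) -> None:
    migration[(a, b)] = rate
    migration[(b, a)] = rate


def default_params() -> dict:
    """Reconstruction defaults for sizes, founder sizes, times and
    migration tiers (the study's exact priors live in unpublished
    supplements, so these are explicit, overridable reconstructions)."""
    p: dict = {"ne_native": 2000.0, "m_weak": 0.002, "m_strong": 0.01}
    for g in GROUPS:
        p[f"ne_{g}"] = 100.0
        p[f"founder_{g}"] = 10.0
    p["bottleneck_duration"] = 5.0
    p["t_primary"] = 30.0
    p["t_secondary"] = 20.0
    p["t_independent"] = 18.0
    return p


def build_model(name: str, params: dict | None = None) -> DemographicModel:
    """Construct one of the ten named invasion-history models.

    Bridgehead variants found all secondary regions simultaneously from
    the focal group; stepping-stone variants found them serially along
    the geographic chain Grp1-Grp2-Grp3-Grp4-Grp5.  ``_indGrp1_5``
    variants colonise Grp1 and Grp5 directly from the native range.
    Bridge models carry the strong migration tier on source-colony
    edges, step models on the chain edges of the colonisation path; all
    models keep weak migration between geographically adjacent colonised
    groups.
    """
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    p = default_params()
    if params:
        p = {**p, **params}
    sizes = {NATIVE: float(p["ne_native"])}
    for g in GROUPS:
        sizes[g] = float(p[f"ne_{g}"])
    dur = float(p["bottleneck_duration"])
    t1, t2, ti = float(p["t_primary"]), float(p["t_secondary"]), float(p["t_independent"])

    def ev(time: float, derived: str, source: str) -> ColonizationEvent:
        return ColonizationEvent(
            time, derived, source, float(p[f"founder_{derived}"]), dur
        )

    events: list[ColonizationEvent]
    strong_edges: list[tuple[str, str]] = []
    if name == "5cols_step":
        events = [ev(t1 - 2 * k, g, NATIVE) for k, g in enumerate(GROUPS)]
    elif name == "Grp3_bridge":
        events = [ev(t1, "Grp3", NATIVE)] + [
            ev(t2, g, "Grp3") for g in ("Grp1", "Grp2", "Grp4", "Grp5")
        ]
        strong_edges = [("Grp3", g) for g in ("Grp1", "Grp2", "Grp4", "Grp5")]
    elif name == "Grp3_bridge_indGrp1_5":
        events = [
            ev(t1, "Grp3", NATIVE),
            ev(t2, "Grp2", "Grp3"),
            ev(t2, "Grp4", "Grp3"),
            ev(ti, "Grp1", NATIVE),
            ev(ti - 1, "Grp5", NATIVE),
        ]
        strong_edges = [("Grp3", "Grp2"), ("Grp3", "Grp4")]
    elif name == "Grp3_step":
        events = [
            ev(t1, "Grp3", NATIVE),
            ev(t2, "Grp2", "Grp3"),
            ev(t2 - 2, "Grp4", "Grp3"),
            ev(t2 - 7, "Grp1", "Grp2"),
            ev(t2 - 9, "Grp5", "Grp4"),
        ]
        strong_edges = [("Grp3", "Grp2"), ("Grp3", "Grp4"), ("Grp2", "Grp1"), ("Grp4", "Grp5")]
    elif name == "Grp3_step_indGrp1_5":
        events = [
            ev(t1, "Grp3", NATIVE),
            ev(t2, "Grp2", "Grp3"),
            ev(t2 - 6, "Grp4", "Grp3"),
            ev(ti, "Grp1", NATIVE),
            ev(ti - 1, "Grp5", NATIVE),
        ]
        strong_edges = [("Grp3", "Grp2"), ("Grp3", "Grp4")]
    elif name == "Grp2_bridge":
        events = [ev(t1, "Grp2", NATIVE)] + [
            ev(t2, g, "Grp2") for g in ("Grp1", "Grp3", "Grp4", "Grp5")
        ]
        strong_edges = [("Grp2", g) for g in ("Grp1", "Grp3", "Grp4", "Grp5")]
    elif name == "Grp2_bridge_indGrp1_5":
        events = [
            ev(t1, "Grp2", NATIVE),
            ev(t2, "Grp3", "Grp2"),
            ev(t2, "Grp4", "Grp2"),
            ev(ti, "Grp1", NATIVE),
            ev(ti - 1, "Grp5", NATIVE),
        ]
        strong_edges = [("Grp2", "Grp3"), ("Grp2", "Grp4")]
    elif name == "Grp2_step":
        events = [
            ev(t1, "Grp2", NATIVE),
            ev(t2, "Grp1", "Grp2"),
            ev(t2, "Grp3", "Grp2"),
            ev(t2 - 6, "Grp4", "Grp3"),
            ev(t2 - 12, "Grp5", "Grp4"),
        ]
        strong_edges = [("Grp2", "Grp1"), ("Grp2", "Grp3"), ("Grp3", "Grp4"), ("Grp4", "Grp5")]
    elif name == "Grp2_step_indGrp1_5":
        events = [
            ev(t1, "Grp2", NATIVE),
            ev(t2, "Grp3", "Grp2"),
            ev(t2 - 6, "Grp4", "Grp3"),
            ev(ti, "Grp1", NATIVE),
            ev(ti - 1, "Grp5", NATIVE),
        ]
        strong_edges = [("Grp2", "Grp3"), ("Grp3", "Grp4")]
    elif name == "W2E_step":
        events = [
            ev(t1, "Grp1", NATIVE),
            ev(t1 - 6, "Grp2", "Grp1"),
            ev(t1 - 12, "Grp3", "Grp2"),
            ev(t1 - 18, "Grp4", "Grp3"),
            ev(t1 - 23, "Grp5", "Grp4"),
        ]
        strong_edges = [
            ("Grp1", "Grp2"), ("Grp2", "Grp3"), ("Grp3", "Grp4"), ("Grp4", "Grp5"),
        ]
    migration: dict[tuple[str, str], float] = {}
    for a, b in (("Grp1", "Grp2"), ("Grp2", "Grp3"), ("Grp3", "Grp4"), ("Grp4", "Grp5")):
        _sym(migration, a, b, float(p["m_weak"]))
    for a, b in strong_edges:
        _sym(migration, a, b, float(p["m_strong"]))
    return DemographicModel(
        name=name,
        pops=[NATIVE, *GROUPS],
        sizes=sizes,
        events=events,
        migration=migration,
        mu=float(p.get("mu", 3.6e-9)),
        seq_len=int(p.get("seq_len", 150)),
    )


# ---------------------------------------------------------------------------
# priors


@dataclass
class PriorSpec:
    """Independent per-parameter priors: name -> (dist, low, high) with
    dist in {"uniform", "loguniform"}."""

    params: dict[str, tuple[str, float, float]]

    def __post_init__(self) -> None:
        for name, (dist, lo, hi) in self.params.items():
            if dist not in ("uniform", "loguniform"):
                raise ValueError(f"unknown distribution {dist!r} for {name}")
            if not (lo < hi) and lo != hi:
                raise ValueError(f"invalid bounds for {name}")
            if dist == "loguniform" and lo <= 0:
                raise ValueError(f"log-uniform support must be positive ({name})")


def default_priors() -> PriorSpec:
    """Log-uniform Ne in [18, 250] per invaded region, a wider native
    range size, log-uniform founder sizes, and two migration tiers."""
    p: dict[str, tuple[str, float, float]] = {
        "ne_native": ("loguniform", 500.0, 5000.0),
        "m_weak": ("loguniform", 1e-4, 5e-3),
        "m_strong": ("loguniform", 2e-3, 2e-2),
    }
    for g in GROUPS:
        p[f"ne_{g}"] = ("loguniform", 18.0, 250.0)
        p[f"founder_{g}"] = ("loguniform", 2.0, 30.0)
    return PriorSpec(p)


def draw_params(priors: PriorSpec, seed_or_rng) -> dict[str, float]:
    """One independent draw from each prior; reproducible under a seed."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    out = {}
    for name, (dist, lo, hi) in priors.params.items():
        if lo == hi:
            out[name] = float(lo)
        elif dist == "uniform":
            out[name] = float(rng.uniform(lo, hi))
        else:
            out[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return out


# ---------------------------------------------------------------------------
# genealogy simulation


class _Compiled:
    """Model unpacked into index arrays for the per-locus event loop."""

    def __init__(self, model: DemographicModel):
        self.pops = list(model.pops)
        self.index = {p: i for i, p in enumerate(self.pops)}
        P = len(self.pops)
        self.contemp = [float(model.sizes[p]) for p in self.pops]
        self.found_time = [math.inf] * P
        self.founder = [0.0] * P
        self.bneck_dur = [0.0] * P
        self.source = [-1] * P
        for e in model.events:
            i = self.index[e.derived]
            self.found_time[i] = e.time
            self.founder[i] = e.founder_size
            self.bneck_dur[i] = e.bottleneck_duration
            self.source[i] = self.index[e.source]
        # boundaries where any rate changes: bottleneck starts and foundings
        bset = set()
        for i in range(P):
            if math.isfinite(self.found_time[i]):
                bset.add(max(self.found_time[i] - self.bneck_dur[i], 0.0))
                bset.add(self.found_time[i])
        self.boundaries = sorted(bset)
        self.mig = [[0.0] * P for _ in range(P)]
        for (a, b), r in model.migration.items():
            self.mig[self.index[a]][self.index[b]] = r

    def size(self, i: int, t: float) -> float:
        ft = self.found_time[i]
        if math.isfinite(ft) and ft - self.bneck_dur[i] <= t < ft:
            return self.founder[i]
        return self.contemp[i]


def _simulate_genealogy(
    comp: _Compiled, sample_counts: list[int], rng: random.Random
) -> tuple[list[int], list[float], float]:
    """One genealogy; returns (segment masks, segment lengths, total length).

    A segment is a branch from a lineage's birth to its coalescence; its
    mask holds the sample haplotypes below it as set bits.
    """
    P = len(comp.pops)
    masks: list[list[int]] = [[] for _ in range(P)]
    births: list[list[float]] = [[] for _ in range(P)]
    bit = 0
    for i in range(P):
        for _ in range(sample_counts[i]):
            masks[i].append(1 << bit)
            births[i].append(0.0)
            bit += 1
    n_total = bit
    alive = [True] * P
    seg_masks: list[int] = []
    seg_lens: list[float] = []
    t = 0.0
    bqueue = [b for b in comp.boundaries if b > 0.0]
    bpos = 0
    remaining = n_total

    while remaining > 1:
        # per-population rates at current time
        coal = [0.0] * P
        migr = [0.0] * P
        total = 0.0
        for i in range(P):
            k = len(masks[i])
            if k == 0:
                continue
            if k > 1:
                coal[i] = k * (k - 1) / (4.0 * comp.size(i, t))
            m = 0.0
            row = comp.mig[i]
            for j in range(P):
                if alive[j] and row[j] > 0.0:
                    m += row[j]
            migr[i] = k * m
            total += coal[i] + migr[i]
        next_b = bqueue[bpos] if bpos < len(bqueue) else math.inf
        if total <= 0.0:
            if math.isinf(next_b):
                raise RuntimeError(
                    "genealogy cannot complete: disconnected populations"
                )
            t = next_b
        else:
            dt = rng.expovariate(total)
            if t + dt >= next_b:
                t = next_b
            else:
                t += dt
                # choose the event
                u = rng.random() * total
                acc = 0.0
                for i in range(P):
                    acc += coal[i]
                    if u < acc:
                        # coalesce two random lineages in pop i
                        k = len(masks[i])
                        a = rng.randrange(k)
                        b = rng.randrange(k - 1)
                        if b >= a:
                            b += 1
                        if a < b:
                            a, b = b, a
                        ma, mb = masks[i][a], masks[i][b]
                        ta, tb = births[i][a], births[i][b]
                        seg_masks.append(ma)
                        seg_lens.append(t - ta)
                        seg_masks.append(mb)
                        seg_lens.append(t - tb)
                        del masks[i][a], births[i][a]
                        masks[i][b] = ma | mb
                        births[i][b] = t
                        remaining -= 1
                        break
                    acc += migr[i]
                    if u < acc:
                        # migrate one lineage out of pop i
                        row = comp.mig[i]
                        tot_m = migr[i] / len(masks[i])
                        v = rng.random() * tot_m
                        a2 = 0.0
                        dest = -1
                        for j in range(P):
                            if alive[j] and row[j] > 0.0:
                                a2 += row[j]
                                if v < a2:
                                    dest = j
                                    break
                        if dest < 0:
                            dest = next(
                                j for j in range(P) if alive[j] and row[j] > 0.0
                            )
                        k = len(masks[i])
                        a = rng.randrange(k)
                        masks[dest].append(masks[i].pop(a))
                        births[dest].append(births[i].pop(a))
                        break
                continue
        # arrived at a boundary: apply any foundings at this time
        while bpos < len(bqueue) and bqueue[bpos] <= t:
            bt = bqueue[bpos]
            bpos += 1
            for i in range(P):
                if comp.found_time[i] == bt and alive[i]:
                    src = comp.source[i]
                    masks[src].extend(masks[i])
                    births[src].extend(births[i])
                    masks[i] = []
                    births[i] = []
                    alive[i] = False
    total_len = sum(seg_lens) if seg_lens else 0.0
    return seg_masks, seg_lens, total_len


def _mask_to_dosages(mask: int, n_diploid: int) -> np.ndarray:
    """Derived-allele dosage per individual from a haplotype bitmask
    (haplotypes 2i and 2i+1 belong to individual i; lineages within a
    population are exchangeable, so sequential pairing is a random
    pairing in distribution)."""
    out = np.empty(n_diploid, dtype=float)
    for i in range(n_diploid):
        out[i] = ((mask >> (2 * i)) & 1) + ((mask >> (2 * i + 1)) & 1)
    return out


def sim_metadata(sample_sizes: dict[str, int]) -> SampleMetadata:
    """Metadata table for a simulated sample configuration."""
    rows = []
    i = 0
    for pop, n in sample_sizes.items():
        lat, lon = GROUP_COORDS.get(pop, (42.0, -83.0))
        for _ in range(n):
            rows.append(
                {
                    "id": f"sim{i:04d}",
                    "waterbody": pop,
                    "group": pop,
                    "sex": "unknown",
                    "lat": lat,
                    "lon": lon,
                }
            )
            i += 1
    return SampleMetadata(pd.DataFrame(rows))


def simulate_snps(
    model: DemographicModel,
    sample_sizes: dict[str, int],
    n_loci: int,
    seed: int | None = None,
    mac_min: int = 3,
    ascertainment_factor: int = 100,
) -> GenotypeMatrix:
    """Simulate ``n_loci`` ascertained SNPs (one per RAD-style locus).

    Each retained locus carries exactly one segregating site: genealogies
    are simulated until ``n_loci`` of them yield a mutation whose pooled
    minor allele count reaches ``mac_min``, mirroring the empirical
    filters the simulated data are compared against.  Conditional on a
    genealogy, the site is placed on a branch chosen proportionally to
    branch length (the infinite-sites distribution of a segregating
    site).  Raises when the ascertainment budget of
    ``ascertainment_factor * n_loci`` genealogies is exhausted, e.g. at
    mutation rate zero.
    """
    if any(n < 1 for n in sample_sizes.values()):
        raise ValueError("sample sizes must be >= 1 per sampled population")
    if model.mu <= 0:
        raise ValueError(
            "zero polymorphic loci: mutation rate is zero, ascertainment "
            "can never succeed"
        )
    comp = _Compiled(model)
    counts = [0] * len(comp.pops)
    pops_in_order = list(sample_sizes)
    for popname, n in sample_sizes.items():
        counts[comp.index[popname]] = 2 * n
    # haplotype bit order follows compiled population order
    order = sorted(range(len(comp.pops)), key=lambda i: i)
    n_diploid = sum(sample_sizes.values())
    rng = random.Random(seed)
    cols = []
    tries = 0
    budget = ascertainment_factor * n_loci
    while len(cols) < n_loci:
        tries += 1
        if tries > budget:
            raise RuntimeError(
                f"zero polymorphic loci: ascertainment budget ({budget}) "
                f"exhausted after retaining {len(cols)}/{n_loci}"
            )
        seg_masks, seg_lens, total_len = _simulate_genealogy(comp, counts, rng)
        if total_len <= 0:
            continue
        # one segregating site, branch chosen by length
        u = rng.random() * total_len
        acc = 0.0
        mask = seg_masks[-1]
        for m, l in zip(seg_masks, seg_lens):
            acc += l
            if u < acc:
                mask = m
                break
        derived = mask.bit_count()
        mac = min(derived, 2 * n_diploid - derived)
        if mac < mac_min:
            continue
        cols.append(_mask_to_dosages(mask, n_diploid))
    dosages = np.column_stack(cols)
    dosages = _reorder_rows(dosages, comp, sample_sizes)
    meta = sim_metadata(sample_sizes)
    locus_meta = pd.DataFrame(
        {
            "chrom": ["sim"] * n_loci,
            "pos": np.arange(1, n_loci + 1) * model.seq_len,
            "qual": [60.0] * n_loci,
            "depth": [np.nan] * n_loci,
        }
    )
    return GenotypeMatrix(dosages, locus_meta, list(meta.table["id"]))


def _reorder_rows(
    dosages: np.ndarray, comp: _Compiled, sample_sizes: dict[str, int]
) -> np.ndarray:
    """Rows of the raw dosage matrix follow compiled population order;
    reorder to the caller's ``sample_sizes`` insertion order."""
    comp_order = [p for p in comp.pops if p in sample_sizes]
    starts = {}
    pos = 0
    for p in comp_order:
        starts[p] = pos
        pos += sample_sizes[p]
    rows = []
    for p in sample_sizes:
        rows.extend(range(starts[p], starts[p] + sample_sizes[p]))
    return dosages[rows, :]


def simulate_sites(
    model: DemographicModel,
    sample_sizes: dict[str, int],
    n_loci: int,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Unascertained infinite-sites simulation for calibration checks.

    Returns ``(dosages, locus_of_site)``: every mutation from a
    Poisson(mu * seq_len * tree length) draw per locus becomes a site
    column; loci with no mutations contribute no columns, so segregating
    site counts and per-locus diversity can be computed against their
    closed-form expectations.
    """
    comp = _Compiled(model)
    counts = [0] * len(comp.pops)
    for popname, n in sample_sizes.items():
        counts[comp.index[popname]] = 2 * n
    n_diploid = sum(sample_sizes.values())
    rng = random.Random(seed)
    mu_locus = model.mu * model.seq_len
    cols = []
    locus_ids = []
    for locus in range(n_loci):
        seg_masks, seg_lens, total_len = _simulate_genealogy(comp, counts, rng)
        k = np.random.default_rng(rng.getrandbits(32)).poisson(mu_locus * total_len)
        for _ in range(int(k)):
            u = rng.random() * total_len
            acc = 0.0
            mask = seg_masks[-1]
            for m, l in zip(seg_masks, seg_lens):
                acc += l
                if u < acc:
                    mask = m
                    break
            cols.append(_mask_to_dosages(mask, n_diploid))
            locus_ids.append(locus)
    if not cols:
        return np.empty((n_diploid, 0)), np.asarray([], dtype=int)
    dosages = np.column_stack(cols)
    dosages = _reorder_rows(dosages, comp, sample_sizes)
    return dosages, np.asarray(locus_ids, dtype=int)
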