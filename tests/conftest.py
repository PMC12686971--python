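import numpy as np
import pandas as pd
import pytest

from invpopgen.core import GenotypeMatrix, SampleMetadata
from invpopgen.synthetic import SyntheticScenario, generate_structured_genotypes


def make_gm(dosages, chrom=None, pos=None, qual=None, depth=None, ids=None):
    """Build a GenotypeMatrix from a plain dosage array with default metadata."""
    dosages = np.asarray(dosages, dtype=float)
    n_ind, n_loci = dosages.shape
    meta = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["chr1"] * n_loci,
            "pos": pos if pos is not None else np.arange(1, n_loci + 1) * 200_000,
            "qual": qual if qual is not None else [50.0] * n_loci,
            "depth": depth if depth is not None else [20.0] * n_loci,
        }
    )
    if ids is None:
        ids = [f"i{k}" for k in range(n_ind)]
    return GenotypeMatrix(dosages, meta, ids)


def make_meta(pop_of_ind, ids=None, coords=None, level_name="waterbody"):
    """Metadata with one population label per individual."""
    n = len(pop_of_ind)
    if ids is None:
        ids = [f"i{k}" for k in range(n)]
    if coords is None:
        coords = {p: (42.0 + 0.1 * k, -83.0 + 0.1 * k) for k, p in enumerate(dict.fromkeys(pop_of_ind))}
    rows = []
    for i, p in enumerate(pop_of_ind):
        lat, lon = coords[p]
        rows.append(
            {"id": ids[i], "waterbody": p, "group": p, "sex": "F", "lat": lat, "lon": lon}
        )
    return SampleMetadata(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def structured_dataset():
    """Six demes in three clusters, moderately differentiated, with missingness."""
    sc = SyntheticScenario(
        n_demes=6,
        deme_sizes=[12] * 6,
        cluster_map=[0, 0, 1, 1, 2, 2],
        target_fst_between=0.25,
        target_fst_within=0.03,
        n_loci=500,
        missing_locus_rate=0.05,
        seed=11,
    )
    gm, meta = generate_structured_genotypes(sc)
    return gm, meta, sc
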