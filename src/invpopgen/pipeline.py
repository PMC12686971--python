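"""Pipeline orchestration over the three dataset tracks.

The analysis distinguishes a gene-flow track (default filters), a
diversity track (extra strict missingness trim before summary
statistics) and a demographic track (stricter locus missingness plus a
depth filter) — each a :class:`~invpopgen.filtering.FilterConfig`.
``run_pipeline`` wires the stages together, writes every artefact under
one output directory and records a machine-readable manifest stamped
with a hash of the configuration, so a rerun with the same seeds is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import clustering, coalescent, diversity, filtering, model_choice, spatial
from .core import SampleMetadata
from .filtering import FilterConfig
from .synthetic import SyntheticScenario, generate_structured_genotypes
from .vcfio import read_vcf, write_vcf

logger = logging.getLogger(__name__)


def gene_flow_filter() -> FilterConfig:
    return FilterConfig()


def diversity_filter() -> FilterConfig:
    return FilterConfig(strict_locus_missing=0.20)


def demographic_filter() -> FilterConfig:
    return FilterConfig(max_locus_missing=0.50, max_ind_missing=0.75, min_depth=5)


@dataclass
class RunConfig:
    """Inputs, per-track filters, stage toggles and seeds for one run."""

    out_dir: str
    vcf: str | None = None
    metadata: str | None = None
    scenario: SyntheticScenario | None = None  # generate instead of read
    seed: int = 0
    stages: tuple[str, ...] = ("filter", "stats", "structure", "ibd", "psi")
    min_pop_n: int = 5
    n_boot_tree: int = 50
    k_max: int = 10
    abc_models: tuple[str, ...] = coalescent.MODEL_NAMES
    abc_n_per_model: int = 100
    abc_n_loci: int = 50
    abc_sample_size: int = 4
    abc_tolerance: float = 0.05

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir")  # same analysis settings hash alike wherever written
        blob = json.dumps(_jsonable(d), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.integer, np.floating)):
        return float(x)
    return x


def _write_csv(df: pd.DataFrame, path: str, cfg_hash: str, index: bool = False) -> str:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=index)
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Raises on missing inputs before any stage runs.
    """
    missing = []
    if config.scenario is None:
        if not config.vcf or not os.path.exists(config.vcf):
            missing.append(f"vcf: {config.vcf}")
        if not config.metadata or not os.path.exists(config.metadata):
            missing.append(f"metadata: {config.metadata}")
    if missing:
        raise FileNotFoundError("missing inputs: " + "; ".join(missing))
    os.makedirs(config.out_dir, exist_ok=True)
    h = config.config_hash()
    manifest: dict = {"config_hash": h, "seed": config.seed, "stages": {}}

    if config.scenario is not None:
        gm, meta = generate_structured_genotypes(config.scenario)
        src_vcf = os.path.join(config.out_dir, "input.vcf")
        write_vcf(gm, src_vcf)
        meta.table.to_csv(os.path.join(config.out_dir, "input_metadata.csv"), index=False)
        manifest["stages"]["generate"] = [src_vcf]
    else:
        gm = read_vcf(config.vcf)
        meta = SampleMetadata(pd.read_csv(config.metadata))

    if "filter" in config.stages:
        gm_f, report = filtering.filter_dataset(gm, gene_flow_filter())
        meta_f = meta.subset_ids(gm_f.ind_ids)
        gm_f, meta_f = filtering.drop_small_pops(gm_f, meta_f, config.min_pop_n)
        out_vcf = os.path.join(config.out_dir, "filtered.vcf")
        write_vcf(gm_f, out_vcf)
        rep_path = os.path.join(config.out_dir, "filter_report.json")
        with open(rep_path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        manifest["stages"]["filter"] = [out_vcf, rep_path]
    else:
        gm_f, meta_f = gm, meta

    if "stats" in config.stages:
        gm_d = filtering.strict_missing_trim(gm_f, diversity_filter().strict_locus_missing)
        meta_d = meta_f.subset_ids(gm_d.ind_ids)
        files = []
        table = diversity.diversity_table(gm_d, meta_d)
        files.append(_write_csv(table, os.path.join(config.out_dir, "diversity.csv"), h, index=True))
        fst = diversity.fst_bootstrap_ci(gm_d, meta_d, n_boot=200, seed=config.seed)
        files.append(
            _write_csv(fst.to_long("fst"), os.path.join(config.out_dir, "pairwise_fst.csv"), h)
        )
        manifest["stages"]["stats"] = files
    if "structure" in config.stages:
        files = []
        res = clustering.pca(gm_f, n_components=10)
        pcs = pd.DataFrame(res.scores, index=gm_f.ind_ids)
        files.append(_write_csv(pcs, os.path.join(config.out_dir, "pca_scores.csv"), h, index=True))
        ca = clustering.find_clusters(gm_f, k_max=min(config.k_max, gm_f.n_individuals - 1), seed=config.seed)
        bic = pd.DataFrame(sorted(ca.bic_curve.items()), columns=["K", "BIC"])
        files.append(_write_csv(bic, os.path.join(config.out_dir, "bic_curve.csv"), h))
        memb = pd.DataFrame(ca.memberships, index=gm_f.ind_ids)
        files.append(_write_csv(memb, os.path.join(config.out_dir, "memberships.csv"), h, index=True))
        tree = clustering.bootstrap_supports(gm_f, meta_f, n_boot=config.n_boot_tree, seed=config.seed)
        tree_path = os.path.join(config.out_dir, "nj_tree.nwk")
        with open(tree_path, "w") as fh:
            fh.write(tree.newick() + "\n")
        files.append(tree_path)
        manifest["stages"]["structure"] = files
    if "ibd" in config.stages:
        fst = diversity.pairwise_fst(gm_f, meta_f)
        dist = spatial.great_circle_km(meta_f)
        mantel = spatial.mantel_ibd(fst, dist, seed=config.seed)
        pairs = pd.DataFrame(
            {
                "pop1": [a for a, _ in fst.pairs()],
                "pop2": [b for _, b in fst.pairs()],
                "linfst": fst.condensed() / (1 - fst.condensed()),
                "lnkm": np.log(dist.reordered(fst.labels).condensed()),
            }
        )
        files = [
            _write_csv(pairs, os.path.join(config.out_dir, "ibd_pairs.csv"), h),
        ]
        mantel_path = os.path.join(config.out_dir, "mantel.json")
        with open(mantel_path, "w") as fh:
            json.dump(dataclasses.asdict(mantel), fh, indent=2)
        files.append(mantel_path)
        manifest["stages"]["ibd"] = files
    if "psi" in config.stages:
        psi, z = spatial.directionality_index(
            gm_f, meta_f, min_pop_n=config.min_pop_n, seed=config.seed
        )
        long = psi.to_long("psi").merge(z.to_long("z"), on=["pop1", "pop2"])
        manifest["stages"]["psi"] = [
            _write_csv(long, os.path.join(config.out_dir, "psi.csv"), h)
        ]
    if "abc" in config.stages:
        ss = {g: config.abc_sample_size for g in coalescent.GROUPS}
        ss[coalescent.NATIVE] = config.abc_sample_size
        table = model_choice.build_reference_table(
            list(config.abc_models),
            coalescent.default_priors(),
            config.abc_n_per_model,
            ss,
            n_loci=config.abc_n_loci,
            seed=config.seed,
        )
        obs = model_choice.summarize(gm_f, meta_f, level="group")
        # observed stats must be comparable: only run when group labels match
        files = []
        if list(obs.index) == table.stat_names:
            rows = []
            for alg, fn in (
                ("rejection", lambda: model_choice.abc_reject(obs, table, config.abc_tolerance)),
                ("mnlogistic", lambda: model_choice.abc_mnlogistic(obs, table, config.abc_tolerance)),
                ("neuralnet", lambda: model_choice.abc_neuralnet(obs, table, config.abc_tolerance, seed=config.seed)),
                ("randomforest", lambda: model_choice.abc_random_forest(obs, table, n_trees=500, seed=config.seed)),
            ):
                post = fn()
                for m, pr in post.probs.items():
                    rows.append({"algorithm": alg, "model": m, "posterior": pr})
            files.append(
                _write_csv(pd.DataFrame(rows), os.path.join(config.out_dir, "abc_posteriors.csv"), h)
            )
        else:
            logger.warning("observed group labels do not match simulated groups; ABC skipped")
        cm = model_choice.cross_validate(table, 5, "randomforest", seed=config.seed)
        files.append(
            _write_csv(cm.counts, os.path.join(config.out_dir, "abc_rf_confusion.csv"), h, index=True)
        )
        manifest["stages"]["abc"] = files

    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2)
    return manifest
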