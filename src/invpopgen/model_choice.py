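"""ABC model choice over coalescent invasion histories.

A reference table of (model, parameter draw, summary statistics) is
simulated with a balanced prior over models.  Summary statistics are the
per-region diversity panel (He, Ho, segregating sites, private alleles)
plus all pairwise and the overall Nei F_ST, computed by exactly the same
code path for observed and simulated data.  Four model-choice algorithms
are provided: plain rejection, weighted multinomial logistic regression,
a small neural-network ensemble (both on the accepted set), and a random
forest trained on the full table, following random-forest-ABC practice.
Statistics are standardised by table median and MAD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, SampleMetadata
from . import coalescent
from .diversity import heterozygosity, overall_fst, pairwise_fst, private_alleles


# ---------------------------------------------------------------------------
# summary statistics


def summary_stat_names(group_labels: list[str]) -> list[str]:
    names = []
    for g in group_labels:
        names += [f"He_{g}", f"Ho_{g}", f"S_{g}", f"Ap_{g}"]
    for i in range(len(group_labels)):
        for j in range(i + 1, len(group_labels)):
            names.append(f"fst_{group_labels[i]}_{group_labels[j]}")
    names.append("fst_overall")
    return names


def summarize(
    gm: GenotypeMatrix, meta: SampleMetadata, level: str = "group"
) -> pd.Series:
    """Summary-statistic vector with a fixed, sorted-by-group ordering.

    Undefined entries (e.g. a pairwise F_ST with no polymorphic loci in
    the pair) are coded as 0, keeping the vector fully numeric so the
    same coding applies to observed and simulated data.
    """
    pops = meta.populations(gm, level=level)
    labels = sorted(pops)
    het = heterozygosity(gm, meta, level=level, pops=pops)
    ap = private_alleles(gm, meta, level=level, pops=pops)
    vals: dict[str, float] = {}
    for g in labels:
        vals[f"He_{g}"] = float(het.loc[g, "He"])
        vals[f"Ho_{g}"] = float(het.loc[g, "Ho"])
        d = gm.dosages[pops[g], :]
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(d, axis=0) / 2.0
        vals[f"S_{g}"] = float(np.sum((freq > 0) & (freq < 1)))
        vals[f"Ap_{g}"] = float(ap[g])
    fst = pairwise_fst(gm, meta, level=level, pops=pops).reordered(labels)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            vals[f"fst_{labels[i]}_{labels[j]}"] = fst.values[i, j]
    vals["fst_overall"] = overall_fst(gm, meta, level=level, pops=pops)
    out = pd.Series(vals, index=summary_stat_names(labels), dtype=float)
    return out.fillna(0.0)


# ---------------------------------------------------------------------------
# reference table


@dataclass
class ReferenceTable:
    """Balanced (model, parameters, summary statistics) simulation table."""

    models: np.ndarray  # (N,) model-name strings
    params: pd.DataFrame  # (N, n_params)
    stats: np.ndarray  # (N, n_stats)
    stat_names: list[str]
    n_per_model: int
    location: np.ndarray = field(init=False)
    scale: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if np.isnan(self.stats).any():
            raise ValueError("reference table contains missing statistics")
        counts = pd.Series(self.models).value_counts()
        if counts.nunique() != 1:
            raise ValueError("reference table must be balanced across models")
        self.location = np.median(self.stats, axis=0)
        mad = np.median(np.abs(self.stats - self.location), axis=0)
        self.scale = np.where(mad > 0, mad, 1.0)

    @property
    def n(self) -> int:
        return len(self.models)

    @property
    def model_labels(self) -> list[str]:
        return sorted(set(self.models.tolist()))

    def standardized(self, x: np.ndarray | None = None) -> np.ndarray:
        """MAD-standardise table rows (or an external vector) with the
        table-derived constants only — an observed vector never leaks
        into the standardisation."""
        if x is None:
            x = self.stats
        return (np.asarray(x, dtype=float) - self.location) / self.scale


def build_reference_table(
    model_names: list[str],
    priors: coalescent.PriorSpec,
    n_per_model: int,
    sample_sizes: dict[str, int],
    n_loci: int = 50,
    seed: int | None = None,
    base_params: dict | None = None,
) -> ReferenceTable:
    """Simulate a balanced ABC reference table.

    Each row draws parameters from ``priors``, builds the named invasion
    model, simulates ``n_loci`` ascertained SNPs, and summarises them
    with :func:`summarize`.
    """
    rng = np.random.default_rng(seed)
    meta = coalescent.sim_metadata(sample_sizes)
    rows_models: list[str] = []
    rows_params: list[dict] = []
    rows_stats: list[np.ndarray] = []
    stat_names: list[str] | None = None
    for name in model_names:
        for _ in range(n_per_model):
            params = coalescent.draw_params(priors, rng)
            if base_params:
                params = {**base_params, **params}
            model = coalescent.build_model(name, params)
            sim_seed = int(rng.integers(0, 2**31 - 1))
            gm = coalescent.simulate_snps(
                model, sample_sizes, n_loci, seed=sim_seed
            )
            s = summarize(gm, meta, level="group")
            if stat_names is None:
                stat_names = list(s.index)
            rows_models.append(name)
            rows_params.append(params)
            rows_stats.append(s.to_numpy())
    return ReferenceTable(
        models=np.asarray(rows_models),
        params=pd.DataFrame(rows_params),
        stats=np.vstack(rows_stats),
        stat_names=stat_names or [],
        n_per_model=n_per_model,
    )


# ---------------------------------------------------------------------------
# model posteriors


@dataclass
class ModelPosterior:
    algorithm: str
    tolerance: float | None
    accepted: int
    probs: pd.Series  # indexed by model label, sums to 1
    votes: pd.Series | None = None

    def best_model(self) -> str:
        return str(self.probs.idxmax())


def _accepted_indices(
    table: ReferenceTable, obs: np.ndarray, tolerance: float
) -> tuple[np.ndarray, np.ndarray]:
    """Indices (stable distance order) and distances of the accepted set."""
    if not (0.0 < tolerance <= 1.0):
        raise ValueError("tolerance must be in (0, 1]")
    z = table.standardized()
    zo = table.standardized(obs)
    d = np.sqrt(((z - zo) ** 2).sum(axis=1))
    n_accept = math.ceil(tolerance * table.n)
    order = np.argsort(d, kind="stable")  # boundary ties: lowest row index
    idx = order[:n_accept]
    return idx, d[idx]


def _probs_series(labels: list[str], values: dict[str, float]) -> pd.Series:
    s = pd.Series({l: values.get(l, 0.0) for l in labels}, dtype=float)
    total = s.sum()
    return s / total if total > 0 else s + 1.0 / len(s)


def abc_reject(
    obs: pd.Series | np.ndarray, table: ReferenceTable, tolerance: float
) -> ModelPosterior:
    """Rejection ABC: Euclidean distance on MAD-standardised statistics;
    model posterior = model frequencies in the accepted set."""
    obs = np.asarray(obs, dtype=float)
    idx, _ = _accepted_indices(table, obs, tolerance)
    acc = pd.Series(table.models[idx]).value_counts(normalize=True)
    return ModelPosterior(
        "rejection", tolerance, len(idx), _probs_series(table.model_labels, acc.to_dict())
    )


def _epanechnikov(d: np.ndarray) -> np.ndarray:
    dmax = d.max()
    if dmax <= 0:
        return np.ones_like(d)
    return np.clip(1.0 - (d / (dmax * (1 + 1e-12))) ** 2, 1e-12, None)


def abc_mnlogistic(
    obs: pd.Series | np.ndarray, table: ReferenceTable, tolerance: float
) -> ModelPosterior:
    """Weighted multinomial logistic regression on the accepted set,
    evaluated at the observed statistics."""
    from sklearn.linear_model import LogisticRegression

    obs = np.asarray(obs, dtype=float)
    idx, d = _accepted_indices(table, obs, tolerance)
    y = table.models[idx]
    labels = table.model_labels
    if len(set(y.tolist())) == 1:
        return ModelPosterior(
            "mnlogistic", tolerance, len(idx), _probs_series(labels, {y[0]: 1.0})
        )
    X = table.standardized()[idx]
    w = _epanechnikov(d)
    clf = LogisticRegression(max_iter=2000)
    clf.fit(X, y, sample_weight=w)
    p = clf.predict_proba(table.standardized(obs)[None, :])[0]
    probs = dict(zip(clf.classes_, p))
    return ModelPosterior("mnlogistic", tolerance, len(idx), _probs_series(labels, probs))


def abc_neuralnet(
    obs: pd.Series | np.ndarray,
    table: ReferenceTable,
    tolerance: float,
    seed: int | None = None,
    n_restarts: int = 10,
    hidden: int = 8,
) -> ModelPosterior:
    """Single-hidden-layer classifier ensemble on the accepted set; the
    softmax outputs of ``n_restarts`` seeded restarts are averaged."""
    from sklearn.neural_network import MLPClassifier

    obs = np.asarray(obs, dtype=float)
    idx, d = _accepted_indices(table, obs, tolerance)
    y = table.models[idx]
    labels = table.model_labels
    if len(set(y.tolist())) == 1:
        return ModelPosterior(
            "neuralnet", tolerance, len(idx), _probs_series(labels, {y[0]: 1.0})
        )
    X = table.standardized()[idx]
    zo = table.standardized(obs)[None, :]
    rng = np.random.default_rng(seed)
    acc: dict[str, float] = {}
    for _ in range(n_restarts):
        clf = MLPClassifier(
            hidden_layer_sizes=(hidden,),
            max_iter=500,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        clf.fit(X, y)
        p = clf.predict_proba(zo)[0]
        for c, v in zip(clf.classes_, p):
            acc[c] = acc.get(c, 0.0) + v / n_restarts
    return ModelPosterior("neuralnet", tolerance, len(idx), _probs_series(labels, acc))


@dataclass
class RandomForestFit:
    """A random forest fitted once to a reference table.

    Fitting dominates the cost of random-forest model choice, so when
    many observed vectors are classified against the same table (e.g.
    pseudo-observed replicates), fit once with :func:`fit_random_forest`
    and pass the result to :func:`abc_random_forest`.
    """

    table: ReferenceTable
    clf: object
    reg: object | None
    n_trees: int


def fit_random_forest(
    table: ReferenceTable, n_trees: int = 1000, seed: int | None = None
) -> RandomForestFit:
    """Fit the classification forest and the out-of-bag success
    regressor (random-forest-ABC style) on the standardised table."""
    from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

    X = table.standardized()
    y = table.models
    clf = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, oob_score=n_trees >= 20
    )
    clf.fit(X, y)
    reg = None
    if n_trees >= 20:
        try:
            oob = clf.oob_decision_function_
            ok = ~np.isnan(oob).any(axis=1)
            success = (clf.classes_[np.argmax(oob[ok], axis=1)] == y[ok]).astype(float)
            reg = RandomForestRegressor(
                n_estimators=min(200, n_trees), random_state=seed
            )
            reg.fit(X[ok], success)
        except Exception:
            reg = None
    return RandomForestFit(table, clf, reg, n_trees)


def abc_random_forest(
    obs: pd.Series | np.ndarray,
    table: ReferenceTable | None = None,
    n_trees: int = 1000,
    seed: int | None = None,
    fitted: RandomForestFit | None = None,
) -> ModelPosterior:
    """Random-forest model choice on the full standardised table.

    Votes are the per-tree classifications of the observed vector; the
    posterior probability of the winning model is estimated by
    regressing out-of-bag classification success on the statistics
    (random-forest-ABC style), falling back to the vote share when the
    out-of-bag information is unavailable (e.g. a single tree).  Pass a
    prefit ``fitted`` forest to classify many observations without
    refitting; otherwise ``table`` is required.
    """
    if fitted is None:
        if table is None:
            raise ValueError("either a reference table or a fitted forest is required")
        fitted = fit_random_forest(table, n_trees=n_trees, seed=seed)
    table = fitted.table
    clf = fitted.clf
    obs = np.asarray(obs, dtype=float)
    labels = table.model_labels
    zo = table.standardized(obs)[None, :]
    tree_votes = np.array([t.predict(zo)[0] for t in clf.estimators_])
    class_of = dict(enumerate(clf.classes_))
    named = [class_of.get(int(v), v) if not isinstance(v, str) else v for v in tree_votes]
    votes = pd.Series(named).value_counts()
    votes = pd.Series({l: int(votes.get(l, 0)) for l in labels})
    best = str(votes.idxmax())
    post = float(votes[best] / votes.sum())
    if fitted.reg is not None:
        post = float(np.clip(fitted.reg.predict(zo)[0], 0.0, 1.0))
    probs = {l: float(votes[l] / votes.sum()) for l in labels}
    out = _probs_series(labels, probs)
    # report the regression-based posterior for the winning model while
    # keeping a valid simplex: scale the losers proportionally
    if 0.0 < post < 1.0 and out[best] < 1.0:
        rest = 1.0 - out[best]
        scaled = {l: (post if l == best else float(out[l]) / rest * (1 - post)) for l in labels}
        out = _probs_series(labels, scaled)
    return ModelPosterior("randomforest", None, table.n, out, votes=votes)


# ---------------------------------------------------------------------------
# parameter estimation


def estimate_params(
    obs: pd.Series | np.ndarray,
    table: ReferenceTable,
    model: str,
    tolerance: float,
    bounds: dict[str, tuple[float, float]] | None = None,
    adjust: bool = True,
) -> pd.DataFrame:
    """Rejection + local-linear regression-adjusted parameter posterior.

    Accepted parameter draws for ``model`` are adjusted Beaumont-style by
    a distance-weighted linear regression of parameters on statistics,
    on a logit scale when prior ``bounds`` are given so the adjusted
    draws respect the prior support.  ``adjust=False`` (or tolerance 1
    with no adjustment) returns the plain accepted draws.
    """
    obs = np.asarray(obs, dtype=float)
    keep = table.models == model
    sub = ReferenceTable(
        models=np.asarray(["m"] * int(keep.sum())),
        params=table.params.loc[keep].reset_index(drop=True),
        stats=table.stats[keep],
        stat_names=table.stat_names,
        n_per_model=int(keep.sum()),
    )
    idx, d = _accepted_indices(sub, obs, tolerance)
    theta = sub.params.iloc[idx].reset_index(drop=True).astype(float)
    if not adjust:
        return theta
    X = sub.standardized()[idx]
    zo = sub.standardized(obs)
    w = _epanechnikov(d)
    out = {}
    for col in theta.columns:
        t = theta[col].to_numpy(dtype=float)
        lo, hi = (bounds or {}).get(col, (None, None))
        if lo is not None and hi is not None and hi > lo:
            eps = 1e-9
            u = np.clip((t - lo) / (hi - lo), eps, 1 - eps)
            tt = np.log(u / (1 - u))
        else:
            tt = t
        A = np.column_stack([np.ones(len(X)), X - zo])
        WA = A * w[:, None]
        coef, *_ = np.linalg.lstsq(WA.T @ A, WA.T @ tt, rcond=None)
        fitted = A @ coef
        adj = coef[0] + (tt - fitted)
        if lo is not None and hi is not None and hi > lo:
            adj = lo + (hi - lo) / (1 + np.exp(-adj))
        out[col] = adj
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class ConfusionMatrix:
    algorithm: str
    counts: pd.DataFrame  # true model x selected model
    accuracy: float
    per_model_error: pd.Series
    oob_error: float | None = None


def _subset_table(table: ReferenceTable, keep: np.ndarray) -> ReferenceTable:
    models = table.models[keep]
    counts = pd.Series(models).value_counts()
    n_min = int(counts.min())
    # rebalance by trimming overfull models (keeps the balance invariant)
    sel = np.zeros(keep.sum(), dtype=bool)
    taken: dict[str, int] = {}
    for i, m in enumerate(models):
        if taken.get(m, 0) < n_min:
            sel[i] = True
            taken[m] = taken.get(m, 0) + 1
    rows = np.flatnonzero(keep)[sel]
    return ReferenceTable(
        models=table.models[rows],
        params=table.params.iloc[rows].reset_index(drop=True),
        stats=table.stats[rows],
        stat_names=table.stat_names,
        n_per_model=n_min,
    )


def cross_validate(
    table: ReferenceTable,
    n_pseudo_per_model: int,
    algorithm: str = "rejection",
    tolerance: float = 0.05,
    seed: int | None = None,
    n_trees: int = 500,
) -> ConfusionMatrix:
    """Leave-one-out cross-validation of a model-choice algorithm.

    Pseudo-observed rows are held out and classified against the
    remaining table; the random forest instead reports its out-of-bag
    confusion over the whole table (the forest's native leave-one-out
    analogue).
    """
    labels = table.model_labels
    rng = np.random.default_rng(seed)
    if algorithm == "randomforest":
        from sklearn.ensemble import RandomForestClassifier

        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed, oob_score=True
        )
        clf.fit(table.standardized(), table.models)
        oob = clf.oob_decision_function_
        ok = ~np.isnan(oob).any(axis=1)
        pred = clf.classes_[np.argmax(oob[ok], axis=1)]
        true = table.models[ok]
    else:
        chosen: list[int] = []
        for m in labels:
            rows = np.flatnonzero(table.models == m)
            chosen += rng.choice(
                rows, size=min(n_pseudo_per_model, len(rows)), replace=False
            ).tolist()
        pred_l, true_l = [], []
        for row in chosen:
            keep = np.ones(table.n, dtype=bool)
            keep[row] = False
            rest = _subset_table(table, keep)
            obs = table.stats[row]
            if algorithm == "rejection":
                post = abc_reject(obs, rest, tolerance)
            elif algorithm == "mnlogistic":
                post = abc_mnlogistic(obs, rest, tolerance)
            elif algorithm == "neuralnet":
                post = abc_neuralnet(
                    obs, rest, tolerance, seed=int(rng.integers(0, 2**31 - 1)),
                    n_restarts=3,
                )
            else:
                raise ValueError(f"unknown algorithm {algorithm!r}")
            pred_l.append(post.best_model())
            true_l.append(str(table.models[row]))
        pred = np.asarray(pred_l)
        true = np.asarray(true_l)
    counts = pd.crosstab(
        pd.Series(true, name="true"), pd.Series(pred, name="selected")
    ).reindex(index=labels, columns=labels, fill_value=0)
    total = counts.to_numpy().sum()
    acc = float(np.trace(counts.to_numpy()) / total) if total else np.nan
    row_sums = counts.sum(axis=1)
    per_err = 1.0 - pd.Series(np.diag(counts), index=labels) / row_sums.replace(0, np.nan)
    oob_error = (1.0 - acc) if algorithm == "randomforest" else None
    return ConfusionMatrix(algorithm, counts, acc, per_err, oob_error)
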