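"""Invasion-history inference by approximate Bayesian computation.

Builds a reference table over the ten named invasion models, classifies
a pseudo-observed dataset simulated under a known model, estimates that
model's parameters with regression adjustment, and cross-validates the
classifier.  Scaled down (60 simulations/model) so it runs in about a
minute; real analyses use thousands per model.

Run: python examples/05_invasion_models_abc.py
"""

import numpy as np

from invpopgen.coalescent import (
    GROUPS,
    MODEL_NAMES,
    NATIVE,
    build_model,
    default_priors,
    draw_params,
    sim_metadata,
    simulate_snps,
)
from invpopgen.model_choice import (
    abc_random_forest,
    abc_reject,
    build_reference_table,
    cross_validate,
    estimate_params,
    summarize,
)

SIZES = {NATIVE: 4, **{g: 4 for g in GROUPS}}
N_LOCI = 50
priors = default_priors()

print("building reference table (10 models x 60 simulations)...")
table = build_reference_table(
    list(MODEL_NAMES), priors, 60, SIZES, n_loci=N_LOCI, seed=1
)

# Pseudo-observed data from a known generating model.
truth = "Grp2_bridge_indGrp1_5"
rng = np.random.default_rng(2)
params = draw_params(priors, rng)
gm = simulate_snps(build_model(truth, params), SIZES, N_LOCI, seed=3)
meta = sim_metadata(SIZES)
obs = summarize(gm, meta, level="group")

print(f"\ntrue model: {truth}")
for name, post in (
    ("rejection", abc_reject(obs.to_numpy(), table, tolerance=0.05)),
    ("random forest", abc_random_forest(obs.to_numpy(), table, n_trees=500, seed=0)),
):
    top = post.probs.sort_values(ascending=False).head(3)
    print(f"  {name}: " + ", ".join(f"{m}={p:.2f}" for m, p in top.items()))

# Parameter estimation under the winning model, regression-adjusted.
post_params = estimate_params(
    obs.to_numpy(), table, truth, tolerance=0.3,
    bounds={"ne_Grp2": (18.0, 250.0)},
)
est = post_params["ne_Grp2"]
print(f"\nne_Grp2: true {params['ne_Grp2']:.0f}, "
      f"posterior median {est.median():.0f} "
      f"[{est.quantile(0.05):.0f}, {est.quantile(0.95):.0f}]")

# How confusable are the models at this scale?
cm = cross_validate(table, 0, "randomforest", seed=0, n_trees=300)
print(f"\nrandom-forest OOB accuracy: {cm.accuracy:.2f} "
      f"(chance would be {1 / len(MODEL_NAMES):.2f})")
print("per-model error rates:")
print(cm.per_model_error.round(2).to_string())
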