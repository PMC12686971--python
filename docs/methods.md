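# Methods and conventions

This document records the statistical definitions, default parameters,
and numerical choices the package implements, along with their known
limitations. File references are to modules under `src/invpopgen/`.

## Filtering (`filtering.py`)

The chain applies, in order within one iteration: site quality
(`min_qual`, default 20; sites with unknown quality are kept), minor
allele count (`min_mac`, default 3, counted over non-missing calls),
per-locus missingness (`max_locus_missing`), read depth (`min_depth`,
only in the demographic track), and per-individual missingness
(`max_ind_missing`). Because removing individuals changes allele counts
and missingness fractions, the chain iterates to a fixed point; the
final step thins to one SNP per `thin_spacing` bp window per chromosome,
keeping the lowest-position SNP. The fixed point makes the whole filter
idempotent, which the tests verify both on hand-built fixtures and
property-based random panels.

Three preset tracks (`pipeline.py`) differ only in thresholds:
gene-flow (locus missingness 0.55, individual 0.70), diversity (same,
plus a strict post-hoc locus trim at 0.20), demographic (locus 0.50,
individual 0.75, depth >= 5). These mirror the common practice of
filtering leniently for sample-hungry clustering analyses and strictly
for site-frequency-sensitive demographic inference.

## Diversity and divergence (`diversity.py`)

- Expected heterozygosity uses the small-sample correction
  `Hs = 2n/(2n-1) * 2p(1-p)` with `n` the non-missing diploid count per
  locus and population. F_IS = 1 - Ho/He, NaN where He = 0.
- Rarefied allelic richness at `g` gene copies is the exact
  hypergeometric expectation
  `Ar = sum_i [1 - C(N - N_i, g) / C(N, g)]`, computed with log-gamma
  factorials. Loci where **any** population has fewer than `g` copies
  are dropped from **all** populations so values stay comparable; the
  reported value is the mean over retained loci. Default `g = 12`.
- Pairwise F_ST is Nei's estimator as a ratio of sums over loci
  polymorphic in the pair: numerator `Ht - Hs_mean`, with
  `Ht = 2*p_bar*(1-p_bar) + Hs_mean/(2*n_harmonic*2)` for a pair (and
  `/(2*n_harmonic*r)` for `r` populations overall). Negative estimates
  are **not** truncated to zero; truncation would bias averages of
  weakly differentiated pairs upward.
- F_ST confidence intervals are percentile bootstraps over loci
  (resampling the per-locus numerator/denominator components).
- Group comparisons use Kruskal-Wallis H with Dunn pairwise z-tests and
  Benjamini-Hochberg correction.

## Clustering (`clustering.py`)

- PCA centres mean-imputed dosages; component signs are fixed so each
  loading vector's largest-magnitude entry is positive, making results
  run-to-run deterministic.
- The number of clusters is chosen by minimising
  `BIC(k) = n*ln(SSE/n) + k*ln(n)` over k-means solutions on retained
  PCs, taking the smallest k within one BIC unit of the minimum (the
  elbow convention rather than the raw argmin, which drifts upward on
  noisy data).
- DAPC runs LDA on retained PC scores; the a-score (observed
  reassignment minus the mean of label-permuted reassignments) selects
  how many PCs to keep. Retaining close to n-1 PCs triggers an
  overfitting warning.
- Neighbour joining follows the canonical Studier-Keppler algorithm
  (via scikit-bio), with negative branch lengths clamped to zero and
  flagged. Bootstrap supports resample loci, rebuild the F_ST matrix
  and count recovered bipartitions of the point-estimate tree.

## Spatial statistics (`spatial.py`)

- Isolation by distance is tested as linearised F_ST, `F/(1-F)`,
  against ln(great-circle km) with a one-sided Mantel permutation test
  (default 999 permutations); `p = (1 + #{r_perm >= r_obs}) / (n_perm + 1)`.
  Pairs at zero distance or with F_ST = 1 are excluded with a warning;
  fewer than five populations sets a low-power flag.
- The directionality index psi compares pooled-minor-allele frequencies
  between populations at loci polymorphic in both:
  `psi(a, b) = mean_l(f_b,l - f_a,l)`, with a locus-bootstrap z-score.
  **Sign convention:** psi(a, b) > 0 means b carries higher shared
  minor-allele frequencies. Serial drift away from a source depletes
  shared minor alleles downstream, so a consistent negative
  psi(source, front) across pairs points back toward the source, while
  equilibrium populations give psi near 0 with calibrated z-scores. An
  optional outgroup repolarises alleles by the outgroup major allele.

## Landscape resistance (`resistance.py`)

Conductance rasters use 4-neighbour connectivity with edge conductance
equal to the mean of the two cell conductances. Effective resistance
between sampled cells is computed per connected component by grounding
one node of the Laplacian and solving with a sparse LU factorisation;
disconnected pairs are reported as infinite. (A numerical note: NumPy's
default SVD-based `pinv` is unreliable on grid Laplacians beyond ~50
nodes; the tests therefore use `pinv(L, hermitian=True)` or a grounded
dense solve as oracles, both of which agree with the implementation to
8+ digits.)

Candidate surfaces are compared by
`AICc = n*ln(RSS/n) + 2k + 2k(k+1)/(n-k-1)` of an OLS fit of linearised
F_ST on effective resistance (or ln distance for the IBD candidate, or
intercept-only for the null), with `k` counting surface parameters plus
slope, intercept and error variance; `AICc = inf` when `n - k - 1 <= 0`.
Categorical surfaces fix the first class at resistance 1 and optimise
the remaining log-resistances (constrained >= 1) by multistart
Nelder-Mead. This is a deliberate, lightweight stand-in for
genetic-algorithm surface optimisers: with few classes and smooth
objectives it recovers planted barriers reliably, but it does not
explore continuous transformations of covariate surfaces.

## Coalescent simulator (`coalescent.py`)

A discrete-event structured coalescent on diploid populations:
within-population coalescence at rate `k(k-1)/(4N)` per generation,
backward-in-time migration of single lineages, and colonisation events
that move all lineages of a derived population into its source at the
founding time. A founder event is modelled as an epoch of
`bottleneck_duration` generations (default 5) at `founder_size`
immediately after founding, then the contemporary size.

Two output modes:

- `simulate_snps`: one SNP per locus, ascertained to pooled minor
  allele count >= 3 (matching the empirical MAC filter), mutation
  placed on a branch proportional to branch length; the ascertainment
  budget is 100 genealogies per requested locus.
- `simulate_sites`: unascertained Poisson(mu * L * tree length)
  mutations for calibration against closed forms (E[pi] = 4*Ne*mu*L,
  E[S] = theta*L*H_{2n-1}); the acceptance tests verify both to within
  3 Monte Carlo standard errors at 2000 loci.

### The ten invasion models

Five invaded regions (`Grp1`..`Grp5`, geographically ordered) plus a
native-range population. Models: `5cols_step` (five independent
introductions), `W2E_step` (serial west-to-east spread),
`Grp3_bridge`/`Grp2_bridge` (one introduction, the focal group seeds
all others simultaneously), `Grp3_step`/`Grp2_step` (the focal group
seeds its neighbours serially along the chain), and `_indGrp1_5`
variants where the terminal groups come directly from the native range.
Bridge models put the strong migration tier on source-colony edges,
step models on the colonisation chain; all models keep weak migration
between geographically adjacent groups.

Default parameters (`default_params`) — native Ne 2000, invaded Ne 100,
founder size 10, bottleneck 5 generations, primary introduction 30
generations ago, secondary 20, independent 18, weak/strong migration
0.002/0.01 — are explicit reconstructions chosen to be biologically
plausible for a recent aquatic invasion; they are not fitted values,
and every one is overridable per call. The ABC priors
(`default_priors`) are log-uniform: invaded Ne in [18, 250], native Ne
in [500, 5000], founder sizes in [2, 30], migration tiers in
[1e-4, 5e-3] and [2e-3, 2e-2].

Note that `Grp3_bridge_indGrp1_5` and `Grp3_step_indGrp1_5` are nearly
topologically identical (they differ only in one founding time), so
high mutual confusion between them in model choice is expected and
correct, not a classifier failure.

## ABC (`model_choice.py`)

Summary statistics per region: He, Ho, number of polymorphic loci,
private alleles, all pairwise F_ST, and overall F_ST. Statistics are
standardised by the reference table's per-statistic median and MAD
(MAD floored at 1 so constant statistics cannot blow up distances);
observed vectors are standardised with the same table constants.

- Rejection: accept the `ceil(tolerance * N)` nearest rows by Euclidean
  distance on standardised statistics, ties broken by stable sort.
  Tolerance 1 returns the prior exactly.
- Multinomial logistic and neural-net (MLP ensemble) classifiers are
  fit on the accepted set with Epanechnikov distance weights.
- Random forest classifies on the full table; the winning model's
  posterior is refined by regressing out-of-bag classification success
  on the statistics. Fitting dominates the cost, so `fit_random_forest`
  returns a reusable fit for classifying many observed vectors (e.g.
  pseudo-observed replicates) against the same table.
- Parameter estimation is rejection plus Beaumont-style local-linear
  regression adjustment, performed on a logit scale when prior bounds
  are supplied so adjusted draws respect the support.
- Cross-validation holds out reference rows as pseudo-observed data
  (the random forest instead reports its native out-of-bag confusion).

## Synthetic generators (`synthetic.py`)

Hierarchical Balding-Nichols sampling: ancestral frequencies
uniform(0.1, 0.9), cluster frequencies Beta-drifted with parameter
`f_between`, deme frequencies further drifted with `f_within`.
Calibration inverts Nei's pairwise expectation: a drift parameter `F`
yields expected pairwise F_ST `F/(2-F)`, so targets are mapped through
`f = 2T/(1+T)` and the between-cluster drift is composed as
`(f_total - f_within)/(1 - f_within)`. Monomorphic loci are redrawn so
panels are fully polymorphic before missingness is injected (missing
completely at random). The IBD generator drifts frequencies along a
transect chain with the per-step drift chosen so the expected
regression slope of `F/(1-F)` on ln(km) equals the requested
`ibd_slope`.

Realism limits: unlinked loci only, no linkage disequilibrium, no
selection, missingness completely at random, and drift applied as a
one-shot Beta rather than generation-by-generation. These generators
exist to provide analytically known truths for tests, not to emulate
every property of RAD-seq data.

## Pipeline determinism (`pipeline.py`)

`run_pipeline` fails fast if inputs are missing, writes each stage's
outputs as CSV stamped with a 16-hex-digit hash of the analysis
configuration (the output directory is excluded from the hash, so the
same analysis hashes alike wherever it is written), and ends with a
`manifest.json` listing stages, files and the hash. Reruns with the
same configuration are byte-identical.
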