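# Methods

## Preprocessing

Input expression is a genes × samples matrix on a log scale (the package
performs no count normalization itself). Samples missing a value for the
modeling target gene are dropped first; then genes with more than 25%
missing values (`na_frac=0.25`) or a sample standard deviation ≤ 0.5
(`sd_min=0.5`, ddof=1 on non-missing entries, on the pre-z-score scale) are
removed, and the survivors are z-scored per gene across all samples of both
conditions jointly. The SD filter is inclusive at the boundary (a gene at
exactly the cutoff is removed). The target gene is exempt from both gene
filters, and an `override` list can rescue further genes whose unfiltered
values are wanted — useful when a biologically required regulator's coding
gene is low-variance. Ordering matters: dropping the target-missing samples
before z-scoring guarantees every retained gene has mean 0 and SD 1 over
the samples actually used downstream. We assume input values are already on
their final (log) scale; the SD filter is applied on that scale.

## Activity inference

Activity is the edge-score-weighted mean of a regulator's target-gene
z-scores, with the modeled target gene excluded from every regulator's sum
so the response never leaks into the predictors. Missing target values are
dropped pairwise per sample (both numerator and denominator), which keeps
activities defined wherever at least one scored target was measured;
regulators undefined in any sample are flagged and excluded from model
fitting. Activities are invariant to rescaling one regulator's edge scores,
and a single-target regulator's activity equals that target's z-score
exactly.

## Best-subset regression MILP

The fit minimizes the L1 norm of the residuals, linearized as
`e_k ≥ ±(g_k − g̃_k)` with `e_k ≥ 0`. L1 was chosen over least squares
because it linearizes exactly (keeping the problem a MILP) and is robust to
the heavy-tailed residuals typical of low-expressed genes. Each coefficient
is gated by a binary `x_t` through `−M·x_t ≤ β_t ≤ M·x_t` with `M = 100`
by default — far above any plausible coefficient on z-scored data; the
solver logs a warning if a fitted |β| reaches the bound, which signals that
`bigM` must be raised. Ties between equally optimal subsets are broken
lexicographically by regulator id via a secondary objective perturbation of
1e-9 per selection rank, so results are reproducible across solver
versions. All MILPs are solved with HiGHS (via `scipy.optimize.milp`) at a
relative MIP gap of 1e-6.

With `size=0` the optimum intercept is any median of the target values;
the reported objective equals the median's absolute-deviation sum even
though the solver may return a different minimizer within the median
interval for even sample counts.

## Cross-validation ensembles and condition comparison

Model ensembles come from repeats × folds × sizes fits: per repeat a seeded
permutation splits samples into `folds` parts differing in size by at most
one; each part is held out once while models of every size are fit on the
rest and scored by Pearson correlation on the held-out part. Defaults
follow the intended study design: 10 repeats, 3 folds, sizes 1–10, i.e.
300 models per condition. Activities are per-sample statistics, so they
are computed once on all samples without train/test leakage.

The per-regulator 2×2 frequency table (selected / not selected in the two
ensembles) is tested with Fisher's exact test (two-sided); Fisher was
preferred over chi-square for its exactness at small counts. Adjustment
uses Benjamini–Hochberg across all tested regulators.

## Modularity

Pair weights multiply the Pearson correlation of the two activity profiles
by the network evidence for the pair. Since es(t1→t2) and es(t2→t1)
generally differ (and one is usually absent, contributing 0), the mean of
both directions is taken, giving a symmetric matrix with zero diagonal.
Constant activity profiles get correlation 0 with a warning rather than an
error. The Newman correction subtracts `d_t1·d_t2/(2m)`; the diagonal of
the corrected matrix keeps its `−d_t²/(2m)` terms so that the corrected
weights sum to zero over all ordered pairs — the conservation identity of
the null model — even though self-pairs can never enter a module.

The module MILP uses binary node and pair variables with the three linking
constraints `x_1 + x_2 − y ≤ 1`, `y ≤ x_1`, `y ≤ x_2`, which force
`y = x_1·x_2` exactly: negative-weight pairs inside the module penalize the
objective instead of being dropped. The objective uses the corrected
weights w̃ by default — that is what makes the degree penalty meaningful —
but `use_corrected=False` scores the raw weights for comparison.

## Combined model and λ tuning

The combined MILP concatenates the regression constraints (over direct
candidates) and the modularity constraints (over direct ∪ indirect
candidates) with shared node indicators and a single budget
`Σ x_t ≤ limit` covering both pools; a candidate appearing in both pools
gets one binary. The objective is `fit error − λ · module weight`. At
λ = 0 it reduces exactly to the best-subset regression; for λ large enough
it reduces to the pure modularity solve.

Indirect candidates are pre-selected by running the single-target CV with
each direct regulator's coding gene as the target and keeping regulators
selected in at least 20% of the models (inclusive threshold); direct
regulators without usable expression are skipped with a warning and
contribute no candidates.

λ is swept over the log grid {0.001, 0.01, 0.1, 0.3, 1, 3, 10, 100, 1000}
by default, with the full CV repeated at each value (same seed, so splits
are identical across the grid). Selected nodes are counted as "direct" if
they belong to the direct candidate pool and "indirect" otherwise. The
tuned λ* is the crossing of the two count curves, linearly interpolated on
the log10(λ) axis between the adjacent grid points where the sign of
(direct − indirect) flips; interpolation in log space is the natural choice
on a logarithmic grid. An exact zero at a grid point returns that value; if
the curves never cross, the grid point minimizing |direct − indirect| is
returned with a warning.

The final module is the most frequent exact direct-regulator combination
over all models at λ* (ties broken by higher mean held-out performance,
then lexicographically), plus every indirect regulator selected in more
than half of the models carrying that combination. "Majority co-selection"
operationalizes the notion of the module's corresponding indirect
regulators; other cutoffs are possible but >50% makes the set unique.

## Synthetic benchmark

The generator plants (i) per-TF latent activities a_t ~ N(0,1), with the
indirect-module TFs sharing a common factor at loading
√module_correlation (default 0.6, a moderately dense co-regulation);
(ii) per-TF readout targets and a coding gene equal to a_t plus N(0, 0.25)
noise, so the weighted-mean activity estimator approximately inverts the
construction; (iii) a target gene following the planted linear model with
condition-specific regulator sets and N(0, noise_sd) noise (default 0.5 on
z-scale data, i.e. roughly a third of the target's variance unexplained);
and (iv) uniformly sprinkled missing values (default 2%). The network
carries TF→target edges with evidence scores ~U(0.5, 1.5), unit-score
TF→target-gene edges for every TF (every TF is a direct candidate),
module-internal TF→TF edges, edges from module TFs onto the planted direct
regulators' coding genes, and 5% random background TF→TF edges.

What the generator does **not** emulate: count-based noise models
(RSEM/negative-binomial), batch effects, correlated decoy TFs sharing
targets, and unbalanced cohort sizes beyond what the caller requests.
Passing recovery tests therefore shows the machinery is correct and
identifiable under its own assumptions, not that real-data performance
will match.

## Validation experiment sizes

The recovery experiments run at desk scale, chosen to exercise the full
machinery while keeping an exact solver in the loop: direct-regulator
ranking uses 200 samples, 20 candidate TFs, noise SD 0.5, and a
27-model ensemble (3 repeats × 3 folds × sizes 1–3) per seed; the
dual-condition experiment uses the full 300-model ensembles per condition
with 10 candidate TFs and 30 samples per condition; module recovery uses 8
TFs, 120 samples, sizes 2–7 and 6 fold-repeats per λ. Success criteria are
majorities over 10 seeds, so single-seed flukes do not flip the outcome.

## Degenerate inputs and numerical notes

Constant prediction or measurement vectors make the Pearson performance
undefined; it is returned as NaN with a warning and excluded from means.
A regulator absent from the network yields an empty target list, not an
error. Zero-SD exempt genes are centered but not scaled during
preprocessing. An all-zero module graph (m = 0) is rejected as degenerate.
Solver failures raise rather than returning silently suboptimal models.
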