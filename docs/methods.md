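# Methods

`cograte` links gut-microbiome metabolic modelling and host multi-omics
layers to a composite measure of spatial-learning performance in aging mice.
This note documents the models, the numerical choices, and what the
synthetic data do and do not establish.

## Composite cognitive rank

Barnes-maze training (six days, three trials per day) yields two trial-level
readouts: the primary latency to the escape hole (capped at 240 s — trials
that hit the cap are right-censored observations of the true search time)
and a discrete cognitive score encoding the search strategy (direct = 1 …
random = 0; the probe trial uses its own value set {0, 0.167, 0.5, 1}).

Latency is modelled on the y = −log(latency s) scale, where the 240 s cap
becomes a *lower* censoring limit L = −log 240 ≈ −5.48 and the 1 s floor an
upper limit U = 0. For each mouse we fit

y = β₀ + β₁·day + ε, ε ~ N(0, σ²),

by maximizing the censored-normal (Tobit) likelihood: uncensored trials
contribute the normal density, capped trials the lower tail Φ((L−μ)/σ),
floored trials the upper tail. σ is parameterized as exp(log σ) and the
optimizer (L-BFGS-B) starts from the OLS solution plus two σ-scale
perturbations; with no censored trials the MLE coincides with OLS (verified
to 1e-6). Mice whose training trials are all censored at one limit carry no
slope information and are flagged non-converged; their regression measures
are treated as missing. The cognitive score is fit by OLS on day. The day
number (1–6) is the predictor for both regressions, with the three daily
trials as repeated observations.

Eight measures per mouse — latency intercept/slope (Tobit), score
intercept/slope (OLS), probe latency and score (day 7, as recorded; a mouse
that never finds the hole in the probe scores 0), retention latency (best of
days 11 and 12) and retention score (day 11) — are each ranked within the
cohort, higher rank = better cognition. Probe and retention latency are
lower-is-better; every other measure, including both latency coefficients
(which live on the −log scale), is higher-is-better. Ties receive average
ranks. A missing value receives rank 1 exactly; when any value is missing,
the observed values are ranked among themselves and shifted up by one, so
missing values never enter an observed tie block. (An alternative reading —
ranking observed values over the full 1..n range — changes at most the top
rank labels; the literal "minimum rank" reading is implemented.) The
composite cognitive rank is the per-mouse median of the eight ranks. It
depends on the raw measures only through within-cohort orderings, which the
suite verifies by applying random strictly-increasing maps to each measure.

## FVA-based reaction abundances

Each taxon carries a genome-scale metabolic model (SBML via cobra, or a
one-reaction-per-line TSV dialect). Flux balance analysis maximizes biomass
production subject to steady state (S v = 0) and flux bounds; flux
variability analysis then computes each reaction's attainable flux range
while growth is constrained to at least 99% of the optimum (implemented as a
raised lower bound on the biomass reaction — equivalent to a constraint row
and numerically simpler). All LPs use HiGHS (scipy) with primal/dual
feasibility tolerances of 1e-9; the test suite cross-checks every generated
fixture against cobra's GLPK-backed FVA, an entirely independent code path,
to 1e-8.

A reaction is *active* for a taxon when its FVA range exceeds 1e-6 in
magnitude in either direction (strict comparison); direction-agnostic
activity is used because a range certifies capability, not sign. Activity
vectors are normalized by each taxon's active-reaction count, weighted by
the taxon's relative abundance per sample, summed over taxa, and finally
renormalized per sample — every column of the reaction × sample matrix sums
to one. Exchange reactions count both in the denominator and as matrix rows.
Taxa with no active reaction are excluded with a warning.

## Community simulations

Per sample, member models are merged into one LP. Member compartments are
namespaced; each member's exchange reactions are rerouted into a shared
environment compartment, and only community-level boundary reactions touch
the outside (the gut lumen). Coupling follows the standard
compartmentalized-coupling formulation: member biomass fluxes are fixed
proportions of community growth (v_bio,i = aᵢ·μ_C) and every non-biomass
member flux obeys |v| ≤ c·v_bio,i with coupling constant c = 400 (exposed in
config). The objective maximizes μ_C. Lumen uptake capacity per metabolite
defaults to the largest uptake capacity any member's own exchange grants
(export is permissive); explicit per-metabolite lumen bounds can override
this, e.g. to close the lumen entirely. Infeasibility is reported as a
status, never an exception, and infeasible samples are dropped from
downstream tables.

From a solved instance we compute, per environment metabolite, each member's
net transfer into the environment; with production P = Σ max(0, tᵢ) and
consumption C = Σ max(0, −tᵢ), the cross-feeding summary is
internal_transfer = min(P, C) and the lumen boundary flux lumen_net = P − C
(positive = export). Net fluxes are read off the single optimal vertex the
solver returns; alternate optima are not disambiguated (no parsimonious or
lexicographic resolution), so degenerate instances are solver-dependent.

## Preprocessing

Near-zero-variance filtering removes a feature when its most-common /
second-most-common value-frequency ratio exceeds 19 *and* fewer than 10% of
its values are distinct, or when it is constant (a single distinct value has
an infinite ratio). Percent-unique is 100·#distinct/#samples. The filter is
idempotent.

Promoter methylation is the unweighted mean of CpG ratios inside the
symmetric window [TSS−1000, TSS+1000) (half-open on the right, per BED
convention; for −-strand genes the TSS is `end − 1`; the window is symmetric
so strand does not change membership). Genes lacking a covered CpG in any
sample are dropped cohort-wide, because the downstream selection admits no
missing values. For the same reason, samples absent from any layer are
excluded by a complete-case intersection across all layers and the rank
table before selection.

## Feature selection

Boruta is re-implemented from scratch on scikit-learn random-forest
regressors (the composite rank is a numeric response). Each iteration
permutes every active feature to create shadow features, fits a forest on
the augmented matrix, and scores a hit for a real feature whose importance
strictly exceeds the best shadow's. A two-sided exact binomial test at
success probability 0.5, Bonferroni-adjusted over the currently undecided
features (α = 0.01), confirms or rejects after every iteration; rejected
features and their shadows leave the matrix; features undecided after
`max_iterations` (default 100) are tentative and count as not confirmed (no
rough-fix pass).

One design point required care. If shadows are drawn only from the
still-active features, mass rejection shrinks the shadow pool, the
best-shadow threshold collapses, and the feature with the largest *chance*
association in a null matrix — the maximum over p features — eventually
beats a maximum over a handful of shadows and is confirmed spuriously. The
shadow pool is therefore floored at `shadow_floor_factor` (default 2) times
the original feature count by appending additional independent permutations
of the active features, keeping the threshold calibrated to the original
dimensionality. With this floor, pure-noise matrices (74 samples × 200–500
features) yield essentially no confirmations, while planted features with
|Spearman ρ| ≈ 0.6 are confirmed in virtually every run.

Importance is the forest's impurity importance (mean decrease in impurity);
permutation importance is selectable. Forests use √p feature subsampling.
The `n_trees` default is 500; the acceptance-scale experiments run 32 trees
(null control) and 96 trees (planted recovery), sizes at which the null and
recovery behavior above were established — importance noise at very small
forests weakens recovery, very large forests gain little.

Stability wrapping: 50 independent runs with seeds seed+1 … seed+50.
Features confirmed in ≥ 10 runs are *robust* (single-layer interpretation);
features confirmed at least once are *candidates*. The integrated stage
pools all layers' candidates under layer-qualified ids over the common
samples and repeats the 50-run scheme; the final cross-layer predictor set
is the robust features of that stage.

## Annotation

Associations between features and the composite rank use Spearman
correlation (average-tie ranks, two-sided p; constant inputs yield missing).
Over-representation analysis restricts GMT gene sets to the layer universe,
keeps sets of within-universe size 10–500, computes the one-sided upper-tail
hypergeometric p (cross-checked against exhaustive enumeration for N ≤ 25),
applies Benjamini–Hochberg across the tested family, and reports sets with
nominal p ≤ 0.05 and overlap ≥ 3, sorted by (q, set size ascending — a
documented choice; the tiebreak direction is not externally fixed).
Functional-category scores are |model ∩ category| / |category| per metabolic
model; categories scored identically in every model are dropped.

## Synthetic data

The generators produce every input the pipeline consumes, at the study's
design: 83 mice in five age groups (3/9/15/24/28 months; 16/16/16/17/18
animals), a 240 s latency cap, and roughly 30% censored training trials.
Mouse i draws a latent intercept and learning slope from age-specific
normals (intercept SD 0.3, slope SD 0.08 across mice); trial-level
performance is y = b₀ᵢ + b₁ᵢ·day + ε with ε ~ N(0, 0.8) on the −log-latency
scale, and latency = clamp(exp(−y), 1, 240) with the censored flag set
exactly when the cap binds. The age-group means (intercepts −5.5 … −6.1,
slopes 0.50 … 0.14 per day) were chosen so that day-one latencies, learning
curves, and the overall censoring fraction (~28%, analytic value) are
realistic for this task; the closed-form normal-tail censoring probability
under the realized latent parameters serves as the oracle for the generator
test. Cognitive scores are produced by thresholding the same latent y into
the legal score sets with fixed cut points chosen to make all score values
non-degenerate; the conditional distribution of scores given ability in real
data is unknown, and this thresholding is a stand-in, not an inference.

Omics layers couple planted features to the cognitive rank through a
Gaussian copula: the latent Pearson coefficient is 2·sin(π·ρₛ/6) so the
*Spearman* correlation targets the configured effect size (0.6 by default,
the regime the selection experiments probe); signs are random. Methylation
layers are mapped through a logistic into [0, 1], expression and metabolome
layers through an exponential into positive values — monotone maps that
preserve rank associations. Sample-level missingness (default 9 of 83
samples withheld from one layer, mirroring complete-case exclusion) is the
only missingness mechanism. Not emulated: count noise, library-size and
batch effects, feature–feature correlation beyond the shared rank signal,
and compositionality of abundances — so passing selection tests demonstrate
recovery of monotone single-feature signals at the study's n, not robustness
to those real-data features.

Metabolic-model fixtures are chain, branch, and cross-feeding motifs (≤ 30
reactions) with parameters drawn per taxon; ground-truth flux ranges are
attached, computed with cobra/GLPK rather than the package's own LP stack.
Taxon abundances are Dirichlet(2) per sample. CpG fixtures scatter sites
inside and outside the ±1000 bp windows with Beta(2,2) ratios.

## Problem sizes and runtime

The heavy stochastic experiments run at deliberately scaled sizes: in the
test suite, null control uses 10 datasets × 200 noise features × 50
stability runs (robust-total threshold ≤ 1) and planted recovery 74 samples
× 500 features (10 planted) across two layers; the acceptance script runs
the same designs at 4 null datasets and 2 × 150 features. The Tobit oracle
is a 50 × 50 × 20 grid over (β₀, β₁, σ). These
sizes keep the full suite in the tens of minutes on one core while leaving
every statistical conclusion at the study's sample size n = 74–83.

## Known limitations

- Community net fluxes inherit the solver's choice among alternate optima.
- The Boruta shadow floor is a deliberate extension of the classical
  algorithm; without it the null false-confirmation pathology described
  above reappears.
- The promoter window is symmetric and strand-independent by construction;
  a strand-aware asymmetric window would require re-deriving the rule.
- Synthetic layers are independent given the rank signal; correlated blocks
  (co-expression modules, methylation neighborhoods) are not modelled.
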