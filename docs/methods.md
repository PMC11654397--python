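# Methods

`rarcat` assesses how much a typology-based association study depends on the
sample it was estimated from.  The pipeline has four statistical layers:
sequence dissimilarity and clustering, bootstrap replication, per-replicate
regression effects, and meta-analytic pooling.  This note records the model
in each layer, the defaults and why, the numerical choices, and what the
synthetic-data checks do and do not demonstrate.

## Dissimilarity and typology

Trajectories are categorical state sequences over a finite alphabet in which
nonresponse is itself a state.  Pairwise dissimilarity is the Optimal
Matching (OM) edit distance: the cheapest way to turn one sequence into the
other by substitutions and insertions/deletions, computed by the standard
dynamic program.  Substitution costs follow the transition-rate ("TRATE")
scheme

    sub(i, j) = c_max − p(j|i) − p(i|j),        c_max = 2 (default),

with `p(j|i)` the observed probability of moving from state *i* to state *j*
between adjacent time points, pooled over the whole sample and all adjacent
pairs (a single, time-invariant cost matrix).  `c_max = 2` keeps the costs
non-negative since `p(j|i) + p(i|j) ≤ 2`; it is exposed as a parameter.  The
indel cost is `c_max / 2`.  Every substitution involving the missing state —
including an aligned missing/missing pair — costs `c_max`, so shared
nonresponse never counts as similarity.  A consequence worth knowing: two
identical sequences that both contain missing positions have a *positive* OM
distance (2 per missing position); the self-distance on the matrix diagonal
is zero by construction.  The missing/missing cost is configurable because
conventions differ.  Whole sequences enter the DP, including trailing runs
of an absorbing death state; nothing is truncated.

Clustering is Partitioning Around Medoids (PAM) on the dissimilarity matrix,
made fully deterministic: greedy BUILD seeding, best strictly-improving SWAP
until convergence, and every tie (seeding, swapping, nearest-medoid
assignment) broken by the lowest index.  Determinism is not cosmetic — it
guarantees that duplicated rows of a bootstrap-sliced matrix, which sit at
mutual distance zero, always land in the same cluster, so an individual
drawn several times gets exactly one effect entry per replicate.  PAM is a
local search: on small adversarial instances the converged solution can
differ from the exhaustively enumerated optimal medoid set, and the
canonical R implementation (`cluster::pam`) returns the same local optimum
on such instances.  The test suite certifies single-swap optimality
exhaustively and exact objective agreement with `cluster::pam`.

Partition quality is reported as the average silhouette width (ASW; members
of singleton clusters contribute 0) and a Calinski–Harabasz pseudo-F
computed from squared dissimilarities, using the identity that a cluster's
within sum of squares equals the sum of its squared pairwise dissimilarities
divided by the cluster size.  Squaring is the default and can be turned
off.  An ASW below 0.25 triggers an advisory low-structure warning — a
conventional cut-off, nothing more.  When the number of clusters is treated
as estimated, replicates select K by maximising CHI over a user range (ties
to the smallest K); the original analysis helper reports both indices and
leaves the choice to the analyst.

## Bootstrap replication and individual-level effects

Each replicate draws `M` individuals with replacement, slices the original
distance matrix (costs and distances are never re-estimated — replication
perturbs the sample, not the metric), and re-clusters with the identical
procedure.  For every bootstrap cluster a binary logistic regression of
"this cluster vs. any other" is fitted on the bootstrap rows (duplicates
enter with their multiplicity) with the same covariate specification as the
original analysis, and the average marginal effect (AME) of the covariate of
interest — with its delta-method standard error — is assigned to every
distinct individual in that cluster.  No mapping of bootstrap clusters to
original clusters is attempted; comparability across replicates lives
entirely at the individual level.  The result is an M×N AME matrix and its
SE companion, with an entry missing when the individual was not drawn or
when its cluster's regression failed.

The logistic fit is a Newton/IRLS maximum-likelihood fit converging when the
largest absolute coefficient change falls below 1e-8 (at most 100
iterations).  Failures are flagged, never raised, so the engine can record a
missing replicate and continue: single-class outcomes, non-convergence,
(quasi-)complete separation (non-convergence with fitted probabilities
pinned at 0/1), and — a deliberate rule — a covariate of interest that takes
a single level inside the target cluster, in which case the cluster's AME is
treated as uninformative for that covariate.  Zero-variance design columns
(e.g. a categorical level absent from a resample) are dropped from the fit
and recorded; levels are always enumerated from the full covariate table so
the design layout is identical across replicates.  Missing covariate values
are handled per model by complete-case analysis with dropped-row counts
logged.

AMEs average over all estimation rows (the observed covariate
distribution).  For a categorical level the AME is the mean difference in
fitted probability between the level of interest and the reference level;
for a numeric covariate it is the mean of `β·p̂(1−p̂)`.  Standard errors
propagate the full coefficient covariance through the analytic gradient of
the AME.

Cluster-wise stability is the Hennig bootstrap Jaccard measure: each
original cluster is scored by the best Jaccard similarity it achieves
against any cluster of the replicate, computed on sets of *distinct*
resampled ids (invariant to draw multiplicity).  A replicate in which no
member of a cluster was resampled is skipped for that cluster — it carries
no information about recovery — and skip counts are reported.

## Pooling

The reference-cluster entries `Y_ij` (individual *i*, replicate *j*) are
pooled with a cross-classified weighted mixed model

    Y_ij = a00 + u_i + v_j + e_ij,
    u_i ~ N(0, σ_u²), v_j ~ N(0, σ_v²), e_ij ~ N(0, σ_e²·SE_ij²),

estimated by restricted maximum likelihood.  The residual variance is
proportional to the squared stored standard error — inverse-variance
weighting with a freely estimated scale σ_e² (a strict σ_e² ≡ 1 option is
exposed).  The intercept `a00` is the pooled AME; `σ_v` measures how much
the effect moves when the whole typology is re-estimated on a new sample
and drives the prediction interval

    a00 ∓ t_{N−2, 1−β/2} · sqrt(s_v² + SE(a00)²),      β = 0.05 by default,

with the t quantile at the *nominal* N−2 degrees of freedom even when some
replicates contributed no entry for the cluster (the choice is invisible at
N in the hundreds).  Individual BLUPs `u_i` flag trajectories whose
bootstrap effects diverge from the cluster: outlier if `|u_i| > s_u`,
central if `|u_i| ≤ 0.5·s_u` (the 0.5 band is this package's convention,
configurable), typical otherwise, with the signed side reported.

Numerically, the fit profiles the intercept out by GLS and the residual
scale out analytically, leaving an optimisation over the log variance
*ratios* (one per random factor) solved by multi-start L-BFGS-B with a
Nelder–Mead polish; working on the log scale avoids boundary pathologies at
zero variance, and the mixed-model-equation formulation keeps the cost at a
dense Cholesky of an (m+N)×(m+N) system per evaluation, independent of the
number of observed cells.  Missing cells are simply absent rows; no
imputation.  With a single individual the model reduces to a weighted
random-effects meta-analysis over replicates (the individual factor is
dropped).  An all-constant effect table short-circuits to the exact
degenerate answer.

One degeneracy deserves its own paragraph.  When the typology is extremely
stable, *every* member of the reference cluster can receive the identical
effect value within each replicate.  The scaled-residual likelihood is then
unbounded (duplicated effect sizes let σ_e → 0 while a variance ratio
escapes to infinity), and any optimiser slides along a ridge that leaves
σ_v meaningless.  The fit detects this boundary escape and automatically
refits with the strict inverse-variance model (σ_e² ≡ 1), which is the
identified limit; the refit is recorded in the fit's notes.  On degenerate
tables this recovers σ_v equal to the empirical between-replicate spread,
which is what the prediction interval needs.

Two alternative specifications probe the model's assumptions.  Individual
*fixed* effects: sum-to-zero contrasts replace `u_i`, so the overall
intercept remains the mean individual effect; the bootstrap factor stays
random and the weighting is kept.  Inverse-hyperbolic-tangent transform:
`Y' = atanh(Y)`, `SE' = SE/(1−Y²)` by the delta method, the main model
fitted on the transformed scale, the estimate mapped back with `tanh`, its
SE with the inverse delta factor, and prediction-interval endpoints mapped
through `tanh` (order-preserving).  Values at ±1 are clipped inward by 1e-8
with a warning.

## Synthetic data and what the checks mean

The generator emulates the structure of a yearly healthcare-utilisation
cohort of people with diabetes: K = 3 prototype trajectories over T = 5
years on a 6-state alphabet (no utilisation / emergency / hospitalisation /
both / dead / missing), an absorbing death state, per-position substitution
noise (uniform over non-self, non-absorbing, non-missing states),
independently overlaid nonresponse, a fraction of borderline individuals
whose sequence blends two prototypes position-wise, and latent type
membership driven by a multinomial logit on a binary exposure and a numeric
comorbidity confounder.  Defaults: n = 348 individuals, base type shares
≈ (0.59, 0.32, 0.09) matching the three-cluster shape of the motivating
cohort, exposure prevalence 0.6 with a +1.0 logit shift toward type 1
(true exposure AME ≈ 0.2 by the Monte-Carlo oracle), confounder
~ N(1.9, 1.3) with a −0.15 logit coefficient, noise 0.08, missing rate
0.05, mixture fraction 0.10.  These were fixed once as a realistic desk-
scale stand-in for the application's conditions.

The true estimand for recovery checks is computed by `oracle_true_ame`:
the mean over the confounder distribution of
`P(type = target | exposure = 1, c) − P(type = target | exposure = 0, c)`,
with membership probabilities evaluated analytically, so Monte-Carlo error
enters only through the confounder integral.

What passing recovery tests show: on data whose cluster structure matches
the generating types reasonably well, the pooled AME plus its 95%
prediction interval brackets the generating effect (and zero, under a null
exposure) at roughly the nominal rate, at n = 150 individuals and N = 200
bootstraps over 50 simulation repetitions per arm.  What they do not show:
behaviour under misspecified alphabets, time-varying covariates,
informative missingness, or weak cluster structure where the cluster-vs-
type mismatch biases the estimand — the generator produces none of these.
The recovery tests identify the reference cluster as the one recovering
most of the target latent type, which is available only in simulation.

## Problem sizes and other choices

Test and acceptance runs use n = 120–150 individuals, N = 150–200 bootstrap
replicates and 50 simulation repetitions per coverage arm — sizes chosen so
the whole suite exercises every code path at desk scale while the full
pipeline remains a few seconds per simulated cohort.  The production default
is N = 1000 replicates, matching the recommendation that several hundred
replicates are needed for stable pooled estimates.  Bootstrap draws use
replicate-indexed RNG streams (`default_rng([seed, replicate])`), so results
are bit-identical regardless of parallel worker scheduling.  Reported
estimates are conventionally rounded to 3 decimals in CLI reports.

Known limitations: the pooled model assumes normal random effects, which
the individual BLUP distribution can visibly violate (left-skew when a few
borderline trajectories flip clusters) — mixed models are tolerant of
moderate violations, and the fixed-effects and atanh specifications are the
built-in sensitivity checks; fuzzy typologies and typology-as-regressor
designs are out of scope; jackknife-after-bootstrap influence diagnostics
and train/test validation of the procedure are left to future work.
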