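# Methods

## Model and estimation

`usemkit` fits the unified structural equation model (uSEM) to one
subject's (optionally concatenated) multivariate series. Writing x_t for
the p endogenous node signals and u_t for q exogenous task regressors,

    x_t = A x_t + Φ x_{t-1} + Λ u_t + ζ_t,   ζ_t ~ N(0, diag(Ψ)),

with zero diagonal in A (no contemporaneous self-loops), autoregressive
terms on the diagonal of Φ, and independent Gaussian innovations. The
series is lag-embedded into z_t = [x_{t-1}; u_{t-1}; u_t; x_t] (the lagged
exogenous block is optional and off by default); segment boundaries are
respected, so concatenating subjects never fabricates a cross-subject
transition, and the effective sample size is the number of valid
(t-1, t) pairs.

The predictor block of z is saturated. The ML discrepancy then reduces to
the conditional Gaussian likelihood of x_t given the predictors; with
residual variances profiled out the objective over structural coefficients
is

    F(A, B) = Σ_i log M_ii − 2 log|det(I − A)| − log|S_x|w|,

where M_ii is the i-th structural residual variance implied by the sample
moments. F and its analytic gradient are cheap (everything depends on the
data only through the m×m covariance), and L-BFGS-B from a per-equation
least-squares start converges in milliseconds for p ≤ 15. Convergence is
declared at gradient infinity-norm < 1e-6 within 500 iterations; the flag
is carried on every fitted model and non-converged subjects count as
non-significant during group search.

χ² = (n−1)·F with df = m(m+1)/2 − k(k+1)/2 − (#free paths) − p. The
baseline for incremental indices is the independence model (all
covariances zero, variances free): χ²_B available in closed form. CFI,
NNFI (TLI), RMSEA follow the standard formulas (CFI defined as 1 when
both excesses are at numerical zero); SRMR is the RMS of standardized
residual covariances over all m(m+1)/2 unique entries.

### Score tests and standard errors

Modification indices are 1-df score tests: MI_c = (n−1) g_c² / (2 H̃_cc)
with g_c the gradient of F in the candidate coordinate and H̃_cc the Schur
complement of the **expected** (Fisher) information over the free
parameters (structural coefficients and residual variances). The expected
information is used deliberately: the observed Hessian, evaluated at a
restricted optimum far from a strong candidate's optimum, can have
non-positive restricted curvature — in development this produced undefined
MIs for exactly the true strong paths and systematic direction errors.
With expected information, MIs of significant candidates agree with the
likelihood-ratio refit χ² drop to within ~6–8% relative error on 5-node
systems (T=300); the agreement is only asymptotic, so it is checked for
candidates whose refit drop is itself significant — relative error against
a near-zero statistic is not meaningful. Standard errors come from the
inverse expected information; candidates that are not identified jointly
with the current free set (e.g. the reciprocal of a free contemporaneous
path) get NaN MIs and are skipped by the search.

### Greedy search and its stopping rule

All searches share one loop: fit, score all admissible fixed paths, free
the best significant candidate (χ²(1) ≥ 3.841), refit. Two tiers govern
stopping. Before the model reaches excellent fit (two of four of
CFI ≥ .95, NNFI ≥ .95, RMSEA ≤ .05, SRMR ≤ .05), any nominally
significant MI may be added. Once fit is excellent, only candidates
surviving a Bonferroni-level threshold (α/#candidates on χ²(1)) are
added. The second tier exists because the two obvious one-tier rules both
fail: global fit indices average one missing strong path over m(m+1)/2
covariance entries and go blind to it (stopping at excellent fit missed
planted β ≥ 0.4 paths even at T=500), while searching until no nominal MI
remains over-adds, since the maximum of ~2p² null MIs exceeds 3.841 with
probability near 1. Backward pruning (drop the least significant freed
path with p ≥ .05, refit, repeat) finishes every search; autoregressive
base paths are never pruned.

Level semantics: `aggregate` (search on the standardized, concatenated
cohort), `individual` from a null start (idiographic), `group` (candidate
added when significant for ≥ γ = 75% of subjects, ties broken by summed
MI then lexicographically; group paths whose estimates are significant
for fewer than γ of subjects are pruned, least-supported first),
`subgroup` (same with a strict > 50% majority within each community), and
individual finalization seeded with the group (+ subgroup) paths, which
stay free regardless of per-subject significance so the nesting
invariant (group ⊆ subgroup ⊆ individual free sets) holds by
construction. Subjects are z-scored per column before every search.

## Subgrouping and robustness

Subject similarity after the group stage counts agreement on candidate
significance and on group-path signs:
s_ij = #{candidates with significant MI for both i and j} +
#{group paths significant with the same sign for both}; the two terms can
be reweighted via configuration. Communities come from Walktrap (walk
length 4) on the weighted graph, with the merge sequence cut at maximal
modularity; an all-zero matrix yields a single community with a warning.

Because Walktrap always returns a partition, two diagnostics gauge
whether it means anything:

* **Stability.** For each fraction f in a grid (default 0.05–1.0), a
  fraction f of edges is rewired to random vacant pairs (weight multiset
  preserved; for dense matrices with too few vacant slots the weights are
  shuffled among the chosen edges instead) and the perturbed matrix is
  re-clustered; the mean Variation of Information against the original
  solution over `reps` repetitions forms the VI curve. The reference VI
  is the mean VI between the original partition and copies with a random
  20% of memberships reassigned to other labels. The criterion passes
  when the smallest fraction at which the VI curve reaches the reference
  is at least 0.20 (a solution that never reaches it passes trivially).
* **Modularity.** The observed weighted Newman Q must reach the 95th
  percentile of Q under a node-exchangeable null that places the observed
  weight multiset on uniformly random pairs (a weighted Erdős–Rényi
  analogue), re-clustered per draw (default 100 draws).

VI uses natural logarithms (0 iff identical partitions; 2·ln 2 for the
fully crossed 4-item pair); ARI is the permutation-adjusted Rand index.

## Heterogeneity summaries

Overlap between the aggregate network and each subject's idiographic
network is counted on (from, to, lag) triples, presence-only; auto-freed
AR base paths are excluded by default since the search never chose them.
"Sharing less than half" means strictly fewer than ceil(|E_agg|/2) paths.
Prevalence tables count, per non-group path, the subjects whose final
model retains it, keeping paths with count ≥ ceil(0.20·n).

## Behavioral association

Features per subject: continuous coefficients for group paths (estimated
for everyone) and 0/1 presence indicators for subgroup/individual paths
passing the prevalence filter (their coefficients would be missing for
non-carriers); constant columns are dropped with a warning. The adaptive
lasso standardizes all columns, derives per-feature penalty factors
w_j = 1/|β̂_ridge,j|^γ (γ = 1) from a 10-fold-CV ridge regression, and runs
the weighted L1 path with 10-fold CV. The penalty is chosen by a
fractional-SE rule — the largest λ within 0.25 standard errors of the CV
minimum. This default sits deliberately between the liberal minimum-CV
rule (measured average per-feature false-selection rate 0.16–0.28 under
pure-noise outcomes at n=200, f=30) and the conservative one-SE rule
(false-selection 0.0 but sensitivity 0.33 for per-SD effects of 0.5 at
n=103): at 0.25 SE the measured null rate is ≈ 0.05–0.06 with adequate
power for moderate effects. `lambda_rule` accepts `"min"`, `"1se"`, or
any float SE factor. R² and adjusted R² come from an unpenalized OLS
refit on the selected set (a penalized-prediction R² is also reported);
binary outcomes use the logistic variant with McFadden pseudo-R².
Post hoc, each selected feature gets its own simple regression (estimate,
SE, p) plus a joint OLS for model R². Subgroup differences use one-way
ANOVAs with Benjamini–Hochberg correction across the outcome family and
Welch pairwise t-tests only for outcomes with q < .05.

## Synthetic cohorts

The generator plants a three-level directed structure: group paths shared
by everyone, optional subgroup-specific paths (membership assigned by
fraction blocks, shuffled under the scenario seed), and a pool of
individual paths each subject carries independently with probability
`individual_prob`. Defaults mirror a reward-task fMRI study design:
103 subjects, 15 nodes, 2 HRF-convolved task regressors, 239 frames at
TR = 2 s; coefficients |β| ∈ [0.3, 0.7] with an 80% positive share, AR
coefficients U(0.4, 0.7), unit innovation SD, 50 burn-in steps discarded.
Structures are redrawn (bounded retries) until every subject's companion
matrix has spectral radius < 0.97. Two identifiability-motivated
constraints shape the planted sets: no contemporaneous reciprocal pair
(2-cycles at lag 0 are not identifiable under diagonal Ψ) and no ordered
pair carrying both its lag-0 and lag-1 path (near-confusable at typical
scan lengths). The task generator emits anticipation (onset +4 s, 6 s)
and outcome (onset +10 s, 1 s) events per 17 s trial with a jittered
intertrial interval of mean 3 s — chosen so the default 24-trial task
fits a 478 s scan; events running past the scan end are clipped.
Regressors are boxcars convolved with the canonical double-gamma HRF
(peak 6 s, undershoot 16 s, dispersions 1, ratio 1/6, 32 s kernel) on a
TR/20 grid, sampled at frame onsets t = i·TR, and peak-normalized.

Behavioral outcomes are linear (or logistic) in selected network
features. Feature columns are z-scored before effects apply by default,
so planted coefficients are per-SD effect sizes — the same scale the
association stage operates on after standardization; group-path
coefficient features are constant in truth (everyone shares the
generating value), so planted behavioral effects should reference
presence-encoded pool paths.

What the generator does **not** emulate: hemodynamic forward modeling of
the endogenous nodes (only exogenous inputs are HRF-convolved),
physiological noise, scanner drift, motion artifacts, and spatially
correlated residuals. Passing recovery tests therefore demonstrate
correctness of the estimation and search machinery under the model's own
assumptions, not robustness to fMRI nuisance structure. A motion-confound
scenario (subgroups differing in head motion) was considered and left
out; the QC stage operates on externally supplied or synthetic
framewise-displacement summaries instead.

## Quality control

Participant exclusion is staged, with quartiles recomputed over the
currently retained set at each stage: (1) behavioral compliance < 0.75;
(2) tSNR below Q1 − 1.5·IQR; (3) mean FD above Q3 + 1.5·IQR; (4) more
than 25% of frames with FD ≥ 2 mm. The IQR fences are one-sided per
metric — only implausibly low tSNR and implausibly high motion are
harmful; both the factor and the thresholds are configurable. With zero
IQR spread no subject is an outlier.

## Problem sizes used in the validation battery

`scripts/acceptance.py` (and the mirror tests in
`tests/test_acceptance.py`) use: MI-vs-LR on 20 five-node systems at
T=300; group recovery with p=6, six planted paths |β| ≥ 0.4, AR 0.5,
n=25, T=200, 10 replicates; idiographic recovery with three planted
paths at T=500, 10 replicates; subgroup recovery with two planted
20-subject subgroups of three distinctive paths each; lasso calibration
at n=200 with 30 features (10 support-recovery and 50 null replicates);
and the end-to-end chain at n=103, p=6, T=500 with three presence
features at β=0.5 per SD and unit outcome noise. These sizes keep the
full battery around three minutes on one CPU while leaving each
statistic's sampling error well inside its margin.

## Known limitations

* ML estimation assumes diagonal residual covariance; correlated
  innovations masquerade as contemporaneous paths.
* Only lag 1 is modeled; slower dynamics alias into lag-1 and
  contemporaneous structure.
* Directionality of contemporaneous paths is identified through lagged
  information only; with weak AR terms direction recovery degrades.
* The adaptive lasso's selections are in-sample; no train/test split is
  performed, and reported R² values are optimistic for prediction.
* Walktrap determinism relies on igraph's fixed tie-breaking; partitions
  are stable across runs but ties may resolve differently across igraph
  versions.
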