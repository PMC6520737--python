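# Methods

`ieinter` models a patient-level outcome — a continuous biomarker such as
percent-predicted FEV1, or right-censored overall survival — from a
high-dimensional table of quantitative histopathological imaging features
(CellProfiler-style, grouped into Texture, Geometry and Holistic families),
a small set of clinical/environmental covariates (age, tumour stage,
smoking history, sex), and, crucially, their pairwise imaging-environment
(I-E) interactions. Two complementary analyses are provided: a marginal
scan that tests one (feature, covariate) pair at a time, and a joint
penalized model that selects effects from all pairs simultaneously while
respecting the main-effect/interaction hierarchy.

## Marginal scan

For each clinical variable `E_j` and imaging feature `X_k` the centered,
no-intercept model

    Y = alpha_j E_j + beta_k X_k + gamma_jk E_j X_k + eps

is fitted by (weighted) least squares; all J x K models are summarised in
one table. Two-sided p-values use the t distribution on N - 3 degrees of
freedom, with model-based standard errors from the (weighted) information
matrix; the variance estimator is a design choice, since weighted AFT
fitting admits several. The discovery family defaults to the interaction
coefficients only (a flag pools imaging main effects into the family), and
multiplicity is controlled by Benjamini-Hochberg FDR (default) or
Bonferroni. A two-sided normal-approximation power calculation
(`power_analysis`) converts a standardized effect, per-test alpha and
target power into a required sample size and back; multiple-testing
targets such as "FDR 0.1 at rank r of m" are mapped to a per-test alpha
(q * r / m under BH) by the caller, keeping the formula convention-free.

## Joint hierarchical model

All effects enter one regression,

    Y = sum_j tau_j E_j + sum_k eta_k X_k
        + sum_jk eta_k theta_jk E_j X_k + eps,

with the interaction coefficient parameterized as the product
`gamma_jk = eta_k * theta_jk`. The product makes the "main effects,
interactions" hierarchy structural: no interaction can be nonzero unless
its imaging main effect is. Estimation minimises

    ||Y - f(E,X)||^2 + lambda1 * sum|eta_k| + lambda2 * sum|theta_jk|,

with the low-dimensional clinical block tau unpenalized.

**Algorithm.** The objective is biconvex, and the literature for this
model class specifies only the criterion, so the solver is this package's
design: deterministic block alternation in which each step is an exact
convex solve. With theta fixed, the model is linear in eta through
composite columns `X_k (1 + sum_j theta_jk E_j)`; with eta fixed, linear
in theta through columns `eta_k E_j X_k` (restricted to active features).
In both steps tau is profiled out by projecting onto the orthocomplement
of the clinical design (QR-based), so the subproblem is a plain lasso
(solved by coordinate descent via scikit-learn, with the exact mapping
`alpha = lambda / (2n)` for no-intercept squared-error form).
Initialization is theta = 0 with eta warm-started from the
interaction-free lasso, making results reproducible without randomness.
When an eta_k hits zero its theta row is zeroed immediately, keeping the
hierarchy structural at every iterate.

**Convergence.** Two stopping rules run together: maximum coefficient
change below `tol` (default 1e-9), and the first sweep whose objective
does not strictly decrease. The first alone can be fooled by slow crawls
along the curved valley the product term creates; the second alone can
fire on a one-sweep plateau that precedes further progress. The objective
is recorded every sweep and asserted non-increasing in the test suite.
Because the alternation is a local method for a nonconvex objective, the
attained point is a blockwise optimum; on noise-free test problems the
recovered coefficients sit within the lasso shrinkage bias of the truth
(about `lambda / (2 ||column||^2)` per coordinate, validated against a
direct minimiser of the restricted problem), which is why exact-recovery
tests use tolerances of a few 1e-3 rather than machine precision.

**Tuning.** (lambda1, lambda2) are chosen by the extended BIC,

    EBIC = n log(rss/n) + df (log n + 2 gamma log p_total),

with `df = #{eta != 0} + #{theta != 0} + J`, `p_total = K + J*K` and
`gamma = 0.5` by default (`gamma = 0` recovers the classical BIC). The
lambda1 grid is log-spaced over three decades below the data-driven
maximum (the smallest value zeroing all imaging mains), 20 points by
default, descending with warm starts; for each lambda1 a lambda2 grid is
built the same way at the current main-effects solution, preceded by the
interactions-free corner. Ties are broken toward the sparser (larger
penalty) corner, encountered first. Two computational devices keep the
grid affordable without changing what the criterion can select: the
lambda1 descent stops once the active set exceeds max(10, n/2) — models
denser than that can never minimise EBIC at these sample sizes but
dominate solve time — and grid-point fits run at a loosened sweep budget
(coefficient tolerance 1e-5, 30 sweeps) with the winning pair refit at
full tolerance. The main-effects-only comparator (`MainEffectsLasso`) is
the same machinery with theta frozen at zero and `p_total = K`.

## Censored outcomes

Survival is handled with the accelerated failure time view: the linear
model above is placed on log survival time. Subjects are sorted by
observed log time (ties: events before censorings, then by subject ID)
and given Kaplan-Meier (Stute) weights

    w_1 = delta_1 / N,
    w_i = delta_i / (N - i + 1) * prod_{j<i} ((N-j)/(N-j+1))^delta_j,

the jump sizes of the KM estimator: censored subjects get weight zero,
all-event data gets uniform 1/N, and the total mass is one minus the KM
survivor mass beyond the last event. The weighted criterion
`sum_i w_i (Y_i - f_i)^2` (the standard Stute least-squares reading of a
componentwise-weighted norm) is folded into the unweighted machinery by
weight-centering Y, E and X and scaling rows by sqrt(w_i). Product
(interaction) columns are always built from the unscaled centered data
and row-scaled afterwards — scaling before multiplying would weight
products by w rather than sqrt(w). With no censoring the entire survival
pipeline reproduces the continuous pipeline on log(time) exactly (the
data-driven penalty grids scale consistently, so even the tuned models
coincide); this reduction is asserted at 1e-8 in the tests. Censored
subjects carry no fitting weight but are retained in evaluation, where
their observed times inform the logrank test.

## Evaluation

Prediction is assessed by repeated random train/test splits (default 100
repetitions, 75% training — the repetition count follows the validation
design this package mirrors; the split ratio is this package's choice).
Models are refit per split, internal tuning included. Continuous outcomes
report mean held-out PMSE; survival outcomes are split at the median
predicted log time into low/high risk groups (ties at the median go to
the high-risk group) and compared with the two-sample logrank test
(lifelines), reporting both the p-value of the averaged statistic and the
averaged p-value, since either convention is defensible. Agreement
between two procedures' selections is quantified by overlap counts and by
the RV coefficient

    RV(A, B) = tr(AA'BB') / sqrt(tr((AA')^2) tr((BB')^2))

of the centered design submatrices of the selected effects (clinical
columns, selected imaging mains, selected product columns; clinical
columns are always included since they are never penalized, which also
keeps RV defined when a model selects no imaging effect).

## Synthetic data

The generator emulates the downstream feature-table domain of a
histopathology cohort, not the images: K = 300 features by default in
three groups (150 Texture, 130 Geometry, 20 Holistic — echoing the
772-feature, three-group structure of the motivating cohort at desk
scale), each group sharing an exchangeable correlation rho = 0.3 through
a single latent factor, unit variances. Clinical covariates: age standard
normal; ordinal stage 1-4 with probabilities (0.55, 0.25, 0.12, 0.08),
reflecting the predominance of early-stage resected adenocarcinoma;
smoking prevalence 0.8 (most lung adenocarcinoma patients are
ever-smokers); sex balanced. Coding follows the analysis convention: age
and stage standardized, smoking and sex centered indicators. Continuous
outcomes add N(0, sigma^2) noise (sigma = 1 by default); survival
outcomes exponentiate the linear predictor plus noise and censor with
times drawn from a pool — either user-supplied observed times or a
calibrated pool targeting a 60% censored fraction, matching cohorts where
roughly four in ten subjects die during follow-up. Default sparse truths
place 11 imaging mains with 11 interactions (continuous layout) or 31
mains with 6 interactions on two features (survival layout) at the
standardized-scale magnitudes of the motivating joint analyses, assigned
to features of the matching group.

What the generator does not emulate: heavy-tailed and highly collinear
near-duplicate features (real CellProfiler tables contain blocks of
correlation near 1), feature scales far from unit variance, missing-data
patterns, or covariate-dependent censoring. Passing tests therefore
demonstrate correctness of the machinery and its behaviour under
idealised second-moment structure, not performance on real slide-derived
tables. In particular, at the printed standardized-scale magnitudes with
unit-variance features and unit noise, interaction signals of |gamma| in
0.003-0.19 are below what any BIC-family criterion can detect at
n = 200 — the per-coefficient fit gain (at most about n * gamma^2) is
smaller than the EBIC charge per degree of freedom (about 12.6 at these
dimensions) — so the replicated study at those exact conditions selects
few or no effects, while the same pipeline recovers all interactions with
near-zero false positives once coefficients reach detectable size (the
strong-signal study in the test suite). On real feature tables, whose
columns are mean-normalized but not variance-standardized, the effective
signal scales are considerably larger.

## The simulation study

`run_simulation_study` resamples n = 200 design rows per replicate with
replacement (from a synthetic base design or user-provided matrices),
regenerates the outcome from the sparse truth with fresh N(0,1) errors
(and resampled censoring in the survival case), fits the EBIC-tuned
hierarchical lasso and counts true/false positives — mains at the eta
level, interactions at the (j,k) gamma level. Replicate r is seeded
`seed + r`. The acceptance script runs 20 continuous and 10 survival
replicates on a 15 x 10 tuning grid; these sizes keep a full run within a
few minutes on one core and are stated here as the package's reporting
protocol (the estimator default remains 20 x 20).

## Degenerate inputs and numerical choices

Zero-variance columns survive centering (as all-zero, logged); features
with ≥ 20% missingness are dropped and the rest median-imputed
(idempotent); all-censored data produce zero total weight and a clear
error at fitting; zero residual variance floors the EBIC log with a
warning; collinear pair designs raise rather than return unstable
estimates; ties at the risk-group median go high-risk; required-n uses a
1e-9 epsilon inside the ceiling so the power round-trip is exact.

## Known limitations

The alternation finds blockwise optima of a nonconvex objective; no
multi-start is attempted (a deterministic single start was preferred for
reproducibility). Joint-model coefficients come without standard errors
or p-values. The marginal scan fits one clinical variable per model; an
all-covariates-per-model variant is out of scope. Cox-type models and
time-dependent covariates are not supported — the AFT form is used for
its interpretability and computational convenience under KM weighting.
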