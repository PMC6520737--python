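# ieinter — imaging–environment interaction analysis

`ieinter` is a Python toolkit for modelling cancer outcomes from
quantitative histopathological imaging features, clinical/environmental
risk factors, and — the part standard pipelines leave out — their
pairwise **imaging–environment (I–E) interactions**. It is aimed at
biostatisticians working with patient-level feature tables extracted
from whole-slide images (e.g. CellProfiler texture / geometry / holistic
features for a TCGA-style lung adenocarcinoma cohort) together with
covariates such as age, tumour stage, smoking and sex, and an outcome
that is either a continuous biomarker (an FEV1-like lung-function
measure) or right-censored overall survival.

## The models

**Marginal scan.** For every clinical variable `E_j` and imaging feature
`X_k` (all centered), the three-coefficient model

    Y = α_j E_j + β_k X_k + γ_jk E_j X_k + ε

is fitted by least squares; the J×K interaction p-values are adjusted by
Benjamini–Hochberg FDR (or Bonferroni). A normal-approximation power
routine converts effect sizes to required sample sizes and back.

**Joint hierarchical lasso.** All effects compete in one model,

    Y = Σ_j τ_j E_j + Σ_k η_k X_k + Σ_j Σ_k η_k θ_jk E_j X_k + ε,

estimated by `min ‖Y − f(E,X)‖² + λ₁ Σ|η_k| + λ₂ Σ|θ_jk|` with the
clinical block τ unpenalized. The interaction coefficient is the product
γ_jk = η_k·θ_jk, so an interaction can only be selected together with
its imaging main effect ("main effects, interactions" hierarchy). The
biconvex objective is solved by deterministic block alternation (each
block an exact lasso with τ profiled out by projection) and (λ₁, λ₂)
are tuned by the extended BIC.

**Censored outcomes.** Survival is modelled on the log-time (AFT) scale
with Kaplan–Meier (Stute) weights: subjects sorted by observed time get
the KM jump sizes as weights (zero when censored), and every
continuous-outcome routine runs on the √w-transformed data, minimising
Σ w_i (Y_i − f_i)². With no censoring the survival pipeline reproduces
the continuous one exactly.

**Evaluation & simulation.** Resampled train/test prediction (PMSE for
continuous outcomes; median-split risk groups with logrank tests for
survival), RV-coefficient agreement between selections, and a replicated
synthetic study that regenerates outcomes from a known sparse truth and
scores true/false positive selections.

## Worked example

Generate a synthetic cohort (150 subjects, 40 correlated features in
three groups, four clinical covariates) with three true imaging main
effects and two true interactions, scan it marginally, then fit the
EBIC-tuned joint model:

```python
import numpy as np
from ieinter import (SyntheticConfig, TrueModel, generate_design,
                     generate_continuous, Dataset, fit_joint,
                     PenaltyConfig, scan)

cfg = SyntheticConfig(n=150, group_sizes={"Texture": 20, "Geometry": 15,
                                          "Holistic": 5}, rho=0.3, seed=7)
eta = np.zeros(cfg.K); gamma = np.zeros((4, cfg.K))
eta[[2, 8, 24]] = [1.2, -1.0, 0.8]
gamma[0, 2] = 1.0        # age  x texture_002
gamma[2, 8] = -0.9       # smoking x texture_008
truth = TrueModel(tau=np.array([0.5, -0.3, 0.4, 0.0]), eta=eta, gamma=gamma)

E, X = generate_design(cfg)
y = generate_continuous(E, X, truth, sigma=1.0, seed=8)
ds = Dataset(E=E, X=X, outcome=y)

table = scan(ds)
print(table[table.partner != "Main"].head(3)[
    ["feature_name", "clinical_variable", "estimate", "p_raw", "p_adjusted"]])

model = fit_joint(ds, PenaltyConfig(n_lambda1=12, n_lambda2=8))
print({model.feature_names_[k]: round(model.eta_[k], 3)
       for k in model.selected_main_})
print({(model.clinical_names_[j], model.feature_names_[k]):
       round(model.gamma_[j, k], 3)
       for j, k in model.selected_interactions_})
```

Output:

```
feature_name clinical_variable  estimate        p_raw   p_adjusted
 texture_002               age  0.966391 1.291655e-10 2.066647e-08
 texture_012               age  0.604639 2.117521e-03 9.845352e-02
 texture_003               age  0.530975 2.651074e-03 9.845352e-02

{'texture_002': 0.885, 'texture_008': -0.573, 'geometry_004': 0.85,
 'holistic_004': 0.054}
{('age', 'texture_002'): 0.701}
```

The marginal scan ranks the true age × texture_002 interaction first
(estimate 0.97 against a true 1.0, FDR-adjusted p ≈ 2e-8). The joint
model recovers all three true mains (plus one small false positive) and
selects the age interaction through the hierarchy — its coefficient
0.701 is the product η̂·θ̂, shrunk toward zero by the double penalty.
The weaker smoking interaction (on a 0/1 indicator, hence less variance
to detect it with) is missed at this sample size, which is exactly the
kind of power boundary the `power_analysis` and simulation tools are
there to map.

A command-line interface mirrors the library:
`ieinter generate | marginal | joint | evaluate | simulate`
(each run writes result tables plus a JSON metadata file; see
`ieinter --help`).

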