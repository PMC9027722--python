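# cuspcat

Stochastic cusp-catastrophe regression for two-condition achievement
studies.

`cuspcat` is for researchers in psychophysiology and the behavioral
sciences who suspect that a performance outcome does not respond smoothly
to its predictors — that past a critical level of arousal or negative
affect, behavior splits into two coexisting regimes (e.g., productive vs.
collapsed task performance) with sudden jumps between them.  The package
fits and stress-tests the simplest model of that phenomenon, the cusp
catastrophe, against conventional linear and logistic alternatives, on
per-participant tables of the form

```
participant_id,condition,blhr,hrdt,anger,achievement
```

where `blhr`/`hrdt` are baseline and during-task heart rate (beats/min),
`anger` is a mean facial-coding anger intensity in [0, 1], `achievement`
is a non-negative task score, and `condition` labels the two experimental
arms (`normative` vs. `outcome` performance goals).

## The model

The deterministic cusp has potential

    f(y; α, β) = α·y + ½·β·y² − ¼·y⁴

with equilibria solving −y³ + β·y + α = 0.  The *asymmetry* control α
tilts the behavioral state y up or down; the *bifurcation* control β
splits one stable state into two once 27α² < 4β³ (the bifurcation set,
delimited by the Cardan discriminant δ = 27α² − 4β³).  The stochastic
counterpart (Cobb's formulation) replaces the deterministic state with the
density

    p(y | α, β) = exp(α·y + ½·β·y² − ¼·y⁴) / Z(α, β),

whose modes are exactly the stable equilibria.  The regression layer makes
the controls linear in standardized covariates and maps the observed state
affinely to the canonical one:

    αᵢ = a₀ + a·Xᵢ,   βᵢ = b₀ + b·Vᵢ,   yᵢ = w₀ + w₁·zᵢ   (w₁ > 0),

here with baseline heart rate driving α and anger plus task heart rate
driving β.  All seven parameters are estimated by maximum likelihood
(the −log w₁ Jacobian of the state map included), with Wald standard
errors from the observed information.  Competing models — a Gaussian
linear model (k = 5) and a logistic-curve model (k = 6) — are compared via
AIC/AICc/BIC, pseudo-R², and likelihood-ratio chi-square tests, and a
cusp-evidence checklist (≥10% of observations inside the bifurcation set,
non-normality inside it, skew outside it) guards against spurious wins.
A noncentral-F power calculator for multiple regression rounds out the
toolkit.

## Worked example

Simulate a default study (50 normative-goal participants with
cusp-structured achievement, 49 outcome-goal participants with linear
achievement), then compare models on the normative arm:

```bash
cuspcat simulate --out study.csv --truth truth.json --seed 5
cuspcat compare study.csv --condition normative
```

prints (abridged):

```json
{
  "preferred_by": {"aic": "cusp", "aicc": "cusp", "bic": "cusp"},
  "models": {
    "linear":   {"k": 5, "aic": 138.765, "bic": 148.325, "pseudo_r2_pct": 21.5},
    "logistic": {"k": 6, "aic": 145.293, "bic": 156.765, "pseudo_r2_pct": 17.3},
    "cusp":     {"k": 7, "aic": 128.898, "bic": 142.282, "pseudo_r2_pct": 64.0}
  },
  "lr_tests": {
    "linear_vs_cusp": {"chi2": 13.867, "df": 2, "p": 0.00097, "direction": "cusp"}
  }
}
```

The cusp beats both competitors on every information criterion, the
likelihood-ratio test rejects the nested linear model (χ²(2) = 13.87,
p < 0.001), and its delay-convention pseudo-R² (64%) triples the linear
one — as it should on data generated with a genuine bifurcation.  The same
pipeline is available programmatically:

```python
from cuspcat import (SyntheticStudyConfig, generate_study, split_by_condition,
                     fit_cusp, evidence_checklist)
from cuspcat.study_data import frame_to_records

df, truth = generate_study(SyntheticStudyConfig(seed=5))
normative, outcome = split_by_condition(frame_to_records(df))
fit = fit_cusp(normative)          # coefficient table: fit.to_report()
print(evidence_checklist(fit).bifurcation_fraction)   # e.g. 0.78
```

The power calculator reproduces the classic design computation — the
smallest n at which the overall F test of a 3-predictor regression reaches
80% power at a medium effect (f² = 0.15, α = 0.05) is 77:

```bash
cuspcat power --f2 0.15 --alpha 0.05 --power 0.80 --predictors 3
# {"required_n": 77, "power_at_n": 0.8018, "power_at_n_minus_1": 0.7957}
```

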