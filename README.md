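# extcox

Extended Cox prognostic modelling for clinical survival cohorts, built around
the workflow used to derive prognostic models for ER/PR-positive,
HER2-negative breast cancer: data-driven cutoff selection for continuous
prognostic factors, a change-point (time-threshold) Cox model for a
late-acting interaction, and the downstream nomogram and evaluation
machinery.

## Who this is for

Biostatisticians and clinical researchers who want to *derive* cutoffs and
interactions from a multivariable survival model instead of fixing them by
convention or univariate screening. The package is a complete, tested
pipeline plus a synthetic-cohort generator, so every stage can be exercised
and validated without patient-level data.

## The model

Each continuous prognostic factor (Ki67, ER, PR percentages and age) is
expanded into a series of binary indicators `1{value >= c}`, one per
admissible partition point `c` (every observed value leaving at least 10
patients on each side). With the canonical partition grids this gives 95
candidate variables (7 categorical + 4 continuous + 84 indicators) and 1664
once the interaction families T x N, ER x PR, age x ER and age x PR are
added. A Cox proportional-hazards model

    h(t | x) = h0(t) exp(x' beta)

is fitted over the candidates with the smoothly clipped absolute deviation
(SCAD) penalty (shape a = 3.7, level chosen by BIC over a 50-point path), so
the selected indicators *are* the cutoffs. The final, extended model allows
one coefficient — the age ≥ 41 & PR ≥ 20% interaction `x8` — to switch on
after a time threshold `tau`:

    h(t | x) = h0(t) exp(A),              t <= tau
    h(t | x) = h0(t) exp(A + beta8 x8),   t >  tau
    A = b1*grade + b2*N + b3*1{Ki67>=60} + b4*1{PR>=20}
        + b5*1{age>=55} + b7*1{age>=41}

fitted in counting-process form with `tau` chosen by the smallest AIC over
candidate thresholds. Evaluation uses Kaplan-Meier curves (Greenwood
intervals), cumulative/dynamic time-dependent AUC with IPCW weights, and a
10-risk-group observed-vs-expected chi-square; the fitted model is exported
as an 11-row nomogram.

## Worked example

```python
import numpy as np
from extcox import (SimulationConfig, generate_cohort, build_design,
                    fit_scad_cox, select_threshold, build_nomogram)
from extcox.changepoint import extended_design

cohort = generate_cohort(SimulationConfig(n_patients=2000, seed=0,
                                          baseline_rates=(4e-4, 4e-4)))
design = build_design(cohort, "reference")          # 95 candidate columns
t = cohort["time_weeks"].to_numpy()
e = cohort["event"].to_numpy()
fit = fit_scad_cox(design.X, t, e, names=design.names)
print(fit.selected_names)

X, x8 = extended_design(cohort)
best, profile = select_threshold(t, e, X, x8, max_candidates=21)
print(round(best.tau, 1), round(best.aic, 1))
```

prints

```
['grade', 'n_stage', 'ki67_ge60', 'pr_ge20', 'age_ge41', 'age_ge55']
167.6 9467.6
```

i.e. the penalized fit recovered exactly the six generating variables —
grade and N as ordinal scores plus the Ki67 60%, PR 20% and age 41/55
cutoffs out of 84 candidate indicators — and the AIC threshold search landed
at 167.6 weeks, one candidate away from the generating change point of 164
weeks (the AIC profile is a step function between event times, so the
threshold is resolved to the candidate grid).

The same stages run from the shell:

```bash
extcox simulate --n 2000 --seed 0 --out cohort.csv
extcox run-all --outdir run --seed 0
```

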