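"""Arm comparisons and forward stepwise logistic modelling on a simulated trial.

Generates a cohort, compares baseline characteristics between arms, then
simulates a binary anticoagulant-use outcome with a known intervention
odds ratio of 3 and checks that the stepwise model recovers it.
"""

import math

import numpy as np
import pandas as pd

from carat import (
    SimulationConfig,
    compare_arms,
    forward_stepwise_wald,
    generate_cohort,
    simulate_clustered_binary,
    univariate_screen,
)

cohort = generate_cohort(SimulationConfig(seed=7, patients_per_gp=(8, 8), dropout=0.0))
print(f"n = {len(cohort)}")

for var in ("stroke.hypertension", "chronic_condition_count", "afib_duration"):
    c = compare_arms(cohort, var)
    print(f"{var:28s} {c.test.value:14s} stat={c.statistic:7.3f}  p={c.p_value:.3f}")

# Simulated outcome: logistic model with cluster random intercept
# (latent ICC 0.03) and a true intervention odds ratio of 3.
gp = [p.gp_id for p in cohort]
arm = np.array([1.0 if p.arm.value == "intervention" else 0.0 for p in cohort])
rng = np.random.default_rng(8)
y = simulate_clustered_binary(gp, math.log(3.0) * arm, icc=0.03, rng=rng)

X = pd.DataFrame({
    "arm": arm,
    "age_ge_75": [float(p.stroke.age_ge_75) for p in cohort],
    "hypertension": [float(p.stroke.hypertension) for p in cohort],
    "diabetes": [float(p.stroke.diabetes) for p in cohort],
    "sex_male": [float(p.sex.value == "male") for p in cohort],
})
screen = univariate_screen(y, X, alpha=0.10)
print(f"\nunivariate screen kept (p < 0.10): {screen.selected}")

model = forward_stepwise_wald(y, X[screen.selected], groups=gp)
for t in model.terms:
    print(f"  {t.name}: OR {t.odds_ratio:.2f} (95% CI {t.ci_low:.2f}-{t.ci_high:.2f}), p={t.p_value:.4f}")
print(f"classification rate at 0.5: {model.classification_rate:.3f}")
print(f"Cox-Snell R2 {model.r2_cox_snell:.3f}, Nagelkerke R2 {model.r2_nagelkerke:.3f}")
print(f"cluster-robust inference: {model.cluster_adjusted}")

# The arm term's odds ratio should land near the generating value of 3,
# with a cluster-robust CI covering it; noise covariates are screened out
# or dropped by the Wald entry test.
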