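"""Simulate a full cluster-randomized trial and measure agreement.

Generates a two-arm GP-clustered cohort with the default registry
marginals (25 GPs per arm, 5-10 patients each, ICC 0.03, 20% dropout),
runs the recommendation engine on every patient, simulates GP decisions,
and summarises the result.
"""

import numpy as np

from carat import (
    SimulationConfig,
    estimate_icc,
    generate_cohort,
    recommend,
    simulate_gp_decisions,
    summarize_agreement,
    therapy_distribution,
)
from carat.records import TherapyClass

cfg = SimulationConfig(seed=42)
cohort = generate_cohort(cfg)
print(f"patients: {len(cohort)} in {len({p.gp_id for p in cohort})} GP clusters")

dist = therapy_distribution([p.baseline_therapy for p in cohort])
print(f"baseline: {dist.pct_any_antithrombotic}% on any antithrombotic, "
      f"{dist.pct_anticoagulant}% on an anticoagulant")

icc = estimate_icc(
    [p.gp_id for p in cohort],
    [float(p.baseline_class is TherapyClass.anticoagulant) for p in cohort],
)
print(f"estimated ICC of baseline anticoagulant use: {icc.estimate:.3f} "
      f"(configured {cfg.icc})")

recs = [recommend(p) for p in cohort]
print(f"recommended change for {np.mean([r.change_required for r in recs]):.1%} of patients")

decisions = simulate_gp_decisions(cohort, recs, cfg.gp_behavior, seed=43)
res = summarize_agreement(decisions)
print(f"GP agreement with the tool: {res.percent_agreement:.1%} "
      f"(class level {res.percent_class_agreement:.1%}, kappa {res.kappa:.2f})")
print(f"disagreement reasons: {res.reason_tally}")

# The generator reproduces the registry's therapy marginals and the
# configured within-GP clustering; simulated GPs accept ~75% of
# recommendations and mostly substitute dabigatran when rejecting a
# warfarin recommendation, so class-level agreement stays well above
# regimen-level agreement.
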