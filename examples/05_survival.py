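"""Outcome statistics: Kaplan-Meier / log-rank and a Cox model.

The clinical simulator plants a protective expression cluster (hazard
multiplier 0.2); the log-rank test detects the difference in
progression-free survival and the Cox model recovers the planted hazard
ratio adjusted for stage and age.
"""

import pandas as pd

from armcna.simulate import SimulationConfig, simulate_clinical
from armcna.stats import cox_multivariate, km_logrank

config = SimulationConfig(seed=1)   # hazard multipliers (1.0, 0.2, 1.0)
labels = pd.Series([1 + i % 3 for i in range(90)],
                   index=[f"S{i:02d}" for i in range(90)])
clinical = simulate_clinical(labels, config)
clinical["group"] = clinical["cluster"]

curves, logrank = km_logrank(clinical, group_col="group")
for g, sub in clinical.groupby("cluster"):
    print(f"cluster {g}: {sub['pfs_event'].sum()} events / {len(sub)} patients, "
          f"median follow-up {sub['pfs_months'].median():.0f} months")
print(f"log-rank chi2 = {logrank.statistic:.2f}, p = {logrank.p_value:.4f}")

clinical["protective"] = (clinical["cluster"] == 2).astype(int)
clinical["advanced_stage"] = (clinical["stage"] == "III/IV").astype(int)
cox = cox_multivariate(clinical, ["protective", "advanced_stage", "age"])
print("\nCox proportional hazards (HR with 95% CI):")
for cov, res in cox.items():
    print(f"  {cov}: HR {res.estimate:.2f} "
          f"[{res.ci_low:.2f}, {res.ci_high:.2f}], p = {res.p_value:.3f}")
print()
print("Cluster 2 was planted with a 0.2 hazard multiplier, so its HR should")
print("sit well below 1 independently of stage and age.")
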