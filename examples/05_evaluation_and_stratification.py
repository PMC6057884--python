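"""Survival evaluation: prediction-error curve and extreme-decile stratification.

Fits the fused model, converts boosted log-hazard scores to survival curves
through the Breslow baseline, compares the IPCW Brier score against the
Kaplan-Meier reference, and tests the separation between the top and bottom
risk deciles with the log-rank test plus per-feature group tests.
"""

import numpy as np
import pandas as pd

from adprog.coxboost import two_step_fusion
from adprog.evaluation import (
    brier_ipcw, group_feature_tests, km_survival, log_rank_test, stratify_extremes,
)
from adprog.evaluation.curves import breslow_baseline
from adprog.synthcohort import SimulationConfig, make_cohort

cfg = SimulationConfig(n_patients=500, n_snps=150, n_clinical=40,
                       n_subpops=1, fst=0.0, ld_block_size=1,
                       censor_rate=0.3, baseline_scale=60.0, seed=19)
cohort = make_cohort(cfg, target_c=0.85, n_informative_snps=2)
t, d = cohort.outcomes.time, cohort.outcomes.event
modalities = {
    "clinical": cohort.clinical.drop(columns="DX").astype(float),
    "snps": cohort.genotypes.to_frame(),
}
res = two_step_fusion(modalities, t, d, seed=1, nu=0.1, n_max=150, inner_folds=3)
joined = pd.concat(modalities.values(), axis=1)
risks = res.predict(joined)

H0 = breslow_baseline(risks, t, d)
km = km_survival(t, d)
print("IPCW Brier score, model vs Kaplan-Meier reference:")
for horizon in (24.0, 48.0, float(np.median(t))):
    S_model = np.exp(-H0(horizon) * np.exp(risks - risks.mean()))
    b_model = brier_ipcw(S_model, t, d, horizon)
    b_km = brier_ipcw(np.full(len(t), km(horizon)), t, d, horizon)
    print(f"  t={horizon:5.1f} months: model {b_model:.4f}  KM {b_km:.4f}")

hi, lo = stratify_extremes(risks, q=0.10)
stat, p = log_rank_test((t[hi], d[hi]), (t[lo], d[lo]))
print(f"\nextreme deciles ({len(hi)} vs {len(lo)} patients): "
      f"log-rank chi2 = {stat:.1f}, p = {p:.2e}")
tests = group_feature_tests(joined.iloc[hi], joined.iloc[lo])
sig = tests[tests["q"] < 0.05].sort_values("q")
print(f"features differing between groups at BY FDR < 5%: {len(sig)}")
print(sig.head(6).to_string(index=False))
print("-> lower model Brier than KM means the risk score carries real")
print("   time-to-conversion information beyond the marginal survival curve.")
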