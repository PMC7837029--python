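"""The statistical chain on a simulated cohort with a planted hazard.

Generates 120 patients whose event hazard rises threefold per unit of the
skewness feature, then runs: random-forest importance -> Mann-Whitney ->
ROC/Youden -> Kaplan-Meier/log-rank -> multivariable Cox.
"""

import numpy as np

from heteroduo import CohortSimParams, PipelineConfig, gen_cohort, run_paper_pipeline

cohort, truth = gen_cohort(CohortSimParams(n=120, beta_skew=float(np.log(3.0)),
                                           seed=42))
print(f"cohort: {len(cohort)} patients, "
      f"{int(cohort['event'].sum())} events, planted HR per unit skewness = "
      f"{np.exp(truth['beta_skew']):.1f}")

report = run_paper_pipeline(cohort, PipelineConfig(seed=42))

rf = report["random_forest"]
print(f"\nrandom forest OOB error: {rf['oob_error']:.3f}")
ranked = sorted(rf["mean_decrease_accuracy"].items(), key=lambda kv: -kv[1])
print("top variables by mean decrease accuracy:")
for name, mda in ranked[:5]:
    print(f"  {name:>20}: {mda:+.4f}")

for var, roc in report["roc"].items():
    print(f"\nROC for {var}: AUC {roc['auc']:.3f} +/- {roc['se']:.3f}, "
          f"cutoff {roc['cutoff']:.3f} ({roc['direction']})")
for var, km in report["km_logrank"].items():
    print(f"log-rank at the {var} cutoff: chi2 {km['logrank_chi2']:.2f}, "
          f"p {km['logrank_p']:.2e}")
if "summary" in report["cox"]:
    print("\nmultivariable Cox hazard ratios:")
    hr = report["cox"]["summary"]
    for var in hr["hr"]:
        print(f"  {var:>15}: HR {hr['hr'][var]:.2f} "
              f"[{hr['hr_ci_lo'][var]:.2f}, {hr['hr_ci_hi'][var]:.2f}], "
              f"p {hr['p'][var]:.3f}")

# The planted skewness feature should dominate the importance ranking, its
# Youden cut-off should split survival sharply (small log-rank p), and the
# Cox hazard ratio per unit skewness should sit near the planted value 3.
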