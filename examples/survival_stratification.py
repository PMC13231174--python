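"""Threshold-optimized survival stratification of TFHI on a simulated cohort.

The simulated cohort has a known hazard jump (HR = 2) when TFHI > 0.70.
The analysis searches the c-index-optimal cutoff, stratifies the cohort and
reports the Kaplan-Meier medians and the univariate Cox hazard ratio.
"""

from ncetseg import generate_survival_cohort, stratify
from ncetseg.phantom import SurvivalSimConfig

cohort = generate_survival_cohort(
    SurvivalSimConfig(n_patients=300, threshold=0.70, hazard_ratio=2.0, seed=0)
)
res = stratify(cohort)

print(f"optimal threshold      : {res.threshold:.3f}")
print(f"c-index at optimum     : {res.c_index:.3f}")
print(f"hazard ratio (95% CI)  : {res.hazard_ratio:.2f} "
      f"[{res.ci95[0]:.2f}-{res.ci95[1]:.2f}], Wald p = {res.wald_p:.4f}")
print(f"median OS low / high   : {res.median_low:.0f} / {res.median_high:.0f} days")
print(f"median OS difference   : {res.delta_os_days:.0f} days")
# The high-TFHI group should show the shorter median survival and an HR
# near the simulated truth of 2; the optimized cutoff sits below the true
# change point because the tie-counting c-index also rewards balanced groups.
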