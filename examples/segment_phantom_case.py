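"""Segment one synthetic case end to end and compare against ground truth.

Builds a 64^3 phantom with a known nCET compartment (25% of the edema),
runs the full per-case pipeline (features -> NLSVFMM -> boundary cleanup ->
validation -> TFHI) and prints the recovered biomarker next to the truth.
"""

import numpy as np

from ncetseg import PhantomConfig, generate_phantom, run_case_arrays

case = generate_phantom(PhantomConfig(seed=1))
report, split = run_case_arrays(case.t2, case.flair, case.anatomy)

truth = case.truth_ncet_mask
pred = split.ncet_mask
dice = 2 * (pred & truth).sum() / (pred.sum() + truth.sum())

print(f"configured nCET fraction : {case.config.ncet_fraction:.3f}")
print(f"estimated TFHI           : {report.biomarkers['tfhi']:.3f}")
print(f"Dice vs ground truth     : {dice:.3f}")
print(f"FLAIR %dI                : {report.validation['percent_delta_i']['flair']:.1f}")
print(f"Mann-Whitney p (FLAIR)   : {report.validation['p_value']['flair']:.2e}")
print(f"statistically / practically significant: "
      f"{report.validation['statistically_significant']} / "
      f"{report.validation['practically_significant']}")
# TFHI close to the configured fraction and Dice >= 0.9 mean the mixture
# model recovered the low-FLAIR subregion; the two validation flags are the
# per-case checks applied before the biomarker is trusted.
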