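"""Score the framework against the naive per-condition-mean baseline.

Runs the complete synthetic study (generate -> split -> standardize -> fit
-> predict -> evaluate) and prints the operator-stratified MRE/MAE/rho
table for both methods, plus convergence and recovery summaries.
"""

import warnings

import mrwindow as mw

warnings.filterwarnings("ignore")

report = mw.end_to_end_recovery(mw.SimulationScenario.default(), seed=1)

print(report.evaluation.to_text())
print()
print(f"max split-Rhat          : {report.rhat.max_rhat:.3f} "
      f"(converged: {report.converged})")
print(f"RMSE of posterior-mean mu: {report.rmse_mu:.3f} standardized units")

# MRE is in percent, MAE in native intensity units, rho dimensionless.
# The framework's average MAE undercuts the naive baseline for both WL and
# WW because the naive method ignores observer identity and each image's
# histogram, while rho stays high for both (window sizes track intensity
# ranges strongly in either method).
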