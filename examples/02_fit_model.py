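"""Fit the Bayesian bivariate-normal mixed-effects model to a synthetic study.

Simulates operators windowing MR series under known ground truth, fits the
model by MCMC on the standardized training records, and prints the
standardized optimal windows (soWL/soWW) per operator and condition next to
the truth.
"""

import warnings

import numpy as np

import mrwindow as mw

warnings.filterwarnings("ignore")

scenario = mw.SimulationScenario.default()
dataset, truth = mw.simulate_dataset(scenario, seed=7)

# train scales on the training split, standardize the training records
by_cond = {}
for img in dataset.images_in("train"):
    by_cond.setdefault(img.condition, []).append(img)
scales = {c: mw.train_standard_scale(lst, c) for c, lst in by_cond.items()}

std_records = []
for r in dataset.train_records:
    img = dataset.images[r.series_id]
    mapping = mw.build_mapping(mw.compute_landmarks(img), scales[img.condition])
    std_records.append(
        mw.WindowingRecord(
            r.series_id, r.patient_id, r.condition, r.operator,
            mw.standardize_window(r.window, mapping), mw.Frame.STANDARDIZED,
        )
    )

spec = mw.ModelSpec(I=scenario.I, J=scenario.J)
samples = mw.fit_mcmc(mw.encode_design(std_records, spec), spec, seed=7)
rhat = mw.compute_rhat(samples)
fitted = mw.extract_mu_hat(samples, spec, scenario.registry().conditions, rhat=rhat)

print(f"max split-Rhat = {rhat.max_rhat:.3f} (converged: {rhat.converged})\n")
print("operator  condition              soWL est/true     soWW est/true")
for i in range(spec.I):
    for j, cond in enumerate(fitted.conditions):
        est = fitted.mu_hat[i, j]
        tru = truth.mu[i, j]
        print(
            f"   {i + 1}      {cond.label:<22}"
            f"{est[0]:6.2f}/{tru[0]:6.2f}     {est[1]:6.2f}/{tru[1]:6.2f}"
        )

# Each cell's posterior mean tracks the realized true mean window within a
# fraction of a standardized unit; operators differ visibly (the fixed
# effect), conditions shift each operator by its random effect.
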