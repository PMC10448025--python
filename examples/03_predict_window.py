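"""Predict each operator's preferred native window for an unseen image.

Runs the full pipeline on a synthetic study, then predicts the optimal
WL/WW of one held-out test series for all three operators, printing the
audit chain (standardized window -> limits -> inverse map -> native).
"""

import warnings

import mrwindow as mw

warnings.filterwarnings("ignore")

report = mw.end_to_end_recovery(mw.SimulationScenario.default(), seed=7)
dataset = report.dataset

# pick one test record and rebuild the scales the pipeline trained
test_rec = dataset.test_records[0]
series = dataset.images[test_rec.series_id]
by_cond = {}
for img in dataset.images_in("train"):
    by_cond.setdefault(img.condition, []).append(img)
scales = {c: mw.train_standard_scale(lst, c) for c, lst in by_cond.items()}

print(f"series {series.series_id} ({series.condition.label})")
print(f"operator {test_rec.operator} actually chose "
      f"WL/WW = {test_rec.window.wl:.0f}/{test_rec.window.ww:.0f}\n")

for op in (1, 2, 3):
    p = mw.predict_window(series, op, report.model, scales)
    print(
        f"operator {op}: soWL/soWW {p.so_window.wl:6.2f}/{p.so_window.ww:6.2f}"
        f"  -> so-limits [{p.so_limits.lw:6.2f}, {p.so_limits.uw:6.2f}]"
        f"  -> native limits [{p.o_limits.lw:7.1f}, {p.o_limits.uw:7.1f}]"
        f"  -> oWL/oWW {p.window.wl:7.1f}/{p.window.ww:7.1f}"
    )

# The three operators receive different native windows for the same image:
# the model's operator fixed effect and operator-by-condition random effect
# personalize the prediction, and the image's own landmark mapping converts
# the shared standardized preference into that image's scanner units.
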