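"""Simulate a larval cohort and classify growth patterns.

Generates one synthetic survey, fits log-linear growth of length and weight
on age, and partitions larvae into OPT (above both growth lines), DEF (below
both) and MIX (discordant) groups.
"""

import numpy as np

from larvaniche import SimulationConfig, fit_and_classify, simulate_cohort

cfg = SimulationConfig()
dataset, truth = simulate_cohort(cfg, seed=42)

fit_sl, fit_dw, labels = fit_and_classify(dataset)

print(f"simulated {len(dataset.larvae)} larvae over {len(dataset.stations)} stations")
print(f"log(SL) = {fit_sl.intercept:.4f} + {fit_sl.slope:.4f} * AGE   (r2 = {fit_sl.r2:.3f})")
print(f"log(DW) = {fit_dw.intercept:.4f} + {fit_dw.slope:.4f} * AGE   (r2 = {fit_dw.r2:.3f})")

counts = {k: sum(1 for l in labels if l.label == k) for k in ("OPT", "DEF", "MIX")}
print(f"growth classes: {counts}")

# how well do the labels track the latent growth potential the generator used?
g_of = {t.larva_id: t.g for t in truth}
decided = [l for l in labels if l.label != "MIX"]
agree = sum(1 for l in decided if (l.label == "OPT") == (g_of[l.larva_id] > 0))
print(
    f"label agrees with the sign of the true growth potential for "
    f"{agree}/{len(decided)} non-MIX larvae "
    f"({100 * agree / len(decided):.0f}%): residual classification recovers "
    f"the latent condition, not just noise"
)
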