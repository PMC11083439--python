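"""Back-calculate maternal isotope values from pre-flexion larvae.

Pre-flexion larvae still carry the female's isotopic signal, decaying with
age.  Regressing the per-larva (egg − larva) difference on age gives a
cohort factor line; adding the age-predicted factor back to each larva's
value reconstructs its maternal signature.
"""

import numpy as np

from larvaniche import (
    EggIsotopeParams,
    SimulationConfig,
    draw_egg_values,
    estimate_maternal_dataset,
    fit_factor_regression,
    simulate_cohort,
)

cfg = SimulationConfig(n_pre=52, n_post=0)
dataset, truth = simulate_cohort(cfg, seed=3)
pre = dataset.larvae

egg_params = EggIsotopeParams(
    mean_d15n_egg=cfg.maternal_d15n_mean,
    sd_d15n_egg=cfg.maternal_d15n_sd,
    mean_d13c_egg=cfg.maternal_d13c_mean,
    sd_d13c_egg=cfg.maternal_d13c_sd,
)
eggs15, eggs13 = draw_egg_values(egg_params, len(pre), seed=3)

reg15 = fit_factor_regression(pre, eggs15, "d15n")
reg13 = fit_factor_regression(pre, eggs13, "d13c")
print(
    f"(δ15N_egg − δ15N_larva) = {reg15.intercept:.3f} + {reg15.slope:.3f} * AGE   "
    f"(p = {reg15.p_value:.3g}, r2 = {reg15.r2:.2f}; generator used {cfg.factor_d15n})"
)
print(
    f"(δ13C_egg − δ13C_larva) = {reg13.intercept:.3f} + {reg13.slope:.3f} * AGE   "
    f"(p = {reg13.p_value:.3g}, r2 = {reg13.r2:.2f}; generator used {cfg.factor_d13c})"
)

estimates = estimate_maternal_dataset(pre, reg15, reg13)
est15 = np.array([e.d15n_maternal for e in estimates])
print(
    f"maternal δ15N estimated {est15.mean():.2f} ± {est15.std(ddof=1):.2f} ‰ "
    f"(true mean {cfg.maternal_d15n_mean}): the back-calculation removes the "
    f"age trend and recovers the spawning-female signal"
)
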