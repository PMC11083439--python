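# larvaniche

Trophodynamics of larval fish from bulk stable isotopes and otolith growth.

Surveys of larval fish (the motivating case is Atlantic bluefin tuna larvae
in the Gulf of Mexico) collect, for each larva, an otolith-derived age,
standard length (SL), dry weight (DW), otolith radius and mean increment
width, a developmental stage (pre-/post-flexion), and bulk tissue δ15N, δ13C
and C:N; each station also contributes zooplankton isotopic baselines and
hydrography. `larvaniche` turns those tables into the standard larval
trophic-ecology analysis:

- **Lipid normalisation** of δ13C from C:N
  (δ13C′ = δ13C + β0 + β1·C:N when C:N exceeds a threshold).
- **Growth classification**: OLS of log SL and log DW on age; larvae with
  positive residuals on *both* fits are OPT (optimal growth), negative on
  both are DEF (deficient), discordant signs are MIX and are dropped from
  OPT/DEF contrasts.
- **Maternal back-calculation**: pre-flexion larvae retain the spawning
  female's isotopic signal, decaying with age. The per-larva
  (egg − larva) factor is regressed on age, and
  δ_maternal = δ_larva + (c0 + c1·AGE) reconstructs the maternal signature;
  egg values are stochastic draws from rearing-experiment means ± sd.
- **Trophic position**: TP = (δ15N_larva − δ15N_micro)/Δ15N + TP_basal with
  a station-matched micro-zooplankton baseline, Δ15N = 1.46 ‰ per trophic
  step and TP_basal = 2.
- **Isotopic niches**: the c = 1 standard ellipse in the (δ13C, δ15N)
  plane (covering ≈ 40 % of bivariate-normal data), its area
  SEA = π·√det Σ̂, the small-sample correction SEAc = SEA·(n−1)/(n−2), an
  exact conjugate normal–inverse-Wishart posterior over SEA with 50/75/95 %
  credible intervals, and polygon-clipped ellipse overlap areas.
- **Group tests**: tie-corrected Mann–Whitney U with Z approximation,
  age-controlled ANCOVA (Type-II F for the group term) with an automatic
  ANOVA fallback when a variable has no age trend.

Because cruise datasets of this kind are typically not deposited, the
package ships a first-class **synthetic cohort generator**
(`larvaniche.synthetic`) whose forward model matches every assumption above
and returns the latent truth (growth potentials, egg values, true TP), so
the whole pipeline is testable end to end with known answers.

## Worked example

```python
from larvaniche import default_cohort_configs, simulate_two_cohorts, tp_for_dataset
import numpy as np

cfg_a, cfg_b = default_cohort_configs()   # two survey years with contrasting baselines
dataset, _ = simulate_two_cohorts(cfg_a, cfg_b, seed=7)
results = {r.larva_id: r for r in tp_for_dataset(dataset)}
for cfg in (cfg_a, cfg_b):
    post = [l for l in dataset.larvae if l.cohort == cfg.cohort and l.stage == "POST"]
    tps = np.array([results[l.larva_id].tp for l in post])
    print(cfg.cohort, f"TP {tps.mean():.2f} ± {tps.std(ddof=1):.2f} (true {cfg.tp_true})")
```

prints

```
GOM17: post-flexion δ15N 3.53 ± 0.42 ‰, TP 4.05 ± 0.23 (true 4.1)
GOM18: post-flexion δ15N 5.93 ± 0.69 ‰, TP 3.50 ± 0.22 (true 3.5)
```

(the `examples/trophic_position.py` version, which also prints the δ15N
means). The point of the contrast: the cohort with the *higher* raw δ15N
sits at the *lower* trophic position once its enriched baseline is
subtracted — raw δ15N is not a trophic level. Each script in `examples/`
demonstrates one capability the same way (growth classification, maternal
back-calculation, niche ellipses and overlap, the full pipeline).

The full pipeline is one call (or `larvaniche run --simulate --seed 1 --out
run/` from the shell):

```python
from larvaniche import run_pipeline
manifest = run_pipeline(out_dir="run", simulate=True, seed=1)
```

It writes per-stage CSVs — growth fits and OPT/DEF/MIX labels, factor
regressions and maternal estimates, per-larva trophic positions, niche
ellipse areas / posteriors / overlaps, and Mann–Whitney/ANCOVA comparison
tables — plus `manifest.json` with the config snapshot, seed and SHA-256
digest of every table. Same seed ⇒ byte-identical tables.

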