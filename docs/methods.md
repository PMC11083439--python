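# Methods

This note documents the models implemented in `larvaniche`, the defaults and
their units, what the synthetic generator does and does not emulate, and the
design decisions taken where the underlying methodology is genuinely open.

## Data model

A survey is a `CohortDataset`: per-larva records (id, cohort, station, age in
days from otolith daily increments, SL in mm, DW in mg, otolith radius and
mean increment width in µm, PRE/POST flexion stage, δ15N and δ13C in ‰, C:N)
plus per-station records (temperature, salinity, micro- and meso-zooplankton
δ15N/δ13C baselines). Stage is an input flag, never inferred from length:
pre- and post-flexion size ranges overlap in field data. C:N is the mass
ratio %C/%N (the bulk-SIA convention; if your lab reports molar ratios,
convert before input). Input column names are remappable via a schema dict;
defaults use the field's symbols (SL, DW, AGE, RADIUS, MIW, d15N, d13C, CN).

## Lipid normalisation (preprocess)

Lipids are 13C-depleted, so δ13C of lipid-rich tissue is corrected by the
linear mass-balance form δ13C′ = δ13C + β0 + β1·C:N, applied only when
C:N > threshold. Defaults β0 = −3.32 ‰, β1 = 0.99 ‰ per C:N unit,
threshold 3.5 are the widely used aquatic-animal coefficients; all three are
configurable per tissue class (larval muscle vs zooplankton) because
taxon-specific calibrations should replace them when available. The formula
is deliberately not idempotent; the pipeline tracks a per-record
`d13c_corrected` flag and applies it exactly once, before any isotope-based
stage.

## Growth fits and OPT/DEF/MIX classification

Daily growth is summarised by OLS of log(SL) and log(DW) on age. Natural
log is the default (`log_base="base10"` is available; slopes differ by
ln 10 and the base is recorded in every output). Residuals are taken
against the pooled, all-cohort fit by default — the classification is
relative to the whole population — with a per-cohort scope for sensitivity
analysis; whether pooling across survey years is "the" correct reference is
genuinely ambiguous, so both are exposed and neither is privileged beyond
the default.

A larva is OPT if both residuals are strictly positive, DEF if both strictly
negative, MIX otherwise. Exact zeros go to MIX: they are measure-zero and
assigning them to either extreme group would bias it asymmetrically.

## Maternal back-calculation

The defining identity δ_maternal = δ_larva + (δ_egg − δ_larva) reduces
algebraically to δ_maternal = δ_egg if the same larva value appears in both
terms. The operational estimator implemented keeps the two roles distinct:
the (egg_i − larva_i) differences of pre-flexion larvae are regressed on
age (one stochastic egg draw per larva from Normal(egg mean, egg sd)), and
each larva's maternal value is its measured value plus the *age-predicted*
factor, δ_maternal,i = δ_larva,i + c0 + c1·AGE_i. This is what yields
per-larva maternal estimates with real variance; the collapse in the
printed identity is documented here rather than silently "fixed".

Egg means and sds are required inputs — they come from rearing experiments
and no literature constants are baked in. The regression is applied even
when its slope is non-significant (significance is reported and surfaced as
a run warning, not gated on). Ages outside the fitted range extrapolate
with a warning. A deterministic expected-value mode (pass the egg mean for
every larva) exists for exact regression tests.

## Trophic position

TP = (δ15N_larva − δ15N_micro)/Δ15N + TP_basal, with Δ15N = 1.46 ‰ per
trophic step (a bluefin-tuna muscle discrimination value; the canonical
3.4 ‰ is one config flag away) and TP_basal = 2 (micro-zooplankton,
0.05–0.2 mm, treated as primary consumers). Baselines are station-matched
by default; when a larva's station lacks a baseline the cohort mean is used
with a logged warning, and a `cohort_mean` scope forces that behaviour
everywhere. TP < 1 is flagged implausible but never clipped.

Note that cohort-mean TP is not recoverable from cohort-mean δ15N and the
cohort-mean baseline: TP is computed per larva against its own station, and
the covariance between larval δ15N and station baselines matters. The
estimator is not tuned to reproduce any published cohort summary.

## Isotopic niches

The standard ellipse of a bivariate (δ13C, δ15N) sample is the c = 1
Mahalanobis contour of the sample mean and covariance (n−1 denominator).
It contains 1 − e^(−1/2) ≈ 39.35 % of bivariate-normal data — the "40 %
ellipse" of the niche literature. SEA = π·√det Σ̂;
SEAc = SEA·(n−1)/(n−2) corrects small-sample bias. Maternal niches use the
back-calculated pre-flexion (δ13C, δ15N) maternal pairs; larval trophic
niches use raw post-flexion pairs, which are free of maternal influence.

The Bayesian posterior over SEA uses the conjugate normal–inverse-Wishart
model sampled exactly (no MCMC): with vague hyperparameters κ0 = 1e−3,
ν0 = 3, Ψ0 = 1e−3·I and μ0 set to the sample mean, the covariance posterior
is IW(ν0 + n, Ψ0 + S), each draw giving SEA* = π·√det Σ*. Central 50/75/95 %
credible intervals are reported. Exact sampling is fast, seedable, and
matches the vague-prior intent of the common Gibbs implementations.

Overlap areas are computed by clipping two 1024-vertex ellipse polygons
(boundary vertices sit on the Mahalanobis-1 shell to 1e−10; polygonal area
error is well under 0.1 %). The field reports overlap "percentages" without
a fixed denominator convention, so all three proportions — intersection
over each ellipse's own area and over the union — are always reported, with
the symmetric union proportion as the headline. A `corrected=True` variant
inflates each boundary by √((n−1)/(n−2)) to the SEAc scale; both are
computed since published overlap figures rarely state which was used.

## Group-comparison tests

Mann–Whitney U uses midranks, the tie-corrected variance
n_a·n_b/12·[(n+1) − Σ(t³−t)/(n(n−1))], and Z = (U − n_a·n_b/2)/σ_U, U being
the first sample's statistic ("Z-adjusted" in the convention of common
statistics packages; continuity correction available, off by default). For
tiny groups note the normal approximation of the *p*-value is only accurate
(within 0.05 of the exact-enumeration p for every achievable U) with the
continuity correction and group sizes ≥ 3; below that, use an exact test.

Age-dependent variables are compared by ANCOVA: OLS of y ~ age + group with
the Type-II partial F for the group term, df (1, n−3) (Type II is
order-invariant for this two-term model). Variables with no significant
linear age trend (slope p ≥ α in y ~ age) fall back to one-way ANOVA; the
choice is deterministic in the slope p-value and recorded in the output. SL
and DW are log-transformed before testing for linearity and variance
homogeneity. α = 0.05 throughout; p-values are reported raw with */** stars
at 0.05/0.01 and no multiple-testing correction, matching how such tables
are conventionally presented.

## Synthetic cohort generator

The generator is the study's forward model with every parameter explicit:

- Ages uniform integers: PRE 5–15 d, POST 16–30 d (larval sizes constrain
  plausible ages; the ranges are configurable).
- log SL = a_SL + b_SL·AGE + g_i + ε, log DW = a_DW + b_DW·AGE + 2·g_i + ε
  with g_i ~ N(0, σ_g²) the latent growth potential (σ_g = 0.08) and
  ε ~ N(0, σ_resid²) (σ_resid = 0.05). The weight coefficient 2 makes
  length and weight residuals correlate without being identical, so all
  four residual-sign classes are populated. Defaults a_SL = 1.35,
  b_SL = 0.03 d⁻¹, a_DW = −2.4, b_DW = 0.10 d⁻¹ give 4–9 mm, 0.1–2.5 mg
  larvae over the age ranges — a realistic scombrid larval window.
- Otolith radius and MIW are monotone noisy functions of SL.
- Pre-flexion isotopes: δ_i = egg_i − (c0 + c1·AGE) + ε_iso with one egg
  draw per larva (egg means/sds per cohort; the default δ15N factor line is
  (0.975, 0.527), the default δ13C line (2.423, −0.200), i.e. opposite age
  trends for the two isotopes). ε_iso has sd σ_iso = 0.3 ‰, a separate
  parameter from σ_resid because ‰ and log-mm scales are not comparable.
- Post-flexion isotopes equilibrate to the configured true trophic
  position: δ15N = δ15N_micro(station) + 1.46·(TP_true − 2) + ε_iso, δ13C
  analogous with a 0.5 ‰ carbon step.
- C:N = 3.8 − 3·g_i + ε: slow growers carry more lipid (higher C:N).
- Growth potential and maternal δ15N are correlated at ρ (default −0.5:
  enriched maternal signatures accompany deficient growth). No published
  effect size exists for this coupling; −0.5 is a deliberate free choice,
  strong enough that OPT/DEF maternal contrasts are detectable at survey
  sample sizes.
- Station baselines, temperature and salinity are drawn per station from
  cohort-level means/sds. The default two-cohort contrast
  (`default_cohort_configs`) sets micro-zooplankton δ15N baselines
  0.56 ± 0.42 vs 3.61 ± 0.39 ‰, TP_true 4.1 vs 3.5, and cohort sizes
  49+34 vs 36+38 (pre+post).

One seeded generator drives everything: a fixed seed is bit-reproducible,
and setting all sds to zero yields a noise-free dataset from which every
estimator recovers its generating coefficients exactly — the backbone of the
test suite.

What the generator does **not** emulate: prey-field or hydrodynamic
structure, otolith microstructure, non-normal isotope noise, within-station
larval clustering (larvae are assigned to stations uniformly), measurement
censoring, or stage-misclassification. Passing tests therefore demonstrate
estimator correctness under the stated model, not robustness to field
pathologies outside it.

## Numerical choices

- OLS via statsmodels; degenerate designs (all ages equal, confounded
  groups) are rejected with explicit errors.
- Ellipse fits reject collinear points at det Σ̂ ≤ 1e−12; boundary polygons
  use 1024 vertices (4096 in convergence tests).
- CSV round-trips are bit-exact: floats are written with shortest
  round-trip repr and parsed with round-trip precision.
- Pipeline tables are byte-identical for a fixed (config, seed, input);
  `manifest.json` carries timestamps and is excluded from that guarantee.
- Seeds: the pipeline derives independent stage streams from the run seed
  via `SeedSequence`; egg draws, posterior draws and the generator never
  share a stream.

## Problem sizes

Default simulated surveys are ~80 larvae per cohort over 6 stations,
matching typical published survey sizes. Parameter-recovery tests use
n = 200–500 and the coverage check 10⁵ points; the Monte-Carlo overlap
oracle uses 10⁶ uniform points per ellipse pair over the pair's common
bounding box, keeping its relative error well below the 1 % assertion.

## Known limitations

- Maternal estimation assumes the (egg − larva) factor is linear in age and
  shared within a cohort; no larva-level random effects.
- TP uses a single baseline (no two-source mixing) and a fixed TEF; TEF
  uncertainty is not propagated into TP.
- The Mann–Whitney p is asymptotic; exact enumeration is only used as a
  test oracle.
- Overlap of more than two groups is pairwise only; no community-level
  metrics (total area, centroid distances).
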