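# Methods

## Abundance and weighting

The abundance currency is the layer count: the number of plot × height
layer cells a species occupies along a site transect. The default design
is 21 plots × 4 layers (0–10, 10–30, 30–50, 50–200 cm), so counts are
capped at 84. Relative abundance at a site is computed over the subset of
species that have leaf chemistry there ("collected" species); species
surveyed but not sampled get no weight but enter the coverage denominator,
and coverage (the sampled subset's share of total layer abundance) is
always reported, never imputed. Within the community-weighted mean (CWM)
computation, weights are recomputed per element over the species having
that element measured, which keeps the weighted mean well defined under
partial chemistry; with complete six-element samples this coincides with
per-site weights.

The fixed species mean is the *unweighted* arithmetic mean of a species'
site-level contents over the sites where it was sampled — deliberately not
abundance-weighted, since it represents the species' typical value rather
than a community property.

## Decomposition

With specific CWM S_j, fixed CWM F_j and I_j = S_j − F_j per site j, the
centred SS identity

    Σ(S−S̄)² = Σ(F−F̄)² + Σ(I−Ī)² + 2Σ(F−F̄)(I−Ī)

partitions across-site variation into turnover, intraspecific and
covariation components. Sites are unweighted. The gradient split fits
separate straight lines of S, F and I on rainfall; a component's explained
SS is the centred SS of its fitted values, its residual SS that of its
residuals, and the covariation cross-term is split as
2Σ(F̂−F̄)(Î−Ī) / remainder. Because least-squares fitting is linear in the
response, Ŝ = F̂ + Î and the full 3 × 3 grid is additive to floating-point
precision (asserted at 1e−9 relative in tests). Shares are signed
fractions of the total SS; negative covariation shares are legitimate
output. Ca, Mg, Na and Ca:P are log10-transformed before decomposition by
default (matching the transform used in the trend models, where the
right-skew of those elements violates normality); the transform map is
configurable per target.

Degenerate inputs: fewer than 3 sites raises an error; a zero total SS
flags the result degenerate with undefined shares; a constant gradient
returns totals with the split columns NaN and a note.

## Trend models

Site-level trends are single-predictor OLS fits on rainfall (mm yr⁻¹).
The reported R² is the adjusted R² — with n = 9 sites it can be negative,
and that is the scale on which such gradient fits are conventionally
summarised. Significance for the "gradient-related" call uses p < 0.1,
mirroring the solid-versus-dashed trendline convention for short
gradients.

Within-species trends use a linear mixed model, content ~ rainfall with a
random intercept per species, fit by REML (statsmodels MixedLM). Only
species sampled at ≥ 3 sites enter (the repeat-species rule). The Wald t
for the slope uses a configurable residual-df rule — n_obs − 2 (default)
or n_obs − 1 − n_species — because the right denominator df for such
designs is a bookkeeping choice; the rule used is recorded in the output.
A single remaining species collapses the model to OLS on that species
(flagged singular); a between-species variance estimated at the zero
boundary is flagged singular but still returned.

Stoichiometric site ratios (N:P, Ca:P, K:Na) divide the specific CWMs of
the two elements (and the fixed CWMs for the turnover series). Sample
ratios divide raw contents per (site, species). The ratio of fixed CWMs
is *not* the fixed CWM of ratios; both exist in the code and the former is
the site series used for decomposition and trends. Within-species ratio
models run on sample-level ratios of raw contents.

## Interpretation thresholds

* θ_contrib = 15% of total SS decides whether a component "contributes" to
  the mechanism call. This separates a genuinely mixed case (e.g. a ~25%
  intraspecific share) from small-but-significant components, while not
  demanding parity. If neither component reaches it, the larger one is
  taken so the call is never empty.
* Gradient-related: site-trend p < 0.1 (see above), applied to the
  specific-CWM series, not to the component-explained shares.
* Intraspecific variability is "variable" only when the intraspecific
  share ≥ θ_contrib *and* the mixed-model slope has p < 0.05; a
  significant slope on a tiny component stays "uniform". Species whose
  within-species max/min content ratio exceeds θ_outlier = 5 are listed as
  outliers, so a "mostly uniform" element can carry its exception.
* Limitation grades operationalise verbal categories: *sufficient* — every
  site CWM and every sample meets every reference herbivore's minimum
  (ties meet); *severely limiting* — at most 20% of sites meet any
  herbivore's minimum; otherwise *moderately limiting*. The 100% / 20%
  cutoffs are configuration values and the underlying fractions are always
  printed. Ratio targets are summarised by the position of site ratios
  relative to the optimal range (below / within / above). The default life
  stage is lactating, reflecting wet-season sampling when most savanna
  herbivores lactate.

All thresholds live in `PipelineConfig`, are echoed into the output
manifest, and can be changed per run.

## Synthetic communities

The generator emulates the sampled design: 9 sites evenly spaced over
681–999 mm yr⁻¹, 45 species, 21 plots × 4 layers, chemistry for every
species present at a site (coverage 1 — real surveys sample only the most
abundant species, typically covering roughly half the layer abundance, so
real coverage effects are *not* emulated). Element means are set at
field-realistic contents (% dry mass): N 2.0, P 0.2, K 1.5, Ca 0.6,
Mg 0.3, Na 0.1. Ca, Mg and Na use lognormal species baselines
(log-SD 0.4) and multiplicative noise; N, P and K use truncated-normal
baselines (relative SD 0.15) and additive noise. Default residual noise is
5% of the element mean.

Mechanisms per scenario preset:

* **a** — Gaussian occupancy niches on the rainfall axis (width 120 mm,
  peak cell-occupancy probability 0.35) generate turnover; coupling
  baselines to niche optima (±30% across the gradient) makes the turnover
  gradient-related. Zero within-species slope, so with zero noise the
  intraspecific SS is exactly 0 (the fixed-mean code short-circuits sum/n
  round-off when all site values are identical, precisely so this holds).
* **b** — identical composition at every site (per-species counts drawn
  once and reused), with a common within-species slope of −0.0015 × mean
  per mm (≈ a halving across the 318-mm gradient, the size of
  within-species declines seen in strongly plastic elements).
* **c** — the niche model evaluated against a site permutation chosen
  among 256 seeded candidates to minimise |corr| with rainfall: turnover
  is structured but deliberately orthogonal to the gradient. The
  orthogonal systematic variation inflates the trend model's residual
  variance, so the gradient-unrelated call is a property of the
  construction rather than a 90% coin flip on the p < 0.1 rule.
* **d** — shared composition plus per-site content offsets (relative
  SD 0.15) drawn randomly and then residualised against rainfall, for the
  same reason.

All randomness flows from one seed through spawned child generators
(composition, chemistry, noise), so identical specs give byte-identical
files; ground truth (niche optima, baselines, slopes, offsets, layer
counts) is written as JSON next to the data.

What passing the scenario-recovery tests shows: the pipeline attributes
variance to the correct mechanism when that mechanism is present at
realistic effect sizes and noise. What it does not show: behaviour under
partial chemistry coverage, unbalanced species occurrence, correlated
multi-element responses, or observational confounding between composition
and environment — all features of real surveys.

## Problem sizes and verification

The test suite verifies the SS identities on 1,000 random communities,
CWM/SS agreement with brute-force loop oracles at 1e−12 on small
communities, scenario recovery on 100 replicates per preset (≥ 90%
required; observed ~100%), and mixed-model CI coverage on 500 replicates
(95% ± 4 pp required). The acceptance script uses 50 recovery replicates
per preset and 300 coverage replicates, chosen as the smallest sizes at
which the Monte-Carlo error of the reported rates is comfortably below
the margins of interest.

## Known limitations

* The decomposition is descriptive: no permutation or parametric inference
  on the component shares themselves.
* One predictor, straight-line gradient models only; no polynomial or
  multi-predictor splits.
* The mixed models fit random intercepts only (no random slopes), and the
  denominator-df question is exposed as a switch rather than resolved.
* Limitation grading treats requirement thresholds as sharp and diets as
  single-species/single-site; it is a screening summary, not a foraging
  model.
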