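# Methods

This note documents the models, numerical choices and limitations of
`pahrisk` — what is computed, under which assumptions, and what the
packaged synthetic scenario does and does not show about real data.

## Risk characterization

Inhalation-only incremental lifetime cancer risk follows the EPA
protocol: ILCR = BaP_eq · 10⁻⁶ · IR · EF · ED · CSF / (BW · AT).  The
ng→mg factor is an explicit field of `ExposureConstants` so the equation
is dimensionally auditable; with the defaults (EF = 365 day·yr⁻¹,
ED = 53 yr, AT = 70 × 365 day, CSF = 3.14 per mg·kg⁻¹·day⁻¹) the
deterministic dose factor collapses to 10⁻⁶ · 3.14 · 53/70 per
(ng·m⁻³ · m³·day⁻¹ · kg⁻¹).

BaP equivalents sum TEF-weighted congener concentrations over congeners
and, when both phases are supplied, over the gaseous and particulate
phases; per-phase values remain available for phase contrasts.  The
default TEF table is a Nisbet–LaGoy-style scheme (BaP = DahA = 1;
BaA/BbF/BkF/IcdP = 0.1; Ant/Chr/BghiP = 0.01; others 0.001) restricted
to the 15 priority congeners; it is config-overridable because TEF
schemes differ (notably DahA, assigned 5 in some schemes).

Risk classes: < 10⁻⁶ below acceptable; [10⁻⁶, 10⁻⁴) exceeds acceptable;
≥ 10⁻⁴ serious.  Both boundaries are closed on the higher-risk side
("one-in-ten-thousand *or greater*").

## Distribution fitting

All lognormals are parameterized on the natural-log scale, LN(a, b) with
a = mean and b = SD of ln X.  Natural logs are the only reading
consistent with the handbook body-weight tables (e^4.169 ≈ 64.6 kg);
base-10 is implausible, and the power-law slope is base-invariant
anyway.

*From samples* — the cumulative-probability convention used with
monitoring data: rank the sample, assign plotting positions
rank/(n + 1) (averaged ranks on ties; positions always lie strictly in
(0, 1) and sum to n/2), and least-squares fit the Gaussian CDF to
(ln value, position) pairs, initialized at the log-moments.  The r² of
the CDF curve is the fit diagnostic.  A maximum-likelihood route
(log-moments) is available behind `method="mle"`; the two agree to
within estimator noise and exactly on noise-free quantile inputs.
A Shapiro-Wilk gate on the log scale (α = 0.05, 3 ≤ n ≤ 5000) screens
log-normality before fitting.

*From quantiles* — handbook tables give quartiles and medians per age
stratum; regressing ln value on the standard-normal quantile z(p) gives
b as the slope and a as the intercept, an exact inversion when the pairs
lie on one lognormal (the round trip through the quantile generator
recovers parameters to ~1e-12).

*IR–BW power law* — ordinary least squares of ln IR on ln BW; residual
SD uses ddof = 2; at least 3 distinct body weights required.  The
intercept is stored with an explicit unit tag.  Internal convention is
m³·day⁻¹; a published intercept of −0.281 in L·min⁻¹ corresponds to
−0.281 + ln 1.44 ≈ 0.084 in m³·day⁻¹.  Only the slope is treated as
unit-free.

*BMR route for individual IR* — where a participant's inhalation rate is
not measured, it is estimated from Schofield-type sex/age-banded linear
BMR equations in body weight (bands 16–<30, 30–<60, 60+), scaled by a
physical activity level (default 2.0) and a ventilation conversion
(0.0502 L O₂ per kJ × ventilatory equivalent 27 L air per L O₂).  The
coefficients are configurable defaults calibrated so that a 67.7 kg,
171 cm adult male lands near 13 L·min⁻¹, in the range of measured adult
male means; they are a documented surrogate for whatever proprietary
appendix method a given field study used.  Height is validated but the
weight-only bands do not use it.

## Monte Carlo engine

One seeded `numpy` Generator per run; identical config + seed is
bit-reproducible.  The stratified variant derives one substream per
(stratum, variable) from the master seed via `SeedSequence.spawn`, so
changing the iteration allocation leaves every stratum's draw prefix
unchanged.  Iterations are allocated to strata by largest-remainder
rounding of weight × total (counts always sum to the total); the default
study weights 19379/8172/2449 ÷ 30000 reproduce those counts exactly.

The correlated variant draws only C and BW and computes IR from the
power law with no residual by default (the deterministic substitution of
a fitted regression); `ir_residual_sd` re-enables scatter for
exploration.  Degenerate b = 0 inputs are accepted and collapse every
iteration to the median-point estimate, which is the zero-variance
sanity check for all four variants.

Convergence is assessed on one long stream evaluated cumulatively at an
ascending grid (default 5,000…50,000 step 5,000): the run is converged
at the earliest grid point from which every successive relative change
of the mean stays below the tolerance (default 2%).  A zero-variance
run is therefore converged at the first grid point, and tolerance 0 is
never met by a stochastic run.

Sensitivity is the Spearman rank correlation of each input's draws with
the ILCR draws (averaged ranks on ties), ranked by |r|; a constant input
is reported as NaN and ranked last.  For independent lognormal inputs
the closed form (6/π)·arcsin(ρ/2) with ρ = ±b_input/√(Σb²) is exact and
serves as the cross-check oracle, as does the product-lognormal identity
ln ILCR ~ N(ln k + a_C + a_IR − a_BW, b_C² + b_IR² + b_BW²).  In the
correlated variant IR is a monotone function of BW, so its rank
correlation is identical to BW's (negative, since ILCR ∝ BW^(slope−1)
at fixed concentration) — a structural fact, not an estimation artifact.

## Individual assessment and grading

Each participant's exposure is the annual BaP_eq of the Euclidean-nearest
site in projected planar coordinates (exact ties break to the smallest
site id, a deterministic convention).  ILCR then uses measured BW and
measured-or-estimated IR.  Unresolvable participants are reported and
skipped unless strict mode is on.  Subgroup contrasts use the
Kruskal-Wallis rank test with per-group geometric means.  The IDW
surface uses weights d^(−power) and returns site values exactly at site
locations.  Goodness of fit reports simulated ÷ actual ratios of mean,
median and SD (ddof = 1) plus the difference of log₁₀(max/min) spans;
the variant ranking is by |mean ratio − 1|.  Multimodality of the
empirical distribution is described (not tested) by a Gaussian KDE on
the log₁₀ scale with peaks counted above 5% relative prominence.

## The synthetic scenario

The default preset emulates a typical single-city PAH study: 25 sites in
three spatial clusters, 2,740 adults in three age strata (weights
0.646/0.272/0.082), handbook lognormals BW LN(4.169, 0.218) and IR
LN(2.788, 0.195) for the whole population with per-stratum variants, and
site concentrations whose marginal is LN(2.21, 1.01).

Design choices, each genuinely open and fixed once here:

- **Spatial clusters.**  Three clusters with log-offsets (−1.2, 0, +1.2);
  the within-cluster log-SD is reduced so the site *marginal* keeps the
  configured LN moments.  Participants are placed around cluster centers
  with weights 0.270/0.582/0.148 (the observed three-peak population
  proportions), skewed toward the lower-exposure clusters.  This yields
  a trimodal actual-risk distribution, an actual min–max span near 1.8
  orders of magnitude, and the population-density bias that makes the
  equal-site-weight (traditional) simulation overestimate the mean.
  The urban label sits on the low-exposure cluster so rural geometric
  mean risk exceeds urban.
- **Sex effect.**  A ±0.0868 log-BW location shift between sexes
  (male/female means ≈ 67.7 vs 56.9 kg), carried *inside* the stratum
  log-SD so the marginal keeps the handbook b; heights are sex-specific
  normals used only by the BMR route.
- **IR model.**  Power law of BW with slope 0.679 and 0.1 log-residual
  SD (enough scatter to be realistic while keeping the BW–IR correlation
  obvious, r² ≈ 0.7).  The intercept, −0.0428 in m³·day⁻¹ natural logs,
  is set so the implied IR marginal location equals the handbook
  whole-population location: the handbook and the measured population
  then describe the same marginal IR, and the only difference the
  correlated variant removes is the independence assumption itself.
- **Printed parameter sets.**  The preset carries the participant-level
  exposure lognormal LN(2.419, 1.317) as a named parameter set for
  fit-recovery checks; the end-to-end comparison instead fits the
  concentration distributions from the generated scenario, which is the
  procedure the adjusted variant formalises.

What passing tests on this scenario show: the *mechanisms* — density-
weighted concentration adjustment and correlation substitution each move
the simulated mean toward the actual one, age stratification with
near-identical stratum parameters does not, and concentration dominates
the sensitivity ranking.  What they do not show: real populations have
measurement error, non-lognormal tails, seasonal structure and
congener-level chemistry that the generator deliberately omits (sites
carry annual BaP_eq directly; congener profiles are supported as a
pass-through for the risk arithmetic only).

## Problem sizes and numerics

Default runs use the study-scale sizes throughout — 30,000 iterations,
2,740 participants, 25 sites, 200 fitting replicates — which keep every
check within seconds on one core.  Monte Carlo checks use 3-standard-
error bands (with the SE of a sample SD taken from the sample's own
fourth moment, since ILCR is heavy-tailed); exact identities are
asserted at 1e-9…1e-12; the headline variant ordering is asserted on a
seeded run at the full iteration budget, where the expected effects
(≈ ×2 traditional overestimate, ≈ 7% correlated improvement) are several
times the Monte Carlo noise.  Curve fits are initialized at log-moments
with b bounded positive; weight vectors must sum to 1 within 1e-9;
degenerate inputs (empty collections, constant samples, zero variance,
non-increasing quantiles) raise validation errors rather than returning
NaN.

## Known limitations

- Inhalation route only; no dermal or ingestion pathways, no
  two-dimensional (uncertainty × variability) simulation.
- The nearest-site exposure model ignores within-city mobility and
  indoor/outdoor differences; IDW is provided for surface description,
  not used to refine individual exposure.
- The BMR coefficients and activity levels are population-average
  surrogates; individual IR estimates inherit their bias.
- Lognormality is assumed for all random inputs (gated, not relaxed);
  no other distribution family is implemented.
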