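# pahrisk

Probabilistic carcinogenic-risk assessment for inhalation exposure to
polycyclic aromatic hydrocarbons (PAHs), built for exposure scientists
who want to compare Monte Carlo risk simulations against individually
assessed ("actual") risks and understand which modelling choices matter.

## The model

The carcinogenic potency of a 15-congener PAH mixture is expressed as a
benzo(a)pyrene-equivalent concentration via toxic equivalency factors,

    BaP_eq = Σ_i C_i · TEF_i        (ng·m⁻³)

and the incremental lifetime cancer risk of an exposed adult is

    ILCR = BaP_eq · 10⁻⁶ · IR · EF · ED · CSF / (BW · AT)

with inhalation rate IR (m³·day⁻¹), body weight BW (kg), exposure
frequency EF = 365 day·yr⁻¹, exposure duration ED = 53 yr, averaging
time AT = 70 × 365 day, and the BaP inhalation cancer slope factor
CSF = 3.14 (mg·kg⁻¹·day⁻¹)⁻¹.  Risks are graded against the EPA
thresholds 10⁻⁶ (acceptable) and 10⁻⁴ (serious).

Population risk is simulated by Monte Carlo sampling of lognormal
inputs, LN(a, b) on the natural-log scale.  Site concentrations are
fitted by ranking monitoring data, assigning plotting positions
rank/(n+1), and least-squares fitting the Gaussian CDF; body weight and
inhalation rate are fitted from handbook quantile tables.  Four
simulation variants are provided:

- **traditional** — C, BW, IR drawn independently from whole-population
  lognormals;
- **concentration-adjusted** — C drawn from the lognormal fitted to
  participant-level (population-density-weighted) exposures;
- **age-stratified** — iterations split across age strata in census
  proportion, each stratum with its own BW/IR lognormals;
- **correlated** — IR computed deterministically from the fitted
  power law log IR = slope·log BW + intercept instead of being drawn.

Spearman rank correlations between each input and ILCR quantify
parameter sensitivity, and each simulated risk distribution is graded
against the individually assessed one by mean/median/SD ratios and the
difference in log₁₀ range span.  A synthetic-scenario generator
(25 clustered sites, 2,740 adults) provides a fully reproducible test
bed with the same statistical structure.

## Worked example

Run the full comparison — synthesize a scenario, assess every
participant from their nearest site, fit the input distributions, run
the four variants at 30,000 iterations, and grade them:

```sh
pahrisk pipeline --seed 1 --iterations 30000 --out demo
```

which prints the goodness-of-fit panel (also written to
`demo/gof_panel.json`):

```
               variant        mean          sd      median  mean_ratio  median_ratio  sd_ratio  span_log10_diff  rank
concentration_adjusted 7.22227e-06 7.35022e-06 5.06914e-06    0.974015      0.903232  0.971884          1.23128     1
            correlated 1.46685e-05 3.22378e-05 5.71539e-06     1.97824       1.01838   4.26264          2.95041     2
           traditional  1.5492e-05 4.07422e-05 5.82285e-06     2.08929       1.03753   5.38714          3.66115     3
        age_stratified  1.5569e-05 4.02251e-05 5.89292e-06     2.09968       1.05002   5.31877          3.24372     4
```

Reading the panel: the actual (individually assessed) population risk in
this scenario has mean 7.41 × 10⁻⁶ and median 5.61 × 10⁻⁶
(`demo/actual_summary.json`; every participant exceeds the 10⁻⁶
acceptable level, none reaches 10⁻⁴).  The traditional simulation
overestimates the mean 2.1-fold and the SD 5.4-fold, because it weights
all sites equally while most participants live near lower-exposure
sites, and because it ignores the IR–BW correlation.  Re-fitting the
concentration distribution from participant-level exposures brings the
mean ratio to 0.97; substituting the fitted power law
(slope 0.685, `demo/fits.json`) for independent IR draws improves the
mean ratio to 1.98; stratifying by age alone does not help (2.10).  The
sensitivity file ranks concentration first with Spearman r = 0.976,
against −0.149 for BW and 0.129 for IR.

The same stages are available piecemeal (`pahrisk synth`, `assess`,
`simulate`, `compare`) and as library functions
(`pahrisk.run_paper_pipeline`, `pahrisk.run_mcs`, …).

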