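"""End-to-end study pipeline: synthesize → assess → simulate ×4 → compare.

Reproduces the full comparison design on a synthetic scenario: generate
the monitoring network and population, compute every participant's
"actual" ILCR from nearest-site exposure and measured factors, fit the
input distributions the way a modeller would (plotting-position CDF fit
to the 25 site concentrations, quantile fit to the handbook tables,
log–log regression of IR on BW, CDF fit to the participant-weighted
exposures), run the four Monte Carlo variants, and grade each simulated
risk distribution against the empirical one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .assessment import AssessmentResult, assess_individuals, goodness_of_fit
from .fitting import (
    LogNormalParams,
    PowerLawModel,
    QuantileSet,
    fit_ir_bw_regression,
    fit_lognormal_from_quantiles,
    fit_lognormal_from_samples,
)
from .mcs import (
    AGE_STRATIFIED,
    CONCENTRATION_ADJUSTED,
    CORRELATED,
    TRADITIONAL,
    MCSConfig,
    SensitivityResult,
    SimulationResult,
    StratumParams,
    run_mcs,
    sensitivity_spearman,
)
from .risk_core import ExposureConstants, convert_ir
from .synth import ScenarioSpec, gen_participants, gen_sites, paper_like_scenario, quantiles_from_scenario

__all__ = ["PipelineResult", "child_seed", "fit_quantile_table", "run_paper_pipeline"]


def child_seed(seed: int, index: int) -> int:
    """Deterministic sub-seed (< 2³¹) for stage ``index`` of a run."""
    return int(np.random.SeedSequence([int(seed), int(index)]).generate_state(1)[0] % 2**31)


def fit_quantile_table(quantiles: pd.DataFrame) -> dict[str, dict[str, LogNormalParams]]:
    """Fit LN(a, b) per (stratum, parameter) from a handbook quantile table."""
    fits: dict[str, dict[str, LogNormalParams]] = {}
    for (stratum, parameter), sub in quantiles.groupby(["stratum", "parameter"]):
        sub = sub.sort_values("p")
        qs = QuantileSet(tuple(sub["p"]), tuple(sub["value"]))
        fits.setdefault(str(stratum), {})[str(parameter)] = (
            fit_lognormal_from_quantiles(qs)
        )
    return fits


@dataclass(frozen=True)
class PipelineResult:
    """Everything one end-to-end run produced."""

    spec: ScenarioSpec
    seed: int
    sites: pd.DataFrame
    participants: pd.DataFrame
    assessment: AssessmentResult
    site_fit: LogNormalParams
    exposure_fit: LogNormalParams
    ir_bw_model: PowerLawModel
    handbook_fits: Mapping[str, Mapping[str, LogNormalParams]]
    simulations: Mapping[str, SimulationResult]
    sensitivities: Mapping[str, SensitivityResult]
    panel: pd.DataFrame


def run_paper_pipeline(
    spec: ScenarioSpec | None = None,
    seed: int = 0,
    iterations: int = 30_000,
    constants: ExposureConstants | None = None,
) -> PipelineResult:
    """Run the full four-variant comparison on a synthetic scenario.

    All randomness derives from ``seed`` through per-stage substreams, so
    a run is bit-reproducible.  The grading panel ranks the variants by
    |mean ratio − 1| against the actual (individually assessed) risks.
    """
    spec = spec or paper_like_scenario()
    constants = constants or ExposureConstants()

    sites = gen_sites(spec, child_seed(seed, 0))
    participants = gen_participants(spec, sites, child_seed(seed, 1))
    assessment = assess_individuals(participants, sites, constants)

    site_fit = fit_lognormal_from_samples(sites["bap_eq"])
    exposure_fit = fit_lognormal_from_samples(assessment.table["bap_eq"])
    ir_bw_model = fit_ir_bw_regression(
        participants["bw_kg"],
        convert_ir(participants["ir_lpm"].to_numpy(), "L/min", "m3/day"),
    )
    handbook_fits = fit_quantile_table(quantiles_from_scenario(spec))
    whole = handbook_fits.get("whole", {})
    whole_bw = whole.get("BW", spec.whole_bw)
    whole_ir = whole.get("IR", spec.whole_ir)
    strata = tuple(
        StratumParams(
            label=s.label,
            weight=s.weight,
            bw=handbook_fits[s.label]["BW"],
            ir=handbook_fits[s.label]["IR"],
        )
        for s in spec.strata
    )

    configs = {
        TRADITIONAL: MCSConfig(
            variant=TRADITIONAL,
            concentration=site_fit,
            iterations=iterations,
            seed=child_seed(seed, 2),
            bw=whole_bw,
            ir=whole_ir,
            constants=constants,
        ),
        CONCENTRATION_ADJUSTED: MCSConfig(
            variant=CONCENTRATION_ADJUSTED,
            concentration=exposure_fit,
            iterations=iterations,
            seed=child_seed(seed, 3),
            bw=whole_bw,
            ir=whole_ir,
            constants=constants,
        ),
        AGE_STRATIFIED: MCSConfig(
            variant=AGE_STRATIFIED,
            concentration=site_fit,
            iterations=iterations,
            seed=child_seed(seed, 4),
            strata=strata,
            constants=constants,
        ),
        CORRELATED: MCSConfig(
            variant=CORRELATED,
            concentration=site_fit,
            iterations=iterations,
            seed=child_seed(seed, 5),
            bw=whole_bw,
            ir_model=ir_bw_model,
            constants=constants,
        ),
    }

    simulations = {name: run_mcs(cfg) for name, cfg in configs.items()}
    sensitivities = {
        name: sensitivity_spearman(res) for name, res in simulations.items()
    }
    actual = assessment.table["ilcr"].to_numpy()
    rows = []
    for name, res in simulations.items():
        gof = goodness_of_fit(actual, res.ilcr)
        summary = res.summary()
        rows.append(
            {
                "variant": name,
                "mean": summary["mean"],
                "sd": summary["sd"],
                "median": summary["median"],
                "mean_ratio": gof.mean_ratio,
                "median_ratio": gof.median_ratio,
                "sd_ratio": gof.sd_ratio,
                "span_log10_diff": gof.span_log10_diff,
            }
        )
    panel = pd.DataFrame(rows)
    panel["rank"] = (panel["mean_ratio"] - 1.0).abs().rank(method="first").astype(int)
    panel = panel.sort_values("rank", kind="stable").reset_index(drop=True)

    return PipelineResult(
        spec=spec,
        seed=seed,
        sites=sites,
        participants=participants,
        assessment=assessment,
        site_fit=site_fit,
        exposure_fit=exposure_fit,
        ir_bw_model=ir_bw_model,
        handbook_fits=handbook_fits,
        simulations=simulations,
        sensitivities=sensitivities,
        panel=panel,
    )
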