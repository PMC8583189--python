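"""Monte Carlo simulation of the inhalation-risk distribution.

Four sampling variants, mirroring the study designs they formalise:

traditional
    concentration, body weight and inhalation rate drawn independently
    from whole-population lognormals fitted to monitoring data and
    handbook quantile tables.
concentration_adjusted
    identical, except the concentration lognormal is the one fitted to
    participant-level (population-density-weighted) exposures.
age_stratified
    iterations allocated to age strata in census proportion, each
    stratum sampling its own BW/IR lognormals; outputs pooled.
correlated
    only concentration and body weight are random; the inhalation rate
    is computed deterministically from a fitted IR–BW power law (an
    optional residual term is off by default).

Also provides the iteration-grid convergence check and the Spearman
rank-correlation sensitivity analysis, plus closed-form oracles for the
all-lognormal case (product of independent lognormals; bivariate-normal
Spearman correlation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import LogNormalParams, PowerLawModel
from .risk_core import ExposureConstants, compute_ilcr

__all__ = [
    "VARIANTS",
    "ConfigError",
    "StratumParams",
    "MCSConfig",
    "SimulationResult",
    "SensitivityResult",
    "ConvergenceReport",
    "allocate_iterations",
    "run_mcs",
    "convergence_check",
    "sensitivity_spearman",
    "analytic_ilcr_params",
    "analytic_spearman",
]

TRADITIONAL = "traditional"
CONCENTRATION_ADJUSTED = "concentration_adjusted"
AGE_STRATIFIED = "age_stratified"
CORRELATED = "correlated"
VARIANTS = (TRADITIONAL, CONCENTRATION_ADJUSTED, AGE_STRATIFIED, CORRELATED)

DEFAULT_PERCENTILES = (5, 25, 50, 75, 95)


class ConfigError(ValueError):
    """The simulation configuration is incomplete for the chosen variant."""


@dataclass(frozen=True)
class StratumParams:
    """Per-stratum exposure-factor distributions and census weight."""

    label: str
    weight: float
    bw: LogNormalParams
    ir: LogNormalParams | None = None

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise ValueError(f"stratum weight must be > 0, got {self.weight}")


@dataclass(frozen=True)
class MCSConfig:
    """Variant selector, iteration budget, seed and input distributions."""

    variant: str
    concentration: LogNormalParams
    iterations: int = 30_000
    seed: int = 0
    bw: LogNormalParams | None = None
    ir: LogNormalParams | None = None
    strata: tuple[StratumParams, ...] | None = None
    ir_model: PowerLawModel | None = None
    ir_residual_sd: float = 0.0
    constants: ExposureConstants = field(default_factory=ExposureConstants)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigError(
                f"variant must be one of {VARIANTS}, got {self.variant!r}"
            )
        if self.iterations < 1:
            raise ConfigError("iterations must be >= 1")
        if self.variant in (TRADITIONAL, CONCENTRATION_ADJUSTED):
            if self.bw is None or self.ir is None:
                raise ConfigError(f"{self.variant} variant requires bw and ir")
        elif self.variant == AGE_STRATIFIED:
            if not self.strata:
                raise ConfigError("age_stratified variant requires strata")
            if any(s.ir is None for s in self.strata):
                raise ConfigError("every stratum needs its own ir distribution")
            total = sum(s.weight for s in self.strata)
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"stratum weights must sum to 1, got {total}")
        elif self.variant == CORRELATED:
            if self.bw is None or self.ir_model is None:
                raise ConfigError("correlated variant requires bw and ir_model")
        if self.ir_residual_sd < 0:
            raise ConfigError("ir_residual_sd must be >= 0")


@dataclass(frozen=True)
class SimulationResult:
    """Per-iteration input draws and ILCR outputs of one simulation."""

    variant: str
    seed: int
    concentration: np.ndarray
    bw: np.ndarray
    ir: np.ndarray
    ilcr: np.ndarray
    stratum: np.ndarray | None
    config: MCSConfig

    def __post_init__(self) -> None:
        n = self.ilcr.size
        for name in ("concentration", "bw", "ir"):
            if getattr(self, name).size != n:
                raise ValueError("per-iteration arrays must have equal length")
        if self.stratum is not None and self.stratum.size != n:
            raise ValueError("per-iteration arrays must have equal length")

    @property
    def iterations(self) -> int:
        return int(self.ilcr.size)

    def summary(self, percentiles: Sequence[float] = DEFAULT_PERCENTILES) -> dict:
        x = self.ilcr
        out = {
            "variant": self.variant,
            "n": int(x.size),
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
            "median": float(np.median(x)),
            "min": float(np.min(x)),
            "max": float(np.max(x)),
            "percentiles": {
                f"p{p:g}": float(np.percentile(x, p)) for p in percentiles
            },
        }
        return out

    def to_frame(self) -> pd.DataFrame:
        data = {
            "iteration": np.arange(self.ilcr.size),
            "concentration": self.concentration,
            "bw": self.bw,
            "ir": self.ir,
            "ilcr": self.ilcr,
        }
        if self.stratum is not None:
            data["stratum"] = self.stratum
        return pd.DataFrame(data)


@dataclass(frozen=True)
class SensitivityResult:
    """Spearman rank correlation of each input with ILCR, ranked by |r|."""

    correlations: Mapping[str, float]
    ranking: tuple[str, ...]

    @property
    def top(self) -> str:
        return self.ranking[0]


@dataclass(frozen=True)
class ConvergenceReport:
    """Summary statistics along the iteration grid plus the converged flag."""

    table: pd.DataFrame
    tolerance: float
    converged: bool
    converged_at: int | None


def allocate_iterations(total: int, weights: Sequence[float]) -> np.ndarray:
    """Largest-remainder allocation of ``total`` iterations to strata.

    Counts sum exactly to ``total``; ties in remainders resolved toward
    the earlier stratum after sorting by remainder.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.size == 0:
        raise ValueError("at least one stratum required")
    if np.any(weights <= 0):
        raise ValueError("stratum weights must be strictly positive")
    if total < weights.size:
        raise ValueError("total iterations must cover every stratum")
    weights = weights / weights.sum()
    quotas = weights * total
    counts = np.floor(quotas).astype(int)
    remainder = int(total - counts.sum())
    if remainder:
        order = np.argsort(-(quotas - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts


def _draw(params: LogNormalParams, n: int, rng: np.random.Generator) -> np.ndarray:
    if params.b == 0:
        return np.full(n, math.exp(params.a))
    return params.sample(n, rng)


def run_mcs(config: MCSConfig) -> SimulationResult:
    """Run one seeded simulation; identical config + seed is bit-reproducible."""
    n = config.iterations
    stratum = None
    if config.variant in (TRADITIONAL, CONCENTRATION_ADJUSTED):
        rng = np.random.default_rng(config.seed)
        conc = _draw(config.concentration, n, rng)
        bw = _draw(config.bw, n, rng)
        ir = _draw(config.ir, n, rng)
    elif config.variant == CORRELATED:
        rng = np.random.default_rng(config.seed)
        conc = _draw(config.concentration, n, rng)
        bw = _draw(config.bw, n, rng)
        ir = config.ir_model.predict(bw)
        if config.ir_residual_sd > 0:
            ir = ir * np.exp(rng.normal(0.0, config.ir_residual_sd, size=n))
    else:  # AGE_STRATIFIED: per-stratum substreams off the master seed so
        # changing the allocation of one stratum does not reshuffle others.
        counts = allocate_iterations(n, [s.weight for s in config.strata])
        children = np.random.SeedSequence(config.seed).spawn(len(config.strata))
        parts_c, parts_b, parts_i, labels = [], [], [], []
        for spec, count, child in zip(config.strata, counts, children):
            # one substream per stratum and variable, so reallocating
            # iterations leaves every stratum's draw prefix unchanged
            rng_c, rng_b, rng_i = map(np.random.default_rng, child.spawn(3))
            parts_c.append(_draw(config.concentration, count, rng_c))
            parts_b.append(_draw(spec.bw, count, rng_b))
            parts_i.append(_draw(spec.ir, count, rng_i))
            labels.append(np.full(count, spec.label, dtype=object))
        conc = np.concatenate(parts_c)
        bw = np.concatenate(parts_b)
        ir = np.concatenate(parts_i)
        stratum = np.concatenate(labels)
    ilcr = compute_ilcr(conc, ir, bw, config.constants)
    return SimulationResult(
        variant=config.variant,
        seed=config.seed,
        concentration=conc,
        bw=bw,
        ir=ir,
        ilcr=np.asarray(ilcr),
        stratum=stratum,
        config=config,
    )


def convergence_check(
    config: MCSConfig,
    grid: Sequence[int] | None = None,
    tolerance: float = 0.02,
) -> ConvergenceReport:
    """Stability of the simulated mean along an ascending iteration grid.

    One long run at the largest grid point is evaluated cumulatively at
    each checkpoint (a common-stream policy, so successive means share
    their draws).  The run is converged at the earliest grid point from
    which every successive relative change of the mean stays below the
    tolerance (default 2%).
    """
    if grid is None:
        grid = tuple(range(5_000, 50_001, 5_000))
    grid = [int(g) for g in grid]
    if len(grid) < 2:
        raise ValueError("convergence grid needs at least two points")
    if any(g2 <= g1 for g1, g2 in zip(grid, grid[1:])) or grid[0] < 1:
        raise ValueError("convergence grid must be ascending and positive")
    result = run_mcs(replace(config, iterations=grid[-1]))
    means = np.array([result.ilcr[:g].mean() for g in grid])
    sds = np.array([result.ilcr[:g].std(ddof=1) for g in grid])
    rel = np.full(len(grid), np.nan)
    rel[1:] = np.abs(np.diff(means)) / np.abs(means[:-1])
    converged_at = None
    for j in range(len(grid)):
        if np.all(rel[max(j, 1):] < tolerance):
            converged_at = grid[j]
            break
    table = pd.DataFrame(
        {"iterations": grid, "mean": means, "sd": sds, "rel_change": rel}
    )
    return ConvergenceReport(
        table=table,
        tolerance=tolerance,
        converged=converged_at is not None,
        converged_at=converged_at,
    )


def sensitivity_spearman(result: SimulationResult) -> SensitivityResult:
    """Spearman rank correlation (averaged ranks on ties) of inputs with ILCR.

    A constant input has no defined rank correlation and is reported as
    NaN, ranked last.
    """
    inputs = {
        "concentration": result.concentration,
        "bw": result.bw,
        "ir": result.ir,
    }
    correlations: dict[str, float] = {}
    for name, values in inputs.items():
        if np.ptp(values) == 0 or np.ptp(result.ilcr) == 0:
            correlations[name] = float("nan")
        else:
            rho = stats.spearmanr(values, result.ilcr).statistic
            correlations[name] = float(rho)
    ranking = tuple(
        sorted(
            correlations,
            key=lambda k: (math.isnan(correlations[k]), -abs(correlations[k])),
        )
    )
    return SensitivityResult(correlations=correlations, ranking=ranking)


def analytic_ilcr_params(
    concentration: LogNormalParams,
    bw: LogNormalParams,
    ir: LogNormalParams,
    constants: ExposureConstants | None = None,
) -> LogNormalParams:
    """Exact ILCR lognormal for independent lognormal C, BW, IR.

    ln ILCR = ln k + ln C + ln IR − ln BW with k the deterministic dose
    factor, so ILCR ~ LN(ln k + a_C + a_IR − a_BW, √(b_C² + b_IR² + b_BW²)).
    """
    if constants is None:
        constants = ExposureConstants()
    mu = math.log(constants.dose_factor) + concentration.a + ir.a - bw.a
    sigma = math.sqrt(concentration.b**2 + ir.b**2 + bw.b**2)
    return LogNormalParams(a=mu, b=sigma, method="analytic")


def analytic_spearman(sigma_input: float, sigma_total: float, sign: float = 1.0) -> float:
    """Population Spearman correlation of one log-input with log-output.

    For jointly normal variables with Pearson correlation rho the Spearman
    coefficient is (6/pi)·arcsin(rho/2); here rho = ±sigma_input/sigma_total
    with sigma_total the SD of the log output.
    """
    rho = sign * sigma_input / sigma_total
    return 6.0 / math.pi * math.asin(rho / 2.0)
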