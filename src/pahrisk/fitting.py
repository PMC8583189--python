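"""Lognormal exposure-factor estimation.

Two routes to LN(a, b) parameters — a is the mean and b the SD of the
natural-log-transformed variable — plus a Shapiro-Wilk log-normality gate,
the IR–BW power-law regression and a basal-metabolic-rate estimator for
individual inhalation rates.

Route 1 (raw monitoring samples): rank the data, assign plotting
positions rank/(n+1), and least-squares fit the Gaussian CDF to the
(log value, plotting position) pairs.  Route 2 (handbook quantile
tables): regress log value on the standard-normal quantile of the tabled
probability; exact inversion when the pairs lie on a lognormal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .risk_core import convert_ir

__all__ = [
    "LogNormalParams",
    "QuantileSet",
    "PowerLawModel",
    "NormalityReport",
    "plotting_positions",
    "fit_lognormal_from_samples",
    "fit_lognormal_from_quantiles",
    "normality_gate",
    "fit_ir_bw_regression",
    "estimate_ir_from_bmr",
]


@dataclass(frozen=True)
class LogNormalParams:
    """Natural-log location/scale of a lognormal variable, LN(a, b).

    ``a`` is the mean and ``b`` the standard deviation of ln X.  ``r2``
    is the goodness of the CDF (or quantile-line) fit when the parameters
    were estimated from data.  ``b = 0`` denotes a degenerate point mass
    at exp(a), accepted for zero-variance scenario configurations;
    fitting routines always return b > 0.
    """

    a: float
    b: float
    r2: float | None = None
    method: str = "specified"

    def __post_init__(self) -> None:
        if not self.b >= 0:
            raise ValueError(f"b must be >= 0, got {self.b}")
        if self.r2 is not None and not 0.0 <= self.r2 <= 1.0:
            raise ValueError(f"r2 must lie in [0, 1], got {self.r2}")

    @property
    def median(self) -> float:
        return math.exp(self.a)

    @property
    def mean(self) -> float:
        return math.exp(self.a + self.b**2 / 2.0)

    @property
    def sd(self) -> float:
        return self.mean * math.sqrt(math.expm1(self.b**2))

    def quantile(self, p):
        return np.exp(self.a + self.b * stats.norm.ppf(p))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.lognormal(mean=self.a, sigma=self.b, size=n)


@dataclass(frozen=True)
class QuantileSet:
    """Ordered (probability, value) pairs, e.g. quartiles and the median."""

    probs: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        probs = tuple(float(p) for p in self.probs)
        values = tuple(float(v) for v in self.values)
        if len(probs) != len(values):
            raise ValueError("probs and values must have equal length")
        if len(probs) < 2:
            raise ValueError("at least two quantile pairs required")
        if any(not 0.0 < p < 1.0 for p in probs):
            raise ValueError("probabilities must lie strictly in (0, 1)")
        if any(q >= r for q, r in zip(probs, probs[1:])):
            raise ValueError("probabilities must be strictly increasing")
        if any(u >= v for u, v in zip(values, values[1:])):
            raise ValueError("quantile values must be strictly increasing")
        if values[0] <= 0:
            raise ValueError("quantile values must be positive")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class PowerLawModel:
    """IR = exp(intercept) · BW^slope with Gaussian log-residuals.

    The slope is invariant to the log base used upstream; the intercept is
    stored on the natural-log scale in the inhalation-rate unit noted in
    ``ir_unit`` (m³·day⁻¹ by internal convention).
    """

    slope: float
    intercept: float
    residual_sd: float = 0.0
    n: int | None = None
    r2: float | None = None
    ir_unit: str = "m3/day"

    def __post_init__(self) -> None:
        if not self.residual_sd >= 0:
            raise ValueError("residual_sd must be >= 0")

    def predict(self, bw):
        """Deterministic IR (model units) at body weight ``bw`` (kg)."""
        return np.exp(self.intercept + self.slope * np.log(bw))


@dataclass(frozen=True)
class NormalityReport:
    """Shapiro-Wilk result on the log scale; ``passed`` = (p > alpha)."""

    statistic: float
    pvalue: float
    passed: bool
    alpha: float = 0.05


def plotting_positions(values) -> np.ndarray:
    """Empirical cumulative proportions rank/(n+1), ties given averaged ranks.

    Returned in the input order of ``values``; strictly inside (0, 1) and
    summing to n/2 for any input.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("plotting_positions requires at least one value")
    ranks = stats.rankdata(values, method="average")
    return ranks / (values.size + 1)


def _validate_positive_samples(values, minimum: int, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.size < minimum:
        raise ValueError(f"{name} requires at least {minimum} values")
    if not np.all(np.isfinite(values)) or np.any(values <= 0):
        raise ValueError(f"{name} requires finite, strictly positive values")
    return values


def fit_lognormal_from_samples(values, method: str = "cdf") -> LogNormalParams:
    """Estimate LN(a, b) from raw positive samples.

    ``method="cdf"`` (default): least-squares fit of the Gaussian CDF to
    (ln value, plotting position) pairs — the cumulative-probability
    fitting convention used with monitoring data.  ``method="mle"``:
    maximum likelihood, i.e. mean/SD of the log data.  Both report the r²
    of the CDF curve as the fit diagnostic.
    """
    values = _validate_positive_samples(values, 5, "fit_lognormal_from_samples")
    logs = np.log(values)
    if np.ptp(logs) == 0:
        raise ValueError("degenerate sample: all values are equal")
    positions = plotting_positions(values)
    order = np.argsort(logs, kind="stable")
    x, y = logs[order], positions[order]
    a0, b0 = float(np.mean(logs)), float(np.std(logs, ddof=0))
    if method == "mle":
        a, b = a0, b0
    elif method == "cdf":
        (a, b), _ = optimize.curve_fit(
            stats.norm.cdf,
            x,
            y,
            p0=(a0, b0),
            bounds=((-np.inf, 1e-12), (np.inf, np.inf)),
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    residuals = y - stats.norm.cdf(x, loc=a, scale=b)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(residuals**2)) / ss_tot
    return LogNormalParams(
        a=float(a), b=float(b), r2=float(np.clip(r2, 0.0, 1.0)), method="samples"
    )


def fit_lognormal_from_quantiles(quantiles: QuantileSet) -> LogNormalParams:
    """Estimate LN(a, b) from tabled quantiles.

    Regresses ln(value) on the standard-normal quantile z(p); the slope is
    b and the intercept a.  Exact (to rounding) when the pairs come from
    one lognormal, as handbook quartile tables do.
    """
    if not isinstance(quantiles, QuantileSet):
        probs, values = zip(*quantiles)
        quantiles = QuantileSet(tuple(probs), tuple(values))
    z = stats.norm.ppf(quantiles.probs)
    logv = np.log(quantiles.values)
    b, a = np.polyfit(z, logv, 1)
    fitted = a + b * z
    ss_tot = float(np.sum((logv - logv.mean()) ** 2))
    r2 = 1.0 if len(z) == 2 else 1.0 - float(np.sum((logv - fitted) ** 2)) / ss_tot
    return LogNormalParams(
        a=float(a), b=float(b), r2=float(np.clip(r2, 0.0, 1.0)), method="quantiles"
    )


def normality_gate(values, alpha: float = 0.05) -> NormalityReport:
    """Shapiro-Wilk test of log-normality for positive samples (3 ≤ n ≤ 5000)."""
    values = _validate_positive_samples(values, 3, "normality_gate")
    if values.size > 5000:
        raise ValueError("normality_gate supports at most 5000 values")
    logs = np.log(values)
    if np.ptp(logs) == 0:
        raise ValueError("degenerate sample: all values are equal")
    statistic, pvalue = stats.shapiro(logs)
    return NormalityReport(
        statistic=float(statistic),
        pvalue=float(pvalue),
        passed=bool(pvalue > alpha),
        alpha=alpha,
    )


def fit_ir_bw_regression(bw, ir, ir_unit: str = "m3/day") -> PowerLawModel:
    """Ordinary least squares of ln IR on ln BW.

    Returns the power-law exponent (base-invariant), the natural-log
    intercept in the supplied IR unit, and the residual SD in log units
    (ddof = 2).  Requires n ≥ 3 with non-degenerate body weights.
    """
    bw = _validate_positive_samples(bw, 3, "fit_ir_bw_regression")
    ir = _validate_positive_samples(ir, 3, "fit_ir_bw_regression")
    if bw.size != ir.size:
        raise ValueError("bw and ir must have equal length")
    log_bw, log_ir = np.log(bw), np.log(ir)
    if np.ptp(log_bw) == 0:
        raise ValueError("zero variance in log BW: slope undefined")
    fit = stats.linregress(log_bw, log_ir)
    residuals = log_ir - (fit.intercept + fit.slope * log_bw)
    n = bw.size
    residual_sd = float(np.sqrt(np.sum(residuals**2) / (n - 2))) if n > 2 else 0.0
    return PowerLawModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        residual_sd=residual_sd,
        n=int(n),
        r2=float(fit.rvalue**2),
        ir_unit=ir_unit,
    )


# Schofield-type weight-only BMR coefficients, MJ·day⁻¹ = c·BW + d,
# banded by sex and age (16–<30, 30–<60, 60+).
_BMR_BANDS = {
    "male": ((30, 0.063, 2.896), (60, 0.048, 3.653), (101, 0.049, 2.459)),
    "female": ((30, 0.062, 2.036), (60, 0.034, 3.538), (101, 0.038, 2.755)),
}


def estimate_ir_from_bmr(
    bw: float,
    height: float,
    age: float,
    sex: str,
    *,
    pal: float = 2.0,
    oxygen_l_per_kj: float = 0.0502,
    ventilatory_equivalent: float = 27.0,
) -> float:
    """Inhalation rate (L·min⁻¹) from the basal-metabolic-rate method.

    BMR (MJ·day⁻¹) comes from sex/age-banded linear equations in body
    weight; daily energy expenditure is BMR × PAL (physical activity
    level); ventilation is expenditure × oxygen uptake per kJ ×
    ventilatory equivalent (L air per L O₂).  Deterministic for a fixed
    coefficient set.  Height is validated for plausibility; the default
    weight-only bands do not use it.
    """
    if not 20 <= bw <= 200:
        raise ValueError(f"body weight {bw} kg outside plausible range [20, 200]")
    if not 100 <= height <= 230:
        raise ValueError(f"height {height} cm outside plausible range [100, 230]")
    if not 16 <= age <= 100:
        raise ValueError(f"age {age} outside supported range [16, 100]")
    key = sex.strip().lower()
    if key in ("m", "male"):
        bands = _BMR_BANDS["male"]
    elif key in ("f", "female"):
        bands = _BMR_BANDS["female"]
    else:
        raise ValueError(f"sex must be male or female, got {sex!r}")
    for upper, c, d in bands:
        if age < upper:
            bmr_mj = c * bw + d
            break
    energy_kj = bmr_mj * 1000.0 * pal
    ir_m3_day = energy_kj * oxygen_l_per_kj * ventilatory_equivalent / 1000.0
    return convert_ir(ir_m3_day, "m3/day", "L/min")
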