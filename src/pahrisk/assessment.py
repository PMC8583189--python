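"""Individual ("actual") risk assessment and model-vs-measured grading.

Each participant's ILCR is computed from the annual BaP-equivalent
concentration of their nearest monitoring site, their measured body
weight, and their measured or BMR-estimated inhalation rate.  The
resulting empirical distribution is the reference against which the
Monte Carlo variants are graded: ratios of mean, median and SD
(simulated ÷ actual) plus the difference in range span (log₁₀ orders of
magnitude), and Kruskal-Wallis subgroup contrasts with geometric means.

Tables are plain pandas DataFrames.  Site tables need ``site_id``,
``x``, ``y`` and either a ``bap_eq`` column or per-congener
concentration columns; participant tables need ``id``, ``age``, ``sex``,
``height_cm``, ``bw_kg`` and either coordinates or a pre-assigned
``site_id`` (``ir_lpm`` is optional and estimated from body metrics when
absent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.spatial.distance import cdist

from .fitting import estimate_ir_from_bmr
from .risk_core import (
    ExposureConstants,
    RiskClass,
    TEFTable,
    classify_risk,
    compute_ilcr,
    convert_ir,
)

__all__ = [
    "GoFReport",
    "SubgroupComparison",
    "AssessmentResult",
    "DensityReport",
    "assign_nearest_site",
    "assess_individuals",
    "compare_subgroups",
    "idw_surface",
    "goodness_of_fit",
    "risk_density",
]


@dataclass(frozen=True)
class GoFReport:
    """Simulated ÷ actual ratios of location/spread, plus range-span gap.

    ``span_log10_diff`` is log10(max/min) of the simulated sample minus
    the same quantity for the actual sample — "orders of magnitude
    larger" when positive.
    """

    mean_ratio: float
    median_ratio: float
    sd_ratio: float
    span_log10_diff: float

    def to_dict(self) -> dict:
        return {
            "mean_ratio": self.mean_ratio,
            "median_ratio": self.median_ratio,
            "sd_ratio": self.sd_ratio,
            "span_log10_diff": self.span_log10_diff,
        }


@dataclass(frozen=True)
class SubgroupComparison:
    """Kruskal-Wallis contrast of ILCR across the levels of one factor."""

    factor: str
    groups: dict
    statistic: float
    pvalue: float


@dataclass(frozen=True)
class AssessmentResult:
    """Participant table with assigned exposure and ILCR, plus summary."""

    table: pd.DataFrame
    summary: dict
    unresolved: tuple


@dataclass(frozen=True)
class DensityReport:
    """Kernel-density description of a risk distribution on the log10 scale."""

    grid: np.ndarray
    density: np.ndarray
    n_modes: int
    mode_locations: tuple


def _site_bap_eq(sites: pd.DataFrame, tefs: TEFTable | None) -> pd.Series:
    if "bap_eq" in sites.columns:
        values = sites["bap_eq"].astype(float)
    else:
        table = tefs if tefs is not None else TEFTable()
        congeners = [c for c in sites.columns if c in table]
        if not congeners:
            raise ValueError(
                "site table needs a bap_eq column or congener concentration columns"
            )
        values = sum(sites[c].astype(float) * table[c] for c in congeners)
    if (values < 0).any():
        raise ValueError("site BaP_eq concentrations must be >= 0")
    return values


def assign_nearest_site(
    participants: pd.DataFrame,
    sites: pd.DataFrame,
    tefs: TEFTable | None = None,
) -> pd.DataFrame:
    """Euclidean-nearest site per participant in projected coordinates.

    Pre-assigned ``site_id`` values are honoured unchanged.  Exact
    distance ties resolve to the lexicographically smallest site id.
    Returns a frame indexed like ``participants`` with ``site_id`` and
    ``bap_eq`` columns.
    """
    if sites.empty:
        raise ValueError("at least one site is required")
    sites = sites.sort_values("site_id", kind="stable").reset_index(drop=True)
    bap = _site_bap_eq(sites, tefs)
    lookup = pd.Series(bap.values, index=sites["site_id"].values)

    assigned = pd.Series(pd.NA, index=participants.index, dtype=object)
    if "site_id" in participants.columns:
        assigned = participants["site_id"].where(participants["site_id"].notna())
    needs = assigned.isna()
    if needs.any():
        if not {"x", "y"}.issubset(participants.columns):
            raise ValueError(
                "participants without a site_id need x/y coordinates"
            )
        coords = participants.loc[needs, ["x", "y"]].to_numpy(dtype=float)
        site_xy = sites[["x", "y"]].to_numpy(dtype=float)
        # argmin returns the first minimum; sites are sorted by id, so exact
        # ties fall to the smallest site id.
        nearest = cdist(coords, site_xy).argmin(axis=1)
        assigned.loc[needs] = sites["site_id"].values[nearest]
    unknown = set(assigned.dropna()) - set(lookup.index)
    if unknown:
        raise ValueError(f"participants reference unknown sites: {sorted(unknown)}")
    return pd.DataFrame(
        {"site_id": assigned, "bap_eq": assigned.map(lookup).astype(float)},
        index=participants.index,
    )


def _participant_ir_m3(row: pd.Series) -> float:
    ir_lpm = row.get("ir_lpm")
    if ir_lpm is not None and not pd.isna(ir_lpm):
        return convert_ir(float(ir_lpm), "L/min", "m3/day")
    estimated = estimate_ir_from_bmr(
        float(row["bw_kg"]), float(row["height_cm"]), float(row["age"]), row["sex"]
    )
    return convert_ir(estimated, "L/min", "m3/day")


def assess_individuals(
    participants: pd.DataFrame,
    sites: pd.DataFrame,
    constants: ExposureConstants | None = None,
    tefs: TEFTable | None = None,
    strict: bool = False,
) -> AssessmentResult:
    """Per-participant ILCR from nearest-site exposure and measured factors.

    Participants that cannot be resolved (missing coordinates/site or
    out-of-range body metrics) are collected into ``unresolved`` and
    skipped, unless ``strict`` is true, in which case the first failure
    raises.  The summary reports n, mean, SD, median, min, max, geometric
    mean and risk-class counts.
    """
    if participants.empty:
        raise ValueError("participant table is empty")
    constants = constants or ExposureConstants()
    table = participants.copy()
    unresolved: list[tuple] = []
    try:
        assignment = assign_nearest_site(table, sites, tefs)
    except ValueError:
        if strict:
            raise
        # fall back to row-by-row assignment so resolvable rows survive
        assignment = pd.DataFrame(
            {"site_id": pd.NA, "bap_eq": np.nan}, index=table.index
        )
        for idx in table.index:
            try:
                assignment.loc[idx] = assign_nearest_site(
                    table.loc[[idx]], sites, tefs
                ).iloc[0]
            except (ValueError, KeyError) as exc:
                unresolved.append((table.at[idx, "id"], str(exc)))
    table[["site_id", "bap_eq"]] = assignment

    ir_m3 = pd.Series(np.nan, index=table.index, dtype=float)
    for idx, row in table.iterrows():
        if pd.isna(table.at[idx, "bap_eq"]):
            continue
        try:
            ir_m3.at[idx] = _participant_ir_m3(row)
        except ValueError as exc:
            if strict:
                raise
            unresolved.append((row["id"], str(exc)))
    table["ir_m3_day"] = ir_m3

    ok = table["bap_eq"].notna() & table["ir_m3_day"].notna()
    if strict and not ok.all():
        bad = table.loc[~ok, "id"].tolist()
        raise ValueError(f"unresolvable participants: {bad}")
    table = table.loc[ok].copy()
    if table.empty:
        raise ValueError("no participant could be resolved")
    table["ilcr"] = compute_ilcr(
        table["bap_eq"].to_numpy(),
        table["ir_m3_day"].to_numpy(),
        table["bw_kg"].to_numpy(dtype=float),
        constants,
    )
    table["risk_class"] = [classify_risk(v).value for v in table["ilcr"]]

    x = table["ilcr"].to_numpy()
    summary = {
        "n": int(x.size),
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        "median": float(np.median(x)),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "geomean": float(np.exp(np.mean(np.log(x)))),
        "risk_class_counts": {
            cls.value: int((table["risk_class"] == cls.value).sum())
            for cls in RiskClass
        },
        "n_unresolved": len(unresolved),
    }
    return AssessmentResult(
        table=table, summary=summary, unresolved=tuple(unresolved)
    )


def compare_subgroups(
    participants: pd.DataFrame,
    factor: str,
    value_col: str = "ilcr",
) -> SubgroupComparison:
    """Kruskal-Wallis rank test of ILCR across the levels of ``factor``.

    Requires at least two groups with at least two members each; reports
    per-group n and geometric mean alongside H and p.
    """
    if factor not in participants.columns:
        raise ValueError(f"unknown grouping factor {factor!r}")
    grouped = {
        str(label): sub[value_col].to_numpy(dtype=float)
        for label, sub in participants.groupby(factor, observed=True)
    }
    if len(grouped) < 2:
        raise ValueError("subgroup comparison needs at least two groups")
    if any(v.size < 2 for v in grouped.values()):
        raise ValueError("every group needs at least two members")
    statistic, pvalue = stats.kruskal(*grouped.values())
    groups = {
        label: {"n": int(v.size), "geomean": float(np.exp(np.mean(np.log(v))))}
        for label, v in grouped.items()
    }
    return SubgroupComparison(
        factor=factor,
        groups=groups,
        statistic=float(statistic),
        pvalue=float(pvalue),
    )


def idw_surface(
    sites: pd.DataFrame,
    x_nodes: Sequence[float],
    y_nodes: Sequence[float],
    power: float = 2.0,
    tefs: TEFTable | None = None,
) -> pd.DataFrame:
    """Inverse-distance-weighted BaP_eq surface on a rectangular grid.

    Node value = Σ wᵢvᵢ / Σ wᵢ with wᵢ = dᵢ^(−power); a node coincident
    with a site takes that site's value exactly (smallest site id if
    several coincide).  Returns long-format columns x, y, value.
    """
    if sites.empty:
        raise ValueError("at least one site is required")
    if not power > 0:
        raise ValueError("power must be > 0")
    x_nodes = np.asarray(x_nodes, dtype=float)
    y_nodes = np.asarray(y_nodes, dtype=float)
    if x_nodes.size == 0 or y_nodes.size == 0:
        raise ValueError("grid must be non-empty")
    sites = sites.sort_values("site_id", kind="stable").reset_index(drop=True)
    values = _site_bap_eq(sites, tefs).to_numpy(dtype=float)
    site_xy = sites[["x", "y"]].to_numpy(dtype=float)
    gx, gy = np.meshgrid(x_nodes, y_nodes, indexing="ij")
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    d = cdist(nodes, site_xy)
    out = np.empty(nodes.shape[0])
    exact = d == 0.0
    has_exact = exact.any(axis=1)
    if has_exact.any():
        out[has_exact] = values[exact[has_exact].argmax(axis=1)]
    rest = ~has_exact
    if rest.any():
        w = d[rest] ** (-power)
        out[rest] = (w * values).sum(axis=1) / w.sum(axis=1)
    return pd.DataFrame({"x": nodes[:, 0], "y": nodes[:, 1], "value": out})


def goodness_of_fit(actual, simulated) -> GoFReport:
    """Grade a simulated risk sample against the empirical one.

    Ratios are simulated ÷ actual for the arithmetic mean, the median and
    the SD (ddof = 1); the range comparison is the difference of
    log₁₀(max/min) spans.  Identical samples give the identity report.
    """
    actual = np.asarray(actual, dtype=float)
    simulated = np.asarray(simulated, dtype=float)
    if actual.size == 0 or simulated.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.any(actual <= 0) or np.any(simulated <= 0):
        raise ValueError("risk samples must be strictly positive")

    def _sd(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1)) if x.size > 1 else 0.0

    def _span(x: np.ndarray) -> float:
        return math.log10(float(np.max(x)) / float(np.min(x)))

    return GoFReport(
        mean_ratio=float(np.mean(simulated) / np.mean(actual)),
        median_ratio=float(np.median(simulated) / np.median(actual)),
        sd_ratio=_sd(simulated) / _sd(actual) if _sd(actual) > 0 else math.inf,
        span_log10_diff=_span(simulated) - _span(actual),
    )


def risk_density(
    values,
    n_grid: int = 256,
    prominence_fraction: float = 0.05,
) -> DensityReport:
    """Descriptive kernel-density report of a risk sample (log10 scale).

    Gaussian KDE with Scott bandwidth; modes counted as local maxima
    whose prominence exceeds ``prominence_fraction`` of the density peak.
    Descriptive only — no formal multimodality test is implied.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3 or np.any(values <= 0):
        raise ValueError("risk_density needs >= 3 strictly positive values")
    logs = np.log10(values)
    kde = stats.gaussian_kde(logs)
    lo, hi = logs.min(), logs.max()
    pad = 0.1 * (hi - lo) if hi > lo else 1.0
    grid = np.linspace(lo - pad, hi + pad, n_grid)
    density = kde(grid)
    peaks, _ = signal.find_peaks(
        density, prominence=prominence_fraction * density.max()
    )
    return DensityReport(
        grid=grid,
        density=density,
        n_modes=int(peaks.size),
        mode_locations=tuple(float(g) for g in grid[peaks]),
    )
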