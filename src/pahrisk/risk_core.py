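"""Deterministic exposure arithmetic for inhalation cancer-risk assessment.

BaP-equivalent (TEF) weighting of PAH congener mixtures, the incremental
lifetime cancer risk (ILCR) equation, inhalation-rate unit conversion,
annual averaging of seasonal profiles, and EPA-style risk classification.

Units follow field convention: concentrations in ng·m⁻³, inhalation rate
in m³·day⁻¹ inside the ILCR equation (L·min⁻¹ at the measurement
boundary), body weight in kg, ILCR as a dimensionless lifetime
probability.  The ng→mg factor is an explicit field of
:class:`ExposureConstants` so the equation is dimensionally auditable.
"""

from __future__ import annotations

import enum
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PRIORITY_CONGENERS",
    "NISBET_LAGOY_TEFS",
    "GASEOUS",
    "PARTICULATE",
    "PHASES",
    "ACCEPTABLE_RISK",
    "SERIOUS_RISK",
    "TEFTable",
    "PAHProfile",
    "ExposureConstants",
    "RiskClass",
    "compute_bap_eq",
    "compute_ilcr",
    "classify_risk",
    "convert_ir",
    "annualize",
]

#: The 15 priority PAH congeners resolved by GC-MS in ambient monitoring.
PRIORITY_CONGENERS: tuple[str, ...] = (
    "Ace", "Acy", "Flo", "Phe", "Ant", "Fla", "Pyr", "BaA", "Chr",
    "BbF", "BkF", "BaP", "DahA", "IcdP", "BghiP",
)

#: Default toxic equivalency factors (potency relative to BaP),
#: Nisbet–LaGoy-style scheme.  Override via :class:`TEFTable` where a
#: different scheme is required.
NISBET_LAGOY_TEFS: Mapping[str, float] = {
    "Ace": 0.001,
    "Acy": 0.001,
    "Flo": 0.001,
    "Phe": 0.001,
    "Ant": 0.01,
    "Fla": 0.001,
    "Pyr": 0.001,
    "BaA": 0.1,
    "Chr": 0.01,
    "BbF": 0.1,
    "BkF": 0.1,
    "BaP": 1.0,
    "DahA": 1.0,
    "IcdP": 0.1,
    "BghiP": 0.01,
}

GASEOUS = "gaseous"
PARTICULATE = "particulate"
PHASES = (GASEOUS, PARTICULATE)

#: EPA acceptable lifetime risk: one additional cancer per million.
ACCEPTABLE_RISK = 1e-6
#: One-in-ten-thousand or greater is considered serious.
SERIOUS_RISK = 1e-4


class MissingTEFError(KeyError):
    """A congener present in a profile has no TEF entry."""


class TEFTable:
    """Mapping congener name → toxic equivalency factor.

    Requires a BaP entry with TEF exactly 1 and all factors positive.  By
    default only the 15 priority congeners are accepted; pass
    ``known_congeners`` to widen or narrow the accepted set.
    """

    def __init__(
        self,
        tefs: Mapping[str, float] | None = None,
        known_congeners: Iterable[str] | None = None,
    ) -> None:
        mapping = dict(NISBET_LAGOY_TEFS if tefs is None else tefs)
        known = frozenset(
            PRIORITY_CONGENERS if known_congeners is None else known_congeners
        )
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise ValueError(f"unknown congener names: {unknown}")
        if "BaP" not in mapping:
            raise ValueError("TEF table must contain a BaP entry")
        if mapping["BaP"] != 1.0:
            raise ValueError("BaP TEF must be exactly 1")
        for name, tef in mapping.items():
            if not tef > 0:
                raise ValueError(f"TEF for {name!r} must be > 0, got {tef}")
        self._tefs = mapping

    def __getitem__(self, congener: str) -> float:
        try:
            return self._tefs[congener]
        except KeyError:
            raise MissingTEFError(f"no TEF for congener {congener!r}") from None

    def __contains__(self, congener: str) -> bool:
        return congener in self._tefs

    def __iter__(self):
        return iter(self._tefs)

    def __len__(self) -> int:
        return len(self._tefs)

    @property
    def congeners(self) -> tuple[str, ...]:
        return tuple(self._tefs)

    def as_dict(self) -> dict[str, float]:
        return dict(self._tefs)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"TEFTable({self._tefs!r})"


@dataclass(frozen=True)
class PAHProfile:
    """Per-congener concentrations (ng·m⁻³) for one phase at one site/period."""

    site_id: str
    phase: str
    period: str
    concentrations: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(
                f"phase must be one of {PHASES}, got {self.phase!r}"
            )
        for name, conc in self.concentrations.items():
            if not math.isfinite(conc) or conc < 0:
                raise ValueError(
                    f"concentration for {name!r} must be finite and >= 0, got {conc}"
                )
        object.__setattr__(self, "concentrations", dict(self.concentrations))


@dataclass(frozen=True)
class ExposureConstants:
    """Fixed exposure factors of the inhalation ILCR equation.

    ef
        exposure frequency, day·yr⁻¹ (default 365).
    ed
        exposure duration, yr (default 53, adult residential).
    at
        averaging time, day (default 70 yr × 365).
    csf
        inhalation cancer slope factor for BaP, per mg·kg⁻¹·day⁻¹
        (default 3.14).
    ng_to_mg
        mass-unit scale factor taking ng·m⁻³ concentrations to the mg
        basis of the slope factor.
    """

    ef: float = 365.0
    ed: float = 53.0
    at: float = 70.0 * 365.0
    csf: float = 3.14
    ng_to_mg: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("ef", "ed", "at", "csf", "ng_to_mg"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def dose_factor(self) -> float:
        """ng_to_mg · EF · ED · CSF / AT — ILCR per (ng·m⁻³ · m³·day⁻¹ / kg)."""
        return self.ng_to_mg * self.ef * self.ed * self.csf / self.at


class RiskClass(enum.Enum):
    """EPA-style lifetime-risk classes with thresholds 1e-6 and 1e-4."""

    BELOW_ACCEPTABLE = "below_acceptable"
    EXCEEDS_ACCEPTABLE = "exceeds_acceptable"
    SERIOUS = "serious"


def compute_bap_eq(
    profiles: PAHProfile | Iterable[PAHProfile],
    tefs: TEFTable | None = None,
) -> float:
    """TEF-weighted BaP-equivalent concentration, Σᵢ Cᵢ·TEFᵢ (ng·m⁻³).

    Sums over congeners and over every profile supplied, so passing the
    gaseous and particulate profiles of one site/period yields the total
    (gas + particulate) BaP_eq.  A congener without a TEF entry raises
    :class:`MissingTEFError` naming the congener.
    """
    if tefs is None:
        tefs = TEFTable()
    if isinstance(profiles, PAHProfile):
        profiles = [profiles]
    total = 0.0
    for profile in profiles:
        for name, conc in profile.concentrations.items():
            total += conc * tefs[name]
    return total


def compute_ilcr(bap_eq, ir, bw, constants: ExposureConstants | None = None):
    """Incremental lifetime cancer risk for inhalation exposure.

    ILCR = BaP_eq·10⁻⁶ · IR · EF · ED · CSF / (BW · AT), with BaP_eq in
    ng·m⁻³, IR in m³·day⁻¹ and BW in kg.  Accepts scalars or numpy
    arrays (broadcasting); strictly linear in ``bap_eq`` and ``ir`` and
    inverse in ``bw``.
    """
    if constants is None:
        constants = ExposureConstants()
    bap_eq = np.asarray(bap_eq, dtype=float)
    ir = np.asarray(ir, dtype=float)
    bw = np.asarray(bw, dtype=float)
    if np.any(bap_eq < 0):
        raise ValueError("bap_eq must be >= 0")
    if np.any(ir <= 0):
        raise ValueError("ir must be strictly positive")
    if np.any(bw <= 0):
        raise ValueError("bw must be strictly positive")
    ilcr = bap_eq * ir / bw * constants.dose_factor
    return float(ilcr) if ilcr.ndim == 0 else ilcr


def classify_risk(ilcr: float) -> RiskClass:
    """Classify one ILCR value against the 1e-6 / 1e-4 thresholds.

    The 1e-4 boundary is assigned to ``SERIOUS`` ("one-in-ten-thousand or
    greater"), the 1e-6 boundary to ``EXCEEDS_ACCEPTABLE``.
    """
    if not ilcr >= 0:
        raise ValueError(f"ilcr must be >= 0, got {ilcr}")
    if ilcr >= SERIOUS_RISK:
        return RiskClass.SERIOUS
    if ilcr >= ACCEPTABLE_RISK:
        return RiskClass.EXCEEDS_ACCEPTABLE
    return RiskClass.BELOW_ACCEPTABLE


_L_MIN = "L/min"
_M3_DAY = "m3/day"
_UNIT_ALIASES = {
    "l/min": _L_MIN,
    "l·min⁻¹": _L_MIN,
    "lpm": _L_MIN,
    "m3/day": _M3_DAY,
    "m³/day": _M3_DAY,
    "m3/d": _M3_DAY,
    "m³·day⁻¹": _M3_DAY,
}
#: 1 L·min⁻¹ = 60·24/1000 m³·day⁻¹
L_MIN_TO_M3_DAY = 1.44


def convert_ir(value, from_unit: str, to_unit: str):
    """Convert inhalation rates between L·min⁻¹ and m³·day⁻¹."""
    try:
        src = _UNIT_ALIASES[from_unit.strip().lower()]
        dst = _UNIT_ALIASES[to_unit.strip().lower()]
    except KeyError as exc:
        raise ValueError(f"unknown inhalation-rate unit: {exc.args[0]!r}") from None
    if src == dst:
        return value
    if src == _L_MIN:
        return value * L_MIN_TO_M3_DAY
    return value / L_MIN_TO_M3_DAY


def annualize(
    profiles: Sequence[PAHProfile],
    weights: Sequence[float] | None = None,
) -> PAHProfile:
    """Weighted per-congener average of per-period profiles of one phase.

    Default is the equal-weight mean over the supplied sampling periods
    (three seasonal campaigns in the usual design).  Explicit weights must
    sum to 1 within 1e-9.  All profiles must share one phase and one
    congener set.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("annualize requires at least one profile")
    if weights is None:
        weights = [1.0 / len(profiles)] * len(profiles)
    weights = [float(w) for w in weights]
    if len(weights) != len(profiles):
        raise ValueError("one weight per profile required")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {sum(weights)}")
    phase = profiles[0].phase
    keys = set(profiles[0].concentrations)
    for p in profiles[1:]:
        if p.phase != phase:
            raise ValueError("all profiles must share one phase")
        if set(p.concentrations) != keys:
            raise ValueError("all profiles must share one congener set")
    averaged = {
        name: sum(w * p.concentrations[name] for w, p in zip(weights, profiles))
        for name in sorted(keys)
    }
    return PAHProfile(
        site_id=profiles[0].site_id,
        phase=phase,
        period="annual",
        concentrations=averaged,
    )
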