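"""Derived developmental traits and plasticity statistics.

Raw inputs are per-case, per-treatment summaries (larval period and mass
at metamorphosis: mean, SD, n).  From these we derive developmental rate
(1/period), mean growth rate (mass/period), log10 transforms, percent
plasticity between constant and drying treatments, and Hedges' d effect
sizes with their sampling variances.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "TraitError",
    "EffectSizeError",
    "TreatmentSummary",
    "StudyCase",
    "DerivedTraits",
    "PlasticityRecord",
    "DeriveResult",
    "RISK_GROUPS",
    "VENUES",
    "PLASTICITY_TRAITS",
    "developmental_rate",
    "mean_growth_rate",
    "volume_to_mass",
    "plasticity_percent",
    "hedges_d",
    "trait_summary",
    "derive_case",
    "derive_all",
]

RISK_GROUPS = ("High", "Low")
VENUES = ("laboratory", "mesocosm", "field")

#: default traits for which plasticity is computed, one record per trait
#: per paired case.  Developmental plasticity is expressed on the period
#: ("dev_time") scale by default; the rate scale is available as
#: "dev_rate".
PLASTICITY_TRAITS = ("dev_time", "growth_rate", "mass")

WATER_DENSITY_G_PER_ML = 1.0


class TraitError(ValueError):
    """Invalid trait value or trait computation."""


class EffectSizeError(TraitError):
    """Effect size not computable from the given summaries."""


@dataclass(frozen=True)
class TreatmentSummary:
    """Summary statistics for one case under one water-level treatment."""

    period_mean: float  # days
    period_sd: float
    period_n: int
    mass_mean: float  # grams
    mass_sd: float
    mass_n: int

    def __post_init__(self) -> None:
        if self.period_mean <= 0:
            raise TraitError(f"period_mean must be > 0, got {self.period_mean}")
        if self.mass_mean <= 0:
            raise TraitError(f"mass_mean must be > 0, got {self.mass_mean}")
        if self.period_sd < 0 or self.mass_sd < 0:
            raise TraitError("standard deviations must be >= 0")
        if self.period_n < 1 or self.mass_n < 1:
            raise TraitError("sample sizes must be >= 1")


@dataclass(frozen=True)
class StudyCase:
    """One observation: a species/population under paired water treatments.

    ``drying`` may be absent (constant-condition-only case); ``constant``
    may be absent only for malformed inputs, which :func:`derive_all`
    rejects with a logged reason.
    """

    case_id: str
    species: str
    risk_group: str
    venue: str
    constant: Optional[TreatmentSummary]
    drying: Optional[TreatmentSummary] = None
    population: Optional[str] = None

    def __post_init__(self) -> None:
        if self.risk_group not in RISK_GROUPS:
            raise TraitError(
                f"risk_group must be one of {RISK_GROUPS}, got {self.risk_group!r}"
            )
        if self.venue not in VENUES:
            raise TraitError(f"venue must be one of {VENUES}, got {self.venue!r}")


@dataclass(frozen=True)
class DerivedTraits:
    dev_rate: float  # days^-1
    growth_rate: float  # g / day
    log10_dev_rate: float
    log10_growth_rate: float
    log10_mass: float


@dataclass(frozen=True)
class PlasticityRecord:
    """Plasticity of one trait in one case, drying relative to constant."""

    case_id: str
    trait: str
    percent: float
    hedges_d: Optional[float]
    hedges_d_var: Optional[float]


def developmental_rate(period_mean: float) -> float:
    """Reciprocal of the larval period, in days^-1."""
    if period_mean <= 0:
        raise TraitError(f"developmental period must be > 0, got {period_mean}")
    return 1.0 / period_mean


def mean_growth_rate(mass_mean: float, period_mean: float) -> float:
    """Mass at metamorphosis divided by larval period (g/day)."""
    if mass_mean <= 0:
        raise TraitError(f"mass must be > 0, got {mass_mean}")
    if period_mean <= 0:
        raise TraitError(f"period must be > 0, got {period_mean}")
    return mass_mean / period_mean


def volume_to_mass(volume_ml: float) -> float:
    """Body volume (mL) to mass (g) at density 1 g/mL."""
    if volume_ml <= 0:
        raise TraitError(f"volume must be > 0, got {volume_ml}")
    return volume_ml * WATER_DENSITY_G_PER_ML


def plasticity_percent(trait_c: float, trait_d: float) -> float:
    """Percent change of a trait under drying relative to constant
    conditions: 100 * (trait_d - trait_c) / trait_c.  Negative values
    mean a reduction under drying."""
    if trait_c <= 0:
        raise TraitError(f"constant-condition trait must be > 0, got {trait_c}")
    return 100.0 * (trait_d - trait_c) / trait_c


def hedges_d(
    mean_d: float,
    sd_d: float,
    n_d: int,
    mean_c: float,
    sd_c: float,
    n_c: int,
) -> tuple[float, float]:
    """Small-sample-corrected standardized mean difference (drying minus
    constant) and its sampling variance.

    d = J * (mean_d - mean_c) / s_pooled, with
    s_pooled^2 = [(n_d - 1) sd_d^2 + (n_c - 1) sd_c^2] / (n_d + n_c - 2)
    and J = 1 - 3 / (4 (n_d + n_c - 2) - 1);
    var(d) = (n_d + n_c) / (n_d n_c) + d^2 / (2 (n_d + n_c - 2)).
    """
    if n_d < 2 or n_c < 2:
        raise EffectSizeError(f"need n >= 2 in both groups, got n_d={n_d}, n_c={n_c}")
    df = n_d + n_c - 2
    s2_pooled = ((n_d - 1) * sd_d**2 + (n_c - 1) * sd_c**2) / df
    if s2_pooled == 0.0:
        if mean_d != mean_c:
            raise EffectSizeError("pooled SD is zero with unequal means")
        d = 0.0
    else:
        j = 1.0 - 3.0 / (4.0 * df - 1.0)
        d = j * (mean_d - mean_c) / math.sqrt(s2_pooled)
    var_d = (n_d + n_c) / (n_d * n_c) + d**2 / (2.0 * df)
    return d, var_d


def trait_summary(ts: TreatmentSummary, trait: str) -> tuple[float, float, int]:
    """(mean, sd, n) of a raw or derived trait for one treatment.

    Measured traits ("dev_time", "mass") pass through the input summary.
    Derived traits propagate the SD to first order: for the rate 1/T,
    sd = sd_T / T^2; for growth m/T (independent numerator/denominator),
    sd = g * sqrt((sd_m/m)^2 + (sd_T/T)^2), with n = min(n_m, n_T).
    """
    if trait == "dev_time":
        return ts.period_mean, ts.period_sd, ts.period_n
    if trait == "mass":
        return ts.mass_mean, ts.mass_sd, ts.mass_n
    if trait == "dev_rate":
        rate = developmental_rate(ts.period_mean)
        return rate, ts.period_sd / ts.period_mean**2, ts.period_n
    if trait == "growth_rate":
        g = mean_growth_rate(ts.mass_mean, ts.period_mean)
        rel = math.sqrt(
            (ts.mass_sd / ts.mass_mean) ** 2 + (ts.period_sd / ts.period_mean) ** 2
        )
        return g, g * rel, min(ts.mass_n, ts.period_n)
    raise TraitError(f"unknown trait {trait!r}")


def derive_case(ts: TreatmentSummary) -> DerivedTraits:
    rate = developmental_rate(ts.period_mean)
    growth = mean_growth_rate(ts.mass_mean, ts.period_mean)
    return DerivedTraits(
        dev_rate=rate,
        growth_rate=growth,
        log10_dev_rate=math.log10(rate),
        log10_growth_rate=math.log10(growth),
        log10_mass=math.log10(ts.mass_mean),
    )


@dataclass
class DeriveResult:
    """Output of :func:`derive_all`."""

    derived: list[tuple[str, str, DerivedTraits]]  # (case_id, treatment, traits)
    plasticity: list[PlasticityRecord]
    rejected: list[tuple[str, str]] = field(default_factory=list)  # (case_id, reason)

    def derived_rows(self) -> list[dict]:
        rows = []
        for case_id, treatment, dt in self.derived:
            rows.append(
                {
                    "case_id": case_id,
                    "treatment": treatment,
                    "dev_rate": dt.dev_rate,
                    "growth_rate": dt.growth_rate,
                    "log10_dev_rate": dt.log10_dev_rate,
                    "log10_growth_rate": dt.log10_growth_rate,
                    "log10_mass": dt.log10_mass,
                }
            )
        return rows

    def plasticity_rows(self) -> list[dict]:
        return [
            {
                "case_id": r.case_id,
                "trait": r.trait,
                "percent": r.percent,
                "hedges_d": r.hedges_d,
                "hedges_d_var": r.hedges_d_var,
            }
            for r in self.plasticity
        ]


def derive_all(
    cases: Iterable[StudyCase],
    plasticity_traits: Sequence[str] = PLASTICITY_TRAITS,
) -> DeriveResult:
    """Derived traits for every case and plasticity records for every case
    with both treatments.

    Cases lacking constant-condition summaries are rejected with a logged
    reason rather than raising.  Hedges' d is set to None (percent is
    still reported) when the summaries do not support it, e.g. n < 2.
    The computation is deterministic and per-case, so permuting the input
    permutes the output identically.
    """
    derived: list[tuple[str, str, DerivedTraits]] = []
    plasticity: list[PlasticityRecord] = []
    rejected: list[tuple[str, str]] = []
    for case in cases:
        if case.constant is None:
            reason = "missing constant-condition summaries"
            logger.warning("case %s rejected: %s", case.case_id, reason)
            rejected.append((case.case_id, reason))
            continue
        derived.append((case.case_id, "constant", derive_case(case.constant)))
        if case.drying is None:
            continue
        derived.append((case.case_id, "drying", derive_case(case.drying)))
        for trait in plasticity_traits:
            mean_c, sd_c, n_c = trait_summary(case.constant, trait)
            mean_d, sd_d, n_d = trait_summary(case.drying, trait)
            pct = plasticity_percent(mean_c, mean_d)
            try:
                d, var_d = hedges_d(mean_d, sd_d, n_d, mean_c, sd_c, n_c)
            except EffectSizeError as exc:
                logger.info(
                    "case %s trait %s: Hedges' d unavailable (%s)",
                    case.case_id,
                    trait,
                    exc,
                )
                d, var_d = None, None
            plasticity.append(
                PlasticityRecord(
                    case_id=case.case_id,
                    trait=trait,
                    percent=pct,
                    hedges_d=d,
                    hedges_d_var=var_d,
                )
            )
    return DeriveResult(derived=derived, plasticity=plasticity, rejected=rejected)
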