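"""Chronic and acute dietary risk quotients for pesticide residues.

Follows the WHO/FAO JMPR deterministic scheme.  Chronic exposure is the
national estimated daily intake

    NEDI = sum_i (STMR_i x F_i) / bw          [mg kg^-1 bw day^-1]

over registered commodities i, with STMR the supervised-trials median
residue and F the mean daily consumption; the chronic risk quotient is
RQc = NEDI / ADI x 100 %.  Acute exposure uses the national estimated
short-term intake NESTI built from the highest residue HR and the large
portion LP (97.5th percentile single-meal consumption), piecewise in the
commodity unit weight Ue with variability factor v:

    no Ue:     NESTI = HR x LP / bw
    Ue <  LP:  NESTI = (Ue x HR x v + (LP - Ue) x HR) / bw
    Ue >= LP:  NESTI = HR x LP x v / bw

and RQa = NESTI / ARfD x 100 %.  Quotients below 100 % are deemed
acceptable.  When a toxicological reference value is not set (no ARfD
for low-toxicity compounds) the corresponding quotient is *not
applicable* — represented as ``None``, never as 0.

Fully censored residue sets (every trial value < LOQ) are summarised
conservatively by setting both STMR and HR to the LOQ.

Raw quotients retain full precision; rounding (2 decimals by default)
happens only in the reporting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Sequence

from .dissipation import ResidueSeries
from .errors import ValidationError

__all__ = [
    "PesticideToxProfile",
    "PopulationGroup",
    "ResidueSummary",
    "RiskResult",
    "nedi",
    "rq_chronic",
    "nesti",
    "rq_acute",
    "assess",
    "summarize_residues",
]


@dataclass(frozen=True)
class PesticideToxProfile:
    """Toxicological reference values for one active ingredient.

    ``arfd`` may be None: regulators set no acute reference dose for
    low-toxicity compounds, in which case acute quotients are not
    applicable (never zero).
    """

    name: str
    adi: float  # mg per kg body weight per day
    arfd: float | None = None  # mg per kg body weight
    mrl: float | None = None  # mg per kg commodity
    loq: float = 0.01  # mg per kg commodity

    def __post_init__(self):
        if not self.adi > 0:
            raise ValidationError(f"ADI must be > 0, got {self.adi}")
        if self.arfd is not None and not self.arfd > 0:
            raise ValidationError(f"ARfD must be > 0 when set, got {self.arfd}")
        if not self.loq > 0:
            raise ValidationError(f"LOQ must be > 0, got {self.loq}")


@dataclass(frozen=True)
class PopulationGroup:
    """Diet and body-weight parameters of one consumer group.

    ``daily_intake_kg`` is the mean consumption of the registered
    commodity; it may be None for groups whose chronic intake is not
    tabulated (the chronic quotient is then not computed).  ``unit
    weight`` and the variability factor only apply to unit-sized
    commodities; cereals carry none.
    """

    name: str
    body_weight_kg: float
    daily_intake_kg: float | None = None
    large_portion_kg: float = 0.0
    unit_weight_kg: float | None = None
    variability_factor: float | None = None

    def __post_init__(self):
        problems = []
        if not self.body_weight_kg > 0:
            problems.append(f"body weight must be > 0 ({self.body_weight_kg})")
        if self.daily_intake_kg is not None and self.daily_intake_kg < 0:
            problems.append(f"daily intake must be >= 0 ({self.daily_intake_kg})")
        if self.large_portion_kg < 0:
            problems.append(f"large portion must be >= 0 ({self.large_portion_kg})")
        if self.unit_weight_kg is not None:
            if self.variability_factor is None:
                problems.append("unit weight given without a variability factor")
            elif self.variability_factor < 1:
                problems.append(
                    f"variability factor must be >= 1 ({self.variability_factor})"
                )
        if problems:
            raise ValidationError(f"invalid population group {self.name!r}", problems)


@dataclass(frozen=True)
class ResidueSummary:
    """STMR / HR residue statistics for one commodity.

    ``source`` records whether the statistics come from field trials or
    from model simulation; mixed-source assessments are allowed but
    flagged downstream.
    """

    stmr: float  # mg per kg
    hr: float  # mg per kg
    source: str = "field"  # "field" | "modeled"
    censored_at_loq: bool = False

    def __post_init__(self):
        if self.stmr < 0 or self.hr < 0:
            raise ValidationError("residue statistics must be >= 0")
        if self.source not in ("field", "modeled", "mixed"):
            raise ValidationError(f"unknown residue source {self.source!r}")
        if self.censored_at_loq and not math.isclose(self.stmr, self.hr):
            raise ValidationError("fully censored summary must have STMR == HR == LOQ")


@dataclass(frozen=True)
class RiskResult:
    """Risk quotients for one population group; raw, unrounded values."""

    group: str
    nedi: float | None  # mg per kg bw per day
    rqc_percent: float | None
    nesti: float | None  # mg per kg bw
    rqa_percent: float | None  # None when not applicable
    acceptable: bool
    source: str = "field"

    def rounded(self, decimals: int = 2) -> dict:
        """Reporting view with rounded percentages; raw values retained
        on the dataclass itself."""

        def rnd(x):
            return None if x is None else round(x, decimals)

        return {
            "group": self.group,
            "nedi_mg_per_kg_bw_day": self.nedi,
            "rqc_percent": rnd(self.rqc_percent),
            "nesti_mg_per_kg_bw": self.nesti,
            "rqa_percent": "not applicable" if self.rqa_percent is None else rnd(self.rqa_percent),
            "acceptable": self.acceptable,
            "source": self.source,
        }


def nedi(
    residues: Iterable[tuple[float, float]], body_weight_kg: float
) -> float:
    """National estimated daily intake, mg per kg bw per day.

    ``residues`` is a sequence of (STMR mg/kg, daily intake kg/day)
    pairs, one per registered commodity.
    """
    if not body_weight_kg > 0:
        raise ValidationError(f"body weight must be > 0, got {body_weight_kg}")
    total = 0.0
    for stmr, intake in residues:
        if stmr < 0 or intake < 0:
            raise ValidationError("STMR and intake must be >= 0")
        total += stmr * intake
    return total / body_weight_kg


def rq_chronic(nedi_value: float, adi: float) -> float:
    """Chronic risk quotient, percent: 100 x NEDI / ADI."""
    if not adi > 0:
        raise ValidationError(f"ADI must be > 0, got {adi}")
    if nedi_value < 0:
        raise ValidationError("NEDI must be >= 0")
    return 100.0 * nedi_value / adi


def nesti(hr: float, group: PopulationGroup) -> float | None:
    """National estimated short-term intake, mg per kg bw (piecewise in Ue).

    Returns None ("not applicable") when the group has no large portion.
    The Ue == LP boundary is assigned to the unit-exceeds-portion branch;
    the two branches coincide there, so the function is continuous.
    """
    if hr < 0:
        raise ValidationError("HR must be >= 0")
    lp = group.large_portion_kg
    if lp == 0.0:
        return None
    bw = group.body_weight_kg
    ue = group.unit_weight_kg
    if ue is None:
        return hr * lp / bw
    v = group.variability_factor
    if ue < lp:
        return (ue * hr * v + (lp - ue) * hr) / bw
    return hr * lp * v / bw


def rq_acute(nesti_value: float | None, arfd: float | None) -> float | None:
    """Acute risk quotient, percent: 100 x NESTI / ARfD.

    None when no ARfD is set (acute assessment not applicable) or when
    NESTI itself is not applicable.
    """
    if arfd is None or nesti_value is None:
        return None
    if not arfd > 0:
        raise ValidationError(f"ARfD must be > 0, got {arfd}")
    if nesti_value < 0:
        raise ValidationError("NESTI must be >= 0")
    return 100.0 * nesti_value / arfd


def assess(
    profile: PesticideToxProfile,
    summary: ResidueSummary,
    groups: Sequence[PopulationGroup],
) -> list[RiskResult]:
    """One RiskResult per population group, order preserved.

    A fully censored summary uses the LOQ as both STMR and HR
    (conservative upper bound).  A result is acceptable when every
    computed quotient is below 100 %.
    """
    stmr, hr = summary.stmr, summary.hr
    if summary.censored_at_loq:
        stmr = hr = profile.loq
    results = []
    for group in groups:
        if group.daily_intake_kg is None:
            nedi_value = rqc = None
        else:
            nedi_value = nedi([(stmr, group.daily_intake_kg)], group.body_weight_kg)
            rqc = rq_chronic(nedi_value, profile.adi)
        nesti_value = nesti(hr, group)
        rqa = rq_acute(nesti_value, profile.arfd)
        quotients = [q for q in (rqc, rqa) if q is not None]
        results.append(
            RiskResult(
                group=group.name,
                nedi=nedi_value,
                rqc_percent=rqc,
                nesti=nesti_value,
                rqa_percent=rqa,
                acceptable=all(q < 100.0 for q in quotients),
                source=summary.source,
            )
        )
    return results


def summarize_residues(
    series_list: Sequence[ResidueSeries],
    at_day: float | None = None,
    source: str = "field",
) -> ResidueSummary:
    """STMR/HR summary over trial series, censoring-aware.

    Uses the observations at ``at_day`` (terminal residue day) from each
    series, or every observation when ``at_day`` is None.  If all
    contributing values are censored, STMR and HR are both set to the
    LOQ and the summary is flagged ``censored_at_loq``.
    """
    values: list[float] = []
    censored: list[bool] = []
    loqs: list[float] = []
    for series in series_list:
        for obs in series.observations:
            if at_day is not None and not math.isclose(
                obs.time_days, at_day, rel_tol=0, abs_tol=1e-9
            ):
                continue
            values.append(obs.concentration)
            censored.append(obs.censored)
            loqs.append(obs.loq)
    if not values:
        raise ValidationError(
            "no observations available to summarize"
            + (f" at day {at_day}" if at_day is not None else "")
        )
    if all(censored):
        loq = max(loqs)
        return ResidueSummary(stmr=loq, hr=loq, source=source, censored_at_loq=True)
    return ResidueSummary(
        stmr=float(median(values)), hr=float(max(values)), source=source
    )
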