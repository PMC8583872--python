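"""Conversion equations between RPQ and SCAT totals, and SCAT severity zones.

The published crosswalk consists of two equations:

* RPQ → SCAT (the published equation, ``eq1``)::

      SCAT = 7 * ((RPQ_total / 16) / 5) * ((RPQ_symptoms / 16) * 22)

  i.e. the mean item intensity rescaled to the 7-point Likert range times the
  endorsement fraction rescaled to 22 items. Over its whole valid domain the
  raw output tops out at 123.2 (< 132): the equation cannot reach the SCAT
  maximum. That is a property of the published formula, not a defect here.

* SCAT → RPQ (``eq2``), a direct proportion::

      RPQ = (SCAT_total / 132) * 64

Two rejected RPQ → SCAT candidates are kept for comparison studies: a direct
proportion ``(RPQ_total / 80) * 132`` (implemented literally, including the
80-point divisor — plausibly 16 items x 5 Likert levels) and a
domain-weighted sum that rescales each named-domain subscore by the ratio of
the two scales' domain maxima.

Raw values are reported alongside integers rounded half-away-from-zero, and
results are clamped into the target scale's range (with a flag) in case a
caller feeds raw, unvalidated values.

SCAT totals are banded into severity zones low (0-25), moderate (26-75) and
high (76-132). The published prose leaves 76 unassigned ("moderate (26-75)"
but "high (>76)"); this package assigns 76 to the high zone, keeping the
moderate band's printed upper bound intact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping

from .errors import ValidationError
from .scales import NAMED_DOMAINS, Domain, ScaleId, domain_maxima, get_scale

__all__ = [
    "EquationId",
    "ConversionResult",
    "Zone",
    "SeverityZone",
    "ZONES",
    "rpq_to_scat",
    "scat_to_rpq",
    "rpq_to_scat_direct_proportion",
    "rpq_to_scat_domain_weighted",
    "classify_severity_zone",
    "round_half_away_from_zero",
]


class EquationId(str, Enum):
    EQ1_RPQ_TO_SCAT = "eq1"
    EQ2_SCAT_TO_RPQ = "eq2"
    DIRECT_PROPORTION = "direct"
    DOMAIN_WEIGHTED = "domain"


#: Equations that predict SCAT from RPQ (target scale = SCAT).
RPQ_TO_SCAT_EQUATIONS = (
    EquationId.EQ1_RPQ_TO_SCAT,
    EquationId.DIRECT_PROPORTION,
    EquationId.DOMAIN_WEIGHTED,
)


def round_half_away_from_zero(x: float) -> int:
    """Round to the nearest integer, ties away from zero (55.5 -> 56)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class ConversionResult:
    source_scale: ScaleId
    target_scale: ScaleId
    raw_value: float
    rounded_value: int
    clamped: bool
    equation_id: EquationId

    def to_dict(self) -> dict:
        return {
            "source_scale": self.source_scale.value,
            "target_scale": self.target_scale.value,
            "raw_value": self.raw_value,
            "rounded_value": self.rounded_value,
            "clamped": self.clamped,
            "equation_id": self.equation_id.value,
        }


def _finish(
    raw: float, source: ScaleId, target: ScaleId, equation_id: EquationId
) -> ConversionResult:
    target_max = get_scale(target).max_total
    rounded = round_half_away_from_zero(raw)
    clamped = rounded < 0 or rounded > target_max
    rounded = min(max(rounded, 0), target_max)
    return ConversionResult(
        source_scale=source,
        target_scale=target,
        raw_value=raw,
        rounded_value=rounded,
        clamped=clamped,
        equation_id=equation_id,
    )


def _check_range(name: str, value: float, lo: int, hi: int) -> None:
    if not lo <= value <= hi:
        raise ValidationError(f"{name} {value} outside [{lo}, {hi}]")


def rpq_to_scat(rpq_total: int, rpq_symptom_count: int) -> ConversionResult:
    """Published RPQ → SCAT conversion (``eq1``).

    Requires a consistent (total, count) pair: a positive count implies at
    least ``count`` and at most ``4 * count`` total points.
    """
    _check_range("rpq_total", rpq_total, 0, 64)
    _check_range("rpq_symptom_count", rpq_symptom_count, 0, 16)
    if (rpq_total == 0) != (rpq_symptom_count == 0):
        raise ValidationError(
            f"inconsistent RPQ scores: total {rpq_total} with "
            f"{rpq_symptom_count} endorsed symptoms"
        )
    if rpq_symptom_count > rpq_total:
        raise ValidationError(
            f"RPQ symptom count {rpq_symptom_count} exceeds total {rpq_total}: "
            "each endorsed symptom contributes at least 1 point"
        )
    if rpq_total > 4 * rpq_symptom_count:
        raise ValidationError(
            f"RPQ total {rpq_total} exceeds the maximum {4 * rpq_symptom_count} "
            f"attainable with {rpq_symptom_count} endorsed symptoms"
        )
    raw = 7.0 * ((rpq_total / 16.0) / 5.0) * ((rpq_symptom_count / 16.0) * 22.0)
    return _finish(raw, ScaleId.RPQ, ScaleId.SCAT, EquationId.EQ1_RPQ_TO_SCAT)


def scat_to_rpq(scat_total: int) -> ConversionResult:
    """Published SCAT → RPQ conversion (``eq2``): (SCAT / 132) * 64."""
    _check_range("scat_total", scat_total, 0, 132)
    raw = (scat_total / 132.0) * 64.0
    return _finish(raw, ScaleId.SCAT, ScaleId.RPQ, EquationId.EQ2_SCAT_TO_RPQ)


def rpq_to_scat_direct_proportion(rpq_total: int) -> ConversionResult:
    """Rejected direct-proportion candidate: (RPQ / 80) * 132."""
    _check_range("rpq_total", rpq_total, 0, 64)
    raw = (rpq_total / 80.0) * 132.0
    return _finish(raw, ScaleId.RPQ, ScaleId.SCAT, EquationId.DIRECT_PROPORTION)


def rpq_to_scat_domain_weighted(
    rpq_domain_scores: Mapping[Domain | str, int],
    fatigue_in_somatic: bool = True,
) -> ConversionResult:
    """Rejected domain-weighted candidate.

    Sums, over the four named domains, the RPQ subscore rescaled from the RPQ
    domain maximum to the SCAT domain maximum. Unclassified items are ignored,
    so the output cannot exceed the sum of SCAT classified-domain maxima.
    """
    scores = {Domain(k): v for k, v in rpq_domain_scores.items() if Domain(k) in NAMED_DOMAINS}
    missing = [d.value for d in NAMED_DOMAINS if d not in scores]
    if missing:
        raise ValidationError(f"missing RPQ domain scores: {missing}")
    rpq_max = domain_maxima(ScaleId.RPQ, fatigue_in_somatic)
    scat_max = domain_maxima(ScaleId.SCAT, fatigue_in_somatic)
    raw = 0.0
    for d in NAMED_DOMAINS:
        _check_range(f"rpq {d.value} domain score", scores[d], 0, rpq_max[d])
        raw += (scores[d] / rpq_max[d]) * scat_max[d]
    return _finish(raw, ScaleId.RPQ, ScaleId.SCAT, EquationId.DOMAIN_WEIGHTED)


class Zone(str, Enum):
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"


@dataclass(frozen=True)
class SeverityZone:
    zone: Zone
    bounds: tuple[int, int]


#: SCAT severity zones; together they partition [0, 132].
ZONES: tuple[SeverityZone, ...] = (
    SeverityZone(Zone.LOW, (0, 25)),
    SeverityZone(Zone.MODERATE, (26, 75)),
    SeverityZone(Zone.HIGH, (76, 132)),
)


def classify_severity_zone(scat_total: float) -> SeverityZone:
    """Band a SCAT total into the low / moderate / high severity zone."""
    _check_range("scat_total", scat_total, 0, 132)
    for zone in ZONES:
        if scat_total <= zone.bounds[1]:
            return zone
    return ZONES[-1]  # unreachable for validated input
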