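"""Instrument definitions and scoring for the RPQ and SCAT symptom checklists.

The two instruments covered by this package:

* **RPQ** — Rivermead Post-concussion Symptoms Questionnaire: 16 symptoms,
  each rated on a 5-point Likert scale (0 = not experienced at all,
  4 = a severe problem). Totals range 0-64.
* **SCAT** — Sport Concussion Assessment Tool symptom evaluation: 22
  symptoms, each rated on a 7-point Likert scale (0 = none, 6 = severe).
  Totals range 0-132.

Both checklists group overlapping symptoms into four named domains
(somatic, cognitive, emotional, sleep). The grouping shipped in
``data/scale_items.csv`` follows the published domain table for this
crosswalk; symptoms outside that table (e.g. blurred vision on either
scale, RPQ restlessness, SCAT "don't feel right") carry the
``unclassified`` domain. Unclassified items contribute to totals and
symptom counts but not to named-domain subscores.

The SCAT fatigue item is the one convention-dependent assignment: it is
somatic by default, and can be treated as unclassified instead via the
``fatigue_in_somatic`` flag, mirroring how somatic subscores are reported
with and without fatigue. RPQ fatigue is never part of a named domain.

The two optional self-disclosed RPQ symptom slots are excluded from the
instrument definition entirely: the symptoms entered there need not be
concussion-related, and they play no part in the 64-point total.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ValidationError

__all__ = [
    "ScaleId",
    "Domain",
    "NAMED_DOMAINS",
    "WEEK_SCHEDULE",
    "ItemDefinition",
    "ScaleDefinition",
    "Assessment",
    "ScoreSummary",
    "PairedRecord",
    "PairingResult",
    "get_scale",
    "score_assessment",
    "domain_maxima",
    "validate_cohort",
]


class ScaleId(str, Enum):
    RPQ = "rpq"
    SCAT = "scat"


class Domain(str, Enum):
    SOMATIC = "somatic"
    COGNITIVE = "cognitive"
    EMOTIONAL = "emotional"
    SLEEP = "sleep"
    UNCLASSIFIED = "unclassified"


#: The four domains with named subscores; ``unclassified`` is the remainder.
NAMED_DOMAINS: tuple[Domain, ...] = (
    Domain.SOMATIC,
    Domain.COGNITIVE,
    Domain.EMOTIONAL,
    Domain.SLEEP,
)

#: Scheduled assessment weeks of the longitudinal design this package models.
WEEK_SCHEDULE: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 12, 16)

_ITEM_MAX = {ScaleId.RPQ: 4, ScaleId.SCAT: 6}

#: The convention-dependent fatigue item (SCAT only; see module docstring).
FATIGUE_ITEM_ID = "fatigue"


@dataclass(frozen=True)
class ItemDefinition:
    """One symptom of one instrument."""

    item_id: str
    label: str
    domain: Domain


@dataclass(frozen=True)
class ScaleDefinition:
    """A full instrument: ordered items plus the Likert maximum per item."""

    scale_id: ScaleId
    items: tuple[ItemDefinition, ...]
    item_max: int

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        if dupes:
            raise ValidationError(
                f"duplicate item ids in {self.scale_id.value}: {dupes}"
            )

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def max_total(self) -> int:
        return self.n_items * self.item_max

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)


def _load_definitions() -> dict[ScaleId, ScaleDefinition]:
    path = resources.files("rpqscat.data").joinpath("scale_items.csv")
    by_scale: dict[ScaleId, list[ItemDefinition]] = {s: [] for s in ScaleId}
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh):
            by_scale[ScaleId(row["scale"])].append(
                ItemDefinition(
                    item_id=row["item_id"],
                    label=row["label"],
                    domain=Domain(row["domain"]),
                )
            )
    return {
        sid: ScaleDefinition(scale_id=sid, items=tuple(items), item_max=_ITEM_MAX[sid])
        for sid, items in by_scale.items()
    }


@lru_cache(maxsize=None)
def get_scale(scale_id: ScaleId | str) -> ScaleDefinition:
    """Return the shipped definition of ``rpq`` or ``scat``."""
    return _load_definitions()[ScaleId(scale_id)]


@dataclass(frozen=True)
class Assessment:
    """One subject-week administration of one scale, item-level.

    ``severities`` is ordered like ``get_scale(scale_id).items``.
    """

    subject_id: str
    week: int
    scale_id: ScaleId
    severities: tuple[int, ...]

    def validate(self) -> None:
        scale = get_scale(self.scale_id)
        if not isinstance(self.week, int) or isinstance(self.week, bool) or self.week < 1:
            raise ValidationError(
                f"subject {self.subject_id}: week must be a positive integer, "
                f"got {self.week!r}"
            )
        if len(self.severities) != scale.n_items:
            raise ValidationError(
                f"subject {self.subject_id} week {self.week}: "
                f"{scale.scale_id.value} expects {scale.n_items} severities, "
                f"got {len(self.severities)}"
            )
        for item, sev in zip(scale.items, self.severities):
            if not isinstance(sev, (int,)) or isinstance(sev, bool):
                raise ValidationError(
                    f"subject {self.subject_id} week {self.week}: item "
                    f"'{item.item_id}' severity {sev!r} is not an integer"
                )
            if not 0 <= sev <= scale.item_max:
                raise ValidationError(
                    f"subject {self.subject_id} week {self.week}: item "
                    f"'{item.item_id}' severity {sev} outside [0, {scale.item_max}]"
                )


@dataclass(frozen=True)
class ScoreSummary:
    """Scored view of one assessment.

    ``domain_scores`` maps every :class:`Domain` (the four named domains plus
    ``unclassified``) to its point sum; it is ``None`` for score-level data
    read without domain columns. ``fatigue_in_somatic`` records the grouping
    convention the domain scores were computed under.
    """

    scale_id: ScaleId
    total: int
    symptom_count: int
    domain_scores: Optional[Mapping[Domain, int]] = None
    fatigue_in_somatic: bool = True

    def __post_init__(self) -> None:
        scale = get_scale(self.scale_id)
        if not 0 <= self.total <= scale.max_total:
            raise ValidationError(
                f"{self.scale_id.value} total {self.total} outside "
                f"[0, {scale.max_total}]"
            )
        if not 0 <= self.symptom_count <= scale.n_items:
            raise ValidationError(
                f"{self.scale_id.value} symptom count {self.symptom_count} "
                f"outside [0, {scale.n_items}]"
            )
        if (self.total == 0) != (self.symptom_count == 0):
            raise ValidationError(
                f"{self.scale_id.value} total {self.total} inconsistent with "
                f"symptom count {self.symptom_count}"
            )


def _effective_domain(
    scale_id: ScaleId, item: ItemDefinition, fatigue_in_somatic: bool
) -> Domain:
    if (
        scale_id is ScaleId.SCAT
        and item.item_id == FATIGUE_ITEM_ID
        and not fatigue_in_somatic
    ):
        return Domain.UNCLASSIFIED
    return item.domain


def score_assessment(
    assessment: Assessment,
    fatigue_in_somatic: bool = True,
    recode_mild: bool = False,
) -> ScoreSummary:
    """Score one assessment: total, symptom count, and domain subscores.

    Parameters
    ----------
    assessment
        Validated item-level responses for one subject-week.
    fatigue_in_somatic
        Whether the SCAT fatigue item counts toward the somatic subscore
        (default) or is left unclassified. Has no effect on RPQ scoring or
        on any total.
    recode_mild
        Classical RPQ scoring convention in which ratings of 1 ("no more of
        a problem than before the injury") are recoded to 0 before summing.
        Off by default: the anchors used here (0 = not experienced at all)
        imply raw summation to the 64-point maximum.
    """
    assessment.validate()
    scale = get_scale(assessment.scale_id)
    severities = assessment.severities
    if recode_mild and scale.scale_id is ScaleId.RPQ:
        severities = tuple(0 if s == 1 else s for s in severities)
    total = sum(severities)
    count = sum(1 for s in severities if s > 0)
    domain_scores: dict[Domain, int] = {d: 0 for d in Domain}
    for item, sev in zip(scale.items, severities):
        domain_scores[_effective_domain(scale.scale_id, item, fatigue_in_somatic)] += sev
    return ScoreSummary(
        scale_id=scale.scale_id,
        total=total,
        symptom_count=count,
        domain_scores=domain_scores,
        fatigue_in_somatic=fatigue_in_somatic,
    )


def domain_maxima(
    scale_id: ScaleId | str, fatigue_in_somatic: bool = True
) -> dict[Domain, int]:
    """Maximum attainable points per domain: (items in domain) x item_max."""
    scale = get_scale(scale_id)
    maxima: dict[Domain, int] = {d: 0 for d in Domain}
    for item in scale.items:
        maxima[_effective_domain(scale.scale_id, item, fatigue_in_somatic)] += scale.item_max
    return maxima


@dataclass(frozen=True)
class PairedRecord:
    """One subject-week with both instruments completed ("matched pair")."""

    subject_id: str
    week: int
    rpq: ScoreSummary
    scat: ScoreSummary
    rpq_assessment: Optional[Assessment] = None
    scat_assessment: Optional[Assessment] = None

    @property
    def has_items(self) -> bool:
        return self.rpq_assessment is not None and self.scat_assessment is not None


@dataclass
class PairingResult:
    """Matched pairs plus an account of the unmatched assessments dropped."""

    pairs: list[PairedRecord]
    dropped: list[tuple[str, int, ScaleId]] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


def validate_cohort(
    assessments: Iterable[Assessment],
    fatigue_in_somatic: bool = True,
    recode_mild: bool = False,
) -> PairingResult:
    """Match RPQ/SCAT assessments into scored subject-week pairs.

    Subject-weeks with only one of the two scales are dropped and reported in
    :attr:`PairingResult.dropped`. Duplicate subject-week-scale rows raise a
    :class:`~rpqscat.errors.ValidationError` listing every duplicate.
    """
    by_key: dict[tuple[str, int], dict[ScaleId, Assessment]] = {}
    duplicates: list[tuple[str, int, str]] = []
    for a in assessments:
        slot = by_key.setdefault((a.subject_id, a.week), {})
        if a.scale_id in slot:
            duplicates.append((a.subject_id, a.week, a.scale_id.value))
        else:
            slot[a.scale_id] = a
    if duplicates:
        raise ValidationError(f"duplicate subject-week-scale rows: {duplicates}")

    pairs: list[PairedRecord] = []
    dropped: list[tuple[str, int, ScaleId]] = []
    for (subject_id, week), slot in sorted(by_key.items()):
        if len(slot) == 2:
            pairs.append(
                PairedRecord(
                    subject_id=subject_id,
                    week=week,
                    rpq=score_assessment(
                        slot[ScaleId.RPQ], fatigue_in_somatic, recode_mild
                    ),
                    scat=score_assessment(slot[ScaleId.SCAT], fatigue_in_somatic),
                    rpq_assessment=slot[ScaleId.RPQ],
                    scat_assessment=slot[ScaleId.SCAT],
                )
            )
        else:
            (scale_id,) = slot.keys()
            dropped.append((subject_id, week, scale_id))
    return PairingResult(pairs=pairs, dropped=dropped)
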