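"""Agreement and validation analyses for a paired RPQ/SCAT cohort.

Given matched subject-week pairs, this module reproduces the crosswalk's
validation program for any of the conversion equations:

* Spearman rank correlations between the two instruments at every
  granularity — totals, symptom counts, named-domain subscores (somatic with
  and without fatigue), per assessment week, and within SCAT severity zones;
* signed prediction-error statistics for the chosen equation (rounded
  prediction minus actual score on the target scale): mean, SD, the 95%
  confidence interval of the mean error, empirical +/-3- and +/-5-point
  coverage, and a least-squares slope of error on actual score that captures
  the tendency to over-predict low scores and under-predict high ones;
* threshold concordance (Mann-Whitney AUC) of the predicted score for
  exceeding each severity-zone boundary on the actual scale;
* a deterministic ranking of the three RPQ→SCAT candidate equations by CI
  half-width, then +/-5-point coverage.

"Confidence interval of the predicted score" is taken to mean the 95% normal
CI of the mean signed error, ``mean +/- 1.96 * SD / sqrt(n)``; the empirical
coverage fractions are reported alongside since the phrase is ambiguous.
Zone stratification uses the *actual* SCAT total. Strata with fewer than 3
pairs, or on which a statistic is undefined (constant scores, one-class
thresholds), are omitted from the report rather than fabricated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .crosswalk import (
    RPQ_TO_SCAT_EQUATIONS,
    EquationId,
    Zone,
    classify_severity_zone,
    round_half_away_from_zero,
    rpq_to_scat,
    rpq_to_scat_direct_proportion,
    rpq_to_scat_domain_weighted,
    scat_to_rpq,
)
from .errors import UndefinedStatisticError, ValidationError
from .scales import NAMED_DOMAINS, Domain, PairedRecord, ScaleId, score_assessment

__all__ = [
    "AgreementReport",
    "CandidateComparison",
    "spearman_rho",
    "evaluate_equation",
    "compare_candidates",
    "concordance_auc",
    "predict_pairs",
]

logger = logging.getLogger(__name__)

#: Severity-zone boundaries on the SCAT total, and their images on the RPQ
#: scale under the published SCAT→RPQ proportion (rounded): 25 → 12, 75 → 36.
ZONE_THRESHOLDS = {
    ScaleId.SCAT: (25, 75),
    ScaleId.RPQ: (
        scat_to_rpq(25).rounded_value,
        scat_to_rpq(75).rounded_value,
    ),
}


def spearman_rho(
    x: Sequence[float], y: Sequence[float], return_pvalue: bool = False
):
    """Spearman rank correlation with mid-ranks (average ranks) for ties.

    Raises :class:`UndefinedStatisticError` for constant input rather than
    returning a silent 0 or NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("spearman_rho expects two equal-length 1-d vectors")
    if x.size < 3:
        raise ValidationError(f"spearman_rho needs >= 3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError(
            "rank correlation is undefined for a constant vector"
        )
    rho, p = stats.spearmanr(x, y)
    return (float(rho), float(p)) if return_pvalue else float(rho)


def _mann_whitney_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """P(score_pos > score_neg) + 0.5 P(tie), via mid-ranks."""
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedStatisticError(
            "concordance is undefined with only one class present"
        )
    ranks = stats.rankdata(scores)
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def concordance_auc(
    pairs: Sequence[PairedRecord],
    equation_id: EquationId | str,
    threshold: float,
) -> float:
    """Concordance of the predicted score for actual-above-threshold.

    The probability that a randomly chosen pair whose actual target-scale
    score exceeds ``threshold`` receives a higher predicted score than one at
    or below it, ties counted one half (the Mann-Whitney construction).
    """
    predicted, actual, _ = predict_pairs(pairs, equation_id)
    return _mann_whitney_auc(
        np.asarray(predicted, dtype=float), np.asarray(actual) > threshold
    )


def _predict_one(pair: PairedRecord, equation_id: EquationId) -> tuple[int, int]:
    if equation_id is EquationId.EQ1_RPQ_TO_SCAT:
        return rpq_to_scat(pair.rpq.total, pair.rpq.symptom_count).rounded_value, pair.scat.total
    if equation_id is EquationId.DIRECT_PROPORTION:
        return rpq_to_scat_direct_proportion(pair.rpq.total).rounded_value, pair.scat.total
    if equation_id is EquationId.DOMAIN_WEIGHTED:
        if pair.rpq.domain_scores is None:
            raise ValidationError(
                "domain-weighted conversion needs RPQ domain subscores "
                f"(missing for subject {pair.subject_id} week {pair.week})"
            )
        return (
            rpq_to_scat_domain_weighted(
                pair.rpq.domain_scores, pair.rpq.fatigue_in_somatic
            ).rounded_value,
            pair.scat.total,
        )
    if equation_id is EquationId.EQ2_SCAT_TO_RPQ:
        return scat_to_rpq(pair.scat.total).rounded_value, pair.rpq.total
    raise ValidationError(f"unknown equation {equation_id!r}")


def predict_pairs(
    pairs: Sequence[PairedRecord], equation_id: EquationId | str
) -> tuple[np.ndarray, np.ndarray, ScaleId]:
    """Rounded predictions and actual scores on the target scale."""
    equation_id = EquationId(equation_id)
    target = (
        ScaleId.SCAT if equation_id in RPQ_TO_SCAT_EQUATIONS else ScaleId.RPQ
    )
    if not pairs:
        raise ValidationError("empty cohort")
    pred_actual = [_predict_one(p, equation_id) for p in pairs]
    predicted = np.array([pa[0] for pa in pred_actual])
    actual = np.array([pa[1] for pa in pred_actual])
    return predicted, actual, target


@dataclass(frozen=True)
class AgreementReport:
    """Full validation report for one conversion equation on one cohort."""

    equation_id: EquationId
    target_scale: ScaleId
    n_pairs: int
    rho_total: float
    p_total: float
    #: None when a symptom count is constant across the cohort (rank
    #: correlation undefined); rho_total stays strict.
    rho_count: Optional[float]
    p_count: Optional[float]
    rho_by_domain: Mapping[str, float]
    rho_by_week: Mapping[int, float]
    rho_by_zone: Mapping[Zone, tuple[float, int]]
    mean_error: float
    sd_error: float
    ci95_half_width: float
    coverage_within_3: float
    coverage_within_5: float
    bias_slope: Optional[float]
    concordance_auc: Mapping[int, float]

    def to_dict(self) -> dict:
        return {
            "equation_id": self.equation_id.value,
            "target_scale": self.target_scale.value,
            "n_pairs": self.n_pairs,
            "rho_total": self.rho_total,
            "p_total": self.p_total,
            "rho_count": self.rho_count,
            "p_count": self.p_count,
            "rho_by_domain": dict(self.rho_by_domain),
            "rho_by_week": {str(k): v for k, v in self.rho_by_week.items()},
            "rho_by_zone": {
                z.value: {"rho": rho, "n": n} for z, (rho, n) in self.rho_by_zone.items()
            },
            "mean_error": self.mean_error,
            "sd_error": self.sd_error,
            "ci95_half_width": self.ci95_half_width,
            "coverage_within_3": self.coverage_within_3,
            "coverage_within_5": self.coverage_within_5,
            "bias_slope": self.bias_slope,
            "concordance_auc": {str(k): v for k, v in self.concordance_auc.items()},
        }


def _safe_rho(x, y) -> Optional[float]:
    try:
        return spearman_rho(x, y)
    except (ValidationError, UndefinedStatisticError):
        return None


def _domain_correlations(pairs: Sequence[PairedRecord]) -> dict[str, float]:
    if any(p.rpq.domain_scores is None or p.scat.domain_scores is None for p in pairs):
        return {}
    out: dict[str, float] = {}
    for d in NAMED_DOMAINS:
        rho = _safe_rho(
            [p.rpq.domain_scores[d] for p in pairs],
            [p.scat.domain_scores[d] for p in pairs],
        )
        if rho is not None:
            out[d.value] = rho
    # somatic subscore without fatigue needs item-level SCAT data when the
    # stored convention included fatigue
    no_fat = _somatic_without_fatigue(pairs)
    if no_fat is not None:
        rho = _safe_rho([p.rpq.domain_scores[Domain.SOMATIC] for p in pairs], no_fat)
        if rho is not None:
            out["somatic_no_fatigue"] = rho
    return out


def _somatic_without_fatigue(
    pairs: Sequence[PairedRecord],
) -> Optional[list[int]]:
    values: list[int] = []
    for p in pairs:
        if not p.scat.fatigue_in_somatic:
            values.append(p.scat.domain_scores[Domain.SOMATIC])
        elif p.scat_assessment is not None:
            summary = score_assessment(p.scat_assessment, fatigue_in_somatic=False)
            values.append(summary.domain_scores[Domain.SOMATIC])
        else:
            return None
    return values


def evaluate_equation(
    pairs: Sequence[PairedRecord],
    equation_id: EquationId | str,
    direction: Optional[str] = None,
) -> AgreementReport:
    """Run the full validation program for one equation on a paired cohort.

    ``direction`` (``"rpq2scat"`` or ``"scat2rpq"``) is optional and only
    checked for consistency with the equation's own direction.
    """
    equation_id = EquationId(equation_id)
    if len(pairs) < 3:
        raise ValidationError(
            f"agreement analysis needs >= 3 matched pairs, got {len(pairs)}"
        )
    predicted, actual, target = predict_pairs(pairs, equation_id)
    if direction is not None:
        expected = "rpq2scat" if target is ScaleId.SCAT else "scat2rpq"
        if direction != expected:
            raise ValidationError(
                f"direction {direction!r} inconsistent with equation "
                f"{equation_id.value} (expects {expected})"
            )

    rpq_totals = [p.rpq.total for p in pairs]
    scat_totals = [p.scat.total for p in pairs]
    rho_total, p_total = spearman_rho(rpq_totals, scat_totals, return_pvalue=True)
    try:
        rho_count, p_count = spearman_rho(
            [p.rpq.symptom_count for p in pairs],
            [p.scat.symptom_count for p in pairs],
            return_pvalue=True,
        )
    except UndefinedStatisticError:
        rho_count, p_count = None, None

    rho_by_week: dict[int, float] = {}
    for week in sorted({p.week for p in pairs}):
        sub = [p for p in pairs if p.week == week]
        if len(sub) < 3:
            continue
        rho = _safe_rho([p.rpq.total for p in sub], [p.scat.total for p in sub])
        if rho is not None:
            rho_by_week[week] = rho

    rho_by_zone: dict[Zone, tuple[float, int]] = {}
    zones = [classify_severity_zone(t).zone for t in scat_totals]
    for zone in Zone:
        sub = [p for p, z in zip(pairs, zones) if z is zone]
        if len(sub) < 3:
            continue
        rho = _safe_rho([p.rpq.total for p in sub], [p.scat.total for p in sub])
        if rho is not None:
            rho_by_zone[zone] = (rho, len(sub))

    errors = (predicted - actual).astype(float)
    n = errors.size
    mean_error = float(errors.mean())
    sd_error = float(errors.std(ddof=1)) if n > 1 else 0.0
    ci95_half_width = float(1.96 * sd_error / np.sqrt(n))
    coverage_within_3 = float(np.mean(np.abs(errors) <= 3))
    coverage_within_5 = float(np.mean(np.abs(errors) <= 5))
    if np.ptp(actual) == 0:
        bias_slope = None
    else:
        bias_slope = float(stats.linregress(actual, errors).slope)

    auc: dict[int, float] = {}
    for thr in ZONE_THRESHOLDS[target]:
        try:
            auc[thr] = _mann_whitney_auc(predicted.astype(float), actual > thr)
        except UndefinedStatisticError:
            logger.warning(
                "one-class threshold %s on %s: concordance omitted", thr, target.value
            )

    return AgreementReport(
        equation_id=equation_id,
        target_scale=target,
        n_pairs=n,
        rho_total=rho_total,
        p_total=p_total,
        rho_count=rho_count,
        p_count=p_count,
        rho_by_domain=_domain_correlations(pairs),
        rho_by_week=rho_by_week,
        rho_by_zone=rho_by_zone,
        mean_error=mean_error,
        sd_error=sd_error,
        ci95_half_width=ci95_half_width,
        coverage_within_3=coverage_within_3,
        coverage_within_5=coverage_within_5,
        bias_slope=bias_slope,
        concordance_auc=auc,
    )


#: Fixed tie-break order for candidate ranking.
_CANDIDATE_ORDER = (
    EquationId.EQ1_RPQ_TO_SCAT,
    EquationId.DIRECT_PROPORTION,
    EquationId.DOMAIN_WEIGHTED,
)


@dataclass(frozen=True)
class CandidateComparison:
    """Deterministic ranking of the RPQ→SCAT candidate equations."""

    ranking: tuple[EquationId, ...]
    reports: Mapping[EquationId, AgreementReport]

    def to_dict(self) -> dict:
        return {
            "ranking": [e.value for e in self.ranking],
            "reports": {e.value: r.to_dict() for e, r in self.reports.items()},
        }


def compare_candidates(pairs: Sequence[PairedRecord]) -> CandidateComparison:
    """Rank the RPQ→SCAT candidates by CI half-width, then ±5 coverage.

    The domain-weighted candidate is omitted, with a logged warning, when the
    cohort carries no RPQ domain subscores.
    """
    if len(pairs) < 3:
        raise ValidationError(
            f"candidate comparison needs >= 3 matched pairs, got {len(pairs)}"
        )
    reports: dict[EquationId, AgreementReport] = {}
    for eq in _CANDIDATE_ORDER:
        try:
            reports[eq] = evaluate_equation(pairs, eq)
        except ValidationError as exc:
            if eq is EquationId.DOMAIN_WEIGHTED:
                logger.warning("domain-weighted candidate omitted: %s", exc)
            else:
                raise
    ranking = tuple(
        sorted(
            reports,
            key=lambda e: (
                reports[e].ci95_half_width,
                -reports[e].coverage_within_5,
                _CANDIDATE_ORDER.index(e),
            ),
        )
    )
    return CandidateComparison(ranking=ranking, reports=reports)
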