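"""Agreement analyses: rank correlations, prediction error, concordance."""

import math
import random

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rpqscat import (
    Domain,
    EquationId,
    PairedRecord,
    ScaleId,
    ScoreSummary,
    UndefinedStatisticError,
    ValidationError,
    calibrate_defaults,
    compare_candidates,
    concordance_auc,
    evaluate_equation,
    rpq_to_scat,
    scat_to_rpq,
    simulate_cohort,
    spearman_rho,
)
from rpqscat.scales import NAMED_DOMAINS


def rank_then_pearson(x, y):
    """Independent oracle: mid-ranks by hand, then a plain Pearson correlation."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    sxy = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    sxx = sum((a - mx) ** 2 for a in rx)
    syy = sum((b - my) ** 2 for b in ry)
    return sxy / math.sqrt(sxx * syy)


def brute_force_auc(scores, positive):
    """Exhaustive pairwise oracle: P(pos > neg) + 0.5 P(tie)."""
    wins = ties = n = 0
    for s, flag in zip(scores, positive):
        if not flag:
            continue
        for t, other in zip(scores, positive):
            if other:
                continue
            n += 1
            wins += s > t
            ties += s == t
    return (wins + 0.5 * ties) / n


def _summary(scale_id, total, count, domains=None):
    return ScoreSummary(
        scale_id=ScaleId(scale_id),
        total=total,
        symptom_count=count,
        domain_scores=domains,
    )


def _pair(i, rpq_total, rpq_count, scat_total, scat_count, rpq_domains=None):
    return PairedRecord(
        subject_id=f"P{i}",
        week=1,
        rpq=_summary("rpq", rpq_total, rpq_count, rpq_domains),
        scat=_summary("scat", scat_total, scat_count),
    )


class TestSpearman:
    def test_monotone_cases(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3, 4], [40, 30, 20, 10]) == pytest.approx(-1.0)

    def test_tied_case_matches_midrank_oracle(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        assert spearman_rho(x, y) == pytest.approx(rank_then_pearson(x, y))

    def test_constant_input_is_an_error_not_a_silent_zero(self):
        with pytest.raises(UndefinedStatisticError):
            spearman_rho([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValidationError):
            spearman_rho([1, 2], [1, 2])

    @given(
        st.lists(st.integers(0, 8), min_size=3, max_size=30),
        st.data(),
    )
    def test_matches_midrank_oracle_on_random_tied_vectors(self, x, data):
        y = data.draw(st.lists(st.integers(0, 8), min_size=len(x), max_size=len(x)))
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        assert spearman_rho(x, y) == pytest.approx(rank_then_pearson(x, y))

    @given(st.lists(st.integers(0, 50), min_size=4, max_size=25, unique=True), st.data())
    def test_invariant_under_strictly_increasing_transforms(self, x, data):
        y = data.draw(st.lists(st.integers(0, 9), min_size=len(x), max_size=len(x)))
        if len(set(y)) < 2:
            return
        base = spearman_rho(x, y)
        assert spearman_rho([math.exp(v / 10) for v in x], y) == pytest.approx(base)
        assert spearman_rho(x, [3 * v + 1 for v in y]) == pytest.approx(base)


class TestEvaluateEquation:
    def _identity_cohort(self):
        # actual RPQ total equals the rounded SCAT->RPQ prediction
        pairs = []
        for i, scat_total in enumerate([10, 25, 40, 60, 85, 110]):
            rpq_total = scat_to_rpq(scat_total).rounded_value
            pairs.append(_pair(i, rpq_total, min(rpq_total, 16), scat_total, 12))
        return pairs

    def test_perfect_predictions(self):
        report = evaluate_equation(self._identity_cohort(), "eq2")
        assert report.mean_error == 0.0
        assert report.coverage_within_3 == 1.0
        assert report.coverage_within_5 == 1.0
        assert report.ci95_half_width == 0.0
        assert report.bias_slope == pytest.approx(0.0)

    def test_constant_offset_predictions(self):
        # actual = prediction - 5, so every signed error is exactly +5
        pairs = []
        for i, (t, c) in enumerate([(20, 10), (30, 12), (40, 14), (52, 15)]):
            pred = rpq_to_scat(t, c).rounded_value
            pairs.append(_pair(i, t, c, pred - 5, 10))
        report = evaluate_equation(pairs, EquationId.EQ1_RPQ_TO_SCAT)
        assert report.mean_error == 5.0
        assert report.coverage_within_3 == 0.0
        assert report.coverage_within_5 == 1.0
        assert report.sd_error == 0.0

    def test_too_few_pairs(self):
        with pytest.raises(ValidationError):
            evaluate_equation(self._identity_cohort()[:2], "eq2")

    def test_direction_consistency_check(self):
        pairs = self._identity_cohort()
        assert evaluate_equation(pairs, "eq2", direction="scat2rpq").n_pairs == 6
        with pytest.raises(ValidationError, match="direction"):
            evaluate_equation(pairs, "eq2", direction="rpq2scat")

    def test_full_report_on_simulated_cohort(self, default_cohort):
        report = evaluate_equation(default_cohort, "eq1")
        assert 0.85 <= report.rho_total <= 0.95
        assert -1 <= report.rho_count <= 1
        assert report.n_pairs == len(default_cohort)
        assert 0 <= report.coverage_within_3 <= report.coverage_within_5 <= 1
        for rho in report.rho_by_domain.values():
            assert -1 <= rho <= 1
        # both somatic conventions present when item-level data is attached
        assert "somatic" in report.rho_by_domain
        assert "somatic_no_fatigue" in report.rho_by_domain
        for week, rho in report.rho_by_week.items():
            assert week in {1, 2, 3, 4, 5, 6, 7, 8, 12, 16}
            assert -1 <= rho <= 1
        assert sum(n for _, n in report.rho_by_zone.values()) <= report.n_pairs
        for auc in report.concordance_auc.values():
            assert 0 <= auc <= 1
        # the published equations under-predict high actual scores on average
        assert report.bias_slope is not None

    def test_report_is_permutation_invariant(self, default_cohort):
        shuffled = list(default_cohort)
        random.Random(1).shuffle(shuffled)
        a = evaluate_equation(default_cohort, "eq1").to_dict()
        b = evaluate_equation(shuffled, "eq1").to_dict()

        def approx_equal(u, v):
            if isinstance(u, dict):
                assert set(u) == set(v)
                for k in u:
                    approx_equal(u[k], v[k])
            elif isinstance(u, float):
                assert v == pytest.approx(u)
            else:
                assert u == v

        approx_equal(a, b)

    def test_total_correlation_dominates_domain_correlations_on_average(self):
        gaps = []
        for seed in range(10):
            pairs = simulate_cohort(calibrate_defaults(seed=seed))
            report = evaluate_equation(pairs, "eq1")
            domain_mean = np.mean(
                [report.rho_by_domain[d.value] for d in NAMED_DOMAINS]
            )
            gaps.append(report.rho_total - domain_mean)
        assert np.mean(gaps) > 0

    def test_small_strata_are_absent_not_fabricated(self):
        # all six pairs sit in the low zone at week 1: no other strata reported
        pairs = [
            _pair(i, t, min(t, 16), s, min(s, 22))
            for i, (t, s) in enumerate([(1, 2), (3, 5), (5, 9), (7, 12), (9, 16), (11, 20)])
        ]
        report = evaluate_equation(pairs, "eq2")
        assert set(report.rho_by_week) == {1}
        assert {z.value for z in report.rho_by_zone} == {"low"}


class TestConcordance:
    def test_perfect_separation(self):
        pairs = [_pair(i, t, min(t, 16), s, 5) for i, (t, s) in
                 enumerate([(5, 10), (10, 20), (20, 40), (30, 60), (40, 90), (50, 120)])]
        assert concordance_auc(pairs, "eq1", 50) == 1.0

    def test_one_class_is_an_error(self):
        pairs = [_pair(i, 5, 5, 10, 5) for i in range(4)]
        with pytest.raises(UndefinedStatisticError):
            concordance_auc(pairs, "eq1", 120)

    def test_four_pair_toy_set_matches_exhaustive_oracle(self):
        pairs = [
            _pair(0, 10, 8, 20, 9),
            _pair(1, 20, 10, 30, 12),
            _pair(2, 15, 9, 40, 14),
            _pair(3, 30, 12, 28, 11),
        ]
        preds = [rpq_to_scat(p.rpq.total, p.rpq.symptom_count).rounded_value for p in pairs]
        actual = [p.scat.total for p in pairs]
        expected = brute_force_auc(preds, [a > 29 for a in actual])
        assert concordance_auc(pairs, "eq1", 29) == pytest.approx(expected)

    def test_matches_brute_force_on_random_cohorts(self):
        rng = random.Random(2024)
        for _ in range(20):
            n = rng.randint(5, 50)
            pairs = []
            for i in range(n):
                t = rng.randint(1, 64)
                c = rng.randint((t + 3) // 4, min(16, t))
                s = rng.randint(0, 132)
                pairs.append(_pair(i, t, c, s, min(max(s, 1), 22) if s else 0))
            thr = rng.choice([25, 50, 75])
            actual = [p.scat.total for p in pairs]
            if len({a > thr for a in actual}) < 2:
                continue
            preds = [
                rpq_to_scat(p.rpq.total, p.rpq.symptom_count).rounded_value
                for p in pairs
            ]
            assert concordance_auc(pairs, "eq1", thr) == pytest.approx(
                brute_force_auc(preds, [a > thr for a in actual])
            )

    def test_class_independent_predictions_give_half(self):
        rng = np.random.default_rng(99)
        scores = rng.integers(0, 100, size=2000).astype(float)
        labels = rng.random(2000) < 0.5
        from rpqscat.agreement import _mann_whitney_auc

        assert _mann_whitney_auc(scores, labels) == pytest.approx(0.5, abs=0.05)


# Rows (rpq_total, rpq_count, somatic, cognitive, emotional, sleep, prediction)
# on which all three RPQ->SCAT candidates round to the same SCAT score;
# found by exhaustive search over the score lattice.
_TIE_ROWS = [
    (15, 14, 0, 0, 8, 3, 25),
    (18, 14, 0, 0, 9, 4, 30),
    (21, 14, 0, 1, 12, 3, 35),
    (24, 14, 0, 2, 12, 4, 40),
    (27, 14, 0, 6, 12, 3, 45),
]


class TestCompareCandidates:
    def _tie_cohort(self):
        pairs = []
        for i, (t, c, som, cog, emo, slp, pred) in enumerate(_TIE_ROWS):
            domains = {
                Domain.SOMATIC: som,
                Domain.COGNITIVE: cog,
                Domain.EMOTIONAL: emo,
                Domain.SLEEP: slp,
                Domain.UNCLASSIFIED: t - som - cog - emo - slp,
            }
            pairs.append(_pair(i, t, c, pred, 10 + i, rpq_domains=domains))
        return pairs

    def test_identical_predictions_tie_broken_by_fixed_order(self):
        from rpqscat import (
            rpq_to_scat_direct_proportion,
            rpq_to_scat_domain_weighted,
        )

        pairs = self._tie_cohort()
        for p in pairs:  # the construction really does tie all three
            e1 = rpq_to_scat(p.rpq.total, p.rpq.symptom_count).rounded_value
            e2 = rpq_to_scat_direct_proportion(p.rpq.total).rounded_value
            e3 = rpq_to_scat_domain_weighted(p.rpq.domain_scores).rounded_value
            assert e1 == e2 == e3 == p.scat.total
        comparison = compare_candidates(pairs)
        assert comparison.ranking == (
            EquationId.EQ1_RPQ_TO_SCAT,
            EquationId.DIRECT_PROPORTION,
            EquationId.DOMAIN_WEIGHTED,
        )
        reports = list(comparison.reports.values())
        assert all(r.ci95_half_width == 0.0 for r in reports)

    def test_single_pair_is_an_error(self):
        with pytest.raises(ValidationError):
            compare_candidates(self._tie_cohort()[:1])

    def test_deterministic_on_simulated_cohort(self, default_cohort):
        a = compare_candidates(default_cohort)
        b = compare_candidates(default_cohort)
        assert a.ranking == b.ranking
        assert set(a.reports) == {
            EquationId.EQ1_RPQ_TO_SCAT,
            EquationId.DIRECT_PROPORTION,
            EquationId.DOMAIN_WEIGHTED,
        }
        for report in a.reports.values():
            assert np.isfinite(report.ci95_half_width)

    def test_domain_candidate_omitted_without_subscores(self, caplog):
        pairs = [_pair(i, t, min(t, 16), s, 8) for i, (t, s) in
                 enumerate([(10, 20), (20, 35), (30, 55), (40, 70)])]
        with caplog.at_level("WARNING", logger="rpqscat.agreement"):
            comparison = compare_candidates(pairs)
        assert EquationId.DOMAIN_WEIGHTED not in comparison.reports
        assert "domain-weighted" in caplog.text
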