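"""Contingency construction and OR/ARI/accuracy/PPV/information gain."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from pgxstrat import (
    Cohort,
    GroupAlleleCounts,
    PGxAnnotation,
    VariantRecord,
    accuracy_ci,
    ari_ci,
    build_contingency,
    info_gain,
    odds_ratio_ci,
    risk_table,
)
from pgxstrat.cohort import UndefinedStatisticError
from pgxstrat.risk import compute_risk_stats, info_gain_by_group

counts_strategy = hst.builds(
    GroupAlleleCounts,
    implicated_group=hst.just("g"),
    unit=hst.just("allele"),
    p_e=hst.integers(1, 200),
    p_n=hst.integers(1, 200),
    q_e=hst.integers(1, 200),
    q_n=hst.integers(1, 200),
)


def _pgx_cohort(group_dosages: dict[str, list], mode="additive"):
    labels, dosages = [], []
    for grp, ds in group_dosages.items():
        labels += [grp] * len(ds)
        dosages += list(ds)
    ann = PGxAnnotation(mode, "warfarin", "dosage", "")
    return Cohort(
        [f"s{i}" for i in range(len(dosages))],
        np.array(dosages, float).reshape(-1, 1),
        [VariantRecord("rs1", "1", 1, "A", "G", ann)],
        sire_labels=np.array(labels, dtype=object),
    ), np.array(labels, dtype=object)


class TestBuildContingency:
    def test_additive_counts_alleles(self):
        cohort, labels = _pgx_cohort({"g": [2, 1, 0], "h": [0, 0]})
        c = build_contingency(cohort, "rs1", "g", labels)
        assert (c.p_e, c.p_n, c.unit) == (3, 3, "allele")

    def test_dominant_counts_carriers(self):
        cohort, labels = _pgx_cohort({"g": [2, 1, 0], "h": [0, 0]}, mode="dominant")
        c = build_contingency(cohort, "rs1", "g", labels)
        assert (c.p_e, c.p_n, c.unit) == (2, 1, "genotype")

    def test_missing_excluded_from_both_strata(self):
        cohort, labels = _pgx_cohort({"g": [1, 1, np.nan], "h": [0, 2]})
        c = build_contingency(cohort, "rs1", "g", labels)
        assert (c.p_e, c.p_n, c.q_e, c.q_n) == (2, 2, 2, 2)

    def test_empty_stratum_errors(self):
        cohort, labels = _pgx_cohort({"g": [1, 1], "h": [np.nan, np.nan]})
        with pytest.raises(UndefinedStatisticError):
            build_contingency(cohort, "rs1", "g", labels)


class TestOddsRatio:
    def test_identical_strata_or_one(self):
        c = GroupAlleleCounts("g", "allele", 10, 90, 10, 90)
        assert odds_ratio_ci(c).estimate == pytest.approx(1.0)

    def test_hand_evaluated_or_and_ci(self):
        c = GroupAlleleCounts("g", "allele", 30, 70, 10, 90)
        res = odds_ratio_ci(c)
        assert res.estimate == pytest.approx(27 / 7, rel=1e-12)
        assert res.low == pytest.approx(1.766, abs=0.005)
        assert res.high == pytest.approx(8.422, abs=0.005)

    def test_zero_cell_undefined_unless_corrected(self):
        c = GroupAlleleCounts("g", "allele", 0, 10, 5, 5)
        with pytest.raises(UndefinedStatisticError):
            odds_ratio_ci(c)
        assert odds_ratio_ci(c, haldane=True).estimate > 0

    @given(counts_strategy)
    def test_swapping_strata_gives_reciprocal(self, c):
        swapped = GroupAlleleCounts("h", c.unit, c.q_e, c.q_n, c.p_e, c.p_n)
        assert odds_ratio_ci(swapped).estimate == pytest.approx(
            1 / odds_ratio_ci(c).estimate, rel=1e-9
        )


class TestAri:
    def test_identical_strata_zero(self):
        c = GroupAlleleCounts("g", "allele", 10, 90, 10, 90)
        assert ari_ci(c).estimate == 0.0

    def test_hand_evaluated_difference(self):
        c = GroupAlleleCounts("g", "allele", 30, 70, 10, 90)
        assert ari_ci(c).estimate == pytest.approx(20.0)

    @given(counts_strategy)
    def test_antisymmetric_under_stratum_swap(self, c):
        swapped = GroupAlleleCounts("h", c.unit, c.q_e, c.q_n, c.p_e, c.p_n)
        assert ari_ci(swapped).estimate == pytest.approx(-ari_ci(c).estimate)


class TestAccuracy:
    def test_perfect_separation(self):
        c = GroupAlleleCounts("g", "allele", 100, 0, 0, 100)
        assert accuracy_ci(c).estimate == 1.0

    def test_hand_evaluated_accuracy(self):
        c = GroupAlleleCounts("g", "allele", 30, 70, 10, 90)
        res = accuracy_ci(c)
        assert res.estimate == pytest.approx(0.60)
        # half-width z*sqrt((err/(1-err))/N) with err = 0.4
        half = 1.959963985 * np.sqrt((0.4 / 0.6) / 200)
        assert res.high - res.estimate == pytest.approx(half, rel=1e-6)

    @given(counts_strategy)
    def test_invariant_under_tp_tn_swap(self, c):
        swapped = GroupAlleleCounts(c.implicated_group, c.unit,
                                    c.q_n, c.q_e, c.p_n, c.p_e)
        assert accuracy_ci(swapped).estimate == pytest.approx(
            accuracy_ci(c).estimate
        )


class TestInfoGain:
    @pytest.mark.parametrize(
        "cells, ppv, prev, gain",
        [
            ((20, 80, 30, 120), 0.2, 0.2, 0.0),   # group freq == prevalence
            ((30, 70, 10, 90), 0.3, 0.2, 10.0),
            ((100, 0, 0, 100), 1.0, 0.5, 50.0),
        ],
    )
    def test_hand_evaluated_gains(self, cells, ppv, prev, gain):
        res = info_gain(GroupAlleleCounts("g", "allele", *cells))
        assert res.ppv == pytest.approx(ppv)
        assert res.prevalence == pytest.approx(prev)
        assert res.info_gain_per_100 == pytest.approx(gain)

    @given(counts_strategy)
    def test_consistency_of_direction_indicators(self, c):
        """OR > 1 iff ARI > 0 iff PPV above the complement rate."""
        or_ = odds_ratio_ci(c).estimate
        ari = ari_ci(c).estimate
        ppv = info_gain(c).ppv
        q_rate = c.q_e / (c.q_e + c.q_n)
        assert (or_ > 1) == (ari > 0) == (ppv > q_rate) or or_ == 1
        res = info_gain(c)
        assert 0 <= res.info_gain_per_100 <= 100 * max(res.ppv, 1 - res.ppv)


class TestRiskTable:
    def test_null_cohort_all_or_one(self):
        cohort, labels = _pgx_cohort(
            {"g": [0, 1, 2, 1], "h": [0, 1, 2, 1], "i": [0, 1, 2, 1]}
        )
        per_variant, per_group = risk_table(cohort, labels)
        row = per_variant.iloc[0]
        assert row.odds_ratio == pytest.approx(1.0)
        assert row.ari == pytest.approx(0.0)
        assert row.info_gain_per_100 == pytest.approx(0.0)
        assert (per_group.info_gain_per_100 == 0).all()

    def test_single_variant_composition(self):
        """Table row composes the four verified statistics for (30,70,10,90)."""
        cohort, labels = _pgx_cohort(
            {"g": [2] * 15 + [0] * 35, "h": [2] * 5 + [0] * 45}
        )
        per_variant, _ = risk_table(cohort, labels)
        row = per_variant.iloc[0]
        assert row.implicated_group == "g"
        assert row.odds_ratio == pytest.approx(27 / 7)
        assert row.ari == pytest.approx(20.0)
        assert row.accuracy == pytest.approx(0.6)
        assert row.info_gain_per_100 == pytest.approx(10.0)
        assert row.freq_g == pytest.approx(0.3)
        assert row.freq_h == pytest.approx(0.1)

    def test_divergent_minority_gains_most(self, default_sim):
        """The most diverged group shows the highest median info gain."""
        cohort, truth = default_sim
        _, per_group = risk_table(cohort, cohort.sire_labels)
        gain = info_gain_by_group(per_group).set_index("group")["median"]
        # Black (82% AFR) is most diverged from the EUR-dominated rest
        assert gain["Black"] > gain["White"]

    def test_compute_risk_stats_confusion_layout(self):
        c = GroupAlleleCounts("g", "allele", 30, 70, 10, 90)
        rs = compute_risk_stats(c)
        assert rs.confusion == (30, 10, 70, 90)  # TP, FP, FN, TN
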