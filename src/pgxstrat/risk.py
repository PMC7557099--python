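"""Evidence-based-medicine layer: OR, ARI, accuracy, PPV, information gain.

For each PGx variant and an implicated group, a 2x2 table is built
against the pooled complement of the other groups. The counting unit
follows the annotated effect mode: additive variants are counted on the
allele scale (P_E/P_N = effect/non-effect allele counts), dominant
variants on the genotype scale (P_E/P_N = carriers/non-carriers, a
carrier having dosage >= 1).

From the table (P_E, P_N, Q_E, Q_N):

* odds ratio  OR = (P_E/P_N) / (Q_E/Q_N), CI on the log scale with
  SE = sqrt(1/P_E + 1/P_N + 1/Q_E + 1/Q_N);
* absolute risk increase  ARI = 100 (p1 - p2) percentage points with a
  Wald CI for a difference of proportions;
* prediction accuracy with TP = P_E, FP = Q_E, FN = P_N, TN = Q_N;
* positive predictive value PPV = P_E/(P_E+P_N) (the post-test
  probability after stratification), overall prevalence as the pre-test
  probability, and information gain per 100 patients
  100 |PPV - prevalence| — the number of additional correct effect
  predictions bought by stratifying on group membership.
"""

from __future__ import annotations

import logging
import math
from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, UndefinedStatisticError

logger = logging.getLogger(__name__)

CI = namedtuple("CI", "estimate low high")


@dataclass(frozen=True)
class GroupAlleleCounts:
    """2x2 effect/non-effect counts: implicated group vs pooled complement."""

    implicated_group: str
    unit: str  # "allele" (additive mode) or "genotype" (dominant mode)
    p_e: int
    p_n: int
    q_e: int
    q_n: int

    def __post_init__(self) -> None:
        if self.unit not in ("allele", "genotype"):
            raise ValueError("unit must be 'allele' or 'genotype'")
        if min(self.p_e, self.p_n, self.q_e, self.q_n) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.p_e + self.p_n + self.q_e + self.q_n


@dataclass
class RiskStats:
    """All risk statistics for one variant x one implicated group."""

    counts: GroupAlleleCounts
    odds_ratio: CI
    ari: CI                  # percentage points
    accuracy: CI
    ppv: float
    prevalence_overall: float
    info_gain_per_100: float
    confusion: tuple[int, int, int, int]  # TP, FP, FN, TN


def _z(alpha: float) -> float:
    return float(stats.norm.ppf(1 - alpha / 2))


def build_contingency(
    cohort: Cohort, variant_id: str, implicated_group: str, group_labels
) -> GroupAlleleCounts:
    """Count effect vs non-effect units for a group and its complement.

    Additive mode counts alleles among typed members; dominant mode
    counts carrier vs non-carrier individuals. Missing genotypes are
    excluded. A stratum with no typed member is an error.
    """
    variant = cohort.variant(variant_id)
    if variant.pgx is None:
        raise ValueError(f"{variant_id} has no PGx annotation")
    labels = np.asarray(group_labels, dtype=object).astype(str)
    g = cohort.dosages(variant_id)
    in_mask = labels == str(implicated_group)
    if not in_mask.any():
        raise ValueError(f"unknown group {implicated_group!r}")
    counts = []
    for mask in (in_mask, ~in_mask):
        sub = g[mask]
        sub = sub[~np.isnan(sub)]
        if sub.size == 0:
            raise UndefinedStatisticError(
                f"{variant_id}: no typed members in one stratum"
            )
        if variant.pgx.mode == "additive":
            eff = int(sub.sum())
            non = 2 * sub.size - eff
        else:  # dominant: carriers vs non-carriers
            eff = int((sub >= 1).sum())
            non = sub.size - eff
        counts.extend((eff, non))
    unit = "allele" if variant.pgx.mode == "additive" else "genotype"
    return GroupAlleleCounts(str(implicated_group), unit, *counts)


def odds_ratio_ci(
    counts: GroupAlleleCounts, alpha: float = 0.05, haldane: bool = False
) -> CI:
    """Cross-product odds ratio with a log-scale Wald CI.

    Zero cells make the OR undefined; with ``haldane=True`` the
    Haldane–Anscombe 0.5 correction is added to every cell instead.
    """
    cells = [counts.p_e, counts.p_n, counts.q_e, counts.q_n]
    if min(cells) == 0:
        if not haldane:
            raise UndefinedStatisticError("zero cell: OR undefined without correction")
        cells = [c + 0.5 for c in cells]
    pe, pn, qe, qn = cells
    or_ = (pe / pn) / (qe / qn)
    se = math.sqrt(1 / pe + 1 / pn + 1 / qe + 1 / qn)
    z = _z(alpha)
    return CI(or_, or_ * math.exp(-z * se), or_ * math.exp(z * se))


def ari_ci(counts: GroupAlleleCounts, alpha: float = 0.05) -> CI:
    """Absolute risk increase, in percentage points, with a Wald CI."""
    n1 = counts.p_e + counts.p_n
    n2 = counts.q_e + counts.q_n
    if n1 == 0 or n2 == 0:
        raise UndefinedStatisticError("empty stratum: ARI undefined")
    p1 = counts.p_e / n1
    p2 = counts.q_e / n2
    ari = p1 - p2
    se = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    z = _z(alpha)
    return CI(100 * ari, 100 * (ari - z * se), 100 * (ari + z * se))


def accuracy_ci(
    counts: GroupAlleleCounts, alpha: float = 0.05, method: str = "error-odds"
) -> CI:
    """Prediction accuracy of group membership for the effect unit.

    TP = effect units in the implicated group, FP = effect units in the
    complement, FN = non-effect units in the implicated group, TN =
    non-effect units in the complement. The default CI half-width is
    z * sqrt((Err/(1-Err))/N) with Err the misclassification rate;
    ``method="wald"`` gives the standard binomial Wald interval.
    """
    tp, fp, fn, tn = counts.p_e, counts.q_e, counts.p_n, counts.q_n
    n = tp + fp + fn + tn
    if n == 0:
        raise UndefinedStatisticError("empty table")
    acc = (tp + tn) / n
    err = (fp + fn) / n
    z = _z(alpha)
    if method == "wald":
        half = z * math.sqrt(acc * (1 - acc) / n)
    elif method == "error-odds":
        if err == 1:
            raise UndefinedStatisticError("error rate 1: CI undefined")
        half = z * math.sqrt((err / (1 - err)) / n)
    else:
        raise ValueError("method must be 'error-odds' or 'wald'")
    return CI(acc, acc - half, acc + half)


InfoGainResult = namedtuple("InfoGainResult", "ppv prevalence info_gain_per_100")


def info_gain(counts: GroupAlleleCounts) -> InfoGainResult:
    """Pre- vs post-test comparison for stratification by group.

    PPV (post-test probability) is the within-group effect fraction;
    prevalence (pre-test probability) is the cohort-wide effect
    fraction; the information gained is 100 |PPV - prevalence| extra
    correct predictions per 100 patients.
    """
    n_in = counts.p_e + counts.p_n
    if n_in == 0:
        raise UndefinedStatisticError("empty implicated group")
    ppv = counts.p_e / n_in
    prevalence = (counts.p_e + counts.q_e) / counts.total
    return InfoGainResult(ppv, prevalence, 100 * abs(ppv - prevalence))


def compute_risk_stats(
    counts: GroupAlleleCounts, alpha: float = 0.05, haldane: bool = False
) -> RiskStats:
    """All statistics for one contingency table."""
    ig = info_gain(counts)
    return RiskStats(
        counts=counts,
        odds_ratio=odds_ratio_ci(counts, alpha, haldane=haldane),
        ari=ari_ci(counts, alpha),
        accuracy=accuracy_ci(counts, alpha),
        ppv=ig.ppv,
        prevalence_overall=ig.prevalence,
        info_gain_per_100=ig.info_gain_per_100,
        confusion=(counts.p_e, counts.q_e, counts.p_n, counts.q_n),
    )


def risk_table(
    cohort: Cohort,
    group_labels,
    alpha: float = 0.05,
    haldane: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Risk statistics for every PGx variant x group.

    Returns ``(per_variant, per_group)``: the first has one row per PGx
    variant with per-group effect frequencies and the full statistics
    for the implicated ("reference") group — the group with the highest
    effect frequency; the second has one row per variant x group for
    group-level distributions such as the per-group information-gain
    spread. Variants whose statistics are undefined (zero cells without
    the Haldane correction, empty strata) are logged and reported with
    ``ok=False`` in the per-variant table.
    """
    labels = np.asarray(group_labels, dtype=object).astype(str)
    groups = sorted(set(labels))
    per_variant_rows = []
    per_group_rows = []
    for variant in cohort.variants:
        if variant.pgx is None:
            continue
        vid = variant.variant_id
        freqs: dict[str, float] = {}
        stats_by_group: dict[str, RiskStats | None] = {}
        for grp in groups:
            try:
                counts = build_contingency(cohort, vid, grp, labels)
                n_in = counts.p_e + counts.p_n
                freqs[grp] = counts.p_e / n_in
                stats_by_group[grp] = compute_risk_stats(counts, alpha, haldane)
            except UndefinedStatisticError as exc:
                logger.warning("%s in group %s: %s", vid, grp, exc)
                freqs[grp] = np.nan
                stats_by_group[grp] = None
        for grp in groups:
            rs = stats_by_group[grp]
            per_group_rows.append(
                {
                    "variant_id": vid,
                    "group": grp,
                    "mode": variant.pgx.mode,
                    "effect_freq": freqs[grp],
                    "ppv": rs.ppv if rs else np.nan,
                    "prevalence": rs.prevalence_overall if rs else np.nan,
                    "info_gain_per_100": rs.info_gain_per_100 if rs else np.nan,
                }
            )
        implicated = max(freqs, key=lambda g: (np.nan_to_num(freqs[g], nan=-1)))
        rs = stats_by_group[implicated]
        row = {
            "variant_id": vid,
            "drug": variant.pgx.drug,
            "effect_type": variant.pgx.effect_type,
            "mode": variant.pgx.mode,
            **{f"freq_{g}": freqs[g] for g in groups},
            "implicated_group": implicated,
            "ok": rs is not None,
        }
        if rs is not None:
            row.update(
                odds_ratio=rs.odds_ratio.estimate,
                or_ci_low=rs.odds_ratio.low,
                or_ci_high=rs.odds_ratio.high,
                ari=rs.ari.estimate,
                ari_ci_low=rs.ari.low,
                ari_ci_high=rs.ari.high,
                accuracy=rs.accuracy.estimate,
                accuracy_ci_low=rs.accuracy.low,
                accuracy_ci_high=rs.accuracy.high,
                ppv=rs.ppv,
                prevalence=rs.prevalence_overall,
                info_gain_per_100=rs.info_gain_per_100,
            )
        per_variant_rows.append(row)
    return pd.DataFrame(per_variant_rows), pd.DataFrame(per_group_rows)


def info_gain_by_group(per_group: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles of information gain per group (Fig-5 style)."""
    return (
        per_group.groupby("group")["info_gain_per_100"]
        .agg(
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
            n="count",
        )
        .reset_index()
    )
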