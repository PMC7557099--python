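"""Regression layer: ancestry-genotype association and SIRE-vs-GA slopes.

Two analyses:

1. Ancestry association — for a variant and a continental component,
   ordinary least squares of the ancestry fraction on the effect-allele
   dosage (0/1/2), with a t test on the slope. A positive slope means
   the effect allele travels with that ancestry.

2. Slope comparison of grouping systems — per-variant effect-allele
   frequency differences for a pair of SIRE groups are regressed on the
   differences for the corresponding GA groups. Two hypotheses are
   tested on the slope: H0: beta = 0 (two-sided; are the two systems
   correlated at all) and H0: beta = 1 against beta < 1 (one-tailed;
   does GA resolve more divergence than SIRE). The effect size
   d = (1 - beta_obs)/2 maps the attainable slope range [-1, 1] onto
   [0, 1].

Degenerate fits with zero residual variance (exactly collinear data)
get limit-case p-values: p0 = 1 if beta = 0 else 0, and p1 = 1 if
beta >= 1 else 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .cohort import ANCESTRY_COMPONENTS, Cohort, UndefinedStatisticError, \
    effect_allele_frequency


@dataclass
class SlopeTest:
    """OLS slope with tests against beta = 0 and beta = 1."""

    beta: float
    intercept: float
    se: float
    df: int
    t0: float
    p0: float  # two-sided, H0: beta = 0
    t1: float
    p1: float  # one-tailed, H0: beta = 1 vs beta < 1
    d: float   # (1 - beta)/2


@dataclass
class AncestryAssociation:
    variant_id: str
    ancestry_component: str
    beta: float
    se: float
    t: float
    p_value: float
    n: int


def fit_slope(x, y) -> SlopeTest:
    """OLS with intercept plus the two slope hypothesis tests."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-D arrays")
    n = x.size
    if n < 3:
        raise UndefinedStatisticError("need at least 3 points")
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("zero variance in x: slope undefined")
    res = stats.linregress(x, y)
    beta, se = float(res.slope), float(res.stderr)
    df = n - 2
    if se == 0.0:  # exact collinearity: limit-case p-values
        t0 = np.inf if beta != 0 else 0.0
        p0 = 0.0 if beta != 0 else 1.0
        t1 = np.inf * np.sign(beta - 1) if beta != 1 else 0.0
        p1 = 1.0 if beta >= 1 else 0.0
    else:
        t0 = beta / se
        p0 = 2 * stats.t.sf(abs(t0), df)
        t1 = (beta - 1.0) / se
        p1 = stats.t.cdf(t1, df)
    return SlopeTest(
        beta=beta, intercept=float(res.intercept), se=se, df=df,
        t0=float(t0), p0=float(p0), t1=float(t1), p1=float(p1),
        d=(1.0 - beta) / 2.0,
    )


def ancestry_association(
    cohort: Cohort, variant_id: str, ancestry_component: str
) -> AncestryAssociation:
    """OLS of an ancestry fraction on effect-allele dosage, with t test."""
    if ancestry_component not in ANCESTRY_COMPONENTS:
        raise ValueError(f"component must be one of {ANCESTRY_COMPONENTS}")
    if cohort.ancestry is None:
        raise ValueError("cohort has no ancestry fractions")
    g = cohort.dosages(variant_id)
    y = cohort.ancestry[:, ANCESTRY_COMPONENTS.index(ancestry_component)]
    keep = ~np.isnan(g) & ~np.isnan(y)
    x, y = g[keep], y[keep]
    if x.size < 3:
        raise UndefinedStatisticError("fewer than 3 typed samples")
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("constant dosage: slope undefined")
    if np.ptp(y) == 0:
        # no ancestry variation at all: slope 0 with no evidence
        return AncestryAssociation(variant_id, ancestry_component,
                                   0.0, 0.0, 0.0, 1.0, int(x.size))
    res = stats.linregress(x, y)
    beta, se = float(res.slope), float(res.stderr)
    if se == 0.0:
        t = np.inf if beta != 0 else 0.0
        p = 0.0 if beta != 0 else 1.0
    else:
        t = beta / se
        p = 2 * stats.t.sf(abs(t), x.size - 2)
    return AncestryAssociation(
        variant_id, ancestry_component, beta, se, float(t), float(p), int(x.size)
    )


def freq_diff_regression(freq_diffs_sire, freq_diffs_ga) -> SlopeTest:
    """Regress SIRE frequency differences (y) on GA differences (x)."""
    return fit_slope(freq_diffs_ga, freq_diffs_sire)


def _pair_freq_diffs(cohort, variant_ids, labels, a, b) -> np.ndarray:
    labels = np.asarray(labels, dtype=object).astype(str)
    diffs = np.full(len(variant_ids), np.nan)
    mask_a = labels == a
    mask_b = labels == b
    for i, vid in enumerate(variant_ids):
        try:
            fa = effect_allele_frequency(cohort, vid, mask_a).frequency
            fb = effect_allele_frequency(cohort, vid, mask_b).frequency
        except UndefinedStatisticError:
            continue
        diffs[i] = fa - fb
    return diffs


def compare_sire_ga_slopes(
    cohort: Cohort,
    sire_labels,
    ga_assignments,
    ga_to_sire: Mapping[int, str],
    variant_ids: Sequence[str] | None = None,
) -> dict[tuple[str, str], SlopeTest]:
    """Slope tests for every aligned SIRE/GA group pair.

    ``ga_to_sire`` is the cluster-to-label pairing from the concordance
    step. For each pair of SIRE labels (lexicographic orientation, so
    delta-p signs are reproducible), per-variant frequency differences
    are computed under both groupings — the GA pair being the clusters
    paired with those labels — and regressed. Defaults to the PGx
    variant subset.
    """
    if variant_ids is None:
        variant_ids = [v.variant_id for v in cohort.variants if v.pgx is not None]
    if len(variant_ids) < 3:
        raise UndefinedStatisticError("need at least 3 variants")
    sire = np.asarray(sire_labels, dtype=object).astype(str)
    ga = np.asarray(ga_assignments)
    sire_of_cluster = {int(k): str(v) for k, v in ga_to_sire.items()}
    cluster_of_sire = {v: k for k, v in sire_of_cluster.items()}
    ga_as_sire = np.array([sire_of_cluster[int(c)] for c in ga], dtype=object)

    results: dict[tuple[str, str], SlopeTest] = {}
    for a, b in combinations(sorted(cluster_of_sire), 2):
        dp_sire = _pair_freq_diffs(cohort, variant_ids, sire, a, b)
        dp_ga = _pair_freq_diffs(cohort, variant_ids, ga_as_sire, a, b)
        keep = ~np.isnan(dp_sire) & ~np.isnan(dp_ga)
        if keep.sum() < 3:
            raise UndefinedStatisticError(f"pair ({a},{b}): fewer than 3 usable variants")
        results[(a, b)] = freq_diff_regression(dp_sire[keep], dp_ga[keep])
    return results
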