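"""Per-variant population differentiation: FST, frequency scans, FDR.

The fixation index follows the two-population Nei decomposition: with
effect-allele frequencies p_i and allele counts n_i in each population,

    H̄_S = sum_i 2 p_i (1 - p_i) * n_i / (n_a + n_b)   (mean within-group
                                                        expected heterozygosity)
    p̄   = count-weighted mean frequency
    H_T  = 2 p̄ (1 - p̄)                                (total expected
                                                        heterozygosity)
    FST  = 1 - H̄_S / H_T

By Jensen's inequality H̄_S <= H_T, so FST lies in [0, 1]; it is
undefined (NaN) when the pooled sample is monomorphic (H_T = 0).

The group-vs-complement scan tests, for every variant and every group,
whether the effect-allele frequency differs between the group and the
pooled remainder, using a Pearson chi-square on the 2x2 allele-count
table (Fisher's exact test when any expected cell is below 5), with
Benjamini–Hochberg correction across all (variant, group) tests.
"""

from __future__ import annotations

import logging
from collections import namedtuple
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import Cohort, UndefinedStatisticError

logger = logging.getLogger(__name__)

FstResult = namedtuple("FstResult", "h_s_bar h_t fst")

FISHER_EXPECTED_MIN = 5.0


def pairwise_fst(p_a, n_a, p_b, n_b) -> FstResult:
    """FST between two populations from frequencies and allele counts.

    Accepts scalars or aligned arrays. ``n_a``/``n_b`` are the allele
    counts (2 x typed individuals) used as weights. Returns
    ``(h_s_bar, h_t, fst)``; ``fst`` is NaN where the pooled sample is
    monomorphic.
    """
    p_a = np.asarray(p_a, float)
    p_b = np.asarray(p_b, float)
    n_a = np.asarray(n_a, float)
    n_b = np.asarray(n_b, float)
    if (n_a <= 0).any() or (n_b <= 0).any():
        raise ValueError("allele counts must be positive")
    for p in (p_a, p_b):
        if np.nanmin(p, initial=0.0) < 0 or np.nanmax(p, initial=0.0) > 1:
            raise ValueError("frequencies must lie in [0,1]")
    w_a = n_a / (n_a + n_b)
    w_b = 1.0 - w_a
    h_s = 2 * p_a * (1 - p_a) * w_a + 2 * p_b * (1 - p_b) * w_b
    p_bar = w_a * p_a + w_b * p_b
    h_t = 2 * p_bar * (1 - p_bar)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(h_t > 0, 1.0 - h_s / h_t, np.nan)
    if fst.ndim == 0:
        return FstResult(float(h_s), float(h_t), float(fst))
    return FstResult(h_s, h_t, fst)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted q-values (monotone step-up)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _chi2_or_fisher_p(a, b, c, d) -> np.ndarray:
    """Two-sided p-values for 2x2 tables [[a,b],[c,d]], vectorized.

    Pearson chi-square (no continuity correction); Fisher's exact test
    where any expected cell is below ``FISHER_EXPECTED_MIN``. Tables with
    an empty margin get p = 1 (no evidence either way).
    """
    a, b, c, d = (np.asarray(x, float) for x in (a, b, c, d))
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    degenerate = (r1 == 0) | (r2 == 0) | (c1 == 0) | (c2 == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
        min_expected = np.minimum(r1, r2) * np.minimum(c1, c2) / n
    p = stats.chi2.sf(stat, df=1)
    p = np.where(degenerate, 1.0, p)
    needs_fisher = (~degenerate) & (min_expected < FISHER_EXPECTED_MIN)
    for i in np.flatnonzero(needs_fisher):
        table = [[int(a.flat[i]), int(b.flat[i])], [int(c.flat[i]), int(d.flat[i])]]
        p.flat[i] = stats.fisher_exact(table, alternative="two-sided")[1]
    return p


def _group_counts(genotypes: np.ndarray, mask: np.ndarray):
    """Per-variant effect-allele counts and allele totals for a sample mask."""
    sub = genotypes[mask]
    typed = ~np.isnan(sub)
    total = 2 * typed.sum(axis=0)
    effect = np.nansum(sub, axis=0)
    return effect, total


def group_vs_complement_scan(
    cohort: Cohort,
    group_labels: Sequence[str] | np.ndarray,
    pgx_only: bool = True,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Scan every variant x group for frequency divergence vs the complement.

    Returns one row per (variant, group) with frequencies, allele
    counts, delta_p, the heterozygosity components and FST, the raw
    p-value and the BH q-value, plus a ``significant`` flag at
    ``fdr_q``. (Variant, group) pairs with zero typed alleles in either
    stratum are excluded with a warning. Dominant-mode PGx variants are
    still treated on the allele scale here; effect mode only matters in
    the risk layer.
    """
    labels = np.asarray(group_labels, dtype=object)
    if labels.shape != (cohort.n_samples,):
        raise ValueError("group_labels must have one entry per sample")
    groups = sorted(set(labels.astype(str)))
    if len(groups) < 2:
        raise ValueError("need at least two groups")

    if pgx_only:
        vmask = cohort.pgx_mask
    else:
        vmask = np.ones(cohort.n_variants, dtype=bool)
    vids = np.array(cohort.variant_ids, dtype=object)[vmask]
    is_pgx = cohort.pgx_mask[vmask]
    geno = cohort.genotypes[:, vmask]

    frames = []
    n_dropped = 0
    for grp in groups:
        in_mask = labels.astype(str) == grp
        e_in, n_in = _group_counts(geno, in_mask)
        e_out, n_out = _group_counts(geno, ~in_mask)
        ok = (n_in > 0) & (n_out > 0)
        n_dropped += int((~ok).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            p_in = np.where(ok, e_in / np.where(n_in > 0, n_in, 1), np.nan)
            p_out = np.where(ok, e_out / np.where(n_out > 0, n_out, 1), np.nan)
        h_s, h_t, fst = pairwise_fst(
            np.where(ok, p_in, 0.5), np.where(ok, n_in, 2),
            np.where(ok, p_out, 0.5), np.where(ok, n_out, 2),
        )
        pvals = _chi2_or_fisher_p(e_in, n_in - e_in, e_out, n_out - e_out)
        frames.append(
            pd.DataFrame(
                {
                    "variant_id": vids,
                    "pgx": is_pgx,
                    "group": grp,
                    "comparator": "complement",
                    "p_a": p_in,
                    "p_b": p_out,
                    "n_a": n_in.astype(int),
                    "n_b": n_out.astype(int),
                    "delta_p": p_in - p_out,
                    "h_s_bar": np.where(ok, h_s, np.nan),
                    "h_t": np.where(ok, h_t, np.nan),
                    "fst": np.where(ok, fst, np.nan),
                    "p_value": np.where(ok, pvals, np.nan),
                }
            )[ok]
        )
    if n_dropped:
        logger.warning("excluded %d (variant, group) strata with no typed alleles",
                       n_dropped)
    scan = pd.concat(frames, ignore_index=True)
    scan["q_value"] = bh_adjust(scan["p_value"].to_numpy())
    scan["significant"] = scan["q_value"] < fdr_q
    return scan


def heterozygosity_fraction(
    cohort: Cohort, variant_id: str, sample_subset=None
) -> float:
    """Fraction of heterozygous (dosage 1) individuals among typed ones."""
    g = cohort.dosages(variant_id)
    if sample_subset is not None:
        g = g[np.asarray(sample_subset)]
    typed = ~np.isnan(g)
    if not typed.any():
        raise UndefinedStatisticError(f"{variant_id}: no typed genotypes in subset")
    return float((g[typed] == 1).mean())


def within_between_partition(fst: float) -> tuple[float, float]:
    """Split variation into (within %, between %) = (100(1-FST), 100 FST)."""
    return 100.0 * (1.0 - fst), 100.0 * fst


def summarize_divergence(scan: pd.DataFrame) -> dict:
    """Headline summary of a scan: mean FST of significant vs other variants.

    A variant counts as significantly diverged if any of its
    group-vs-complement tests is significant; its FST summary value is
    the mean of its defined per-group FST values.
    """
    per_variant = scan.groupby("variant_id").agg(
        fst=("fst", "mean"), significant=("significant", "any")
    )
    sig = per_variant[per_variant["significant"]]
    rest = per_variant[~per_variant["significant"]]
    return {
        "n_tests": int(scan.shape[0]),
        "n_variants": int(per_variant.shape[0]),
        "n_significant_variants": int(sig.shape[0]),
        "mean_fst_significant": float(sig["fst"].mean()) if len(sig) else None,
        "mean_fst_nonsignificant": float(rest["fst"].mean()) if len(rest) else None,
    }


def pgx_background_comparison(
    cohort: Cohort, group_labels: Sequence[str] | np.ndarray
) -> pd.DataFrame:
    """Compare PGx vs non-PGx variants on frequency, |delta p|, heterozygosity.

    For each variant: pooled effect-allele frequency, the largest
    absolute between-group frequency difference over all group pairs,
    and the pooled heterozygote fraction, with a ``pgx`` flag — the
    distribution comparison behind 'PGx variants are more diverged than
    the genomic background'.
    """
    labels = np.asarray(group_labels, dtype=object).astype(str)
    groups = sorted(set(labels))
    geno = cohort.genotypes
    typed = ~np.isnan(geno)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = np.nansum(geno, axis=0) / (2 * typed.sum(axis=0))
        het = (geno == 1).sum(axis=0) / typed.sum(axis=0)
    gfreq = []
    for grp in groups:
        e, t = _group_counts(geno, labels == grp)
        with np.errstate(invalid="ignore", divide="ignore"):
            gfreq.append(np.where(t > 0, e / np.where(t > 0, t, 1), np.nan))
    gfreq = np.vstack(gfreq)
    max_dp = np.nanmax(gfreq, axis=0) - np.nanmin(gfreq, axis=0)
    return pd.DataFrame(
        {
            "variant_id": cohort.variant_ids,
            "pgx": cohort.pgx_mask,
            "pooled_freq": pooled,
            "max_abs_delta_p": max_dp,
            "het_fraction": het,
        }
    )
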