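"""Cohort container and I/O for genotype, ancestry, SIRE, and PGx tables.

The analyses in this package operate on a cohort of individuals carrying

* effect-allele dosage genotypes (0, 1, 2, or missing) at biallelic SNVs,
* a self-identified race/ethnicity (SIRE) label per individual,
* continental ancestry fractions (European, African, Native American)
  per individual, summing to one, and
* pharmacogenomic (PGx) annotations for a subset of variants: the effect
  allele, its mode of effect (additive or dominant), the drug, and the
  kind of response affected (dosage, efficacy, metabolism, toxicity).

Dosages are always counted with respect to the annotated *effect* allele,
not the VCF REF/ALT orientation.
"""

from __future__ import annotations

import logging
from collections import namedtuple
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EFFECT_MODES = ("additive", "dominant")
EFFECT_TYPES = ("dosage", "efficacy", "metabolism", "toxicity")
ANCESTRY_COMPONENTS = ("european", "african", "native_american")

ANCESTRY_SUM_TOL = 1e-6


class CohortValidationError(ValueError):
    """Raised when input tables violate the cohort invariants."""


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is undefined (e.g. no typed genotypes)."""


@dataclass(frozen=True)
class PGxAnnotation:
    """Pharmacogenomic annotation of one variant.

    ``mode`` is ``"additive"`` (per-allele effect; allele counts are the
    unit downstream) or ``"dominant"`` (carrier effect; genotype counts
    are the unit). ``effect_type`` names the affected drug-response
    dimension; ``direction`` is free text such as
    ``"decreased dose requirement"``.
    """

    mode: str
    drug: str
    effect_type: str
    direction: str = ""

    def __post_init__(self) -> None:
        if self.mode not in EFFECT_MODES:
            raise CohortValidationError(
                f"mode must be one of {EFFECT_MODES}, got {self.mode!r}"
            )
        if self.effect_type not in EFFECT_TYPES:
            raise CohortValidationError(
                f"effect_type must be one of {EFFECT_TYPES}, got {self.effect_type!r}"
            )


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNV, oriented by its effect allele."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    pgx: PGxAnnotation | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise CohortValidationError(f"{self.variant_id}: pos must be >= 1")
        if self.effect_allele == self.other_allele:
            raise CohortValidationError(
                f"{self.variant_id}: effect and other allele are identical"
            )


@dataclass(frozen=True)
class AncestryProfile:
    """Continental ancestry fractions (E_i, A_i, N_i) of one individual."""

    european: float
    african: float
    native_american: float

    def __post_init__(self) -> None:
        vals = (self.european, self.african, self.native_american)
        if any(v < -ANCESTRY_SUM_TOL or v > 1 + ANCESTRY_SUM_TOL for v in vals):
            raise CohortValidationError(f"ancestry fractions out of [0,1]: {vals}")
        if abs(sum(vals) - 1.0) > ANCESTRY_SUM_TOL:
            raise CohortValidationError(f"ancestry fractions do not sum to 1: {vals}")

    def as_array(self) -> np.ndarray:
        return np.array([self.european, self.african, self.native_american])


@dataclass
class Cohort:
    """N individuals x V biallelic SNVs with SIRE labels and ancestry.

    ``genotypes`` is an N x V float matrix of effect-allele dosages with
    ``np.nan`` marking missing calls. ``ancestry`` is an optional N x 3
    matrix of (European, African, Native American) fractions.
    """

    sample_ids: list[str]
    genotypes: np.ndarray
    variants: list[VariantRecord]
    sire_labels: np.ndarray | None = None
    ancestry: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        n, v = self.genotypes.shape
        if n != len(self.sample_ids) or v != len(self.variants):
            raise CohortValidationError(
                f"genotype matrix is {self.genotypes.shape}, expected "
                f"{len(self.sample_ids)} x {len(self.variants)}"
            )
        if len(set(self.sample_ids)) != n:
            raise CohortValidationError("duplicate sample ids")
        vids = [vr.variant_id for vr in self.variants]
        if len(set(vids)) != v:
            raise CohortValidationError("duplicate variant ids")
        observed = self.genotypes[~np.isnan(self.genotypes)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise CohortValidationError("non-missing dosages must be 0, 1, or 2")
        if self.sire_labels is not None:
            self.sire_labels = np.asarray(self.sire_labels, dtype=object)
            if self.sire_labels.shape != (n,):
                raise CohortValidationError("sire_labels length mismatch")
        if self.ancestry is not None:
            self.ancestry = np.asarray(self.ancestry, dtype=float)
            if self.ancestry.shape != (n, 3):
                raise CohortValidationError("ancestry must be N x 3")
            if np.abs(self.ancestry.sum(axis=1) - 1.0).max() > ANCESTRY_SUM_TOL:
                bad = np.flatnonzero(
                    np.abs(self.ancestry.sum(axis=1) - 1.0) > ANCESTRY_SUM_TOL
                )
                names = [self.sample_ids[i] for i in bad[:10]]
                raise CohortValidationError(
                    f"ancestry rows do not sum to 1 for samples {names}"
                )
        self._vindex = {vid: i for i, vid in enumerate(vids)}

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    @property
    def pgx_mask(self) -> np.ndarray:
        """Boolean mask over variants flagging those with a PGx annotation."""
        return np.array([v.pgx is not None for v in self.variants], dtype=bool)

    def variant_index(self, variant_id: str) -> int:
        try:
            return self._vindex[variant_id]
        except KeyError:
            raise KeyError(f"unknown variant id {variant_id!r}") from None

    def variant(self, variant_id: str) -> VariantRecord:
        return self.variants[self.variant_index(variant_id)]

    def dosages(self, variant_id: str) -> np.ndarray:
        return self.genotypes[:, self.variant_index(variant_id)]

    def ancestry_profiles(self) -> list[AncestryProfile]:
        if self.ancestry is None:
            raise CohortValidationError("cohort has no ancestry fractions")
        return [AncestryProfile(*row) for row in self.ancestry]


FrequencyResult = namedtuple("FrequencyResult", "frequency effect_count total_count")


def effect_allele_frequency(
    cohort: Cohort,
    variant_id: str,
    sample_subset: np.ndarray | Sequence[int] | None = None,
) -> FrequencyResult:
    """Effect-allele frequency in a sample subset.

    Returns (effect allele count) / (2 x typed individuals), plus the raw
    numerator and denominator. Missing genotypes are excluded from both.
    Raises :class:`UndefinedStatisticError` if the subset has no typed
    genotype at the variant (an undefined frequency, never reported as 0).
    """
    g = cohort.dosages(variant_id)
    if sample_subset is not None:
        g = g[np.asarray(sample_subset)]
    if g.size == 0:
        raise UndefinedStatisticError(f"{variant_id}: empty sample subset")
    typed = ~np.isnan(g)
    total = 2 * int(typed.sum())
    if total == 0:
        raise UndefinedStatisticError(f"{variant_id}: all genotypes missing in subset")
    effect = int(g[typed].sum())
    return FrequencyResult(effect / total, effect, total)


# ----------------------------------------------------------------------
# VCF I/O
# ----------------------------------------------------------------------

def read_genotypes_vcf(
    path: str | Path,
    effect_allele_map: Mapping[str, str] | None = None,
) -> Cohort:
    """Read a biallelic-SNV VCF into a cohort of effect-allele dosages.

    ``effect_allele_map`` maps variant id -> effect allele; dosages are
    oriented to that allele regardless of REF/ALT polarity. Variants
    missing from the map default to ALT as the effect allele. Variants
    whose mapped effect allele is neither REF nor ALT, multi-allelic
    records, and indels are excluded with a logged warning. SIRE labels
    and ancestry must be supplied separately (see :func:`read_tables`).
    """
    from cyvcf2 import VCF

    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare Exception on bad input
        raise CohortValidationError(f"cannot parse VCF {path}: {exc}") from exc

    sample_ids = list(vcf.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    alt_dosage = np.array([0.0, 1.0, np.nan, 2.0])
    for line_no, rec in enumerate(vcf, start=1):
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            logger.warning("skipping non-biallelic-SNV record %s", vid)
            continue
        ref, alt = rec.REF, rec.ALT[0]
        effect = alt
        if effect_allele_map is not None and vid in effect_allele_map:
            effect = effect_allele_map[vid]
        if effect == alt:
            other = ref
            dos = alt_dosage[rec.gt_types]
        elif effect == ref:
            other = alt
            dos = 2.0 - alt_dosage[rec.gt_types]
        else:
            n_skipped += 1
            logger.warning(
                "excluding %s: effect allele %s not among REF/ALT (%s/%s)",
                vid, effect, ref, alt,
            )
            continue
        variants.append(VariantRecord(vid, rec.CHROM, rec.POS, effect, other))
        columns.append(dos)
    vcf.close()
    if n_skipped:
        logger.info("excluded %d VCF records", n_skipped)
    if not columns:
        raise CohortValidationError(f"no usable biallelic SNV records in {path}")
    genotypes = np.column_stack(columns)
    return Cohort(sample_ids, genotypes, variants)


def write_genotypes_vcf(cohort: Cohort, path: str | Path) -> Path:
    """Write the cohort genotypes as an uncompressed VCF 4.2 file.

    REF is the non-effect allele and ALT the effect allele, so the ALT
    dosage equals the stored effect-allele dosage and a read with the
    matching effect-allele map round-trips exactly.
    """
    path = Path(path)
    gt_str = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.sample_ids)
            + "\n"
        )
        for j, v in enumerate(cohort.variants):
            gts = [
                "./." if np.isnan(g) else gt_str[g] for g in cohort.genotypes[:, j]
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.other_allele}\t"
                f"{v.effect_allele}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )
    return path


# ----------------------------------------------------------------------
# TSV I/O
# ----------------------------------------------------------------------

def read_tables(
    genotype_tsv: str | Path,
    ancestry_tsv: str | Path | None = None,
    sire_tsv: str | Path | None = None,
    pgx_tsv: str | Path | None = None,
    sire_levels: Sequence[str] | None = None,
) -> tuple[Cohort, int]:
    """Assemble a cohort from the four tab-separated tables.

    * genotype TSV: ``sample_id`` column then one column per variant id,
      cells 0/1/2/NA;
    * ancestry TSV: ``sample_id, european, african, native_american``;
    * sire TSV: ``sample_id, sire``;
    * pgx/variants TSV: ``variant_id, chrom, pos, effect_allele,
      other_allele, mode, drug, effect_type, direction`` — rows with an
      empty ``mode`` carry metadata for non-PGx variants.

    If ``sire_levels`` is given, individuals whose SIRE label is outside
    that set are excluded; the second return value counts the exclusions.
    """
    geno = pd.read_csv(genotype_tsv, sep="\t", dtype={"sample_id": str})
    if geno["sample_id"].duplicated().any():
        raise CohortValidationError("duplicate sample ids in genotype table")
    geno = geno.set_index("sample_id")
    sample_ids = list(geno.index)
    variant_ids = list(geno.columns)

    meta: dict[str, VariantRecord] = {}
    if pgx_tsv is not None:
        vt = pd.read_csv(pgx_tsv, sep="\t", dtype=str).fillna("")
        if vt["variant_id"].duplicated().any():
            raise CohortValidationError("duplicate variant ids in pgx table")
        for row in vt.itertuples(index=False):
            pgx = None
            if row.mode:
                pgx = PGxAnnotation(row.mode, row.drug, row.effect_type, row.direction)
            meta[row.variant_id] = VariantRecord(
                row.variant_id, row.chrom, int(row.pos),
                row.effect_allele, row.other_allele, pgx,
            )
    variants = []
    for i, vid in enumerate(variant_ids):
        variants.append(
            meta.get(vid) or VariantRecord(vid, "0", i + 1, "A", "G")
        )

    sire = None
    if sire_tsv is not None:
        st = pd.read_csv(sire_tsv, sep="\t", dtype=str)
        if st["sample_id"].duplicated().any():
            raise CohortValidationError("duplicate sample ids in sire table")
        lookup = dict(zip(st["sample_id"], st["sire"]))
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise CohortValidationError(f"samples without SIRE label: {missing[:10]}")
        sire = np.array([lookup[s] for s in sample_ids], dtype=object)

    ancestry = None
    if ancestry_tsv is not None:
        at = pd.read_csv(ancestry_tsv, sep="\t", dtype={"sample_id": str})
        if at["sample_id"].duplicated().any():
            raise CohortValidationError("duplicate sample ids in ancestry table")
        at = at.set_index("sample_id")
        missing = [s for s in sample_ids if s not in at.index]
        if missing:
            raise CohortValidationError(f"samples without ancestry: {missing[:10]}")
        ancestry = at.loc[sample_ids, list(ANCESTRY_COMPONENTS)].to_numpy(float)
        sums = ancestry.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > ANCESTRY_SUM_TOL)
        if bad.size:
            names = [sample_ids[i] for i in bad[:10]]
            raise CohortValidationError(
                f"ancestry rows do not sum to 1 for samples {names}"
            )

    n_excluded = 0
    keep = np.ones(len(sample_ids), dtype=bool)
    if sire_levels is not None and sire is not None:
        keep = np.isin(sire.astype(str), list(sire_levels))
        n_excluded = int((~keep).sum())
        if n_excluded:
            logger.info(
                "excluded %d individuals with SIRE outside %s",
                n_excluded, list(sire_levels),
            )
    genotypes = geno.to_numpy(float)[keep]
    cohort = Cohort(
        [s for s, k in zip(sample_ids, keep) if k],
        genotypes,
        variants,
        sire_labels=sire[keep] if sire is not None else None,
        ancestry=ancestry[keep] if ancestry is not None else None,
    )
    return cohort, n_excluded


def write_tables(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort as the four TSVs read by :func:`read_tables`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": outdir / "genotypes.tsv",
        "ancestry": outdir / "ancestry.tsv",
        "sire": outdir / "sire.tsv",
        "pgx": outdir / "pgx.tsv",
    }
    geno = pd.DataFrame(
        cohort.genotypes, index=pd.Index(cohort.sample_ids, name="sample_id"),
        columns=cohort.variant_ids,
    )
    # dosages are integral; render without trailing .0 and NaN as NA
    geno = geno.map(lambda x: "NA" if np.isnan(x) else str(int(x)))
    geno.to_csv(paths["genotypes"], sep="\t")

    if cohort.ancestry is not None:
        anc = pd.DataFrame(
            cohort.ancestry,
            index=pd.Index(cohort.sample_ids, name="sample_id"),
            columns=list(ANCESTRY_COMPONENTS),
        )
        anc.to_csv(paths["ancestry"], sep="\t", float_format="%.10g")
    else:
        paths.pop("ancestry")

    if cohort.sire_labels is not None:
        pd.DataFrame(
            {"sample_id": cohort.sample_ids, "sire": cohort.sire_labels}
        ).to_csv(paths["sire"], sep="\t", index=False)
    else:
        paths.pop("sire")

    rows = []
    for v in cohort.variants:
        rows.append(
            {
                "variant_id": v.variant_id,
                "chrom": v.chrom,
                "pos": v.pos,
                "effect_allele": v.effect_allele,
                "other_allele": v.other_allele,
                "mode": v.pgx.mode if v.pgx else "",
                "drug": v.pgx.drug if v.pgx else "",
                "effect_type": v.pgx.effect_type if v.pgx else "",
                "direction": v.pgx.direction if v.pgx else "",
            }
        )
    pd.DataFrame(rows).to_csv(paths["pgx"], sep="\t", index=False)
    return paths
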