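"""Synthetic admixed-cohort generator with ground truth.

Emulates a three-way admixed cohort of the kind studied in US
pharmacogenomic surveys: each self-identified group draws individual
continental ancestry profiles (European, African, Native American) from
its own Dirichlet distribution, and genotypes are generated per allele
copy conditional on ancestry — for each of the two copies at each
variant, a continental origin is drawn from the individual's ancestry
fractions and the allele is then Bernoulli with that continent's
ancestral frequency. This admixture model (rather than group-level
Hardy–Weinberg sampling) is what induces the ancestry–genotype
correlation the regression layer measures.

Default group profiles mirror the published cohort structure: a
majority group with ~99% European ancestry, a group with ~82% African
ancestry, and a group with ~60% European / ~37% Native American
ancestry and the largest ancestry variance. A configurable fraction of
variants carries PGx annotations, with both additive and dominant
effect modes represented; by default the PGx subset is drawn with
inflated between-continent frequency divergence so the PGx layer has
planted signal, as observed for real PGx panels.

All randomness flows from a single :class:`numpy.random.Generator`
seeded by ``SimConfig.seed``; the documented draw order (PGx subset,
ancestral frequencies, per-group ancestries, SIRE mislabels, allele
copies, missingness mask) keeps output stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import cycle

import numpy as np

from .cohort import Cohort, PGxAnnotation, VariantRecord
from .divergence import FstResult, pairwise_fst

DEFAULT_GROUPS = ("White", "Black", "Hispanic")
# Dirichlet concentrations proportional to the groups' published mean
# ancestry percentages (EUR, AFR, NAT).
DEFAULT_ALPHAS = ((99.0, 0.5, 0.5), (17.0, 82.0, 1.0), (60.0, 3.0, 37.0))
_DRUGS = (
    "warfarin", "clopidogrel", "simvastatin", "tacrolimus", "carbamazepine",
    "nortriptyline", "fentanyl", "azathioprine", "allopurinol", "codeine",
)
_EFFECT_TYPES = ("dosage", "efficacy", "metabolism", "toxicity")


class SimConfigError(ValueError):
    """Raised for degenerate simulation configurations."""


@dataclass
class SimConfig:
    """Parameters of one simulated cohort.

    Parameters
    ----------
    n_per_group
        Individuals per simulated SIRE group.
    dirichlet_alphas
        Per-group Dirichlet concentration 3-vectors over (EUR, AFR, NAT).
    n_variants, n_pgx
        Total variant count and the number receiving a PGx annotation.
    ancestral_freqs
        Optional explicit V x 3 matrix of per-continent effect-allele
        frequencies; when omitted, frequencies are drawn iid
        Beta(``beta_a``, ``beta_b``) per continent.
    pgx_divergent, pgx_divergent_fraction
        When ``pgx_divergent`` is true, a ``pgx_divergent_fraction``
        share of the PGx panel is redrawn until the largest
        between-continent frequency gap is at least ``min_pgx_gap``,
        planting a subpanel of strongly diverged PGx variants against a
        background-like remainder.
    mislabel_rate
        Probability that an individual's SIRE label is reassigned
        uniformly to one of the other groups (SIRE/GA discordance dial).
    missing_rate
        Per-genotype missingness probability.
    mode_mix
        Fraction of PGx variants with dominant (vs additive) effect mode.
    """

    group_names: tuple[str, ...] = DEFAULT_GROUPS
    n_per_group: tuple[int, ...] = (300, 300, 300)
    dirichlet_alphas: tuple[tuple[float, float, float], ...] = DEFAULT_ALPHAS
    n_variants: int = 1000
    n_pgx: int = 100
    ancestral_freqs: np.ndarray | None = None
    beta_a: float = 0.8
    beta_b: float = 0.8
    pgx_divergent: bool = True
    pgx_divergent_fraction: float = 0.5
    min_pgx_gap: float = 0.7
    mislabel_rate: float = 0.0
    missing_rate: float = 0.01
    mode_mix: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        g = len(self.group_names)
        if g < 2:
            raise SimConfigError("need at least two groups")
        if len(self.n_per_group) != g or len(self.dirichlet_alphas) != g:
            raise SimConfigError("per-group fields must match group_names length")
        if any(n < 1 for n in self.n_per_group):
            raise SimConfigError("empty group")
        if self.n_variants < 1:
            raise SimConfigError("need at least one variant")
        if not 0 <= self.n_pgx <= self.n_variants:
            raise SimConfigError("n_pgx must be in [0, n_variants]")
        for alpha in self.dirichlet_alphas:
            if len(alpha) != 3 or any(a <= 0 for a in alpha):
                raise SimConfigError("Dirichlet alphas must be positive 3-vectors")
        for name, val in (
            ("mislabel_rate", self.mislabel_rate),
            ("missing_rate", self.missing_rate),
        ):
            if not 0 <= val < 1:
                raise SimConfigError(f"{name} must be in [0,1)")
        if not 0 <= self.mode_mix <= 1:
            raise SimConfigError("mode_mix must be in [0,1]")
        if not 0 <= self.pgx_divergent_fraction <= 1:
            raise SimConfigError("pgx_divergent_fraction must be in [0,1]")
        if self.ancestral_freqs is not None:
            f = np.asarray(self.ancestral_freqs, float)
            if f.shape != (self.n_variants, 3):
                raise SimConfigError("ancestral_freqs must be n_variants x 3")
            if (f < 0).any() or (f > 1).any():
                raise SimConfigError("ancestral_freqs must lie in [0,1]")


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort.

    ``expected_group_freqs[v, g]`` is the closed-form effect-allele
    frequency p_g = sum_pop(mean group ancestry x f_pop) implied by the
    group's Dirichlet mean, against which observed group frequencies and
    FST can be checked.
    """

    group_names: tuple[str, ...]
    group_sizes: tuple[int, ...]
    true_group: np.ndarray            # N ints
    true_ancestry: np.ndarray         # N x 3
    ancestral_freqs: np.ndarray       # V x 3
    expected_group_freqs: np.ndarray  # V x G
    pgx_indices: np.ndarray
    pgx_divergent_indices: np.ndarray


def simulate_cohort(config: SimConfig) -> tuple[Cohort, SimTruth]:
    """Generate a cohort plus its ground truth, reproducibly from the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    g = len(config.group_names)
    n = int(sum(config.n_per_group))
    v = config.n_variants

    # 1) PGx subset
    pgx_idx = np.sort(rng.choice(v, size=config.n_pgx, replace=False))
    is_pgx = np.zeros(v, dtype=bool)
    is_pgx[pgx_idx] = True

    # 2) ancestral frequencies per continent
    n_div = round(config.pgx_divergent_fraction * config.n_pgx)
    divergent_idx = np.sort(rng.choice(pgx_idx, size=n_div, replace=False)) \
        if config.n_pgx else np.array([], dtype=int)
    if config.ancestral_freqs is not None:
        freqs = np.asarray(config.ancestral_freqs, float).copy()
    else:
        freqs = rng.beta(config.beta_a, config.beta_b, size=(v, 3))
        if config.pgx_divergent:
            for i in divergent_idx:
                for _ in range(1000):
                    if freqs[i].max() - freqs[i].min() >= config.min_pgx_gap:
                        break
                    freqs[i] = rng.beta(config.beta_a, config.beta_b, size=3)

    # 3) per-group ancestry profiles
    true_group = np.repeat(np.arange(g), config.n_per_group)
    ancestry = np.empty((n, 3))
    start = 0
    for gi, (ng, alpha) in enumerate(zip(config.n_per_group, config.dirichlet_alphas)):
        ancestry[start : start + ng] = rng.dirichlet(alpha, size=ng)
        start += ng

    # 4) SIRE labels with optional mislabelling
    sire_idx = true_group.copy()
    if config.mislabel_rate > 0:
        flip = rng.random(n) < config.mislabel_rate
        shift = rng.integers(1, g, size=n)
        sire_idx = np.where(flip, (true_group + shift) % g, true_group)
    sire = np.array([config.group_names[i] for i in sire_idx], dtype=object)

    # 5) genotypes: two allele copies, each with its own continental origin
    cum = np.cumsum(ancestry, axis=1)
    dosage = np.zeros((n, v))
    for _copy in range(2):
        u = rng.random((n, v, 1))
        comp = (u > cum[:, None, :2]).sum(axis=2)  # continent per copy per variant
        p = np.take_along_axis(freqs[None, :, :], comp[:, :, None], axis=2)[:, :, 0]
        dosage += rng.random((n, v)) < p
    genotypes = dosage.astype(float)

    # 6) missingness mask
    if config.missing_rate > 0:
        genotypes[rng.random((n, v)) < config.missing_rate] = np.nan

    # variant records + PGx annotations
    modes = np.where(
        np.arange(config.n_pgx) < round(config.mode_mix * config.n_pgx),
        "dominant", "additive",
    )
    rng.shuffle(modes)
    drug_cycle = cycle(_DRUGS)
    type_cycle = cycle(_EFFECT_TYPES)
    variants = []
    k = 0
    for i in range(v):
        pgx = None
        if is_pgx[i]:
            pgx = PGxAnnotation(
                mode=str(modes[k]),
                drug=next(drug_cycle),
                effect_type=next(type_cycle),
                direction="increased risk",
            )
            k += 1
        variants.append(
            VariantRecord(f"rs{1000000 + i}", "1", i + 1, "A", "G", pgx)
        )

    sample_ids = [f"S{i:05d}" for i in range(n)]
    cohort = Cohort(sample_ids, genotypes, variants, sire_labels=sire, ancestry=ancestry)

    alpha_arr = np.asarray(config.dirichlet_alphas, float)
    mean_anc = alpha_arr / alpha_arr.sum(axis=1, keepdims=True)  # G x 3
    expected = freqs @ mean_anc.T                                # V x G
    truth = SimTruth(
        group_names=tuple(config.group_names),
        group_sizes=tuple(int(x) for x in config.n_per_group),
        true_group=true_group,
        true_ancestry=ancestry,
        ancestral_freqs=freqs,
        expected_group_freqs=expected,
        pgx_indices=pgx_idx,
        pgx_divergent_indices=divergent_idx if config.pgx_divergent
        else np.array([], dtype=int),
    )
    return cohort, truth


def expected_pairwise_fst(truth: SimTruth, group_a: str, group_b: str) -> FstResult:
    """Per-variant expected FST between two simulated groups.

    Evaluates the fixation-index formula on the closed-form expected
    group frequencies with the simulated group sizes as weights; serves
    as the independent oracle for the divergence layer. Variants
    monomorphic in both groups come back as NaN.
    """
    names = list(truth.group_names)
    ia, ib = names.index(group_a), names.index(group_b)
    na = 2 * truth.group_sizes[ia]
    nb = 2 * truth.group_sizes[ib]
    return pairwise_fst(
        truth.expected_group_freqs[:, ia], na,
        truth.expected_group_freqs[:, ib], nb,
    )
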