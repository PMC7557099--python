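"""Genome-wide PGx structure: IBS distances, classical MDS, clustering.

Inter-individual distance is the allele-sharing distance 1 - IBS, where
identity-by-state between two dosage vectors scores each co-typed
variant as 2 - |g_i - g_j| shared alleles out of 2. Missing data are
handled pairwise: the denominator counts only variants typed in both
individuals. The distance is a pseudo-metric on dosage vectors bounded
in [0, 1].

The embedding is classical (Torgerson) metric scaling: double-center
-1/2 D^2, take the top eigenpairs, and scale eigenvectors by the square
roots of the (non-negative-truncated) eigenvalues, i.e. ``cmdscale``
semantics rather than stress-minimizing SMACOF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import eigh

from .grouping import ConcordanceReport, GAGrouping, align_and_concord, cluster_points

logger = logging.getLogger(__name__)

_SYM_TOL = 1e-12


@dataclass
class DistanceMatrix:
    """Symmetric non-negative pairwise distance matrix with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValueError("values must be N x N matching sample_ids")
        finite = np.isfinite(v)
        if not np.allclose(
            np.where(finite, v, 0), np.where(finite.T, v.T, 0), atol=_SYM_TOL
        ):
            raise ValueError("distance matrix is not symmetric")
        if np.diagonal(v).any():
            raise ValueError("diagonal must be exactly zero")
        self.values = v


def pgx_distance(cohort, variant_ids: Sequence[str] | None = None) -> DistanceMatrix:
    """Allele-sharing distance 1 - IBS between all pairs of individuals.

    ``variant_ids`` restricts the computation (default: the cohort's
    PGx-annotated variants). Pairs with zero co-typed variants get NaN
    with a warning; a sample with no typed genotype at all is an error.
    """
    if variant_ids is None:
        mask = cohort.pgx_mask
        if not mask.any():
            raise ValueError("cohort has no PGx-annotated variants")
        G = cohort.genotypes[:, mask]
    else:
        idx = [cohort.variant_index(v) for v in variant_ids]
        if not idx:
            raise ValueError("empty variant subset")
        G = cohort.genotypes[:, idx]

    typed = ~np.isnan(G)
    empty = ~typed.any(axis=1)
    if empty.any():
        bad = [cohort.sample_ids[i] for i in np.flatnonzero(empty)[:5]]
        raise ValueError(f"samples with all genotypes missing: {bad}")

    n = G.shape[0]
    G0 = np.nan_to_num(G)
    M = typed.astype(float)
    cotyped = M @ M.T
    dist = np.zeros((n, n))
    chunk = max(1, int(2**24 // max(1, n * G.shape[1])))
    for start in range(0, n, chunk):
        stop = min(n, start + chunk)
        diff = np.abs(G0[start:stop, None, :] - G0[None, :, :])
        diff *= M[start:stop, None, :] * M[None, :, :]
        dist[start:stop] = diff.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(cotyped > 0, dist / (2 * cotyped), np.nan)
    if np.isnan(dist).any():
        logger.warning("pairs with zero co-typed variants have undefined distance")
    np.fill_diagonal(dist, 0.0)
    # enforce exact symmetry against floating-point summation order
    dist = (dist + dist.T) / 2.0
    return DistanceMatrix(list(cohort.sample_ids), dist)


def classical_mds(dist: DistanceMatrix | np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) scaling of a distance matrix into ``dims`` axes.

    Eigenvalues are taken in descending order and negative ones (from
    non-Euclidean distances) are truncated at zero, so trailing axes of
    a non-embeddable input collapse rather than turning imaginary.
    """
    D = dist.values if isinstance(dist, DistanceMatrix) else np.asarray(dist, float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("input must be a symmetric square matrix")
    if not 1 <= dims < n:
        raise ValueError("dims must satisfy 1 <= dims < N")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains undefined entries")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2.0
    w, v = eigh(B, subset_by_index=(n - dims, n - 1))
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    v = v[:, order]
    return v * np.sqrt(w)


def cluster_embedding_and_correspond(
    embedding: np.ndarray,
    k: int,
    sire_labels,
    restarts: int = 100,
    seed: int | None = None,
) -> tuple[GAGrouping, ConcordanceReport]:
    """k-means the MDS embedding and measure correspondence with SIRE.

    Shares the consensus-restart machinery of the ancestry grouping and
    the bijection-based concordance measure, so the correspondence score
    is invariant to axis sign flips and cluster relabeling.
    """
    grouping = cluster_points(np.asarray(embedding, float), k, restarts, seed)
    report = align_and_concord(grouping.assignments, sire_labels)
    return grouping, report
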