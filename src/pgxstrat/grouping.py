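"""Genetic-ancestry (GA) grouping by consensus k-means and SIRE concordance.

Individuals are points in the 3-D ancestry simplex (European, African,
Native American fractions). Groups are formed by Euclidean k-means run
from many independent initializations; because k-means labelings are
only defined up to permutation, each restart's labels are first aligned
to the best restart's centroids by a minimum-cost bijection, and each
individual then receives the modal label across restarts. The fraction
of restarts agreeing with that modal label is recorded per individual
as an assignment-stability score.

Concordance between a grouping and categorical SIRE labels is measured
after choosing the label pairing (a bijection between cluster indices
and SIRE categories) that maximizes the number of matched individuals,
so it is invariant to any permutation of cluster indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)


@dataclass
class GAGrouping:
    """Result of consensus k-means: assignments, centroids, stability."""

    k: int
    assignments: np.ndarray        # N ints in [0, k)
    centroids: np.ndarray          # k x d
    restart_agreement: np.ndarray  # N fractions in (0, 1]
    inertia: float                 # within-cluster sum of squares


@dataclass
class ConcordanceReport:
    """Agreement between a clustering and categorical labels.

    ``mapping`` pairs each cluster index with its matched label under
    the total-match-maximizing bijection. The two conditional views
    differ: ``per_group_given_ga[g]`` is the fraction of cluster ``g``
    carrying the paired label, while ``per_group_given_sire[s]`` is the
    fraction of label ``s`` falling into its paired cluster.
    """

    mapping: dict[int, str]
    overall_concordance: float
    per_group_given_ga: dict[int, float]
    per_group_given_sire: dict[str, float]
    contingency: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "mapping": {str(k): v for k, v in self.mapping.items()},
            "overall_concordance": self.overall_concordance,
            "per_group_given_ga": {str(k): v for k, v in self.per_group_given_ga.items()},
            "per_group_given_sire": dict(self.per_group_given_sire),
        }


def _as_points(profiles) -> np.ndarray:
    X = np.asarray(
        [p.as_array() if hasattr(p, "as_array") else p for p in profiles], float
    )
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("profiles must be a non-empty list of points")
    return X


def _match_labels(centers: np.ndarray, ref_centers: np.ndarray) -> np.ndarray:
    """Permutation mapping ``centers``' labels onto ``ref_centers``' labels."""
    cost = cdist(centers, ref_centers, metric="sqeuclidean")
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(centers), dtype=int)
    perm[rows] = cols
    return perm


def _inertia(X: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    return float(((X - centers[labels]) ** 2).sum())


def cluster_points(
    X: np.ndarray, k: int, restarts: int = 100, seed: int | None = None
) -> GAGrouping:
    """Consensus k-means over ``restarts`` independent initializations.

    Labels of every restart are aligned to the lowest-inertia restart by
    nearest-centroid bijection; each sample gets its modal label (ties
    broken in favor of the best restart, which is also the alignment
    reference). If the modal consensus ever has a worse within-cluster
    sum of squares than the best single restart — possible only in
    pathological geometries — the best restart is returned instead, so
    the returned objective never exceeds that of any restart.
    """
    X = np.asarray(X, float)
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    n_distinct = np.unique(X, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct points")
    rng = np.random.default_rng(seed)
    states = rng.integers(0, 2**31 - 1, size=restarts)
    fits = []
    for rs in states:
        km = KMeans(
            n_clusters=k, n_init=1, init="k-means++",
            max_iter=300, tol=1e-6, random_state=int(rs),
        ).fit(X)
        fits.append((km.labels_.copy(), km.cluster_centers_.copy(), float(km.inertia_)))

    best_idx = int(np.argmin([f[2] for f in fits]))
    ref_labels, ref_centers, best_inertia = fits[best_idx]

    votes = np.zeros((X.shape[0], k), dtype=int)
    for labels, centers, _ in fits:
        perm = _match_labels(centers, ref_centers)
        votes[np.arange(X.shape[0]), perm[labels]] += 1

    modal = votes.argmax(axis=1)
    top = votes.max(axis=1)
    tied = (votes == top[:, None]).sum(axis=1) > 1
    modal[tied] = ref_labels[tied]
    agreement = votes[np.arange(X.shape[0]), modal] / restarts

    # consensus centroids; fall back to the best restart if any cluster
    # lost all its members or the consensus objective is worse
    counts = np.bincount(modal, minlength=k)
    if (counts > 0).all():
        centers = np.vstack(
            [X[modal == j].mean(axis=0) for j in range(k)]
        )
        inertia = _inertia(X, modal, centers)
        if inertia <= best_inertia + 1e-9:
            return GAGrouping(k, modal, centers, agreement, inertia)
    logger.debug("consensus worse than best restart; returning best restart")
    return GAGrouping(k, ref_labels, ref_centers, agreement, best_inertia)


def cluster_ancestry(
    profiles, k: int = 3, restarts: int = 100, seed: int | None = None
) -> GAGrouping:
    """Define non-overlapping GA groups from ancestry profiles by k-means.

    ``profiles`` is a list of :class:`~pgxstrat.cohort.AncestryProfile`
    or an N x 3 array of ancestry fractions. ``k`` defaults to 3 so GA
    groups are directly comparable to the three SIRE categories.
    """
    return cluster_points(_as_points(profiles), k, restarts, seed)


def stability_subsample(
    profiles,
    k: int,
    fractions,
    reps: int,
    seed: int | None = None,
    restarts: int = 10,
) -> pd.DataFrame:
    """Robustness of the grouping to sample-size changes, by subsampling.

    For each fraction and repetition, a without-replacement subsample is
    re-clustered, its labels aligned to the full-data grouping by
    maximal overlap, and the agreement on the subsampled individuals
    recorded. Returns one row per fraction with the mean agreement;
    cells whose subsample is smaller than ``k`` are skipped with a
    warning.
    """
    X = _as_points(profiles)
    rng = np.random.default_rng(seed)
    full = cluster_points(X, k, restarts=restarts, seed=int(rng.integers(2**31 - 1)))
    rows = []
    for frac in fractions:
        if not 0 < frac <= 1:
            raise ValueError("fractions must lie in (0, 1]")
        size = int(round(frac * X.shape[0]))
        agreements = []
        for _ in range(reps):
            if size < k:
                logger.warning("subsample of %d < k=%d at fraction %s; skipped",
                               size, k, frac)
                continue
            idx = rng.choice(X.shape[0], size=size, replace=False)
            sub = cluster_points(
                X[idx], k, restarts=restarts, seed=int(rng.integers(2**31 - 1))
            )
            # align by maximal overlap with the full-data assignment
            overlap = np.zeros((k, k), dtype=int)
            for a, b in zip(sub.assignments, full.assignments[idx]):
                overlap[a, b] += 1
            rows_, cols_ = linear_sum_assignment(-overlap)
            perm = np.empty(k, dtype=int)
            perm[rows_] = cols_
            agreements.append(
                float((perm[sub.assignments] == full.assignments[idx]).mean())
            )
        rows.append(
            {
                "fraction": frac,
                "n_reps": len(agreements),
                "mean_agreement": float(np.mean(agreements)) if agreements else np.nan,
            }
        )
    return pd.DataFrame(rows)


def align_and_concord(grouping, sire_labels) -> ConcordanceReport:
    """Pair clusters with SIRE labels and quantify membership overlap.

    The pairing maximizes total matched individuals over all bijections
    (assignment problem), which requires as many clusters as SIRE
    categories. Reports the overall concordance plus both conditional
    concordances (given cluster, given SIRE label).
    """
    assignments = np.asarray(
        grouping.assignments if hasattr(grouping, "assignments") else grouping
    )
    sire = np.asarray(sire_labels, dtype=object).astype(str)
    if assignments.shape != sire.shape:
        raise ValueError("assignments and sire_labels must align")
    clusters = np.unique(assignments)
    labels = sorted(set(sire))
    if len(clusters) != len(labels):
        raise ValueError(
            f"{len(clusters)} clusters vs {len(labels)} SIRE categories: "
            "pairing undefined"
        )
    k = len(labels)
    cont = np.zeros((k, k), dtype=int)
    cl_index = {c: i for i, c in enumerate(clusters)}
    lb_index = {s: j for j, s in enumerate(labels)}
    for a, s in zip(assignments, sire):
        cont[cl_index[a], lb_index[s]] += 1
    rows, cols = linear_sum_assignment(-cont)
    mapping = {int(clusters[r]): labels[c] for r, c in zip(rows, cols)}
    matched = int(cont[rows, cols].sum())
    total = int(cont.sum())
    per_ga = {
        int(clusters[r]): cont[r, c] / cont[r].sum() if cont[r].sum() else np.nan
        for r, c in zip(rows, cols)
    }
    per_sire = {
        labels[c]: cont[r, c] / cont[:, c].sum() if cont[:, c].sum() else np.nan
        for r, c in zip(rows, cols)
    }
    contingency = pd.DataFrame(
        cont, index=pd.Index(clusters, name="cluster"),
        columns=pd.Index(labels, name="sire"),
    )
    return ConcordanceReport(
        mapping=mapping,
        overall_concordance=matched / total,
        per_group_given_ga=per_ga,
        per_group_given_sire=per_sire,
        contingency=contingency,
    )
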