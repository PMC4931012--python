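"""Community-state typing: sqrt-JSD distances, PAM, CH scoring, k voting, PCoA.

The enterotype-style procedure: compute the square root of the Jensen-Shannon
divergence (natural log) between every pair of family-composition profiles,
partition the samples around medoids (PAM), and pick the number of clusters by
repeatedly subsampling the cohort, scoring every candidate k with the
Calinski-Harabasz (CH) index, and voting for the k that wins most often.

All clustering here is deterministic given the distance matrix and its sample
order; the only randomness in the pipeline is the subsampling in
:func:`estimate_k`, driven by an explicit seed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .profiles import AbundanceTable

__all__ = [
    "DistanceMatrix",
    "ClusterSolution",
    "VotingResult",
    "PcoaResult",
    "HclustResult",
    "jsd_divergence",
    "jsd_distance",
    "jsd_matrix",
    "pam",
    "ch_index",
    "estimate_k",
    "pcoa",
    "hclust_complete",
]

#: analytic upper bound of sqrt-JSD with natural logarithms
MAX_JSD_DISTANCE = float(np.sqrt(np.log(2.0)))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample dissimilarities with zero diagonal."""

    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if not np.isfinite(d).all():
            raise ValueError("non-finite distances")
        if (d < 0).any():
            raise ValueError("negative distances")
        if not np.array_equal(d, d.T):
            raise ValueError("distance matrix not exactly symmetric")
        if np.diag(d).any():
            raise ValueError("nonzero diagonal")
        self.d = d
        self.sample_ids = list(self.sample_ids)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def subset(self, indices: Sequence[int]) -> "DistanceMatrix":
        idx = np.asarray(indices, dtype=int)
        return DistanceMatrix(
            [self.sample_ids[i] for i in idx], self.d[np.ix_(idx, idx)]
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids)
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", float_format="%.12g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        d = df.to_numpy(dtype=float)
        d = (d + d.T) / 2.0  # absorb decimal round-trip asymmetry
        np.fill_diagonal(d, 0.0)
        return cls(list(df.index.astype(str)), d)


@dataclass
class ClusterSolution:
    """PAM output: medoids, assignments, total cost and CH score."""

    k: int
    medoid_ids: list[str]
    assignment: dict[str, int]  # sample_id -> cluster index in 1..k
    labels: np.ndarray  # per-sample cluster index, sample order of the input
    total_cost: float
    ch: float | None  # None when k < 2 or k > n-1

    def members(self, cluster: int) -> list[str]:
        return [s for s, c in self.assignment.items() if c == cluster]

    def sizes(self) -> dict[int, int]:
        return dict(Counter(self.assignment.values()))


@dataclass
class VotingResult:
    """Vote histogram of the subsampled cluster-number selection."""

    trials: int
    k_range: list[int]
    votes: dict[int, int]
    optimal_k: int
    subsample_fraction: float
    seed: int

    def __post_init__(self) -> None:
        if sum(self.votes.values()) != self.trials:
            raise ValueError("votes must sum to trials")
        if self.optimal_k not in self.k_range:
            raise ValueError("optimal_k outside k_range")


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy with natural log; 0*ln(0) terms contribute 0."""
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def jsd_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence (natural log) between two probability vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("length mismatch")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("negative components")
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} sums to {v.sum():.6g}, expected 1")
    m = (p + q) / 2.0
    js = _entropy(m) - (_entropy(p) + _entropy(q)) / 2.0
    return max(js, 0.0)  # clip float noise on identical inputs


def jsd_distance(p: np.ndarray, q: np.ndarray) -> float:
    """sqrt-JSD, a metric in [0, sqrt(ln 2)]."""
    return float(np.sqrt(jsd_divergence(p, q)))


def jsd_matrix(table: AbundanceTable) -> DistanceMatrix:
    """All pairwise sqrt-JSD distances between the table's samples."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    x = table.values
    n = x.shape[0]
    # vectorized pairwise JS divergence via entropies
    h = np.array([_entropy(row) for row in x])
    d = np.zeros((n, n))
    for i in range(n - 1):
        m = (x[i] + x[i + 1 :]) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            hm = -np.where(m > 0, m * np.log(np.where(m > 0, m, 1.0)), 0.0).sum(axis=1)
        js = np.maximum(hm - (h[i] + h[i + 1 :]) / 2.0, 0.0)
        d[i, i + 1 :] = np.sqrt(js)
    d = d + d.T
    return DistanceMatrix(table.sample_ids, d)


def _pam_build(d: np.ndarray, k: int) -> list[int]:
    """Greedy BUILD seeding: ties broken toward the lowest sample index."""
    n = d.shape[0]
    first = int(np.argmin(d.sum(axis=0)))
    medoids = [first]
    nearest = d[first].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[:, None] - d, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        j = int(np.argmax(gains))  # argmax returns the first (lowest) index
        medoids.append(j)
        nearest = np.minimum(nearest, d[j])
    return medoids


def pam(dist: DistanceMatrix, k: int) -> ClusterSolution:
    """Partitioning around medoids: BUILD seeding then best-improvement SWAP.

    Deterministic: all ties (seeding, swaps, nearest-medoid assignment) break
    toward the lowest sample index.  SWAP accepts the best strictly
    cost-decreasing medoid/non-medoid exchange and iterates to a local optimum.
    """
    n = dist.n
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    d = dist.d
    medoids = sorted(_pam_build(d, k))

    if k < n:
        while True:
            med = np.array(medoids)
            non = np.array([i for i in range(n) if i not in set(medoids)])
            dm = d[:, med]  # n x k distances to current medoids
            if k == 1:
                d1 = dm[:, 0]
                d2 = np.full(n, np.inf)
                nearest_pos = np.zeros(n, dtype=int)
            else:
                part = np.partition(dm, 1, axis=1)
                d1, d2 = part[:, 0], part[:, 1]
                nearest_pos = np.argmin(dm, axis=1)
            cost = d1.sum()
            dh = d[:, non]  # n x |non|
            best = (cost, None)
            for pos, m in enumerate(med):
                base = np.where(nearest_pos == pos, d2, d1)
                new_costs = np.minimum(base[:, None], dh).sum(axis=0)
                j = int(np.argmin(new_costs))
                if new_costs[j] < best[0] - 1e-12:
                    best = (new_costs[j], (int(m), int(non[j])))
            if best[1] is None:
                break
            m_out, h_in = best[1]
            medoids = sorted(set(medoids) - {m_out} | {h_in})

    med = np.array(sorted(medoids))
    dm = d[:, med]
    nearest_pos = np.argmin(dm, axis=1)  # ties -> lowest medoid index (med sorted)
    labels = nearest_pos + 1
    total_cost = float(dm[np.arange(n), nearest_pos].sum())
    assignment = {dist.sample_ids[i]: int(labels[i]) for i in range(n)}
    ch = ch_index(dist, labels) if 2 <= k <= n - 1 else None
    return ClusterSolution(
        k=k,
        medoid_ids=[dist.sample_ids[i] for i in med],
        assignment=assignment,
        labels=labels,
        total_cost=total_cost,
        ch=ch,
    )


def ch_index(dist: DistanceMatrix, labels: Sequence[int] | Mapping[str, int]) -> float:
    """Calinski-Harabasz index computed directly from pairwise distances.

    Uses the identity that a cluster's sum of squared deviations from its
    centroid equals the sum of squared pairwise distances within the cluster
    divided by twice its size, so no coordinates are needed:

        W = sum_c (1 / 2 n_c) * sum_{i,j in c} d(i,j)^2
        T = (1 / 2n) * sum_{i,j} d(i,j)^2,  B = T - W
        CH = (B / (k-1)) / (W / (n-k))

    Equals the textbook coordinate-based CH whenever the distances are
    Euclidean.  Defined for 2 <= k <= n-1 with every cluster non-empty.
    """
    if isinstance(labels, Mapping):
        lab = np.array([labels[s] for s in dist.sample_ids])
    else:
        lab = np.asarray(labels)
    n = dist.n
    uniq = np.unique(lab)
    k = len(uniq)
    if k < 2 or k > n - 1:
        raise ValueError(f"CH undefined for k={k} with n={n}")
    sq = dist.d**2
    total = sq.sum() / (2.0 * n)
    within = 0.0
    for c in uniq:
        idx = np.flatnonzero(lab == c)
        within += sq[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    between = total - within
    if within <= 0:
        return np.inf if between > 0 else 0.0
    return float((between / (k - 1)) / (within / (n - k)))


def estimate_k(
    dist: DistanceMatrix,
    k_range: Sequence[int] = range(2, 11),
    trials: int = 1000,
    subsample_fraction: float = 0.8,
    seed: int = 0,
) -> VotingResult:
    """Pick the cluster number by CH voting over random subsamples.

    Per trial: draw ``floor(subsample_fraction * n)`` samples uniformly
    without replacement, restrict the distance matrix, run PAM + CH for every
    k in ``k_range``, and record the k with the highest CH (ties toward the
    smallest k).  The modal winning k over all trials is the optimal cluster
    number; the full vote histogram is returned.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")
    n = dist.n
    m = int(np.floor(subsample_fraction * n))
    if min(k_range) < 2 or max(k_range) > m - 1:
        raise ValueError(
            f"k_range {k_range} outside [2, {m - 1}] allowed by subsample size {m}"
        )
    rng = np.random.default_rng(seed)
    votes: Counter[int] = Counter()
    for _ in range(trials):
        idx = rng.choice(n, size=m, replace=False)
        sub = dist.subset(np.sort(idx))
        best_k, best_ch = None, -np.inf
        for k in k_range:
            ch = pam(sub, k).ch
            if ch > best_ch:
                best_k, best_ch = k, ch
        votes[best_k] += 1
    full_votes = {k: votes.get(k, 0) for k in k_range}
    top = max(full_votes.values())
    optimal = min(k for k, v in full_votes.items() if v == top)
    return VotingResult(
        trials=trials,
        k_range=k_range,
        votes=full_votes,
        optimal_k=optimal,
        subsample_fraction=subsample_fraction,
        seed=seed,
    )


@dataclass
class PcoaResult:
    """Classical metric scaling of a distance matrix."""

    sample_ids: list[str]
    coordinates: np.ndarray  # samples x retained positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives reported)
    proportion_explained: np.ndarray  # over positive eigenvalues only

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def pcoa(dist: DistanceMatrix, n_axes: int = 2) -> PcoaResult:
    """Principal coordinates analysis (Torgerson classical scaling).

    Double-centers -d^2/2, eigendecomposes, and scales eigenvectors by the
    square roots of the non-negative eigenvalues.  Negative eigenvalues (the
    non-Euclidean part of the distance) are reported but excluded from the
    coordinates.  Sign convention: each axis's first nonzero loading is
    positive.
    """
    n = dist.n
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    if n_axes > n - 1:
        raise ValueError(f"n_axes={n_axes} exceeds n-1={n - 1}")
    sq = dist.d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ sq @ j
    b = (b + b.T) / 2.0
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * 1e-12
    positive = evals > tol
    n_pos = min(int(positive.sum()), n_axes)
    coords = evecs[:, :n_pos] * np.sqrt(evals[:n_pos])
    for a in range(n_pos):
        col = coords[:, a]
        nz = np.flatnonzero(np.abs(col) > tol)
        if nz.size and col[nz[0]] < 0:
            coords[:, a] = -col
    pos_sum = evals[positive].sum()
    prop = (evals[:n_pos] / pos_sum) if pos_sum > 0 else np.zeros(n_pos)
    return PcoaResult(
        sample_ids=list(dist.sample_ids),
        coordinates=coords,
        eigenvalues=evals,
        proportion_explained=prop,
    )


@dataclass
class HclustResult:
    """Complete-linkage merge tree (scipy linkage format) and leaf order."""

    sample_ids: list[str]
    merges: np.ndarray  # (n-1) x 4 linkage matrix
    leaf_order: list[str] = field(default_factory=list)


def hclust_complete(dist: DistanceMatrix) -> HclustResult:
    """Agglomerative complete-linkage clustering for heatmap sample ordering."""
    if dist.n < 2:
        raise ValueError("need at least 2 samples")
    condensed = squareform(dist.d, checks=False)
    merges = linkage(condensed, method="complete")
    order = leaves_list(merges)
    return HclustResult(
        sample_ids=list(dist.sample_ids),
        merges=merges,
        leaf_order=[dist.sample_ids[i] for i in order],
    )
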