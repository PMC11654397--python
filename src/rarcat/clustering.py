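"""Deterministic Partitioning Around Medoids and cluster-quality indices.

PAM here is fully deterministic: the BUILD phase seeds medoids greedily, the
SWAP phase repeatedly applies the best strictly-improving (medoid, candidate)
swap, and every tie — seeding, swapping, and nearest-medoid assignment — is
broken by the lowest index.  Determinism matters beyond reproducibility: it
guarantees that duplicated rows of a bootstrap-sliced distance matrix (at
mutual distance zero) are always assigned to the same cluster.

Quality indices operate directly on the dissimilarity matrix: the average
silhouette width (ASW), and a Calinski–Harabasz pseudo-F computed from
squared dissimilarities, the standard generalisation used for edit-distance
typologies (within-cluster sum of squares of a cluster equals the sum of its
squared pairwise dissimilarities divided by the cluster size).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dissimilarity import DistanceMatrix

__all__ = [
    "Partition",
    "pam",
    "silhouette_asw",
    "calinski_harabasz",
    "select_k",
]

#: ASW below which a partition is conventionally said to carry no
#: substantial structure; advisory only.
LOW_STRUCTURE_ASW = 0.25

_SWAP_TOL = 1e-12


@dataclass
class Partition:
    """Cluster labels 1..K with medoid indices and quality indices."""

    labels: np.ndarray
    medoids: np.ndarray
    k: int
    asw: float | None = None
    chi: float | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.medoids = np.asarray(self.medoids, dtype=int)
        if self.labels.min(initial=1) < 1 or self.labels.max(initial=1) > self.k:
            raise ValueError("labels must lie in 1..K")
        counts = np.bincount(self.labels, minlength=self.k + 1)[1:]
        if (counts == 0).any():
            raise ValueError("no cluster may be empty")
        for c, m in enumerate(self.medoids, start=1):
            if self.labels[m] != c:
                raise ValueError("each medoid must belong to its own cluster")

    def cluster_members(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.labels == c)

    def to_frame(self, ids) -> pd.DataFrame:
        return pd.DataFrame({"id": list(ids), "label": self.labels})


def _as_array(dist) -> np.ndarray:
    d = dist.d if isinstance(dist, DistanceMatrix) else np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    return d


def pam(dist, k: int, compute_indices: bool = False) -> Partition:
    """Partitioning Around Medoids on a dissimilarity matrix.

    BUILD seeds medoids greedily (largest cost reduction, ties to the lowest
    index); SWAP applies the best strictly-improving swap until none exists;
    points are assigned to the nearest medoid, ties to the lowest medoid
    index.  ``k = 1`` returns the single global medoid.
    """
    d = _as_array(dist)
    n = d.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of points n={n}")

    # BUILD
    medoids = [int(np.argmin(d.sum(axis=1)))]
    dnear = d[:, medoids[0]].copy()
    while len(medoids) < k:
        reduction = np.maximum(dnear[:, None] - d, 0.0).sum(axis=0)
        reduction[medoids] = -np.inf
        h = int(np.argmax(reduction))
        medoids.append(h)
        np.minimum(dnear, d[:, h], out=dnear)

    # SWAP: best strictly-improving swap, repeated to convergence
    if k >= 2:
        while True:
            cost = d[:, medoids].min(axis=1).sum()
            best_cost, best_swap = cost, None
            for mi in range(len(medoids)):
                others = medoids[:mi] + medoids[mi + 1:]
                dmin_excl = d[:, others].min(axis=1)
                new_costs = np.minimum(dmin_excl[:, None], d).sum(axis=0)
                new_costs[medoids] = np.inf
                h = int(np.argmin(new_costs))
                if new_costs[h] < best_cost - _SWAP_TOL:
                    best_cost, best_swap = new_costs[h], (mi, h)
            if best_swap is None:
                break
            medoids[best_swap[0]] = best_swap[1]

    medoids = sorted(medoids)
    labels = np.argmin(d[:, medoids], axis=1) + 1
    for c, m in enumerate(medoids, start=1):
        labels[m] = c  # a medoid always belongs to its own cluster
    part = Partition(labels=labels, medoids=np.array(medoids), k=k)
    if compute_indices and k >= 2:
        part.asw = silhouette_asw(d, labels)
        part.chi = calinski_harabasz(d, labels)
    return part


def pam_cost(dist, medoids) -> float:
    """Total distance of every point to its nearest medoid."""
    d = _as_array(dist)
    return float(d[:, list(medoids)].min(axis=1).sum())


def silhouette_asw(dist, labels) -> float:
    """Average silhouette width of a partition on a dissimilarity matrix.

    s(i) = (b(i) − a(i)) / max(a(i), b(i)), with a(i) the mean distance to
    the own cluster excluding self and b(i) the smallest mean distance to any
    other cluster; members of singleton clusters contribute s(i) = 0.
    """
    d = _as_array(dist)
    labels = np.asarray(labels, dtype=int)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least two clusters")
    n = d.shape[0]
    sizes = {c: int((labels == c).sum()) for c in uniq}
    s = np.zeros(n)
    mean_to = np.stack([d[:, labels == c].sum(axis=1) / sizes[c] for c in uniq],
                       axis=1)  # biased for the own cluster; corrected below
    for pos, c in enumerate(uniq):
        own = labels == c
        nc = sizes[c]
        if nc == 1:
            s[own] = 0.0
            continue
        a = mean_to[own, pos] * nc / (nc - 1)  # exclude self from the mean
        b = np.min(mean_to[own][:, [p for p in range(len(uniq)) if p != pos]],
                   axis=1)
        denom = np.maximum(a, b)
        si = np.where(denom > 0, (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
        s[own] = si
    return float(s.mean())


def calinski_harabasz(dist, labels, squared: bool = True) -> float:
    """Calinski–Harabasz pseudo-F from (squared) dissimilarities.

    W = Σ_clusters (Σ_{i<j∈c} d(i,j)²)/n_c, T likewise over all pairs / n,
    B = T − W, CHI = (B/(K−1)) / (W/(n−K)).  A partition with W = 0 is
    perfect and returns +inf.
    """
    d = _as_array(dist)
    labels = np.asarray(labels, dtype=int)
    uniq = np.unique(labels)
    K = len(uniq)
    if K < 2:
        raise ValueError("CHI requires at least two clusters")
    n = d.shape[0]
    if n == K:
        raise ValueError("CHI undefined when every cluster is a singleton")
    dd = d ** 2 if squared else d
    total = dd.sum() / (2.0 * n)
    W = 0.0
    for c in uniq:
        mask = labels == c
        nc = mask.sum()
        W += dd[np.ix_(mask, mask)].sum() / (2.0 * nc)
    B = total - W
    if W <= 0:
        return np.inf
    return float((B / (K - 1)) / (W / (n - K)))


def select_k(dist, k_range, rule: str = "report"):
    """Run PAM over a range of k and report/select by quality index.

    With ``rule="chi"`` (the rule applied inside bootstrap replicates when
    the number of clusters is treated as estimated) the partition maximising
    CHI is returned, ties to the smallest k.  With ``rule="report"`` the
    caller chooses: the partition slot of the return value is None.
    Returns ``(partition_or_None, table)`` where the table lists ASW and CHI
    per k.
    """
    d = _as_array(dist)
    ks = list(k_range) if not isinstance(k_range, tuple) else list(
        range(k_range[0], k_range[1] + 1))
    if len(ks) == 0:
        raise ValueError("empty k range")
    if min(ks) < 2 or max(ks) > d.shape[0] - 1:
        raise ValueError("k range must lie within [2, n-1]")
    parts, rows = [], []
    for k in ks:
        p = pam(d, k, compute_indices=True)
        parts.append(p)
        rows.append({"k": k, "asw": p.asw, "chi": p.chi})
    table = pd.DataFrame(rows)
    if rule == "report":
        return None, table
    if rule != "chi":
        raise ValueError(f"unknown selection rule {rule!r}")
    best = int(np.argmax(table["chi"].to_numpy()))  # first occurrence: smallest k
    chosen = parts[best]
    if chosen.asw is not None and chosen.asw < LOW_STRUCTURE_ASW:
        warnings.warn(
            f"selected k={chosen.k} has ASW={chosen.asw:.3f} < "
            f"{LOW_STRUCTURE_ASW}: little clustering structure",
            UserWarning, stacklevel=2)
    return chosen, table
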