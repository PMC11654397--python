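"""Bootstrap resampling and cluster-wise Jaccard stability of a typology.

Following Hennig's cluster-wise stability assessment, bootstrap samples of
the original size are drawn with replacement, each sample is re-clustered
with the exact same procedure (same distance matrix — sliced, never
re-estimated — same algorithm, same rule for the number of clusters), and
each original cluster is scored by the best Jaccard similarity it achieves
against any bootstrap cluster, computed on sets of distinct resampled ids.
A replicate in which no member of an original cluster was resampled carries
no information about that cluster's recovery and is skipped, not scored 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import Partition, pam, select_k
from .dissimilarity import DistanceMatrix

__all__ = [
    "BootstrapDraw",
    "StabilityReport",
    "draw_bootstrap",
    "clusterwise_jaccard",
]


@dataclass
class BootstrapDraw:
    """One bootstrap resample: a size-M multiset of ids drawn with replacement."""

    replicate_index: int
    sampled_ids: list
    positions: np.ndarray  # positions into the original id list, length M

    @property
    def distinct_ids(self) -> set:
        return set(self.sampled_ids)


@dataclass
class StabilityReport:
    """Per-cluster Jaccard stability across bootstrap replicates.

    ``values`` is an n_boot × K table of per-replicate best-match Jaccard
    coefficients (NaN where the replicate was skipped for that cluster).
    """

    values: pd.DataFrame
    mean_jaccard: pd.Series
    n_used: pd.Series
    n_skipped: pd.Series

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mean_jaccard": self.mean_jaccard,
            "n_used": self.n_used,
            "n_skipped": self.n_skipped,
        })

    def to_csv(self, summary_path, long_path=None) -> None:
        out = self.summary().reset_index(names="cluster")
        out.to_csv(summary_path, index=False)
        if long_path is not None:
            long = self.values.reset_index(names="replicate").melt(
                id_vars="replicate", var_name="cluster", value_name="jaccard")
            long.dropna(subset=["jaccard"]).to_csv(long_path, index=False)


def replicate_rng(seed: int, replicate_index: int) -> np.random.Generator:
    """Replicate-indexed RNG stream, independent of worker scheduling."""
    return np.random.default_rng([int(seed), int(replicate_index)])


def draw_bootstrap(ids, seed: int, replicate_index: int) -> BootstrapDraw:
    """Draw a with-replacement sample of the same size as ``ids``.

    Reproducible from ``(seed, replicate_index)`` alone.
    """
    ids = list(ids)
    if len(ids) < 1:
        raise ValueError("cannot bootstrap an empty id list")
    rng = replicate_rng(seed, replicate_index)
    pos = rng.integers(0, len(ids), size=len(ids))
    return BootstrapDraw(replicate_index=replicate_index,
                         sampled_ids=[ids[p] for p in pos],
                         positions=pos)


def jaccard_scores_for_draw(original: Partition, positions: np.ndarray,
                            boot_labels: np.ndarray) -> list:
    """Best-match Jaccard per original cluster for one re-clustered resample.

    ``positions`` are original-sample positions of the resampled rows (with
    multiplicity) and ``boot_labels`` the cluster labels of those rows.
    Jaccard is computed on sets of distinct positions — invariant to the
    multiplicity of the draw — restricting each original cluster to the
    resampled ids.  Returns one value per original cluster, NaN where no
    member was resampled.
    """
    sampled = set(int(p) for p in positions)
    boot_sets = []
    for c in range(1, int(boot_labels.max()) + 1):
        members = {int(positions[r]) for r in np.flatnonzero(boot_labels == c)}
        boot_sets.append(members)
    scores = []
    for c in range(1, original.k + 1):
        A = set(map(int, original.cluster_members(c))) & sampled
        if not A:
            scores.append(np.nan)
            continue
        best = max(len(A & C) / len(A | C) for C in boot_sets if C)
        scores.append(best)
    return scores


def clusterwise_jaccard(original: Partition, dist: DistanceMatrix,
                        n_boot: int, k_mode: str = "fixed",
                        k_range=None, seed: int = 0) -> StabilityReport:
    """Hennig-style cluster-wise bootstrap stability of ``original``.

    Each replicate slices the original distance matrix to the resampled rows
    (duplicated draws become duplicated rows/columns), re-clusters with PAM —
    K fixed to the original K, or chosen by maximising CHI when
    ``k_mode="chi"`` — and scores every original cluster by its best-match
    Jaccard coefficient over distinct resampled ids.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if k_mode not in ("fixed", "chi"):
        raise ValueError("k_mode must be 'fixed' or 'chi'")
    if k_mode == "chi" and k_range is None:
        raise ValueError("k_mode='chi' requires k_range")
    d = dist.d
    rows = []
    for j in range(1, n_boot + 1):
        draw = draw_bootstrap(dist.ids, seed, j)
        sub = d[np.ix_(draw.positions, draw.positions)]
        if k_mode == "fixed":
            part = pam(sub, original.k)
        else:
            part, _ = select_k(sub, k_range, rule="chi")
        rows.append(jaccard_scores_for_draw(original, draw.positions, part.labels))
    values = pd.DataFrame(rows, columns=range(1, original.k + 1),
                          index=pd.RangeIndex(1, n_boot + 1, name="replicate"))
    return StabilityReport(
        values=values,
        mean_jaccard=values.mean(axis=0, skipna=True),
        n_used=values.notna().sum(axis=0),
        n_skipped=values.isna().sum(axis=0),
    )
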