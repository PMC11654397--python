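"""Substitution/indel costs and Optimal Matching edit distance.

Costs follow the transition-rate ("TRATE") scheme: the substitution cost
between two distinct states is ``cmax − p(j|i) − p(i|j)``, where ``p(j|i)``
is the observed probability of moving from state i to state j between
adjacent time points, pooled over the whole sample.  States that frequently
transition into each other are therefore cheap to substitute.  Following
Halpin's treatment of nonresponse, every substitution involving the missing
state — including missing versus missing — costs the maximum, so that shared
missingness never acts as a factor of similarity.  Indel cost is half the
maximum substitution cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequence_data import StateSequenceSet

__all__ = [
    "TransitionRates",
    "CostMatrix",
    "DistanceMatrix",
    "transition_rates",
    "trate_costs",
    "om_distance",
    "pairwise_matrix",
]


@dataclass
class TransitionRates:
    """Observed state-to-state transition probabilities.

    ``rates[i, j]`` is the probability of state j at t+1 given state i at t,
    pooled over all individuals and adjacent time-point pairs.  Rows of states
    never observed as a transition origin are all-zero and flagged in
    ``never_observed_from``.
    """

    alphabet: list
    rates: np.ndarray
    never_observed_from: np.ndarray

    def __post_init__(self):
        observed = ~self.never_observed_from
        sums = self.rates[observed].sum(axis=1)
        if observed.any() and not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError("observed-from rows must sum to 1")


@dataclass
class CostMatrix:
    """Symmetric substitution costs plus the indel cost (= cmax/2)."""

    alphabet: list
    sub: np.ndarray
    indel: float
    cmax: float

    def __post_init__(self):
        self.sub = np.asarray(self.sub, dtype=float)
        if not np.allclose(self.sub, self.sub.T):
            raise ValueError("substitution cost matrix must be symmetric")
        if (self.sub < -1e-12).any() or (self.sub > self.cmax + 1e-12).any():
            raise ValueError("substitution costs must lie in [0, cmax]")
        if self.indel < 0:
            raise ValueError("indel cost must be nonnegative")

    def index_of(self, state) -> int:
        try:
            return self.alphabet.index(state)
        except ValueError:
            raise KeyError(f"state {state!r} not covered by the cost matrix")


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative pairwise dissimilarities with aligned ids."""

    ids: list
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape must match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(self.d) != 0).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < 0).any():
            raise ValueError("distances must be nonnegative")

    def to_csv(self, path) -> None:
        pd.DataFrame(self.d, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(ids=list(df.index.astype(str)), d=df.to_numpy(dtype=float))


def transition_rates(seqs: StateSequenceSet) -> TransitionRates:
    """Pooled adjacent-pair transition rates over the whole sample."""
    if seqs.n_timepoints < 2:
        raise ValueError("transition rates require at least two time points")
    A = len(seqs.alphabet)
    codes = seqs.codes()
    counts = np.zeros((A, A))
    np.add.at(counts, (codes[:, :-1].ravel(), codes[:, 1:].ravel()), 1.0)
    totals = counts.sum(axis=1)
    never = totals == 0
    rates = np.zeros_like(counts)
    rates[~never] = counts[~never] / totals[~never, None]
    return TransitionRates(alphabet=list(seqs.alphabet), rates=rates,
                           never_observed_from=never)


def trate_costs(rates: TransitionRates, missing_code,
                cmax: float = 2.0, missing_missing_cost: float | None = None) -> CostMatrix:
    """Transition-rate substitution costs with maximal missing-state costs.

    ``sub(i, j) = cmax − p(j|i) − p(i|j)`` for distinct non-missing states
    (clipped to [0, cmax]); every pair involving the missing state — the
    missing/missing pair included, unless ``missing_missing_cost`` overrides
    it — costs ``cmax``; indel = cmax/2.
    """
    alphabet = list(rates.alphabet)
    if missing_code not in alphabet:
        raise ValueError(f"missing_code {missing_code!r} not in alphabet")
    p = rates.rates
    sub = np.clip(cmax - p - p.T, 0.0, cmax)
    np.fill_diagonal(sub, 0.0)
    mi = alphabet.index(missing_code)
    sub[mi, :] = cmax
    sub[:, mi] = cmax
    sub[mi, mi] = cmax if missing_missing_cost is None else missing_missing_cost
    return CostMatrix(alphabet=alphabet, sub=sub, indel=cmax / 2.0, cmax=cmax)


def om_distance(x, y, costs: CostMatrix) -> float:
    """Optimal Matching edit distance between two label sequences.

    Classic Needleman–Wunsch dynamic program with substitution cost
    ``costs.sub`` and constant indel cost; symmetric in its arguments.
    """
    xi = [costs.index_of(s) for s in x]
    yi = [costs.index_of(s) for s in y]
    a, b = len(xi), len(yi)
    indel = costs.indel
    sub = costs.sub
    prev = np.arange(b + 1, dtype=float) * indel
    for i in range(1, a + 1):
        cur = np.empty(b + 1)
        cur[0] = i * indel
        row_costs = sub[xi[i - 1]]
        for j in range(1, b + 1):
            cur[j] = min(prev[j - 1] + row_costs[yi[j - 1]],
                         prev[j] + indel,
                         cur[j - 1] + indel)
        prev = cur
    return float(prev[b])


def _om_all_pairs(codes: np.ndarray, sub: np.ndarray, indel: float) -> np.ndarray:
    """All-pairs OM distances for equal-length coded sequences, vectorised.

    Runs the (T+1)×(T+1) dynamic program once with u×u matrices in each cell,
    where u is the number of sequences; O(T² u²) but fully in numpy.
    """
    u, T = codes.shape
    prev = [np.full((u, u), j * indel) for j in range(T + 1)]
    for i in range(1, T + 1):
        cur = [np.full((u, u), i * indel)]
        for j in range(1, T + 1):
            subc = sub[codes[:, i - 1][:, None], codes[None, :, j - 1]]
            cell = np.minimum(prev[j - 1] + subc, prev[j] + indel)
            np.minimum(cell, cur[j - 1] + indel, out=cell)
            cur.append(cell)
        prev = cur
    out = prev[T]
    return 0.5 * (out + out.T)  # symmetrise away float noise


def pairwise_matrix(seqs: StateSequenceSet, costs: CostMatrix) -> DistanceMatrix:
    """M×M OM dissimilarity matrix, computed once and reused by all bootstraps.

    Duplicate sequences are detected and computed only once (the grid of a
    few prototypes plus noise typically contains many repeats).
    """
    if seqs.n_individuals < 2:
        raise ValueError("need at least two sequences")
    if list(costs.alphabet) != list(seqs.alphabet):
        raise ValueError("cost matrix alphabet does not match the sequence set")
    codes = seqs.codes()
    uniq, inverse = np.unique(codes, axis=0, return_inverse=True)
    du = _om_all_pairs(uniq, costs.sub, costs.indel)
    d = du[inverse][:, inverse]
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=list(seqs.ids), d=d)
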