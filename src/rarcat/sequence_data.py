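"""Data model and I/O for categorical state sequences with aligned covariates.

A state sequence dataset is a rectangular grid of categorical states — one row
per individual, one column per time point — over a finite alphabet in which
nonresponse is itself a state (one reserved label, never an empty cell),
together with a covariate table keyed by individual id.  The on-disk format is
a comma-delimited wide table with a header row and a leading ``id`` column,
states stored as labels ("STS" layout).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StateSequenceSet",
    "read_sequences",
    "write_sequences",
    "state_distribution",
    "sequence_frequencies",
]


class SequenceValidationError(ValueError):
    """Raised when a grid, alphabet or covariate table violates an invariant."""


@dataclass
class StateSequenceSet:
    """Individuals × time grid of categorical states plus covariates.

    Parameters
    ----------
    ids
        Unique individual identifiers (length M).
    states
        M×T array of state labels; every entry must be in ``alphabet``.
    alphabet
        Ordered list of state labels; defines the integer coding used by
        downstream modules.
    missing_code
        The alphabet label reserved for nonresponse.
    covariates
        Table indexed by id containing exactly the grid's ids.  Covariate
        values may be missing (handled downstream by complete-case analysis);
        grid states may not.
    """

    ids: list
    states: np.ndarray
    alphabet: list
    missing_code: str
    covariates: pd.DataFrame = field(default=None)

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=object)
        if self.states.ndim != 2:
            raise SequenceValidationError("states must be a 2-D grid")
        if len(self.ids) != self.states.shape[0]:
            raise SequenceValidationError(
                f"{len(self.ids)} ids but {self.states.shape[0]} grid rows"
            )
        if len(set(self.ids)) != len(self.ids):
            dupes = pd.Series(self.ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise SequenceValidationError(f"duplicate ids: {dupes}")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise SequenceValidationError("alphabet labels must be unique")
        if self.missing_code not in self.alphabet:
            raise SequenceValidationError(
                f"missing_code {self.missing_code!r} not in alphabet"
            )
        allowed = set(self.alphabet)
        for i in range(self.states.shape[0]):
            for t in range(self.states.shape[1]):
                s = self.states[i, t]
                if s not in allowed:
                    raise SequenceValidationError(
                        f"state {s!r} at id {self.ids[i]!r}, column {t + 1} "
                        "is not in the alphabet"
                    )
        if self.covariates is None:
            self.covariates = pd.DataFrame(index=pd.Index(self.ids, name="id"))
        if set(self.covariates.index) != set(self.ids):
            raise SequenceValidationError(
                "covariate table must contain exactly the grid ids"
            )
        # align covariate rows with grid order
        self.covariates = self.covariates.loc[self.ids]

    @property
    def n_individuals(self) -> int:
        return self.states.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.states.shape[1]

    def codes(self) -> np.ndarray:
        """Grid as integer codes (position in the alphabet), dtype intp."""
        lookup = {s: k for k, s in enumerate(self.alphabet)}
        out = np.empty(self.states.shape, dtype=np.intp)
        for k in range(self.states.shape[0]):
            for t in range(self.states.shape[1]):
                out[k, t] = lookup[self.states[k, t]]
        return out


def read_sequences(path_states, path_covariates, alphabet, missing_code) -> StateSequenceSet:
    """Read a wide state-sequence CSV and a covariate CSV into a validated set.

    Covariate rows are inner-joined on id; ids present in only one of the two
    files are dropped and logged.  Empty grid cells are a parse error
    (missingness must use the reserved label).
    """
    try:
        states_df = pd.read_csv(path_states, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SequenceValidationError(f"cannot parse {path_states}: {exc}") from exc
    if states_df.shape[1] < 2 or states_df.columns[0] != "id":
        raise SequenceValidationError(
            f"{path_states}: first column must be 'id' followed by state columns"
        )
    if states_df.isna().any().any():
        cell = np.argwhere(states_df.isna().to_numpy())[0]
        raise SequenceValidationError(
            f"{path_states}: empty cell at row {cell[0] + 1}, "
            f"column {states_df.columns[cell[1]]!r}; missing states must use "
            f"the reserved label {missing_code!r}"
        )
    ids = states_df["id"].tolist()
    grid = states_df.iloc[:, 1:].to_numpy(dtype=object)

    try:
        cov = pd.read_csv(path_covariates)
    except Exception as exc:  # pragma: no cover
        raise SequenceValidationError(f"cannot parse {path_covariates}: {exc}") from exc
    if cov.columns[0] != "id":
        raise SequenceValidationError(f"{path_covariates}: first column must be 'id'")
    cov["id"] = cov["id"].astype(str)
    cov = cov.set_index("id")
    if cov.index.duplicated().any():
        raise SequenceValidationError(
            f"{path_covariates}: duplicate ids "
            f"{sorted(cov.index[cov.index.duplicated()].unique())}"
        )

    common = [i for i in ids if i in set(cov.index)]
    dropped_seq = [i for i in ids if i not in set(cov.index)]
    dropped_cov = sorted(set(cov.index) - set(ids))
    if dropped_seq:
        logger.warning("dropped %d sequence ids without covariates: %s",
                       len(dropped_seq), dropped_seq)
    if dropped_cov:
        logger.warning("dropped %d covariate ids without sequences: %s",
                       len(dropped_cov), dropped_cov)
    keep = [k for k, i in enumerate(ids) if i in set(common)]
    return StateSequenceSet(
        ids=[ids[k] for k in keep],
        states=grid[keep],
        alphabet=list(alphabet),
        missing_code=missing_code,
        covariates=cov.loc[common],
    )


def write_sequences(seqs: StateSequenceSet, path_states, path_covariates) -> None:
    """Write the grid and covariates back to the CSV dialect read_sequences expects."""
    T = seqs.n_timepoints
    df = pd.DataFrame(seqs.states, columns=[f"t{t + 1}" for t in range(T)])
    df.insert(0, "id", seqs.ids)
    df.to_csv(path_states, index=False)
    cov = seqs.covariates.copy()
    cov.index.name = "id"
    cov.to_csv(path_covariates)


def state_distribution(seqs: StateSequenceSet) -> pd.DataFrame:
    """Cross-sectional state proportions: T × |alphabet|, each row sums to 1.

    The missing state counts as a regular state.
    """
    if seqs.n_individuals < 1:
        raise SequenceValidationError("empty sequence set")
    M, T = seqs.states.shape
    counts = np.zeros((T, len(seqs.alphabet)))
    lookup = {s: k for k, s in enumerate(seqs.alphabet)}
    for t in range(T):
        for i in range(M):
            counts[t, lookup[seqs.states[i, t]]] += 1
    out = pd.DataFrame(counts / M, columns=seqs.alphabet)
    out.index = pd.RangeIndex(1, T + 1, name="t")
    return out


def sequence_frequencies(seqs: StateSequenceSet, top: int = 10) -> pd.DataFrame:
    """The ``top`` most frequent distinct sequences with their counts.

    Sorted descending by count; ties broken lexicographically by state codes.
    """
    if top < 1:
        raise ValueError("top must be >= 1")
    tuples = [tuple(row) for row in seqs.states]
    counter: dict[tuple, int] = {}
    for tup in tuples:
        counter[tup] = counter.get(tup, 0) + 1
    ranked = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))[:top]
    return pd.DataFrame(
        {
            "sequence": ["-".join(map(str, seq)) for seq, _ in ranked],
            "count": [c for _, c in ranked],
        }
    )
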