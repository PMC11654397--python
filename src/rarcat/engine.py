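"""The RARCAT bootstrap loop: replicate typologies, collect individual AMEs.

Each replicate draws a with-replacement sample of the original size, slices
the precomputed distance matrix (costs are never re-estimated), re-clusters
it with the exact same procedure as the original analysis, fits one
cluster-vs-rest logistic regression per bootstrap cluster on the bootstrap
rows (duplicated individuals contribute with their multiplicity), and
assigns the cluster's AME and SE for the covariate of interest to every
distinct individual in that cluster.  Individuals not drawn get no entry;
clusters whose regression fails contribute missing entries for their
members.  No mapping of bootstrap clusters to original clusters is ever
attempted — comparability across replicates lives entirely at the
individual level.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .clustering import Partition, pam, select_k
from .dissimilarity import DistanceMatrix
from .regression import (DesignMatrix, average_marginal_effect, build_design,
                         fit_logistic)
from .sequence_data import StateSequenceSet
from .stability import draw_bootstrap

logger = logging.getLogger(__name__)

__all__ = ["RarcatConfig", "ReplicateResult", "RarcatResult",
           "replicate_once", "run_rarcat"]


@dataclass
class RarcatConfig:
    """Configuration of a RARCAT run.

    ``covariates`` lists the regression terms (identical across bootstraps);
    ``covariate_of_interest`` names the term whose AME is collected, with
    ``level_of_interest`` selecting the non-reference level for categorical
    terms with more than two levels.
    """

    covariates: list
    covariate_of_interest: str
    level_of_interest: object = None
    n_boot: int = 1000
    seed: int = 0
    k_mode: str = "fixed"
    k: int | None = None
    k_range: tuple | None = None
    n_jobs: int = 1

    def __post_init__(self):
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.k_mode == "fixed":
            if self.k is None:
                raise ValueError("k_mode='fixed' requires k")
        elif self.k_mode == "chi":
            if self.k_range is None:
                raise ValueError("k_mode='chi' requires k_range")
        else:
            raise ValueError("k_mode must be 'fixed' or 'chi'")
        if self.covariate_of_interest not in {t.name for t in self.covariates}:
            raise ValueError("covariate_of_interest must be one of the terms")


@dataclass
class ReplicateResult:
    """One column of the AME/SE matrices plus its log record."""

    replicate_index: int
    ame: dict
    se: dict
    chosen_k: int
    n_distinct: int
    failed_clusters: list = field(default_factory=list)


def _slice_design(design: DesignMatrix, positions: np.ndarray) -> DesignMatrix:
    return replace(design, X=design.X[positions], row_ok=design.row_ok[positions])


def replicate_once(seqs: StateSequenceSet, dist: DistanceMatrix,
                   config: RarcatConfig, replicate_index: int,
                   design: DesignMatrix | None = None,
                   positions: np.ndarray | None = None) -> ReplicateResult:
    """Run one bootstrap replicate and return its per-individual AME column.

    ``positions`` (original-sample positions, with multiplicity) may be
    supplied to force a particular resample; by default they are drawn from
    the replicate-indexed RNG stream.
    """
    if design is None:
        design = build_design(seqs.covariates, config.covariates)
    if positions is None:
        positions = draw_bootstrap(dist.ids, config.seed, replicate_index).positions
    sub = dist.d[np.ix_(positions, positions)]
    if config.k_mode == "fixed":
        part = pam(sub, config.k)
    else:
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            part, _ = select_k(sub, config.k_range, rule="chi")

    bdesign = _slice_design(design, positions)
    ok = bdesign.row_ok
    coi_cols = design.term_columns[config.covariate_of_interest]

    ame: dict = {}
    se: dict = {}
    failed = []
    # each distinct individual takes the cluster of its first drawn copy
    # (deterministic assignment makes copies co-cluster in practice)
    first_label: dict[int, int] = {}
    for r, p in enumerate(positions):
        first_label.setdefault(int(p), int(part.labels[r]))

    for c in range(1, part.k + 1):
        in_c = part.labels == c
        y = in_c[ok].astype(float)
        members = sorted({p for p, lab in first_label.items() if lab == c})
        # contract: the covariate of interest must vary within the cluster
        coi_vals = bdesign.X[in_c & ok][:, coi_cols]
        if coi_vals.size == 0 or all(np.ptp(coi_vals[:, j]) == 0
                                     for j in range(coi_vals.shape[1])):
            failed.append({"cluster": c, "reason": "single_covariate_level"})
            continue
        fit = fit_logistic(y, bdesign.X[ok], columns=bdesign.columns,
                           n_dropped=int((~ok).sum()))
        if not fit.ok:
            failed.append({"cluster": c, "reason": fit.failure})
            continue
        if any(k not in fit.kept for k in coi_cols):
            failed.append({"cluster": c, "reason": "covariate_dropped"})
            continue
        try:
            res = average_marginal_effect(fit, bdesign,
                                          config.covariate_of_interest,
                                          config.level_of_interest)
        except ValueError as exc:
            failed.append({"cluster": c, "reason": str(exc)})
            continue
        for p in members:
            ame[p] = res.estimate
            se[p] = res.se
    return ReplicateResult(replicate_index=replicate_index, ame=ame, se=se,
                           chosen_k=part.k,
                           n_distinct=len(set(map(int, positions))),
                           failed_clusters=failed)


@dataclass
class RarcatResult:
    """M×N AME and SE matrices (NaN = individual not drawn or failed cluster)."""

    ame: pd.DataFrame
    se: pd.DataFrame
    log: pd.DataFrame
    summary: dict

    def to_long(self) -> pd.DataFrame:
        long = self.ame.reset_index(names="id").melt(
            id_vars="id", var_name="replicate", value_name="ame")
        long_se = self.se.reset_index(names="id").melt(
            id_vars="id", var_name="replicate", value_name="se")
        long["se"] = long_se["se"]
        return long.dropna(subset=["ame"]).reset_index(drop=True)

    def export(self, prefix) -> None:
        self.to_long().to_csv(f"{prefix}_long.csv", index=False)
        self.ame.to_csv(f"{prefix}_ame_wide.csv")
        self.se.to_csv(f"{prefix}_se_wide.csv")
        self.log.to_csv(f"{prefix}_log.csv", index=False)
        with open(f"{prefix}_summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2)


def run_rarcat(seqs: StateSequenceSet, dist: DistanceMatrix,
               original: Partition, config: RarcatConfig) -> RarcatResult:
    """Assemble N bootstrap replicates into the AME and SE matrices.

    Reproducible from ``config.seed``; with ``n_jobs > 1`` replicates run in
    parallel on replicate-indexed RNG streams, so results are independent of
    worker scheduling.  ``original`` pins the row order/ids; its labels are
    never used inside replicates.
    """
    design = build_design(seqs.covariates, config.covariates)
    design_ok_frac = design.row_ok.mean()
    if design_ok_frac < 1.0:
        logger.info("complete-case analysis drops %.1f%% of rows per model",
                    100 * (1 - design_ok_frac))
    indices = range(1, config.n_boot + 1)
    if config.n_jobs == 1:
        reps = [replicate_once(seqs, dist, config, j, design=design)
                for j in indices]
    else:
        reps = Parallel(n_jobs=config.n_jobs)(
            delayed(replicate_once)(seqs, dist, config, j, design=design)
            for j in indices)

    M = len(dist.ids)
    N = config.n_boot
    ame = np.full((M, N), np.nan)
    sem = np.full((M, N), np.nan)
    log_rows = []
    for rep in reps:
        col = rep.replicate_index - 1
        for p, v in rep.ame.items():
            ame[p, col] = v
            sem[p, col] = rep.se[p]
        log_rows.append({
            "replicate": rep.replicate_index,
            "chosen_k": rep.chosen_k,
            "n_distinct": rep.n_distinct,
            "n_failed_clusters": len(rep.failed_clusters),
            "failure_reasons": ";".join(f["reason"] for f in rep.failed_clusters),
        })
    if not np.isfinite(ame).any():
        raise RuntimeError("all bootstrap replicates failed to produce AMEs")
    idx = pd.Index(dist.ids, name="id")
    cols = pd.RangeIndex(1, N + 1, name="replicate")
    log = pd.DataFrame(log_rows)
    summary = {
        "n_boot": N,
        "n_individuals": M,
        "mean_distinct_fraction": float(log["n_distinct"].mean() / M),
        "replicates_with_failures": int((log["n_failed_clusters"] > 0).sum()),
        "total_failed_clusters": int(log["n_failed_clusters"].sum()),
        "present_entry_fraction": float(np.isfinite(ame).mean()),
        "chosen_k_counts": {int(k): int(v) for k, v in
                            log["chosen_k"].value_counts().items()},
    }
    return RarcatResult(ame=pd.DataFrame(ame, index=idx, columns=cols),
                        se=pd.DataFrame(sem, index=idx, columns=cols),
                        log=log, summary=summary)
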