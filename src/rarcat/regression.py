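"""Cluster-membership logistic regression and average marginal effects.

The association between a typology and covariates is estimated one cluster
at a time: a binary logistic regression of "this cluster vs. any other",
reported on the probability scale through average marginal effects (AMEs).
For a binary or categorical covariate the AME is the mean, over the observed
covariate distribution of the estimation rows, of the difference in fitted
membership probability between the level of interest and the reference
level; for a numeric covariate it is the mean of β·p̂(1−p̂).  Standard
errors come from the delta method, propagating the full coefficient
covariance through the analytic gradient of the AME.

Fits are flagged, never raised: a single-class outcome, non-convergence or
(quasi-)complete separation yield a ``LogisticFit`` with ``converged=False``
so that the bootstrap engine can record a missing replicate and continue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

logger = logging.getLogger(__name__)

__all__ = [
    "CovariateTerm",
    "RegressionSpec",
    "DesignMatrix",
    "LogisticFit",
    "AMEResult",
    "build_design",
    "fit_logistic",
    "average_marginal_effect",
    "ame_table",
]

MAX_ITER = 100
COEF_TOL = 1e-8
SEPARATION_EPS = 1e-10


@dataclass(frozen=True)
class CovariateTerm:
    """One model term: name, declared type, and reference level if categorical.

    ``kind`` is "binary", "categorical" or "numeric".  Binary terms are
    categorical terms with exactly two levels; if no reference is declared
    the lowest-sorted observed level is used.
    """

    name: str
    kind: str
    reference: object = None

    def __post_init__(self):
        if self.kind not in ("binary", "categorical", "numeric"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")


@dataclass
class RegressionSpec:
    """Which cluster is modelled against the rest, and with which terms."""

    target_cluster: int
    covariates: list

    def __post_init__(self):
        names = [t.name for t in self.covariates]
        if len(set(names)) != len(names):
            raise ValueError("duplicate covariate names")

    def validate_against(self, table: pd.DataFrame) -> None:
        for t in self.covariates:
            if t.name not in table.columns:
                raise ValueError(f"covariate {t.name!r} not in the table")


@dataclass
class DesignMatrix:
    """Intercept-first design matrix with level bookkeeping for AMEs.

    ``row_ok`` marks complete cases; rows with any missing covariate are
    excluded from estimation (and counted) but kept here so that bootstrap
    slicing by position stays trivial.
    """

    X: np.ndarray
    columns: list
    terms: list
    row_ok: np.ndarray
    term_columns: dict = field(default_factory=dict)
    term_levels: dict = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return int((~self.row_ok).sum())


def build_design(table: pd.DataFrame, terms) -> DesignMatrix:
    """Build an intercept + dummy/numeric design from declared terms.

    Categorical levels are taken from the *full* table so that the design is
    identical across bootstrap resamples even when a level is absent from a
    particular resample (its column is then constant zero and dropped at fit
    time).
    """
    terms = list(terms)
    n = len(table)
    cols = [np.ones(n)]
    names = ["intercept"]
    row_ok = np.ones(n, dtype=bool)
    term_columns: dict = {}
    term_levels: dict = {}
    for t in terms:
        series = table[t.name]
        missing = series.isna().to_numpy()
        row_ok &= ~missing
        if t.kind == "numeric":
            term_columns[t.name] = [len(names)]
            names.append(t.name)
            cols.append(series.to_numpy(dtype=float))
        else:
            levels = sorted(series.dropna().unique().tolist())
            if t.kind == "binary" and len(levels) > 2:
                raise ValueError(f"binary covariate {t.name!r} has levels {levels}")
            ref = t.reference if t.reference is not None else levels[0]
            if t.reference is not None and ref not in levels:
                raise ValueError(
                    f"reference level {ref!r} of {t.name!r} not observed")
            others = [lv for lv in levels if lv != ref]
            term_levels[t.name] = {"reference": ref, "levels": others}
            term_columns[t.name] = []
            for lv in others:
                term_columns[t.name].append(len(names))
                names.append(f"{t.name}[{lv}]")
                cols.append((series == lv).to_numpy(dtype=float))
    X = np.column_stack(cols)
    X[~row_ok] = np.nan
    return DesignMatrix(X=X, columns=names, terms=terms, row_ok=row_ok,
                        term_columns=term_columns, term_levels=term_levels)


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with failure flags instead of raises."""

    params: np.ndarray | None
    cov: np.ndarray | None
    columns: list
    n_used: int
    n_dropped: int
    converged: bool
    separation: bool = False
    failure: str | None = None
    kept: np.ndarray | None = None  # indices of design columns kept in the fit

    @property
    def ok(self) -> bool:
        return self.converged and not self.separation


def fit_logistic(y, X: np.ndarray, columns=None,
                 n_dropped: int = 0) -> LogisticFit:
    """Newton (IRLS) maximum-likelihood logistic regression.

    Convergence requires the maximum absolute coefficient change to fall
    below 1e-8 within 100 iterations.  Constant (zero-variance) non-intercept
    columns are dropped before fitting and recorded via ``kept``.  Complete
    separation is flagged when the fit fails to converge with fitted
    probabilities pinned at 0 or 1.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    columns = list(columns) if columns is not None else [
        f"x{i}" for i in range(X.shape[1])]
    n = len(y)
    if y.min(initial=1) == y.max(initial=0) or n == 0:
        return LogisticFit(None, None, columns, n, n_dropped,
                           converged=False, failure="single_class")
    # drop non-intercept columns without variation (e.g. unobserved levels)
    keep = [0] + [j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0]
    Xk = X[:, keep]
    beta = np.zeros(Xk.shape[1])
    converged = False
    p = np.full(n, y.mean())
    for _ in range(MAX_ITER):
        eta = np.clip(Xk @ beta, -35, 35)
        p = expit(eta)
        w = np.clip(p * (1 - p), 1e-12, None)
        z = eta + (y - p) / w
        Xw = Xk * w[:, None]
        try:
            beta_new = np.linalg.solve(Xk.T @ Xw, Xk.T @ (w * z))
        except np.linalg.LinAlgError:
            return LogisticFit(None, None, columns, n, n_dropped,
                               converged=False, failure="singular")
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < COEF_TOL:
            converged = True
            break
    separation = False
    if not converged:
        frac_extreme = np.mean((p < SEPARATION_EPS) | (p > 1 - SEPARATION_EPS))
        if frac_extreme > 0:
            separation = True
    if not converged:
        return LogisticFit(None, None, columns, n, n_dropped, converged=False,
                           separation=separation,
                           failure="separation" if separation else "no_convergence",
                           kept=np.array(keep))
    eta = np.clip(Xk @ beta, -35, 35)
    p = expit(eta)
    w = np.clip(p * (1 - p), 1e-12, None)
    info = Xk.T @ (Xk * w[:, None])
    try:
        cov_k = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov_k = np.linalg.pinv(info)
    # expand back to the full design layout (dropped columns get 0 / 0 cov)
    params = np.zeros(X.shape[1])
    cov = np.zeros((X.shape[1], X.shape[1]))
    keep = np.array(keep)
    params[keep] = beta
    cov[np.ix_(keep, keep)] = cov_k
    return LogisticFit(params=params, cov=cov, columns=columns, n_used=n,
                       n_dropped=n_dropped, converged=True, kept=keep)


def fit_cluster_model(design: DesignMatrix, outcome) -> LogisticFit:
    """Complete-case cluster-vs-rest fit on a (possibly resampled) design."""
    ok = design.row_ok
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.debug("dropping %d incomplete rows", n_dropped)
    return fit_logistic(np.asarray(outcome)[ok], design.X[ok],
                        columns=design.columns, n_dropped=n_dropped)


@dataclass
class AMEResult:
    """Average marginal effect of one covariate (level) with its SE."""

    covariate: str
    level: object
    estimate: float
    se: float

    def __post_init__(self):
        if abs(self.estimate) > 1 + 1e-12:
            raise ValueError("an AME is a probability change, |estimate| <= 1")


def _counterfactual_pair(design: DesignMatrix, rows: np.ndarray,
                         covariate: str, level):
    """Design copies with ``covariate`` set to ``level`` resp. the reference."""
    info = design.term_levels[covariate]
    if level is None:
        if len(info["levels"]) != 1:
            raise ValueError(
                f"{covariate!r} has levels {info['levels']}; specify one")
        level = info["levels"][0]
    if level not in info["levels"]:
        raise ValueError(f"{level!r} is not a non-reference level of {covariate!r}")
    X1 = design.X[rows].copy()
    X0 = design.X[rows].copy()
    for pos, lv in zip(design.term_columns[covariate], info["levels"]):
        X1[:, pos] = 1.0 if lv == level else 0.0
        X0[:, pos] = 0.0
    return X1, X0, level


def average_marginal_effect(fit: LogisticFit, design: DesignMatrix,
                            covariate: str, level=None) -> AMEResult:
    """AME of one covariate with a delta-method standard error.

    Averaging is over all estimation rows (the observed covariate
    distribution, with multiplicity when rows are a bootstrap resample).
    """
    if not fit.ok:
        raise ValueError("AME requires a converged, non-separated fit")
    rows = np.flatnonzero(design.row_ok)
    beta, V = fit.params, fit.cov
    term = next((t for t in design.terms if t.name == covariate), None)
    if term is None:
        raise ValueError(f"{covariate!r} is not a model term")
    if term.kind == "numeric":
        j = design.term_columns[covariate][0]
        X = design.X[rows]
        p = expit(np.clip(X @ beta, -35, 35))
        w = p * (1 - p)
        est = float(beta[j] * w.mean())
        # d/db_k = mean( b_j * w * (1-2p) * x_k ) + 1{k=j} mean(w)
        grad = (beta[j] * (w * (1 - 2 * p))[:, None] * X).mean(axis=0)
        grad[j] += w.mean()
        lv = None
    else:
        X1, X0, lv = _counterfactual_pair(design, rows, covariate, level)
        p1 = expit(np.clip(X1 @ beta, -35, 35))
        p0 = expit(np.clip(X0 @ beta, -35, 35))
        est = float((p1 - p0).mean())
        grad = ((p1 * (1 - p1))[:, None] * X1
                - (p0 * (1 - p0))[:, None] * X0).mean(axis=0)
    se = float(np.sqrt(max(grad @ V @ grad, 0.0)))
    return AMEResult(covariate=covariate, level=lv, estimate=est, se=se)


def ame_table(fit: LogisticFit, design: DesignMatrix) -> pd.DataFrame:
    """AMEs for every model term (one row per non-reference level)."""
    rows = []
    for t in design.terms:
        if t.kind == "numeric":
            r = average_marginal_effect(fit, design, t.name)
            rows.append({"covariate": t.name, "level": "",
                         "estimate": r.estimate, "se": r.se})
        else:
            for lv in design.term_levels[t.name]["levels"]:
                r = average_marginal_effect(fit, design, t.name, lv)
                rows.append({"covariate": t.name, "level": lv,
                             "estimate": r.estimate, "se": r.se})
    return pd.DataFrame(rows)
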