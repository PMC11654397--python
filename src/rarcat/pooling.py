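"""Meta-analytic pooling of the bootstrap AME matrix.

The per-individual, per-replicate effect estimates Y_ij (restricted to the
individuals of the reference cluster in the original typology) are pooled
with a cross-classified weighted mixed model,

    Y_ij = a00 + u_i + v_j + e_ij,
    u_i ~ N(0, s_u**2),  v_j ~ N(0, s_v**2),  e_ij ~ N(0, s_e**2 * SE_ij**2),

i.e. a meta-analysis with inverse-variance weights in which each effect size
belongs to two crossed dependency structures: the individual and the
bootstrap replicate.  Estimation is restricted maximum likelihood over the
variance components with the intercept profiled out by generalised least
squares; the bootstrap variance s_v**2 drives the prediction interval for
the effect expected in a new sample, and the individual BLUPs u_i flag
central versus outlier trajectories within the cluster.

The observed table is unbalanced (an individual absent from a replicate is
simply an absent row); the implementation works on the sparse mixed-model
equations, so the cost scales with m + N rather than with the number of
cells, and variance components are optimised on the log scale to avoid
boundary pathologies at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.stats import t as t_dist

logger = logging.getLogger(__name__)

__all__ = [
    "PoolingInput",
    "MultilevelFit",
    "TransformedFit",
    "PredictionInterval",
    "pooling_input",
    "fit_crossed_reml",
    "prediction_interval",
    "classify_trajectories",
    "pool_fixed_effects_alt",
    "pool_atanh_alt",
]

_LOG_GAMMA_BOUNDS = (-30.0, 15.0)


@dataclass
class PoolingInput:
    """Long records (id, replicate, y, se) for one reference cluster."""

    data: pd.DataFrame
    ids: list = field(init=False)
    replicates: list = field(init=False)

    def __post_init__(self):
        need = {"id", "replicate", "y", "se"}
        if not need.issubset(self.data.columns):
            raise ValueError(f"pooling input needs columns {sorted(need)}")
        if (self.data["se"] <= 0).any():
            raise ValueError("every SE must be strictly positive")
        if self.data["y"].isna().any():
            raise ValueError("missing cells must be absent rows, not NaN")
        self.data = self.data.reset_index(drop=True)
        self.ids = sorted(self.data["id"].unique().tolist())
        self.replicates = sorted(self.data["replicate"].unique().tolist())
        if len(self.replicates) < 2:
            raise ValueError("need at least two replicates")

    @property
    def m(self) -> int:
        return len(self.ids)

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


def pooling_input(result, partition, cluster: int) -> PoolingInput:
    """Extract the reference-cluster long table from a RARCAT result.

    ``partition`` is the ORIGINAL typology; rows are restricted to the
    individuals assigned to ``cluster`` there, whatever cluster they landed
    in inside each bootstrap.
    """
    members = partition.cluster_members(cluster)
    if len(members) < 2:
        raise ValueError("reference cluster must contain at least 2 individuals")
    ids = [result.ame.index[p] for p in members]
    long = result.to_long()
    long = long[long["id"].isin(ids)].rename(columns={"ame": "y"})
    return PoolingInput(data=long[["id", "replicate", "y", "se"]])


@dataclass
class MultilevelFit:
    """Estimates from the cross-classified weighted REML fit."""

    a00: float
    se_a00: float
    s_u: float
    s_v: float
    s_e: float
    blup_u: pd.Series
    blup_v: pd.Series
    converged: bool
    loglik: float
    n_obs: int
    m: int
    n_replicates: int
    method: str = "random"
    extras: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def report(self) -> dict:
        return {
            "pooled_ame": round(self.a00, 3),
            "se": round(self.se_a00, 4),
            "individual_sd": round(self.s_u, 4),
            "bootstrap_sd": round(self.s_v, 4),
            "residual_scale": round(self.s_e, 4),
            "n_obs": self.n_obs,
            "m": self.m,
            "n_replicates": self.n_replicates,
            "converged": self.converged,
            "method": self.method,
        }


class _WeightedREML:
    """Profiled restricted likelihood of the weighted crossed model.

    Works on the mixed-model-equation Gram matrices; each evaluation costs a
    dense Cholesky of the (m + N) system plus p×p solves.  ``X`` may be
    sparse (used by the individual-fixed-effects specification).
    """

    def __init__(self, y, w, X, blocks, residual="estimate"):
        # blocks: list of (name, index_array, size)
        self.y = np.asarray(y, float)
        self.w = np.asarray(w, float)
        self.n = len(self.y)
        self.residual = residual
        self.blocks = blocks
        dinv = 1.0 / self.w
        self.sum_log_w = float(np.log(self.w).sum())
        X = sp.csr_matrix(X) if not sp.issparse(X) else X.tocsr()
        self.X = X
        self.p = X.shape[1]
        Dx = sp.diags(dinv)
        self.XtDX = (X.T @ Dx @ X).toarray()
        self.XtDy = np.asarray(X.T @ (dinv * self.y)).ravel()
        self.ytDy = float(self.y @ (dinv * self.y))
        self.q = sum(b[2] for b in blocks)
        if self.q:
            rows = np.arange(self.n)
            zc, off = [], 0
            for _, idx, size in blocks:
                zc.append(sp.coo_matrix(
                    (np.ones(self.n), (rows, idx + off)),
                    shape=(self.n, self.q)))
                off += size
            # each Z block is n×q with one 1 per row in its own column range
            Z = sum(zc).tocsr()
            self.Z = Z
            self.A0 = (Z.T @ Dx @ Z).toarray()
            self.ZtDX = np.asarray((Z.T @ Dx @ X).todense())
            self.ZtDy = np.asarray(Z.T @ (dinv * self.y)).ravel()

    def _gamma_vector(self, gammas):
        out = np.empty(self.q)
        off = 0
        for (name, _, size), g in zip(self.blocks, gammas):
            out[off:off + size] = g
            off += size
        return out

    def solve(self, gammas):
        """GLS pieces at variance ratios ``gammas`` (one per block)."""
        if self.q:
            gvec = self._gamma_vector(gammas)
            C = self.A0 + np.diag(1.0 / gvec)
            cho = cho_factor(C, lower=True)
            logdetC = 2.0 * np.log(np.diag(cho[0])).sum()
            CiU = cho_solve(cho, self.ZtDX)
            CiZy = cho_solve(cho, self.ZtDy)
            XtWX = self.XtDX - self.ZtDX.T @ CiU
            XtWy = self.XtDy - self.ZtDX.T @ CiZy
            ytWy = self.ytDy - self.ZtDy @ CiZy
            logdetW = logdetC + float(np.log(gvec).sum()) + self.sum_log_w
        else:
            cho = None
            XtWX, XtWy, ytWy = self.XtDX, self.XtDy, self.ytDy
            logdetW = self.sum_log_w
        cho_x = cho_factor(XtWX, lower=True)
        beta = cho_solve(cho_x, XtWy)
        logdetX = 2.0 * np.log(np.diag(cho_x[0])).sum()
        qform = max(ytWy - XtWy @ beta, 0.0)
        return {"beta": beta, "qform": qform, "logdetW": logdetW,
                "logdetX": logdetX, "XtWX": XtWX, "cho_x": cho_x, "cho": cho}

    def neg2_reml(self, log_gammas):
        log_gammas = np.clip(log_gammas, *_LOG_GAMMA_BOUNDS)
        try:
            sol = self.solve(np.exp(log_gammas))
        except np.linalg.LinAlgError:
            return np.inf
        npp = self.n - self.p
        c = npp * np.log(2 * np.pi)
        if self.residual == "estimate":
            s2 = max(sol["qform"] / npp, 1e-300)
            return c + npp * (1.0 + np.log(s2)) + sol["logdetW"] + sol["logdetX"]
        return c + sol["logdetW"] + sol["logdetX"] + sol["qform"]

    def blups(self, gammas, beta):
        if not self.q:
            return np.array([])
        gvec = self._gamma_vector(gammas)
        C = self.A0 + np.diag(1.0 / gvec)
        rhs = self.ZtDy - self.ZtDX @ beta
        return cho_solve(cho_factor(C, lower=True), rhs)


def _optimize(model: _WeightedREML, n_blocks: int):
    """Multi-start quasi-Newton on log variance ratios, Nelder-Mead polish."""
    vy = float(np.var(model.y)) if model.n > 1 else 1.0
    mw = float(np.mean(model.w))
    s0 = np.log(max(vy / mw, 1e-6))
    base = np.full(n_blocks, s0)
    starts = [base]
    for b in range(n_blocks):
        s = base.copy()
        s[b] -= 4.0
        starts.append(s)
    starts.append(base - 4.0)
    starts.append(np.zeros(n_blocks))
    best = None
    for x0 in starts:
        x0 = np.clip(x0, *_LOG_GAMMA_BOUNDS)
        res = minimize(model.neg2_reml, x0, method="L-BFGS-B",
                       bounds=[_LOG_GAMMA_BOUNDS] * n_blocks,
                       options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    polish = minimize(model.neg2_reml, best.x, method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12,
                               "maxiter": 2000})
    if polish.fun <= best.fun:
        best = polish
    x = np.clip(best.x, *_LOG_GAMMA_BOUNDS)
    return x, float(model.neg2_reml(x)), bool(np.isfinite(best.fun))


def fit_crossed_reml(data: PoolingInput, include_u: bool | str = "auto",
                     include_v: bool = True,
                     residual: str = "estimate") -> MultilevelFit:
    """Fit the cross-classified weighted random-effects model by REML.

    ``residual="estimate"`` (default) treats the residual variance as
    proportional to SE_ij² with a freely estimated scale s_e²;
    ``residual="fixed"`` pins s_e² to 1 (strict inverse-variance weights).
    With a single individual (``include_u`` resolves to False) the model
    reduces to a weighted random-effects meta-analysis over replicates.
    """
    df = data.data
    y = df["y"].to_numpy(float)
    w = df["se"].to_numpy(float) ** 2
    i_idx = pd.Categorical(df["id"], categories=data.ids).codes.astype(np.intp)
    j_idx = pd.Categorical(df["replicate"],
                           categories=data.replicates).codes.astype(np.intp)
    m, N = data.m, data.n_replicates
    if include_u == "auto":
        include_u = m >= 2
    notes = []

    # degenerate: no dispersion at all
    if np.ptp(y) == 0:
        notes.append("all effect sizes identical; variance components are 0")
        return MultilevelFit(
            a00=float(y[0]), se_a00=0.0, s_u=0.0, s_v=0.0, s_e=0.0,
            blup_u=pd.Series(0.0, index=data.ids),
            blup_v=pd.Series(0.0, index=data.replicates),
            converged=True, loglik=np.inf, n_obs=len(y), m=m,
            n_replicates=N, notes=notes)

    blocks = []
    if include_u:
        blocks.append(("u", i_idx, m))
    if include_v:
        blocks.append(("v", j_idx, N))
    X = np.ones((len(y), 1))
    model = _WeightedREML(y, w, X, blocks, residual=residual)

    if blocks:
        log_g, crit, ok = _optimize(model, len(blocks))
        if residual == "estimate" and log_g.max() >= _LOG_GAMMA_BOUNDS[1] - 0.5:
            # The scaled-residual likelihood is unbounded when effect sizes
            # are exactly duplicated within replicates (s_e^2 -> 0 with a
            # variance ratio escaping to infinity).  The identified limit is
            # the strict inverse-variance model, so refit with s_e^2 = 1.
            notes.append("residual scale collapsed to 0; refitted with "
                         "strict inverse-variance weights (s_e^2 = 1)")
            residual = "fixed"
            model = _WeightedREML(y, w, X, blocks, residual=residual)
            log_g, crit, ok = _optimize(model, len(blocks))
        gammas = np.exp(log_g)
    else:
        gammas = np.array([])
        crit, ok = model.neg2_reml(gammas), True
    sol = model.solve(gammas)
    npp = model.n - model.p
    s2 = sol["qform"] / npp if residual == "estimate" else 1.0
    beta = sol["beta"]
    var_beta = s2 * cho_solve(sol["cho_x"], np.eye(1))[0, 0]
    b = model.blups(gammas, beta)
    off = 0
    blup = {}
    sds = {}
    for (name, _, size), g in zip(blocks, gammas):
        blup[name] = b[off:off + size]
        sds[name] = float(np.sqrt(s2 * g))
        off += size
    fit = MultilevelFit(
        a00=float(beta[0]), se_a00=float(np.sqrt(max(var_beta, 0.0))),
        s_u=sds.get("u", 0.0), s_v=sds.get("v", 0.0),
        s_e=float(np.sqrt(s2)),
        blup_u=pd.Series(blup.get("u", np.zeros(m)), index=data.ids),
        blup_v=pd.Series(blup.get("v", np.zeros(N)), index=data.replicates),
        converged=ok, loglik=-0.5 * crit, n_obs=model.n, m=m,
        n_replicates=N, notes=notes)
    if not include_u:
        fit.notes.append("individual random effect omitted")
    return fit


@dataclass
class PredictionInterval:
    """Interval for the pooled effect expected in a new sample."""

    lower: float
    upper: float
    level: float
    df: int

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError("lower endpoint exceeds upper endpoint")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def prediction_interval(fit, n_boot: int, beta: float = 0.05) -> PredictionInterval:
    """a00 ∓ t_{N−2, 1−β/2} · sqrt(s_v² + se(a00)²).

    ``n_boot`` is the nominal number of bootstrap replicates N; the t
    quantile uses N−2 degrees of freedom.  For an atanh-transformed fit the
    endpoints are computed on the transformed scale and mapped back.
    """
    if n_boot < 3:
        raise ValueError("prediction interval requires n_boot >= 3")
    if isinstance(fit, TransformedFit):
        inner = prediction_interval(fit.inner, n_boot, beta)
        return PredictionInterval(lower=float(np.tanh(inner.lower)),
                                  upper=float(np.tanh(inner.upper)),
                                  level=1 - beta, df=n_boot - 2)
    tq = float(t_dist.ppf(1 - beta / 2, n_boot - 2))
    half = tq * float(np.sqrt(fit.s_v ** 2 + fit.se_a00 ** 2))
    return PredictionInterval(lower=fit.a00 - half, upper=fit.a00 + half,
                              level=1 - beta, df=n_boot - 2)


def classify_trajectories(fit: MultilevelFit,
                          central_band: float = 0.5) -> pd.DataFrame:
    """Label each individual central / typical / outlier from its BLUP.

    Outlier: |u_i| > s_u (more than one individual-SD from the cluster
    mean); central: |u_i| ≤ central_band·s_u; typical otherwise.  The signed
    side (below/above) is reported so that the two tails can be told apart.
    """
    u = fit.blup_u
    if fit.s_u == 0:
        out = pd.DataFrame({"id": u.index, "blup_u": u.to_numpy(),
                            "category": "central", "side": ""})
        out.attrs["note"] = "s_u = 0: no individual heterogeneity detected"
        return out
    absu = u.abs().to_numpy()
    category = np.where(absu > fit.s_u, "outlier",
                        np.where(absu <= central_band * fit.s_u,
                                 "central", "typical"))
    side = np.where(u.to_numpy() < 0, "below", "above")
    return pd.DataFrame({"id": u.index, "blup_u": u.to_numpy(),
                         "category": category, "side": side})


def pool_fixed_effects_alt(data: PoolingInput,
                           residual: str = "estimate") -> MultilevelFit:
    """Alternative specification: individual deviations as fixed effects.

    Individuals enter as sum-to-zero contrasts, so the overall intercept is
    the mean of the individual intercepts; the bootstrap effect stays random
    and the SE² residual weighting is kept.
    """
    df = data.data
    if data.m < 2:
        raise ValueError("fixed-effects specification needs m >= 2")
    y = df["y"].to_numpy(float)
    w = df["se"].to_numpy(float) ** 2
    i_idx = pd.Categorical(df["id"], categories=data.ids).codes.astype(np.intp)
    j_idx = pd.Categorical(df["replicate"],
                           categories=data.replicates).codes.astype(np.intp)
    m, N = data.m, data.n_replicates
    n = len(y)
    # X = [1 | sum-to-zero individual contrasts]
    rows, cols, vals = [np.arange(n)], [np.zeros(n, dtype=np.intp)], [np.ones(n)]
    not_last = i_idx < m - 1
    rows.append(np.flatnonzero(not_last))
    cols.append(i_idx[not_last] + 1)
    vals.append(np.ones(not_last.sum()))
    last_rows = np.flatnonzero(~not_last)
    for c in range(1, m):
        rows.append(last_rows)
        cols.append(np.full(len(last_rows), c, dtype=np.intp))
        vals.append(np.full(len(last_rows), -1.0))
    X = sp.coo_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n, m)).tocsr()
    if np.ptp(y) == 0:
        return MultilevelFit(
            a00=float(y[0]), se_a00=0.0, s_u=0.0, s_v=0.0, s_e=0.0,
            blup_u=pd.Series(0.0, index=data.ids),
            blup_v=pd.Series(0.0, index=data.replicates),
            converged=True, loglik=np.inf, n_obs=n, m=m, n_replicates=N,
            method="fixed_individuals",
            extras={"individual_effects": pd.Series(0.0, index=data.ids)})

    blocks = [("v", j_idx, N)]
    notes = ["blup_u holds the estimated individual fixed effects"]
    model = _WeightedREML(y, w, X, blocks, residual=residual)
    log_g, crit, ok = _optimize(model, 1)
    if residual == "estimate" and log_g.max() >= _LOG_GAMMA_BOUNDS[1] - 0.5:
        notes.append("residual scale collapsed to 0; refitted with strict "
                     "inverse-variance weights (s_e^2 = 1)")
        residual = "fixed"
        model = _WeightedREML(y, w, X, blocks, residual=residual)
        log_g, crit, ok = _optimize(model, 1)
    gammas = np.exp(log_g)
    sol = model.solve(gammas)
    s2 = sol["qform"] / (model.n - model.p) if residual == "estimate" else 1.0
    beta = sol["beta"]
    cov0 = s2 * cho_solve(sol["cho_x"], np.eye(m))[0, 0]
    effects = np.empty(m)
    effects[:m - 1] = beta[1:]
    effects[m - 1] = -beta[1:].sum()
    blup_v = model.blups(gammas, beta)
    return MultilevelFit(
        a00=float(beta[0]), se_a00=float(np.sqrt(max(cov0, 0.0))),
        s_u=0.0, s_v=float(np.sqrt(s2 * gammas[0])),
        s_e=float(np.sqrt(s2)),
        blup_u=pd.Series(effects, index=data.ids),
        blup_v=pd.Series(blup_v, index=data.replicates),
        converged=ok, loglik=-0.5 * crit, n_obs=n, m=m, n_replicates=N,
        method="fixed_individuals",
        extras={"individual_effects": pd.Series(effects, index=data.ids)},
        notes=notes)


@dataclass
class TransformedFit:
    """Back-transformed wrapper around a fit on atanh-transformed effects."""

    inner: MultilevelFit
    a00: float
    se_a00: float

    @property
    def s_u(self) -> float:  # transformed scale
        return self.inner.s_u

    @property
    def s_v(self) -> float:  # transformed scale
        return self.inner.s_v

    @property
    def converged(self) -> bool:
        return self.inner.converged


def pool_atanh_alt(data: PoolingInput, clip: float = 1e-8,
                   **kwargs) -> TransformedFit:
    """Alternative specification: pool atanh-transformed effects.

    Y' = atanh(Y) (values at ±1 clipped inward by ``clip`` with a warning),
    SE' = SE/(1−Y²) by the delta method; the main model is fitted on
    (Y', SE') and the pooled estimate mapped back with tanh, its SE with the
    inverse delta factor.  Prediction-interval endpoints are the tanh of the
    transformed-scale endpoints (tanh is increasing, so ordering is kept).
    """
    df = data.data.copy()
    y = df["y"].to_numpy(float)
    if (np.abs(y) >= 1 + 1e-12).any():
        raise ValueError("|Y| >= 1 cannot be atanh-transformed")
    if (np.abs(y) >= 1 - clip).any():
        logger.warning("clipping %d effect sizes at ±(1-%g)",
                       int((np.abs(y) >= 1 - clip).sum()), clip)
        y = np.clip(y, -(1 - clip), 1 - clip)
    se = df["se"].to_numpy(float) / (1 - y ** 2)
    df["y"] = np.arctanh(y)
    df["se"] = se
    inner = fit_crossed_reml(PoolingInput(data=df), **kwargs)
    inner.method = "atanh"
    a = float(np.tanh(inner.a00))
    return TransformedFit(inner=inner, a00=a,
                          se_a00=float((1 - a ** 2) * inner.se_a00))
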