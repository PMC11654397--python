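"""Crossed weighted REML against grid-search and lme4 oracles; PI; diagnostics."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.special import stdtr

from rarcat import (MultilevelFit, PoolingInput, classify_trajectories,
                    fit_crossed_reml, pool_atanh_alt, pool_fixed_effects_alt,
                    prediction_interval)


def make_long(y, se, ids, reps):
    return PoolingInput(data=pd.DataFrame(
        {"id": ids, "replicate": reps, "y": y, "se": se}))


def balanced_table(rng, m, N, a=0.2, s_u=0.1, s_v=0.15, s_e=0.0, se_val=0.05):
    u = rng.normal(0, s_u, m)
    v = rng.normal(0, s_v, N)
    ids, reps, ys, ses = [], [], [], []
    for i in range(m):
        for j in range(N):
            e = rng.normal(0, s_e * se_val) if s_e else 0.0
            ids.append(f"i{i:03d}")
            reps.append(j + 1)
            ys.append(a + u[i] + v[j] + e)
            ses.append(se_val)
    return make_long(ys, ses, ids, reps), u, v


def dense_neg2_reml(y, se, i_idx, j_idx, m, N, s_u, s_v, s_e):
    """Restricted likelihood from the dense covariance matrix (oracle path)."""
    n = len(y)
    V = (s_e ** 2) * np.diag(se ** 2)
    if m:
        Zu = np.zeros((n, m))
        Zu[np.arange(n), i_idx] = 1
        V = V + (s_u ** 2) * (Zu @ Zu.T)
    Zv = np.zeros((n, N))
    Zv[np.arange(n), j_idx] = 1
    V = V + (s_v ** 2) * (Zv @ Zv.T)
    sign, logdetV = np.linalg.slogdet(V)
    if sign <= 0 or np.linalg.cond(V) > 1e10:
        return np.inf, np.nan
    Vi = np.linalg.inv(V)
    X = np.ones((n, 1))
    XtViX = (X.T @ Vi @ X).item()
    beta = (X.T @ Vi @ y).item() / XtViX
    r = y - beta
    crit = (logdetV + np.log(XtViX) + float(r @ Vi @ r)
            + (n - 1) * np.log(2 * np.pi))
    if not np.isfinite(crit):
        return np.inf, np.nan
    return crit, beta


def grid_search_reml(y, se, i_idx, j_idx, m, N, with_u=True, stages=8,
                     points=17):
    """Nested grid refinement of the dense restricted likelihood."""
    span = max(np.std(y) * 2, 0.2)
    dims = (3 if with_u else 2)
    lo = np.zeros(dims)
    hi = np.full(dims, span)
    hi[-1] = max(span / np.mean(se), 4.0)  # residual axis is a scale factor
    best = None
    for _ in range(stages):
        axes = [np.linspace(lo[d], hi[d], points) for d in range(dims)]
        for su in (axes[0] if with_u else [0.0]):
            for sv in axes[-2]:
                for sc in axes[-1]:
                    crit, beta = dense_neg2_reml(y, se, i_idx, j_idx,
                                                 m if with_u else 0, N,
                                                 su, sv, sc)
                    if best is None or crit < best[0]:
                        best = (crit, su, sv, sc, beta)
        centre = np.array(best[1:1 + dims]) if with_u else np.array(best[2:4])
        width = (hi - lo) / (points - 1) * 2
        lo = np.maximum(centre - width, 0.0)
        hi = centre + width
    return {"crit": best[0], "s_u": best[1] if with_u else 0.0,
            "s_v": best[2], "s_e": best[3], "a00": best[4]}


class TestFitCrossedReml:
    def test_constant_table_is_exactly_recovered(self):
        data, _, _ = balanced_table(np.random.default_rng(0), 4, 5,
                                    a=0.3, s_u=0.0, s_v=0.0)
        fit = fit_crossed_reml(data)
        assert fit.a00 == pytest.approx(0.3)
        assert fit.s_u == 0.0 and fit.s_v == 0.0

    def test_zero_variance_components_give_inverse_variance_weighted_mean(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0.2, 0.1, 30)
        se = rng.uniform(0.05, 0.3, 30)
        data = make_long(y, se, [f"i{k}" for k in range(15)] * 2,
                         np.repeat([1, 2], 15))
        fit = fit_crossed_reml(data, include_u=False, include_v=False)
        expected = np.sum(y / se ** 2) / np.sum(1 / se ** 2)
        assert fit.a00 == pytest.approx(expected, abs=1e-12)

    def test_single_individual_matches_grid_search_meta_analysis(self):
        # m = 1: the model reduces to a weighted random-effects meta-analysis
        # over replicates; compare with a 2-parameter dense-grid REML oracle
        # sigma_v and the residual scale are separated only through the
        # heterogeneous weights, so use many replicates with spread-out SEs
        rng = np.random.default_rng(2)
        N = 30
        v = rng.normal(0, 0.2, N)
        se = rng.uniform(0.05, 0.3, N)
        y = 0.25 + v + rng.normal(0, se)
        data = make_long(y, se, ["solo"] * N, np.arange(1, N + 1))
        fit = fit_crossed_reml(data)
        assert "individual random effect omitted" in fit.notes
        oracle = grid_search_reml(y, se, np.zeros(N, int), np.arange(N),
                                  1, N, with_u=False)
        assert fit.a00 == pytest.approx(oracle["a00"], abs=1e-4)
        assert fit.s_v == pytest.approx(oracle["s_v"], abs=1e-4)
        assert fit.s_e == pytest.approx(oracle["s_e"], abs=1e-4)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_small_instances_match_dense_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m, N = 3, 4
        se = rng.uniform(0.05, 0.12, m * N)
        i_idx = np.repeat(np.arange(m), N)
        j_idx = np.tile(np.arange(N), m)
        y = (0.2 + rng.normal(0, 0.15, m)[i_idx]
             + rng.normal(0, 0.2, N)[j_idx] + rng.normal(0, se))
        data = make_long(y, se, [f"i{k}" for k in i_idx], j_idx + 1)
        fit = fit_crossed_reml(data)
        oracle = grid_search_reml(y, se, i_idx, j_idx, m, N)
        assert fit.a00 == pytest.approx(oracle["a00"], abs=1e-4)
        assert fit.s_u == pytest.approx(oracle["s_u"], abs=1e-4)
        assert fit.s_v == pytest.approx(oracle["s_v"], abs=1e-4)
        assert fit.s_e == pytest.approx(oracle["s_e"], abs=1e-4)
        assert -2 * fit.loglik <= oracle["crit"] + 1e-6

    def test_parameter_recovery_on_balanced_table(self):
        rng = np.random.default_rng(5)
        data, u, v = balanced_table(rng, 50, 200, a=0.25, s_u=0.1, s_v=0.15)
        fit = fit_crossed_reml(data)
        assert fit.a00 == pytest.approx(0.25, abs=3 * 0.15 / np.sqrt(200))
        assert fit.s_u == pytest.approx(np.std(u, ddof=1), rel=0.15)
        assert fit.s_v == pytest.approx(np.std(v, ddof=1), rel=0.15)
        # BLUPs track the generating draws
        assert np.corrcoef(fit.blup_u, u)[0, 1] > 0.99

    def test_matches_lme4_on_unbalanced_weighted_fit(self, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.xfail("Rscript not on PATH")
        rng = np.random.default_rng(6)
        m, N = 8, 12
        rows = []
        for i in range(m):
            for j in range(N):
                if rng.random() < 0.3:
                    continue
                se = rng.uniform(0.05, 0.2)
                rows.append((f"i{i}", j + 1, se))
        df = pd.DataFrame(rows, columns=["id", "replicate", "se"])
        u = rng.normal(0, 0.12, m)
        v = rng.normal(0, 0.18, N)
        i_codes = df["id"].str.slice(1).astype(int)
        df["y"] = (0.3 + u[i_codes] + v[df["replicate"] - 1]
                   + rng.normal(0, df["se"]))
        csv = tmp_path / "long.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(f"""
suppressMessages(library(lme4))
d <- read.csv("{csv}")
fit <- lmer(y ~ 1 + (1|id) + (1|replicate), data=d, weights=1/se^2, REML=TRUE)
vc <- as.data.frame(VarCorr(fit))
cat(fixef(fit)[1], sqrt(diag(vcov(fit)))[1],
    vc$sdcor[vc$grp=="id"], vc$sdcor[vc$grp=="replicate"],
    sigma(fit), sep="\\n")
""")
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        a00_r, se_r, su_r, sv_r, sig_r = map(float, out.stdout.split())
        fit = fit_crossed_reml(PoolingInput(data=df))
        assert fit.a00 == pytest.approx(a00_r, abs=2e-4)
        assert fit.se_a00 == pytest.approx(se_r, rel=2e-3)
        assert fit.s_u == pytest.approx(su_r, abs=2e-3)
        assert fit.s_v == pytest.approx(sv_r, abs=2e-3)
        assert fit.s_e == pytest.approx(sig_r, abs=2e-3)

    def test_se_decreases_with_more_replicates(self):
        ses = []
        for N in (40, 160, 640):
            rng = np.random.default_rng(100 + N)
            data, _, _ = balanced_table(rng, 10, N, s_u=0.05, s_v=0.15)
            ses.append(fit_crossed_reml(data).se_a00)
        assert ses[0] > ses[1] > ses[2]


class TestPredictionInterval:
    def test_degenerate_interval_collapses_to_point(self):
        fit = MultilevelFit(a00=0.1, se_a00=0.0, s_u=0.0, s_v=0.0, s_e=1.0,
                            blup_u=pd.Series(dtype=float),
                            blup_v=pd.Series(dtype=float), converged=True,
                            loglik=0.0, n_obs=10, m=2, n_replicates=5)
        pi = prediction_interval(fit, n_boot=100)
        assert pi.lower == pi.upper == pytest.approx(0.1)

    def test_midpoint_and_halfwidth_against_independent_t_quantile(self):
        fit = MultilevelFit(a00=0.21, se_a00=0.011, s_u=0.0, s_v=0.08, s_e=1.0,
                            blup_u=pd.Series(dtype=float),
                            blup_v=pd.Series(dtype=float), converged=True,
                            loglik=0.0, n_obs=10, m=2, n_replicates=500)
        pi = prediction_interval(fit, n_boot=500, beta=0.05)
        # invert the t CDF by root finding, independently of stats.t.ppf
        tq = brentq(lambda q: stdtr(498, q) - 0.975, 0, 50)
        half = tq * np.sqrt(0.08 ** 2 + 0.011 ** 2)
        assert (pi.lower + pi.upper) / 2 == pytest.approx(0.21)
        assert (pi.upper - pi.lower) / 2 == pytest.approx(half, rel=1e-9)
        assert pi.contains(fit.a00)

    def test_width_monotone_in_sv_and_se(self):
        def width(sv, se):
            fit = MultilevelFit(a00=0.0, se_a00=se, s_u=0.0, s_v=sv, s_e=1.0,
                                blup_u=pd.Series(dtype=float),
                                blup_v=pd.Series(dtype=float), converged=True,
                                loglik=0.0, n_obs=10, m=2, n_replicates=100)
            pi = prediction_interval(fit, n_boot=100)
            return pi.upper - pi.lower
        assert width(0.05, 0.01) < width(0.10, 0.01) < width(0.10, 0.05)


class TestClassifyTrajectories:
    def _fit(self, blups, s_u):
        return MultilevelFit(a00=0.2, se_a00=0.01, s_u=s_u, s_v=0.1, s_e=1.0,
                             blup_u=pd.Series(blups,
                                              index=[f"i{k}" for k in
                                                     range(len(blups))]),
                             blup_v=pd.Series(dtype=float), converged=True,
                             loglik=0.0, n_obs=10, m=len(blups),
                             n_replicates=5)

    def test_all_zero_blups_are_central(self):
        out = classify_trajectories(self._fit([0.0, 0.0, 0.0], 0.1))
        assert (out["category"] == "central").all()

    def test_threshold_arithmetic(self):
        out = classify_trajectories(self._fit([0.0, 0.06, 0.3], 0.1))
        assert out["category"].tolist() == ["central", "typical", "outlier"]
        assert out.loc[2, "side"] == "above"

    def test_zero_variance_fit_notes_all_central(self):
        out = classify_trajectories(self._fit([0.0, 0.0], 0.0))
        assert (out["category"] == "central").all()
        assert "note" in out.attrs


class TestAlternativeSpecifications:
    def test_fixed_effects_constant_table(self):
        data, _, _ = balanced_table(np.random.default_rng(7), 4, 5,
                                    a=0.4, s_u=0.0, s_v=0.0)
        fit = pool_fixed_effects_alt(data)
        assert fit.a00 == pytest.approx(0.4)
        assert np.allclose(fit.extras["individual_effects"], 0.0)

    def test_fixed_effects_balanced_intercept_is_grand_mean(self):
        rng = np.random.default_rng(8)
        data, _, _ = balanced_table(rng, 6, 8, a=0.2, s_u=0.15, s_v=0.1,
                                    s_e=1.0)
        fit = pool_fixed_effects_alt(data)
        assert fit.a00 == pytest.approx(data.data["y"].mean(), abs=1e-8)
        assert fit.extras["individual_effects"].sum() == pytest.approx(0.0,
                                                                       abs=1e-8)

    def test_fixed_effects_close_to_random_effects_estimate(self):
        rng = np.random.default_rng(9)
        data, _, _ = balanced_table(rng, 50, 200, a=0.25, s_u=0.08, s_v=0.12,
                                    s_e=1.0)
        random_fit = fit_crossed_reml(data)
        fixed_fit = pool_fixed_effects_alt(data)
        assert abs(fixed_fit.a00 - random_fit.a00) < 0.05

    def test_atanh_zero_effects_pool_to_zero(self):
        rng = np.random.default_rng(10)
        data, _, _ = balanced_table(rng, 5, 10, a=0.0, s_u=0.0, s_v=0.02,
                                    s_e=1.0)
        fit = pool_atanh_alt(data)
        assert fit.a00 == pytest.approx(0.0, abs=0.02)

    def test_atanh_close_to_untransformed_for_small_effects(self):
        rng = np.random.default_rng(11)
        data, _, _ = balanced_table(rng, 20, 60, a=0.2, s_u=0.05, s_v=0.08,
                                    s_e=1.0)
        plain = fit_crossed_reml(data)
        trans = pool_atanh_alt(data)
        assert abs(trans.a00 - plain.a00) < 0.01

    def test_atanh_pi_preserves_ordering_and_bounds(self):
        rng = np.random.default_rng(12)
        data, _, _ = balanced_table(rng, 10, 30, a=0.3, s_u=0.05, s_v=0.1,
                                    s_e=1.0)
        fit = pool_atanh_alt(data)
        pi = prediction_interval(fit, n_boot=30)
        assert -1 < pi.lower < pi.upper < 1
        assert pi.lower < fit.a00 < pi.upper

    def test_out_of_range_effects_rejected(self):
        data = make_long([0.5, 1.2, 0.1, 0.3], [0.1] * 4,
                         ["a", "a", "b", "b"], [1, 2, 1, 2])
        with pytest.raises(ValueError, match="atanh"):
            pool_atanh_alt(data)
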