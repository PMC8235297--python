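"""Mixed-model ranking of sleep parameters against self-rated health.

For every sleep parameter a random-intercept linear mixed model

    EQVAS_ij = beta0 + beta1 * z(parameter)_ij + beta2 * age_i
               + beta3 * sex_i + u_i + eps_ij,
    u_i ~ N(0, sigma2_u),  eps_ij ~ N(0, sigma2_e)

is fit by (restricted) maximum likelihood, parameters are ranked by the
absolute slope t score, and Holm's step-down correction controls the
family-wise error over the 20 tests.  Two-sided p-values use Satterthwaite
degrees of freedom.

The estimator is written from first principles: the likelihood is profiled
over the variance ratio theta = sigma2_u / sigma2_e, for which beta and
sigma2_e have closed-form per-group GLS updates, and theta is found by
Brent-style bounded scalar minimization on the log scale.  Established
mixed-model implementations (statsmodels, lme4/lmerTest) appear only as
independent cross-checks in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

DEFAULT_ALPHA = 0.05


class RankingError(ValueError):
    pass


@dataclass
class LMMFit:
    beta: np.ndarray
    se: np.ndarray
    sigma2_u: float
    sigma2_e: float
    theta: float
    t_score: float
    df: float
    df_flag: str  # "satterthwaite" | "ols_limit" | "residual_fallback"
    p: float
    loglik: float
    method: str
    converged: bool
    n: int
    n_groups: int
    rank_x: int


# ---------------------------------------------------------------------------
# random-intercept LMM


class _GroupData:
    """Per-group sufficient statistics for the profiled likelihood."""

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        order = np.argsort(groups, kind="stable")
        self.y = y[order]
        self.X = X[order]
        g = groups[order]
        _, idx, counts = np.unique(g, return_index=True, return_counts=True)
        self.n_g = counts.astype(float)
        self.G = len(counts)
        self.n, self.p = X.shape
        # group-wise sums
        bounds = np.concatenate(([0], np.cumsum(counts)))
        self.Sx = np.add.reduceat(self.X, bounds[:-1], axis=0)  # G x p
        self.Sy = np.add.reduceat(self.y, bounds[:-1])  # G
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)

    def gls(self, theta: float) -> tuple[np.ndarray, np.ndarray, float]:
        """(X' W X, X' W y, y' W y) for W = (I + theta Z Z')^{-1}."""
        c = theta / (1.0 + theta * self.n_g)  # G
        XtWX = self.XtX - (self.Sx * c[:, None]).T @ self.Sx
        XtWy = self.Xty - self.Sx.T @ (c * self.Sy)
        ytWy = self.yty - float(c @ (self.Sy ** 2))
        return XtWX, XtWy, ytWy


def _neg2_profiled(theta: float, gd: _GroupData, reml: bool) -> tuple[float, np.ndarray, float]:
    """Profiled -2 log-(restricted-)likelihood at variance ratio theta."""
    XtWX, XtWy, ytWy = gd.gls(theta)
    beta = np.linalg.solve(XtWX, XtWy)
    rss = ytWy - float(beta @ XtWy)
    rss = max(rss, 1e-300)
    logdet_W_inv = float(np.sum(np.log1p(theta * gd.n_g)))
    if reml:
        dof = gd.n - gd.p
        sigma2 = rss / dof
        sign, logdet_XtWX = np.linalg.slogdet(XtWX)
        val = logdet_W_inv + logdet_XtWX + dof * (1.0 + np.log(2 * np.pi * sigma2))
    else:
        sigma2 = rss / gd.n
        val = logdet_W_inv + gd.n * (1.0 + np.log(2 * np.pi * sigma2))
    return val, beta, sigma2


def _neg2_full(sigma2_u: float, sigma2_e: float, gd: _GroupData, reml: bool) -> float:
    """-2 log-(restricted-)likelihood as a function of both variances."""
    theta = sigma2_u / sigma2_e
    XtWX, XtWy, ytWy = gd.gls(theta)
    beta = np.linalg.solve(XtWX, XtWy)
    rss = (ytWy - float(beta @ XtWy)) / sigma2_e
    logdet_V = gd.n * np.log(sigma2_e) + float(np.sum(np.log1p(theta * gd.n_g)))
    val = logdet_V + rss
    if reml:
        sign, logdet = np.linalg.slogdet(XtWX / sigma2_e)
        val += logdet + (gd.n - gd.p) * np.log(2 * np.pi)
    else:
        val += gd.n * np.log(2 * np.pi)
    return val


def fit_random_intercept_lmm(y: np.ndarray, X: np.ndarray, groups: np.ndarray,
                             method: str = "reml", slope_index: int = 1,
                             theta_bounds: tuple[float, float] = (1e-8, 1e6),
                             ) -> LMMFit:
    """Fit y = X beta + u_group + eps with a scalar random intercept.

    ``X`` must contain an explicit intercept column.  ``slope_index`` names
    the fixed-effect coefficient whose t score, Satterthwaite df and
    p-value are reported.  ``method`` is ``"reml"`` (default) or ``"ml"``.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    if X.ndim != 2 or len(y) != len(X) or len(groups) != len(y):
        raise RankingError("y, X and groups must have matching lengths")
    if np.unique(groups).size < 2:
        raise RankingError("need at least 2 groups")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankingError("fixed-effect design is singular")
    reml = method.lower() == "reml"
    if method.lower() not in ("reml", "ml"):
        raise RankingError(f"unknown method {method!r}")

    gd = _GroupData(y, X, groups)

    def obj(log_theta: float) -> float:
        return _neg2_profiled(np.exp(log_theta), gd, reml)[0]

    lo, hi = np.log(theta_bounds[0]), np.log(theta_bounds[1])
    res = optimize.minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-12, "maxiter": 500})
    theta = float(np.exp(res.x))
    val_opt = float(res.fun)
    # compare against the theta -> 0 (pure OLS) boundary
    val0, _, _ = _neg2_profiled(0.0, gd, reml)
    boundary = val0 <= val_opt + 1e-10 or theta <= theta_bounds[0] * np.e
    if boundary and val0 <= val_opt + 1e-8:
        theta = 0.0
        val_opt = val0

    val, beta, sigma2_e = _neg2_profiled(theta, gd, reml)
    sigma2_u = theta * sigma2_e
    XtWX, _, _ = gd.gls(theta)
    cov_beta = sigma2_e * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov_beta))
    t = float(beta[slope_index] / se[slope_index])

    fit = LMMFit(
        beta=beta, se=se, sigma2_u=float(sigma2_u), sigma2_e=float(sigma2_e),
        theta=float(theta), t_score=t, df=np.nan, df_flag="", p=np.nan,
        loglik=-0.5 * val, method=method.lower(), converged=bool(res.success or theta == 0.0),
        n=gd.n, n_groups=gd.G, rank_x=gd.p,
    )
    fit.df, fit.df_flag = satterthwaite_df(fit, gd=gd, slope_index=slope_index, reml=reml)
    fit.p = float(2.0 * stats.t.sf(abs(t), fit.df)) if np.isfinite(fit.df) else np.nan
    fit._gd = gd  # retained for df recomputation on other coefficients
    return fit


def _var_beta1(sigma2_u: float, sigma2_e: float, gd: _GroupData, slope_index: int) -> float:
    theta = sigma2_u / sigma2_e
    XtWX, _, _ = gd.gls(theta)
    return sigma2_e * float(np.linalg.inv(XtWX)[slope_index, slope_index])


def satterthwaite_df(fit: LMMFit, gd: Optional[_GroupData] = None,
                     slope_index: int = 1, reml: Optional[bool] = None) -> tuple[float, str]:
    """Satterthwaite effective degrees of freedom for the slope t-statistic.

    df = 2 [Var(b1)]^2 / Var[Var(b1)], where the denominator is the delta-
    method variance: the gradient of Var(b1) w.r.t. (sigma2_u, sigma2_e) by
    central finite differences, combined with the asymptotic covariance of
    the variance estimates, 2 * H^{-1} with H the finite-difference Hessian
    of the (restricted) deviance.  At the sigma2_u = 0 boundary the model
    collapses to OLS and df = n - rank(X) exactly; non-finite curvature
    falls back to the residual df n - rank(X) - G + 1.
    """
    if gd is None:
        gd = fit._gd
    if reml is None:
        reml = fit.method == "reml"
    n, p, G = gd.n, gd.p, gd.G
    if fit.sigma2_u <= 0.0 or fit.theta == 0.0:
        return float(n - p), "ols_limit"

    params = np.array([fit.sigma2_u, fit.sigma2_e])
    rel = 1e-5
    grad = np.empty(2)
    for k in range(2):
        h = rel * params[k]
        up, dn = params.copy(), params.copy()
        up[k] += h
        dn[k] -= h
        grad[k] = (_var_beta1(up[0], up[1], gd, slope_index)
                   - _var_beta1(dn[0], dn[1], gd, slope_index)) / (2 * h)

    def hessian(hrel: float) -> np.ndarray:
        H = np.empty((2, 2))
        f0 = _neg2_full(params[0], params[1], gd, reml)
        steps = hrel * params
        for k in range(2):
            for l in range(k, 2):
                if k == l:
                    up, dn = params.copy(), params.copy()
                    up[k] += steps[k]
                    dn[k] -= steps[k]
                    H[k, k] = (_neg2_full(up[0], up[1], gd, reml) - 2 * f0
                               + _neg2_full(dn[0], dn[1], gd, reml)) / steps[k] ** 2
                else:
                    pp, pm, mp, mm = (params.copy() for _ in range(4))
                    pp[[k, l]] += steps[[k, l]]
                    mm[[k, l]] -= steps[[k, l]]
                    pm[k] += steps[k]
                    pm[l] -= steps[l]
                    mp[k] -= steps[k]
                    mp[l] += steps[l]
                    H[k, l] = H[l, k] = (
                        _neg2_full(*pp, gd, reml) - _neg2_full(*pm, gd, reml)
                        - _neg2_full(*mp, gd, reml) + _neg2_full(*mm, gd, reml)
                    ) / (4 * steps[k] * steps[l])
        return H

    # Richardson extrapolation kills the O(h^2) truncation term; the base
    # steps stay large enough that roundoff in the deviance is negligible
    H = (4.0 * hessian(5e-3) - hessian(1e-2)) / 3.0

    try:
        cov = 2.0 * np.linalg.inv(H)
        denom = float(grad @ cov @ grad)
    except np.linalg.LinAlgError:
        denom = np.nan
    if not np.isfinite(denom) or denom <= 0:
        return float(max(n - p - G + 1, 1)), "residual_fallback"
    v = _var_beta1(params[0], params[1], gd, slope_index)
    df = 2.0 * v ** 2 / denom
    df = min(df, float(n - p))
    return float(df), "satterthwaite"


# ---------------------------------------------------------------------------
# multiple-testing correction


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm's step-down adjusted p-values, returned in input order.

    adj_(i) = max_{j <= i} min(1, (m - j + 1) * p_(j)) over the ascending
    ordering; NaNs (untested hypotheses) are passed through and do not
    count toward m.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv <= 0) | (pv > 1)).any():
        raise RankingError("p-values must lie in (0, 1]")
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for i, j in enumerate(order):
        running = max(running, min(1.0, (m - i) * pv[j]))
        adj[j] = running
    out[mask] = adj
    return out


# ---------------------------------------------------------------------------
# parameter ranking


def rank_parameters(matched: pd.DataFrame, parameters: Sequence[str],
                    method: str = "reml", alpha: float = DEFAULT_ALPHA,
                    covariates: Sequence[str] = ("age", "sex")) -> pd.DataFrame:
    """One random-intercept LMM per sleep parameter, ranked by |t|.

    ``matched`` must hold one row per matched (report, night) with columns
    ``participant_id``, ``eqvas``, the covariates and the (standardized)
    parameter columns.  Returns a table with estimate, t score, raw and
    Holm-adjusted p, significance at ``alpha`` and the rank; parameters
    whose column is entirely missing are dropped with a flag.
    """
    if matched["participant_id"].nunique() < 2:
        raise RankingError("need matched data from at least 2 participants")
    rows = []
    for param in parameters:
        col = matched[param] if param in matched else pd.Series(np.nan, index=matched.index)
        sub = matched[["participant_id", "eqvas", *covariates]].copy()
        sub["x"] = col.to_numpy(dtype=float)
        sub = sub.dropna(subset=["x", "eqvas"])
        # constant covariates (e.g. single-sex subcohorts) carry no information
        usable_covs = [c for c in covariates if sub[c].nunique() > 1]
        if len(sub) < len(usable_covs) + 3 or sub["x"].nunique() < 2:
            rows.append({"parameter": param, "estimate": np.nan, "t_score": np.nan,
                         "df": np.nan, "p": np.nan, "converged": False, "n": len(sub)})
            continue
        X = np.column_stack([np.ones(len(sub)), sub["x"].to_numpy(),
                             *(sub[c].to_numpy(dtype=float) for c in usable_covs)])
        fit = fit_random_intercept_lmm(sub["eqvas"].to_numpy(dtype=float), X,
                                       sub["participant_id"].to_numpy(), method=method)
        rows.append({"parameter": param, "estimate": float(fit.beta[1]),
                     "t_score": fit.t_score, "df": fit.df,
                     "p": fit.p if fit.converged else np.nan,
                     "converged": fit.converged, "n": fit.n})
    table = pd.DataFrame(rows)
    table["p_adjusted"] = holm_adjust(table["p"].to_numpy())
    table["significant"] = table["p_adjusted"] < alpha
    table = table.sort_values("t_score", key=lambda s: s.abs(), ascending=False,
                              na_position="last", kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


# ---------------------------------------------------------------------------
# correlations and bias checks


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (midrank ties, t-approximation p-value).

    Returns ``(nan, nan)`` for constant input or fewer than 3 pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return (np.nan, np.nan)
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def correlation_table(features: pd.DataFrame, anchor: str = "n_toss_turns",
                      parameters: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Spearman correlation of one anchor parameter with every other one."""
    from .features import FEATURE_NAMES

    parameters = list(parameters) if parameters is not None else [
        c for c in FEATURE_NAMES if c != anchor]
    rows = []
    for param in parameters:
        rho, p = spearman(features[anchor], features[param])
        rows.append({"parameter": param, "rho": rho, "p": p})
    return pd.DataFrame(rows).sort_values("rho", ascending=False).reset_index(drop=True)


def bias_checks(matched: pd.DataFrame, all_reports: pd.DataFrame,
                missingness: pd.DataFrame) -> dict:
    """Data-loss bias diagnostics.

    (a) Spearman correlation between each participant's missing-night
    fraction and mean EQ-VAS (among participants with matched data);
    (b) Welch two-sample t-test comparing mean EQ-VAS of participants with
    at least one matched point against those without any.

    ``missingness`` needs ``participant_id`` and ``fraction_missing``.
    """
    included = set(matched["participant_id"].unique()) if len(matched) else set()
    per_pid = all_reports.groupby("participant_id")["eqvas"].mean()

    merged = missingness.set_index("participant_id").join(per_pid, how="inner")
    merged = merged[merged.index.isin(included)]
    rho, rho_p = spearman(merged["fraction_missing"], merged["eqvas"])

    inc = per_pid[per_pid.index.isin(included)]
    exc = per_pid[~per_pid.index.isin(included)]
    if len(exc) >= 2 and len(inc) >= 2:
        t, t_p = stats.ttest_ind(inc, exc, equal_var=False)
        t_note = ""
    else:
        t, t_p = np.nan, np.nan
        t_note = "fewer than 2 excluded participants; t test skipped"
    return {
        "missingness_rho": rho,
        "missingness_rho_p": rho_p,
        "n_participants": int(len(merged)),
        "welch_t": float(t) if np.isfinite(t) else np.nan,
        "welch_p": float(t_p) if np.isfinite(t_p) else np.nan,
        "n_included": int(len(inc)),
        "n_excluded": int(len(exc)),
        "note": t_note,
    }
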