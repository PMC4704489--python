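"""Weighted gamma mixed model with log link for variance responses.

The unit of analysis is the across-cell sample variance of the
arcsine-transformed inclusion level of one cassette exon in one condition —
a strictly positive, right-skewed quantity. It is modeled as gamma
distributed with

    log E[y_i] = x_i' beta + b_{g(i)},    b_g ~ N(0, sigma_b^2),

a fixed-effect design x_i (conservation, mean expression, condition), a
normal random intercept per cassette exon g, and an intercept-only
log-shape (dispersion) submodel: a location-scale model of the kind the
GAMLSS framework fits. Responses carry prior weights (the number of cells
behind each sample variance, scaled to mean 1) that multiply their
log-likelihood contributions.

Estimation maximizes the Laplace-approximated marginal likelihood: the
random intercepts are profiled out per group by Newton's method (the inner
problem is strictly concave), and the outer optimization runs over
(beta, log shape, log sigma_b). Adaptive Gauss-Hermite quadrature with more
than one node is available for accuracy checks. Standard errors come from
the numerical Hessian of the marginal log-likelihood; coefficient p-values
use a t-distribution with n - p residual degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .outliers import grubbs_test

__all__ = [
    "GlmmFit",
    "LrtResult",
    "build_design",
    "fit_gamma_glmm",
    "lrt",
    "lrt_term",
    "remove_residual_outliers",
]

_ETA_CLIP = 40.0  # linear-predictor clip before exponentiation


def build_design(table: pd.DataFrame, fixed) -> tuple[pd.DataFrame, dict]:
    """Design matrix with intercept and treatment-coded categoricals.

    Categorical terms (object/category/bool columns) are dummy-coded against
    the lexicographically first level; numeric terms enter as-is. Returns
    the design frame and a map from term name to its column names.
    """
    n = len(table)
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(n)}
    term_map: dict[str, list[str]] = {"Intercept": ["Intercept"]}
    for term in fixed:
        if term not in table.columns:
            raise KeyError(f"term {term!r} not in table")
        s = table[term]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            levels = sorted(map(str, s.astype(str).unique()))
            if len(levels) < 2:
                raise ValueError(f"categorical term {term!r} has fewer than 2 levels")
            names = []
            for lev in levels[1:]:
                name = f"{term}[T.{lev}]"
                cols[name] = (s.astype(str) == lev).to_numpy(dtype=float)
                names.append(name)
            term_map[term] = names
        else:
            cols[term] = s.to_numpy(dtype=float)
            term_map[term] = [term]
    X = pd.DataFrame(cols, index=table.index)
    return X, term_map


@dataclass
class GlmmFit:
    """A fitted weighted gamma mixed model."""

    params: pd.Series
    se: pd.Series | None
    tvalues: pd.Series | None
    pvalues: pd.Series | None
    loglik: float
    shape: float  # gamma shape (dispersion submodel intercept, exp scale)
    sigma_re: float  # SD of the per-exon random intercept
    converged: bool
    n_obs: int
    df_resid: int
    term_map: dict
    random_effects: pd.Series
    fitted: np.ndarray  # conditional means, exp(X beta + b)
    residuals: np.ndarray  # normalized quantile residuals
    table: pd.DataFrame = field(repr=False)
    spec: dict = field(repr=False, default_factory=dict)
    message: str = ""

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({"coef": self.params})
        if self.se is not None:
            out["se"] = self.se
            out["t"] = self.tvalues
            out["p"] = self.pvalues
        return out


def _gamma_loglik_terms(y, w, alpha):
    """Per-observation weighted gamma log-likelihood pieces free of mu."""
    return w * (
        alpha * np.log(alpha)
        - special.gammaln(alpha)
        + (alpha - 1.0) * np.log(y)
    )


def _profile_random_effects(eta, y, w, alpha, sigma2, gidx, n_groups, b0):
    """Newton maximization of the per-group joint log-density over b.

    The objective is strictly concave in b (second derivative
    -alpha * sum w y/mu - 1/sigma2 < 0), so undamped Newton with step
    clipping converges in a handful of iterations.
    """
    b = b0.copy()
    for _ in range(50):
        mu = np.exp(np.clip(eta + b[gidx], -_ETA_CLIP, _ETA_CLIP))
        r = y / mu
        g1 = alpha * np.bincount(gidx, w * (r - 1.0), minlength=n_groups) - b / sigma2
        g2 = -alpha * np.bincount(gidx, w * r, minlength=n_groups) - 1.0 / sigma2
        step = g1 / g2
        np.clip(step, -2.0, 2.0, out=step)
        b -= step
        if np.max(np.abs(step)) < 1e-11:
            break
    mu = np.exp(np.clip(eta + b[gidx], -_ETA_CLIP, _ETA_CLIP))
    curv = -alpha * np.bincount(gidx, w * y / mu, minlength=n_groups) - 1.0 / sigma2
    return b, curv


def _group_data_loglik(eta, b, y, w, alpha, gidx, n_groups, const_terms):
    mu = np.exp(np.clip(eta + b[gidx], -_ETA_CLIP, _ETA_CLIP))
    per_obs = const_terms + w * alpha * (-np.log(mu) - y / mu)
    return np.bincount(gidx, per_obs, minlength=n_groups)


def _marginal_negloglik(theta, X, y, w, gidx, n_groups, quad_points, b_cache):
    p = X.shape[1]
    beta = theta[:p]
    alpha = np.exp(np.clip(theta[p], -30, 30))
    sigma2 = np.exp(np.clip(2.0 * theta[p + 1], -60, 60))
    eta = X @ beta
    b_hat, curv = _profile_random_effects(
        eta, y, w, alpha, sigma2, gidx, n_groups, b_cache[0]
    )
    b_cache[0] = b_hat
    const_terms = _gamma_loglik_terms(y, w, alpha)
    h_hat = (
        _group_data_loglik(eta, b_hat, y, w, alpha, gidx, n_groups, const_terms)
        - 0.5 * b_hat**2 / sigma2
        - 0.5 * np.log(2.0 * np.pi * sigma2)
    )
    if quad_points <= 1:
        ll_groups = h_hat + 0.5 * np.log(2.0 * np.pi) - 0.5 * np.log(-curv)
    else:
        nodes, weights = np.polynomial.hermite.hermgauss(quad_points)
        sd_hat = 1.0 / np.sqrt(-curv)
        vals = np.empty((quad_points, n_groups))
        for j, z in enumerate(nodes):
            b_j = b_hat + np.sqrt(2.0) * sd_hat * z
            h_j = (
                _group_data_loglik(eta, b_j, y, w, alpha, gidx, n_groups, const_terms)
                - 0.5 * b_j**2 / sigma2
                - 0.5 * np.log(2.0 * np.pi * sigma2)
            )
            vals[j] = np.log(weights[j]) + z * z + h_j
        m = vals.max(axis=0)
        ll_groups = m + np.log(np.exp(vals - m).sum(axis=0)) + np.log(np.sqrt(2.0) * sd_hat)
    return -float(ll_groups.sum())


def fit_gamma_glmm(
    table: pd.DataFrame,
    response: str = "var_t",
    fixed=("group", "mean_expression", "condition"),
    group: str = "exon_id",
    weight: str | None = "weight",
    quad_points: int = 1,
    compute_se: bool = True,
    start: np.ndarray | None = None,
) -> GlmmFit:
    """Fit the weighted gamma mixed model by Laplace / adaptive quadrature.

    ``table`` must contain the response (strictly positive), the fixed-term
    columns, the random-effect grouping column and, optionally, a prior
    weight column (normalized internally to mean 1, so fits are invariant to
    rescaling all weights by a constant).
    """
    fixed = list(fixed)
    y = table[response].to_numpy(dtype=float)
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        raise ValueError("response must be finite and strictly positive (gamma support)")
    X_df, term_map = build_design(table, fixed)
    X = X_df.to_numpy(dtype=float)
    w = (
        table[weight].to_numpy(dtype=float)
        if weight is not None and weight in table.columns
        else np.ones(len(table))
    )
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    w = w / w.mean()
    codes, levels = pd.factorize(table[group], sort=True)
    gidx = codes.astype(np.int64)
    n_groups = len(levels)
    n, p = X.shape
    if n <= p + 2:
        raise ValueError("too few rows for the requested fixed effects")

    # standardize continuous columns internally (conditioning); coefficients
    # and their covariance are mapped back to the original scale below
    col_mean = np.zeros(p)
    col_scale = np.ones(p)
    for j, name in enumerate(X_df.columns):
        col = X[:, j]
        if name != "Intercept" and not set(np.unique(col)) <= {0.0, 1.0}:
            sd = col.std()
            if sd > 0:
                col_mean[j] = col.mean()
                col_scale[j] = sd
    Xs = (X - col_mean) / col_scale
    # beta_orig = T @ beta_std: diagonal 1/scale, intercept absorbs the centers
    T = np.diag(1.0 / col_scale)
    i0 = list(X_df.columns).index("Intercept")
    T[i0, :] -= col_mean / col_scale
    T[i0, i0] = 1.0
    T_inv = np.linalg.inv(T)

    if start is not None:
        start = np.asarray(start, dtype=float).copy()
        start[:p] = T_inv @ start[:p]

    if start is None:
        logy = np.log(y)
        wls = np.linalg.lstsq(Xs * np.sqrt(w)[:, None], logy * np.sqrt(w), rcond=None)
        beta0 = wls[0]
        resid = logy - Xs @ beta0
        v = max(float(np.var(resid)), 1e-3)
        alpha0 = float(np.clip(1.0 / v, 0.2, 200.0))
        theta0 = np.concatenate([beta0, [np.log(alpha0), np.log(0.3)]])
    else:
        theta0 = np.asarray(start, dtype=float)

    b_cache = [np.zeros(n_groups)]
    args = (Xs, y, w, gidx, n_groups, quad_points, b_cache)
    bounds = [(None, None)] * p + [(-6.0, 12.0), (-8.0, 3.0)]
    res = optimize.minimize(
        _marginal_negloglik,
        theta0,
        args=args,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-8},
    )
    theta = res.x
    loglik = -float(res.fun)
    beta = T @ theta[:p]
    alpha = float(np.exp(theta[p]))
    sigma = float(np.exp(theta[p + 1]))
    eta = Xs @ theta[:p]
    b_hat, _ = _profile_random_effects(
        eta, y, w, alpha, sigma**2, gidx, n_groups, b_cache[0]
    )
    mu = np.exp(np.clip(eta + b_hat[gidx], -_ETA_CLIP, _ETA_CLIP))

    # normalized quantile residuals (weight-adjusted gamma shape)
    shape_i = alpha * w
    u = stats.gamma.cdf(y, a=shape_i, scale=mu / shape_i)
    u = np.clip(u, 1e-10, 1.0 - 1e-10)
    residuals = stats.norm.ppf(u)

    params = pd.Series(beta, index=X_df.columns)
    se = tvalues = pvalues = None
    if compute_se:
        hess = _numerical_hessian(_marginal_negloglik, theta, args)
        cov = _safe_inverse(hess)
        if cov is not None:
            cov_beta = T @ cov[:p, :p] @ T.T
            se = pd.Series(np.sqrt(np.maximum(np.diag(cov_beta), 0.0)), index=X_df.columns)
            df_resid = max(n - p, 1)
            with np.errstate(divide="ignore", invalid="ignore"):
                tv = params / se
            tvalues = tv
            pvalues = pd.Series(
                2.0 * stats.t.sf(np.abs(tv.to_numpy()), df_resid), index=X_df.columns
            )

    return GlmmFit(
        params=params,
        se=se,
        tvalues=tvalues,
        pvalues=pvalues,
        loglik=loglik,
        shape=alpha,
        sigma_re=sigma,
        converged=bool(res.success),
        n_obs=n,
        df_resid=max(n - p, 1),
        term_map=term_map,
        random_effects=pd.Series(b_hat, index=list(levels)),
        fitted=mu,
        residuals=residuals,
        table=table,
        spec={
            "response": response,
            "fixed": fixed,
            "group": group,
            "weight": weight,
            "quad_points": quad_points,
        },
        message=str(res.message),
    )


def _numerical_hessian(f, x, args, eps: float = 1e-4):
    k = x.size
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = eps
            ej[j] = eps
            fpp = f(x + ei + ej, *args)
            fpm = f(x + ei - ej, *args)
            fmp = f(x - ei + ej, *args)
            fmm = f(x - ei - ej, *args)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * eps * eps)
    return hess


def _safe_inverse(h):
    try:
        return np.linalg.inv(h)
    except np.linalg.LinAlgError:
        try:
            return np.linalg.pinv(h)
        except np.linalg.LinAlgError:
            return None


@dataclass(frozen=True)
class LrtResult:
    statistic: float
    df: int
    pvalue: float


def lrt(full: GlmmFit, reduced: GlmmFit) -> LrtResult:
    """Likelihood ratio test between nested fits: 2(l_full - l_reduced) ~ chi2."""
    full_cols = set(full.params.index)
    red_cols = set(reduced.params.index)
    if not red_cols <= full_cols:
        raise ValueError("reduced model is not nested in the full model")
    if full.spec.get("group") != reduced.spec.get("group") or full.spec.get(
        "response"
    ) != reduced.spec.get("response"):
        raise ValueError("models differ in response or random-effect structure")
    df = len(full_cols) - len(red_cols)
    statistic = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    pvalue = 1.0 if df == 0 else float(stats.chi2.sf(statistic, df))
    return LrtResult(float(statistic), df, pvalue)


def lrt_term(table: pd.DataFrame, term: str, fixed, **fit_kwargs) -> tuple[LrtResult, GlmmFit, GlmmFit]:
    """Fit the model with and without one fixed term and test it by LRT."""
    fixed = list(fixed)
    if term not in fixed:
        raise ValueError(f"term {term!r} is not among the fixed terms")
    fit_kwargs.setdefault("compute_se", False)
    full = fit_gamma_glmm(table, fixed=fixed, **fit_kwargs)
    reduced_fixed = [t for t in fixed if t != term]
    start = np.concatenate(
        [
            [
                full.params[c]
                for cols in [full.term_map[t] for t in ["Intercept"] + reduced_fixed]
                for c in cols
            ],
            [np.log(full.shape), np.log(max(full.sigma_re, 1e-3))],
        ]
    )
    reduced = fit_gamma_glmm(table, fixed=reduced_fixed, start=start, **fit_kwargs)
    return lrt(full, reduced), full, reduced


def remove_residual_outliers(
    fit: GlmmFit, alpha: float = 0.05, max_iter: int = 10
) -> tuple[GlmmFit, pd.DataFrame, list]:
    """Iteratively drop rows whose fit residuals are Grubbs outliers, refit.

    Two-sided Grubbs on the normalized quantile residuals, one removal per
    refit, until no outlier is flagged or ``max_iter`` is hit (then the
    partial result is returned with ``converged`` untouched and a message).
    Refuses a removal that would empty a fixed-effect factor level.

    Returns (final fit, final table, removed row labels).
    """
    removed: list = []
    table = fit.table
    spec = fit.spec
    for it in range(max_iter + 1):
        res = grubbs_test(fit.residuals, alpha=alpha, alternative="two-sided")
        if not res.is_outlier:
            return fit, table, removed
        if it == max_iter:
            fit.message = (fit.message + "; " if fit.message else "") + (
                "outlier pruning stopped at max_iter with outliers remaining"
            )
            return fit, table, removed
        label = table.index[res.index]
        candidate = table.drop(index=label)
        for term in spec["fixed"]:
            s = candidate[term]
            if (s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype)) and s.nunique() < 2:
                warnings.warn(
                    f"stopping outlier pruning: removing row {label!r} would "
                    f"empty a level of {term!r}"
                )
                return fit, table, removed
        removed.append(label)
        table = candidate
        fit = fit_gamma_glmm(
            table,
            response=spec["response"],
            fixed=spec["fixed"],
            group=spec["group"],
            weight=spec["weight"],
            quad_points=spec["quad_points"],
        )
    return fit, table, removed
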