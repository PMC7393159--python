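"""REML linear mixed models with variance components and Satterthwaite df.

A small dense-matrix engine for models of the form

    y = X beta + sum_k Z_k u_k + eps,   u_k ~ N(0, s2_k I),  eps ~ N(0, s2_e I)

covering everything the analysis needs: a single fish-level random
intercept (paired otoliths) and the crossed variance components of the
stacked divergence model.  Fixed effects are profiled out; the REML
criterion is minimized over log-variances.  Approximate denominator degrees
of freedom for t-tests and contrasts use the Satterthwaite method: the
variance of a contrast's sampling variance is propagated through the
inverse expected (REML) information of the variance parameters.

An optional boundary-avoiding penalty — an improper Gamma(shape, rate=0)
prior on each random-effect standard deviation, adding
(shape - 1) * log(sd_k) to the REML log-likelihood — keeps variance
components off zero in small designs (the maximum-a-posteriori analogue of
weakly-informative covariance priors).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import linalg, optimize, stats

logger = logging.getLogger(__name__)

__all__ = ["LmmFit", "fit_reml", "fit_lmm", "tukey_adjust"]

_LOGV_LO, _LOGV_HI = -24.0, 8.0


@dataclass
class LmmFit:
    """Fitted mixed model: fixed effects, variance components, df machinery."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    df: pd.Series
    pvalues: pd.Series
    cov_params: pd.DataFrame
    vcomp: dict
    reml_loglik: float
    converged: bool
    nobs: int
    design_info: object = None
    _internals: dict = field(default_factory=dict, repr=False)

    def contrast(self, L: np.ndarray) -> dict:
        """Estimate, SE, Satterthwaite df, t and p for a contrast L @ beta."""
        L = np.asarray(L, dtype=float).ravel()
        beta = self.params.to_numpy()
        C = self.cov_params.to_numpy()
        est = float(L @ beta)
        var = float(L @ C @ L)
        se = np.sqrt(var)
        df = _satterthwaite_df(L, self._internals)
        t = est / se
        p = 2.0 * stats.t.sf(abs(t), df)
        return {"estimate": est, "se": se, "t": t, "df": df, "p": p}


def _build_V(theta: np.ndarray, ZZt: list[np.ndarray], n: int) -> np.ndarray:
    V = np.exp(theta[-1]) * np.eye(n)
    for k, G in enumerate(ZZt):
        V += np.exp(theta[k]) * G
    return V


def _reml_deviance(
    theta: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    ZZt: list[np.ndarray],
    penalty_shape: float | None,
) -> float:
    n = y.shape[0]
    V = _build_V(theta, ZZt, n)
    try:
        cf = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return np.inf
    logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vi_X = linalg.cho_solve(cf, X, check_finite=False)
    Vi_y = linalg.cho_solve(cf, y, check_finite=False)
    XtViX = X.T @ Vi_X
    sign, logdetXVX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    quad = float(r @ linalg.cho_solve(cf, r, check_finite=False))
    dev = logdetV + logdetXVX + quad
    if penalty_shape is not None:
        # -2 * log prior, Gamma(shape, 0) on each random-effect SD
        dev -= 2.0 * (penalty_shape - 1.0) * 0.5 * np.sum(theta[:-1])
    return dev


def _satterthwaite_df(L: np.ndarray, internals: dict) -> float:
    """nu = 2 (L C L')^2 / Var(L C(theta) L') via the REML information."""
    Vi = internals["Vi"]
    Vi_X = internals["Vi_X"]
    C = internals["C"]
    ZZt = internals["ZZt"]
    n = Vi.shape[0]
    P = Vi - Vi_X @ C @ Vi_X.T
    comps = list(ZZt) + [np.eye(n)]
    m = len(comps)
    PVk = [P @ G for G in comps]
    info = np.empty((m, m))
    for i in range(m):
        for j in range(i, m):
            info[i, j] = info[j, i] = 0.5 * np.sum(PVk[i] * PVk[j].T)
    # gradient of L C L' wrt each variance parameter
    g = np.empty(m)
    LC_XtVi = (L @ C) @ Vi_X.T  # 1 x n
    for k, G in enumerate(comps):
        g[k] = float(LC_XtVi @ G @ LC_XtVi.T)
    var_lcl = float(L @ C @ L)
    try:
        denom = float(g @ np.linalg.solve(info, g))
    except np.linalg.LinAlgError:
        denom = float(g @ np.linalg.pinv(info) @ g)
    if denom <= 0:
        return float(n - C.shape[0])
    return max(1.0, 2.0 * var_lcl**2 / denom)


def fit_reml(
    y: np.ndarray,
    X: np.ndarray,
    Z_list: list[np.ndarray],
    component_names: list[str] | None = None,
    param_names: list[str] | None = None,
    penalty_shape: float | None = None,
    design_info=None,
) -> LmmFit:
    """Fit the variance-components model by (penalized) REML.

    ``Z_list`` holds one incidence/design matrix per random term; the
    residual variance is always included.  Raises on a rank-deficient fixed
    design or on optimizer failure.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design matrix is singular (rank-deficient)")
    if n <= p:
        raise ValueError("more fixed-effect parameters than observations")
    ZZt = [np.asarray(Z, float) @ np.asarray(Z, float).T for Z in Z_list]
    m = len(ZZt)
    var_y = max(float(np.var(y, ddof=1)), 1e-12)

    if penalty_shape is None:
        # profile out the residual scale: V = s2_e (I + sum gamma_k G_k)
        eye = np.eye(n)

        def objective(loggam: np.ndarray) -> float:
            H = eye + sum(np.exp(g) * G for g, G in zip(loggam, ZZt))
            try:
                cf = linalg.cho_factor(H, lower=True, check_finite=False)
            except linalg.LinAlgError:
                return np.inf
            logdetH = 2.0 * np.sum(np.log(np.diag(cf[0])))
            Hi_X = linalg.cho_solve(cf, X, check_finite=False)
            Hi_y = linalg.cho_solve(cf, y, check_finite=False)
            XtHiX = X.T @ Hi_X
            sign, logdetXHX = np.linalg.slogdet(XtHiX)
            if sign <= 0:
                return np.inf
            beta = np.linalg.solve(XtHiX, X.T @ Hi_y)
            r = y - X @ beta
            quad = float(r @ linalg.cho_solve(cf, r, check_finite=False))
            if quad <= 0:
                return np.inf
            return (n - p) * np.log(quad) + logdetH + logdetXHX

        res = optimize.minimize(
            objective,
            np.zeros(m),
            method="Nelder-Mead",
            bounds=[(_LOGV_LO, _LOGV_HI)] * m,
            options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 2000, "maxfev": 4000},
        )
        if not res.success:
            raise RuntimeError(
                f"REML optimization did not converge: {res.message} "
                f"(final deviance {res.fun:.6g})"
            )
        gamma = np.exp(res.x)
        H = eye + sum(g * G for g, G in zip(gamma, ZZt))
        cf = linalg.cho_factor(H, lower=True, check_finite=False)
        Hi_X = linalg.cho_solve(cf, X, check_finite=False)
        beta_tmp = np.linalg.solve(X.T @ Hi_X, Hi_X.T @ y)
        r = y - X @ beta_tmp
        s2e = float(r @ linalg.cho_solve(cf, r, check_finite=False)) / (n - p)
        theta = np.log(np.concatenate([gamma * s2e, [s2e]]))
        reml_dev = _reml_deviance(theta, y, X, ZZt, None)
    else:
        def objective(u: np.ndarray) -> float:
            return _reml_deviance(u + np.log(var_y), y, X, ZZt, penalty_shape)

        x0 = np.full(m + 1, np.log(0.5 / (m + 1)))
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            bounds=[(_LOGV_LO, _LOGV_HI)] * (m + 1),
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000, "maxfev": 8000},
        )
        if not res.success:
            raise RuntimeError(
                f"REML optimization did not converge: {res.message} "
                f"(final deviance {res.fun:.6g})"
            )
        theta = res.x + np.log(var_y)
        reml_dev = float(res.fun)
    V = _build_V(theta, ZZt, n)
    cf = linalg.cho_factor(V, lower=True, check_finite=False)
    Vi = linalg.cho_solve(cf, np.eye(n), check_finite=False)
    Vi_X = Vi @ X
    C = np.linalg.inv(X.T @ Vi_X)
    beta = C @ (Vi_X.T @ y)
    se = np.sqrt(np.diag(C))

    names = param_names or [f"x{j}" for j in range(p)]
    comp_names = component_names or [f"vc{k}" for k in range(m)]
    internals = {"Vi": Vi, "Vi_X": Vi_X, "C": C, "ZZt": ZZt}
    dfs = np.array(
        [_satterthwaite_df(np.eye(p)[j], internals) for j in range(p)]
    )
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dfs)
    vcomp = {nm: float(np.exp(theta[k])) for k, nm in enumerate(comp_names)}
    vcomp["residual"] = float(np.exp(theta[-1]))
    idx = pd.Index(names)
    return LmmFit(
        params=pd.Series(beta, index=idx),
        bse=pd.Series(se, index=idx),
        tvalues=pd.Series(tvals, index=idx),
        df=pd.Series(dfs, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        cov_params=pd.DataFrame(C, index=idx, columns=idx),
        vcomp=vcomp,
        reml_loglik=-0.5 * reml_dev,
        converged=True,
        nobs=n,
        design_info=design_info,
        _internals=internals,
    )


def fit_lmm(
    records: pd.DataFrame,
    fixed_spec: str,
    random_intercept_group: str,
    penalty_shape: float | None = None,
) -> LmmFit:
    """Fit ``fixed_spec`` (patsy formula, response included) with a single
    random intercept per level of ``random_intercept_group``.

    The returned fit keeps the patsy design info so marginal-mean rows can
    be built for new covariate settings.
    """
    records = records.reset_index(drop=True)
    ymat, X = patsy.dmatrices(fixed_spec, records, return_type="dataframe")
    groups = pd.Categorical(records.loc[X.index.astype(int), random_intercept_group])
    Z = pd.get_dummies(groups, dtype=float).to_numpy()
    return fit_reml(
        ymat.to_numpy().ravel(),
        X.to_numpy(),
        [Z],
        component_names=[random_intercept_group],
        param_names=list(X.columns),
        penalty_shape=penalty_shape,
        design_info=X.design_info,
    )


def tukey_adjust(t: float, k: int, df: float) -> float:
    """Tukey (studentized-range) adjusted p for one of k(k-1)/2 pairwise
    contrasts among k groups: p = P(Q_{k,df} >= sqrt(2) |t|)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    df = min(max(df, 2.0), 1e6)
    return float(np.clip(stats.studentized_range.sf(np.sqrt(2.0) * abs(t), k, df), 0.0, 1.0))
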