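"""Mixed-effects model for repeated measures (MMRM) with unstructured covariance.

The primary longitudinal analysis of the trial: a fixed-effects cell-means
model (arm x visit, visit categorical so no shape is assumed) for the weekly
Ham-D totals, with one unstructured positive-definite covariance matrix
shared across participants for the within-participant errors.  Missing visits
after dropout are handled by the likelihood (each participant contributes the
marginal normal of their observed visits) - no imputation.

Estimation profiles the fixed effects out by generalized least squares and
maximizes the REML (default) or ML log-likelihood over the Cholesky factor of
the covariance with a quasi-Newton optimizer; on complete balanced data this
reduces to the closed form (cell means, pooled within-arm covariance), which
the optimizer start values exploit.

Reported per-week contrasts are control minus active (CT - EFMT), so positive
differences favour the active arm on a severity scale.  The omnibus group x
visit interaction Wald statistic is converted to an F with the multivariate
(Hotelling T^2) denominator by default, which is exact on complete balanced
data; the residual-degrees-of-freedom convention (total observations minus
fixed-effect parameters, the convention behind per-week contrast t tests) is
also available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["MMRMResult", "fit_mmrm"]


@dataclass
class MMRMResult:
    lsmeans: pd.DataFrame          # arm, week, estimate, se
    contrasts: pd.DataFrame        # week, difference, se, df, t, p
    sigma: pd.DataFrame            # estimated within-participant covariance
    beta: np.ndarray               # cell means, ordered (arm, week)
    cov_beta: np.ndarray
    interaction: dict              # F, df1, df2, p, method
    arms: tuple[str, ...]
    weeks: tuple[int, ...]
    n_subjects: int
    n_obs: int
    loglik: float
    reml: bool
    converged: bool
    contrast_df_method: str
    used_fallback_start: bool = False

    @property
    def contrast_arms(self) -> str:
        return f"{self.arms[1]} - {self.arms[0]}" if len(self.arms) == 2 else ""


def _prepare(data: pd.DataFrame, response: str, subject: str, arm: str, week: str):
    d = data[[subject, arm, week, response]].dropna()
    weeks = tuple(sorted(d[week].unique()))
    arm_names = sorted(d[arm].unique())
    # canonical order: active (EFMT) first so contrasts read CT - EFMT
    if set(arm_names) == {"EFMT", "CT"}:
        arm_names = ["EFMT", "CT"]
    T, G = len(weeks), len(arm_names)
    widx = {w: j for j, w in enumerate(weeks)}
    aidx = {a: j for j, a in enumerate(arm_names)}
    subjects = list(dict.fromkeys(d[subject]))
    Y = np.full((len(subjects), T), np.nan)
    arm_of = np.zeros(len(subjects), dtype=int)
    sidx = {s: i for i, s in enumerate(subjects)}
    for s, a, w, y in d.itertuples(index=False):
        Y[sidx[s], widx[w]] = y
        arm_of[sidx[s]] = aidx[a]
    return Y, arm_of, tuple(arm_names), weeks


def _pattern_groups(Y: np.ndarray, arm_of: np.ndarray):
    """Group subjects by (arm, missingness pattern) for vectorized likelihoods."""
    obs = ~np.isnan(Y)
    groups = {}
    for i in range(Y.shape[0]):
        key = (arm_of[i], obs[i].tobytes())
        groups.setdefault(key, []).append(i)
    out = []
    for (a, _), idx in groups.items():
        o = obs[idx[0]]
        out.append((a, np.flatnonzero(o), Y[np.ix_(idx, np.flatnonzero(o))]))
    return out


def _neg_loglik(theta: np.ndarray, groups, T: int, G: int, reml: bool) -> float:
    L = np.zeros((T, T))
    tril = np.tril_indices(T)
    L[tril] = theta
    diag = np.arange(T)
    L[diag, diag] = np.exp(np.clip(theta[_diag_positions(T)], -20, 20))
    sigma = L @ L.T
    try:
        beta, XtWX, ll_parts = _profile_beta(sigma, groups, T, G)
    except np.linalg.LinAlgError:
        return 1e12
    ll = ll_parts
    if reml:
        sign, logdet = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return 1e12
        ll -= 0.5 * logdet
    return -ll


def _diag_positions(T: int) -> np.ndarray:
    tril = np.tril_indices(T)
    return np.flatnonzero(tril[0] == tril[1])


def _profile_beta(sigma: np.ndarray, groups, T: int, G: int):
    """GLS cell means and the profiled log-likelihood pieces for a fixed sigma.

    The design is saturated (one parameter per arm x week cell), so X'WX is
    block-diagonal by arm with per-arm blocks sum over patterns of
    n_pattern * Sigma_oo^{-1} scattered to the full week grid.
    """
    p = G * T
    XtWX = np.zeros((p, p))
    XtWy = np.zeros(p)
    quad_parts = []
    logdet_sum = 0.0
    n_obs = 0
    for a, o, Yg in groups:
        S = sigma[np.ix_(o, o)]
        Sinv = np.linalg.inv(S)
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            raise np.linalg.LinAlgError("sigma_oo not PD")
        ng = Yg.shape[0]
        logdet_sum += ng * logdet
        n_obs += ng * len(o)
        cols = a * T + o
        XtWX[np.ix_(cols, cols)] += ng * Sinv
        XtWy[cols] += Sinv @ Yg.sum(axis=0)
        quad_parts.append((o, Sinv, Yg))
    if (np.diag(XtWX) <= 0).any():
        raise ValueError("every arm x week cell needs at least one observation")
    beta = np.linalg.solve(XtWX, XtWy)
    quad = 0.0
    for (a, o, Yg), (_, Sinv, _) in zip(groups, quad_parts):
        r = Yg - beta[a * T + o]
        quad += float(np.einsum("ij,jk,ik->", r, Sinv, r))
    ll = -0.5 * (n_obs * np.log(2 * np.pi) + logdet_sum + quad)
    return beta, XtWX, ll


def _closed_form_start(Y: np.ndarray, arm_of: np.ndarray, G: int, reml: bool):
    """Cell means + pooled within-arm covariance from complete cases (or
    available-case moments when nobody is complete)."""
    T = Y.shape[1]
    beta = np.zeros(G * T)
    for a in range(G):
        Ya = Y[arm_of == a]
        with np.errstate(invalid="ignore"):
            beta[a * T:(a + 1) * T] = np.nanmean(Ya, axis=0)
    R = Y - beta[arm_of[:, None] * T + np.arange(T)[None, :]]
    complete = ~np.isnan(R).any(axis=1)
    if complete.sum() >= T + G:
        Rc = R[complete]
        denom = complete.sum() - (G if reml else 0)
        S = (Rc.T @ Rc) / max(denom, 1)
    else:
        Rm = np.ma.masked_invalid(R)
        S = np.ma.cov(Rm, rowvar=False, allow_masked=True).filled(0.0)
    # guard against a start that is not PD
    eig = np.linalg.eigvalsh(S)
    if eig.min() <= 1e-8:
        S = S + (1e-6 + abs(min(eig.min(), 0))) * np.eye(T)
    return beta, S


def _cs_start(Y: np.ndarray) -> np.ndarray:
    """Compound-symmetry fallback start values."""
    T = Y.shape[1]
    v = float(np.nanvar(Y))
    return v * (0.5 * np.ones((T, T)) + 0.5 * np.eye(T))


def _theta_from_sigma(S: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(S)
    T = S.shape[0]
    theta = L[np.tril_indices(T)].copy()
    theta[_diag_positions(T)] = np.log(np.diag(L))
    return theta


def fit_mmrm(data: pd.DataFrame, response: str = "hamd_total",
             subject: str = "participant_id", arm: str = "arm",
             week: str = "week", reml: bool = True,
             contrast_df_method: str = "residual",
             interaction_df_method: str = "hotelling",
             tol: float = 1e-9) -> MMRMResult:
    """Fit the MMRM and derive LS means, weekly contrasts and the omnibus test.

    ``contrast_df_method``: "residual" (observations minus fixed-effect
    parameters; the convention behind the trial's printed df) or "subjects"
    (subjects minus arms).  ``interaction_df_method``: "hotelling" (default,
    exact on complete balanced data) or "residual".
    """
    Y, arm_of, arms, weeks = _prepare(data, response, subject, arm, week)
    T, G = len(weeks), len(arms)
    if T < 2:
        raise ValueError("need at least 2 observed visits")
    if G < 2:
        raise ValueError("need at least 2 arms")
    groups = _pattern_groups(Y, arm_of)
    n_subjects = Y.shape[0]
    n_obs = int((~np.isnan(Y)).sum())

    used_fallback = False
    complete = not np.isnan(Y).any()
    if complete:
        # Saturated mean + complete data: GLS estimates are the cell means for
        # any sigma, and the (RE)ML covariance is the pooled residual SSP with
        # divisor N - G (REML) or N (ML) -- no iteration needed.
        beta = np.zeros(G * T)
        for a in range(G):
            beta[a * T:(a + 1) * T] = Y[arm_of == a].mean(axis=0)
        R = Y - beta.reshape(G, T)[arm_of]
        sigma = (R.T @ R) / (n_subjects - G if reml else n_subjects)
        if np.linalg.eigvalsh(sigma).min() < 1e-10:
            # degenerate (e.g. noiseless) data: ridge keeps the GLS algebra
            # defined; the cell means themselves are unaffected
            sigma = sigma + 1e-8 * np.eye(T)
        beta, XtWX, ll = _profile_beta(sigma, groups, T, G)
        if reml:
            ll -= 0.5 * np.linalg.slogdet(XtWX)[1]
        converged = True
    else:
        beta0, S0 = _closed_form_start(Y, arm_of, G, reml)
        res = optimize.minimize(_neg_loglik, _theta_from_sigma(S0),
                                args=(groups, T, G, reml), method="L-BFGS-B",
                                options={"maxiter": 500, "ftol": tol, "gtol": 1e-8})
        if not res.success or not np.isfinite(res.fun):
            used_fallback = True
            res2 = optimize.minimize(_neg_loglik, _theta_from_sigma(_cs_start(Y)),
                                     args=(groups, T, G, reml), method="L-BFGS-B",
                                     options={"maxiter": 1000, "ftol": tol, "gtol": 1e-8})
            if res2.fun < res.fun:
                res = res2
        theta = res.x
        L = np.zeros((T, T))
        L[np.tril_indices(T)] = theta
        L[np.arange(T), np.arange(T)] = np.exp(theta[_diag_positions(T)])
        sigma = L @ L.T
        beta, XtWX, ll = _profile_beta(sigma, groups, T, G)
        if reml:
            ll -= 0.5 * np.linalg.slogdet(XtWX)[1]
        converged = bool(res.success)
    cov_beta = np.linalg.inv(XtWX)

    p = G * T
    df_resid = n_obs - p
    df_subj = n_subjects - G
    cdf = df_resid if contrast_df_method == "residual" else df_subj

    lsrows, crows = [], []
    for a in range(G):
        for j, w in enumerate(weeks):
            k = a * T + j
            lsrows.append({"arm": arms[a], "week": w, "estimate": beta[k],
                           "se": float(np.sqrt(cov_beta[k, k]))})
    for j, w in enumerate(weeks):
        c = np.zeros(p)
        c[1 * T + j] = 1.0   # control
        c[0 * T + j] = -1.0  # active
        diff = float(c @ beta)
        se = float(np.sqrt(c @ cov_beta @ c))
        tval = diff / se
        crows.append({"week": w, "difference": diff, "se": se, "df": cdf,
                      "t": tval, "p": float(2 * stats.t.sf(abs(tval), cdf))})

    # omnibus group x visit interaction: difference-in-differences vs baseline
    q = T - 1
    Lc = np.zeros((q, p))
    for j in range(1, T):
        Lc[j - 1, 1 * T + j] = 1.0
        Lc[j - 1, 0 * T + j] = -1.0
        Lc[j - 1, 1 * T + 0] = -1.0
        Lc[j - 1, 0 * T + 0] = 1.0
    d = Lc @ beta
    wald = float(d @ np.linalg.solve(Lc @ cov_beta @ Lc.T, d))
    if interaction_df_method == "hotelling":
        nu = n_subjects - G
        df2 = nu - q + 1
        F = wald * df2 / (nu * q)
    else:
        df2 = df_resid
        F = wald / q
    interaction = {"F": float(F), "df1": q, "df2": int(df2),
                   "p": float(stats.f.sf(F, q, df2)), "wald": wald,
                   "method": interaction_df_method}

    return MMRMResult(
        lsmeans=pd.DataFrame(lsrows), contrasts=pd.DataFrame(crows),
        sigma=pd.DataFrame(sigma, index=list(weeks), columns=list(weeks)),
        beta=beta, cov_beta=cov_beta, interaction=interaction,
        arms=arms, weeks=weeks, n_subjects=n_subjects, n_obs=n_obs,
        loglik=float(ll), reml=reml,
        converged=converged, contrast_df_method=contrast_df_method,
        used_fallback_start=used_fallback)
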