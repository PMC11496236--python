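"""Characterizing classes by background variables and predicting transitions.

Both analyses follow the two-step scheme: the step-1 measurement model is
frozen and enters only through posterior class probabilities (profiles) or
class-specific log-densities (transition models).

* :func:`profile_classes` estimates class-specific covariate means or
  proportions by posterior-weighted estimating equations and tests their
  equality across classes with a Wald test whose variance is clustered on
  person (records from the same respondent are dependent).
* :func:`transition_logit` re-estimates the latent Markov model with the
  transition probabilities parameterized by origin-specific multinomial
  logits in one covariate measured at wave T (predicting the T -> T+1
  transition); staying in the origin class is the reference destination.
  Missing covariate values are mean-imputed. Each coefficient gets a
  cluster-robust Wald test, flagged at both p < 0.001 (the stricter level
  used for the many transition tests) and p < 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .errors import NonEstimableError, ValidationError
from .lca import LCAFit, posterior_classes
from .markov import (fit_latent_markov, forward_backward,
                     sequence_log_densities)
from .panel import CLASS_LABELS, PanelDataset

_TINY = 1e-300


# --------------------------------------------------------------------------
# Class profiles (Table-1 machinery)
# --------------------------------------------------------------------------

@dataclass
class CovariateProfile:
    name: str
    estimates: np.ndarray          # (K,) class-specific mean / proportion
    se: np.ndarray                 # (K,) cluster-robust SEs
    wald: float                    # equality-across-classes statistic
    df: int
    p: float
    n_used: int
    is_proportion: bool

    def to_row(self) -> dict:
        d = {"covariate": self.name, "wald": self.wald, "df": self.df,
             "p": self.p, "n_used": self.n_used}
        for c, (e, s) in enumerate(zip(self.estimates, self.se)):
            d[f"class{c + 1}"] = e
            d[f"class{c + 1}_se"] = s
        return d


def profile_classes(measurement: LCAFit, data: PanelDataset,
                    covariate_names: list[str] | None = None
                    ) -> list[CovariateProfile]:
    """Class-specific covariate means with clustered Wald equality tests.

    Records with a missing value are dropped for that covariate only. A
    covariate that is constant in the analysed records has an undefined
    Wald test, reported as NaN.
    """
    if covariate_names is None:
        covariate_names = data.covariate_names
    W_all = posterior_classes(measurement, data)
    K = measurement.K
    ids = pd.factorize(data.df["person_id"])[0]
    out = []
    for name in covariate_names:
        if name not in data.df.columns:
            raise ValidationError(f"unknown covariate {name!r}")
        z = data.df[name].to_numpy(dtype=float)
        keep = ~np.isnan(z)
        zk, Wk, idk = z[keep], W_all[keep], ids[keep]
        n_used = int(keep.sum())
        if n_used == 0:
            raise ValidationError(f"covariate {name!r} has no observed values")
        denom = Wk.sum(axis=0)
        mu = (Wk * zk[:, None]).sum(axis=0) / np.maximum(denom, _TINY)
        is_prop = bool(np.isin(np.unique(zk), [0.0, 1.0]).all())
        if K == 1:
            out.append(CovariateProfile(name, mu, np.zeros(1), np.nan, 0,
                                        np.nan, n_used, is_prop))
            continue
        # clustered sandwich for the weighted-mean estimating equations
        psi = Wk * (zk[:, None] - mu[None, :])          # (n, K)
        sums = np.zeros((idk.max() + 1, K))
        np.add.at(sums, idk, psi)
        meat = sums.T @ sums                            # (K, K)
        Binv = np.diag(1.0 / np.maximum(denom, _TINY))
        V = Binv @ meat @ Binv
        se = np.sqrt(np.maximum(np.diag(V), 0.0))
        if np.ptp(zk) == 0:
            wald_stat, p = np.nan, np.nan
        else:
            D = np.hstack([np.eye(K - 1), -np.ones((K - 1, 1))])
            dmu = D @ mu
            VD = D @ V @ D.T
            try:
                wald_stat = float(dmu @ np.linalg.solve(VD, dmu))
                p = float(chi2.sf(wald_stat, K - 1))
            except np.linalg.LinAlgError:
                wald_stat, p = np.nan, np.nan
        out.append(CovariateProfile(name, mu, se, wald_stat, K - 1, p,
                                    n_used, is_prop))
    return out


def profiles_table(profiles: list[CovariateProfile]) -> pd.DataFrame:
    return pd.DataFrame([p.to_row() for p in profiles])


# --------------------------------------------------------------------------
# Transition predictors (Table-3 machinery)
# --------------------------------------------------------------------------

@dataclass
class TransitionCovariateResult:
    covariate: str
    table: pd.DataFrame            # origin, destination, estimate, se, ...
    pi0: np.ndarray
    alpha: np.ndarray              # (K, K) intercept logits, diag 0
    beta: np.ndarray               # (K, K) slope logits, diag 0
    loglik: float
    converged: bool
    imputed_mean: float
    n_imputed: int
    origin_informative: np.ndarray

    def implied_transition_matrix(self, x: float = 0.0) -> np.ndarray:
        eta = self.alpha + self.beta * x
        e = np.exp(eta - eta.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)


def _pack(th_pi, alpha_off, beta_off):
    return np.concatenate([th_pi, alpha_off.ravel(), beta_off.ravel()])


def _unpack(theta, K):
    th_pi = np.append(theta[:K - 1], 0.0)
    pi0 = np.exp(th_pi - th_pi.max())
    pi0 /= pi0.sum()
    off = K - 1
    alpha_off = theta[off:off + K * (K - 1)].reshape(K, K - 1)
    beta_off = theta[off + K * (K - 1):].reshape(K, K - 1)
    alpha = np.zeros((K, K))
    beta = np.zeros((K, K))
    keep = ~np.eye(K, dtype=bool)
    alpha[keep] = alpha_off.ravel()
    beta[keep] = beta_off.ravel()
    return pi0, alpha, beta


def _transition_matrices(alpha, beta, x):
    """(n, T-1, K, K) row-stochastic matrices from logits and covariate."""
    eta = alpha[None, None] + beta[None, None] * x[:, :, None, None]
    eta = eta - eta.max(axis=3, keepdims=True)
    e = np.exp(eta)
    return e / e.sum(axis=3, keepdims=True)


def _person_scores_cov(theta, K, ld, mask, x, fit_slopes):
    """Per-person Fisher-identity scores and total loglik."""
    pi0, alpha, beta = _unpack(theta, K)
    A = _transition_matrices(alpha, beta, x)
    fb = forward_backward(pi0, A, ld, mask)
    n = ld.shape[0]
    s_pi = fb.gamma[:, 0, :K - 1] - pi0[None, :K - 1]
    mass = fb.xi.sum(axis=3)                            # (n, T-1, K)
    resid = fb.xi - mass[:, :, :, None] * A             # (n, T-1, K, K)
    keep = ~np.eye(K, dtype=bool)
    s_alpha = resid.sum(axis=1)[:, keep]                # (n, K*(K-1))
    s_beta = (resid * x[:, :, None, None]).sum(axis=1)[:, keep]
    if not fit_slopes:
        s_beta = np.zeros_like(s_beta)
    scores = np.concatenate([s_pi, s_alpha, s_beta], axis=1)
    return scores, float(fb.loglik.sum())


def transition_logit(measurement: LCAFit, data: PanelDataset,
                     covariate_name: str, *, fit_slopes: bool = True,
                     min_informative: float = 2.0, gtol: float = 1e-7,
                     max_fun_iter: int = 500,
                     compute_se: bool = True) -> TransitionCovariateResult:
    """Latent Markov model with covariate-dependent transition logits.

    One covariate per run (exploratory, single-predictor models). The
    covariate value at wave T enters the multinomial logit of the T -> T+1
    transition; staying in the origin class is the reference destination,
    so its coefficients are identically zero. Missing covariate values are
    mean-imputed before fitting. Origin classes with fewer than
    ``min_informative`` expected informative transitions are reported as
    non-estimable rather than silently returned.
    """
    if covariate_name not in data.df.columns:
        raise ValidationError(f"unknown covariate {covariate_name!r}")
    ld, mask, persons = sequence_log_densities(data, measurement)
    n, T, K = ld.shape
    if T < 2:
        raise ValidationError("need at least two waves")

    # covariate at wave t (predicting the t -> t+1 transition), mean-imputed
    z = data.df[covariate_name].to_numpy(dtype=float)
    obs_mean = np.nanmean(z)
    if np.isnan(obs_mean):
        raise ValidationError(f"covariate {covariate_name!r} entirely missing")
    n_imputed = int(np.isnan(z).sum())
    z = np.where(np.isnan(z), obs_mean, z)
    pid = pd.factorize(data.df["person_id"], sort=True)[0]
    x_full = np.full((n, T), obs_mean)
    x_full[pid, data.wave] = z
    x = x_full[:, :T - 1]
    if fit_slopes and np.ptp(z) == 0:
        raise NonEstimableError(
            f"covariate {covariate_name!r} is constant after imputation; "
            "transition slopes are not estimable")

    # initialize from the covariate-free EM fit
    base = fit_latent_markov(data, measurement, compute_se=False)
    A0 = np.clip(base.A, 1e-8, None)
    alpha0 = np.log(A0 / np.diag(A0)[:, None])
    keep = ~np.eye(K, dtype=bool)
    lp = np.log(np.maximum(base.pi0, _TINY))
    theta0 = _pack(lp[:K - 1] - lp[-1], alpha0[keep].reshape(K, K - 1),
                   np.zeros((K, K - 1)))

    p_pi = K - 1
    p_ab = K * (K - 1)
    free = np.ones(len(theta0), dtype=bool)
    if not fit_slopes:
        free[p_pi + p_ab:] = False

    def negloglik(th_free):
        th = theta0.copy()
        th[free] = th_free
        scores, ll = _person_scores_cov(th, K, ld, mask, x, fit_slopes)
        return -ll, -scores.sum(axis=0)[free]

    res = minimize(negloglik, theta0[free], jac=True, method="L-BFGS-B",
                   options={"gtol": gtol, "maxiter": max_fun_iter})
    theta = theta0.copy()
    theta[free] = res.x
    pi0, alpha, beta = _unpack(theta, K)
    loglik = -float(res.fun)

    # expected informative transitions per origin class
    A = _transition_matrices(alpha, beta, x)
    fb = forward_backward(pi0, A, ld, mask)
    pair = mask[:, 1:] & mask[:, :-1]
    origin_inf = (fb.xi.sum(axis=3) * pair[:, :, None]).sum(axis=(0, 1))
    estimable = origin_inf >= min_informative
    if not estimable.all():
        warnings.warn(
            "origin class(es) with < "
            f"{min_informative} informative transitions reported as "
            f"non-estimable: {np.flatnonzero(~estimable) + 1}", stacklevel=2)

    se_alpha = np.full((K, K), np.nan)
    se_beta = np.full((K, K), np.nan)
    if compute_se:
        scores, _ = _person_scores_cov(theta, K, ld, mask, x, fit_slopes)
        scores = scores[:, free]
        meat = scores.T @ scores
        pfree = int(free.sum())
        H = np.empty((pfree, pfree))
        h = 1e-5
        for j in range(pfree):
            tp = theta[free].copy(); tp[j] += h
            tm = theta[free].copy(); tm[j] -= h
            thp = theta.copy(); thp[free] = tp
            thm = theta.copy(); thm[free] = tm
            sp, _ = _person_scores_cov(thp, K, ld, mask, x, fit_slopes)
            sm, _ = _person_scores_cov(thm, K, ld, mask, x, fit_slopes)
            H[:, j] = (sp.sum(axis=0) - sm.sum(axis=0))[free] / (2 * h)
        H = 0.5 * (H + H.T)
        Hinv = np.linalg.pinv(-H)
        V = Hinv @ meat @ Hinv
        d = np.sqrt(np.maximum(np.diag(V), 0.0))
        se_alpha[keep] = d[p_pi:p_pi + p_ab]
        if fit_slopes:
            se_beta[keep] = d[p_pi + p_ab:]

    labels = list(CLASS_LABELS[:K]) if K <= len(CLASS_LABELS) else \
        [f"class {c + 1}" for c in range(K)]
    rows = []
    for a in range(K):
        for b in range(K):
            ref = a == b
            est = 0.0 if ref else (beta[a, b] if fit_slopes else np.nan)
            se = 0.0 if ref else se_beta[a, b]
            if ref or not fit_slopes or not estimable[a] or \
                    not np.isfinite(se) or se == 0:
                wald_stat = p = np.nan
            else:
                wald_stat = (est / se) ** 2
                p = float(chi2.sf(wald_stat, 1))
            rows.append({
                "origin": labels[a], "destination": labels[b],
                "estimate": np.nan if (not estimable[a] and not ref) else est,
                "se": np.nan if (not estimable[a] and not ref) else se,
                "wald": wald_stat, "p": p,
                "flag_001": bool(np.isfinite(p) and p < 0.001),
                "flag_01": bool(np.isfinite(p) and p < 0.01),
                "reference": ref,
                "estimable": bool(estimable[a]),
                "direction": ("--" if ref else
                              "favorable" if b < a else "unfavorable"),
            })
    table = pd.DataFrame(rows)
    return TransitionCovariateResult(
        covariate_name, table, pi0, alpha, beta, loglik,
        bool(res.success), obs_mean, n_imputed, origin_inf)


__all__ = ["CovariateProfile", "profile_classes", "profiles_table",
           "TransitionCovariateResult", "transition_logit"]
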