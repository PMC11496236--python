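"""Model choice and diagnostics for the pooled latent class model.

Implements the selection toolkit used to pick the number of classes:
information criteria (AIC, BIC, AIC3), parametric-bootstrap goodness-of-fit
and likelihood-ratio tests, bivariate residuals (BVR), and the design-effect
check for within-person clustering of the pooled records.

The BVR is defined here as a Pearson X^2 comparing the observed two-way
table of an indicator pair (or an external variable x indicator) with the
model-expected table built from record-level posterior class probabilities,
divided by the table's degrees of freedom. This preserves the conventional
"values below 3 or 4 are acceptable" calibration scale. The sample size in
the BIC is the number of pooled records (each wave is a case), switchable
to persons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConvergenceError, ValidationError
from .lca import (LCAFit, _aggregate_patterns, _pattern_logdens, fit_lca,
                  posterior_classes)
from .panel import PanelDataset

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Information criteria
# --------------------------------------------------------------------------

def information_criteria(fit: LCAFit, n: int | None = None) -> dict:
    """AIC, BIC and AIC3 (penalty 3 per parameter); smaller is better."""
    n = fit.n_records if n is None else n
    if n < 2:
        raise ValidationError("information criteria need n >= 2")
    ll, p = fit.loglik, fit.n_params
    return {"AIC": -2 * ll + 2 * p,
            "AIC3": -2 * ll + 3 * p,
            "BIC": -2 * ll + p * np.log(n)}


# --------------------------------------------------------------------------
# Goodness of fit
# --------------------------------------------------------------------------

def l2_statistic(fit: LCAFit, data: PanelDataset) -> float:
    """Likelihood-ratio goodness-of-fit statistic over response patterns.

    L2 = 2 * sum_patterns obs * log(obs / expected), with expected counts
    computed separately for baseline and follow-up records (the baseline
    flag is a model covariate, not a response).
    """
    Yp, bp, w = _aggregate_patterns(data.y, data.is_baseline)
    lb = _pattern_logdens(fit.measurement.beta0, fit.measurement.delta,
                          Yp, bp)
    probs = np.exp(lb) @ fit.weights
    n_flag = np.array([w[~bp].sum(), w[bp].sum()])
    expected = probs * n_flag[bp.astype(int)]
    return float(2.0 * np.sum(w * np.log(w / np.maximum(expected, 1e-300))))


def _simulate_from_fit(fit: LCAFit, is_baseline: np.ndarray,
                       rng: np.random.Generator,
                       indicators: list[str]) -> PanelDataset:
    n = len(is_baseline)
    z = rng.choice(fit.K, size=n, p=fit.weights)
    p0 = fit.measurement.emission_probs(False)
    p1 = fit.measurement.emission_probs(True)
    p = np.where(is_baseline[:, None], p1[z], p0[z])
    y = (rng.random(p.shape) < p).astype(np.int8)
    df = pd.DataFrame(y, columns=indicators)
    df.insert(0, "wave", 0)
    df.insert(0, "person_id", np.arange(n))
    df["baseline"] = is_baseline.astype(int)
    return PanelDataset(df, indicators, validate=False)


def bootstrap_gof(fit: LCAFit, data: PanelDataset, B: int = 99,
                  seed: int = 0, n_starts: int = 8,
                  start_iters: int = 50, tol: float = 1e-7) -> dict:
    """Parametric-bootstrap p value of the L2 goodness-of-fit statistic.

    Simulates ``B`` datasets from the fitted model (matching the record
    count and baseline flags), refits the same-K model on each with a
    reduced multi-start budget, and applies the add-one rule
    p = (1 + #{L2_b >= L2_obs}) / (B + 1).
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    obs = l2_statistic(fit, data)
    rng = np.random.default_rng(seed)
    flags = data.is_baseline
    stats = np.empty(B)
    for b in range(B):
        sim = _simulate_from_fit(fit, flags, rng, data.indicators)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            refit = fit_lca(sim, fit.K, n_starts=n_starts,
                            start_iters=start_iters, tol=tol,
                            seed=int(rng.integers(2**31 - 1)),
                            baseline_effect=fit.measurement.delta.any())
        stats[b] = l2_statistic(refit, sim)
    p = (1.0 + np.sum(stats >= obs)) / (B + 1.0)
    return {"statistic": obs, "p": p, "B": B, "bootstrap_stats": stats}


def bootstrap_lrt(data: PanelDataset, K: int, B: int = 99, seed: int = 0,
                  n_starts: int = 8, start_iters: int = 50,
                  tol: float = 1e-7, data_n_starts: int | None = None,
                  max_fail_frac: float = 0.2) -> dict:
    """Bootstrap likelihood-ratio test of K classes against K-1.

    The statistic is -2 (LL_{K-1} - LL_K); its null distribution is drawn
    by simulating from the K-1 fit and refitting both models on each
    replicate. Non-convergent replicates are logged and excluded; more than
    ``max_fail_frac`` exclusions is a hard error.
    """
    if K < 2:
        raise ValidationError("bootstrap LRT needs K >= 2")
    if B < 1:
        raise ValidationError("B must be >= 1")
    rng = np.random.default_rng(seed)
    dstarts = n_starts if data_n_starts is None else data_n_starts
    baseline = bool(data.is_baseline.any() and (~data.is_baseline).any())

    def _fit(d, k, s):
        return fit_lca(d, k, n_starts=s, start_iters=start_iters, tol=tol,
                       seed=int(rng.integers(2**31 - 1)),
                       baseline_effect=baseline)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit_small = _fit(data, K - 1, dstarts)
        fit_big = _fit(data, K, dstarts)
    obs = -2.0 * (fit_small.loglik - fit_big.loglik)

    stats, n_fail = [], 0
    flags = data.is_baseline
    for b in range(B):
        sim = _simulate_from_fit(fit_small, flags, rng, data.indicators)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f0 = _fit(sim, K - 1, n_starts)
            f1 = _fit(sim, K, n_starts)
        if not (f0.converged and f1.converged):
            n_fail += 1
            logger.info("bootstrap LRT replicate %d excluded "
                        "(non-convergent)", b)
            continue
        stats.append(-2.0 * (f0.loglik - f1.loglik))
    if n_fail > max_fail_frac * B:
        raise ConvergenceError(
            f"{n_fail}/{B} bootstrap replicates failed to converge")
    stats = np.asarray(stats)
    p = (1.0 + np.sum(stats >= obs)) / (len(stats) + 1.0)
    return {"statistic": obs, "p": p, "B": B, "n_excluded": n_fail,
            "bootstrap_stats": stats,
            "loglik_small": fit_small.loglik, "loglik_big": fit_big.loglik}


# --------------------------------------------------------------------------
# Bivariate residuals
# --------------------------------------------------------------------------

def bivariate_residuals(fit: LCAFit, data: PanelDataset,
                        extra_vars: list[str] | None = None) -> pd.DataFrame:
    """BVR table for all indicator pairs and optional external variables.

    For an indicator pair (j, k): the observed 2x2 cross-table is compared
    with the expected one accumulated record-by-record as
    ``sum_c w_ic * p_cj * p_ck`` (and complements), where ``w_ic`` are the
    posterior class probabilities. For an external variable (e.g. the wave
    number): an L x 2 table of the variable's levels against each
    indicator. Each X^2 is divided by its degrees of freedom.
    """
    W = posterior_classes(fit, data)            # (n, K)
    Y = data.y.astype(float)
    b = data.is_baseline
    p0 = fit.measurement.emission_probs(False)  # (K, J)
    p1 = fit.measurement.emission_probs(True)
    # per-record expected indicator probabilities given class
    P = np.where(b[:, None, None], p1[None], p0[None])  # (n, K, J)
    mu = np.einsum("nk,nkj->nj", W, P)          # (n, J) marginal fitted probs
    n, J = Y.shape
    rows = []

    for j in range(J):
        for k in range(j + 1, J):
            o11 = float((Y[:, j] * Y[:, k]).sum())
            o10 = float((Y[:, j] * (1 - Y[:, k])).sum())
            o01 = float(((1 - Y[:, j]) * Y[:, k]).sum())
            o00 = n - o11 - o10 - o01
            pj, pk = P[:, :, j], P[:, :, k]
            e11 = float(np.einsum("nk,nk,nk->", W, pj, pk))
            e10 = float(np.einsum("nk,nk,nk->", W, pj, 1 - pk))
            e01 = float(np.einsum("nk,nk,nk->", W, 1 - pj, pk))
            e00 = n - e11 - e10 - e01
            x2, clipped = _pearson(np.array([o11, o10, o01, o00]),
                                   np.array([e11, e10, e01, e00]))
            rows.append({"var1": data.indicators[j],
                         "var2": data.indicators[k],
                         "bvr": x2 / 1.0, "df": 1, "clipped": clipped})

    for name in (extra_vars or []):
        if name == "wave":
            v = data.wave
        elif name in data.df.columns:
            v = data.df[name].to_numpy()
        else:
            raise ValidationError(f"unknown external variable {name!r}")
        levels = np.unique(v)
        L = len(levels)
        for j in range(J):
            obs = np.empty((L, 2))
            exp = np.empty((L, 2))
            for li, lev in enumerate(levels):
                sel = v == lev
                nl = int(sel.sum())
                obs[li, 1] = Y[sel, j].sum()
                obs[li, 0] = nl - obs[li, 1]
                exp[li, 1] = mu[sel, j].sum()
                exp[li, 0] = nl - exp[li, 1]
            x2, clipped = _pearson(obs.ravel(), exp.ravel())
            df_tab = max(L - 1, 1)
            rows.append({"var1": name, "var2": data.indicators[j],
                         "bvr": x2 / df_tab, "df": df_tab,
                         "clipped": clipped})
    return pd.DataFrame(rows)


def _pearson(obs: np.ndarray, exp: np.ndarray) -> tuple[float, bool]:
    clipped = bool((exp < 1e-12).any())
    exp = np.maximum(exp, 1e-12)
    return float(np.sum((obs - exp) ** 2 / exp)), clipped


# --------------------------------------------------------------------------
# Design effect
# --------------------------------------------------------------------------

def design_effect(data: PanelDataset, fit: LCAFit,
                  cluster: str = "person_id") -> float:
    """Variance inflation of the class proportions due to clustering.

    Ratio of the cluster-robust (clustered on person) to the naive sandwich
    variance of the K-1 free class-proportion moment estimators
    ``sum_i (w_ic - pi_c) = 0``, averaged over the free proportions.
    Returns exactly 1.0 when every cluster contributes one record.
    """
    ids = data.df[cluster].to_numpy()
    if len(np.unique(ids)) < 2:
        raise ValidationError("design effect needs >= 2 clusters")
    W = posterior_classes(fit, data)
    K = fit.K
    if K == 1:
        return 1.0
    psi = W[:, :K - 1] - fit.weights[None, :K - 1]
    codes = pd.factorize(ids)[0]
    if codes.max() + 1 == len(codes):
        return 1.0  # one record per cluster: independence holds exactly
    m0 = (psi ** 2).sum(axis=0)
    sums = np.zeros((codes.max() + 1, K - 1))
    np.add.at(sums, codes, psi)
    m1 = (sums ** 2).sum(axis=0)
    ok = m0 > 0
    if not ok.any():
        return 1.0
    return float(np.mean(m1[ok] / m0[ok]))


# --------------------------------------------------------------------------
# K-selection driver
# --------------------------------------------------------------------------

@dataclass
class SelectionReport:
    table: pd.DataFrame
    chosen_K: int
    criterion: str

    def __str__(self) -> str:
        return (self.table.to_string(index=False,
                                     float_format=lambda v: f"{v:.3f}")
                + f"\nchosen K = {self.chosen_K} (by {self.criterion})")


def select_k(data: PanelDataset, k_min: int = 1, k_max: int = 5,
             n_starts: int = 16, start_iters: int = 100, seed: int = 0,
             bootstrap_B: int = 0, criterion: str = "AIC3",
             tol: float = 1e-8, **lrt_kwargs) -> SelectionReport:
    """Fit a range of class counts and assemble the selection statistics.

    With ``bootstrap_B > 0`` the bootstrap goodness-of-fit p value (per K)
    and the bootstrap LRT p value (K against K-1) are included.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for K in range(k_min, k_max + 1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_lca(data, K, n_starts=n_starts,
                          start_iters=start_iters, tol=tol,
                          seed=int(rng.integers(2**31 - 1)))
        ic = information_criteria(fit)
        bvr = bivariate_residuals(fit, data)
        row = {"K": K, "loglik": fit.loglik, "n_params": fit.n_params,
               **ic, "max_BVR": float(bvr["bvr"].max()),
               "bootstrap_gof_p": np.nan, "bootstrap_lrt_p": np.nan}
        if bootstrap_B > 0:
            row["bootstrap_gof_p"] = bootstrap_gof(
                fit, data, B=bootstrap_B,
                seed=int(rng.integers(2**31 - 1)))["p"]
            if K > k_min:
                row["bootstrap_lrt_p"] = bootstrap_lrt(
                    data, K, B=bootstrap_B,
                    seed=int(rng.integers(2**31 - 1)), **lrt_kwargs)["p"]
        rows.append(row)
        logger.info("select_k: K=%d loglik=%.2f BIC=%.2f", K, fit.loglik,
                    row["BIC"])
    table = pd.DataFrame(rows).sort_values("K", ignore_index=True)
    chosen = int(table.loc[table[criterion].idxmin(), "K"])
    return SelectionReport(table, chosen, criterion)


__all__ = ["information_criteria", "l2_statistic", "bootstrap_gof",
           "bootstrap_lrt", "bivariate_residuals", "design_effect",
           "SelectionReport", "select_k"]
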