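"""Step-1 measurement model: latent class analysis of pooled binary records.

The model is a finite mixture over K latent classes with conditionally
independent Bernoulli indicators. A baseline measurement effect is supported:
records flagged as baseline get a shared per-indicator logit offset ``delta``
added to the class-specific emission logits, absorbing the elevated indicator
prevalence produced by the lifetime-frame baseline interview without letting
the baseline wave shift the class proportions.

Estimation is EM on the unique-response-pattern representation (at most
2^J * 2 patterns), with a multi-start protocol: ``n_starts`` random
initializations run ``start_iters`` EM steps each (batched over start
sets), all still-unconverged sets are continued to convergence, and the
best by log-likelihood is returned. Classes are relabeled by
descending mixing weight (ties broken on the first indicator's emission
probability) so labels are deterministic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import expit, logit as _logit, logsumexp

from .errors import ConvergenceWarning, ValidationError
from .panel import PanelDataset

_PCLIP = (1e-6, 1 - 1e-6)  # emission probability clip during EM


# --------------------------------------------------------------------------
# Model containers
# --------------------------------------------------------------------------

@dataclass
class MeasurementModel:
    """Per-class emission logits plus the shared baseline offsets.

    ``beta0[c, j]`` is the follow-up-wave logit of indicator *j* in class
    *c*; at baseline the logit is ``beta0[c, j] + delta[j]``.
    """

    beta0: np.ndarray            # (K, J)
    delta: np.ndarray            # (J,)
    class_order: np.ndarray = None  # permutation fixing label identity

    def __post_init__(self):
        self.beta0 = np.atleast_2d(np.asarray(self.beta0, dtype=float))
        self.delta = np.asarray(self.delta, dtype=float)
        if self.class_order is None:
            self.class_order = np.arange(self.K)
        self.class_order = np.asarray(self.class_order, dtype=int)
        if sorted(self.class_order.tolist()) != list(range(self.K)):
            raise ValidationError("class_order: must be a permutation of 0..K-1")

    @property
    def K(self) -> int:
        return self.beta0.shape[0]

    @property
    def J(self) -> int:
        return self.beta0.shape[1]

    def emission_probs(self, is_baseline: bool = False) -> np.ndarray:
        """(K, J) indicator probabilities for the given measurement context."""
        logits = self.beta0 + (self.delta[None, :] if is_baseline else 0.0)
        return expit(logits)


@dataclass
class LCAFit:
    """Converged step-1 fit: the frozen input of all step-2 analyses."""

    measurement: MeasurementModel
    weights: np.ndarray
    loglik: float
    n_params: int
    n_records: int
    n_persons: int
    converged: bool
    n_starts_used: int
    best_start_seed: int
    loglik_path: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)

    @property
    def K(self) -> int:
        return self.measurement.K

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "beta0": self.measurement.beta0.tolist(),
            "delta": self.measurement.delta.tolist(),
            "class_order": self.measurement.class_order.tolist(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "n_records": self.n_records,
            "n_persons": self.n_persons,
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
            "best_start_seed": self.best_start_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LCAFit":
        meas = MeasurementModel(np.array(d["beta0"]), np.array(d["delta"]),
                                np.array(d["class_order"]))
        return cls(meas, np.array(d["weights"]), d["loglik"], d["n_params"],
                   d["n_records"], d["n_persons"], d["converged"],
                   d["n_starts_used"], d["best_start_seed"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LCAFit":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def measurement_from_probs(emissions: np.ndarray,
                           delta: np.ndarray | float = 0.0,
                           weights: np.ndarray | None = None,
                           clip: float = 1e-12) -> LCAFit:
    """Build a (pseudo-)fit directly from emission probabilities.

    Useful for two-step analyses with a known measurement model and for the
    degenerate 0/1-emission constructions used in closed-form checks.
    """
    p = np.clip(np.atleast_2d(np.asarray(emissions, dtype=float)), clip, 1 - clip)
    K, J = p.shape
    delta = np.full(J, float(delta)) if np.isscalar(delta) else np.asarray(delta)
    w = np.full(K, 1.0 / K) if weights is None else np.asarray(weights, float)
    meas = MeasurementModel(_logit(p), delta)
    return LCAFit(meas, w, np.nan, (K - 1) + K * J, 0, 0, True, 0, -1)


# --------------------------------------------------------------------------
# Likelihood pieces
# --------------------------------------------------------------------------

def emission_logprob(meas: MeasurementModel, y: np.ndarray, c: int,
                     is_baseline: bool = False) -> float:
    """log p(y | class c) under conditional independence."""
    y = np.asarray(y)
    if y.shape != (meas.J,):
        raise ValidationError(f"y must have length J={meas.J}")
    if not np.isin(y, [0, 1]).all():
        raise ValidationError("y entries must be binary 0/1")
    logits = meas.beta0[c] + (meas.delta if is_baseline else 0.0)
    # log sigma(logits) and log sigma(-logits), numerically safe
    lp1 = -np.logaddexp(0.0, -logits)
    lp0 = -np.logaddexp(0.0, logits)
    return float(y @ lp1 + (1 - y) @ lp0)


def _pattern_logdens(beta0: np.ndarray, delta: np.ndarray, Yp: np.ndarray,
                     bp: np.ndarray) -> np.ndarray:
    """(P, K) log p(pattern | class), honoring the baseline flag."""
    out = np.empty((Yp.shape[0], beta0.shape[0]))
    for flag in (False, True):
        sel = bp == flag
        if not sel.any():
            continue
        logits = beta0 + (delta[None, :] if flag else 0.0)
        lp1 = -np.logaddexp(0.0, -logits)   # (K, J)
        lp0 = -np.logaddexp(0.0, logits)
        Ys = Yp[sel].astype(float)
        out[sel] = Ys @ lp1.T + (1.0 - Ys) @ lp0.T
    return out


def log_densities(meas: MeasurementModel, Y: np.ndarray,
                  is_baseline: np.ndarray) -> np.ndarray:
    """(n, K) per-record class-specific log-densities."""
    return _pattern_logdens(meas.beta0, meas.delta, np.asarray(Y),
                            np.asarray(is_baseline, dtype=bool))


# --------------------------------------------------------------------------
# EM
# --------------------------------------------------------------------------

def _aggregate_patterns(Y: np.ndarray, b: np.ndarray):
    arr = np.column_stack([Y.astype(np.int8), b.astype(np.int8)])
    pats, counts = np.unique(arr, axis=0, return_counts=True)
    return pats[:, :-1], pats[:, -1].astype(bool), counts.astype(float)


def _m_step_emissions(Yp, bp, w, resp, beta0, delta, fit_delta):
    """Maximize the expected complete-data emission likelihood.

    With no baseline offset the update is closed-form. With the offset the
    problem per indicator is a two-cell logistic model (class logit + shared
    baseline shift); it is solved by Newton iterations on aggregated
    sufficient statistics, vectorized over indicators via the Schur
    complement of the (diagonal + border) Hessian.
    """
    wr = resp * w[:, None]                     # (P, K)
    Nc = wr.sum(axis=0)                        # (K,)
    if not fit_delta:
        S1 = wr.T @ Yp                          # (K, J) weighted successes
        p = np.clip(S1 / np.maximum(Nc[:, None], 1e-300), *_PCLIP)
        return _logit(p), np.zeros_like(delta)
    m0, m1 = ~bp, bp
    N0 = wr[m0].sum(axis=0)                    # (K,)
    N1 = wr[m1].sum(axis=0)
    S0 = wr[m0].T @ Yp[m0]                     # (K, J)
    S1 = wr[m1].T @ Yp[m1]
    beta = beta0.copy()
    dlt = delta.copy()
    for _ in range(60):
        p0 = expit(beta)                       # (K, J)
        p1 = expit(beta + dlt[None, :])
        g_beta = (S0 - N0[:, None] * p0) + (S1 - N1[:, None] * p1)
        g_dlt = (S1 - N1[:, None] * p1).sum(axis=0)            # (J,)
        W0 = N0[:, None] * p0 * (1 - p0)
        W1 = N1[:, None] * p1 * (1 - p1)
        D = W0 + W1                            # (K, J) Hessian diagonal
        c = W1                                 # (K, J) beta-delta border
        d = W1.sum(axis=0)                     # (J,)
        D = np.maximum(D, 1e-12)
        s = np.maximum(d - (c * c / D).sum(axis=0), 1e-12)
        step_d = (g_dlt - (c * g_beta / D).sum(axis=0)) / s
        step_b = (g_beta - c * step_d[None, :]) / D
        step_d = np.clip(step_d, -4, 4)
        step_b = np.clip(step_b, -4, 4)
        dlt = dlt + step_d
        beta = beta + step_b
        if max(np.abs(step_b).max(), np.abs(step_d).max()) < 1e-10:
            break
    lim = _logit(np.array(_PCLIP))
    beta = np.clip(beta, lim[0], lim[1])
    dlt = np.clip(dlt, -lim[1], lim[1])
    return beta, dlt


def _pattern_logdens_batch(beta0, delta, Yp, bp):
    """Batched over start sets: beta0 (S,K,J), delta (S,J) -> (S,P,K)."""
    S, K, J = beta0.shape
    out = np.empty((S, Yp.shape[0], K))
    Yf = Yp.astype(float)
    for flag in (False, True):
        sel = bp == flag
        if not sel.any():
            continue
        logits = beta0 + (delta[:, None, :] if flag else 0.0)
        lp1 = -np.logaddexp(0.0, -logits)
        lp0 = -np.logaddexp(0.0, logits)
        out[:, sel, :] = (np.einsum("pj,skj->spk", Yf[sel], lp1) +
                          np.einsum("pj,skj->spk", 1.0 - Yf[sel], lp0))
    return out


def _m_step_emissions_batch(Yp, bp, w, resp, beta0, delta, fit_delta):
    """Batched emission M-step; resp (S,P,K)."""
    Yf = Yp.astype(float)
    wr = resp * w[None, :, None]
    Nc = wr.sum(axis=1)                                  # (S,K)
    if not fit_delta:
        S1 = np.einsum("spk,pj->skj", wr, Yf)
        p = np.clip(S1 / np.maximum(Nc[:, :, None], 1e-300), *_PCLIP)
        return _logit(p), np.zeros_like(delta)
    m0, m1 = ~bp, bp
    N0 = wr[:, m0].sum(axis=1)
    N1 = wr[:, m1].sum(axis=1)
    S0 = np.einsum("spk,pj->skj", wr[:, m0], Yf[m0])
    S1s = np.einsum("spk,pj->skj", wr[:, m1], Yf[m1])
    beta = beta0.copy()
    dlt = delta.copy()
    for _ in range(60):
        p0 = expit(beta)
        p1 = expit(beta + dlt[:, None, :])
        g_beta = (S0 - N0[..., None] * p0) + (S1s - N1[..., None] * p1)
        g_dlt = (S1s - N1[..., None] * p1).sum(axis=1)   # (S,J)
        W0 = N0[..., None] * p0 * (1 - p0)
        W1 = N1[..., None] * p1 * (1 - p1)
        D = np.maximum(W0 + W1, 1e-12)
        c = W1
        d = W1.sum(axis=1)
        s = np.maximum(d - (c * c / D).sum(axis=1), 1e-12)
        step_d = np.clip((g_dlt - (c * g_beta / D).sum(axis=1)) / s, -4, 4)
        step_b = np.clip((g_beta - c * step_d[:, None, :]) / D, -4, 4)
        dlt = dlt + step_d
        beta = beta + step_b
        if max(np.abs(step_b).max(), np.abs(step_d).max()) < 1e-10:
            break
    lim = _logit(np.array(_PCLIP))
    return np.clip(beta, lim[0], lim[1]), np.clip(dlt, -lim[1], lim[1])


def _em_run_batch(Yp, bp, w, pi, beta0, delta, fit_delta, n_iter, tol):
    """EM over S start sets at once; frozen once a set converges.

    Returns (pi, beta0, delta, loglik (S,), converged (S,)).
    """
    N = w.sum()
    S = pi.shape[0]
    prev = np.full(S, -np.inf)
    ll_all = np.full(S, -np.inf)
    conv = np.zeros(S, dtype=bool)
    active = np.arange(S)
    for _ in range(n_iter):
        pa, ba, da = pi[active], beta0[active], delta[active]
        lb = _pattern_logdens_batch(ba, da, Yp, bp)
        a = lb + np.log(np.maximum(pa, 1e-300))[:, None, :]
        amax = a.max(axis=2)
        m = amax + np.log(np.exp(a - amax[:, :, None]).sum(axis=2))
        ll = m @ w
        ll_all[active] = ll
        done = np.isfinite(prev[active]) & \
            ((ll - prev[active]) <= tol * np.maximum(1.0, np.abs(ll)))
        conv[active[done]] = True
        prev[active] = ll
        keep = ~done
        if not keep.any():
            break
        resp = np.exp(a[keep] - m[keep][:, :, None])
        sub = active[keep]
        pi[sub] = np.einsum("spk,p->sk", resp, w) / N
        beta0[sub], delta[sub] = _m_step_emissions_batch(
            Yp, bp, w, resp, beta0[sub], delta[sub], fit_delta)
        active = sub
    # refresh loglik for sets whose parameters moved after their last eval
    if active.size:
        lb = _pattern_logdens_batch(beta0[active], delta[active], Yp, bp)
        ll_all[active] = logsumexp(
            lb + np.log(np.maximum(pi[active], 1e-300))[:, None, :],
            axis=2) @ w
    return pi, beta0, delta, ll_all, conv


def _em_run(Yp, bp, w, pi, beta0, delta, fit_delta, n_iter, tol,
            track=False):
    """Run EM; returns (pi, beta0, delta, loglik, n_done, converged, path)."""
    N = w.sum()
    prev = -np.inf
    path = [] if track else None
    converged = False
    it = 0
    for it in range(n_iter):
        lb = _pattern_logdens(beta0, delta, Yp, bp)
        a = lb + np.log(np.maximum(pi, 1e-300))[None, :]
        m = logsumexp(a, axis=1)
        ll = float(w @ m)
        if track:
            path.append(ll)
        resp = np.exp(a - m[:, None])
        pi = (w @ resp) / N
        beta0, delta = _m_step_emissions(Yp, bp, w, resp, beta0, delta,
                                         fit_delta)
        if np.isfinite(prev) and (ll - prev) <= tol * max(1.0, abs(ll)):
            converged = True
            prev = ll
            break
        prev = ll
    # loglik of the returned (post-M-step) parameters
    lb = _pattern_logdens(beta0, delta, Yp, bp)
    ll = float(w @ logsumexp(lb + np.log(np.maximum(pi, 1e-300))[None, :],
                             axis=1))
    if track:
        path.append(ll)
    return pi, beta0, delta, ll, it + 1, converged, \
        (np.array(path) if track else None)


def fit_lca(data: PanelDataset, K: int, n_starts: int = 64,
            start_iters: int = 250, max_iter: int = 5000, tol: float = 1e-8,
            seed: int = 0, baseline_effect: bool = True,
            n_final: int | None = None) -> LCAFit:
    """Fit the pooled latent class model by multi-start EM.

    Parameters follow the published estimation protocol: ``n_starts`` random
    start sets (default 64), each run for ``start_iters`` initial EM
    iterations (default 250); every start still making headway at the cut
    (relative improvement above 1e-6 per iteration, or the top ``n_final``
    if set) is continued until the relative log-likelihood change drops
    below ``tol``, and the overall best is returned. Continuing more than
    the single best-ranked set matters: solutions carrying a very small
    class approach their optimum slowly and can rank behind already-flat
    shallow optima at the initial-iteration cut, while the flat sets cost
    nothing to skip.

    ``baseline_effect`` adds the shared per-indicator baseline logit offset;
    it is automatically disabled (offset fixed at 0) when the data contain
    only one level of the baseline flag, where it would be unidentified.
    """
    if K < 1:
        raise ValidationError("K must be >= 1")
    if data.n_records == 0:
        raise ValidationError("data is empty")
    Y = data.y
    if np.isnan(Y.astype(float)).any():
        raise ValidationError("missing indicator values are not allowed")
    b = data.is_baseline
    Yp, bp, w = _aggregate_patterns(Y, b)
    P, J = Yp.shape[0], Yp.shape[1]
    fit_delta = bool(baseline_effect) and (bp.any() and (~bp).any())
    if K > P:
        warnings.warn(f"K={K} exceeds the {P} distinct response patterns; "
                      "expect a boundary solution", stacklevel=2)

    rng = np.random.default_rng(seed)
    start_seeds = rng.integers(0, 2**31 - 1, size=n_starts)
    # dispersed starts: random emission profiles + random weights.
    # (Random flat-simplex memberships average out to near-identical
    # marginal profiles and systematically miss small-class optima.)
    pi_b = np.empty((n_starts, K))
    beta_b = np.empty((n_starts, K, J))
    for i, s in enumerate(start_seeds):
        srng = np.random.default_rng(int(s))
        beta_b[i] = _logit(srng.uniform(0.05, 0.95, size=(K, J)))
        pi_b[i] = srng.dirichlet(np.ones(K))
    delta_b = np.zeros((n_starts, J))
    # initial-iteration phase, all start sets batched
    pi_b, beta_b, delta_b, ll_b, conv_b = _em_run_batch(
        Yp, bp, w, pi_b, beta_b, delta_b, fit_delta, start_iters, tol)
    # continue sets to convergence (all by default): small-class solutions
    # approach their optimum slowly and can trail shallow already-flat
    # optima at the cut, so top-1 continuation is not reliable
    if n_final is not None and n_final < n_starts:
        order = np.argsort(-ll_b)
        cont = np.zeros(n_starts, dtype=bool)
        cont[order[:max(1, n_final)]] = True
    else:
        cont = np.ones(n_starts, dtype=bool)
    cont &= ~conv_b
    if cont.any():
        idx = np.flatnonzero(cont)
        out = _em_run_batch(Yp, bp, w, pi_b[idx], beta_b[idx],
                            delta_b[idx], fit_delta, max_iter, tol)
        pi_b[idx], beta_b[idx], delta_b[idx], ll_b[idx], conv_b[idx] = out
    best = int(np.argmax(ll_b))
    best_seed = int(start_seeds[best])
    # final single-set polish at the full tolerance (records the path)
    pi, beta0, delta, ll, _, conv, path = _em_run(
        Yp, bp, w, pi_b[best], beta_b[best], delta_b[best], fit_delta,
        max_iter, tol, track=True)
    if not conv:
        warnings.warn("EM reached max_iter before meeting tolerance",
                      ConvergenceWarning, stacklevel=2)

    # deterministic labels: descending weight, tie-break on first indicator
    p_first = expit(beta0[:, 0])
    order = np.lexsort((-p_first, -pi))
    pi, beta0 = pi[order], beta0[order]
    meas = MeasurementModel(beta0, delta if fit_delta else np.zeros(J))
    n_params = (K - 1) + K * J + (J if fit_delta else 0)
    return LCAFit(meas, pi, ll, n_params, data.n_records, data.n_persons,
                  conv, n_starts, best_seed, loglik_path=path)


# --------------------------------------------------------------------------
# Posteriors and log-density export
# --------------------------------------------------------------------------

def class_log_densities(fit: LCAFit, data: PanelDataset) -> np.ndarray:
    """(n, K) log p(y_i | class c): the frozen step-1 -> step-2 currency."""
    if data.J != fit.measurement.J:
        raise ValidationError(
            f"indicator count mismatch: data J={data.J}, model J="
            f"{fit.measurement.J}")
    return log_densities(fit.measurement, data.y, data.is_baseline)


def posterior_classes(fit: LCAFit, data: PanelDataset) -> np.ndarray:
    """(n, K) posterior class-membership probabilities (rows sum to 1)."""
    ld = class_log_densities(fit, data)
    a = ld + np.log(np.maximum(fit.weights, 1e-300))[None, :]
    return np.exp(a - logsumexp(a, axis=1, keepdims=True))


def export_log_densities(fit: LCAFit, data: PanelDataset):
    """Copy of the panel table with ld_class1..K columns appended."""
    df = data.df.copy()
    ld = class_log_densities(fit, data)
    for c in range(fit.K):
        df[f"ld_class{c + 1}"] = ld[:, c]
    return df


def match_classes(est_emissions: np.ndarray,
                  ref_emissions: np.ndarray) -> np.ndarray:
    """Permutation aligning estimated classes to reference classes.

    Minimizes the total absolute difference between emission-probability
    profiles over all pairings. Returns ``perm`` such that estimated class
    ``perm[c]`` corresponds to reference class ``c``.
    """
    cost = np.abs(est_emissions[None, :, :] -
                  ref_emissions[:, None, :]).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(rows), dtype=int)
    perm[rows] = cols
    return perm


__all__ = [
    "MeasurementModel", "LCAFit", "measurement_from_probs",
    "emission_logprob", "log_densities", "fit_lca", "posterior_classes",
    "class_log_densities", "export_log_densities", "match_classes",
]
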