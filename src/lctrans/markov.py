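"""Step-2 latent Markov (latent transition) model over the step-1 classes.

The hidden chain has an initial distribution ``pi0`` and a time-homogeneous
transition matrix ``A`` per inter-wave interval; the measurement model is
frozen at its step-1 estimates and enters only through the class-specific
log-densities of each observed wave (the two-step scheme). A missing wave
contributes a unit emission term, so the chain marginalizes over it and a
missing wave carries no information about the adjacent transitions.

Standard errors are cluster-robust sandwich estimates, clustered on person,
computed from per-person observed-data scores (obtained via Fisher's
identity from the smoothed expected sufficient statistics) and a
finite-difference observed information. Step-1 sampling uncertainty is not
propagated (documented limitation of the plain two-step variance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConvergenceWarning, ValidationError
from .lca import LCAFit, class_log_densities
from .panel import CLASS_LABELS, PanelDataset

_TINY = 1e-300


# --------------------------------------------------------------------------
# Forward-backward
# --------------------------------------------------------------------------

@dataclass
class FBResult:
    loglik: np.ndarray     # (n,) per-person log-likelihood
    gamma: np.ndarray      # (n, T, K) smoothed state marginals
    xi: np.ndarray         # (n, T-1, K, K) pairwise transition posteriors


def forward_backward(pi0: np.ndarray, A: np.ndarray, logdens: np.ndarray,
                     mask: np.ndarray | None = None) -> FBResult:
    """Scaled forward-backward over latent classes.

    Parameters
    ----------
    pi0
        (K,) initial distribution.
    A
        Transition matrix: (K, K) time-homogeneous, or (n, T-1, K, K) for
        person- and interval-specific matrices (covariate models).
    logdens
        (T, K) for a single person or (n, T, K): per-wave class-specific
        log-densities. Waves masked out contribute a unit emission term.
    mask
        (T,) or (n, T) boolean, True = observed. Default: all observed.
    """
    logdens = np.asarray(logdens, dtype=float)
    single = logdens.ndim == 2
    if single:
        logdens = logdens[None]
    n, T, K = logdens.shape
    if T < 1:
        raise ValidationError("sequence must have at least one wave")
    if mask is None:
        mask = np.ones((n, T), dtype=bool)
    else:
        mask = np.atleast_2d(np.asarray(mask, dtype=bool))
    if not mask.any(axis=1).all():
        raise ValidationError("every person needs at least one observed wave")
    A = np.asarray(A, dtype=float)
    hom = A.ndim == 2

    ld = np.where(mask[:, :, None], logdens, 0.0)
    m = ld.max(axis=2, keepdims=True)
    B = np.exp(ld - m)                              # (n, T, K), scaled

    alpha = np.empty((n, T, K))
    c = np.empty((n, T))
    a = pi0[None, :] * B[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, T):
        pred = alpha[:, t - 1] @ A if hom else \
            np.einsum("nk,nkl->nl", alpha[:, t - 1], A[:, t - 1])
        a = pred * B[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t, None]

    beta = np.empty((n, T, K))
    beta[:, T - 1] = 1.0
    xi = np.empty((n, T - 1, K, K))
    for t in range(T - 2, -1, -1):
        bb = B[:, t + 1] * beta[:, t + 1]           # (n, K)
        At = A if hom else A[:, t]
        beta[:, t] = (bb @ At.T if hom else
                      np.einsum("nl,nkl->nk", bb, At)) / c[:, t + 1, None]
        xi[:, t] = (alpha[:, t, :, None] *
                    (At[None] if hom else At) *
                    bb[:, None, :] / c[:, t + 1, None, None])

    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    loglik = np.log(c).sum(axis=1) + m.sum(axis=(1, 2))
    if single:
        return FBResult(loglik[0], gamma[0], xi[0])
    return FBResult(loglik, gamma, xi)


# --------------------------------------------------------------------------
# Data layout
# --------------------------------------------------------------------------

def sequence_log_densities(data: PanelDataset,
                           measurement: LCAFit | None = None,
                           log_density_values: np.ndarray | None = None):
    """Arrange per-record class log-densities into (n, T, K) + mask.

    Either a frozen step-1 fit or precomputed per-record log-density values
    (e.g. reimported ld_class* columns) must be supplied. Wave-0 records use
    the baseline-adjusted densities.
    """
    if log_density_values is None:
        if measurement is None:
            raise ValidationError("need a measurement fit or log densities")
        ld_rec = class_log_densities(measurement, data)
    else:
        ld_rec = np.asarray(log_density_values, dtype=float)
        if ld_rec.shape[0] != data.n_records:
            raise ValidationError("log density rows must match records")
    K = ld_rec.shape[1]
    T = data.n_waves
    pid, persons = pd.factorize(data.df["person_id"], sort=True)
    n = len(persons)
    ld = np.zeros((n, T, K))
    mask = np.zeros((n, T), dtype=bool)
    wv = data.wave
    ld[pid, wv] = ld_rec
    mask[pid, wv] = True
    return ld, mask, persons


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------

@dataclass
class MarkovFit:
    """Initial distribution and transition matrix with clustered SEs."""

    pi0: np.ndarray
    A: np.ndarray
    loglik: float
    se_pi0: np.ndarray | None
    se_A: np.ndarray | None
    n_persons: int
    n_transitions_informative: int
    converged: bool
    measurement_source: LCAFit | None = None
    loglik_path: np.ndarray = field(default=None, repr=False)
    expected_origin_counts: np.ndarray | None = None

    @property
    def K(self) -> int:
        return self.pi0.shape[0]


def _em_markov(ld, mask, pi0, A, max_iter, tol, track=False):
    prev = -np.inf
    path = [] if track else None
    conv = False
    fb = None
    for _ in range(max_iter):
        fb = forward_backward(pi0, A, ld, mask)
        ll = float(fb.loglik.sum())
        if track:
            path.append(ll)
        pi0 = fb.gamma[:, 0].mean(axis=0)
        pi0 = np.maximum(pi0, 0)
        pi0 /= pi0.sum()
        num = fb.xi.sum(axis=(0, 1))
        A = num / np.maximum(num.sum(axis=1, keepdims=True), _TINY)
        if np.isfinite(prev) and (ll - prev) <= tol * max(1.0, abs(ll)):
            conv = True
            break
        prev = ll
    fb = forward_backward(pi0, A, ld, mask)
    ll = float(fb.loglik.sum())
    if track:
        path.append(ll)
    return pi0, A, ll, conv, fb, (np.array(path) if track else None)


def _free_logits(pi0, A):
    """Pack (pi0, A) into unconstrained logits: last class / diagonal refs."""
    K = len(pi0)
    lp = np.log(np.maximum(pi0, _TINY))
    th_pi = lp[:-1] - lp[-1]
    lA = np.log(np.maximum(A, _TINY))
    th_A = np.array([np.delete(lA[a] - lA[a, a], a) for a in range(K)])
    return np.concatenate([th_pi, th_A.ravel()])


def _unpack_logits(theta, K):
    th_pi = np.append(theta[:K - 1], 0.0)
    pi0 = np.exp(th_pi - th_pi.max())
    pi0 /= pi0.sum()
    A = np.empty((K, K))
    rest = theta[K - 1:].reshape(K, K - 1)
    for a in range(K):
        row = np.insert(rest[a], a, 0.0)
        e = np.exp(row - row.max())
        A[a] = e / e.sum()
    return pi0, A


def _person_scores(theta, K, ld, mask):
    """Per-person observed-data scores via Fisher's identity, plus loglik."""
    pi0, A = _unpack_logits(theta, K)
    fb = forward_backward(pi0, A, ld, mask)
    n = ld.shape[0]
    s_pi = fb.gamma[:, 0, :K - 1] - pi0[None, :K - 1]
    mass = fb.xi.sum(axis=3)                    # (n, T-1, K)
    sA = fb.xi.sum(axis=1) - np.einsum("ntk,kl->nkl", mass, A)
    # drop the diagonal (reference) entry of each row
    keep = np.ones((K, K), dtype=bool)
    np.fill_diagonal(keep, False)
    s_A = sA[:, keep].reshape(n, K * (K - 1))
    return np.concatenate([s_pi, s_A], axis=1), float(fb.loglik.sum())


def _sandwich(theta, K, ld, mask, h=1e-5):
    """Cluster-robust covariance of the free logits."""
    scores, _ = _person_scores(theta, K, ld, mask)
    meat = scores.T @ scores
    p = len(theta)
    H = np.empty((p, p))
    for j in range(p):
        tp = theta.copy(); tp[j] += h
        tm = theta.copy(); tm[j] -= h
        sp, _ = _person_scores(tp, K, ld, mask)
        sm, _ = _person_scores(tm, K, ld, mask)
        H[:, j] = (sp.sum(axis=0) - sm.sum(axis=0)) / (2 * h)
    H = 0.5 * (H + H.T)
    Hinv = np.linalg.pinv(-H)
    return Hinv @ meat @ Hinv


def _prob_se(theta, K, V):
    """Delta-method SEs of pi0 and A entries from logit covariance."""
    pi0, A = _unpack_logits(theta, K)
    # pi0: d pi_c / d th_d = pi_c (I[c=d] - pi_d), free d < K-1
    Jp = pi0[:, None] * (np.eye(K)[:, :K - 1] - pi0[None, :K - 1])
    Vp = V[:K - 1, :K - 1]
    se_pi = np.sqrt(np.maximum(np.einsum("cd,de,ce->c", Jp, Vp, Jp), 0))
    se_A = np.zeros((K, K))
    off = K - 1
    for a in range(K):
        idx = np.arange(off + a * (K - 1), off + (a + 1) * (K - 1))
        Va = V[np.ix_(idx, idx)]
        free = [b for b in range(K) if b != a]
        Ja = np.empty((K, K - 1))
        for bi, b in enumerate(range(K)):
            for di, d in enumerate(free):
                Ja[bi, di] = A[a, b] * ((b == d) - A[a, d])
        se_A[a] = np.sqrt(np.maximum(
            np.einsum("bd,de,be->b", Ja, Va, Ja), 0))
    return se_pi, se_A


def fit_latent_markov(data: PanelDataset, measurement: LCAFit | None = None,
                      *, log_density_values: np.ndarray | None = None,
                      max_iter: int = 1000, tol: float = 1e-10,
                      init: tuple[np.ndarray, np.ndarray] | None = None,
                      seed: int | None = None,
                      compute_se: bool = True) -> MarkovFit:
    """Estimate (pi0, A) by EM with the measurement model frozen.

    The step-1 measurement parameters are never updated; each record enters
    only through its class-specific log-densities (baseline offset applied
    at wave 0). ``init`` overrides the default initialization
    (posterior-based pi0, diagonally dominant A); passing ``seed`` draws a
    random initialization instead, for multi-start stability checks.
    """
    ld, mask, persons = sequence_log_densities(
        data, measurement, log_density_values)
    n, T, K = ld.shape
    if init is not None:
        pi0, A = np.asarray(init[0], float).copy(), np.asarray(init[1], float).copy()
    elif seed is not None:
        rng = np.random.default_rng(seed)
        pi0 = rng.dirichlet(np.ones(K))
        A = rng.dirichlet(np.ones(K), size=K)
    else:
        w0 = ld[:, 0] - ld[:, 0].max(axis=1, keepdims=True)
        w0 = np.exp(w0)
        w0 /= w0.sum(axis=1, keepdims=True)
        pi0 = w0.mean(axis=0)
        A = 0.8 * np.eye(K) + 0.2 / K

    pi0, A, ll, conv, fb, path = _em_markov(ld, mask, pi0, A, max_iter, tol,
                                            track=True)
    if not conv:
        warnings.warn("latent Markov EM reached max_iter before tolerance",
                      ConvergenceWarning, stacklevel=2)
    # informative transitions: consecutive observed wave pairs
    n_inf = int((mask[:, 1:] & mask[:, :-1]).sum())
    pair = (mask[:, 1:] & mask[:, :-1])
    origin_counts = (fb.xi.sum(axis=3) * pair[:, :, None]).sum(axis=(0, 1))

    se_pi = se_A = None
    if compute_se:
        theta = _free_logits(pi0, A)
        V = _sandwich(theta, K, ld, mask)
        se_pi, se_A = _prob_se(theta, K, V)
    return MarkovFit(pi0, A, ll, se_pi, se_A, n, n_inf, conv,
                     measurement_source=measurement, loglik_path=path,
                     expected_origin_counts=origin_counts)


def transition_table(fit: MarkovFit, labels: list[str] | None = None,
                     decimals: int = 1) -> pd.DataFrame:
    """Transition matrix in percentages, labeled in prevalence order."""
    K = fit.K
    if labels is None:
        labels = list(CLASS_LABELS[:K]) if K <= len(CLASS_LABELS) else \
            [f"class {c + 1}" for c in range(K)]
    tab = pd.DataFrame(np.round(100.0 * fit.A, decimals),
                       index=labels, columns=labels)
    tab.index.name = "from \\ to"
    return tab


__all__ = ["FBResult", "forward_backward", "sequence_log_densities",
           "MarkovFit", "fit_latent_markov", "transition_table"]
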