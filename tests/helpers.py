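"""Independent oracles and small builders shared by the test modules."""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.special import logsumexp

import lctrans as lt


def brute_force_chain_loglik(pi0, A, logdens, mask=None):
    """Log-likelihood of one person's sequence by exhaustive path summation.

    Enumerates all K^T latent paths; masked (missing) waves contribute no
    emission term. Independent of the forward-backward implementation.
    """
    logdens = np.asarray(logdens, dtype=float)
    T, K = logdens.shape
    if mask is None:
        mask = np.ones(T, dtype=bool)
    lpi = np.log(pi0)
    lA = np.log(np.maximum(A, 1e-300))
    terms = []
    for path in product(range(K), repeat=T):
        lp = lpi[path[0]]
        for t in range(1, T):
            lp += lA[path[t - 1], path[t]]
        for t in range(T):
            if mask[t]:
                lp += logdens[t, path[t]]
        terms.append(lp)
    return float(logsumexp(terms))


def bernoulli_product_logprob(p, y):
    """Direct product-of-Bernoullis oracle for one emission vector."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.sum(np.log(np.where(y == 1, p, 1 - p))))


def two_class_config(J=6, p_lo=0.15, p_hi=0.7, w=(0.6, 0.4), seed=0):
    """Well-separated two-class generator for quick mixture tests."""
    emissions = np.vstack([np.full(J, p_lo), np.full(J, p_hi)])
    return lt.GeneratorConfig(
        n_individuals=100, n_waves=2, pi0=np.asarray(w, float),
        A=np.array([[0.9, 0.1], [0.2, 0.8]]), emissions=emissions,
        baseline_delta=0.0, retention=np.array([1.0]), seed=seed)


def three_state_chain_config(seed=0, n=800):
    """Moderate three-class longitudinal generator for machinery tests."""
    emissions = np.array([
        [0.05, 0.05, 0.10, 0.05, 0.10, 0.05],
        [0.50, 0.45, 0.55, 0.50, 0.45, 0.55],
        [0.90, 0.85, 0.90, 0.85, 0.90, 0.85],
    ])
    A = np.array([[0.85, 0.10, 0.05],
                  [0.15, 0.75, 0.10],
                  [0.10, 0.20, 0.70]])
    return lt.GeneratorConfig(
        n_individuals=n, n_waves=4, pi0=np.array([0.6, 0.3, 0.1]),
        A=A, emissions=emissions, baseline_delta=0.0,
        retention=np.ones(3), seed=seed)
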