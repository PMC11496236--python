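"""Parameter-recovery experiments on calibrated synthetic cohorts.

The published estimates cannot be recomputed from the original (non-public)
survey, so the package's headline checks are recovery experiments: simulate
cohorts from the calibrated generator, run the estimation pipeline, and
compare the estimates with the generating values. These drivers are shared
by the test suite, the acceptance script and the analysis scripts.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import datagen
from .lca import fit_lca, match_classes
from .markov import fit_latent_markov


def _replicate_seeds(master_seed: int, n: int) -> np.ndarray:
    rng = np.random.default_rng(master_seed)
    return rng.integers(0, 2**31 - 1, size=2 * n).reshape(n, 2)


def pooled_lca_recovery(n_seeds: int = 25, master_seed: int = 0,
                        n_records: int = 20574, K: int = 4,
                        n_starts: int = 16, start_iters: int = 250,
                        tol: float = 1e-8) -> dict:
    """Recover the class proportions from pooled iid records.

    Simulates ``n_records`` independent records with the calibrated class
    prevalences and default emissions (no baseline effect), fits the
    K-class model, aligns the estimated classes to the generator's by
    emission-profile matching, and averages the estimated proportions over
    ``n_seeds`` replicate seeds.
    """
    cfg = datagen.default_cohort_config(seed=0, baseline_delta=0.0)
    props = np.zeros((n_seeds, cfg.K))
    for i, (s_gen, s_fit) in enumerate(_replicate_seeds(master_seed, n_seeds)):
        data = datagen.simulate_pooled(cfg, n_records, seed=int(s_gen))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_lca(data, K, n_starts=n_starts,
                          start_iters=start_iters, tol=tol, seed=int(s_fit))
        perm = match_classes(fit.measurement.emission_probs(False),
                             cfg.emissions)
        props[i] = fit.weights[perm]
    return {"mean_proportions": props.mean(axis=0),
            "proportions": props,
            "true_proportions": cfg.pi0,
            "n_records": n_records, "n_seeds": n_seeds}


def cohort_markov_recovery(n_seeds: int = 25, master_seed: int = 0,
                           K: int = 4, n_starts: int = 64,
                           start_iters: int = 250,
                           lca_tol: float = 1e-8,
                           markov_tol: float = 1e-9,
                           markov_max_iter: int = 3000) -> dict:
    """Recover the transition matrix via the full two-step pipeline.

    Simulates the calibrated four-wave cohort (n = 6646, quota attrition
    reproducing the printed wave sizes, baseline logit offset 0.5), fits
    the pooled K-class measurement model with the baseline direct effect,
    freezes it, fits the latent Markov model, aligns classes to the
    generator by emission-profile matching, and averages the estimated
    transition matrices over replicate seeds.
    """
    cfg = datagen.default_cohort_config(seed=0)
    A_hat = np.zeros((n_seeds, cfg.K, cfg.K))
    pi_hat = np.zeros((n_seeds, cfg.K))
    for i, (s_gen, s_fit) in enumerate(_replicate_seeds(master_seed, n_seeds)):
        data = datagen.simulate_panel(cfg, seed=int(s_gen))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_lca(data, K, n_starts=n_starts,
                          start_iters=start_iters, tol=lca_tol,
                          seed=int(s_fit))
            mfit = fit_latent_markov(data, fit, tol=markov_tol,
                                     max_iter=markov_max_iter,
                                     compute_se=False)
        perm = match_classes(fit.measurement.emission_probs(False),
                             cfg.emissions)
        A_hat[i] = mfit.A[np.ix_(perm, perm)]
        pi_hat[i] = mfit.pi0[perm]
    return {"mean_A": A_hat.mean(axis=0), "A_hats": A_hat,
            "mean_pi0": pi_hat.mean(axis=0),
            "true_A": cfg.A, "true_pi0": cfg.pi0, "n_seeds": n_seeds}


__all__ = ["pooled_lca_recovery", "cohort_markov_recovery"]
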