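"""Step-2: latent Markov model of three-year class transitions.

Freezes the step-1 measurement fit (results/lca_fit.json), estimates the
initial class distribution and the time-homogeneous transition matrix with
cluster-robust standard errors, and prints the percentage transition table
next to the generator truth.

Run:  python analysis/04_fit_transitions.py
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import lctrans as lt

out = Path("results")
data = lt.read_panel(out / "cohort.csv")
truth = lt.config_from_yaml(out / "generator.yaml")
fit = lt.LCAFit.from_json(out / "lca_fit.json")

mfit = lt.fit_latent_markov(data, fit)
perm = lt.match_classes(fit.measurement.emission_probs(False),
                        truth.emissions)
inv = np.argsort(perm)

print(f"loglik = {mfit.loglik:.2f}, persons = {mfit.n_persons}, "
      f"informative transitions = {mfit.n_transitions_informative}")
labels = list(lt.CLASS_LABELS)
A = 100 * mfit.A[np.ix_(perm, perm)]
seA = 100 * mfit.se_A[np.ix_(perm, perm)]
print("estimated transition matrix (%, cluster-robust SE):")
for a in range(4):
    cells = "  ".join(f"{A[a, b]:5.1f} ({seA[a, b]:4.1f})"
                      for b in range(4))
    print(f"  {labels[a]:<18} {cells}")
print("generator truth (%):")
print(pd.DataFrame(np.round(100 * truth.A, 1), index=labels,
                   columns=labels).to_string())
print("expected informative transitions per origin class:",
      np.round(mfit.expected_origin_counts[perm], 1))

table = lt.transition_table(
    lt.MarkovFit(mfit.pi0[perm], mfit.A[np.ix_(perm, perm)], mfit.loglik,
                 mfit.se_pi0[perm], seA / 100, mfit.n_persons,
                 mfit.n_transitions_informative, mfit.converged))
table.to_csv(out / "transitions_pct.csv")
with open(out / "markov_fit.json", "w") as fh:
    json.dump({"pi0": mfit.pi0[perm].tolist(),
               "A": mfit.A[np.ix_(perm, perm)].tolist(),
               "se_A": (seA / 100).tolist(),
               "loglik": mfit.loglik}, fh, indent=1)
print(f"wrote {out/'transitions_pct.csv'} and {out/'markov_fit.json'}")
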