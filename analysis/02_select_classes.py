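"""Choose the number of latent classes on the pooled synthetic records.

Fits 1-5 class models to results/pooled.csv (run 01 first), computes the
information criteria, bivariate residuals and - with --bootstrap B > 0 -
the bootstrap goodness-of-fit and likelihood-ratio p values, and writes the
selection table. On cohorts generated with the calibrated four-class
defaults the criteria should point at K = 4.

Run:  python analysis/02_select_classes.py [--seed 0] [--bootstrap 19]
"""

import argparse
from pathlib import Path

import lctrans as lt

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--bootstrap", type=int, default=0,
                help="bootstrap replicates per K (0 = information criteria "
                     "and BVR only)")
ap.add_argument("--k-max", type=int, default=5)
args = ap.parse_args()

out = Path("results")
data = lt.read_panel(out / "pooled.csv")
report = lt.select_k(data, k_min=1, k_max=args.k_max, n_starts=16,
                     start_iters=100, seed=args.seed,
                     bootstrap_B=args.bootstrap, criterion="AIC3")
print(report)
report.table.to_csv(out / "selection.csv", index=False)
print(f"wrote {out/'selection.csv'}")
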