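# Methods

## The model

`lctrans` implements a two-step latent-class / latent-transition analysis of
panel data on eight binary 12-month mood and anxiety disorder indicators
(major depression `mdd`, dysthymia `dys`, bipolar disorder `bip`, panic
disorder `pan`, agoraphobia `ago`, social phobia `soc`, specific phobia
`spe`, generalized anxiety disorder `gad`).

**Step 1 — measurement.** All person-waves are pooled ("each wave is a
case") and modelled as a K-class mixture with conditionally independent
Bernoulli indicators,

    P(y | class c, baseline b) = prod_j sigma(beta0[c,j] + b * delta[j])^y_j
                                 * (1 - sigma(...))^(1 - y_j),

where `b` flags the first wave. The shared per-indicator offset `delta`
captures measurement non-invariance of the baseline interview (a
lifetime-frame instrument that elevates observed 12-month prevalences at
wave 0) while leaving class membership untouched, so class proportions stay
comparable across waves. `delta` is shared across classes: a class-specific
offset would be estimated from a handful of records in the rare classes and
is available only behind a flag.

**Step 2 — structure.** The step-1 parameters are frozen. Every structural
model consumes the records only through their class-specific log-densities
`log P(y_i | c)` (the baseline offset applied at wave 0), which is the
two-step scheme of Bakk and Kuha: it avoids the large classification errors
that modal assignment would produce for classes with prevalences below 2%.
Three structural analyses are provided:

* a latent Markov chain with initial distribution `pi0` and a single
  time-homogeneous K x K transition matrix `A` per ~3-year inter-wave
  interval, fitted by EM over `(pi0, A)` with forward-backward smoothing;
* posterior-weighted class profiles of background covariates with Wald
  equality tests, variance clustered on person;
* transition models in which the logit of moving from origin class *a* to
  destination *b* between waves T and T+1 is `alpha[a,b] + beta[a,b] *
  x_T`, with *staying in a* the reference destination, one covariate per
  run, missing covariate values mean-imputed.

Missing waves (monotone attrition) contribute a unit emission term, so the
chain marginalizes over them: a missing wave carries no information about
its adjacent transitions, and a person observed at a single wave still
informs `pi0`.

## Estimation and numerics

* **EM on response patterns.** The pooled likelihood depends on the data
  only through the (at most 2^J x 2) distinct response-pattern /
  baseline-flag combinations; EM runs on pattern counts, making a fit on
  20 574 records cost the same as one on a few hundred.
* **Baseline-offset M-step.** With `delta` in the model the emission
  update has no closed form; it is solved by Newton iterations on
  aggregated sufficient statistics (per indicator: weighted successes and
  totals by class and baseline flag), vectorized across indicators through
  the Schur complement of the bordered-diagonal Hessian.
* **Multi-start protocol.** `n_starts` random initializations (default 64)
  run `start_iters` EM steps each (default 250); every set still
  unconverged at the cut is then continued until the relative change drops
  below 1e-8 (cap 5000 iterations) and the best is returned. All sets run
  batched over the shared pattern data, so the continuation is cheap.
  Continuing only the single best-ranked set is unreliable here: solutions
  carrying a 0.6%-class approach their optimum slowly and, at the
  250-iteration cut, can trail shallow already-flat optima by a fraction
  of a log-likelihood unit while the converged gap is tens of units.
  Starts draw random emission profiles — the logit of U(0.05, 0.95) per
  class and indicator — plus Dirichlet(1) weights. Random per-pattern
  membership simplices were tried first and rejected: after one M-step all
  classes collapse to near-identical marginal profiles and systematically
  miss the small-class global optimum; dispersed emission starts do not.
* **Labels.** Classes are relabelled by descending weight (tie-break on
  the first indicator's emission), making labels deterministic. For
  recovery experiments, estimated classes are aligned to generator classes
  by minimal total absolute emission-profile difference (Hungarian
  assignment).
* **Boundaries.** Emission probabilities are clipped to
  [1e-6, 1 - 1e-6] during EM; expected bootstrap/BVR cell counts below
  1e-12 are clipped and flagged.
* **Markov EM.** Initialization: `pi0` from the average wave-0 posterior,
  `A` diagonally dominant (0.8 I + 0.2/K); convergence at relative change
  1e-10. On well-separated data 20 random restarts agree to 1e-6 in
  log-likelihood (tested), so a single start is the default.
* **Transition-covariate models** are maximized directly by L-BFGS on the
  observed-data log-likelihood, with exact gradients from Fisher's
  identity (expected complete-data score via forward-backward).
* **Variances.** All structural standard errors are cluster-robust
  sandwich estimates, clustered on person: per-person observed-data scores
  (Fisher identity) for the meat, a central-finite-difference observed
  information for the bread, delta method back to the probability scale.
  Step-1 sampling uncertainty is *not* propagated into step-2 standard
  errors (the plain two-step variance); this is a known limitation.

## Model selection and diagnostics

AIC, AIC3 (penalty 3 per parameter) and BIC, each preferring the smallest
value; the BIC sample size is the number of pooled records (each wave is a
case), switchable to persons. The likelihood-ratio goodness-of-fit
statistic L2 is compared to a parametric bootstrap (add-one rule
p = (1 + #{L2_b >= L2_obs}) / (B + 1), so p is never 0); the bootstrap
likelihood-ratio test of K against K-1 simulates from the K-1 fit and
refits both models per replicate with a reduced multi-start budget
(default 8 x 50, configurable); non-convergent replicates are excluded,
more than 20% exclusions is a hard error.

The bivariate residual (BVR) for an indicator pair is a Pearson X^2
comparing the observed 2 x 2 table with the table expected from
record-level posteriors (`sum_c w_ic p_cj p_ck` and complements), divided
by the table's degrees of freedom; for an external variable (e.g. the wave
number 0-3) the analogous L x 2 table is used with df = L - 1. This
preserves the conventional "below 3 or 4 is acceptable" reading for
misfit. Note that the statistic is *not* chi-square calibrated under the
null: posterior weighting shrinks its typical null value to roughly 0.4-0.7
rather than the 0.2-0.5 of the original software's proprietary variant, so
"all wave BVRs below 1" is a stricter event here than in the published
software (see Limitations).

The design effect is the ratio of the cluster-robust to the naive sandwich
variance of the posterior-mean class-proportion estimating equations,
averaged over the K - 1 free proportions. It is exactly 1 when every
person contributes one record and exactly doubles under within-person
record duplication. Monte Carlo validation (300 replicate cohorts of a
3-state chain) shows the clustered variance tracks the empirical
replication variance while the naive one understates it. Under the
calibrated generator's strong persistence the true design effect of the
pooled class proportions is around 1.9 — repeated observations of a
persistent state are genuinely informative-redundant — so a value well
above 1 on simulated cohorts is expected behaviour of this definition, not
misfit.

## The synthetic cohort generator

The generator is calibrated so that its defaults *are* the published study
conditions:

| quantity | default | source |
|---|---|---|
| cohort size / waves | 6646 persons, 4 waves | printed wave sizes |
| retention | 0.7979 / 0.8708 / 0.8677 | reproduces 5303 / 4618 / 4007 |
| class prevalences | 94.1 / 3.6 / 1.8 / 0.6 %, normalized | printed (sum 100.1 by rounding) |
| transition matrix | printed entries, rows normalized | printed stay/switch percentages |
| baseline offset | 0.5 logit on every indicator | direction printed, size not |
| emissions | see `default_emissions()` | qualitative class descriptions |

Two printed transition-matrix rows are incomplete. The healthy row prints
97.6 (stay) and 1.9 (to depressed-worried) with "even lower" remainders:
the remaining 0.5 pp is split 0.4 (fear) / 0.1 (high-comorbidity). The
depressed-worried row prints 39.7 (healthy), 36.5 (stay) and "more than
5%" to high-comorbidity: that entry is set to 5.6 (the value printed for
the fear row) and the remainder, 18.2, goes to fear. These two choices are
calibration decisions, not published values. A consequence worth knowing:
the printed initial prevalences are **not** the stationary distribution of
the resulting matrix (the depressed-worried outflow into fear/
high-comorbidity exceeds the return flow), so simulated class composition
drifts slightly across waves — about −0.6 pp per wave for the healthy
class. Experiments that need a genuinely time-invariant cohort (e.g. the
wave-BVR diagnostic) start the chain at the stationary distribution of the
transition matrix instead.

Attrition is monotone and class-independent by default — the estimators
assume ignorable missingness — with class- or covariate-dependent dropout
available through the covariate machinery if needed. Retention is
implemented either as per-person Bernoulli draws or as fixed per-wave
quotas; quotas reproduce the printed wave sizes (and hence the 20 574
total) exactly and are the default. Covariates are drawn from
class-conditional distributions (binary or normal), optionally
time-invariant (drawn once per person) and optionally masked at a missing
rate; a covariate may also shift the transition logits of the latent
chain, which is how "predictor of transition" scenarios are generated.

What the generator does **not** emulate: the diagnostic interview's skip
logic and hierarchy-free DSM-IV algorithms (indicators are generated
directly), survey weighting and household sampling, non-ignorable
attrition, and any time trend in the measurement model beyond the wave-0
offset. Passing recovery tests therefore show that the estimation
machinery inverts the assumed data-generating process at the published
scale — not that the published substantive estimates are correct.

## Recovery experiments (the package's headline checks)

Because the original survey data are not public, the published tables
cannot be re-estimated; instead the pipeline must recover the generator's
truth at the published scale:

1. **Pooled prevalences.** 25 replicates of 20 574 iid records, K = 4
   with 16 starts; mean estimated proportions match the calibrated
   prevalences to about 0.1-0.2 pp.
2. **Transitions.** 25 replicate cohorts through the full two-step
   pipeline (step 1 at the published 64 x 250 protocol); mean estimated
   transition probabilities match truth to well under 1 pp for the
   healthy and depressed-worried origin rows. The fear-origin diagonal
   shows a reproducible −1.5 to −2.5 pp deviation (mirrored by
   +1 to +2 pp into high-comorbidity): with the measurement model fixed
   at its *true* values the same Markov EM recovers every row to about
   1 pp, so the gap is measurement-noise attenuation of the plain
   two-step — the fear emission profile is estimated from only ~370
   pooled records and its error lets fear and high-comorbidity posteriors
   mix. This is a property of the estimator at the published class sizes,
   shared by any plain two-step implementation, and it is reported rather
   than patched.

## Known limitations

* Step-2 standard errors ignore step-1 estimation error.
* The BVR and design-effect formulas of the original closed-source
  software are unspecified; both are implemented under the documented
  definitions above and their null scales differ from that software
  (BVR null mean here ~0.6; design effect genuinely ~1.9 under Markov
  persistence where the published analysis reported 1.07 on real data).
* Binary indicators only; no ordinal/nominal emissions, no mover-stayer
  mixture, no continuous-time transitions.
* One covariate per transition model (by design, mirroring the exploratory
  published analysis); no multiple-testing correction beyond the stricter
  alpha, and both the p < 0.001 and p < 0.01 flags are reported because
  the published text and table notes disagree.
* Whether the original analysis re-estimated transition intercepts per
  covariate run is not stated; they are re-estimated here. Whether the
  baseline offset also entered the original Markov step is not stated; it
  is applied there (wave-0 densities use it), which keeps steps 1 and 2
  consistent.
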