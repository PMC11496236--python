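"""Synthetic cohort generator for latent-class / latent-transition analyses.

Generates person-wave panels of eight binary 12-month mood/anxiety disorder
indicators driven by a hidden first-order Markov chain over latent classes,
with

* a baseline measurement effect (indicator logits shifted upward at wave 0,
  emulating the lifetime-frame interview used at the first assessment),
* monotone attrition (binomial per-wave retention or fixed per-wave quotas),
* optional class-linked covariates, which may in turn shift the transition
  logits of the latent chain.

Defaults are calibrated to the published quantities of a four-wave Dutch
adult population cohort: class prevalences 94.1 / 3.6 / 1.8 / 0.6 %, wave
sizes 6646 / 5303 / 4618 / 4007 (20 574 person-wave records in total), and
the published three-year latent transition matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .panel import CLASS_LABELS, INDICATORS, PanelDataset

# --------------------------------------------------------------------------
# Published calibration constants
# --------------------------------------------------------------------------

#: Wave sample sizes of the reference cohort (T0..T3).
WAVE_SIZES = (6646, 5303, 4618, 4007)

#: Printed class prevalences, in percent (sum 100.1 due to rounding).
PRINTED_PREVALENCES = (94.1, 3.6, 1.8, 0.6)

#: Printed three-year transition matrix, in percent. Rows: origin class in
#: prevalence order (healthy, depressed-worried, fear, high-comorbidity).
#: The healthy row prints only the stay (97.6) and ->depressed-worried (1.9)
#: entries with "even lower" remainders (set 0.4 / 0.1 here); the
#: depressed-worried row prints stay 36.5, ->healthy 39.7 and ">5%" to the
#: high-comorbidity class (set 5.6, the value printed for the fear row), the
#: remainder going to the fear class.
PRINTED_TRANSITIONS = (
    (97.6, 1.9, 0.4, 0.1),
    (39.7, 36.5, 18.2, 5.6),
    (12.5, 14.7, 67.3, 5.6),
    (7.0, 11.1, 43.5, 38.4),
)


def _simplex(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / v.sum()


def default_prevalences() -> np.ndarray:
    """Printed class prevalences normalized to a proper simplex."""
    return _simplex(PRINTED_PREVALENCES)


def default_transition_matrix() -> np.ndarray:
    """Printed transition matrix with rows normalized to sum to one."""
    A = np.asarray(PRINTED_TRANSITIONS, dtype=float)
    return A / A.sum(axis=1, keepdims=True)


def default_retention() -> np.ndarray:
    """Per-wave retention probabilities reproducing the printed wave sizes."""
    n = np.asarray(WAVE_SIZES, dtype=float)
    return n[1:] / n[:-1]


def default_emissions() -> np.ndarray:
    """Default per-class indicator probabilities (follow-up waves).

    The published per-class indicator probabilities are not available; this
    profile matches the qualitative class descriptions (healthy: near-zero on
    everything; depressed-worried: mood disorders + GAD; fear: panic and
    phobias; high-comorbidity: elevated on all) while keeping the classes
    separable. Columns follow :data:`lctrans.panel.INDICATORS`
    (mdd, dys, bip, pan, ago, soc, spe, gad).
    """
    return np.array([
        # mdd   dys   bip   pan   ago   soc   spe   gad
        [0.01, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01],   # healthy
        [0.75, 0.30, 0.15, 0.10, 0.08, 0.12, 0.12, 0.35],   # depressed-worried
        [0.12, 0.08, 0.05, 0.35, 0.30, 0.55, 0.65, 0.12],   # fear
        [0.70, 0.50, 0.30, 0.55, 0.50, 0.60, 0.65, 0.55],   # high-comorbidity
    ])


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass
class CovariateSpec:
    """Class-conditional covariate for simulation.

    Parameters
    ----------
    name
        Column name in the generated panel.
    kind
        ``"binary"`` (class-conditional Bernoulli) or ``"normal"``
        (class-conditional mean, shared ``sd``).
    class_params
        Length-K vector: success probability (binary) or mean (normal)
        per latent class.
    sd
        Standard deviation for ``kind="normal"``.
    time_varying
        If False the value is drawn once per person (from the wave-0 class)
        and repeated across waves (e.g. sex, childhood abuse).
    missing_rate
        Probability that a generated value is blanked to missing.
    transition_effects
        Optional K x K matrix of transition-logit coefficients: the value at
        wave *t* shifts the logit of the *t -> t+1* transition from origin
        *a* to destination *b* by ``transition_effects[a, b] * x`` (the
        diagonal, i.e. staying, is the reference and must be zero).
    """

    name: str
    kind: str
    class_params: np.ndarray
    sd: float = 1.0
    time_varying: bool = True
    missing_rate: float = 0.0
    transition_effects: np.ndarray | None = None

    def __post_init__(self):
        self.class_params = np.asarray(self.class_params, dtype=float)
        if self.kind not in ("binary", "normal"):
            raise ValidationError(
                f"covariate {self.name!r}: unknown distribution kind {self.kind!r}")
        if self.kind == "binary" and (
                (self.class_params < 0).any() or (self.class_params > 1).any()):
            raise ValidationError(
                f"covariate {self.name!r}: binary class_params must lie in [0,1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError(
                f"covariate {self.name!r}: missing_rate must lie in [0,1)")
        if self.transition_effects is not None:
            eff = np.asarray(self.transition_effects, dtype=float)
            if np.abs(np.diag(eff)).max() > 0:
                raise ValidationError(
                    f"covariate {self.name!r}: transition_effects diagonal "
                    "(the stay reference) must be zero")
            self.transition_effects = eff


@dataclass
class GeneratorConfig:
    """All true parameters of the synthetic cohort.

    Defaults reproduce the published study conditions: four classes with the
    printed prevalences, the printed transition matrix, retention matching
    the printed wave sizes, and a baseline logit shift of 0.5 on every
    indicator.
    """

    n_individuals: int = WAVE_SIZES[0]
    n_waves: int = 4
    pi0: np.ndarray = field(default_factory=default_prevalences)
    A: np.ndarray = field(default_factory=default_transition_matrix)
    emissions: np.ndarray = field(default_factory=default_emissions)
    baseline_delta: np.ndarray | float = 0.5
    retention: np.ndarray = field(default_factory=default_retention)
    retention_mode: str = "quota"  # "quota" | "binomial"
    covariate_spec: list[CovariateSpec] = field(default_factory=list)
    seed: int = 0
    indicator_names: tuple[str, ...] = INDICATORS

    def __post_init__(self):
        self.pi0 = np.asarray(self.pi0, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.emissions = np.asarray(self.emissions, dtype=float)
        self.retention = np.asarray(self.retention, dtype=float)
        K = self.pi0.shape[0]
        J = self.emissions.shape[1]
        if isinstance(self.baseline_delta, (int, float)):
            self.baseline_delta = np.full(J, float(self.baseline_delta))
        else:
            self.baseline_delta = np.asarray(self.baseline_delta, dtype=float)
        self.validate()
        self.indicator_names = tuple(self.indicator_names[:J]) if len(
            self.indicator_names) >= J else tuple(
            f"y{j + 1}" for j in range(J))

    @property
    def K(self) -> int:
        return self.pi0.shape[0]

    @property
    def J(self) -> int:
        return self.emissions.shape[1]

    def validate(self) -> None:
        if self.n_waves < 2:
            raise ValidationError("n_waves: must be >= 2")
        if self.n_individuals < 1:
            raise ValidationError("n_individuals: must be >= 1")
        if (self.pi0 < 0).any() or abs(self.pi0.sum() - 1.0) > 1e-8:
            raise ValidationError("pi0: must be a probability vector summing to 1")
        if self.A.shape != (self.K, self.K):
            raise ValidationError("A: must be K x K")
        if (self.A < 0).any() or np.abs(self.A.sum(axis=1) - 1.0).max() > 1e-8:
            raise ValidationError("A: every row must sum to 1")
        if self.emissions.shape[0] != self.K:
            raise ValidationError("emissions: must have K rows")
        if (self.emissions < 0).any() or (self.emissions > 1).any():
            raise ValidationError("emissions: entries must lie in [0,1]")
        if self.baseline_delta.shape != (self.J,):
            raise ValidationError("baseline_delta: must have length J")
        if (self.baseline_delta < 0).any():
            raise ValidationError("baseline_delta: entries must be >= 0")
        if self.retention.shape != (self.n_waves - 1,):
            raise ValidationError("retention: must have length n_waves - 1")
        if (self.retention <= 0).any() or (self.retention > 1).any():
            raise ValidationError("retention: entries must lie in (0,1]")
        if self.retention_mode not in ("quota", "binomial"):
            raise ValidationError("retention_mode: must be 'quota' or 'binomial'")
        for spec in self.covariate_spec:
            if spec.class_params.shape[0] != self.K:
                raise ValidationError(
                    f"covariate {spec.name!r}: class_params must have length K")
            if spec.transition_effects is not None and \
                    spec.transition_effects.shape != (self.K, self.K):
                raise ValidationError(
                    f"covariate {spec.name!r}: transition_effects must be K x K")

    def with_(self, **kwargs) -> "GeneratorConfig":
        """Copy with fields replaced (validated)."""
        return replace(self, **kwargs)

    def expected_records(self) -> float:
        """E[number of person-wave records] = n * (1 + sum_t prod_{s<=t} r_s)."""
        cum = np.cumprod(self.retention)
        return float(self.n_individuals * (1.0 + cum.sum()))


def default_cohort_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Calibrated four-wave cohort configuration (published study conditions)."""
    return GeneratorConfig(seed=seed, **overrides)


# --------------------------------------------------------------------------
# Simulation
# --------------------------------------------------------------------------

def _emission_probs(config: GeneratorConfig, baseline: bool) -> np.ndarray:
    p = np.clip(config.emissions, 1e-12, 1 - 1e-12)
    if not baseline:
        return config.emissions
    logit = np.log(p / (1 - p)) + config.baseline_delta[None, :]
    return 1.0 / (1.0 + np.exp(-logit))


def _draw_covariate_values(spec: CovariateSpec, classes: np.ndarray,
                           rng: np.random.Generator) -> np.ndarray:
    par = spec.class_params[classes]
    if spec.kind == "binary":
        return (rng.random(classes.shape) < par).astype(float)
    return rng.normal(par, spec.sd)


def simulate_panel(config: GeneratorConfig,
                   seed: int | None = None) -> PanelDataset:
    """Simulate a full longitudinal cohort.

    Latent class paths are sampled from ``pi0`` and ``A`` (with optional
    covariate shifts on the transition logits), indicators from the
    class-conditional Bernoulli model (baseline logit offset applied at wave
    0), and monotone dropout applied after wave 0. The true class path is
    retained in a ``class_truth`` column (1-based).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, T, K = config.n_individuals, config.n_waves, config.K

    # retention: observed[i, t] flags
    observed = np.ones((n, T), dtype=bool)
    if config.retention_mode == "binomial":
        for t in range(1, T):
            stay = rng.random(n) < config.retention[t - 1]
            observed[:, t] = observed[:, t - 1] & stay
    else:  # fixed per-wave quotas
        retained = np.arange(n)
        target = float(n)
        for t in range(1, T):
            target *= config.retention[t - 1]
            m = int(round(target))
            retained = rng.permutation(retained)[:m]
            observed[:, t] = False
            observed[retained, t] = True

    # latent paths (sampled for all waves; unobserved waves are simply
    # never emitted, matching marginalization over missing waves)
    z = np.empty((n, T), dtype=int)
    z[:, 0] = rng.choice(K, size=n, p=config.pi0)
    logA = np.log(np.clip(config.A, 1e-300, None))
    trans_covs = [s for s in config.covariate_spec
                  if s.transition_effects is not None]
    cov_values: dict[str, np.ndarray] = {}
    for spec in config.covariate_spec:
        cov_values[spec.name] = np.empty((n, T))
    for t in range(T):
        for spec in config.covariate_spec:
            if spec.time_varying or t == 0:
                cov_values[spec.name][:, t] = _draw_covariate_values(
                    spec, z[:, t] if spec.time_varying else z[:, 0], rng)
            else:
                cov_values[spec.name][:, t] = cov_values[spec.name][:, 0]
        if t == T - 1:
            break
        logits = logA[z[:, t]]  # (n, K)
        for spec in trans_covs:
            logits = logits + spec.transition_effects[z[:, t]] \
                * cov_values[spec.name][:, t][:, None]
        probs = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(n)
        z[:, t + 1] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)

    # indicators
    p_follow = _emission_probs(config, baseline=False)
    p_base = _emission_probs(config, baseline=True)
    rows = []
    for t in range(T):
        idx = np.flatnonzero(observed[:, t])
        p = (p_base if t == 0 else p_follow)[z[idx, t]]
        y = (rng.random(p.shape) < p).astype(np.int8)
        block = pd.DataFrame(y, columns=list(config.indicator_names))
        block.insert(0, "wave", t)
        block.insert(0, "person_id", idx)
        for spec in config.covariate_spec:
            vals = cov_values[spec.name][idx, t].copy()
            if spec.missing_rate > 0:
                miss = rng.random(vals.shape) < spec.missing_rate
                vals[miss] = np.nan
            block[spec.name] = vals
        block["class_truth"] = z[idx, t] + 1
        rows.append(block)
    df = pd.concat(rows, ignore_index=True)
    df = df.sort_values(["person_id", "wave"], kind="stable",
                        ignore_index=True)
    return PanelDataset(df, list(config.indicator_names), validate=False)


def simulate_pooled(config: GeneratorConfig, n_records: int,
                    is_baseline: bool = False,
                    seed: int | None = None) -> PanelDataset:
    """Simulate independent single-wave records (no Markov structure).

    Each record is its own person; the latent class is drawn from ``pi0``
    and indicators from the class-conditional model. ``is_baseline`` applies
    the baseline logit offset to every record and is stored in an explicit
    ``baseline`` column.
    """
    if n_records < 1:
        raise ValidationError("n_records: must be >= 1")
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    z = rng.choice(config.K, size=n_records, p=config.pi0)
    p = _emission_probs(config, baseline=is_baseline)[z]
    y = (rng.random(p.shape) < p).astype(np.int8)
    df = pd.DataFrame(y, columns=list(config.indicator_names))
    df.insert(0, "wave", 0)
    df.insert(0, "person_id", np.arange(n_records))
    df["baseline"] = int(is_baseline)
    df["class_truth"] = z + 1
    return PanelDataset(df, list(config.indicator_names), validate=False)


def attach_covariates(data: PanelDataset, config: GeneratorConfig,
                      seed: int | None = None) -> PanelDataset:
    """Draw class-conditional covariates for an existing simulated panel.

    Requires ``class_truth``. Time-invariant covariates are drawn once per
    person from the class at their first record; time-varying covariates are
    drawn per record from the record's class. Missingness is injected at
    each spec's ``missing_rate``.
    """
    if not config.covariate_spec:
        raise ValidationError("covariate_spec: empty; nothing to attach")
    truth = data.truth
    if truth is None:
        raise ValidationError("class_truth column required to attach covariates")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    df = data.df.copy()
    first_idx = df.groupby("person_id", sort=False).head(1).index
    person_codes = pd.factorize(df["person_id"])[0]
    for spec in config.covariate_spec:
        if spec.time_varying:
            vals = _draw_covariate_values(spec, truth, rng)
        else:
            per_person = _draw_covariate_values(
                spec, truth[first_idx], rng)
            vals = per_person[person_codes]
        if spec.missing_rate > 0:
            miss = rng.random(vals.shape) < spec.missing_rate
            vals = np.where(miss, np.nan, vals)
        df[spec.name] = vals
    return PanelDataset(df, data.indicators, validate=False)


__all__ = [
    "WAVE_SIZES", "PRINTED_PREVALENCES", "PRINTED_TRANSITIONS",
    "default_prevalences", "default_transition_matrix", "default_retention",
    "default_emissions", "CovariateSpec", "GeneratorConfig",
    "default_cohort_config", "simulate_panel", "simulate_pooled",
    "attach_covariates", "CLASS_LABELS",
]
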