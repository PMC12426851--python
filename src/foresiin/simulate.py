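"""Synthetic AF cohort generator with planted, recoverable stroke signal.

Emulates the statistical structure the stroke-forecasting pipeline assumes:
irregular visits over the two years before a first atrial-fibrillation (AF)
diagnosis, ~40 mixed-type features with high and feature-specific missingness,
a binary stroke-within-one-year outcome at low prevalence driven by a small
planted feature subset, and time-to-event/censoring columns for survival
analysis.  Every random draw flows from a single seed, so identical
configurations reproduce identical cohorts byte for byte.

Generative model
----------------
Each patient i carries a latent trait per feature: numeric traits are Gaussian
around the schema's marginal mean, binary/categorical traits are patient-level
constants.  Visit-level values add within-patient measurement noise to the
trait.  The outcome is logistic on standardized traits,

    P(stroke <= 1 y) = sigmoid(b0 + sum_j beta_j * z_ij),

where beta_j is nonzero only for the planted features and b0 is calibrated by
bisection so the mean outcome probability hits the target prevalence
(default 8.6%).  Positives receive an event day uniform on (0, 365]; negatives
are censored after a minimum one-year follow-up with a geometric tail.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import CalibrationError, ConfigurationError
from .schema import FeatureSchema, default_schema

__all__ = [
    "SimConfig",
    "PlantedTruth",
    "Cohort",
    "DEFAULT_PLANTED_EFFECTS",
    "calibrate_prevalence",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

# Planted per-SD log-odds (log odds ratio for the binary flag). Prior TIA/IS
# dominates, mirroring its established role as the strongest stroke predictor
# in AF; renal function, inflammation, hematocrit and glycemia carry the rest.
DEFAULT_PLANTED_EFFECTS = {
    "history_tia_is": 2.0,
    "egfr": -1.0,
    "hscrp": 0.9,
    "hematocrit": -0.8,
    "fpg": 0.8,
}

WINDOW_DAYS = 720  # days -719..0 relative to the first AF event
OUTCOME_WINDOW = 365

# visit-level measurement noise, as a fraction of the between-patient SD
WITHIN_NOISE_FRAC = 0.3


@dataclass
class SimConfig:
    """Cohort simulation settings.

    Parameters
    ----------
    n_patients : int
        Cohort size.
    target_prevalence : float
        Desired fraction with stroke within 1 year of first AF (default 0.086).
    visit_rate : float
        Expected visits per patient-month over the 24-month feature window.
        A visit at day 0 (the AF diagnosis encounter) is always present.
    planted_effects : dict
        Feature name -> outcome weight beta_j on the logit scale (per SD for
        numeric features, log odds ratio for binary flags).
    intercept : float or None
        Outcome logit intercept b0. None (default) means calibrate to
        ``target_prevalence`` by bisection.
    censor_min_day, censor_geom_mean : int, float
        Negatives are censored at ``censor_min_day + Geometric`` with the
        given mean tail, guaranteeing one full outcome window of follow-up.
    mar_missing : bool
        If True, high-risk patients are observed slightly more often
        (informative lab ordering); default False (MCAR).
    seed : int
        Master seed for all randomness.
    """

    n_patients: int = 4000
    target_prevalence: float = 0.086
    visit_rate: float = 1.0
    planted_effects: dict = field(default_factory=lambda: dict(DEFAULT_PLANTED_EFFECTS))
    intercept: float | None = None
    censor_min_day: int = 365
    censor_geom_mean: float = 180.0
    mar_missing: bool = False
    mar_strength: float = 0.3
    seed: int = 0

    def validate(self, schema: FeatureSchema) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ConfigurationError("target_prevalence must be in (0, 1)")
        if self.visit_rate < 0:
            raise ConfigurationError("visit_rate must be >= 0")
        known = set(schema.names)
        unknown = sorted(set(self.planted_effects) - known)
        if unknown:
            raise ConfigurationError(f"planted feature(s) not in schema: {unknown}")


@dataclass
class PlantedTruth:
    """Ground truth recorded at generation time for recovery testing."""

    feature_names: list
    weights: np.ndarray          # (m,), zero for non-planted features
    intercept: float
    realized_prevalence: float
    latent_risk: np.ndarray      # (n,), per-patient outcome probability
    seed: int

    def planted_names(self) -> list:
        return [n for n, w in zip(self.feature_names, self.weights) if w != 0.0]


@dataclass
class Cohort:
    """A generated cohort: long-format visits, per-patient timelines and truth.

    ``baseline`` carries patient-level fields (age, sex, comorbidity flags,
    creatinine/eGFR, echo dimensions, BSA) used by the clinical risk-score
    comparators.
    """

    visits: pd.DataFrame      # patient_id, day, feature, value
    timelines: pd.DataFrame   # patient_id, event_day (nullable), censor_day
    truth: PlantedTruth
    baseline: pd.DataFrame

    def __iter__(self):  # allow visits, timelines, truth = cohort
        return iter((self.visits, self.timelines, self.truth))


def _trait_matrix(config: SimConfig, schema: FeatureSchema, rng: np.random.Generator):
    """Patient-level traits and their standardized versions for the logit."""
    n, m = config.n_patients, len(schema)
    traits = np.empty((n, m))
    zscores = np.zeros((n, m))
    for j, desc in enumerate(schema.entries):
        if desc.kind == "numeric":
            t = rng.standard_normal(n)
            traits[:, j] = desc.mean + desc.sd * t
            zscores[:, j] = t
        elif desc.kind == "binary":
            x = rng.binomial(1, desc.prevalence, size=n).astype(float)
            traits[:, j] = x
            zscores[:, j] = x - desc.prevalence  # weight is a log odds ratio
        else:
            probs = np.asarray(desc.category_probs)
            codes = rng.choice(len(probs), size=n, p=probs).astype(float)
            traits[:, j] = codes
            zscores[:, j] = codes - float(probs @ np.arange(len(probs)))
    return traits, zscores


def _weight_vector(config: SimConfig, schema: FeatureSchema) -> np.ndarray:
    w = np.zeros(len(schema))
    for name, beta in config.planted_effects.items():
        w[schema.index(name)] = float(beta)
    return w


def _latent_scores(config: SimConfig, schema: FeatureSchema, rng) -> np.ndarray:
    _, z = _trait_matrix(config, schema, rng)
    return z @ _weight_vector(config, schema)


def calibrate_prevalence(
    config: SimConfig,
    schema: FeatureSchema | None = None,
    *,
    tol: float = 0.002,
    max_iter: int = 100,
    n_mc: int | None = None,
) -> float:
    """Find the logit intercept b0 giving the target outcome prevalence.

    Bisection on b0 over the mean of sigmoid(b0 + s_i) for a Monte-Carlo
    draw of latent scores s_i (the mean is monotone increasing in b0).

    Raises
    ------
    CalibrationError
        If the bracket cannot be established or bisection fails to reach
        ``tol`` within ``max_iter`` iterations.
    """
    schema = schema if schema is not None else default_schema()
    config.validate(schema)
    target = config.target_prevalence
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xCA11]))
    n = n_mc if n_mc is not None else max(config.n_patients, 20_000)
    mc_config = SimConfig(**{**config.__dict__, "n_patients": n})
    s = _latent_scores(mc_config, schema, rng)

    def mean_prob(b0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + s)))))

    lo, hi = -30.0, 30.0
    if not mean_prob(lo) <= target <= mean_prob(hi):
        raise CalibrationError(f"target prevalence {target} unreachable by intercept")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p = mean_prob(mid)
        if abs(p - target) <= tol:
            return mid
        if p < target:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(f"intercept search did not converge in {max_iter} iterations")


def generate_cohort(config: SimConfig, schema: FeatureSchema | None = None) -> Cohort:
    """Generate a cohort of visits, timelines and recorded ground truth.

    Every patient has at least one in-window visit (the day-0 AF encounter);
    no patient is excluded for sparsity.  Identical ``(config, schema)``
    reproduce identical output.
    """
    schema = schema if schema is not None else default_schema()
    config.validate(schema)
    n, m = config.n_patients, len(schema)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0C0]))

    traits, zscores = _trait_matrix(config, schema, rng)
    weights = _weight_vector(config, schema)
    intercept = (
        config.intercept
        if config.intercept is not None
        else calibrate_prevalence(config, schema)
    )
    latent = 1.0 / (1.0 + np.exp(-(intercept + zscores @ weights)))
    y = rng.binomial(1, latent).astype(int)

    # timelines: positives get an event day in (0, 365]; negatives are
    # censored after a minimum follow-up with a geometric tail
    event_day = np.where(y == 1, rng.integers(1, OUTCOME_WINDOW + 1, size=n), -1)
    geom_p = min(1.0, 1.0 / max(config.censor_geom_mean, 1.0))
    censor_tail = rng.geometric(geom_p, size=n)
    censor_day = np.where(y == 1, event_day, config.censor_min_day + censor_tail)

    # visit process: homogeneous Poisson over the 24-month window plus the
    # guaranteed index visit at day 0
    counts = rng.poisson(24.0 * config.visit_rate, size=n)
    pat_idx = np.concatenate([np.repeat(np.arange(n), counts), np.arange(n)])
    days = np.concatenate(
        [rng.integers(-(WINDOW_DAYS - 1), 0, size=int(counts.sum())), np.zeros(n, int)]
    )
    order = np.lexsort((days, pat_idx))
    pat_idx, days = pat_idx[order], days[order]
    n_rows = len(days)

    # visit-level values with per-feature missingness
    values = np.empty((n_rows, m))
    miss_rates = np.array([e.missing_rate for e in schema.entries])
    if config.mar_missing:
        # informative observation: high-risk patients get labs slightly more often
        risk_z = (latent - latent.mean()) / (latent.std() + 1e-12)
        factor = np.clip(1.0 - config.mar_strength * risk_z[pat_idx, None], 0.0, 2.0)
        miss = rng.random((n_rows, m)) < np.clip(miss_rates[None, :] * factor, 0, 1)
    else:
        miss = rng.random((n_rows, m)) < miss_rates[None, :]
    for j, desc in enumerate(schema.entries):
        base = traits[pat_idx, j]
        if desc.kind == "numeric":
            noise = rng.standard_normal(n_rows) * (WITHIN_NOISE_FRAC * desc.sd)
            values[:, j] = base + noise
        else:
            values[:, j] = base
    values[miss] = np.nan

    wide = pd.DataFrame(values, columns=schema.names)
    wide.insert(0, "patient_id", pat_idx)
    wide.insert(1, "day", days)
    visits = wide.melt(
        id_vars=["patient_id", "day"], var_name="feature", value_name="value"
    ).dropna(subset=["value"])
    visits = visits.sort_values(["patient_id", "day", "feature"], kind="stable")
    visits = visits.reset_index(drop=True)

    timelines = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "event_day": pd.array(
                np.where(y == 1, event_day, np.nan), dtype="Int64"
            ),
            "censor_day": censor_day.astype(int),
        }
    )

    baseline = _baseline_table(config, schema, traits, rng)

    truth = PlantedTruth(
        feature_names=schema.names,
        weights=weights,
        intercept=float(intercept),
        realized_prevalence=float(y.mean()),
        latent_risk=latent,
        seed=config.seed,
    )
    return Cohort(visits=visits, timelines=timelines, truth=truth, baseline=baseline)


def _baseline_table(config, schema, traits, rng) -> pd.DataFrame:
    """Patient-level fields for the clinical risk-score comparators."""
    n = config.n_patients

    def col(name):
        return traits[:, schema.index(name)]

    egfr = col("egfr")
    return pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "age": np.clip(col("age"), 18.0, None),
            "sex_male": col("sex_male").astype(int),
            "heart_failure": col("hf").astype(int),
            "hypertension": col("htn").astype(int),
            "diabetes": col("dm").astype(int),
            "prior_stroke_tia": col("history_tia_is").astype(int),
            "cad": col("cad").astype(int),
            "paod": col("paod").astype(int),
            "proteinuria": col("proteinuria").astype(int),
            "esrd": (egfr < 15.0).astype(int),
            "creatinine": np.clip(col("creatinine"), 0.3, None),
            "egfr": np.clip(egfr, 2.0, None),
            "race_black": np.zeros(n, int),
            "lvedd": np.clip(col("lvidd"), 2.0, None),
            "ivsd": np.clip(col("ivsd"), 0.4, None),
            "pwd": np.clip(col("pwd"), 0.4, None),
            "bsa": np.clip(rng.normal(1.73, 0.19, size=n), 1.2, None),
        }
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write visits/timelines/baseline as CSV and the planted truth as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.visits.to_csv(out / "visits.csv", index=False)
    cohort.timelines.to_csv(out / "timelines.csv", index=False)
    cohort.baseline.to_csv(out / "baseline.csv", index=False)
    t = cohort.truth
    (out / "truth.json").write_text(
        json.dumps(
            {
                "feature_names": t.feature_names,
                "weights": t.weights.tolist(),
                "intercept": t.intercept,
                "realized_prevalence": t.realized_prevalence,
                "latent_risk": t.latent_risk.tolist(),
                "seed": t.seed,
            },
            indent=1,
        )
    )


def read_cohort(in_dir: str | Path) -> Cohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    p = Path(in_dir)
    visits = pd.read_csv(p / "visits.csv")
    timelines = pd.read_csv(p / "timelines.csv")
    timelines["event_day"] = pd.array(timelines["event_day"], dtype="Int64")
    baseline = pd.read_csv(p / "baseline.csv")
    d = json.loads((p / "truth.json").read_text())
    truth = PlantedTruth(
        feature_names=d["feature_names"],
        weights=np.asarray(d["weights"]),
        intercept=d["intercept"],
        realized_prevalence=d["realized_prevalence"],
        latent_risk=np.asarray(d["latent_risk"]),
        seed=d["seed"],
    )
    return Cohort(visits=visits, timelines=timelines, truth=truth, baseline=baseline)
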