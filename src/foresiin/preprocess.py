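"""Irregular visit records -> fixed 24 x 40 summarized model inputs.

The two-year feature window before the first AF event (days -719..0) is tiled
into 24 fixed 30-day intervals; interval 24 is [-29, 0] and contains the AF
diagnosis day.  Within each interval, numeric features are summarized by their
mean and binary/categorical features by their mode (ties broken toward the
smallest code).  Cells with no observation stay missing and are resolved by
one of two policies: imputation with training-set means/modes, or the
imputation-free sentinel -1, which lies strictly outside the [0, 1] range all
observed values are scaled to and lets the model distinguish absence from any
measurement.

Splits follow the study protocol: stratified 60/40 train/test, a validation
set carved as 20% of training, and 4:1 negative:positive down-sampling of the
training set only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.model_selection import train_test_split

from .exceptions import ConfigurationError
from .schema import FeatureSchema, default_schema

logger = logging.getLogger(__name__)

__all__ = [
    "N_INTERVALS",
    "INTERVAL_DAYS",
    "SequenceData",
    "TrainStats",
    "SplitAssignment",
    "SequenceScaler",
    "interval_bounds",
    "build_window",
    "summarize_cohort",
    "make_labels",
    "split_cohort",
    "downsample_train",
]

N_INTERVALS = 24
INTERVAL_DAYS = 30
WINDOW_START = -719  # inclusive; window is [-719, 0]


def interval_bounds() -> list[tuple[int, int]]:
    """The 24 half-open-by-days interval bounds tiling days -719..0.

    Interval t (1-based) covers days [-719 + 30(t-1), -719 + 30t - 1];
    interval 24 is [-29, 0], containing the first AF event.
    """
    return [
        (WINDOW_START + INTERVAL_DAYS * t, WINDOW_START + INTERVAL_DAYS * (t + 1) - 1)
        for t in range(N_INTERVALS)
    ]


@dataclass
class SequenceData:
    """Interval-summarized sequences for a cohort.

    ``values`` is (n_patients, 24, n_features) with NaN marking missing cells
    until a :class:`SequenceScaler` resolves them; ``mask`` is True where a
    cell was observed.
    """

    patient_ids: np.ndarray
    values: np.ndarray  # (N, T, m), NaN = missing (pre-scaling)
    mask: np.ndarray    # (N, T, m) bool
    feature_names: list
    bounds: list = field(default_factory=interval_bounds)

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]


def build_window(visits: pd.DataFrame) -> pd.DataFrame:
    """Restrict visits to the feature window, days -719..0 inclusive."""
    return visits[(visits["day"] >= WINDOW_START) & (visits["day"] <= 0)]


def _interval_index(day: np.ndarray) -> np.ndarray:
    """0-based interval index for in-window day offsets."""
    return (day - WINDOW_START) // INTERVAL_DAYS


def summarize_cohort(
    visits: pd.DataFrame,
    patient_ids: np.ndarray | list,
    schema: FeatureSchema | None = None,
) -> SequenceData:
    """Summarize windowed visits into 24 x m sequences, one per patient.

    Patients with no in-window observations yield an all-missing sequence
    (no patient is excluded).  Values violating the schema kind raise a
    validation error naming the offender.
    """
    schema = schema if schema is not None else default_schema()
    patient_ids = np.asarray(patient_ids)
    m = len(schema)
    n = len(patient_ids)
    values = np.full((n, N_INTERVALS, m), np.nan)

    w = build_window(visits)
    unknown = set(w["feature"].unique()) - set(schema.names)
    if unknown:
        raise ConfigurationError(f"features not in schema: {sorted(unknown)}")
    if len(w):
        _validate_kinds(w, schema)
        row_of = {pid: i for i, pid in enumerate(patient_ids)}
        w = w[w["patient_id"].isin(row_of)].copy()
        w["row"] = w["patient_id"].map(row_of)
        w["t"] = _interval_index(w["day"].to_numpy())
        w["j"] = w["feature"].map({name: j for j, name in enumerate(schema.names)})

        numeric = {j for j, k in enumerate(schema.kinds) if k == "numeric"}
        is_num = w["j"].isin(numeric)

        if is_num.any():
            g = w[is_num].groupby(["row", "t", "j"], sort=False)["value"].mean()
            idx = np.array(list(g.index), dtype=int)
            values[idx[:, 0], idx[:, 1], idx[:, 2]] = g.to_numpy()
        cat = w[~is_num]
        if len(cat):
            counts = (
                cat.groupby(["row", "t", "j", "value"], sort=False)
                .size()
                .reset_index(name="count")
            )
            # mode with smallest-code tie-break: order by count desc, value asc
            counts = counts.sort_values(
                ["row", "t", "j", "count", "value"],
                ascending=[True, True, True, False, True],
                kind="stable",
            )
            modes = counts.drop_duplicates(["row", "t", "j"], keep="first")
            idx = modes[["row", "t", "j"]].to_numpy(dtype=int)
            values[idx[:, 0], idx[:, 1], idx[:, 2]] = modes["value"].to_numpy()

    n_empty = int(np.all(np.isnan(values), axis=(1, 2)).sum())
    if n_empty:
        logger.info("%d patient(s) have no in-window observations; kept as all-missing", n_empty)
    return SequenceData(
        patient_ids=patient_ids,
        values=values,
        mask=~np.isnan(values),
        feature_names=list(schema.names),
    )


def _validate_kinds(w: pd.DataFrame, schema: FeatureSchema) -> None:
    for name in w["feature"].unique():
        desc = schema[name]
        if desc.kind == "numeric":
            continue
        vals = w.loc[w["feature"] == name, "value"].to_numpy(dtype=float)
        codes_ok = np.all(vals == np.round(vals)) and np.all(vals >= 0)
        n_codes = 2 if desc.kind == "binary" else len(desc.category_probs)
        if not codes_ok or np.any(vals >= n_codes):
            bad = w[(w["feature"] == name)].iloc[0]
            raise ConfigurationError(
                f"value {bad['value']!r} for {desc.kind} feature {name!r} "
                f"(patient {bad['patient_id']}, day {bad['day']}) violates schema"
            )


# ---------------------------------------------------------------------------
# labels and splits
# ---------------------------------------------------------------------------

def make_labels(timelines: pd.DataFrame, horizon: int = 365) -> np.ndarray:
    """Binary outcome: 1 iff an event occurred within ``horizon`` days of AF.

    Patients censored (or dying) before the horizon without an event are
    labeled 0; no patient is excluded.
    """
    ev = timelines["event_day"]
    if (ev.dropna() <= 0).any():
        raise ValueError("event_day must be > 0 (event precedes first AF)")
    return ((ev.notna()) & (ev <= horizon)).to_numpy(dtype=int)


@dataclass
class SplitAssignment:
    """Stratified train/validation/test indices plus the down-sampled train set."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    train_ds_idx: np.ndarray | None = None
    seed: int = 0

    def assignment(self, n: int) -> np.ndarray:
        out = np.empty(n, dtype=object)
        out[self.train_idx] = "train"
        out[self.val_idx] = "validation"
        out[self.test_idx] = "test"
        return out


def split_cohort(labels: np.ndarray, seed: int = 0) -> SplitAssignment:
    """Stratified 60/40 train/test split; validation = 20% of the training set."""
    labels = np.asarray(labels)
    idx = np.arange(len(labels))
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need both outcome classes to split")
    if counts.min() < 5:
        logger.warning("a class has <5 patients; stratification is best-effort")
    train_idx, test_idx = train_test_split(
        idx, test_size=0.40, stratify=labels, random_state=seed
    )
    train_idx, val_idx = train_test_split(
        train_idx, test_size=0.20, stratify=labels[train_idx], random_state=seed
    )
    return SplitAssignment(
        train_idx=np.sort(train_idx),
        val_idx=np.sort(val_idx),
        test_idx=np.sort(test_idx),
        seed=seed,
    )


def downsample_train(
    split: SplitAssignment,
    labels: np.ndarray,
    ratio: float = 4.0,
    seed: int | None = None,
) -> np.ndarray:
    """Down-sample training negatives to a ratio:1 negative:positive balance.

    All training positives are kept; negatives are drawn without replacement.
    If there are fewer negatives than ratio x positives, all are kept.
    Validation and test sets are untouched.
    """
    labels = np.asarray(labels)
    seed = split.seed if seed is None else seed
    pos = split.train_idx[labels[split.train_idx] == 1]
    neg = split.train_idx[labels[split.train_idx] == 0]
    if len(pos) == 0:
        raise ValueError("no positive patients in the training split")
    n_keep = min(len(neg), int(round(ratio * len(pos))))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD0D0]))
    kept_neg = rng.choice(neg, size=n_keep, replace=False)
    out = np.sort(np.concatenate([pos, kept_neg]))
    split.train_ds_idx = out
    return out


# ---------------------------------------------------------------------------
# scaling and imputation
# ---------------------------------------------------------------------------

@dataclass
class TrainStats:
    """Per-feature summaries pooled over observed training cells only."""

    mean: np.ndarray      # numeric mean / categorical mode (raw scale)
    minimum: np.ndarray
    maximum: np.ndarray
    max_code: np.ndarray  # for binary/categorical scaling
    n_observed: np.ndarray
    feature_names: list


class SequenceScaler(TransformerMixin, BaseEstimator):
    """Scale summarized sequences to [0, 1] and resolve missing cells.

    Fit on training-set sequences only (leakage guard: statistics never see
    validation or test values).  Numeric cells are min-max scaled by the
    training range and clipped to [0, 1]; categorical codes are divided by
    the maximum training code.  Missing cells then become either the scaled
    training mean/mode (``policy="train_mean_mode"``) or the sentinel -1
    (``policy="sentinel"``), which is guaranteed out-of-range.

    Parameters
    ----------
    schema : FeatureSchema, optional
        Feature kinds; defaults to the standard 40-feature schema.
    policy : {"sentinel", "train_mean_mode"}
        Missing-cell resolution policy.
    sentinel : float
        Sentinel value, default -1.
    """

    def __init__(self, schema=None, policy: str = "sentinel", sentinel: float = -1.0):
        self.schema = schema
        self.policy = policy
        self.sentinel = sentinel

    def _resolve_schema(self) -> FeatureSchema:
        return self.schema if self.schema is not None else default_schema()

    def fit(self, X, y=None):
        """Compute per-feature training statistics from (N, T, m) NaN-coded X."""
        if self.policy not in ("sentinel", "train_mean_mode"):
            raise ConfigurationError(f"unknown missing policy {self.policy!r}")
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("expected (n_patients, n_intervals, n_features)")
        schema = self._resolve_schema()
        m = X.shape[2]
        mean = np.zeros(m)
        mn = np.zeros(m)
        mx = np.zeros(m)
        max_code = np.ones(m)
        n_obs = np.zeros(m, dtype=int)
        for j in range(m):
            col = X[:, :, j]
            obs = col[~np.isnan(col)]
            n_obs[j] = obs.size
            if obs.size == 0:
                logger.warning(
                    "feature %r never observed in training; imputing 0 after scaling",
                    schema.names[j],
                )
                continue
            if schema.kinds[j] == "numeric":
                mean[j] = obs.mean()
                mn[j], mx[j] = obs.min(), obs.max()
            else:
                codes, counts = np.unique(obs, return_counts=True)
                mean[j] = codes[np.argmax(counts)]  # mode; unique() sorts, so
                # the first max is the smallest code
                mn[j], mx[j] = obs.min(), obs.max()
                max_code[j] = max(obs.max(), 1.0)
        self.stats_ = TrainStats(
            mean=mean, minimum=mn, maximum=mx, max_code=max_code,
            n_observed=n_obs, feature_names=list(schema.names),
        )
        return self

    def transform(self, X) -> np.ndarray:
        """Scale observed cells to [0, 1] and fill missing cells per policy."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "stats_")
        X = np.asarray(X, dtype=float)
        stats = self.stats_
        schema = self._resolve_schema()
        out = np.empty_like(X)
        for j in range(X.shape[2]):
            col = X[:, :, j]
            never_seen = stats.n_observed[j] == 0
            if schema.kinds[j] == "numeric":
                span = stats.maximum[j] - stats.minimum[j]
                if span > 0:
                    scaled = np.clip((col - stats.minimum[j]) / span, 0.0, 1.0)
                    fill = float(np.clip((stats.mean[j] - stats.minimum[j]) / span, 0, 1))
                else:
                    # degenerate training range: observed cells map to 0.5
                    scaled = np.where(np.isnan(col), np.nan, 0.5)
                    fill = 0.0 if never_seen else 0.5
            else:
                scaled = col / stats.max_code[j]
                fill = 0.0 if never_seen else stats.mean[j] / stats.max_code[j]
            if self.policy == "sentinel":
                fill = self.sentinel
            out[:, :, j] = np.where(np.isnan(col), fill, scaled)
        return out
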