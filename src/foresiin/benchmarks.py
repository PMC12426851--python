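"""Comparison harness: classic learners, the pooled GRU, and clinical scores.

Reproduces the structure of the study's benchmark matrix: every model is
trained on the down-sampled training set, thresholded on the validation set,
and evaluated on the independent test set with the full metric suite.
Nonsequential learners (logistic regression, RBF-kernel SVM, random forest,
XGBoost) consume one of two flat representations of the same summarized
sequences — the last summarization interval only (the 40 values of the month
containing the AF event) or the full flattened 24 x 40 sequence — under
either missing-data policy.  The sequential models (pooled GRU, ForeSIIN)
always consume the full sequence.  CHA2DS2-VASc and ATRIA join the table with
the integer score used directly as the ranking statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clinical, evaluate
from .exceptions import ConfigurationError
from .model import ForeSIINClassifier
from .preprocess import SequenceScaler, SplitAssignment

__all__ = ["BenchmarkSpec", "extract_features", "default_specs", "run_benchmarks"]

SEQUENTIAL = ("pooled_gru", "foresiin")


@dataclass
class BenchmarkSpec:
    """One benchmark row: model, input representation and missing policy."""

    model: str               # logistic | svm | random_forest | gradient_boosting
    #                          | pooled_gru | foresiin | cha2ds2_vasc | atria
    input_mode: str = "last_interval"   # last_interval | flattened_sequence
    policy: str = "sentinel"            # sentinel | train_mean_mode
    params: dict = field(default_factory=dict)

    @property
    def name(self) -> str:
        return f"{self.model}[{self.input_mode},{self.policy}]"


def extract_features(X: np.ndarray, mode: str) -> np.ndarray:
    """Flatten scaled (N, T, m) sequences for nonsequential learners.

    ``last_interval`` keeps the m values of interval T (the month containing
    the first AF event); ``flattened_sequence`` yields T*m values in
    time-major order, so the last m entries equal the last-interval vector.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ValueError("expected (n_patients, T, m)")
    if mode == "last_interval":
        return X[:, -1, :]
    if mode == "flattened_sequence":
        return X.reshape(X.shape[0], -1)
    raise ConfigurationError(f"unknown input mode {mode!r}")


def default_specs(seed: int = 0) -> list:
    """The study-style benchmark matrix (each model at its reported setting)."""
    return [
        BenchmarkSpec("logistic", "flattened_sequence", "train_mean_mode"),
        BenchmarkSpec("svm", "last_interval", "sentinel"),
        BenchmarkSpec("random_forest", "last_interval", "train_mean_mode"),
        BenchmarkSpec("gradient_boosting", "last_interval", "sentinel"),
        BenchmarkSpec("pooled_gru", "flattened_sequence", "sentinel"),
        BenchmarkSpec("foresiin", "flattened_sequence", "sentinel"),
    ]


def _make_model(spec: BenchmarkSpec, seed: int):
    p = dict(spec.params)
    if spec.model == "logistic":
        from sklearn.linear_model import LogisticRegression

        return LogisticRegression(max_iter=2000, **({"C": 1.0} | p))
    if spec.model == "svm":
        from sklearn.svm import SVC

        return SVC(kernel="rbf", probability=True, random_state=seed, **p)
    if spec.model == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(
            n_estimators=p.pop("n_estimators", 300), random_state=seed, **p
        )
    if spec.model == "gradient_boosting":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=p.pop("n_estimators", 200),
            max_depth=p.pop("max_depth", 3),
            learning_rate=p.pop("learning_rate", 0.1),
            random_state=seed,
            eval_metric="logloss",
            verbosity=0,
            **p,
        )
    if spec.model in SEQUENTIAL:
        variant = "pooled_gru" if spec.model == "pooled_gru" else "independent"
        return ForeSIINClassifier(variant=variant, random_state=seed, **p)
    raise ConfigurationError(f"unknown benchmark model {spec.model!r}")


def run_benchmarks(
    values: np.ndarray,
    labels: np.ndarray,
    split: SplitAssignment,
    schema=None,
    times=None,
    events=None,
    baseline: pd.DataFrame | None = None,
    specs: list | None = None,
    threshold_mode: str = "youden_max",
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Train/evaluate every spec; one row per spec x metric, plus score rows.

    ``values`` is the NaN-coded summarized cohort (N, 24, m); scaling and
    imputation are fit on the down-sampled training set per spec so each row's
    policy is honored without leakage.  A model that fails to fit is recorded
    as failed and the run continues.
    """
    if specs is None:
        specs = default_specs(seed)
    labels = np.asarray(labels).astype(int)
    tr = split.train_ds_idx if split.train_ds_idx is not None else split.train_idx
    va, te = split.val_idx, split.test_idx
    rows = []

    def eval_scores(name, s_te, s_va):
        rep = evaluate.evaluate_scores(
            s_te, labels[te], s_va, labels[va],
            times=None if times is None else np.asarray(times)[te],
            events=None if events is None else np.asarray(events)[te],
            threshold_mode=threshold_mode, B=n_bootstrap, seed=seed,
        )
        rep.insert(0, "model", name)
        rep["threshold"] = rep.attrs["threshold"]
        rows.append(rep)

    for spec in specs:
        try:
            scaler = SequenceScaler(schema=schema, policy=spec.policy)
            scaler.fit(values[tr])
            Xs = scaler.transform(values)
            if spec.model in SEQUENTIAL:
                model = _make_model(spec, seed)
                model.fit(Xs[tr], labels[tr], validation_data=(Xs[va], labels[va]))
                s_te = model.predict_proba(Xs[te])[:, 1]
                s_va = model.predict_proba(Xs[va])[:, 1]
            else:
                F = extract_features(Xs, spec.input_mode)
                model = _make_model(spec, seed)
                model.fit(F[tr], labels[tr])
                s_te = model.predict_proba(F[te])[:, 1]
                s_va = model.predict_proba(F[va])[:, 1]
            eval_scores(spec.name, s_te, s_va)
        except Exception as exc:  # keep the table going; mark the row failed
            rows.append(
                pd.DataFrame(
                    [{"model": spec.name, "metric": "failed", "point": np.nan,
                      "ci_lower": np.nan, "ci_upper": np.nan, "threshold": np.nan}]
                ).assign(error=str(exc))
            )

    if baseline is not None:
        score_tbl = clinical.scores_from_baseline(baseline)
        for col in ("cha2ds2_vasc", "atria"):
            s = score_tbl[col].to_numpy(dtype=float)
            smax = max(s.max(), 1.0)
            eval_scores(col, s[te] / smax, s[va] / smax)

    return pd.concat(rows, ignore_index=True)
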