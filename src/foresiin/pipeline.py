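"""End-to-end study pipeline: simulate -> summarize -> split -> train -> report.

Convenience layer tying the modules together under the study protocol
(stratified 60/40 split, validation = 20% of training, 4:1 down-sampling,
sentinel missing-data policy, validation-selected thresholds).  Used by the
command-line interface and the reproduction script; every step is driven by
explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import evaluate, interpret, preprocess, simulate
from .model import ForeSIINClassifier
from .schema import FeatureSchema, default_schema

__all__ = ["PreparedCohort", "prepare_cohort", "train_variant", "survival_arrays"]


@dataclass
class PreparedCohort:
    """Cohort plus everything the models need, aligned by patient row."""

    cohort: simulate.Cohort
    schema: FeatureSchema
    seq: preprocess.SequenceData
    labels: np.ndarray
    times: np.ndarray       # days from first AF to event or censoring
    events: np.ndarray      # 1 = TIA/IS observed
    split: preprocess.SplitAssignment


def survival_arrays(timelines) -> tuple[np.ndarray, np.ndarray]:
    """(time, event) pairs: event day when observed, else censor day."""
    ev = timelines["event_day"]
    events = ev.notna().to_numpy()
    times = np.where(events, ev.fillna(0).to_numpy(dtype=float),
                     timelines["censor_day"].to_numpy(dtype=float))
    return times, events.astype(int)


def prepare_cohort(
    config: simulate.SimConfig,
    schema: FeatureSchema | None = None,
    split_seed: int | None = None,
    downsample_ratio: float = 4.0,
) -> PreparedCohort:
    """Generate and summarize a cohort and assign the study splits."""
    schema = schema if schema is not None else default_schema()
    cohort = simulate.generate_cohort(config, schema)
    ids = cohort.timelines["patient_id"].to_numpy()
    seq = preprocess.summarize_cohort(cohort.visits, ids, schema)
    labels = preprocess.make_labels(cohort.timelines)
    times, events = survival_arrays(cohort.timelines)
    split = preprocess.split_cohort(labels, seed=config.seed if split_seed is None else split_seed)
    preprocess.downsample_train(split, labels, ratio=downsample_ratio)
    return PreparedCohort(
        cohort=cohort, schema=schema, seq=seq,
        labels=labels, times=times, events=events, split=split,
    )


def train_variant(
    prep: PreparedCohort,
    variant: str = "independent",
    policy: str = "sentinel",
    seed: int = 0,
    **model_kwargs,
):
    """Fit one architecture variant under the protocol; returns (model, scaler, Xs).

    The scaler is fit on the down-sampled training rows only; the model
    early-stops on the untouched validation split.
    """
    split = prep.split
    tr = split.train_ds_idx if split.train_ds_idx is not None else split.train_idx
    scaler = preprocess.SequenceScaler(schema=prep.schema, policy=policy)
    scaler.fit(prep.seq.values[tr])
    Xs = scaler.transform(prep.seq.values)
    model = ForeSIINClassifier(variant=variant, random_state=seed, **model_kwargs)
    model.fit(
        Xs[tr], prep.labels[tr],
        validation_data=(Xs[split.val_idx], prep.labels[split.val_idx]),
    )
    return model, scaler, Xs


def evaluate_variant(
    prep: PreparedCohort,
    model: ForeSIINClassifier,
    Xs: np.ndarray,
    threshold_mode: str = "youden_max",
    B: int = 1000,
    seed: int = 0,
):
    """Test-set metric report plus (for per-feature variants) the impact report."""
    split = prep.split
    s_te = model.predict_proba(Xs[split.test_idx])[:, 1]
    s_va = model.predict_proba(Xs[split.val_idx])[:, 1]
    report = evaluate.evaluate_scores(
        s_te, prep.labels[split.test_idx], s_va, prep.labels[split.val_idx],
        times=prep.times[split.test_idx], events=prep.events[split.test_idx],
        threshold_mode=threshold_mode, B=B, seed=seed,
    )
    impact = None
    if model.variant != "pooled_gru":
        effects = model.feature_effects(Xs[split.test_idx])
        impact = interpret.group_impact(
            effects, prep.labels[split.test_idx], prep.seq.feature_names
        )
    return report, impact
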