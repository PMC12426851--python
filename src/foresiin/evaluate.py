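"""Discrimination metrics, threshold policies, bootstrap CIs and survival analysis.

The evaluation protocol mirrors the study design: discrimination is measured
on the independent test set by AUROC, AUPRC and Harrell's c-index with 95%
percentile confidence intervals over 1,000 patient-level bootstrap resamples;
classification metrics (Youden index J, F1, recall, precision, G-mean) are
reported at a decision threshold chosen on the validation set under one of
three policies (fixed 0.5, Youden-maximizing, F1-maximizing); and survival is
summarized by Kaplan-Meier curves per predicted risk group with a log-rank
test, plus decision-curve net benefit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .exceptions import UndefinedMetricError

__all__ = [
    "ThresholdPolicy",
    "roc_auc",
    "pr_auc",
    "select_threshold",
    "confusion_at",
    "harrell_c",
    "bootstrap_ci",
    "km_curve",
    "logrank_test",
    "decision_curve",
    "evaluate_scores",
]


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("metric undefined with a single label class")


def roc_auc(scores, labels) -> float:
    """AUROC (equals the pairwise concordance probability, ties at 0.5)."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pr_auc(scores, labels) -> float:
    """AUPRC by step interpolation; a random scorer lands near prevalence."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class ThresholdPolicy:
    """A decision threshold and how it was chosen."""

    mode: str                 # "fixed" | "youden_max" | "f1_max"
    threshold: float = 0.5
    selection_split: str = "none"


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    s = np.unique(scores)
    mids = (s[:-1] + s[1:]) / 2.0 if len(s) > 1 else np.array([])
    return np.unique(np.concatenate([[0.0], mids, [1.0]]))


def select_threshold(val_scores, val_labels, mode: str = "youden_max") -> ThresholdPolicy:
    """Choose a decision threshold on the validation split.

    Candidates are midpoints between consecutive sorted unique scores plus
    {0, 1}; the threshold maximizing the Youden index J = sens + spec - 1
    (or F1) is returned, ties broken toward the smallest threshold.
    """
    if mode == "fixed":
        return ThresholdPolicy(mode="fixed", threshold=0.5)
    if mode not in ("youden_max", "f1_max"):
        raise ValueError(f"unknown threshold mode {mode!r}")
    scores = np.asarray(val_scores, dtype=float)
    labels = np.asarray(val_labels).astype(int)
    _check_two_classes(labels)
    cands = _candidate_thresholds(scores)
    pred = scores[None, :] >= cands[:, None]          # (n_thr, n)
    tp = (pred & (labels == 1)).sum(axis=1).astype(float)
    fp = (pred & (labels == 0)).sum(axis=1).astype(float)
    npos, nneg = (labels == 1).sum(), (labels == 0).sum()
    sens = tp / npos
    spec = (nneg - fp) / nneg
    if mode == "youden_max":
        crit = sens + spec - 1.0
    else:
        prec = np.divide(tp, tp + fp, out=np.zeros_like(tp), where=(tp + fp) > 0)
        crit = np.divide(
            2 * prec * sens, prec + sens,
            out=np.zeros_like(tp), where=(prec + sens) > 0,
        )
    best = cands[np.argmax(crit)]  # argmax returns first max = smallest threshold
    return ThresholdPolicy(mode=mode, threshold=float(best), selection_split="validation")


def confusion_at(scores, labels, threshold: float) -> dict:
    """Confusion counts and threshold-dependent metrics at score >= threshold.

    Zero-denominator conventions: precision and F1 are 0 when nothing is
    predicted positive; G-mean = sqrt(sensitivity * specificity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sensitivity": sens, "specificity": spec, "recall": sens,
        "precision": prec, "f1": f1,
        "youden": sens + spec - 1.0,
        "g_mean": float(np.sqrt(sens * spec)),
        "threshold": float(threshold),
    }


def harrell_c(scores, times, events) -> float:
    """Harrell's concordance index.

    A pair (i, j) is comparable when time_i < time_j and subject i had an
    observed event; it is concordant when the earlier-event subject has the
    higher risk score, with score ties counting 1/2.  Pairs where the earlier
    time is censored are not comparable.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    comparable = (times[:, None] < times[None, :]) & events[:, None]
    n_comp = comparable.sum()
    if n_comp == 0:
        raise UndefinedMetricError("no comparable pairs for the c-index")
    higher = scores[:, None] > scores[None, :]
    tied = scores[:, None] == scores[None, :]
    conc = (comparable & higher).sum() + 0.5 * (comparable & tied).sum()
    return float(conc / n_comp)


def bootstrap_ci(metric_fn, *arrays, B: int = 1000, seed: int = 0, alpha: float = 0.05):
    """Percentile bootstrap CI for a metric over patient-level resamples.

    ``metric_fn`` is called on each resample of the aligned input arrays.
    Resamples on which the metric is undefined (e.g. one class only) are
    skipped; more than 50% degenerate resamples is an error.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    n = len(arrays[0])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB007]))
    stats = []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            stats.append(metric_fn(*(np.asarray(a)[idx] for a in arrays)))
        except UndefinedMetricError:
            skipped += 1
    if skipped > B / 2:
        raise UndefinedMetricError(f"{skipped}/{B} bootstrap resamples degenerate")
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def km_curve(times, events, groups) -> pd.DataFrame:
    """Kaplan-Meier survival per group as a tidy table.

    Columns: group, time, survival, at_risk.  Survival is the product-limit
    estimate, non-increasing from 1.
    """
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    groups = np.asarray(groups)
    frames = []
    for g in np.unique(groups):
        sel = groups == g
        if sel.sum() == 0:
            raise ValueError(f"group {g!r} has no subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        sf = kmf.survival_function_.iloc[:, 0]
        at_risk = kmf.event_table["at_risk"].reindex(sf.index)
        frames.append(
            pd.DataFrame(
                {
                    "group": g,
                    "time": sf.index.to_numpy(dtype=float),
                    "survival": sf.to_numpy(dtype=float),
                    "at_risk": at_risk.to_numpy(dtype=float),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def logrank_test(times, events, groups):
    """Two-group log-rank test; returns (chi2, p) with 1 df."""
    from lifelines.statistics import logrank_test as _lr

    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError("log-rank test requires exactly 2 groups")
    a, b = (groups == uniq[0]), (groups == uniq[1])
    res = _lr(times[a], times[b], event_observed_A=events[a], event_observed_B=events[b])
    return float(res.test_statistic), float(res.p_value)


def decision_curve(scores, labels, thresholds=None) -> pd.DataFrame:
    """Net benefit of treating above each threshold probability p_t.

    NB(p_t) = TP/n - (FP/n) * p_t / (1 - p_t), with treat-all and treat-none
    reference lines.  p_t = 1 is excluded (undefined odds).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if thresholds is None:
        thresholds = np.arange(0.01, 0.51, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    thresholds = thresholds[(thresholds > 0) & (thresholds < 1)]
    n = len(labels)
    prev = labels.mean()
    rows = []
    for pt in thresholds:
        pred = scores >= pt
        tp = (pred & (labels == 1)).sum() / n
        fp = (pred & (labels == 0)).sum() / n
        odds = pt / (1 - pt)
        rows.append(
            {
                "threshold": pt,
                "nb_model": tp - fp * odds,
                "nb_treat_all": prev - (1 - prev) * odds,
                "nb_treat_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# one-call report
# ---------------------------------------------------------------------------

def evaluate_scores(
    test_scores,
    test_labels,
    val_scores=None,
    val_labels=None,
    times=None,
    events=None,
    threshold_mode: str = "youden_max",
    B: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Full metric suite with bootstrap CIs, one row per metric.

    Threshold-dependent metrics are computed on the test set at the
    validation-selected threshold.  Survival metrics require ``times`` and
    ``events`` (days from first AF, event indicator).
    """
    test_scores = np.asarray(test_scores, dtype=float)
    test_labels = np.asarray(test_labels).astype(int)
    if val_scores is not None and threshold_mode != "fixed":
        policy = select_threshold(val_scores, val_labels, threshold_mode)
    else:
        policy = ThresholdPolicy(mode="fixed", threshold=0.5)
    thr = policy.threshold

    rows = []

    def add(name, fn, *arrays):
        point = fn(*arrays)
        lo, hi = bootstrap_ci(fn, *arrays, B=B, seed=seed)
        rows.append({"metric": name, "point": point, "ci_lower": lo, "ci_upper": hi})

    add("auprc", pr_auc, test_scores, test_labels)
    add("auroc", roc_auc, test_scores, test_labels)
    for key in ("youden", "f1", "recall", "precision", "g_mean"):
        add(
            key,
            lambda s, l, key=key: confusion_at(s, l, thr)[key],
            test_scores,
            test_labels,
        )
    if times is not None:
        add("c_index", harrell_c, test_scores, np.asarray(times), np.asarray(events))
    out = pd.DataFrame(rows)
    out.attrs["threshold"] = thr
    out.attrs["threshold_mode"] = policy.mode
    out.attrs["n_bootstrap"] = B
    return out
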