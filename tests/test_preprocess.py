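"""Interval summarization, scaling/imputation policies, labels and splits."""

import numpy as np
import pandas as pd
import pytest

from foresiin import preprocess
from foresiin.preprocess import (
    SequenceScaler,
    build_window,
    downsample_train,
    interval_bounds,
    make_labels,
    split_cohort,
    summarize_cohort,
)

from conftest import random_visit_table


def brute_force_summary(visits, patient_ids, schema):
    """Independent oracle: python-loop grouping into 24 x m cells."""
    bounds = interval_bounds()
    n, m = len(patient_ids), len(schema)
    out = np.full((n, 24, m), np.nan)
    row_of = {pid: i for i, pid in enumerate(patient_ids)}
    cells = {}
    for rec in visits.itertuples():
        if rec.day < -719 or rec.day > 0 or rec.patient_id not in row_of:
            continue
        for t, (lo, hi) in enumerate(bounds):
            if lo <= rec.day <= hi:
                cells.setdefault((row_of[rec.patient_id], t, rec.feature), []).append(rec.value)
    for (i, t, name), vals in cells.items():
        j = schema.index(name)
        if schema[name].kind == "numeric":
            out[i, t, j] = sum(vals) / len(vals)
        else:
            counts = {}
            for v in vals:
                counts[v] = counts.get(v, 0) + 1
            best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
            out[i, t, j] = best[0]
    return out


class TestWindowAndTiling:
    def test_interval_tiling_covers_720_days(self):
        b = interval_bounds()
        assert len(b) == 24
        assert b[0][0] == -719 and b[-1][1] == 0
        days = [d for lo, hi in b for d in range(lo, hi + 1)]
        assert days == list(range(-719, 1))  # no gaps, no overlaps

    def test_window_boundaries(self):
        v = pd.DataFrame(
            {"patient_id": 0, "day": [-800, -720, -719, -400, 0, 10],
             "feature": "bmi", "value": 1.0}
        )
        kept = build_window(v)["day"].tolist()
        assert kept == [-719, -400, 0]

    def test_empty_visits_all_missing(self, schema):
        seq = summarize_cohort(pd.DataFrame(columns=["patient_id", "day", "feature", "value"]),
                               [0, 1], schema)
        assert seq.values.shape == (2, 24, 40)
        assert not seq.mask.any()


class TestSummarize:
    def test_numeric_mean_and_categorical_mode(self, schema):
        v = pd.DataFrame(
            [
                {"patient_id": 0, "day": -10, "feature": "bmi", "value": 2.0},
                {"patient_id": 0, "day": -5, "feature": "bmi", "value": 4.0},
                {"patient_id": 0, "day": -10, "feature": "smoking_status", "value": 1.0},
                {"patient_id": 0, "day": -9, "feature": "smoking_status", "value": 1.0},
                {"patient_id": 0, "day": -8, "feature": "smoking_status", "value": 2.0},
            ]
        )
        seq = summarize_cohort(v, [0], schema)
        j_bmi = schema.index("bmi")
        j_smk = schema.index("smoking_status")
        assert seq.values[0, 23, j_bmi] == pytest.approx(3.0)
        assert seq.values[0, 23, j_smk] == 1.0

    def test_mode_tie_smallest_code(self, schema):
        v = pd.DataFrame(
            [
                {"patient_id": 0, "day": -3, "feature": "smoking_status", "value": 2.0},
                {"patient_id": 0, "day": -2, "feature": "smoking_status", "value": 1.0},
            ]
        )
        seq = summarize_cohort(v, [0], schema)
        assert seq.values[0, 23, schema.index("smoking_status")] == 1.0

    def test_brute_force_oracle_equivalence(self, schema):
        rng = np.random.default_rng(42)
        for _ in range(60):
            v = random_visit_table(rng, schema, n_patients=3, n_rows=40)
            seq = summarize_cohort(v, [0, 1, 2], schema)
            ref = brute_force_summary(v, [0, 1, 2], schema)
            np.testing.assert_array_equal(np.isnan(seq.values), np.isnan(ref))
            np.testing.assert_allclose(
                np.nan_to_num(seq.values), np.nan_to_num(ref), rtol=0, atol=1e-12
            )

    def test_schema_violation_named(self, schema):
        v = pd.DataFrame(
            [{"patient_id": 7, "day": -3, "feature": "smoking_status", "value": 9.0}]
        )
        with pytest.raises(Exception, match="smoking_status"):
            summarize_cohort(v, [7], schema)


class TestLabelsAndSplits:
    def test_label_rules(self):
        tl = pd.DataFrame(
            {"patient_id": [0, 1, 2],
             "event_day": pd.array([100, 400, None], dtype="Int64"),
             "censor_day": [100, 400, 200]}
        )
        assert make_labels(tl).tolist() == [1, 0, 0]

    def test_event_before_af_rejected(self):
        tl = pd.DataFrame(
            {"patient_id": [0], "event_day": pd.array([-5], dtype="Int64"),
             "censor_day": [10]}
        )
        with pytest.raises(ValueError):
            make_labels(tl)

    def test_split_fractions_and_stratification(self):
        labels = np.array([1] * 10 + [0] * 90)
        s = split_cohort(labels, seed=0)
        assert len(s.test_idx) == 40
        assert len(s.val_idx) == 12
        assert len(s.train_idx) == 48
        assert labels[s.test_idx].sum() == 4
        assert labels[s.train_idx].sum() + labels[s.val_idx].sum() == 6

    def test_split_disjoint_and_deterministic(self):
        labels = np.array([1] * 20 + [0] * 180)
        a = split_cohort(labels, seed=3)
        b = split_cohort(labels, seed=3)
        assert np.array_equal(a.train_idx, b.train_idx)
        assert not (set(a.train_idx) | set(a.val_idx)) & set(a.test_idx)
        assert not set(a.train_idx) & set(a.val_idx)

    def test_downsample_ratio_exact(self):
        labels = np.zeros(1000, dtype=int)
        rng = np.random.default_rng(0)
        labels[rng.choice(1000, 120, replace=False)] = 1
        s = split_cohort(labels, seed=1)
        kept = downsample_train(s, labels, ratio=4.0)
        pos = labels[kept].sum()
        assert pos == labels[s.train_idx].sum()  # all positives kept
        assert (labels[kept] == 0).sum() == 4 * pos

    def test_downsample_insufficient_negatives_keeps_all(self):
        labels = np.array([1] * 50 + [0] * 60)
        s = split_cohort(labels, seed=1)
        kept = downsample_train(s, labels, ratio=4.0)
        assert set(kept) == set(s.train_idx)

    def test_downsample_deterministic(self):
        labels = np.array([1] * 30 + [0] * 470)
        s = split_cohort(labels, seed=2)
        a = downsample_train(s, labels, ratio=4.0, seed=9)
        b = downsample_train(s, labels, ratio=4.0, seed=9)
        assert np.array_equal(a, b)


class TestScaler:
    def _toy(self, schema):
        # one numeric feature observed at known values, rest missing
        X = np.full((3, 24, 40), np.nan)
        j = schema.index("bmi")
        X[0, 0, j] = 0.0
        X[1, 0, j] = 1.0
        X[2, 0, j] = 0.5
        return X, j

    def test_minmax_and_sentinel(self, schema):
        X, j = self._toy(schema)
        sc = SequenceScaler(schema=schema, policy="sentinel").fit(X)
        out = sc.transform(X)
        assert out[2, 0, j] == pytest.approx(0.5)
        assert out[0, 1, j] == -1.0  # missing cell
        assert (out[:, :, j][np.isnan(X[:, :, j])] == -1).all()

    def test_mean_mode_imputation(self, schema):
        X, j = self._toy(schema)
        sc = SequenceScaler(schema=schema, policy="train_mean_mode").fit(X)
        out = sc.transform(X)
        assert out[0, 1, j] == pytest.approx(0.5)  # scaled train mean

    def test_clip_above_training_max(self, schema):
        X, j = self._toy(schema)
        sc = SequenceScaler(schema=schema, policy="sentinel").fit(X)
        X2 = X.copy()
        X2[0, 0, j] = 10.0
        assert sc.transform(X2)[0, 0, j] == 1.0

    def test_sentinel_separation(self, small_prepared):
        prep = small_prepared
        tr = prep.split.train_ds_idx
        sc = SequenceScaler(schema=prep.schema, policy="sentinel").fit(prep.seq.values[tr])
        out = sc.transform(prep.seq.values)
        observed = out[prep.seq.mask]
        assert (observed != -1.0).all()
        assert observed.min() >= 0.0 and observed.max() <= 1.0

    def test_leakage_guard(self, small_prepared):
        """Perturbing test-set values never changes training statistics."""
        prep = small_prepared
        tr = prep.split.train_ds_idx
        te = prep.split.test_idx
        sc1 = SequenceScaler(schema=prep.schema).fit(prep.seq.values[tr])
        V2 = prep.seq.values.copy()
        V2[te] = V2[te] * 3.7 + 1.0
        sc2 = SequenceScaler(schema=prep.schema).fit(V2[tr])
        np.testing.assert_array_equal(sc1.stats_.mean, sc2.stats_.mean)
        np.testing.assert_array_equal(sc1.stats_.minimum, sc2.stats_.minimum)
        np.testing.assert_array_equal(sc1.stats_.maximum, sc2.stats_.maximum)
        np.testing.assert_array_equal(
            sc1.transform(prep.seq.values[tr]), sc2.transform(V2[tr])
        )
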