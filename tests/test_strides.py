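"""Stride segmentation and muscular indexes: conservation, exactness, pooling."""

import numpy as np
import pytest

from wotrack._utils import MUSCLES, SAMPLE_MS
from wotrack.strides import compute_indexes, pool_legs, segment_strides, session_features
from wotrack.triggers import TriggerTrain


def train_from_mask(mask, label="LG"):
    return TriggerTrain(muscle_label=label, values=np.asarray(mask, dtype=np.uint8))


def leg_triggers(length, lg=(), ta=(), bf=(), rf=()):
    out = {}
    for name, spans in (("LG", lg), ("TA", ta), ("BF", bf), ("RF", rf)):
        m = np.zeros(length, dtype=np.uint8)
        for a, b in spans:
            m[a:b] = 1
        out[name] = train_from_mask(m, name)
    return out


class TestSegmentStrides:
    def test_two_onsets_one_stride(self):
        m = np.zeros(700, dtype=np.uint8)
        m[10:110] = 1
        m[550:570] = 1
        strides = segment_strides(train_from_mask(m))
        assert strides == [(10, 550)]
        assert (strides[0][1] - strides[0][0]) * SAMPLE_MS == 1080

    def test_initial_contraction_is_not_a_phantom_onset(self):
        m = np.ones(600, dtype=np.uint8)
        m[100:540] = 0
        with pytest.warns(UserWarning):
            assert segment_strides(train_from_mask(m)) == []

    def test_three_onsets_two_strides(self):
        m = np.zeros(1300, dtype=np.uint8)
        for s in (10, 510, 1050):
            m[s:s + 60] = 1
        strides = segment_strides(train_from_mask(m))
        assert [(b - a) * SAMPLE_MS for a, b in strides] == [1000, 1080]

    def test_single_onset_warns_empty(self):
        m = np.zeros(100, dtype=np.uint8)
        m[10:60] = 1
        with pytest.warns(UserWarning):
            assert segment_strides(train_from_mask(m)) == []

    def test_detected_count_matches_truth(self, pre_session, pre_triggers):
        for leg in ("R", "L"):
            strides = segment_strides(pre_triggers[f"{leg}_LG"])
            expected = (pre_session.truth.stride_table["leg"] == leg).sum()
            assert len(strides) == expected


class TestComputeIndexes:
    def test_contraction_and_duty_cycle(self):
        # one stride [0, 540); TA active on [100, 235)
        trig = leg_triggers(600, lg=[(0, 20), (540, 560)], ta=[(100, 235)])
        tab = compute_indexes([(0, 540)], trig)
        row = tab.iloc[0]
        assert row["contraction_ta_ms"] == 135 * SAMPLE_MS == 270
        assert row["dc_ta_pct"] == pytest.approx(25.0)
        assert row["relaxation_ta_ms"] == row["stride_time_ms"] - 270

    def test_cocontraction_is_interval_overlap(self):
        trig = leg_triggers(300, lg=[(50, 150)], ta=[(125, 200)])
        tab = compute_indexes([(0, 250)], trig)
        assert tab.iloc[0]["cocon_lg_ta_ms"] == 25 * SAMPLE_MS == 50

    def test_conservation_and_overlap_bounds(self, pre_session, pre_triggers):
        feat = session_features(pre_session, pre_triggers)
        for m in MUSCLES:
            m = m.lower()
            total = feat[f"contraction_{m}_ms"] + feat[f"relaxation_{m}_ms"]
            assert (total == feat["stride_time_ms"]).all()
        assert (feat["cocon_lg_ta_ms"]
                <= np.minimum(feat["contraction_lg_ms"], feat["contraction_ta_ms"])).all()
        assert (feat["cocon_rf_bf_ms"]
                <= np.minimum(feat["contraction_rf_ms"], feat["contraction_bf_ms"])).all()
        lower = np.maximum(
            0, feat["contraction_lg_ms"] + feat["contraction_ta_ms"] - feat["stride_time_ms"])
        assert (feat["cocon_lg_ta_ms"] >= lower).all()
        for col in ("stride_time_ms", "cocon_lg_ta_ms", "cocon_rf_bf_ms"):
            assert (feat[col] % SAMPLE_MS == 0).all()

    def test_noiseless_triggers_reproduce_truth_exactly(self, pre_session):
        """Feeding the ground-truth masks as triggers recovers the truth table."""
        rec = pre_session
        trigs = {lab: train_from_mask(rec.truth.masks[i], lab)
                 for i, lab in enumerate(rec.emg_labels)}
        feat = session_features(rec, trigs)
        truth = rec.truth.stride_table
        merged = feat.merge(truth, on=["leg", "onset"], suffixes=("", "_true"))
        assert len(merged) == len(truth)
        for col in ("stride_time_ms", "cocon_lg_ta_ms", "cocon_rf_bf_ms"):
            assert (merged[col] == merged[f"{col}_true"]).all(), col
        for m in MUSCLES:
            col = f"contraction_{m.lower()}_ms"
            assert (merged[col] == merged[f"{col}_true"]).all(), col

    def test_stride_past_trigger_end_marked_invalid(self):
        trig = leg_triggers(200, lg=[(0, 50)])
        tab = compute_indexes([(0, 180), (180, 260)], trig)
        assert tab["valid"].tolist() == [True, False]


class TestPoolLegs:
    def test_concatenation_counts(self):
        trig = leg_triggers(2000, lg=[(i * 100, i * 100 + 30) for i in range(20)])
        left = compute_indexes([(i * 100, (i + 1) * 100) for i in range(10)], trig, leg="L")
        right = compute_indexes([(i * 100, (i + 1) * 100) for i in range(12)], trig, leg="R")
        pooled = pool_legs([left, right])
        assert len(pooled) == 22
        assert pool_legs([left.iloc[:0], right]).shape[0] == 12

    def test_pooled_mean_is_weighted_leg_mean(self):
        trig = leg_triggers(2000, lg=[(i * 100, i * 100 + 30) for i in range(20)],
                            ta=[(i * 100 + 10, i * 100 + 50) for i in range(20)])
        left = compute_indexes([(i * 100, (i + 1) * 100) for i in range(5)], trig, leg="L")
        right = compute_indexes([(i * 100, (i + 1) * 100) for i in range(15)], trig, leg="R")
        pooled = pool_legs([left, right])
        expected = (left["dc_ta_pct"].sum() + right["dc_ta_pct"].sum()) / 20
        assert pooled["dc_ta_pct"].mean() == pytest.approx(expected)
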