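"""Generator tests: parameter defaults, calibration, determinism, truth."""

import numpy as np
import pandas as pd
import pytest

from wotrack._utils import SAMPLE_MS
from wotrack.session import GroundTruth, SessionRecording
from wotrack.synth import (ConditionParams, NoiseProfile, default_params,
                           realized_statistics, simulate_feature_tables,
                           simulate_session, subject_params)

from conftest import TABLE1


class TestDefaultParams:
    def test_published_means(self):
        pre, post = default_params("pre"), default_params("post")
        assert pre.stride_time_mean_ms == pytest.approx(1081.09)
        assert post.cocon_rf_bf_mean_ms == pytest.approx(228.02)
        assert post.stride_time_mean_ms < pre.stride_time_mean_ms

    def test_ta_dc_differs_negligibly_between_conditions(self):
        pre, post = default_params("pre"), default_params("post")
        assert abs(pre.dc_mean_pct["TA"] - post.dc_mean_pct["TA"]) < 0.05

    @pytest.mark.parametrize("condition", ["pre", "post"])
    def test_duty_cycle_pair_sums_bounded(self, condition):
        p = default_params(condition)
        for pair in (("LG", "TA"), ("RF", "BF")):
            assert sum(p.dc_mean_pct[m] for m in pair) < 200

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            default_params("during")

    def test_text_convention_swaps_ta_rf(self):
        table = default_params("pre")
        text = default_params("pre", dc_convention="text")
        assert text.dc_mean_pct["TA"] == table.dc_mean_pct["RF"]
        assert text.dc_mean_pct["RF"] == table.dc_mean_pct["TA"]

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ConditionParams(condition="pre", stride_time_mean_ms=-1,
                            stride_time_sd_ms=1, dc_mean_pct={m: 50 for m in "ABCD"},
                            dc_sd_pct={m: 1 for m in "ABCD"},
                            cocon_lg_ta_mean_ms=1, cocon_lg_ta_sd_ms=1,
                            cocon_rf_bf_mean_ms=1, cocon_rf_bf_sd_ms=1)


class TestSimulateSession:
    def test_deterministic_under_seed(self):
        p = default_params("post")
        a = simulate_session(p, 10, seed=5)
        b = simulate_session(p, 10, seed=5)
        assert np.array_equal(a.emg, b.emg)
        assert np.array_equal(a.eeg, b.eeg)
        assert np.array_equal(a.truth.masks, b.truth.masks)
        pd.testing.assert_frame_equal(a.truth.stride_table, b.truth.stride_table)

    def test_degenerate_zero_sd_gives_constant_stride_times(self):
        from dataclasses import replace
        p = replace(default_params("pre"), stride_time_sd_ms=0.0)
        rec = simulate_session(p, 20, seed=0, include_eeg=False)
        expected = round(p.stride_time_mean_ms / SAMPLE_MS) * SAMPLE_MS
        assert (rec.truth.stride_table["stride_time_ms"] == expected).all()

    def test_durations_on_two_ms_grid(self, pre_session):
        t = pre_session.truth.stride_table
        for col in ("stride_time_ms", "cocon_lg_ta_ms", "cocon_rf_bf_ms",
                    "contraction_lg_ms", "contraction_ta_ms"):
            assert (t[col] % SAMPLE_MS == 0).all()

    def test_onsets_strictly_increasing(self, pre_session):
        for leg in ("R", "L"):
            assert (np.diff(pre_session.truth.onsets[leg]) > 0).all()

    def test_rejects_bad_inputs(self):
        p = default_params("pre")
        with pytest.raises(ValueError):
            simulate_session(p, 0, seed=1)
        with pytest.raises(ValueError):
            simulate_session(p, 4, seed=1, noise=NoiseProfile(curve_steps=3))

    def test_curve_steps_flagged_at_run_ends(self):
        rec = simulate_session(default_params("pre"), 10, seed=3,
                               noise=NoiseProfile(curve_steps=2), include_eeg=False)
        t = rec.truth.stride_table
        for leg in ("R", "L"):
            flags = t[t.leg == leg].sort_values("stride_idx")["curve_step"].to_numpy()
            assert flags[[0, 1, -2, -1]].all() and not flags[2:-2].any()

    @pytest.mark.parametrize("condition", ["pre", "post"])
    def test_calibration_against_configured_means(self, condition):
        """Ground-truth sample means within 4*sd/sqrt(n) of configured means."""
        p = default_params(condition)
        rec = simulate_session(p, 600, seed=101, include_eeg=False)
        stats = realized_statistics(rec)
        n = stats["n"].iloc[0]
        assert n >= 1000
        for feat, (mean, sd) in TABLE1[condition].items():
            tol = 4.0 * sd / np.sqrt(n)
            assert stats.loc[feat, "mean"] == pytest.approx(mean, abs=tol), feat


class TestRealizedStatistics:
    def test_matches_stride_table(self, pre_session):
        """Mask-level recount agrees with the recorded per-stride truth."""
        stats = realized_statistics(pre_session)
        t = pre_session.truth.stride_table
        for feat in ("stride_time_ms", "cocon_lg_ta_ms", "dc_lg_pct", "dc_bf_pct"):
            assert stats.loc[feat, "mean"] == pytest.approx(t[feat].mean(), rel=1e-12)

    def test_dc_bounds_and_saturation(self):
        rec = simulate_session(default_params("pre"), 5, seed=2, include_eeg=False)
        stats = realized_statistics(rec)
        for m in ("lg", "ta", "rf", "bf"):
            assert 0.0 <= stats.loc[f"dc_{m}_pct", "mean"] <= 100.0
        # force LG always on (both legs) -> DC saturates at 100
        rec.truth.masks[0][:] = 1
        rec.truth.masks[4][:] = 1
        stats = realized_statistics(rec)
        assert stats.loc["dc_lg_pct", "mean"] == pytest.approx(100.0)

    def test_requires_ground_truth(self, pre_session):
        bare = SessionRecording(emg=pre_session.emg, eeg=None)
        with pytest.raises(ValueError):
            realized_statistics(bare)

    def test_mask_validation(self):
        with pytest.raises(ValueError):
            GroundTruth(masks=np.array([[0, 2]], dtype=np.uint8),
                        onsets={"R": [0]}, stride_table=pd.DataFrame(),
                        eeg_amplitudes=None)


class TestEEGNull:
    def test_ground_truth_band_draws_identical_across_conditions(self):
        """Matched seeds give bit-identical cortical truth pre vs post."""
        pre = simulate_session(default_params("pre"), 8, seed=9, eeg_seed=77)
        post = simulate_session(default_params("post"), 8, seed=10, eeg_seed=77)
        a = pre.truth.eeg_amplitudes.filter(like="_dbu")
        b = post.truth.eeg_amplitudes.filter(like="_dbu")
        pd.testing.assert_frame_equal(a, b)

    def test_feature_table_cortical_columns_identical(self):
        pre, post = simulate_feature_tables(
            default_params("pre"), default_params("post"), 300, seed=4)
        eeg_cols = [c for c in pre.columns if c.endswith("_dbu")]
        assert len(eeg_cols) == 21
        assert pre[eeg_cols].equals(post[eeg_cols])


class TestFeatureTables:
    def test_row_counts_and_columns(self):
        pre, post = simulate_feature_tables(
            default_params("pre"), default_params("post"), 100, seed=0)
        assert len(pre) == len(post) == 100
        assert set(pre["subject_id"]) == {"S1", "S2", "S3"}

    def test_subject_effect_shared_across_conditions(self):
        p = default_params("pre")
        a = subject_params(p, 7, "S1")
        b = subject_params(default_params("post"), 7, "S1")
        # same multiplier stream: the pre/post ratio of means is preserved
        assert a.stride_time_mean_ms / p.stride_time_mean_ms == pytest.approx(
            b.stride_time_mean_ms / default_params("post").stride_time_mean_ms)
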