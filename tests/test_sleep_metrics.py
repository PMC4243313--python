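"""Standard vigilance parameters: hand-enumerated oracles and invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypnomarkov.hypnogram_io import FINE_STAGES, Hypnogram
from hypnomarkov.sleep_metrics import (
    aggregate_metrics,
    compare_groups,
    episodes,
    filter_rem_attempts,
    first_rem_item,
    metrics_frame,
    rem_latency,
    sleep_fragmentation,
    stage_latency,
)


def fine(*stages, **kw):
    return Hypnogram(subject_id=kw.pop("subject_id", "t"),
                     group=kw.pop("group", "HC-VEH"),
                     stages=stages, vocabulary="fine", **kw)


class TestEpisodes:
    def test_wake_runs_on_two_state(self, two_state_hypnogram):
        eps = episodes(two_state_hypnogram, "WAKE")
        assert [(e.start_epoch, e.length) for e in eps] == [(0, 2), (4, 1)]
        assert [e.duration(4.0) for e in eps] == [8.0, 4.0]

    def test_absent_stage_gives_empty_list(self):
        assert episodes(fine("AW", "SWS1"), "REM") == []

    def test_constant_recording_single_episode(self):
        eps = episodes(fine("REM", "REM", "REM"), "REM")
        assert [(e.start_epoch, e.length) for e in eps] == [(0, 3)]

    def test_fine_label_episodes(self):
        eps = episodes(fine("AW", "PW", "AW"), "AW")
        assert len(eps) == 2


class TestAggregateMetrics:
    def test_worked_toy_example(self, toy_fine):
        m = aggregate_metrics(toy_fine)
        assert m.wake_time == 12.0
        assert m.nrem_time == 20.0
        assert m.rem_time == 8.0
        assert m.sleep_time == 28.0
        assert m.sleep_episode_count == 2  # epochs 2-7 and 9
        assert m.wake_episode_count == 2
        assert m.rem_episode_count == 1

    def test_stage_class_conservation(self, toy_fine):
        m = aggregate_metrics(toy_fine)
        assert m.wake_time + m.nrem_time + m.rem_time == toy_fine.duration == 40.0
        assert m.sleep_time == m.nrem_time + m.rem_time

    def test_total_equals_count_times_mean(self, toy_fine):
        m = aggregate_metrics(toy_fine)
        for prefix in ("wake", "nrem", "rem", "sleep"):
            total = getattr(m, f"{prefix}_time")
            count = getattr(m, f"{prefix}_episode_count")
            mean = getattr(m, f"{prefix}_mean_duration")
            assert total == count * mean

    def test_requires_fine_vocabulary(self, two_state_hypnogram):
        with pytest.raises(ValueError, match="fine"):
            aggregate_metrics(two_state_hypnogram)

    @settings(max_examples=40, deadline=None)
    @given(stages=st.lists(st.sampled_from(FINE_STAGES), min_size=1, max_size=60))
    def test_conservation_property(self, stages):
        h = fine(*stages)
        m = aggregate_metrics(h)
        assert m.wake_time + m.nrem_time + m.rem_time == pytest.approx(h.duration)
        if m.rem_latency is not None:
            assert m.rem_latency >= 0
        if m.first_rem_item is not None:
            assert m.first_rem_item >= 4.0


class TestFragmentation:
    @pytest.mark.parametrize("stages,expected", [
        (("SWS1", "AW", "SWS1"), 1),
        (("SWS1", "AW", "PW", "SWS1"), 2),
        (("AW", "SWS1", "SWS1", "AW"), 0),
        (("SWS1", "AW", "PW", "AW", "SWS1"), 3),
        (("SWS1", "SWS2", "IS", "REM"), 0),
    ])
    def test_fine_level_counting(self, stages, expected):
        assert sleep_fragmentation(fine(*stages)) == expected

    def test_bout_level_variant(self):
        h = fine("SWS1", "AW", "PW", "AW", "SWS1")
        assert sleep_fragmentation(h, level="bout") == 1


class TestLatencies:
    def test_rem_latency_worked_example(self):
        assert rem_latency(fine("AW", "AW", "SWS1", "SWS2", "REM")) == 8.0

    def test_rem_latency_zero_when_sleep_starts_with_rem(self):
        assert rem_latency(fine("AW", "REM", "SWS1")) == 0.0

    def test_rem_latency_undefined_without_rem(self):
        assert rem_latency(fine("AW", "SWS1")) is None

    def test_sws1_latency(self):
        assert stage_latency(fine("AW", "PW", "AW", "SWS1"), "SWS1") == 12.0
        assert stage_latency(fine("SWS1", "AW"), "SWS1") == 0.0
        assert stage_latency(fine("AW", "PW"), "SWS1") is None

    def test_latency_respects_start_time(self):
        h = fine("AW", "SWS2", start_time=100.0)
        assert stage_latency(h, "SWS2") == 104.0


class TestFirstRemItem:
    def test_rem_is_run_with_interleaved_is(self):
        assert first_rem_item(fine("REM", "REM", "IS", "REM", "SWS1")) == 16.0

    def test_single_rem_epoch(self):
        assert first_rem_item(fine("AW", "REM", "AW")) == 4.0

    def test_undefined_without_rem(self):
        assert first_rem_item(fine("AW", "SWS1")) is None

    def test_preceding_is_excluded(self):
        # IS before the first REM epoch does not count toward the item
        assert first_rem_item(fine("IS", "IS", "REM", "IS")) == 8.0


class TestFilterRemAttempts:
    def test_merged_item_retained(self):
        h = fine("REM", "REM", "REM", "SWS1", "SWS1", "REM", "REM")
        # 12 s REM + 8 s gap + 8 s REM: gap < 16 s, span 28 s >= 16 s
        assert filter_rem_attempts(h).stages == h.stages

    def test_isolated_short_attempt_relabelled(self):
        h = fine("SWS1", "SWS1", "SWS1", "SWS1", "REM", "REM",
                 "SWS1", "SWS1", "SWS1", "SWS1")
        out = filter_rem_attempts(h)
        assert "REM" not in out.stages
        assert out.stages[4:6] == ("SWS1", "SWS1")

    def test_long_runs_unchanged(self):
        h = fine("REM", "REM", "REM", "REM", "SWS1", "SWS1", "SWS1", "SWS1",
                 "REM", "REM", "REM", "REM")
        assert filter_rem_attempts(h).stages == h.stages

    def test_never_increases_rem_time(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            h = fine(*rng.choice(FINE_STAGES, size=50))
            before = sum(s == "REM" for s in h.stages)
            after = sum(s == "REM" for s in filter_rem_attempts(h).stages)
            assert after <= before


def _two_way_anova_oracle(values: np.ndarray) -> dict[str, float]:
    """From-scratch balanced two-way ANOVA; values shaped (2, 2, n)."""
    a, b, n = values.shape
    grand = values.mean()
    mean_a = values.mean(axis=(1, 2))
    mean_b = values.mean(axis=(0, 2))
    mean_cell = values.mean(axis=2)
    ss_a = b * n * np.sum((mean_a - grand) ** 2)
    ss_b = a * n * np.sum((mean_b - grand) ** 2)
    ss_ab = n * np.sum(
        (mean_cell - mean_a[:, None] - mean_b[None, :] + grand) ** 2
    )
    ss_e = np.sum((values - mean_cell[:, :, None]) ** 2)
    df_e = a * b * (n - 1)
    mse = ss_e / df_e
    return {
        "treatment": (ss_a / (a - 1)) / mse,
        "rebound": (ss_b / (b - 1)) / mse,
        "interaction": (ss_ab / ((a - 1) * (b - 1))) / mse,
    }


def _metric_table(values: np.ndarray) -> pd.DataFrame:
    treatments = ("VEH", "SSRI")
    rebounds = ("HC", "RD")
    rows = []
    for i, tr in enumerate(treatments):
        for j, rb in enumerate(rebounds):
            for k, v in enumerate(values[i, j]):
                rows.append({"subject_id": f"{rb}-{tr}-{k}", "group": f"{rb}-{tr}",
                             "m": v})
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_matches_sums_of_squares_oracle(self, rng):
        values = rng.normal(size=(2, 2, 6)) + np.array([[0.0, 1.0], [0.5, 2.0]])[..., None]
        oracle = _two_way_anova_oracle(values)
        cmp = compare_groups(_metric_table(values), "m")
        assert cmp.f_statistic("C(treatment)") == pytest.approx(oracle["treatment"], abs=1e-8)
        assert cmp.f_statistic("C(rebound)") == pytest.approx(oracle["rebound"], abs=1e-8)
        assert cmp.f_statistic("C(treatment):C(rebound)") == pytest.approx(
            oracle["interaction"], abs=1e-8)

    def test_degenerate_constant_values(self):
        values = np.ones((2, 2, 3))
        cmp = compare_groups(_metric_table(values), "m")
        assert np.isnan(cmp.f_statistic("C(treatment)"))
        assert cmp.note

    def test_undefined_values_dropped_pairwise(self, rng):
        df = _metric_table(rng.normal(size=(2, 2, 4)))
        df.loc[0, "m"] = np.nan
        cmp = compare_groups(df, "m")
        assert cmp.n_dropped == 1 and cmp.n_used == 15

    def test_empty_cell_rejected(self, rng):
        df = _metric_table(rng.normal(size=(2, 2, 4)))
        df = df[df["group"] != "HC-VEH"]
        with pytest.raises(ValueError, match="cell"):
            compare_groups(df, "m")

    def test_tukey_reports_all_six_pairs(self, rng):
        cmp = compare_groups(_metric_table(rng.normal(size=(2, 2, 5))), "m")
        assert len(cmp.tukey) == 6

    def test_metrics_frame_round_trip(self, toy_fine):
        df = metrics_frame([aggregate_metrics(toy_fine)])
        assert df.loc[0, "subject_id"] == "toy"
        assert df.loc[0, "sleep_fragmentation"] == 1
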