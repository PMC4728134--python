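"""Per-filopodium metric computations and their invariants."""


import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from filodyn import (
    classify_dynamics,
    count_events,
    filopodium_metrics,
    growth_cone_summary,
    inactivity,
    lifetime_bin,
    mean_speed,
    step_deltas,
)

from conftest import make_session, make_track, naive_metrics, WORKED_LENGTHS


class TestStepDeltas:
    def test_constant_length_is_all_static(self):
        steps = step_deltas(make_track((2.0, 2.0, 2.0)))
        assert [s.kind for s in steps] == ["static", "static"]

    def test_worked_trajectory_partition(self, worked_track):
        steps = step_deltas(worked_track)
        assert [round(s.delta_um, 10) for s in steps] == [0.5, 0.2, 0.8, 0.0]
        assert [s.kind for s in steps] == [
            "extension", "static", "extension", "static",
        ]

    def test_delta_exactly_at_threshold_is_movement(self):
        up = step_deltas(make_track((1.0, 1.3)))
        down = step_deltas(make_track((1.3, 1.0)))
        assert up[0].kind == "extension"
        assert down[0].kind == "retraction"

    def test_single_sample_gives_no_steps(self):
        assert step_deltas(make_track((1.0,))) == []

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            step_deltas(make_track((1.0, 2.0)), 0.0)


class TestEventsSpeedInactivity:
    def test_worked_trajectory_values(self, worked_track):
        steps = step_deltas(worked_track)
        assert count_events(steps) == (2, 0)
        assert mean_speed(steps, 1.0) == pytest.approx(0.65)
        assert inactivity(steps) == pytest.approx(0.5)

    def test_adjacent_moving_steps_merge_into_events(self):
        steps = step_deltas(make_track((0.0, 0.5, 1.0, 0.5)))
        assert count_events(steps) == (1, 1)

    def test_empty_steps(self):
        assert count_events([]) == (0, 0)
        assert mean_speed([], 1.0) is None
        assert inactivity([]) is None

    def test_all_static_track(self):
        steps = step_deltas(make_track((1.0,) * 5))
        assert mean_speed(steps, 1.0) is None
        assert inactivity(steps) == 1.0

    def test_single_moving_step(self):
        steps = step_deltas(make_track((0.0, 1.2)))
        assert mean_speed(steps, 1.0) == pytest.approx(1.2)
        assert inactivity(steps) == 0.0

    def test_speed_scales_with_interval(self):
        # a 1.2 um change over a 30-min frame is a slow filopodium
        steps = step_deltas(make_track((0.0, 1.2), interval=30.0))
        assert mean_speed(steps, 30.0) == pytest.approx(0.04)


class TestClassification:
    @pytest.mark.parametrize(
        "lifetime,left,right,expected",
        [
            (5, False, False, "transient"),
            (70, False, True, "stable"),
            (60, True, True, "stable"),
            (5, False, True, "indeterminate"),
            (5, True, False, "indeterminate"),
            (30, False, False, "intermediate"),
            (8, False, False, "intermediate"),
            (7.9, False, False, "transient"),
            (59, False, True, "indeterminate"),
        ],
    )
    def test_classify(self, lifetime, left, right, expected):
        assert classify_dynamics(lifetime, left, right) == expected

    def test_negative_lifetime_rejected(self):
        with pytest.raises(ValueError):
            classify_dynamics(-1, False, False)
        with pytest.raises(ValueError):
            lifetime_bin(-0.1)

    @pytest.mark.parametrize(
        "lifetime,label",
        [
            (0, "<1 min"), (1, "<1 min"), (1.9, "<1 min"),
            (2, "2-3 min"), (3, "2-3 min"),
            (4, "4-7 min"), (7, "4-7 min"),
            (8, "8-15 min"), (15, "8-15 min"),
            (16, "16-31 min"), (31, "16-31 min"),
            (32, "32-59 min"), (59, "32-59 min"),
            (60, ">=60 min"), (1000, ">=60 min"),
        ],
    )
    def test_lifetime_bins(self, lifetime, label):
        assert lifetime_bin(lifetime) == label

    @given(st.floats(min_value=0, max_value=200), st.floats(min_value=0, max_value=50))
    @settings(derandomize=True, max_examples=200)
    def test_classification_monotone_in_lifetime(self, lifetime, bump):
        # growing older can never demote a filopodium from stable to transient
        order = {"transient": 0, "indeterminate": 1, "intermediate": 1, "stable": 2}
        a = classify_dynamics(lifetime, False, False)
        b = classify_dynamics(lifetime + bump, False, False)
        assert order[b] >= order[a]


class TestFilopodiumMetrics:
    def test_worked_trajectory_composition(self, worked_track):
        m = filopodium_metrics(worked_track, 1.0, window=(0.0, 60.0))
        assert m.lifetime_min == 4.0
        assert (m.n_ext_events, m.n_ret_events) == (2, 0)
        assert m.mean_speed_um_min == pytest.approx(0.65)
        assert m.inactivity == pytest.approx(0.5)
        assert not m.left_censored and not m.right_censored
        assert m.dyn_class == "transient"
        assert m.lifetime_bin == "4-7 min"
        assert m.mean_length_um == pytest.approx(np.mean(WORKED_LENGTHS))

    def test_track_at_window_start_is_left_censored(self):
        track = make_track(WORKED_LENGTHS, t0=0.0)
        m = filopodium_metrics(track, 1.0, window=(0.0, 60.0))
        assert m.left_censored and not m.right_censored
        assert m.dyn_class == "indeterminate"

    def test_full_window_constant_track_is_stable(self):
        track = make_track((2.0,) * 61, t0=0.0)
        m = filopodium_metrics(track, 1.0, window=(0.0, 60.0))
        assert m.lifetime_min == 60.0
        assert m.inactivity == 1.0
        assert m.mean_speed_um_min is None
        assert m.dyn_class == "stable"
        assert m.left_censored and m.right_censored

    def test_single_frame_track_degenerate(self):
        track = make_track((1.0,), t0=5.0)
        m = filopodium_metrics(track, 1.0, window=(0.0, 60.0))
        assert m.lifetime_min == 0.0
        assert m.inactivity is None
        assert m.mean_speed_um_min is None
        assert m.dyn_class == "transient"
        assert m.lifetime_bin == "<1 min"

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=10.0, allow_nan=False),
            min_size=1,
            max_size=20,
        )
    )
    @settings(derandomize=True, max_examples=300)
    def test_agrees_with_bruteforce_oracle(self, lengths):
        track = make_track(lengths, t0=2.0)
        m = filopodium_metrics(track, 1.0, window=(0.0, 60.0))
        ref = naive_metrics(lengths, 1.0, 0.3, t0=2.0, window=(0.0, 60.0))
        assert m.n_frames == ref["n_frames"]
        assert (m.n_ext_events, m.n_ret_events) == (
            ref["n_ext_events"], ref["n_ret_events"],
        )
        assert m.dyn_class == ref["dyn_class"]
        assert m.lifetime_bin == ref["lifetime_bin"]
        for field in ("lifetime_min", "mean_length_um", "mean_speed_um_min", "inactivity"):
            got, want = getattr(m, field), ref[field]
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want, abs=1e-12)

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=5.0, allow_nan=False),
            min_size=2,
            max_size=20,
        )
    )
    @settings(derandomize=True, max_examples=300)
    def test_partition_and_complement_invariants(self, lengths):
        track = make_track(lengths)
        steps = step_deltas(track)
        n_static = sum(1 for s in steps if not s.moving)
        n_moving = sum(1 for s in steps if s.moving)
        assert n_static + n_moving == track.n_frames - 1
        inact = inactivity(steps)
        assert 0.0 <= inact <= 1.0
        assert inact + n_moving / len(steps) == pytest.approx(1.0)
        speed = mean_speed(steps, 1.0)
        assert (speed is None) == (inact == 1.0)
        if speed is not None:
            assert speed >= 0.3 / 1.0 - 1e-12


class TestGrowthConeSummary:
    def test_counts_and_fractions(self):
        tracks = [
            make_track((1.0, 1.5), f"t{i}", t0=float(i + 1)) for i in range(9)
        ] + [make_track((2.0,) * 61, "s0", t0=0.0)]
        session = make_session(tracks)
        summary = growth_cone_summary(session)
        assert summary.n_filopodia == 10
        assert summary.class_counts["transient"] == 9
        assert summary.class_counts["stable"] == 1
        assert summary.class_counts["transient"] / summary.n_filopodia == 0.9

    def test_empty_session(self):
        summary = growth_cone_summary(make_session([]))
        assert summary.n_filopodia == 0
        assert summary.mean_length_um is None
        assert all(v == 0 for v in summary.class_counts.values())

    def test_grand_mean_of_mean_lengths(self):
        tracks = [
            make_track((1.0, 1.0), "a", t0=1.0),
            make_track((2.0, 2.0), "b", t0=1.0),
            make_track((3.0, 3.0), "c", t0=1.0),
        ]
        summary = growth_cone_summary(make_session(tracks))
        assert summary.mean_length_um == pytest.approx(2.0)
        assert summary.bin_counts["<1 min"] == 3
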