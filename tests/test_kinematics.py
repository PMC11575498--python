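import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadcoord.errors import InputError, LengthError
from dyadcoord.kinematics import (
    compute_speed,
    preprocess,
    remove_outliers,
    smooth,
    trim_series,
)
from dyadcoord.pose_io import CANONICAL_MARKERS, MarkerId, PoseTrack


def _track_from_xy(xy, fps=60.0):
    xy = np.asarray(xy, dtype=float)
    data = {
        m: np.column_stack([xy[:, 0], xy[:, 1], np.full(len(xy), 0.9)])
        for m in CANONICAL_MARKERS
    }
    return PoseTrack(fps=fps, data=data)


class TestComputeSpeed:
    def test_stationary_marker_gives_zeros(self):
        track = _track_from_xy([[5.0, 5.0]] * 10)
        s = compute_speed(track, CANONICAL_MARKERS[0])
        np.testing.assert_array_equal(s.values, np.zeros(9))

    def test_3_4_5_displacement_at_60fps(self):
        track = _track_from_xy([[0.0, 0.0], [3.0, 4.0]])
        s = compute_speed(track, CANONICAL_MARKERS[0])
        assert s.values[0] == pytest.approx(300.0)  # 5 px / (1/60 s)

    def test_length_is_frames_minus_one(self, rng):
        track = _track_from_xy(rng.normal(size=(5400, 2)))
        assert len(compute_speed(track, CANONICAL_MARKERS[0])) == 5399

    def test_single_frame_rejected(self):
        track = _track_from_xy([[0.0, 0.0]])
        with pytest.raises(InputError):
            compute_speed(track, CANONICAL_MARKERS[0])

    @pytest.mark.parametrize("angle", [0.3, np.pi / 2, 2.0])
    def test_rotation_invariance(self, rng, angle):
        xy = rng.normal(size=(300, 2)) * 50
        c, s_ = np.cos(angle), np.sin(angle)
        rot = xy @ np.array([[c, -s_], [s_, c]]) + [10.0, -4.0]
        v1 = compute_speed(_track_from_xy(xy), CANONICAL_MARKERS[0]).values
        v2 = compute_speed(_track_from_xy(rot), CANONICAL_MARKERS[0]).values
        np.testing.assert_allclose(v1, v2, atol=1e-9)


class TestTrim:
    def test_surplus_removed_from_end(self, speed_factory):
        s = speed_factory(np.arange(54_099, dtype=float))
        out = trim_series(s, 54_000)
        assert len(out) == 53_999
        assert out.values[-1] == 53_998.0  # end dropped, start intact

    def test_exact_length_is_identity(self, speed_factory):
        s = speed_factory(np.arange(59, dtype=float))
        assert trim_series(s, 60) is s

    def test_shorter_input_is_length_error(self, speed_factory):
        with pytest.raises(LengthError):
            trim_series(speed_factory(np.zeros(10)), 60)


class TestRemoveOutliers:
    def test_clean_series_unchanged(self, rng, speed_factory):
        # bounded (uniform) noise never reaches 3 local SDs
        s = speed_factory(10.0 + 0.1 * rng.uniform(-1, 1, size=600))
        out = remove_outliers(s)
        np.testing.assert_array_equal(out.values, s.values)
        assert out.outlier_fraction == 0.0

    def test_single_spike_replaced_by_neighbour_midpoint(self, speed_factory):
        values = np.zeros(181)
        values[::2] = 1.0  # alternating series: local SD > 0 everywhere
        values[90] = 500.0  # far beyond 3 local SDs
        s = speed_factory(values)
        out = remove_outliers(s)
        # index 90 had value 1.0-slot; replaced by midpoint of neighbours (0, 0)
        assert out.values[90] == pytest.approx(
            0.5 * (values[89] + values[91])
        )
        assert out.outlier_fraction == pytest.approx(1 / 181)

    def test_spike_detection_against_local_statistics(self, rng, speed_factory):
        """A hand-computed 61-sample local mean/SD flags the injected spike."""
        base = 5.0 + rng.normal(size=600)
        idx = 300
        window = slice(idx - 30, idx + 31)
        local = base[window].copy()
        spike = local.mean() + 10 * local.std(ddof=1)
        values = base.copy()
        values[idx] = spike
        out = remove_outliers(speed_factory(values))
        assert out.values[idx] != spike
        assert out.values[idx] == pytest.approx(
            0.5 * (values[idx - 1] + values[idx + 1]), rel=1e-6
        )

    def test_injected_spike_fraction_recovered(self, rng, speed_factory):
        n = 6000
        values = 20.0 + rng.normal(size=n)
        n_spikes = int(0.02 * n)
        pos = rng.choice(np.arange(30, n - 30), size=n_spikes, replace=False)
        values[pos] += 40.0  # ~40 local SDs
        out = remove_outliers(speed_factory(values))
        assert out.outlier_fraction == pytest.approx(0.02, abs=0.005)

    def test_idempotent_on_own_output(self, rng, speed_factory):
        # bounded background noise with isolated large spikes: once the
        # spikes are bridged, a second pass finds nothing new
        values = 20.0 + rng.uniform(-1, 1, size=2000)
        values[rng.choice(2000, size=20, replace=False)] += 50.0
        once = remove_outliers(speed_factory(values))
        twice = remove_outliers(once)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_constant_series_flags_nothing(self, speed_factory):
        out = remove_outliers(speed_factory(np.full(600, 7.0)))
        assert out.outlier_fraction == 0.0


class TestSmooth:
    def test_constant_unchanged(self, speed_factory):
        out = smooth(speed_factory(np.full(100, 2.5)))
        np.testing.assert_allclose(out.values, 2.5)

    def test_impulse_spreads_to_plateau(self, speed_factory):
        values = np.zeros(200)
        values[100] = 1.0
        out = smooth(speed_factory(values))  # 0.5 s -> 30 samples
        covered = out.values[out.values > 0]
        assert covered.size == 30
        np.testing.assert_allclose(covered, 1 / 30)

    def test_matches_naive_per_window_mean(self, rng, speed_factory):
        values = rng.normal(size=400)
        out = smooth(speed_factory(values), window=0.5)
        w = 30
        lo, hi = w // 2, (w - 1) // 2  # pandas centered-window convention
        naive = np.array(
            [
                values[max(0, i - lo) : min(len(values), i + hi + 1)].mean()
                for i in range(len(values))
            ]
        )
        np.testing.assert_allclose(out.values, naive)

    @settings(max_examples=30, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0, max_value=1e3),
            min_size=40,
            max_size=200,
        )
    )
    def test_variance_never_increases_and_stays_nonnegative(self, values):
        from dyadcoord.kinematics import SpeedSeries

        series = SpeedSeries(
            fps=60.0, values=np.asarray(values), marker=CANONICAL_MARKERS[0]
        )
        out = smooth(series)
        assert np.all(out.values >= 0)
        assert out.values.var() <= np.asarray(values).var() + 1e-9


class TestPreprocess:
    def test_returns_four_series_of_expected_length(self, short_session):
        speeds = preprocess(short_session.track, short_session.track.frames)
        assert set(speeds) == set(CANONICAL_MARKERS)
        assert all(len(s) == short_session.track.frames - 1 for s in speeds.values())

    def test_equals_manual_chaining(self, short_session):
        track = short_session.track
        marker = MarkerId("B", "right")
        auto = preprocess(track, track.frames)[marker]
        manual = smooth(
            remove_outliers(trim_series(compute_speed(track, marker), track.frames))
        )
        np.testing.assert_array_equal(auto.values, manual.values)

    def test_order_matters_on_spiked_input(self, rng, speed_factory):
        """Smoothing before outlier removal smears spikes: the composition
        order is observable."""
        values = 20.0 + rng.normal(size=1200)
        values[600] += 300.0
        s = speed_factory(values)
        canonical = smooth(remove_outliers(s)).values
        swapped = remove_outliers(smooth(s)).values
        assert not np.allclose(canonical, swapped)
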