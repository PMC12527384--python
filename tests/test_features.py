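"""Kinetic features: closed-form examples and geometric invariances."""

import numpy as np
import pandas as pd
import pytest

from trackpheno import features as F
from trackpheno.types import TrackphenoWarning, TrackTable

from conftest import concat_tracks, make_track


class TestInterpolation:
    def test_linear_signal_recovered_exactly(self):
        # observed at t=0,1,3 with x linear in t: interpolation fills x(2)=2
        df = pd.DataFrame(
            {
                "mouse_id": "m1", "position_id": "p1", "track_id": 1,
                "t": [0.0, 1.0, 3.0], "x": [0.0, 1.0, 3.0], "y": 0.0, "z": 0.0,
            }
        )
        out = F.interpolate_to_grid(TrackTable.from_dataframe(df), dt=1.0)
        assert list(out.df["t"]) == [0.0, 1.0, 2.0, 3.0]
        assert out.df["x"].tolist() == pytest.approx([0.0, 1.0, 2.0, 3.0])

    def test_complete_track_is_identity(self):
        track = make_track(np.random.default_rng(0).normal(size=(6, 3)))
        out = F.interpolate_to_grid(track, dt=1.0)
        assert np.allclose(out.df[["x", "y", "z"]], track.df[["x", "y", "z"]], atol=1e-12)

    def test_quadratic_motion_gets_linear_estimate(self):
        # x = t^2 sampled at t=0,2: the linear estimate at t=1 is 2, not 1
        df = pd.DataFrame(
            {
                "mouse_id": "m1", "position_id": "p1", "track_id": 1,
                "t": [0.0, 2.0], "x": [0.0, 4.0], "y": 0.0, "z": 0.0,
            }
        )
        out = F.interpolate_to_grid(TrackTable.from_dataframe(df), dt=1.0)
        assert out.df.loc[out.df["t"] == 1.0, "x"].item() == pytest.approx(2.0)

    def test_random_dropout_of_linear_motion_recovered(self):
        # 30% of interior frames removed from affine-in-t motion: exact recovery
        rng = np.random.default_rng(42)
        t_full = np.arange(11, dtype=float)
        v = np.array([1.5, -2.0, 0.5])
        pos = np.outer(t_full, v)
        keep = np.ones(11, dtype=bool)
        keep[rng.choice(np.arange(1, 10), size=3, replace=False)] = False
        df = pd.DataFrame(
            {
                "mouse_id": "m1", "position_id": "p1", "track_id": 1,
                "t": t_full[keep], "x": pos[keep, 0], "y": pos[keep, 1], "z": pos[keep, 2],
            }
        )
        out = F.interpolate_to_grid(TrackTable.from_dataframe(df), dt=1.0)
        assert len(out.df) == 11
        assert np.allclose(out.df[["x", "y", "z"]], pos, atol=1e-9)

    def test_span_shorter_than_dt_drops_track(self):
        short = make_track([[0, 0, 0], [1, 0, 0]], dt=0.1, tid=1)
        ok = make_track(np.zeros((5, 3)), dt=1.0, tid=2)
        both = concat_tracks([short, ok])
        with pytest.warns(TrackphenoWarning, match="span shorter"):
            out = F.interpolate_to_grid(both, dt=1.0)
        assert out.n_tracks == 1

    def test_dt_must_be_positive(self):
        with pytest.raises(ValueError):
            F.interpolate_to_grid(make_track(np.zeros((3, 3))), dt=0.0)


class TestCrop:
    def test_crops_to_minimum_length(self):
        tracks = [make_track(np.zeros((n, 3)), tid=i) for i, n in enumerate([8, 10, 14], 1)]
        out = F.crop_common_length(concat_tracks(tracks))
        assert (out.groupby_tracks().size() == 8).all()
        assert out.report["common_length"] == 8

    def test_equal_lengths_identity(self):
        tracks = [make_track(np.random.default_rng(i).normal(size=(5, 3)), tid=i) for i in (1, 2)]
        table = concat_tracks(tracks)
        out = F.crop_common_length(table)
        pd.testing.assert_frame_equal(out.df, table.df)

    def test_too_short_errors(self):
        tracks = [make_track(np.zeros((2, 3)), tid=1), make_track(np.zeros((9, 3)), tid=2)]
        with pytest.raises(ValueError, match="minimal common track length"):
            F.crop_common_length(concat_tracks(tracks))

    def test_twenty_minute_frames_span_2p6_hours(self):
        # 20-min interval: cropping a 2.6 h span keeps L with (L-1)*dt <= 2.6
        dt = 1.0 / 3.0
        L = int(np.floor(2.6 / dt + 1e-9)) + 1
        tracks = [
            make_track(np.zeros((L, 3)), dt=dt, tid=1),
            make_track(np.zeros((17, 3)), dt=dt, tid=2),
        ]
        out = F.crop_common_length(concat_tracks(tracks))
        assert out.report["common_length"] == L
        spans = out.groupby_tracks()["t"].agg(lambda s: s.max() - s.min())
        assert np.allclose(spans, (L - 1) * dt)


class TestKinetics:
    def test_static_track_all_zero(self):
        tensor = F.compute_kinetic_features(make_track(np.ones((5, 3)) * 7.0))
        for f in ("speed", "disp2", "disp_d", "disp_l", "persistence"):
            assert np.allclose(tensor.values[0, :, tensor.feature_names.index(f)], 0.0)

    def test_straight_line_speed_and_persistence(self):
        # collinear 2 µm steps at dt = 1/3 h: speed 6 µm/h, persistence 1
        pts = np.array([[2.0 * i, 0, 0] for i in range(6)])
        tensor = F.compute_kinetic_features(make_track(pts, dt=1.0 / 3.0))
        speed = tensor.values[0, :, tensor.feature_names.index("speed")]
        pers = tensor.values[0, :, tensor.feature_names.index("persistence")]
        assert np.allclose(speed[1:], 6.0)
        assert np.allclose(pers[1:], 1.0)

    def test_l_shaped_path_geometry(self):
        tensor = F.compute_kinetic_features(
            make_track([[0, 0, 0], [1, 0, 0], [1, 1, 0]], dt=1.0)
        )
        names = tensor.feature_names
        v = tensor.values[0]
        assert v[2, names.index("disp_l")] == pytest.approx(2.0)
        assert v[2, names.index("disp_d")] == pytest.approx(np.sqrt(2.0))
        assert v[2, names.index("persistence")] == pytest.approx(np.sqrt(2.0) / 2.0)
        assert v[2, names.index("disp2")] == pytest.approx(2.0)

    def test_invasion_is_edge_distance_rate(self):
        tensor = F.compute_kinetic_features(
            make_track(
                [[1, 0, 0], [3, 0, 0], [2, 0, 0]], dt=0.5, dist_to_edge=[1.0, 3.0, 2.0]
            )
        )
        inv = tensor.values[0, :, tensor.feature_names.index("invasion")]
        assert inv == pytest.approx([0.0, 4.0, -2.0])

    def test_invasion_without_edge_column_errors(self):
        with pytest.raises(ValueError, match="dist_to_edge"):
            F.compute_kinetic_features(make_track(np.zeros((4, 3))), include_invasion=True)

    def test_translation_invariance(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(7, 3))
        t1 = F.compute_kinetic_features(make_track(pts))
        t2 = F.compute_kinetic_features(make_track(pts + np.array([100.0, -50.0, 3.0])))
        assert np.allclose(t1.values, t2.values, atol=1e-9)

    def test_rotation_invariance_of_kinetics(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(7, 3))
        theta = 0.7
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        t1 = F.compute_kinetic_features(make_track(pts))
        t2 = F.compute_kinetic_features(make_track(pts @ R.T))
        assert np.allclose(t1.values, t2.values, atol=1e-9)

    def test_ordering_and_monotonicity_invariants(self, small_tensor):
        _, tensor = small_tensor
        names = tensor.feature_names
        disp_l = tensor.values[:, :, names.index("disp_l")]
        disp_d = tensor.values[:, :, names.index("disp_d")]
        pers = tensor.values[:, :, names.index("persistence")]
        speed = tensor.values[:, :, names.index("speed")]
        assert np.all(disp_l >= disp_d - 1e-9)
        assert np.all(disp_d >= 0)
        assert np.all((pers >= 0) & (pers <= 1 + 1e-12))
        assert np.all(speed >= 0)
        assert np.all(np.diff(disp_l, axis=1) >= -1e-9)

    def test_persistence_mode_reciprocal(self):
        pts = [[0, 0, 0], [1, 0, 0], [1, 1, 0]]
        net = F.compute_kinetic_features(make_track(pts), persistence_mode="net_over_path")
        path = F.compute_kinetic_features(make_track(pts), persistence_mode="path_over_net")
        i = net.feature_names.index("persistence")
        assert path.values[0, 2, i] == pytest.approx(1.0 / net.values[0, 2, i])


from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    pts=arrays(np.float64, st.tuples(st.integers(3, 10), st.just(3)),
               elements=st.floats(-100, 100)),
    shift=arrays(np.float64, (3,), elements=st.floats(-1000, 1000)),
)
def test_property_kinetics_translation_invariant_and_ordered(pts, shift):
    """disp_l >= disp_d, persistence in [0,1], translation invariance."""
    t1 = F.compute_kinetic_features(make_track(pts))
    t2 = F.compute_kinetic_features(make_track(pts + shift))
    assert np.allclose(t1.values, t2.values, atol=1e-6)
    names = t1.feature_names
    disp_l = t1.values[0, :, names.index("disp_l")]
    disp_d = t1.values[0, :, names.index("disp_d")]
    pers = t1.values[0, :, names.index("persistence")]
    assert np.all(disp_l >= disp_d - 1e-9)
    assert np.all((pers >= 0) & (pers <= 1 + 1e-9))


class TestSummaries:
    def test_mean_and_range(self):
        pts = [[0, 0, 0], [1, 0, 0], [1, 1, 0]]
        tensor = F.compute_kinetic_features(make_track(pts, dt=1.0))
        s = F.summarize_track_features(tensor)
        assert s["mean_disp2"].item() == pytest.approx((0 + 1 + 2) / 3)
        assert s["disp_l_range"].item() == pytest.approx(2.0)

    def test_constant_feature_zero_range(self):
        tensor = F.compute_kinetic_features(make_track(np.ones((4, 3))))
        s = F.summarize_track_features(tensor)
        assert s["speed_range"].item() == 0.0
        assert s["mean_speed"].item() == 0.0

    def test_explicit_arithmetic(self):
        from trackpheno.types import FeatureTensor
        import pandas as pd

        tensor = FeatureTensor(
            track_index=pd.MultiIndex.from_tuples(
                [("m1", "p1", 1)], names=["mouse_id", "position_id", "track_id"]
            ),
            time_grid=np.array([0.0, 1.0, 2.0]),
            feature_names=["f"],
            values=np.array([[[1.0], [4.0], [2.0]]]),
        )
        s = F.summarize_track_features(tensor)
        assert s["mean_f"].item() == pytest.approx(7 / 3)
        assert s["f_range"].item() == pytest.approx(3.0)
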