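import warnings

import numpy as np
import pandas as pd
import pytest

from trackpheno import features as F
from trackpheno.simulate import SceneConfig, simulate_scene
from trackpheno.types import TrackphenoWarning, TrackTable


@pytest.fixture(scope="session")
def small_scene():
    """Shared small 3-mouse scene with dropout and planted vessels."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", TrackphenoWarning)
        return simulate_scene(
            n_tracks_per_archetype=6,
            seed=101,
            dropout_rate=0.15,
            vessel_near_archetype="invading",
            vessels_per_position=1,
        )


@pytest.fixture(scope="session")
def small_tensor(small_scene):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", TrackphenoWarning)
        t = F.interpolate_to_grid(small_scene.tracks, small_scene.config.dt)
        t = F.crop_common_length(t)
        return t, F.compute_kinetic_features(t)


def make_track(points, dt=1.0, mouse="m1", pos="p1", tid=1, dist_to_edge=None):
    """TrackTable from an explicit list of (x, y, z) positions."""
    pts = np.asarray(points, dtype=float)
    df = pd.DataFrame(
        {
            "mouse_id": mouse,
            "position_id": pos,
            "track_id": tid,
            "t": dt * np.arange(len(pts)),
            "x": pts[:, 0],
            "y": pts[:, 1],
            "z": pts[:, 2] if pts.shape[1] > 2 else 0.0,
        }
    )
    if dist_to_edge is not None:
        df["dist_to_edge"] = np.asarray(dist_to_edge, dtype=float)
    return TrackTable.from_dataframe(df)


def concat_tracks(tables):
    df = pd.concat([t.df for t in tables], ignore_index=True)
    cols = set()
    for t in tables:
        cols.update(t.extra_features)
    return TrackTable.from_dataframe(df, extra_features=sorted(cols))
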