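"""Small-scale phenotyping: single-cell spatial statistics against the TME.

Tracked cell positions are measured against static point clouds of
microenvironment components (e.g. SR101+ glia, CD20r+ macrophages, blood
vessel spots): mean distance to the k nearest fellow cells (local density),
counts within a radius, minimum component distances, and proximity
classification.  Components are treated as a single static snapshot; for
track-level values, per-timepoint measurements are averaged over time.

Spatial features can be integrated *upstream* (appended to the feature
tensor before clustering) or *downstream* (summarized per behavioral
cluster after clustering).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import stats as tp_stats
from .types import (
    TRACK_KEY,
    ClusterResult,
    FeatureTensor,
    TMEComponentSet,
    TrackphenoWarning,
    TrackTable,
)

#: Proximity thresholds (µm, inclusive) by the kind of reference object:
#: rendered surfaces have extended boundaries, spot detections are
#: centroids, so spots warrant a more stringent cutoff.
PROXIMITY_THRESHOLDS = {"surface_sample": 15.0, "spot": 3.0}

DEFAULT_RADIUS = 30.0  # µm, neighborhood radius for component counts


def knn_mean_distance(cells: np.ndarray, k: int) -> np.ndarray:
    """Mean Euclidean distance from each cell to its k nearest other cells.

    The local-density proxy: small values mean densely packed cells.  Cells
    with fewer than k others available get NaN (missing, never padded).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    cells = np.asarray(cells, dtype=float)
    n = cells.shape[0]
    out = np.full(n, np.nan)
    if n <= k:
        return out
    tree = cKDTree(cells)
    dist, _ = tree.query(cells, k=k + 1)  # includes self at distance 0
    out[:] = dist[:, 1:].mean(axis=1)
    return out


def count_within_radius(
    cells: np.ndarray,
    component: TMEComponentSet,
    radius: float = DEFAULT_RADIUS,
) -> np.ndarray:
    """Number of component points within ``radius`` µm (boundary inclusive)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    cells = np.asarray(cells, dtype=float)
    pts = np.asarray(component.points, dtype=float)
    if pts.shape[0] == 0:
        warnings.warn(
            f"component {component.component_name!r} is empty; all counts 0",
            TrackphenoWarning,
            stacklevel=2,
        )
        return np.zeros(cells.shape[0], dtype=int)
    tree = cKDTree(pts)
    counts = tree.query_ball_point(cells, r=radius, return_length=True)
    return np.asarray(counts, dtype=int)


def min_component_distance(cells: np.ndarray, component: TMEComponentSet) -> np.ndarray:
    """Euclidean distance from each cell to its nearest component point."""
    cells = np.asarray(cells, dtype=float)
    pts = np.asarray(component.points, dtype=float)
    if pts.shape[0] == 0:
        warnings.warn(
            f"component {component.component_name!r} is empty; distances missing",
            TrackphenoWarning,
            stacklevel=2,
        )
        return np.full(cells.shape[0], np.nan)
    tree = cKDTree(pts)
    dist, _ = tree.query(cells, k=1)
    return np.asarray(dist, dtype=float)


def classify_proximity(
    min_dist: np.ndarray,
    object_kind: str | None = None,
    threshold: float | None = None,
) -> np.ndarray:
    """Classify cells as 'close' to a component: min_dist <= threshold.

    The threshold defaults by reference-object kind (surface boundaries:
    15 µm; centroid spots: 3 µm) and may be overridden explicitly.  Missing
    distances (empty component) are never close.
    """
    if threshold is None:
        if object_kind is None:
            raise ValueError("provide object_kind or an explicit threshold")
        if object_kind not in PROXIMITY_THRESHOLDS:
            raise ValueError(f"unknown object_kind {object_kind!r}")
        threshold = PROXIMITY_THRESHOLDS[object_kind]
    d = np.asarray(min_dist, dtype=float)
    out = np.zeros(d.shape, dtype=bool)
    finite = np.isfinite(d)
    out[finite] = d[finite] <= threshold
    return out


def write_components_csv(components: dict[tuple, list[TMEComponentSet]], path) -> None:
    """Write TME component point clouds as one long CSV."""
    rows = []
    for (mouse, pos), sets in components.items():
        for comp in sets:
            pts = np.asarray(comp.points, dtype=float)
            for x, y, z in pts:
                rows.append(
                    {
                        "mouse_id": mouse,
                        "position_id": pos,
                        "component_name": comp.component_name,
                        "x": x,
                        "y": y,
                        "z": z,
                        "object_kind": comp.object_kind,
                    }
                )
    pd.DataFrame(
        rows,
        columns=["mouse_id", "position_id", "component_name", "x", "y", "z", "object_kind"],
    ).to_csv(path, index=False)


def read_components_csv(path) -> dict[tuple, list[TMEComponentSet]]:
    """Read the component CSV written by :func:`write_components_csv`."""
    df = pd.read_csv(path, dtype={"mouse_id": str, "position_id": str})
    req = ["mouse_id", "position_id", "component_name", "x", "y", "z", "object_kind"]
    missing = [c for c in req if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: component CSV missing columns {missing}")
    out: dict[tuple, list[TMEComponentSet]] = {}
    for (mouse, pos, name), g in df.groupby(
        ["mouse_id", "position_id", "component_name"], sort=False
    ):
        kinds = g["object_kind"].unique()
        if len(kinds) != 1:
            raise ValueError(
                f"component {name!r} at {(mouse, pos)} has mixed object kinds {list(kinds)}"
            )
        comp = TMEComponentSet(
            component_name=name,
            points=g[["x", "y", "z"]].to_numpy(dtype=float),
            object_kind=kinds[0],
        )
        comp.validate()
        out.setdefault((mouse, pos), []).append(comp)
    return out


@dataclass
class SpatialFeatureTable:
    """Per-(track, timepoint) spatial features plus per-track time means."""

    per_timepoint: pd.DataFrame  # keyed like the track table
    per_track: pd.DataFrame  # indexed by track key, time-averaged
    feature_names: list[str] = field(default_factory=list)
    proximity_flags: pd.DataFrame | None = None  # per track: close_<comp> booleans


def compute_spatial_features(
    table: TrackTable,
    components: dict[tuple, list[TMEComponentSet]],
    knn_list: tuple[int, ...] = (3, 10),
    radius: float = DEFAULT_RADIUS,
    proximity_overrides: dict[str, float] | None = None,
) -> SpatialFeatureTable:
    """Measure every tracked cell against the TME components of its position.

    ``components`` maps (mouse_id, position_id) to that position's component
    sets.  kNN density is computed among tumor cells of the same position
    and timepoint; component counts/min-distances against the position's
    static snapshot.  Track-level values are means over the track's
    timepoints; proximity flags are decided on the track-level mean minimum
    distance.
    """
    proximity_overrides = proximity_overrides or {}
    df = table.df.copy()
    comp_names: list[str] = []
    for sets in components.values():
        for c in sets:
            c.validate()
            if c.component_name not in comp_names:
                comp_names.append(c.component_name)

    feat_cols: list[str] = [f"dist_{k}_neigh" for k in knn_list]
    for name in comp_names:
        feat_cols += [f"n_{name}", f"min_{name}"]
    for c in feat_cols:
        df[c] = np.nan

    for (mouse, pos), g in df.groupby(["mouse_id", "position_id"], sort=False):
        sets = {c.component_name: c for c in components.get((mouse, pos), [])}
        for t_val, gt in g.groupby("t", sort=False):
            cells = gt[["x", "y", "z"]].to_numpy(dtype=float)
            idx = gt.index
            for k in knn_list:
                df.loc[idx, f"dist_{k}_neigh"] = knn_mean_distance(cells, k)
            for name in comp_names:
                if name not in sets:
                    continue
                df.loc[idx, f"n_{name}"] = count_within_radius(cells, sets[name], radius)
                df.loc[idx, f"min_{name}"] = min_component_distance(cells, sets[name])

    per_track = df.groupby(TRACK_KEY, sort=False)[feat_cols].mean()

    # proximity on the track-level mean min distance per component
    flags = {}
    kinds = {}
    for sets in components.values():
        for c in sets:
            kinds[c.component_name] = c.object_kind
    for name in comp_names:
        thr = proximity_overrides.get(name)
        flags[f"close_{name}"] = classify_proximity(
            per_track[f"min_{name}"].to_numpy(),
            object_kind=kinds[name],
            threshold=thr,
        )
    prox = pd.DataFrame(flags, index=per_track.index)

    return SpatialFeatureTable(
        per_timepoint=df,
        per_track=per_track,
        feature_names=feat_cols,
        proximity_flags=prox,
    )


def integrate_upstream(
    tensor: FeatureTensor,
    spatial: SpatialFeatureTable,
    feature_names: list[str] | None = None,
) -> FeatureTensor:
    """Append per-timepoint spatial features to the tensor before clustering.

    The spatial table must cover every (track, timepoint) of the tensor;
    per-track-only features cannot be time-aligned and are rejected.
    """
    if feature_names is None:
        feature_names = list(spatial.feature_names)
    if not feature_names:
        return tensor
    missing = [f for f in feature_names if f not in spatial.per_timepoint.columns]
    if missing:
        raise ValueError(f"spatial features not available per timepoint: {missing}")
    n, t, _ = tensor.values.shape
    sp = spatial.per_timepoint.set_index(TRACK_KEY)
    blocks = []
    for key in tensor.track_index:
        g = sp.loc[key]
        if len(g) < t:
            raise ValueError(
                f"track {key} has {len(g)} spatial timepoints but the tensor has {t}; "
                "compute spatial features on the interpolated, cropped table"
            )
        block = g.sort_values("t")[feature_names].to_numpy(dtype=float)[:t]
        if np.isnan(block).any():
            raise ValueError(
                f"missing spatial feature values for track {key}; fill or drop "
                "undefined features before upstream integration"
            )
        blocks.append(block)
    extra = np.stack(blocks)
    out = FeatureTensor(
        track_index=tensor.track_index,
        time_grid=tensor.time_grid,
        feature_names=tensor.feature_names + list(feature_names),
        values=np.concatenate([tensor.values, extra], axis=2),
        provenance={**tensor.provenance, **{f: "computed" for f in feature_names}},
    )
    out.validate()
    return out


def integrate_downstream(
    result: ClusterResult,
    spatial: SpatialFeatureTable,
    use_mixed_model: bool = False,
) -> dict:
    """Relate behavioral clusters to spatial features after clustering.

    Returns a dict with:

    ``cluster_summary``
        per (cluster, spatial feature): mean, sd, n, and a one-way ANOVA
        p-value across clusters.
    ``proximity_by_position``
        per (position, cluster, component): % of tracks classified close.
    ``mixed_model`` (optional)
        per component, a mixed-effects comparison of closeness across
        clusters with mouse as random effect.
    """
    result.validate()
    per_track = spatial.per_track.loc[result.track_index]
    labels = np.asarray(result.labels)

    rows = []
    for feat in spatial.feature_names:
        vals = per_track[feat].to_numpy(dtype=float)
        groups = {}
        for c in range(result.k):
            v = vals[labels == c]
            v = v[np.isfinite(v)]
            if len(v):
                groups[c] = v
        testable = {c: g for c, g in groups.items() if len(g) >= 2}
        p = np.nan
        if len(testable) >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", TrackphenoWarning)
                p = tp_stats.one_way_anova(testable).pvalue
        for c in range(result.k):
            v = groups.get(c, np.array([]))
            rows.append(
                {
                    "cluster": c,
                    "feature": feat,
                    "mean": v.mean() if len(v) else np.nan,
                    "sd": v.std(ddof=1) if len(v) > 1 else np.nan,
                    "n": len(v),
                    "anova_p": p,
                }
            )
    cluster_summary = pd.DataFrame(rows)

    prox_rows = []
    out: dict = {"cluster_summary": cluster_summary}
    if spatial.proximity_flags is not None and len(spatial.proximity_flags.columns):
        prox = spatial.proximity_flags.loc[result.track_index].copy()
        prox["cluster"] = labels
        prox = prox.reset_index()
        for (mouse, pos, clus), g in prox.groupby(["mouse_id", "position_id", "cluster"]):
            for col in spatial.proximity_flags.columns:
                prox_rows.append(
                    {
                        "mouse_id": mouse,
                        "position_id": pos,
                        "cluster": clus,
                        "component": col.removeprefix("close_"),
                        "n_tracks": len(g),
                        "n_close": int(g[col].sum()),
                        "pct_close": 100.0 * g[col].mean(),
                    }
                )
        out["proximity_by_position"] = pd.DataFrame(prox_rows)
        if use_mixed_model and prox_rows:
            mm = {}
            pbp = out["proximity_by_position"]
            for comp in pbp["component"].unique():
                sub = pbp[pbp["component"] == comp].rename(columns={"pct_close": "value"})
                try:
                    mm[comp] = tp_stats.mixed_model_compare(
                        sub, "value", "cluster", ["mouse_id"]
                    )
                except (ValueError, np.linalg.LinAlgError) as err:
                    mm[comp] = str(err)
            out["mixed_model"] = mm
    return out
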