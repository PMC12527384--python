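"""Kinetic feature extraction from cell tracks.

Turns a :class:`~trackpheno.types.TrackTable` into a uniform, gap-free,
length-matched multivariate time-series tensor.  The kinetic vocabulary
follows the conventions of intravital track analysis:

``speed``
    step displacement per unit time, µm/h (0 at the first timepoint).
``disp_d``
    displacement delta: straight-line distance to the track start, µm.
``disp2``
    squared displacement from the track start, µm².
``disp_l``
    displacement length: cumulative path length since the start, µm.
``persistence``
    directionality ratio disp_d / disp_l in [0, 1]; 1 = perfectly straight.
``invasion``
    velocity relative to the tumor edge, µm/h: backward difference of the
    distance to the tumor-edge surface.  Positive = moving away from the
    edge (into healthy tissue).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .types import TRACK_KEY, FeatureTensor, TrackphenoWarning, TrackTable

KINETIC_FEATURES = ["speed", "disp2", "disp_d", "disp_l", "persistence"]


def interpolate_to_grid(table: TrackTable, dt: float) -> TrackTable:
    """Resample every track to a uniform grid of spacing ``dt`` hours.

    Each track is resampled to t0, t0+dt, ... within its own observed span
    (no extrapolation).  Coordinates, ``dist_to_edge`` and numeric
    passthrough features are linearly interpolated.  Tracks whose span is
    shorter than ``dt`` cannot produce two grid points and are dropped with
    a warning.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    num_cols = ["x", "y", "z"]
    if "dist_to_edge" in table.df.columns:
        num_cols.append("dist_to_edge")
    num_cols += [c for c in table.extra_features if pd.api.types.is_numeric_dtype(table.df[c])]
    pieces = []
    n_dropped = 0
    for key, g in table.groupby_tracks():
        t = g["t"].to_numpy(dtype=float)
        span = t[-1] - t[0]
        n_steps = int(np.floor(span / dt + 1e-9))
        if n_steps < 1:
            n_dropped += 1
            continue
        grid = t[0] + dt * np.arange(n_steps + 1)
        out = pd.DataFrame({"t": grid})
        for name, val in zip(TRACK_KEY, key):
            out[name] = val
        for c in num_cols:
            out[c] = np.interp(grid, t, g[c].to_numpy(dtype=float))
        pieces.append(out)
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} track(s) with span shorter than dt={dt}",
            TrackphenoWarning,
            stacklevel=2,
        )
    if not pieces:
        raise ValueError("no track survived interpolation; dt is too large")
    df = pd.concat(pieces, ignore_index=True)[list(table.df.columns)]
    report = dict(table.report)
    report["tracks_dropped_interpolation"] = n_dropped
    return table.with_df(df, report=report)


def crop_common_length(table: TrackTable) -> TrackTable:
    """Truncate every track to the minimal common length L (first L points).

    Requires a uniform grid (apply :func:`interpolate_to_grid` first) so
    that equal lengths mean equal durations.  Errors if L < 3, which
    indicates the input needs minimum-track-length filtering upstream.
    """
    sizes = table.groupby_tracks().size()
    L = int(sizes.min())
    if L < 3:
        raise ValueError(
            f"minimal common track length is {L} (< 3); filter out very short "
            "tracks before cropping"
        )
    df = table.df.groupby(TRACK_KEY, sort=False, group_keys=False).head(L)
    report = dict(table.report)
    report["common_length"] = L
    return table.with_df(df.reset_index(drop=True), report=report)


def _check_uniform(table: TrackTable) -> tuple[np.ndarray, float, int]:
    """Return (track index order, dt, L) after verifying the tensor layout."""
    sizes = table.groupby_tracks().size()
    L = int(sizes.iloc[0])
    if not (sizes == L).all():
        raise ValueError("tracks have unequal lengths; apply crop_common_length first")
    dts = table.df.groupby(TRACK_KEY, sort=False)["t"].diff().dropna()
    if len(dts) and np.max(np.abs(dts - dts.iloc[0])) > 1e-9:
        raise ValueError("time spacing is not uniform; apply interpolate_to_grid first")
    dt = float(dts.iloc[0]) if len(dts) else np.nan
    return sizes, dt, L


def compute_kinetic_features(
    table: TrackTable,
    include_invasion: bool | None = None,
    passthrough: Sequence[str] = (),
    persistence_mode: str = "net_over_path",
) -> FeatureTensor:
    """Compute per-timepoint kinetic features for every track.

    Parameters
    ----------
    include_invasion
        Whether to compute the edge-referenced invasion velocity.  Default:
        include it iff the table carries ``dist_to_edge``; requesting it
        explicitly without that column is an error.
    passthrough
        Extra feature columns copied verbatim into the tensor (morphology
        statistics exported by the upstream tool).
    persistence_mode
        ``net_over_path`` (default): disp_d / disp_l, the conventional
        movement-efficiency ratio in [0, 1].  ``path_over_net`` exposes the
        reciprocal for users matching other tools' conventions.
    """
    if persistence_mode not in ("net_over_path", "path_over_net"):
        raise ValueError(f"unknown persistence_mode {persistence_mode!r}")
    has_edge = "dist_to_edge" in table.df.columns
    if include_invasion is None:
        include_invasion = has_edge
    if include_invasion and not has_edge:
        raise ValueError(
            "invasion velocity requested but the track table has no "
            "'dist_to_edge' column"
        )
    for c in passthrough:
        if c not in table.df.columns:
            raise ValueError(f"passthrough column {c!r} not in track table")
    _, dt, L = _check_uniform(table)

    names = list(KINETIC_FEATURES)
    if include_invasion:
        names.append("invasion")
    names += list(passthrough)
    provenance = {f: "computed" for f in KINETIC_FEATURES}
    if include_invasion:
        provenance["invasion"] = "computed"
    provenance.update({c: "passthrough" for c in passthrough})

    track_keys = []
    blocks = []
    time_grid = None
    for key, g in table.groupby_tracks():
        pos = g[["x", "y", "z"]].to_numpy(dtype=float)
        if time_grid is None:
            t0 = g["t"].to_numpy(dtype=float)
            time_grid = t0 - t0[0]
        steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        speed = np.concatenate([[0.0], steps / dt])
        disp_d = np.linalg.norm(pos - pos[0], axis=1)
        disp2 = disp_d**2
        disp_l = np.concatenate([[0.0], np.cumsum(steps)])
        with np.errstate(divide="ignore", invalid="ignore"):
            if persistence_mode == "net_over_path":
                persistence = np.where(disp_l > 0, disp_d / np.where(disp_l > 0, disp_l, 1.0), 0.0)
            else:
                persistence = np.where(disp_d > 0, disp_l / np.where(disp_d > 0, disp_d, 1.0), 0.0)
        cols = [speed, disp2, disp_d, disp_l, persistence]
        if include_invasion:
            edge = g["dist_to_edge"].to_numpy(dtype=float)
            invasion = np.concatenate([[0.0], np.diff(edge) / dt])
            cols.append(invasion)
        for c in passthrough:
            cols.append(g[c].to_numpy(dtype=float))
        blocks.append(np.column_stack(cols))
        track_keys.append(key)

    values = np.stack(blocks)  # (n, L, f)
    tensor = FeatureTensor(
        track_index=pd.MultiIndex.from_tuples(track_keys, names=TRACK_KEY),
        time_grid=np.asarray(time_grid, dtype=float),
        feature_names=names,
        values=values,
        provenance=provenance,
    )
    tensor.validate()
    return tensor


def summarize_track_features(tensor: FeatureTensor) -> pd.DataFrame:
    """Per-track time-summaries: ``mean_<f>`` and ``<f>_range`` per feature.

    The range is max - min of the feature over the track's timepoints, the
    variability summary used alongside the time mean.
    """
    tensor.validate()
    out = {}
    for j, f in enumerate(tensor.feature_names):
        vals = tensor.values[:, :, j]
        out[f"mean_{f}"] = vals.mean(axis=1)
        out[f"{f}_range"] = vals.max(axis=1) - vals.min(axis=1)
    return pd.DataFrame(out, index=tensor.track_index)
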