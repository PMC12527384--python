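"""Core data containers shared across the pipeline.

The canonical in-memory representation of tracking data is a long-format
:class:`pandas.DataFrame` wrapped in :class:`TrackTable`, with one row per
(cell track, timepoint).  All coordinates are micrometres and all times are
hours; readers convert at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Columns that jointly identify one cell track.
TRACK_KEY = ["mouse_id", "position_id", "track_id"]

#: Columns every TrackTable carries.
CORE_COLUMNS = TRACK_KEY + ["t", "x", "y", "z"]


class TrackphenoWarning(UserWarning):
    """Base warning for data-quality events (dropped tracks, orphan rows...)."""


@dataclass
class TrackTable:
    """Long-format per-timepoint cell records.

    Parameters
    ----------
    df
        One row per (track, timepoint). Must contain :data:`CORE_COLUMNS`;
        may contain ``dist_to_edge`` (µm, distance to the tumor-edge
        surface) and arbitrary numeric passthrough feature columns.
    dimensionality
        2 or 3. 2D data is stored with ``z = 0`` so all geometry is written
        once for 3D and degrades correctly.
    extra_features
        Names of passthrough feature columns (morphology statistics exported
        by the upstream tracking tool; never computed here).
    report
        Parse bookkeeping: rows/tracks dropped and why.
    """

    df: pd.DataFrame
    dimensionality: int = 3
    extra_features: list[str] = field(default_factory=list)
    time_unit: str = "h"
    coordinate_unit: str = "um"
    report: dict = field(default_factory=dict)

    # -- construction --------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        dimensionality: int | None = None,
        extra_features: Sequence[str] | None = None,
        drop_short: bool = True,
        report: dict | None = None,
    ) -> "TrackTable":
        """Build a validated table from a raw long-format frame.

        Sorts rows by track and time, optionally drops length-1 tracks
        (counted in ``report['short_tracks_dropped']``), and validates
        invariants.
        """
        df = df.copy()
        missing = [c for c in CORE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"track table is missing required columns: {missing}")
        report = dict(report or {})
        if dimensionality is None:
            dimensionality = 2 if (df["z"] == 0).all() else 3
        if extra_features is None:
            known = set(CORE_COLUMNS) | {"dist_to_edge"}
            extra_features = [c for c in df.columns if c not in known]
        df = df.sort_values(TRACK_KEY + ["t"], kind="mergesort").reset_index(drop=True)
        if drop_short and len(df):
            sizes = df.groupby(TRACK_KEY, sort=False)["t"].transform("size")
            n_short = int((sizes < 2).sum())
            if n_short:
                warnings.warn(
                    f"dropped {n_short} row(s) from length-1 tracks",
                    TrackphenoWarning,
                    stacklevel=2,
                )
                report["short_tracks_dropped"] = n_short
                df = df[sizes >= 2].reset_index(drop=True)
        table = cls(
            df=df,
            dimensionality=int(dimensionality),
            extra_features=list(extra_features),
            report=report,
        )
        table.validate()
        return table

    # -- invariants ----------------------------------------------------

    def validate(self) -> None:
        df = self.df
        if self.dimensionality not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")
        if len(df) == 0:
            return
        for c in ("t", "x", "y", "z"):
            vals = df[c].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"non-finite values in column {c!r}")
        if "dist_to_edge" in df.columns:
            d = df["dist_to_edge"].to_numpy(dtype=float)
            ok = np.isfinite(d) & (d >= 0)
            if not np.all(ok | np.isnan(d)):
                raise ValueError("dist_to_edge must be finite and >= 0")
        dup = df.duplicated(subset=TRACK_KEY + ["t"])
        if dup.any():
            keys = df.loc[dup, TRACK_KEY + ["t"]].to_records(index=False)[:5]
            raise ValueError(f"duplicate (track, time) keys, e.g. {list(keys)}")
        # sorted + unique keys => strictly increasing t within each track
        dt = df.groupby(TRACK_KEY, sort=False)["t"].diff().dropna()
        if (dt <= 0).any():
            raise ValueError("time must be strictly increasing within each track")

    # -- convenience ---------------------------------------------------

    @property
    def n_tracks(self) -> int:
        if len(self.df) == 0:
            return 0
        return self.df.groupby(TRACK_KEY, sort=False).ngroups

    def track_ids(self) -> pd.MultiIndex:
        """Ordered unique (mouse_id, position_id, track_id) index."""
        if len(self.df) == 0:
            return pd.MultiIndex.from_arrays([[], [], []], names=TRACK_KEY)
        uniq = self.df[TRACK_KEY].drop_duplicates()
        return pd.MultiIndex.from_frame(uniq)

    def groupby_tracks(self):
        return self.df.groupby(TRACK_KEY, sort=False)

    def with_df(self, df: pd.DataFrame, **updates) -> "TrackTable":
        """Copy of this table with a replaced frame (revalidated)."""
        kwargs = dict(
            dimensionality=self.dimensionality,
            extra_features=list(self.extra_features),
            time_unit=self.time_unit,
            coordinate_unit=self.coordinate_unit,
            report=dict(self.report),
        )
        kwargs.update(updates)
        out = TrackTable(df=df.reset_index(drop=True), **kwargs)
        out.validate()
        return out


@dataclass
class FeatureTensor:
    """Tracks x uniform timepoints x features, gap-free and length-matched."""

    track_index: pd.MultiIndex
    time_grid: np.ndarray  # hours, uniform spacing
    feature_names: list[str]
    values: np.ndarray  # (n_tracks, n_timepoints, n_features)
    provenance: dict = field(default_factory=dict)  # name -> computed | passthrough

    def validate(self) -> None:
        n, t, f = self.values.shape
        if n != len(self.track_index):
            raise ValueError("track_index length mismatch")
        if t != len(self.time_grid):
            raise ValueError("time_grid length mismatch")
        if f != len(self.feature_names):
            raise ValueError("feature_names length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature tensor contains non-finite values")
        if t >= 2:
            steps = np.diff(self.time_grid)
            if np.max(np.abs(steps - steps[0])) > 1e-9:
                raise ValueError("time grid spacing is not constant")

    @property
    def dt(self) -> float:
        return float(self.time_grid[1] - self.time_grid[0])

    def to_long(self) -> pd.DataFrame:
        """Long-format (track, t, feature, value) audit dump."""
        n, t, f = self.values.shape
        idx = self.track_index.repeat(t * f)
        out = pd.DataFrame(idx.to_frame(index=False))
        out["t"] = np.tile(np.repeat(self.time_grid, f), n)
        out["feature"] = np.tile(self.feature_names, n * t)
        out["value"] = self.values.reshape(-1)
        return out

    def select(self, names: Sequence[str]) -> "FeatureTensor":
        missing = [f for f in names if f not in self.feature_names]
        if missing:
            raise KeyError(f"unknown features: {missing}")
        cols = [self.feature_names.index(f) for f in names]
        return FeatureTensor(
            track_index=self.track_index,
            time_grid=self.time_grid,
            feature_names=list(names),
            values=self.values[:, :, cols],
            provenance={k: v for k, v in self.provenance.items() if k in names},
        )


@dataclass
class PCSeries:
    """Per-track principal-component time series."""

    track_index: pd.MultiIndex
    time_grid: np.ndarray
    pc_values: np.ndarray  # (n_tracks, n_timepoints, n_pc)
    explained_variance_ratio: np.ndarray  # retained PCs only
    n_pc: int

    def validate(self) -> None:
        if self.pc_values.shape[2] != self.n_pc:
            raise ValueError("n_pc mismatch")
        if len(self.explained_variance_ratio) != self.n_pc:
            raise ValueError("explained_variance_ratio length mismatch")


@dataclass
class DistanceMatrix:
    """Symmetric DTW cross-distance over tracks."""

    track_index: pd.MultiIndex
    D: np.ndarray

    def validate(self) -> None:
        D = self.D
        if D.shape[0] != D.shape[1] or D.shape[0] != len(self.track_index):
            raise ValueError("distance matrix shape mismatch")
        if np.any(np.abs(np.diag(D)) > 0):
            raise ValueError("diagonal must be exactly zero")
        if np.max(np.abs(D - D.T)) > 1e-9:
            raise ValueError("distance matrix must be symmetric to 1e-9")
        if np.any(D < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class ClusterResult:
    """Embedding coordinates + cluster label per track."""

    track_index: pd.MultiIndex
    embedding: np.ndarray  # (n, 2)
    labels: np.ndarray  # int cluster id per track, in 0..k-1
    k: int
    params: dict = field(default_factory=dict)  # seeds + hyperparameters
    summary: pd.DataFrame | None = None

    def validate(self) -> None:
        n = len(self.track_index)
        if self.embedding.shape != (n, 2):
            raise ValueError("embedding must be n x 2")
        if len(self.labels) != n:
            raise ValueError("labels length mismatch")
        lab = np.asarray(self.labels)
        if lab.min() < 0 or lab.max() >= self.k:
            raise ValueError("labels must lie in 0..k-1")
        if len(np.unique(lab)) != self.k:
            raise ValueError("every cluster must be non-empty")

    def to_frame(self) -> pd.DataFrame:
        out = self.track_index.to_frame(index=False)
        out["umap_1"] = self.embedding[:, 0]
        out["umap_2"] = self.embedding[:, 1]
        out["cluster"] = self.labels
        return out


@dataclass
class TMEComponentSet:
    """A named static point cloud for one microenvironment component.

    ``object_kind`` distinguishes centroid-based spot detections (e.g. blood
    vessel spots) from boundary samples of rendered surfaces (e.g. TAMM
    surfaces); the proximity threshold convention depends on it.
    """

    component_name: str
    points: np.ndarray  # (m, 3) µm
    object_kind: str = "spot"  # spot | surface_sample
    static_snapshot: bool = True

    def validate(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be (m, 3)")
        if not np.all(np.isfinite(pts)):
            raise ValueError("component points must be finite")
        if self.object_kind not in ("spot", "surface_sample"):
            raise ValueError(f"unknown object_kind {self.object_kind!r}")


@dataclass
class RegionAssignment:
    """Externally supplied mapping of positions (or cells) to TME regions."""

    df: pd.DataFrame  # mouse_id, position_id [, track_id], region_label
    label_set: list[str]
    source: str = "per_position_label"  # or per_cell_table

    def validate(self) -> None:
        req = ["mouse_id", "position_id", "region_label"]
        missing = [c for c in req if c not in self.df.columns]
        if missing:
            raise ValueError(f"region table missing columns: {missing}")
        bad = set(self.df["region_label"]) - set(self.label_set)
        if bad:
            raise ValueError(f"region labels outside declared set: {sorted(bad)}")
        if self.source not in ("per_position_label", "per_cell_table"):
            raise ValueError(f"unknown region source {self.source!r}")
        if self.source == "per_cell_table" and "track_id" not in self.df.columns:
            raise ValueError("per_cell_table source requires a track_id column")
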