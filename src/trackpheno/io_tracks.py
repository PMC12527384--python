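"""Readers and writers for the supported tracking-export dialects.

Every reader returns the canonical :class:`~trackpheno.types.TrackTable`
(µm / hours), converting units exactly once at the boundary:

* Imaris statistics exports: one Position CSV plus optional per-statistic
  CSVs sharing (TrackID, Time) keys, with the Imaris three-line preamble.
* TrackMate "allspots" CSV, with its non-numeric extra header rows.
* MTrackJ and ManualTracking point lists from Fiji.

Numeric cells must use "." as decimal separator; a "," in a numeric cell is
a hard error (a known hazard of European spreadsheet exports).
"""

from __future__ import annotations

import io
import os
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .types import TRACK_KEY, ClusterResult, TrackTable

_IMARIS_META_COLS = {"Unit", "Category", "Collection", "ID"}


def _check_decimal_commas(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    for c in cols:
        if c in df.columns and df[c].dtype == object:
            s = df[c].astype(str)
            if s.str.contains(",").any():
                raise ValueError(
                    f"{path}: column {c!r} contains ',' in numeric cells; "
                    "exports must use '.' as decimal separator"
                )


def _to_float(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    _check_decimal_commas(df, cols, path)
    for c in cols:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as err:
            bad = pd.to_numeric(df[c], errors="coerce")
            idx = int(bad.index[bad.isna() & df[c].notna()][0])
            raise ValueError(f"{path}: non-numeric value in column {c!r} at row {idx}") from err


# ---------------------------------------------------------------------------
# Imaris
# ---------------------------------------------------------------------------


def _read_imaris_csv(path) -> pd.DataFrame:
    """Read one Imaris statistic CSV, skipping the preamble before the header."""
    with open(path, "r", encoding="utf-8-sig") as fh:
        lines = fh.readlines()
    header_i = None
    for i, line in enumerate(lines[:10]):
        if "TrackID" in line and "Time" in line:
            header_i = i
            break
    if header_i is None:
        raise ValueError(f"{path}: no header row with TrackID/Time found")
    return pd.read_csv(io.StringIO("".join(lines[header_i:])))


def read_imaris_export(
    paths,
    edge_column: str | None = None,
    frame_interval: float = 1.0 / 3.0,
    mouse_id: str = "m1",
    position_id: str = "p1",
) -> TrackTable:
    """Parse an Imaris per-statistic export into a TrackTable.

    Parameters
    ----------
    paths
        A directory of Imaris statistic CSVs, or an explicit list of files.
        Exactly one file must be the Position export (name contains
        ``Position``); every other file contributes one statistic column
        named after the file, joined on (TrackID, Time).
    edge_column
        Name of the statistic to map to ``dist_to_edge`` (the distance to
        the tumor-edge surface).  Imaris does not fix which statistic holds
        it, so the choice is explicit.
    frame_interval
        Hours per Imaris time index step (Time is 1-based).
    """
    if isinstance(paths, (str, Path)) and os.path.isdir(paths):
        files = sorted(Path(paths).glob("*.csv"))
    else:
        files = [Path(p) for p in (paths if isinstance(paths, (list, tuple)) else [paths])]
    pos_files = [f for f in files if "Position" in f.stem]
    if len(pos_files) != 1:
        raise ValueError(
            f"expected exactly one Position file among {[f.name for f in files]}, "
            f"found {len(pos_files)}"
        )
    pos_path = pos_files[0]
    pos = _read_imaris_csv(pos_path)
    req = ["Position X", "Position Y", "Position Z", "Time", "TrackID"]
    missing = [c for c in req if c not in pos.columns]
    if missing:
        raise ValueError(f"{pos_path}: Position file missing columns {missing}")
    if len(pos) == 0:
        raise ValueError(f"{pos_path}: Position file has no rows")
    _to_float(pos, req, pos_path)
    dup = pos.duplicated(subset=["TrackID", "Time"])
    if dup.any():
        keys = pos.loc[dup, ["TrackID", "Time"]].to_records(index=False)[:5]
        raise ValueError(f"{pos_path}: duplicate (TrackID, Time) keys: {list(keys)}")

    df = pd.DataFrame(
        {
            "mouse_id": mouse_id,
            "position_id": position_id,
            "track_id": pos["TrackID"].astype(int),
            "t": (pos["Time"] - 1) * frame_interval,
            "x": pos["Position X"],
            "y": pos["Position Y"],
            "z": pos["Position Z"],
        }
    )

    extra_features: list[str] = []
    for f in files:
        if f == pos_path:
            continue
        stat = _read_imaris_csv(f)
        stat_name = _imaris_stat_name(f)
        value_cols = [c for c in stat.columns if c not in _IMARIS_META_COLS | {"Time", "TrackID"}]
        if len(value_cols) != 1:
            raise ValueError(f"{f}: expected one value column, found {value_cols}")
        _to_float(stat, value_cols + ["Time", "TrackID"], f)
        dup = stat.duplicated(subset=["TrackID", "Time"])
        if dup.any():
            keys = stat.loc[dup, ["TrackID", "Time"]].to_records(index=False)[:5]
            raise ValueError(f"{f}: duplicate (TrackID, Time) keys: {list(keys)}")
        sub = stat[["TrackID", "Time", value_cols[0]]].rename(columns={value_cols[0]: stat_name})
        key_pos = set(zip(pos["TrackID"].astype(int), pos["Time"].astype(int)))
        key_stat = set(zip(sub["TrackID"].astype(int), sub["Time"].astype(int)))
        orphans = (key_pos - key_stat) | (key_stat - key_pos)
        if orphans:
            raise ValueError(
                f"{f}: (TrackID, Time) keys do not match the Position file; "
                f"orphans include {sorted(orphans)[:5]}"
            )
        sub = sub.copy()
        sub["track_id"] = sub["TrackID"].astype(int)
        sub["t"] = (sub["Time"] - 1) * frame_interval
        df = df.merge(sub[["track_id", "t", stat_name]], on=["track_id", "t"], how="inner")
        extra_features.append(stat_name)

    if edge_column is not None:
        if edge_column not in df.columns:
            raise ValueError(
                f"edge_column {edge_column!r} not among parsed statistics {extra_features}"
            )
        df = df.rename(columns={edge_column: "dist_to_edge"})
        extra_features.remove(edge_column)
    return TrackTable.from_dataframe(df, extra_features=extra_features)


def _imaris_stat_name(path: Path) -> str:
    stem = path.stem
    return stem.split("_", 1)[1] if "_" in stem else stem


def read_imaris_positions(
    root,
    edge_column: str | None = None,
    frame_interval: float = 1.0 / 3.0,
) -> TrackTable:
    """Read a directory of per-position Imaris exports.

    Subdirectories must be named ``<mouse>__<position>`` and each contain
    one position's statistic CSVs.
    """
    root = Path(root)
    subdirs = sorted(d for d in root.iterdir() if d.is_dir() and "__" in d.name)
    if not subdirs:
        raise ValueError(f"{root}: no '<mouse>__<position>' subdirectories found")
    parts = []
    extra = None
    dim = 3
    for d in subdirs:
        mouse, pos = d.name.split("__", 1)
        t = read_imaris_export(
            d, edge_column=edge_column, frame_interval=frame_interval,
            mouse_id=mouse, position_id=pos,
        )
        parts.append(t.df)
        extra = t.extra_features
        dim = t.dimensionality
    df = pd.concat(parts, ignore_index=True)
    return TrackTable.from_dataframe(df, dimensionality=dim, extra_features=extra)


# ---------------------------------------------------------------------------
# TrackMate
# ---------------------------------------------------------------------------

_TRACKMATE_META = {"LABEL", "ID", "TRACK_ID", "QUALITY", "POSITION_X", "POSITION_Y",
                   "POSITION_Z", "POSITION_T", "FRAME", "RADIUS", "VISIBILITY"}


def read_trackmate_spots(
    path,
    frame_interval: float,
    track_column: str = "TRACK_ID",
    mouse_id: str = "m1",
    position_id: str = "p1",
) -> TrackTable:
    """Parse a TrackMate "allspots" CSV.

    TrackMate writes up to three extra non-numeric header rows (long names,
    short names, units) under the column row; they are detected by sniffing
    and skipped.  Spots without a track assignment are dropped and counted
    in ``report['unassigned_spots_dropped']``.  FRAME (0-based) is converted
    to hours via ``frame_interval``; any non-standard column (morphology
    such as AREA, SOLIDITY, SHAPE_INDEX, ellipse axes) is kept as a
    passthrough feature.
    """
    raw = pd.read_csv(path, dtype=str)
    if track_column not in raw.columns:
        raise ValueError(f"{path}: no {track_column!r} column")
    req = ["POSITION_X", "POSITION_Y", "FRAME"]
    missing = [c for c in req if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    # drop the extra header rows: leading rows whose FRAME is not numeric
    n_skip = 0
    for _, v in raw["FRAME"].items():
        if pd.isna(v) or _is_number(v):
            break
        n_skip += 1
    df = raw.iloc[n_skip:].reset_index(drop=True)

    unassigned = df[track_column].isna() | df[track_column].isin(["", "None", "nan"])
    n_dropped = int(unassigned.sum())
    df = df[~unassigned].reset_index(drop=True)
    report = {"unassigned_spots_dropped": n_dropped}
    if len(df) == 0:
        empty = pd.DataFrame(columns=TRACK_KEY + ["t", "x", "y", "z"])
        return TrackTable(df=empty, dimensionality=3, extra_features=[], report=report)

    has_z = "POSITION_Z" in df.columns
    num_cols = ["POSITION_X", "POSITION_Y", "FRAME"] + (["POSITION_Z"] if has_z else [])
    _to_float(df, num_cols, path)
    morph_cols = [c for c in df.columns if c not in _TRACKMATE_META]
    _to_float(df, morph_cols, path)

    out = pd.DataFrame(
        {
            "mouse_id": mouse_id,
            "position_id": position_id,
            "track_id": pd.to_numeric(df[track_column]).astype(int),
            "t": df["FRAME"] * frame_interval,
            "x": df["POSITION_X"],
            "y": df["POSITION_Y"],
            "z": df["POSITION_Z"] if has_z else 0.0,
        }
    )
    for c in morph_cols:
        out[c] = df[c]
    dim = 3 if has_z and (out["z"] != 0).any() else 2
    return TrackTable.from_dataframe(
        out, dimensionality=dim, extra_features=morph_cols, report=report
    )


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# MTrackJ / ManualTracking
# ---------------------------------------------------------------------------


def read_fiji_manual(
    path,
    dialect: str,
    frame_interval: float,
    mouse_id: str = "m1",
    position_id: str = "p1",
) -> TrackTable:
    """Parse MTrackJ or ManualTracking point exports.

    ``mtrackj``: columns TID, PID, x, y [, z], t (1-based slice).
    ``manual_tracking``: columns "Track n°", "Slice n°", "X", "Y" (2D).
    Slice numbers convert to hours via ``frame_interval``; 2D data gets
    z = 0.  Length-1 tracks are dropped with a warning count.
    """
    if dialect not in ("mtrackj", "manual_tracking"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path)
    if dialect == "mtrackj":
        req = ["TID", "PID", "x", "y", "t"]
        missing = [c for c in req if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: MTrackJ export missing columns {missing}")
        has_z = "z" in df.columns
        _to_float(df, req + (["z"] if has_z else []), path)
        out = pd.DataFrame(
            {
                "mouse_id": mouse_id,
                "position_id": position_id,
                "track_id": df["TID"].astype(int),
                "t": (df["t"] - 1) * frame_interval,
                "x": df["x"],
                "y": df["y"],
                "z": df["z"] if has_z else 0.0,
            }
        )
    else:
        req = ["Track n°", "Slice n°", "X", "Y"]
        missing = [c for c in req if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: ManualTracking export missing columns {missing}")
        _to_float(df, req, path)
        out = pd.DataFrame(
            {
                "mouse_id": mouse_id,
                "position_id": position_id,
                "track_id": df["Track n°"].astype(int),
                "t": (df["Slice n°"] - 1) * frame_interval,
                "x": df["X"],
                "y": df["Y"],
                "z": 0.0,
            }
        )
    dim = 3 if (out["z"] != 0).any() else 2
    return TrackTable.from_dataframe(out, dimensionality=dim, extra_features=[])


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

#: Stable column order of the back-projection CSV.
BACKPROJECTION_COLUMNS = TRACK_KEY + ["t", "x", "y", "z", "cluster", "cluster_color"]


def write_backprojection(result: ClusterResult, table: TrackTable, path) -> Path:
    """Write per-timepoint cluster annotations for import into Imaris/Fiji.

    One row per (track, timepoint) of every labeled track, with the cluster
    label and a color index (equal to the label) for palette lookup.
    Labeled tracks missing from the table are an error.
    """
    result.validate()
    labels = pd.Series(np.asarray(result.labels), index=result.track_index, name="cluster")
    present = set(map(tuple, table.df[TRACK_KEY].drop_duplicates().itertuples(index=False)))
    absent = [k for k in result.track_index if tuple(k) not in present]
    if absent:
        raise ValueError(f"labeled tracks absent from the track table: {absent[:5]}")
    df = table.df.merge(
        labels.reset_index(), on=TRACK_KEY, how="inner"
    )
    df["cluster_color"] = df["cluster"]
    out = df[BACKPROJECTION_COLUMNS]
    path = Path(path)
    out.to_csv(path, index=False)
    return path


def read_backprojection(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"mouse_id": str, "position_id": str})
    missing = [c for c in BACKPROJECTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: back-projection file missing columns {missing}")
    return df


# --- fixture writers (used by the simulator's export round-trips) ---------


def write_imaris_position(df: pd.DataFrame, outdir, frame_interval: float,
                          extra_features: list[str], edge_stat: str) -> None:
    """Write one position's rows in the Imaris per-statistic layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    time_idx = (df["t"] / frame_interval).round().astype(int) + 1

    def _preamble(name: str, frame: pd.DataFrame, path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{name}\n")
            fh.write("====================\n")
            frame.to_csv(fh, index=False)

    pos = pd.DataFrame(
        {
            "Position X": df["x"],
            "Position Y": df["y"],
            "Position Z": df["z"],
            "Unit": "um",
            "Category": "Spot",
            "Collection": "Position",
            "Time": time_idx,
            "TrackID": df["track_id"].astype(int),
            "ID": np.arange(len(df)),
        }
    )
    _preamble("Position", pos, outdir / "tracks_Position.csv")

    stats = list(extra_features)
    if "dist_to_edge" in df.columns:
        stats = [edge_stat] + stats
    for name in stats:
        col = "dist_to_edge" if name == edge_stat else name
        stat = pd.DataFrame(
            {
                name: df[col],
                "Unit": "um",
                "Category": "Spot",
                "Time": time_idx,
                "TrackID": df["track_id"].astype(int),
                "ID": np.arange(len(df)),
            }
        )
        _preamble(name, stat, outdir / f"tracks_{name}.csv")


def write_trackmate_spots(df: pd.DataFrame, path, frame_interval: float,
                          extra_features: list[str]) -> None:
    """Write one position's rows in the TrackMate allspots layout."""
    frame = (df["t"] / frame_interval).round().astype(int)
    out = pd.DataFrame(
        {
            "LABEL": ["ID" + str(i) for i in range(len(df))],
            "ID": np.arange(len(df)),
            "TRACK_ID": df["track_id"].astype(int),
            "QUALITY": 1.0,
            "POSITION_X": df["x"],
            "POSITION_Y": df["y"],
            "POSITION_Z": df["z"],
            "POSITION_T": df["t"] * 3600.0,
            "FRAME": frame,
        }
    )
    for c in extra_features:
        out[c] = df[c].to_numpy()
    header = pd.DataFrame(
        [
            {c: c.replace("_", " ").title() for c in out.columns},
            {c: ("" if c in ("LABEL",) else "(unit)") for c in out.columns},
        ]
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(out.columns) + "\n")
        header.to_csv(fh, index=False, header=False)
        out.to_csv(fh, index=False, header=False)


def write_mtrackj(df: pd.DataFrame, path, frame_interval: float) -> None:
    g = df.sort_values(["track_id", "t"])
    out = pd.DataFrame(
        {
            "TID": g["track_id"].astype(int),
            "PID": g.groupby("track_id").cumcount() + 1,
            "x": g["x"],
            "y": g["y"],
            "z": g["z"],
            "t": (g["t"] / frame_interval).round().astype(int) + 1,
        }
    )
    out.to_csv(path, index=False)


def write_manual_tracking(df: pd.DataFrame, path, frame_interval: float) -> None:
    if (df["z"] != 0).any():
        raise ValueError("ManualTracking is a 2D dialect; table has nonzero z")
    out = pd.DataFrame(
        {
            "Track n°": df["track_id"].astype(int),
            "Slice n°": (df["t"] / frame_interval).round().astype(int) + 1,
            "X": df["x"],
            "Y": df["y"],
        }
    )
    out.to_csv(path, index=False)
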