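"""Large-scale phenotyping: behavioral-cluster frequencies across TME regions.

Region labels (e.g. Void, TAMM/Oligo, TAMM/vascularized) come from an
external spatial-phenotyping tool and are consumed as a CSV mapping, either
one label per imaging position (default) or one per cell.  Cluster
frequencies are computed per position, z-scored within each (mouse,
cluster) across that mouse's positions to absorb inter-mouse variability,
and compared across regions with one-way ANOVA plus Tukey HSD.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import stats as tp_stats
from .types import (
    TRACK_KEY,
    ClusterResult,
    RegionAssignment,
    TrackphenoWarning,
    TrackTable,
)


def read_region_csv(path, label_set=None) -> RegionAssignment:
    """Read a region-assignment CSV (mouse_id, position_id[, track_id], region_label)."""
    df = pd.read_csv(path, dtype={"mouse_id": str, "position_id": str})
    source = "per_cell_table" if "track_id" in df.columns else "per_position_label"
    if label_set is None:
        label_set = sorted(df["region_label"].unique())
    regions = RegionAssignment(df=df, label_set=list(label_set), source=source)
    regions.validate()
    return regions


def assign_regions(table: TrackTable, regions: RegionAssignment) -> pd.Series:
    """Region label per track.

    Per-position sources label every track of the position; per-cell tables
    label tracks individually and take precedence where both could apply.
    Tracks not covered by the assignment raise an error naming them.
    """
    regions.validate()
    tracks = table.track_ids().to_frame(index=False)
    if regions.source == "per_cell_table":
        merged = tracks.merge(
            regions.df[TRACK_KEY + ["region_label"]], on=TRACK_KEY, how="left"
        )
    else:
        merged = tracks.merge(
            regions.df[["mouse_id", "position_id", "region_label"]],
            on=["mouse_id", "position_id"],
            how="left",
        )
    missing = merged[merged["region_label"].isna()]
    if len(missing):
        keys = missing[TRACK_KEY].drop_duplicates().to_records(index=False)[:10]
        raise ValueError(f"tracks without a region assignment: {list(keys)}")
    return pd.Series(
        merged["region_label"].to_numpy(),
        index=pd.MultiIndex.from_frame(merged[TRACK_KEY]),
        name="region_label",
    )


def cluster_frequencies(
    result: ClusterResult,
    regions: RegionAssignment | pd.Series,
    table: TrackTable | None = None,
) -> pd.DataFrame:
    """Per-position behavioral-cluster percentages, z-scored within mouse.

    Returns one row per (mouse, position, cluster) with the raw percentage
    of the position's tracks falling in the cluster (zeros included, so
    percentages per position sum to 100) and the z-score of that percentage
    across the mouse's positions for the same cluster.  Mice with a single
    position get missing z-scores.
    """
    result.validate()
    df = result.track_index.to_frame(index=False)
    df["cluster"] = np.asarray(result.labels)
    if isinstance(regions, RegionAssignment):
        if table is None:
            raise ValueError("pass the track table to resolve a RegionAssignment")
        region_per_track = assign_regions(table, regions)
    else:
        region_per_track = regions
    df = df.merge(
        region_per_track.rename("region_label").reset_index(), on=TRACK_KEY, how="left"
    )
    if df["region_label"].isna().any():
        raise ValueError("some clustered tracks have no region label")

    counts = (
        df.groupby(["mouse_id", "position_id", "region_label", "cluster"])
        .size()
        .rename("n")
        .reset_index()
    )
    # complete the (position x cluster) grid with zeros
    positions = df[["mouse_id", "position_id", "region_label"]].drop_duplicates()
    grid = positions.merge(pd.DataFrame({"cluster": range(result.k)}), how="cross")
    freq = grid.merge(
        counts, on=["mouse_id", "position_id", "region_label", "cluster"], how="left"
    ).fillna({"n": 0})
    totals = freq.groupby(["mouse_id", "position_id"])["n"].transform("sum")
    freq["pct"] = 100.0 * freq["n"] / totals
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", TrackphenoWarning)
        freq["pct_z"] = tp_stats.zscore_within(
            freq["pct"].to_numpy(),
            (freq["mouse_id"].astype(str) + "||" + freq["cluster"].astype(str)).to_numpy(),
        )
    single = freq["pct_z"].isna().sum()
    if single:
        warnings.warn(
            f"{single} (mouse, cluster) percentage(s) without a z-score "
            "(single-position mouse or zero variance)",
            TrackphenoWarning,
            stacklevel=2,
        )
    return freq


def compare_regions(
    freqs: pd.DataFrame, alpha: float = 0.05, post_hoc: bool = True
) -> dict[int, dict]:
    """Per-cluster ANOVA + Tukey HSD of z-scored percentages across regions.

    Returns ``{cluster: {"anova": AnovaResult, "tukey": DataFrame}}``.
    Clusters whose groups are degenerate (fewer than 2 regions with >= 2
    positions, or no finite z-scores) are skipped with a warning.
    ``post_hoc=False`` skips the Tukey tables (omnibus tests only).
    """
    out: dict[int, dict] = {}
    for clus, g in freqs.groupby("cluster"):
        groups = {}
        for region, gr in g.groupby("region_label"):
            v = gr["pct_z"].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            if len(v) >= 2:
                groups[region] = v
        if len(groups) < 2:
            warnings.warn(
                f"cluster {clus}: fewer than 2 regions with enough positions; skipped",
                TrackphenoWarning,
                stacklevel=2,
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", TrackphenoWarning)
            anova = tp_stats.one_way_anova(groups)
            tukey = tp_stats.tukey_hsd(groups, alpha=alpha) if post_hoc else None
        out[int(clus)] = {"anova": anova, "tukey": tukey}
    return out


def region_tests_table(tests: dict[int, dict]) -> pd.DataFrame:
    """Flatten :func:`compare_regions` output into one tidy CSV-able table."""
    rows = []
    for clus, res in tests.items():
        anova = res["anova"]
        for _, r in res["tukey"].iterrows():
            rows.append(
                {
                    "cluster": clus,
                    "anova_F": anova.statistic,
                    "anova_p": anova.pvalue,
                    "region_1": r["group_1"],
                    "region_2": r["group_2"],
                    "mean_diff": r["mean_diff"],
                    "tukey_p": r["p_adj"],
                }
            )
    return pd.DataFrame(rows)
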