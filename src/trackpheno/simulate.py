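"""Synthetic intravital-imaging scenes with planted behavioral archetypes.

The generator is the package's test bed: it produces cell tracks following
a persistent biased random walk with archetype-specific parameters, a
planar tumor-edge reference, static microenvironment point clouds (blood
vessels, macrophage and glial markers), a region partition, and export
fixtures in every supported tracking dialect.

The motion model is a persistent biased random walk — chosen for its
closed-form limiting cases (it is a stand-in for observed glioma motility,
not a biological claim).  Per step the heading is

    direction = normalize(p * prev_direction + (1 - p) * u + b * e_x)

with ``u`` uniform on the unit sphere, persistence ``p`` in [0, 1] and edge
drift ``b`` in [-1, 1] (positive = away from the tumor edge).  Step lengths
are Gamma-distributed with the archetype's mean.  The tumor edge is the
plane x = 0 with tumor tissue at x < 0, so ``dist_to_edge = max(x, 0)`` is
analytically checkable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import (
    TRACK_KEY,
    RegionAssignment,
    TMEComponentSet,
    TrackphenoWarning,
    TrackTable,
)

ARCHETYPE_NAMES = [
    "invading",
    "slow_invading",
    "retreating",
    "slow_retreating",
    "erratic",
    "static",
    "slow",
]


@dataclass(frozen=True)
class ArchetypeSpec:
    """Parameters of one planted behavioral archetype.

    mean_step: µm per frame; directional_persistence p in [0, 1];
    edge_drift b in [-1, 1] (positive = away from the tumor edge);
    noise_sd: positional measurement noise, µm.
    """

    name: str
    mean_step: float
    directional_persistence: float
    edge_drift: float
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.mean_step < 0:
            raise ValueError("mean_step must be >= 0")
        if not 0 <= self.directional_persistence <= 1:
            raise ValueError("directional_persistence must be in [0, 1]")
        if not -1 <= self.edge_drift <= 1:
            raise ValueError("edge_drift must be in [-1, 1]")


def easy_archetypes() -> list[ArchetypeSpec]:
    """Well-separated parameter set: clear speed / drift / persistence contrasts.

    Steps are µm per 20-min frame (mean speed = 3 * mean_step µm/h).
    """
    return [
        ArchetypeSpec("invading", 4.0, 0.9, 0.9, 0.3),
        ArchetypeSpec("slow_invading", 1.5, 0.8, 0.8, 0.3),
        ArchetypeSpec("retreating", 4.0, 0.9, -0.9, 0.3),
        ArchetypeSpec("slow_retreating", 1.5, 0.8, -0.8, 0.3),
        ArchetypeSpec("erratic", 4.0, 0.05, 0.0, 0.3),
        ArchetypeSpec("static", 0.1, 0.0, 0.0, 0.1),
        ArchetypeSpec("slow", 1.5, 0.3, 0.0, 0.3),
    ]


def hard_archetypes() -> list[ArchetypeSpec]:
    """Weakly separated regime: smaller contrasts, more measurement noise."""
    return [
        ArchetypeSpec("invading", 2.5, 0.7, 0.5, 0.8),
        ArchetypeSpec("slow_invading", 1.5, 0.6, 0.4, 0.8),
        ArchetypeSpec("retreating", 2.5, 0.7, -0.5, 0.8),
        ArchetypeSpec("slow_retreating", 1.5, 0.6, -0.4, 0.8),
        ArchetypeSpec("erratic", 2.5, 0.1, 0.0, 0.8),
        ArchetypeSpec("static", 0.3, 0.0, 0.0, 0.5),
        ArchetypeSpec("slow", 1.2, 0.3, 0.0, 0.8),
    ]


@dataclass
class SceneConfig:
    """Study-design parameters of a synthetic scene.

    Defaults mirror the acquisition design emulated by the generator:
    20-minute frame interval (dt = 1/3 h), 9 uniform timepoints (a 2.67 h
    track horizon), several mice each imaged at several positions.
    """

    archetypes: list[ArchetypeSpec] = field(default_factory=easy_archetypes)
    n_tracks_per_archetype: int = 40
    n_timepoints: int = 9
    dt: float = 1.0 / 3.0  # hours
    n_mice: int = 3
    positions_per_mouse: int = 3
    dropout_rate: float = 0.0  # fraction of interior timepoints dropped
    gamma_shape: float = 3.0  # step-length Gamma shape
    dimensionality: int = 3
    start_x: tuple[float, float] = (15.0, 40.0)  # µm from the tumor edge
    position_extent: float = 100.0  # y-slab width per position, µm
    z_extent: float = 50.0
    with_morphology: bool = False  # emit synthetic AREA/SOLIDITY passthroughs
    # --- microenvironment ---
    vessels_per_position: int = 2
    vessel_spacing: float = 5.0  # µm between sampled vessel spots
    vessel_near_archetype: str | None = None  # route a vessel along each such track
    vessel_jitter: float = 4.0  # lateral offset of routed vessels, µm
    tamm_count: int = 60  # mean CD20r points per position
    sr101_count: int = 60  # mean SR101 points per position
    enrich_component: str | None = None
    enrich_archetype: str | None = None
    enrich_radius: float = 20.0
    enrich_boost: int = 40
    # --- regions ---
    region_names: tuple[str, ...] = ("Void", "TAMM/Oligo", "TAMM/vascularized")
    archetype_mix_by_region: dict | None = None  # region -> {archetype: weight}
    tracks_per_position: int | None = None  # required with a region mix
    seed: int = 42

    def __post_init__(self):
        if not 0 <= self.dropout_rate <= 0.5:
            raise ValueError("dropout_rate must be in [0, 0.5]")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        if self.dimensionality not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")
        if self.archetype_mix_by_region is not None and self.tracks_per_position is None:
            raise ValueError("tracks_per_position is required with archetype_mix_by_region")


def _positions(config: SceneConfig) -> list[tuple[str, str, int]]:
    """(mouse_id, position_id, slab index within mouse) for every position."""
    out = []
    for m in range(config.n_mice):
        for p in range(config.positions_per_mouse):
            out.append((f"m{m + 1}", f"p{p + 1}", p))
    return out


def _region_of_slab(config: SceneConfig, slab: int) -> str:
    """Region by partition-plane membership of the position's y-slab."""
    n_regions = len(config.region_names)
    per = max(1, math.ceil(config.positions_per_mouse / n_regions))
    return config.region_names[min(slab // per, n_regions - 1)]


def _unit_sphere(rng: np.random.Generator, dim3: bool) -> np.ndarray:
    v = rng.normal(size=3)
    if not dim3:
        v[2] = 0.0
    nrm = np.linalg.norm(v)
    while nrm < 1e-12:
        v = rng.normal(size=3)
        if not dim3:
            v[2] = 0.0
        nrm = np.linalg.norm(v)
    return v / nrm


def _walk(
    rng: np.random.Generator,
    spec: ArchetypeSpec,
    start: np.ndarray,
    n_steps: int,
    gamma_shape: float,
    dim3: bool,
) -> np.ndarray:
    ex = np.array([1.0, 0.0, 0.0])
    b = spec.edge_drift
    p = spec.directional_persistence
    prev = ex * np.sign(b) if b != 0 else _unit_sphere(rng, dim3)
    pos = np.empty((n_steps + 1, 3))
    pos[0] = start
    for i in range(n_steps):
        u = _unit_sphere(rng, dim3)
        d = p * prev + (1 - p) * u + b * ex
        if not dim3:
            d[2] = 0.0
        nrm = np.linalg.norm(d)
        d = d / nrm if nrm > 1e-12 else u
        if spec.mean_step > 0:
            step = rng.gamma(gamma_shape, spec.mean_step / gamma_shape)
        else:
            step = 0.0
        pos[i + 1] = pos[i] + step * d
        prev = d
    return pos


def _tracks_for_position(config: SceneConfig, pos_idx: int, slab: int, rng) -> list[str]:
    """Archetype name per track to simulate at this position."""
    names = [a.name for a in config.archetypes]
    if config.archetype_mix_by_region is None:
        # balanced round-robin: track j of archetype a goes to position (j + a) mod P
        P = config.n_mice * config.positions_per_mouse
        out = []
        for ai, name in enumerate(names):
            for j in range(config.n_tracks_per_archetype):
                if (j + ai) % P == pos_idx:
                    out.append(name)
        return out
    region = _region_of_slab(config, slab)
    mix = config.archetype_mix_by_region.get(region, {})
    weights = np.array([mix.get(n, 1.0) for n in names], dtype=float)
    if weights.sum() <= 0:
        raise ValueError(f"region {region!r} has all-zero archetype weights")
    counts = rng.multinomial(config.tracks_per_position, weights / weights.sum())
    out = []
    for name, c in zip(names, counts):
        out += [name] * int(c)
    return out


def simulate_tracks(config: SceneConfig) -> tuple[TrackTable, pd.Series]:
    """Simulate the scene's tracks.

    Returns the canonical track table (with ``dist_to_edge``) and the
    planted ground-truth archetype per track, indexed by
    (mouse_id, position_id, track_id).
    """
    rng = np.random.default_rng(config.seed)
    dim3 = config.dimensionality == 3
    specs = {a.name: a for a in config.archetypes}
    rows = []
    truth_keys, truth_vals = [], []
    for pos_idx, (mouse, pos, slab) in enumerate(_positions(config)):
        y_lo = slab * config.position_extent
        names = _tracks_for_position(config, pos_idx, slab, rng)
        for tid, name in enumerate(names, start=1):
            spec = specs[name]
            start = np.array(
                [
                    rng.uniform(*config.start_x),
                    rng.uniform(y_lo + 5.0, y_lo + config.position_extent - 5.0),
                    rng.uniform(0.0, config.z_extent) if dim3 else 0.0,
                ]
            )
            path = _walk(rng, spec, start, config.n_timepoints - 1, config.gamma_shape, dim3)
            if spec.noise_sd > 0:
                noise = rng.normal(0.0, spec.noise_sd, size=path.shape)
                if not dim3:
                    noise[:, 2] = 0.0
                path = path + noise
            keep = np.ones(config.n_timepoints, dtype=bool)
            if config.dropout_rate > 0 and config.n_timepoints > 2:
                interior = rng.random(config.n_timepoints - 2) < config.dropout_rate
                keep[1:-1] = ~interior
            morph = None
            if config.with_morphology:
                area = 50.0 + np.cumsum(rng.normal(0.0, 2.0, config.n_timepoints))
                solidity = np.clip(
                    0.8 + np.cumsum(rng.normal(0.0, 0.01, config.n_timepoints)), 0.0, 1.0
                )
                morph = (area, solidity)
            for i in np.flatnonzero(keep):
                row = {
                    "mouse_id": mouse,
                    "position_id": pos,
                    "track_id": tid,
                    "t": i * config.dt,
                    "x": path[i, 0],
                    "y": path[i, 1],
                    "z": path[i, 2],
                    "dist_to_edge": max(path[i, 0], 0.0),
                }
                if morph is not None:
                    row["AREA"] = morph[0][i]
                    row["SOLIDITY"] = morph[1][i]
                rows.append(row)
            truth_keys.append((mouse, pos, tid))
            truth_vals.append(name)
    df = pd.DataFrame(rows)
    extra = ["AREA", "SOLIDITY"] if config.with_morphology else []
    table = TrackTable.from_dataframe(
        df, dimensionality=config.dimensionality, extra_features=extra
    )
    truth = pd.Series(
        truth_vals,
        index=pd.MultiIndex.from_tuples(truth_keys, names=TRACK_KEY),
        name="archetype",
    )
    return table, truth


def simulate_tme(
    config: SceneConfig,
    table: TrackTable,
    truth: pd.Series,
) -> tuple[dict[tuple, list[TMEComponentSet]], RegionAssignment]:
    """Static TME point clouds per position, plus the region partition.

    Vessels are polylines along the drift (x) axis sampled every
    ``vessel_spacing`` µm (object_kind ``spot``).  CD20r and SR101 are
    Poisson point clouds (object_kind ``surface_sample``), optionally
    intensity-boosted within ``enrich_radius`` of tracks of a named
    archetype.  When ``vessel_near_archetype`` is set, one vessel is routed
    along each such track's path (laterally jittered), planting perivascular
    structure for that archetype.
    """
    rng = np.random.default_rng(config.seed + 1)
    dim3 = config.dimensionality == 3
    components: dict[tuple, list[TMEComponentSet]] = {}
    region_rows = []
    df = table.df
    for mouse, pos, slab in _positions(config):
        g = df[(df["mouse_id"] == mouse) & (df["position_id"] == pos)]
        y_lo = slab * config.position_extent
        y_hi = y_lo + config.position_extent
        if len(g):
            x_lo, x_hi = g["x"].min() - 10.0, g["x"].max() + 10.0
        else:
            x_lo, x_hi = -10.0, 60.0
        box_lo = np.array([x_lo, y_lo, 0.0])
        box_hi = np.array([x_hi, y_hi, config.z_extent if dim3 else 0.0])

        # --- blood vessels ---
        anchors = []
        if config.vessel_near_archetype is not None:
            keys = truth[truth == config.vessel_near_archetype]
            for mk, pk, tk in keys.index:
                if mk != mouse or pk != pos:
                    continue
                tr = g[g["track_id"] == tk]
                a = tr[["y", "z"]].iloc[0].to_numpy(dtype=float)
                jit = rng.normal(0.0, config.vessel_jitter, size=2)
                if not dim3:
                    jit[1] = 0.0
                anchors.append(a + jit)
        for _ in range(config.vessels_per_position):
            yz = np.array(
                [rng.uniform(y_lo, y_hi), rng.uniform(0, config.z_extent) if dim3 else 0.0]
            )
            anchors.append(yz)
        bv_pts = []
        for yz in anchors:
            xs = np.arange(x_lo, x_hi + config.vessel_spacing, config.vessel_spacing)
            seg = np.column_stack([xs, np.full_like(xs, yz[0]), np.full_like(xs, yz[1])])
            bv_pts.append(seg)
        bv = np.concatenate(bv_pts) if bv_pts else np.empty((0, 3))

        def _cloud(mean_count):
            n = rng.poisson(mean_count)
            pts = rng.uniform(box_lo, box_hi, size=(n, 3))
            if not dim3:
                pts[:, 2] = 0.0
            return pts

        clouds = {"CD20r": _cloud(config.tamm_count), "SR101": _cloud(config.sr101_count)}
        if config.enrich_component and config.enrich_archetype:
            keys = truth[truth == config.enrich_archetype]
            pool = []
            for mk, pk, tk in keys.index:
                if mk == mouse and pk == pos:
                    pool.append(g[g["track_id"] == tk][["x", "y", "z"]].to_numpy(dtype=float))
            if pool:
                pool = np.concatenate(pool)
                centers = pool[rng.integers(0, len(pool), size=config.enrich_boost)]
                offs = rng.normal(0.0, config.enrich_radius / 2.0, size=(config.enrich_boost, 3))
                if not dim3:
                    offs[:, 2] = 0.0
                extra = centers + offs
                clouds[config.enrich_component] = np.concatenate(
                    [clouds[config.enrich_component], extra]
                )

        sets = [
            TMEComponentSet("BV", bv, object_kind="spot"),
            TMEComponentSet("CD20r", clouds["CD20r"], object_kind="surface_sample"),
            TMEComponentSet("SR101", clouds["SR101"], object_kind="surface_sample"),
        ]
        for s in sets:
            if s.points.shape[0] == 0:
                warnings.warn(
                    f"component {s.component_name!r} empty at {(mouse, pos)}",
                    TrackphenoWarning,
                    stacklevel=2,
                )
            s.validate()
        components[(mouse, pos)] = sets
        region_rows.append(
            {
                "mouse_id": mouse,
                "position_id": pos,
                "region_label": _region_of_slab(config, slab),
            }
        )
    regions = RegionAssignment(
        df=pd.DataFrame(region_rows),
        label_set=list(config.region_names),
        source="per_position_label",
    )
    regions.validate()
    return components, regions


@dataclass
class Scene:
    """Bundle of everything one simulated scene produces."""

    config: SceneConfig
    tracks: TrackTable
    truth: pd.Series
    components: dict[tuple, list[TMEComponentSet]]
    regions: RegionAssignment


def simulate_scene(config: SceneConfig | None = None, **overrides) -> Scene:
    """Simulate tracks + TME + regions in one call."""
    if config is None:
        config = SceneConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    tracks, truth = simulate_tracks(config)
    components, regions = simulate_tme(config, tracks, truth)
    return Scene(config, tracks, truth, components, regions)


DIALECTS = ("imaris", "trackmate", "mtrackj", "manual_tracking")

#: Statistic name used for the tumor-edge distance in Imaris fixtures
#: (the Distance Transformation surface statistic).
IMARIS_EDGE_STAT = "Shortest_Distance_to_Surfaces"


def write_fixtures(
    scene: Scene,
    dialect: str,
    outdir,
) -> "Path":
    """Write a scene as files in one tracking dialect's on-disk layout.

    The corresponding :mod:`trackpheno.io_tracks` reader parses the files
    back to equality.  Alongside the tracks, the scene's TME components,
    region partition and planted ground truth are written as plain CSVs.
    """
    from pathlib import Path

    from . import io_tracks
    from .tme_spatial import write_components_csv

    if dialect not in DIALECTS:
        raise ValueError(f"unsupported dialect {dialect!r}; choose from {DIALECTS}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = scene.tracks
    dt = scene.config.dt
    for (mouse, pos), g in table.df.groupby(["mouse_id", "position_id"], sort=False):
        tag = f"{mouse}__{pos}"
        if dialect == "imaris":
            io_tracks.write_imaris_position(
                g, outdir / tag, dt, table.extra_features, IMARIS_EDGE_STAT
            )
        elif dialect == "trackmate":
            io_tracks.write_trackmate_spots(
                g, outdir / f"{tag}_spots.csv", dt, table.extra_features
            )
        elif dialect == "mtrackj":
            io_tracks.write_mtrackj(g, outdir / f"{tag}_points.csv", dt)
        else:
            io_tracks.write_manual_tracking(g, outdir / f"{tag}_manual.csv", dt)
    write_components_csv(scene.components, outdir / "components.csv")
    scene.regions.df.to_csv(outdir / "regions.csv", index=False)
    scene.truth.reset_index().to_csv(outdir / "ground_truth.csv", index=False)
    return outdir
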