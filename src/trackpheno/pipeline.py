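"""End-to-end orchestration from a single config file.

``run_pipeline`` executes read -> interpolate -> crop -> features ->
(optional upstream spatial) -> PCA -> DTW -> embed/cluster -> characterize
-> (optional downstream spatial, large-scale regions), writing every
artifact as CSV plus a JSON manifest of content hashes.  Stage outputs are
pure functions of (inputs, config, seeds), so re-running an identical
config reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as tp_features
from . import heterogeneity as tp_het
from . import io_tracks, tme_regions, tme_spatial
from .types import TrackphenoWarning

log = logging.getLogger("trackpheno")


@dataclass
class RunConfig:
    """Validated run configuration (see ``RunConfig.from_yaml``)."""

    input_dialect: str  # imaris | trackmate | mtrackj | manual_tracking
    input_path: str
    output_dir: str
    k: int
    dt: float = 1.0 / 3.0
    frame_interval: float = 1.0 / 3.0
    edge_column: str | None = None
    features: list[str] = field(default_factory=list)  # empty = all kinetic
    passthrough_features: list[str] = field(default_factory=list)
    var_threshold: float = 0.90
    dtw_step: str = "symmetric2"
    dtw_window: int | None = None
    dtw_normalize: bool = False
    seed: int = 42
    umap_n_neighbors: int = 15
    umap_min_dist: float = 0.1
    cluster_on: str = "embedding"
    # small-scale options
    components_file: str | None = None
    spatial_mode: str = "downstream"  # upstream | downstream
    spatial_radius: float = 30.0
    spatial_knn: tuple[int, ...] = (3, 10)
    proximity_overrides: dict = field(default_factory=dict)
    # large-scale options
    regions_file: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        missing = [k for k in ("input_dialect", "input_path", "output_dir", "k") if k not in d]
        if missing:
            raise ValueError(f"config is missing required keys: {missing}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def validate(self) -> None:
        if self.input_dialect not in ("imaris", "trackmate", "mtrackj", "manual_tracking"):
            raise ValueError(f"unknown input dialect {self.input_dialect!r}")
        if not Path(self.input_path).exists():
            raise ValueError(f"input path does not exist: {self.input_path}")
        for attr in ("components_file", "regions_file"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{attr} does not exist: {p}")
        if not isinstance(self.k, int) or self.k < 2:
            raise ValueError("k must be an integer >= 2")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        if self.spatial_mode not in ("upstream", "downstream"):
            raise ValueError(f"unknown spatial_mode {self.spatial_mode!r}")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["spatial_knn"] = list(self.spatial_knn)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_input(cfg: RunConfig):
    dialect = cfg.input_dialect
    path = Path(cfg.input_path)
    if dialect == "imaris":
        return io_tracks.read_imaris_positions(
            path, edge_column=cfg.edge_column, frame_interval=cfg.frame_interval
        )
    parts = []
    dim = 2
    extras = []
    patterns = {
        "trackmate": "*_spots.csv",
        "mtrackj": "*_points.csv",
        "manual_tracking": "*_manual.csv",
    }
    files = sorted(path.glob(patterns[dialect])) if path.is_dir() else [path]
    if not files:
        raise ValueError(f"no {dialect} files found under {path}")
    for f in files:
        name = f.name
        for suffix in ("_spots.csv", "_points.csv", "_manual.csv"):
            name = name.removesuffix(suffix)
        mouse, _, pos = name.partition("__")
        if not pos:
            mouse, pos = "m1", name or "p1"
        if dialect == "trackmate":
            t = io_tracks.read_trackmate_spots(
                f, frame_interval=cfg.frame_interval, mouse_id=mouse, position_id=pos
            )
        else:
            t = io_tracks.read_fiji_manual(
                f, dialect=dialect, frame_interval=cfg.frame_interval,
                mouse_id=mouse, position_id=pos,
            )
        if len(t.df):
            parts.append(t.df)
            dim = max(dim, t.dimensionality)
            extras = t.extra_features
    if not parts:
        raise ValueError(f"no tracks parsed from {path}")
    df = pd.concat(parts, ignore_index=True)
    from .types import TrackTable

    return TrackTable.from_dataframe(df, dimensionality=dim, extra_features=extras)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the manifest dict (also written as JSON).

    The manifest lists every artifact with its SHA-256 content hash, plus
    the config, seeds and package versions used.
    """
    import sklearn
    import umap

    from . import __version__

    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def _emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        artifacts[name] = _sha256(path)
        log.info("wrote %s (%s)", path, artifacts[name][:12])

    stage = "read"
    try:
        table = _read_input(config)
        log.info("parsed %d tracks (%d rows)", table.n_tracks, len(table.df))

        stage = "interpolate"
        table = tp_features.interpolate_to_grid(table, config.dt)
        stage = "crop"
        table = tp_features.crop_common_length(table)
        _emit("track_table.csv", lambda p: table.df.to_csv(p, index=False))

        stage = "features"
        tensor = tp_features.compute_kinetic_features(
            table, passthrough=config.passthrough_features
        )
        if config.features:
            tensor = tensor.select(config.features)

        spatial = None
        if config.components_file is not None:
            stage = "spatial_features"
            components = tme_spatial.read_components_csv(config.components_file)
            spatial = tme_spatial.compute_spatial_features(
                table,
                components,
                knn_list=tuple(config.spatial_knn),
                radius=config.spatial_radius,
                proximity_overrides=config.proximity_overrides,
            )
            _emit(
                "spatial_features.csv",
                lambda p: spatial.per_timepoint.to_csv(p, index=False),
            )
            if config.spatial_mode == "upstream":
                tensor = tme_spatial.integrate_upstream(tensor, spatial)

        _emit("feature_tensor.csv", lambda p: tensor.to_long().to_csv(p, index=False))

        stage = "pca"
        pcs = tp_het.scale_and_pca(tensor, var_threshold=config.var_threshold)
        log.info("retained %d PCs", pcs.n_pc)

        stage = "dtw"
        dmat = tp_het.cross_distance(
            pcs, step=config.dtw_step, window=config.dtw_window,
            normalize=config.dtw_normalize,
        )
        _emit(
            "distance_matrix.csv",
            lambda p: pd.DataFrame(
                dmat.D,
                index=["|".join(map(str, k)) for k in dmat.track_index],
                columns=["|".join(map(str, k)) for k in dmat.track_index],
            ).to_csv(p),
        )

        stage = "embed_cluster"
        result = tp_het.embed_and_cluster(
            dmat,
            k=config.k,
            seed=config.seed,
            n_neighbors=config.umap_n_neighbors,
            min_dist=config.umap_min_dist,
            cluster_on=config.cluster_on,
        )
        _emit("embedding_labels.csv", lambda p: result.to_frame().to_csv(p, index=False))

        stage = "characterize"
        summaries = tp_features.summarize_track_features(tensor)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", TrackphenoWarning)
            summary = tp_het.characterize_clusters(result, summaries)
        _emit("cluster_summary.csv", lambda p: summary.to_csv(p, index=False))

        stage = "backprojection"
        _emit(
            "backprojection.csv",
            lambda p: io_tracks.write_backprojection(result, table, p),
        )

        if spatial is not None and config.spatial_mode == "downstream":
            stage = "spatial_downstream"
            down = tme_spatial.integrate_downstream(result, spatial)
            _emit(
                "spatial_cluster_summary.csv",
                lambda p: down["cluster_summary"].to_csv(p, index=False),
            )
            if "proximity_by_position" in down:
                _emit(
                    "proximity_summary.csv",
                    lambda p: down["proximity_by_position"].to_csv(p, index=False),
                )

        if config.regions_file is not None:
            stage = "largescale"
            regions = tme_regions.read_region_csv(config.regions_file)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", TrackphenoWarning)
                freqs = tme_regions.cluster_frequencies(result, regions, table)
                tests = tme_regions.compare_regions(freqs)
            _emit("region_frequencies.csv", lambda p: freqs.to_csv(p, index=False))
            _emit(
                "region_tests.csv",
                lambda p: tme_regions.region_tests_table(tests).to_csv(p, index=False),
            )
    except Exception as err:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r}: {err}. Partial outputs (if any) "
            f"are in {outdir} and are not listed in a manifest."
        ) from err

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {
            "trackpheno": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "umap-learn": umap.__version__,
        },
        "artifacts": artifacts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
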