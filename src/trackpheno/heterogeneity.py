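"""Behavioral classification of track time series.

The engine standardizes the per-timepoint features, projects them onto the
principal components explaining a configurable share of variance, computes a
multivariate dynamic-time-warping (DTW) cross-distance between tracks,
embeds the distance matrix in 2D with UMAP and clusters the embedding with
k-means.  Every stochastic step takes an explicit seed and records it.

The DTW used is the *dependent* multivariate variant: a single warping path
aligns all feature dimensions, with the Euclidean norm across dimensions as
local cost.  An independent per-dimension variant is available as an option.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from . import stats as tp_stats
from .types import (
    ClusterResult,
    DistanceMatrix,
    FeatureTensor,
    PCSeries,
    TrackphenoWarning,
)


def scale_and_pca(tensor: FeatureTensor, var_threshold: float = 0.90) -> PCSeries:
    """Standardize features and project timepoints onto principal components.

    Features are standardized to mean 0, sd 1 over all pooled
    (track, timepoint) rows — without this, PCA is dominated by whichever
    feature has the largest physical unit.  PCA is fit on the pooled rows
    and the number of retained components is the smallest m whose
    cumulative explained variance reaches ``var_threshold``.

    Constant features carry no information and are dropped with a warning.
    """
    if not 0 < var_threshold <= 1:
        raise ValueError("var_threshold must be in (0, 1]")
    tensor.validate()
    n, t, f = tensor.values.shape
    if f < 2:
        raise ValueError("need at least 2 features for PCA")
    X = tensor.values.reshape(n * t, f)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [nm for nm, k in zip(tensor.feature_names, keep) if not k]
        warnings.warn(f"dropping constant feature(s): {dropped}", TrackphenoWarning, stacklevel=2)
        X = X[:, keep]
        sd = sd[keep]
    if X.shape[1] < 1:
        raise ValueError("no non-constant features left for PCA")
    Xs = (X - X.mean(axis=0)) / sd
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(Xs)
    cumvar = np.cumsum(pca.explained_variance_ratio_)
    n_pc = int(np.searchsorted(cumvar, var_threshold - 1e-12) + 1)
    n_pc = min(n_pc, scores.shape[1])
    pcs = PCSeries(
        track_index=tensor.track_index,
        time_grid=tensor.time_grid,
        pc_values=scores[:, :n_pc].reshape(n, t, n_pc),
        explained_variance_ratio=pca.explained_variance_ratio_[:n_pc].copy(),
        n_pc=n_pc,
    )
    pcs.validate()
    return pcs


def dtw_distance(
    a: np.ndarray,
    b: np.ndarray,
    step: str = "symmetric2",
    window: int | None = None,
    normalize: bool = False,
) -> float:
    """Dependent multivariate DTW distance between two series.

    Parameters
    ----------
    a, b
        Arrays of shape (length, dims); 1-D input is treated as one
        dimension.  Both series must share the same dimensionality.
    step
        ``symmetric2`` (default): the diagonal transition carries weight 2
        and the edge transitions weight 1, the standard symmetric step
        pattern.  ``symmetric1``: all transitions weight 1.
    window
        Sakoe–Chiba band half-width: only alignments with |i - j| <= window
        are allowed.  Must be at least |len(a) - len(b)| to be feasible.
    normalize
        Divide the terminal cumulative cost by len(a) + len(b) (the
        symmetric2 path-length normalizer).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("series must be 1-D or (length, dims) arrays")
    n, m = a.shape[0], b.shape[0]
    if n == 0 or m == 0:
        raise ValueError("empty series")
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"dimension mismatch: {a.shape[1]} vs {b.shape[1]}")
    if step not in ("symmetric1", "symmetric2"):
        raise ValueError(f"unknown step pattern {step!r}")
    if window is not None:
        if window < 0:
            raise ValueError("window must be non-negative")
        if window < abs(n - m):
            raise ValueError(
                f"window {window} is infeasible for lengths {n} and {m}; "
                f"needs at least {abs(n - m)}"
            )
    cost = cdist(a, b, metric="euclidean")
    D = np.full((n, m), np.inf)
    diag_w = 2.0 if step == "symmetric2" else 1.0
    for i in range(n):
        if window is not None:
            j_lo = max(0, i - window)
            j_hi = min(m, i + window + 1)
        else:
            j_lo, j_hi = 0, m
        for j in range(j_lo, j_hi):
            c = cost[i, j]
            if i == 0 and j == 0:
                D[i, j] = c
                continue
            best = np.inf
            if i > 0:
                best = D[i - 1, j] + c
            if j > 0:
                best = min(best, D[i, j - 1] + c)
            if i > 0 and j > 0:
                best = min(best, D[i - 1, j - 1] + diag_w * c)
            D[i, j] = best
    total = float(D[n - 1, m - 1])
    if normalize:
        total /= n + m
    return total


def dtw_distance_independent(a, b, **kwargs) -> float:
    """Independent multivariate DTW: sum of per-dimension univariate DTWs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"dimension mismatch: {a.shape[1]} vs {b.shape[1]}")
    return float(sum(dtw_distance(a[:, d : d + 1], b[:, d : d + 1], **kwargs) for d in range(a.shape[1])))


def cross_distance(
    pcs: PCSeries,
    step: str = "symmetric2",
    window: int | None = None,
    normalize: bool = False,
    variant: str = "dependent",
) -> DistanceMatrix:
    """Pairwise DTW cross-distance matrix over all tracks.

    Computed for i < j and mirrored; the diagonal is exactly zero.
    """
    n = pcs.pc_values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 tracks")
    fn = dtw_distance if variant == "dependent" else dtw_distance_independent
    if variant not in ("dependent", "independent"):
        raise ValueError(f"unknown DTW variant {variant!r}")
    D = np.zeros((n, n))
    series = [pcs.pc_values[i] for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = fn(series[i], series[j], step=step, window=window, normalize=normalize)
    out = DistanceMatrix(track_index=pcs.track_index, D=D)
    out.validate()
    return out


def _pam_medoids(D: np.ndarray, k: int, seed: int, max_iter: int = 100) -> np.ndarray:
    """Simple seeded PAM (k-medoids) directly on a precomputed distance matrix."""
    rng = np.random.default_rng(seed)
    n = D.shape[0]
    medoids = rng.choice(n, size=k, replace=False)
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        new = medoids.copy()
        for c in range(k):
            members = np.where(labels == c)[0]
            if len(members) == 0:
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new[c] = members[np.argmin(within)]
        if np.array_equal(np.sort(new), np.sort(medoids)):
            break
        medoids = new
    return np.argmin(D[:, medoids], axis=1)


def embed_and_cluster(
    dmat: DistanceMatrix,
    k: int,
    seed: int = 42,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    cluster_on: str = "embedding",
) -> ClusterResult:
    """UMAP-embed the cross-distance matrix and k-means the embedding.

    UMAP runs in precomputed-distance mode with a fixed ``random_state`` so
    repeated runs are identical.  ``cluster_on='embedding'`` (default) runs
    k-means with multiple restarts on the 2D coordinates;
    ``cluster_on='distance'`` clusters the distance matrix directly with a
    seeded PAM (k-medoids) instead.
    """
    import umap  # deferred: heavy import

    dmat.validate()
    n = dmat.D.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n_tracks ({n}); got {k}")
    if cluster_on not in ("embedding", "distance"):
        raise ValueError(f"unknown cluster_on {cluster_on!r}")
    nn = min(n_neighbors, n - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2,
            metric="precomputed",
            n_neighbors=nn,
            min_dist=min_dist,
            random_state=seed,
        )
        embedding = reducer.fit_transform(dmat.D)
    embedding = np.asarray(embedding, dtype=float)
    if cluster_on == "embedding":
        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        labels = km.fit_predict(embedding)
    else:
        labels = _pam_medoids(dmat.D, k, seed)
    labels = _relabel_canonical(labels, k)
    result = ClusterResult(
        track_index=dmat.track_index,
        embedding=embedding,
        labels=labels,
        k=k,
        params={
            "seed": seed,
            "n_neighbors": nn,
            "min_dist": min_dist,
            "cluster_on": cluster_on,
        },
    )
    result.validate()
    return result


def _relabel_canonical(labels: np.ndarray, k: int) -> np.ndarray:
    """Relabel clusters by order of first appearance so ids are stable."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) != k:
        raise ValueError("clustering produced an empty cluster; lower k")
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def silhouette_vs_k(
    dmat: DistanceMatrix,
    k_range=range(2, 11),
    seed: int = 42,
    **embed_kwargs,
) -> pd.DataFrame:
    """Diagnostic: mean silhouette (on the precomputed distances) per k.

    Provided to help users choose k; never applied automatically.
    """
    from sklearn.metrics import silhouette_score

    rows = []
    for k in k_range:
        if k >= dmat.D.shape[0]:
            break
        res = embed_and_cluster(dmat, k=k, seed=seed, **embed_kwargs)
        score = silhouette_score(dmat.D, res.labels, metric="precomputed")
        rows.append({"k": k, "silhouette": float(score)})
    return pd.DataFrame(rows)


def characterize_clusters(
    result: ClusterResult,
    track_summaries: pd.DataFrame,
) -> pd.DataFrame:
    """Per-cluster feature means with per-feature ANOVA across clusters.

    Returns a tidy table with one row per (cluster, feature): the raw mean
    of track-level values, the display value min-max rescaled per feature to
    [0, 1] across clusters (constant features rescale to 0), and the
    one-way-ANOVA p-value for that feature across clusters.  Clusters with
    fewer than 2 tracks are excluded from the ANOVA (with a warning) but
    their means are still reported.
    """
    result.validate()
    summaries = track_summaries.loc[result.track_index]
    labels = np.asarray(result.labels)
    rows = []
    for feat in summaries.columns:
        vals = summaries[feat].to_numpy(dtype=float)
        means = {c: vals[labels == c].mean() for c in range(result.k)}
        groups = {c: vals[labels == c] for c in range(result.k)}
        testable = {c: g for c, g in groups.items() if len(g) >= 2}
        if len(testable) < 2:
            warnings.warn(
                f"too few clusters with >= 2 tracks to test feature {feat!r}",
                TrackphenoWarning,
                stacklevel=2,
            )
            p = np.nan
        else:
            if len(testable) < len(groups):
                warnings.warn(
                    f"excluding singleton cluster(s) from ANOVA for {feat!r}",
                    TrackphenoWarning,
                    stacklevel=2,
                )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", TrackphenoWarning)
                res = tp_stats.one_way_anova(testable)
            p = res.pvalue
            if not np.isfinite(p):
                warnings.warn(
                    f"degenerate variance for feature {feat!r}; ANOVA p undefined",
                    TrackphenoWarning,
                    stacklevel=2,
                )
        mvals = np.array([means[c] for c in range(result.k)])
        span = mvals.max() - mvals.min()
        scaled = (mvals - mvals.min()) / span if span > 0 else np.zeros_like(mvals)
        for c in range(result.k):
            rows.append(
                {
                    "cluster": c,
                    "feature": feat,
                    "mean": means[c],
                    "scaled_mean": scaled[c],
                    "anova_p": p,
                }
            )
    summary = pd.DataFrame(rows)
    result.summary = summary
    return summary


def plot_cluster_heatmap(summary: pd.DataFrame, ax=None):
    """Heatmap of rescaled per-cluster feature means (display aid only)."""
    import matplotlib.pyplot as plt

    pivot = summary.pivot(index="feature", columns="cluster", values="scaled_mean")
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * pivot.shape[1] + 2, 0.5 * pivot.shape[0] + 1))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(pivot.shape[1]), [str(c) for c in pivot.columns])
    ax.set_yticks(range(pivot.shape[0]), list(pivot.index))
    ax.set_xlabel("cluster")
    ax.figure.colorbar(im, ax=ax, label="scaled mean")
    return ax
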