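# trackpheno

Behavioral phenotyping of single-cell migration tracks from time-lapse
(intravital) microscopy, and correlation of the resulting behavioral
clusters with tumor-microenvironment (TME) composition.

Traditional track analysis compares one parameter at a time (mean speed,
displacement). That misses cells that share a speed but differ in what
matters — e.g. fast cells invading *away from* a tumor edge versus fast
cells retreating *toward* it. `trackpheno` instead classifies whole
multivariate time series: for every track it builds per-timepoint series of
speed, squared displacement (`disp2`), displacement delta (`disp_d`),
displacement length (`disp_l`), persistence (`disp_d/disp_l`) and, when a
tumor-edge reference exists, the invasion velocity (rate of change of the
distance to the edge). The series are standardized, projected on the
principal components explaining ≥ 90% of variance, compared pairwise with
dependent multivariate dynamic time warping (one warping path across all
dimensions, Euclidean local cost, `symmetric2` step pattern)

```
D[i,j] = DTW(PC-series of track i, PC-series of track j)
```

then embedded in 2-D with UMAP (precomputed-distance mode, fixed seed) and
clustered with k-means. Per cluster, feature means are summarized in a
heatmap-ready table with one-way-ANOVA significance per feature, and the
labels are back-projected onto the original per-timepoint records for
visualization in the source imaging software.

Two optional TME modules relate behavior to microenvironment:

- **small scale** — per-cell spatial statistics against static component
  point clouds (blood-vessel spots, macrophage/glial surfaces): local cell
  density (mean distance to the 3/10 nearest cells), counts within a 30 µm
  radius, minimum component distances, and proximity classification (≤ 15 µm
  for surfaces, ≤ 3 µm for spots), integrated either upstream (as extra
  clustering features) or downstream (per-cluster comparisons, with a
  mixed-effects model using mouse as random effect);
- **large scale** — behavioral-cluster frequencies per imaging position,
  z-scored per mouse, compared across externally defined TME regions
  (e.g. Void / TAMM-Oligo / TAMM-vascularized) by ANOVA + Tukey HSD.

Supported inputs: Imaris per-statistic CSV exports, TrackMate "allspots"
CSVs, MTrackJ and ManualTracking point lists. A synthetic-scene generator
(persistent biased random walks with seven planted behavioral archetypes, a
planar tumor edge, vessels and marker point clouds, and a region partition)
provides ground truth for every claim the test suite makes.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from sklearn.metrics import adjusted_rand_score
from trackpheno.simulate import simulate_scene
from trackpheno import features as F, heterogeneity as H

scene = simulate_scene(n_tracks_per_archetype=40, seed=1)   # 7 archetypes
table = F.crop_common_length(F.interpolate_to_grid(scene.tracks, scene.config.dt))
tensor = F.compute_kinetic_features(table)
pcs = H.scale_and_pca(tensor, var_threshold=0.90)
dmat = H.cross_distance(pcs)
result = H.embed_and_cluster(dmat, k=7, seed=42)
summary = H.characterize_clusters(result, F.summarize_track_features(tensor))

print(f"{result.k} clusters over {len(result.labels)} tracks; "
      f"{pcs.n_pc} PCs explain {pcs.explained_variance_ratio.sum():.1%} of variance")
pivot = summary.pivot(index="feature", columns="cluster", values="scaled_mean").round(2)
print(pivot.loc[["mean_speed", "mean_disp2", "mean_persistence", "mean_invasion"]])
ari = adjusted_rand_score(scene.truth.loc[result.track_index].to_numpy(), result.labels)
print(f"ARI vs planted archetypes: {ari:.2f}")
```

prints

```
7 clusters over 280 tracks; 4 PCs explain 96.6% of variance
cluster              0     1     2     3     4     5     6
feature
mean_speed        0.95  0.36  0.98  0.40  1.00  0.00  0.41
mean_disp2        0.98  0.15  1.00  0.16  0.24  0.00  0.04
mean_persistence  1.00  0.87  0.96  0.87  0.32  0.00  0.29
mean_invasion     1.00  0.64  0.00  0.21  0.44  0.43  0.44
ARI vs planted archetypes: 0.86
```

Read the rescaled heatmap rows per cluster (0 = lowest cluster mean for
that feature, 1 = highest): cluster 0 is fast, persistent and moving away
from the tumor edge (invading); cluster 2 is equally fast and persistent
but with the *lowest* invasion velocity (retreating) — the distinction a
mean-speed comparison cannot make. Cluster 5 is static. The adjusted Rand
index of 0.86 scores agreement with the generator's planted archetypes.

## Command line

```sh
trackpheno simulate --config scene.yaml --dialect imaris --out data/
trackpheno heterogeneity --config run.yaml     # clustering only
trackpheno smallscale    --config run.yaml --mode downstream
trackpheno largescale    --config run.yaml
trackpheno run-all       --config run.yaml     # everything configured
trackpheno show-config                         # config template
```

Every run writes CSV artifacts (track table, distance matrix,
embedding + labels, cluster summary, back-projection, spatial and region
tables) plus `manifest.json` with a SHA-256 hash per artifact; identical
configs and seeds reproduce identical hashes.

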