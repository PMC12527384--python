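# Methods

## Scope and model

`trackpheno` classifies the migratory behavior of single cells tracked in
time-lapse (typically intravital) microscopy, and relates the resulting
behavioral clusters to the composition of the tumor microenvironment (TME).
It consumes the outputs of upstream segmentation/tracking tools (Imaris
statistics exports, TrackMate "allspots" CSVs, MTrackJ and ManualTracking
point lists) and never touches images: segmentation, tracking and region
discovery (e.g. CytoMAP neighborhoods) are external computations whose
results are inputs here.

The classification engine works on multivariate per-timepoint feature
series per track:

1. **Harmonization.** Tracks are linearly interpolated onto a uniform grid
   of spacing `dt` (hours) within each track's observed span (no
   extrapolation), then cropped to the minimal common length so all series
   are directly comparable. With a 20-minute frame interval (`dt = 1/3 h`)
   and the default 9 timepoints, the common horizon is 2.67 h.
2. **Kinetic features** per timepoint: speed, squared displacement from the
   start (`disp2`), displacement delta (`disp_d`, straight-line distance to
   the start), displacement length (`disp_l`, cumulative path length),
   persistence (`disp_d / disp_l`, the directionality ratio in [0, 1]) and,
   when a tumor-edge distance is available, the invasion velocity (backward
   difference of the edge distance; positive = moving away from the edge
   into healthy tissue). Morphology columns exported by the upstream tool
   can be passed through but are never computed here.
3. **Standardize + PCA.** Each feature is standardized to mean 0, sd 1 over
   all pooled (track, timepoint) rows (without this the decomposition is
   dominated by whichever feature has the largest unit), then projected on
   the smallest number of principal components whose cumulative explained
   variance reaches a threshold (default 0.90).
4. **Multivariate DTW.** The cross-distance between tracks is dependent
   multivariate dynamic time warping: one warping path aligns all PC
   dimensions, with the Euclidean norm across dimensions as local cost.
   Default step pattern is `symmetric2` (diagonal weight 2), no band, no
   normalization — the common defaults of time-series-clustering packages;
   all three are configurable, and an independent per-dimension variant is
   available.
5. **Embed + cluster.** UMAP in precomputed-distance mode (defaults
   `n_neighbors = 15`, `min_dist = 0.1`, both logged; these are generic
   UMAP defaults, not values with special meaning here) gives 2-D
   coordinates; k-means with multiple restarts on those coordinates gives
   the cluster labels. `k` is always user-chosen; a silhouette-vs-k
   diagnostic is provided but never applied automatically. Clustering the
   distance matrix directly with a seeded PAM is available as an
   alternative (`cluster_on="distance"`).
6. **Characterization.** Per cluster, track-level feature summaries
   (`mean_<f>`, `<f>_range`) are averaged; per feature, a one-way ANOVA
   across clusters gives a significance level, and the display values are
   min–max rescaled per feature to [0, 1].

Every stochastic step (UMAP, k-means, PAM, simulation) takes an explicit
seed and records it; identical inputs + seeds reproduce byte-identical
outputs, which the run manifest (SHA-256 per artifact) makes checkable.

## Spatial statistics (small scale)

TME components are static 3-D point clouds, one snapshot per imaging
position: centroid "spots" (e.g. blood-vessel detections) or boundary
samples of rendered surfaces. For each tracked cell: mean distance to its
k nearest fellow cells (local density; k = 3 and 10 by default), the count
of component points within a 30 µm radius (boundary inclusive), and the
minimum distance to each component. Track-level values are means over the
track's timepoints — the components are a single co-registered snapshot, so
averaging over time is the natural per-track reduction. Proximity is
`min_dist <= threshold` with kind-dependent defaults: 15 µm for surface
boundaries, 3 µm for centroid spots (surfaces have physical extent; spots
are centroids, hence the stricter cutoff). When fewer than k neighbors
exist the density feature is missing, never padded.

Spatial features integrate either **upstream** (appended to the feature
tensor before PCA/DTW, which requires per-timepoint coverage) or
**downstream** (per-cluster distribution summaries, per-position
percentages of "close" cells, and a mixed-effects comparison across
clusters with mouse as a random intercept).

## Regions (large scale)

Region labels are supplied externally as CSV, per position (default) or per
cell (which takes precedence). Per position, the percentage of tracks in
each behavioral cluster is computed with zeros included (so percentages sum
to 100), then z-scored within each (mouse, cluster) across that mouse's
positions to absorb inter-mouse offsets (sd uses n−1; singleton groups give
missing values). Regions are compared per cluster by one-way ANOVA with
Tukey HSD post hoc.

A caveat the tests quantify: z-scoring couples the positions of one mouse
(they must average to zero), so with very few positions per mouse the
region ANOVA on z-scores is mildly anti-conservative (~0.11 at two
positions per region in our null simulations); with four or more positions
per region the empirical type-I rate is at the nominal 0.05. Designs that
thin, not the test, are the limitation.

## Statistical primitives

ANOVA (sum-of-squares F with F(k−1, N−k) tail), Tukey–Kramer HSD
(studentized-range tail at N−k df), and the Pearson chi-square (no
continuity correction) are written from their definitions, with reference
distributions from scipy; the test suite cross-checks each against an
independent implementation. The linear mixed-effects comparison is a
contract over statsmodels `MixedLM` (random intercept for mouse, optional
variance component for TME class); non-convergence is reported, never
silently replaced by a fixed-effects ANOVA. The cluster effect is a Wald
chi-square on the fixed-effect block and pairwise contrasts use the normal
approximation — adequate at the group counts the tests use, slightly
anti-conservative with very few grouping levels. No across-feature
multiple-testing correction is applied beyond Tukey's within-family
adjustment; users comparing many features should correct downstream.

## The synthetic-data generator

The generator exists so that every downstream claim can be checked against
planted truth. Tracks follow a persistent biased random walk: per frame the
heading is `normalize(p·prev + (1−p)·u + b·ê_x)` with `u` uniform on the
sphere, persistence `p ∈ [0, 1]`, and edge drift `b ∈ [−1, 1]` along the
x-axis; step lengths are Gamma (shape 3) with the archetype's mean. The
tumor edge is the plane x = 0 (tumor at x < 0), so `dist_to_edge = max(x, 0)`
and the deterministic limits are closed-form: `p = 1, b = 1` gives perfectly
straight outward motion (persistence ≡ 1), `mean_step = 0` gives all-zero
kinetics, and mean speed converges to `mean_step/dt` by the law of large
numbers. The model is a stand-in with checkable limits, not a claim about
tumor-cell biophysics; curved tumor edges, confinement, cell–cell exclusion
and division are deliberately absent, so passing recovery tests demonstrates
the pipeline's discriminative machinery, not its performance on any real
tissue.

Seven archetypes are planted, named by the behavior they emulate:
invading / slow invading (outward drift), retreating / slow retreating
(inward drift), erratic (fast, non-persistent), slow, and static. The
"easy" parameter set uses clearly separated speeds (4.0 vs 1.5 vs 0.1 µm
per 20-min frame), drifts (|b| = 0.8–0.9 vs 0) and small positional noise
(0.3 µm); a "hard" set with overlapping parameters and larger noise is
provided for stress testing. Scene defaults (3 mice × 3 positions,
dt = 1/3 h, 9 frames) mirror a typical multi-position intravital session.

The TME generator samples blood vessels as polylines along the drift axis
(spots every 5 µm), and macrophage/glial markers as uniform Poisson clouds
per position (surface samples, mean 60 points). Two kinds of structure can
be planted: vessels routed along the paths of a named archetype's tracks
(perivascular migration), and component clouds intensity-boosted near a
named archetype's tracks. Positions occupy disjoint y-slabs; region labels
(Void, TAMM/Oligo, TAMM/vascularized by default) are assigned by slab
membership, with an optional per-region archetype mix to plant
region-specific behavior frequencies.

## Numerical choices and edge cases

- Speed at the first timepoint is 0 (not missing) so tensors stay gap-free;
  persistence with zero path length is defined as 0.
- `disp2` is the squared distance from the track start (consistent with
  `disp_d`), not a per-step quantity.
- Cropping keeps the *first* L timepoints of each track (aligned at track
  start), not a sliding window.
- 2-D data is stored with z = 0; all geometry is written once for 3-D.
- Time grids are exact multiples of `dt`; readers convert frame indices by
  one multiplication so write→read round-trips are exact to float
  precision.
- Sakoe–Chiba windows narrower than the length difference of the two series
  are rejected rather than silently returning infinity.
- Constant features are dropped before PCA with a warning; a min–max
  rescaling of a constant column is defined as 0.
- Decimal commas in numeric CSV cells are a hard parse error.

## Problem sizes used in the automated checks

The planted-truth experiments run at desk scale: archetype recovery uses
7 × 40 tracks × 9 timepoints (ARI of the full pipeline against planted
labels, threshold 0.7); the perivascular-enrichment check uses 20 seeded
replicates of 16 tracks per archetype across 2 mice × 2 positions, scoring
the ANOVA on mean vessel distance per planted archetype at α = 0.01 (the
recovery of those archetypes by clustering is scored separately, so the two
failure modes stay distinguishable); calibration checks use 250 null
simulations. `scripts/acceptance.py --seed <int> --out <path>` recomputes
all of these from scratch and writes the measured values as JSON.

## Known limitations

- DTW cross-distance is O(n² · L²); at a few hundred tracks it runs in
  seconds, at tens of thousands it will not.
- UMAP determinism is per-environment: fixed seeds reproduce results on the
  same software stack, not necessarily across library versions.
- Distance-to-surface is approximated by distance to sampled boundary
  points; the approximation error is bounded by the sampling spacing.
- Track-level proximity uses the time-mean minimum distance, so transient
  contacts shorter than the frame interval are invisible.
- The mixed-model p-values use large-sample approximations; with two or
  three mice they are indicative, not exact.
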