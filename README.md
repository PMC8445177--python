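# fiberclust

Fast, deterministic clustering of whole-brain tractography streamlines.

Diffusion-MRI tractography reconstructs white-matter pathways as millions of
3D polylines ("fibers" or "streamlines"). Grouping them into anatomically
coherent bundles is a prerequisite for bundle inspection, atlas construction
and inter-subject analysis — but classical clustering algorithms do not scale
to million-fiber tractograms, and streamlines carry no canonical orientation:
the same curve may be stored forwards or backwards, so naive point-wise
distances mis-pair curves stored in opposite order.

`fiberclust` implements a four-step map/reduce-style clustering pipeline over
fibers resampled to 21 equidistant 3D points, built on the orientation-
invariant **minimum direct-flip distance**

```
d_P(a_i, b_i) = ||a_i − b_i||
d_E(a, b)     = max_{i∈21} d_P(a_i, b_i)          (direct order)
d_EF(a, b)    = d_E(a, b^F)                        (one fiber reversed)
d_ME(a, b)    = min(d_E(a, b), d_EF(a, b))
```

The four steps:

1. **Point clustering** — the 3D points at positions {1, 4, 11, 18, 21} of
   every fiber are clustered independently with Lloyd's k-means. Seeding is
   either random, deterministic farthest-first k-means++ (each new centroid is
   the point farthest from all previous ones), or farthest-first followed by
   **centroid retraction**: every initial centroid is pulled a fraction
   *r* toward the centroid mean, `q_i = C_i(1−r) + C_m·r` (default r = 0.05),
   damping the farthest-first rule's attraction to outliers.
2. **Grouping** — fibers sharing the same 5-label membership key form
   preliminary clusters (a sort-by-key / reduce-by-key group-by).
3. **Reassignment** — preliminary clusters with < 6 fibers are merged into
   the nearest large cluster when their centroids lie within d_Rmax = 6 mm
   under d_ME (a per-position lower-bound filter cascade prunes the search);
   residual 1–2 fiber clusters are discarded as noise.
4. **Clique merging** — within each middle-point membership group, candidate
   clusters become vertices of a graph with edges below d_Mmax = 6 mm; all
   maximal cliques (Bron–Kerbosch with pivoting over a degeneracy ordering)
   are merged in decreasing size order. An optional post-filter drops final
   clusters with intra-cluster distance > 70 mm.

Quality is summarised by fiber coverage and the Davies–Bouldin index computed
under d_ME. A synthetic-tractogram generator (planted bundles with Gaussian
spread, a configurable fraction of reversed-order fibers, optional noise
fibers) makes every stage testable end to end without any imaging data.

## Worked example

Simulate 8 bundles of 50 fibers each, cluster them, and score the result
against the planted labels:

```sh
$ fiberclust simulate -o demo.npy --labels-out demo_labels.csv \
      --n-bundles 8 --fibers-per-bundle 50 --seed 7
wrote 400 fibers (8 bundles) to demo.npy

$ fiberclust cluster demo.npy -o demo_run --kpc 8 --kpo 16 --seed 7
8 clusters, coverage 100.0%, 0 noise fibers

$ fiberclust evaluate demo.npy demo_run.clusters.json --labels demo_labels.csv
8 clusters, coverage 100.0%, DB 0.071
agreement vs ground truth (ARI): 1.000
```

All 8 planted bundles are recovered exactly (adjusted Rand index 1.0) with
every fiber assigned (coverage 100 %). The Davies–Bouldin index of 0.071 says
clusters are ~14× more separated than dispersed. `demo_run.stats.csv` holds
per-cluster size and dispersion:

```
cluster_id,size,intra_mm,mean_dispersion_mm
0,50,4.11825249793347,2.7315442094690514
1,50,4.246018477812368,2.6644021853717583
```

The same pipeline is available as a library:

```python
from fiberclust import SyntheticSpec, generate_tractogram, \
    PipelineConfig, run_pipeline, labels_to_reference

t, labels = generate_tractogram(SyntheticSpec(seed=1))
fc, report = run_pipeline(t, PipelineConfig(k_pc=20, k_po=40, seed=1))
print(labels_to_reference(labels, fc), report.coverage_pct)
```

Tractograms are read and written as TrackVis `.trk`, BrainVISA-style
`.bundles`/`.bundlesdata` pairs, or raw `(n, 21, 3)` float32 `.npy` dumps;
fibers of any length are resampled to 21 equidistant points on read.

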