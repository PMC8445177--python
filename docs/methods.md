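# Methods

## Fiber representation and distances

A fiber is a 3D polyline resampled to exactly 21 points placed at equal
arc-length intervals (linear interpolation along the input polyline; the two
endpoints are preserved bit-exactly). The fixed-length representation makes
every fiber pair comparable point-by-point and lets a tractogram live in a
single `(n, 21, 3)` array.

Streamline orientation is arbitrary: tractography may store the same curve
with its points in either order. All fiber-to-fiber comparisons therefore use
the minimum direct-flip distance d_ME — the smaller of the direct and the
reversed max-point-distance (Chebyshev over positions, Euclidean per point).
d_P and d_E are true metrics; d_ME is symmetric, non-negative and invariant
to flipping either argument, but it does **not** satisfy the triangle
inequality, so nothing in the pipeline relies on it.

A consequence used heavily in step 3: for any single position j,
`min(d_P(a_j, b_j), d_P(a_j, b_{22−j})) ≤ d_ME(a, b)`, because d_ME realises
one of the two correspondences and is a maximum over positions within it.
Any one position therefore yields a cheap lower bound, and a sequence of
positions yields a pruning cascade that can never discard a true
within-threshold neighbour. The equivalence of the cascaded and the
brute-force reassignment is asserted by test, not assumed.

Cluster centroids are point-wise arithmetic means of orientation-aligned
members: each member is kept or flipped, whichever is closer (d_E) to a
reference member (the first, by default — deterministic and order-stable).
Alignment makes the centroid invariant to the storage order of any subset of
members; a flag disables it for experiments.

## Step 1 — per-position point clustering

The points at positions 1, 4, 11, 18 and 21 (endpoints, two intermediates,
middle) are clustered independently with Lloyd's k-means. Three seedings are
provided:

* `random` — k distinct data points, uniform;
* `kpp` — deterministic farthest-first (maximin) seeding: after a random
  first pick, each next centroid is the data point maximising the distance to
  its nearest chosen centroid. Note this is the argmax variant, **not** the
  D²-weighted sampling form of k-means++; the argmax is what makes the
  procedure deterministic given the first pick.
* `kpp_retract` — farthest-first followed by one retraction step
  `q_i = C_i(1−r) + C_m·r` toward the centroid mean C_m. Farthest-first
  seeding by construction favours outliers; retraction (default r = 0.05)
  pulls seeds back toward the data mass. With r = 0 it reduces exactly to
  `kpp`; with r = 1 all seeds collapse onto C_m.

Determinism contracts in Lloyd's iteration: assignment ties go to the lowest
centroid index; an empty cluster is repaired by stealing the point currently
farthest from its assigned centroid (stolen points become ineligible for
further steals within the pass, which bounds repairs at k and guarantees
termination even on pathological all-duplicate inputs); iteration stops when
the fraction of points changing label is ≤ tol (default 0, i.e. exact
convergence) or after max_iter = 100 rounds.

### Cluster counts

Defaults are k = 200 at the middle position and k = 300 at the other four —
the values established by the elbow method on million-fiber whole-brain
tractograms. They are properties of that data scale, not of the algorithm,
so `select_k_elbow` re-derives k at any scale: fit k-means over a candidate
grid and pick the k following the largest *relative* drop in within-cluster
sum of squares. When point blobs are well separated this is the k where
inertia falls from between-blob to within-blob magnitude.

On the synthetic recovery benchmark (20 bundles, 30 % flipped) the selector
chooses ~20 clusters at the middle position and ~40 at the endpoints. The
asymmetry is structural: position 11 is its own flip partner, so reversing a
fiber leaves its middle point in the same blob, while each bundle's endpoint
points split into two blobs (one per orientation). The same mechanism
explains why the full-scale middle count (200) is below the endpoint count
(300). Choosing the middle k well matters more than any other parameter:
step 4 merges candidates only within a middle-membership group, so
oversegmentation at the middle position can never be repaired downstream.

## Step 2 — grouping

Fibers sharing the identical 5-label key form a preliminary cluster. The
implementation sorts rows lexicographically (stable) and cuts segments at key
changes, mirroring sort-by-key/reduce-by-key semantics; output order is
deterministic (lexicographic by key) and independent of input row order.

## Step 3 — reassignment

Preliminary clusters split at the size-6 threshold into small (S_S, < 6
fibers) and large (S_L, ≥ 6). Each small cluster merges into the nearest
large cluster iff the centroid d_ME is **strictly** below d_Rmax = 6 mm. The
search runs in one pass against the pre-merge large centroids — small
clusters never chain onto each other, so the result is independent of
processing order. Ties take the lowest large-cluster index. Unmerged small
clusters of 3–5 fibers survive as candidates; clusters of 1–2 fibers are
discarded as noise. Merged clusters inherit the large cluster's membership
key (the large cluster dominates the merge) and carry centroids recomputed
over the final membership.

The probe order of the pruning cascade is middle point, endpoints,
intermediate positions, then the rest; correctness is guaranteed by the lower
bound regardless of order, so order only affects how early candidates die.

## Step 4 — clique merging

Candidates are grouped by the middle component of their key. Within a group,
the candidate-centroid graph has an edge where d_ME < d_Mmax = 6 mm
(strict). Maximal cliques are enumerated with Bron–Kerbosch using pivoting
inside an outer loop over a degeneracy vertex ordering — near-linear on the
sparse graphs this refinement step produces, and verified in tests against
exhaustive subset enumeration. Cliques are processed by decreasing vertex
count (ties: lexicographically smallest vertex set — the tie rule and the
post-merge centroid recomputation are choices this package fixes for
determinism, since either convention is defensible); each clique merges its
not-yet-consumed members, so the final clusters partition the candidates.
Isolated vertices are size-1 maximal cliques and pass through unchanged.

The optional post-filter removes final clusters whose intra-cluster distance
(max member-to-centroid d_ME) exceeds 70 mm — at full scale such clusters
are short-fiber noise — moving their fibers to the noise set.

## Quality metrics

Davies–Bouldin under d_ME: `DB = (1/n) Σ_i max_{j≠i} (α_i + α_j)/d(c_i, c_j)`
with α_i the **mean** member-to-centroid d_ME and d(c_i, c_j) the centroid
d_ME; the max runs over all j ≠ i literally. Coincident centroids are an
error (named pair) rather than a silent infinity. On degenerate fibers whose
21 points coincide, d_ME collapses to the 3D Euclidean metric and the index
equals the standard Euclidean Davies–Bouldin score — the cross-check used in
tests. The dispersion convention is a package decision: α_i = mean matches
common DB usage, while the 70 mm filter uses the max so a single stray fiber
is enough to flag a cluster; both are configurable. The normalised index
DB_n = DB_ref / DB_method and the population variance (÷ n, not n−1)
support comparisons across pipeline variants and trials. Coverage is the
percentage of fibers in final clusters; the inter-cluster histogram uses all
centroid pairs by default with a nearest-neighbour mode behind a flag.

## Synthetic tractograms

The generator plants bundles around smooth centerlines (cubic Bézier curves,
control points a bounded random walk in a 150 mm box, rejection-sampled until
all pairwise centerline d_ME ≥ the requested separation). Members add i.i.d.
per-point Gaussian offsets (sd = within_spread) and are resampled back to 21
points; a flip_fraction subset is stored reversed; optional noise fibers are
independent random curves labelled −1. All randomness flows from one seed
through a single generator; fiber order is shuffled so bundles are not
contiguous.

Defaults (20 bundles × 100 fibers, 1 mm spread, 20 mm separation, 30 %
flipped, no noise) define the recovery benchmark used by the test suite and
`scripts/acceptance.py`; at this size the full pipeline runs in ~2 s on one
CPU. What the benchmark emulates — and what it does not: real tractograms
have ~10⁶ fibers, anatomy-shaped (non-Bézier) bundles with varying width and
length, overlapping and crossing pathways, and a much larger unstructured
fraction. Perfect recovery here shows the pipeline's logic is sound under
clean separation and arbitrary orientation; it does not predict coverage or
cluster quality on clinical data. Agreement with planted labels is scored
with the adjusted Rand index, excluding planted-noise fibers by default (a
mode treating noise as its own label exists).

## Numerical and I/O notes

* Distances and centroids are float64 throughout; files store float32.
* `.bundles`/`.bundlesdata` and `.npy` round trips are bit-exact at float32.
  TRK passes through nibabel's affine machinery in float32 arithmetic, so
  round trips agree to ~1e-4 mm rather than bit-exactly.
* Strict `<` at both 6 mm thresholds and strict `>` at the 70 mm filter;
  boundary cases are covered by tests.
* `fit_point_clusters` clamps k to N with a warning when a tractogram is
  smaller than the requested cluster count, keeping small runs total.
* Per-position k-means runs derive independent child seeds from the master
  seed, so columns are mutually independent but jointly reproducible.

## Known limitations

* Middle-position oversegmentation is unrecoverable by design (step 4 never
  merges across middle groups); choose k_pc with care or use the elbow
  selector.
* d_ME is sensitive to partial overlap: a short fiber running along part of
  a long one is far from it under the max-point distance.
* The pipeline is single-threaded; the step structure (independent
  positions, independent groups) parallelises naturally but this
  implementation favours determinism and simplicity.
* No TCK/VTK formats and no affine/world-space handling; coordinates are
  taken as given in mm.
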