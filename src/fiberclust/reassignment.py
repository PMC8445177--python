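"""Reassignment of small preliminary clusters to large ones (step 3).

Step 1/2 can split a coherent bundle whenever some of its fibers are stored
in reversed point order: the reversed fibers get different point-cluster
labels and therefore a different membership key.  This step repairs those
splits.  Preliminary clusters are divided into *small* (< 6 fibers, S_S)
and *large* (>= 6, S_L); each small cluster whose centroid lies within
d_Rmax (default 6 mm, strict) of the nearest large-cluster centroid under
the orientation-invariant distance d_ME is merged into that large cluster.
Residual small clusters of 1-2 fibers are discarded as noise; those of 3-5
fibers survive as candidate clusters in their own right.

The nearest-neighbour search prunes with a cascade of per-position
lower bounds on d_ME (middle point first, then endpoints, then the
intermediate positions, then the rest); the cascade is an optimisation
only — `reassign_small_bruteforce` computes the identical result with no
pruning and serves as the equivalence oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fiber_model import N_POINTS
from .grouping import PreliminaryCluster
from .metrics import centroid, pairwise_min_distance

__all__ = [
    "CandidateCluster",
    "split_small_large",
    "reassign_small",
    "reassign_small_bruteforce",
    "pruning_filter_cascade",
    "SMALL_THRESHOLD",
    "D_RMAX",
]

#: Clusters with fewer fibers than this are "small".
SMALL_THRESHOLD = 6
#: Reassignment distance threshold in mm (strict less-than).
D_RMAX = 6.0

# probe order of 1-based positions for the pruning cascade:
# middle, endpoints, the two intermediates, then all remaining positions
_CASCADE_STAGES = (
    (11,),
    (1, 21),
    (4, 18),
    tuple(p for p in range(1, N_POINTS + 1) if p not in (1, 4, 11, 18, 21)),
)


@dataclass(frozen=True)
class SizedCluster:
    """A preliminary cluster annotated with its centroid (internal)."""

    key: tuple
    fiber_ids: tuple
    centroid: np.ndarray

    @property
    def size(self) -> int:
        return len(self.fiber_ids)


@dataclass(frozen=True)
class CandidateCluster:
    """A step-3 survivor: fiber-id set, aligned mean centroid, and the
    membership key inherited from its (dominant) preliminary cluster."""

    key: tuple
    fiber_ids: tuple
    centroid: np.ndarray

    @property
    def size(self) -> int:
        return len(self.fiber_ids)


def _with_centroid(c: PreliminaryCluster, points: np.ndarray,
                   align: bool = True) -> SizedCluster:
    return SizedCluster(
        key=c.key,
        fiber_ids=c.fiber_ids,
        centroid=centroid(points[list(c.fiber_ids)], align=align),
    )


def split_small_large(
    prelim: list[PreliminaryCluster],
    t,
    small_threshold: int = SMALL_THRESHOLD,
    align: bool = True,
):
    """Partition preliminary clusters into (S_S, S_L) and attach centroids.

    S_S holds clusters with fewer than ``small_threshold`` fibers, S_L the
    rest; both keep their input order.
    """
    points = t.points
    S_S = [_with_centroid(c, points, align) for c in prelim if c.size < small_threshold]
    S_L = [_with_centroid(c, points, align) for c in prelim if c.size >= small_threshold]
    return S_S, S_L


def pruning_filter_cascade(c_s: np.ndarray, large_centroids: np.ndarray,
                           d_rmax: float = D_RMAX) -> np.ndarray:
    """Indices of large clusters whose full d_ME to ``c_s`` could still be
    below ``d_rmax``.

    Stage by stage, discards every large centroid whose per-position lower
    bound  min(d_P(c_s[j], c_l[j]), d_P(c_s[j], c_l[22-j]))  at a probe
    position j already reaches d_rmax.  Because the bound never exceeds
    d_ME, survivors are a superset of the within-threshold clusters.
    """
    large_centroids = np.asarray(large_centroids, dtype=float)
    alive = np.arange(large_centroids.shape[0])
    for stage in _CASCADE_STAGES:
        if alive.size == 0:
            break
        keep = np.ones(alive.size, dtype=bool)
        for pos in stage:
            j = pos - 1
            jf = N_POINTS - pos  # 0-based index of position 22 - pos
            p = c_s[j]
            d_direct = np.linalg.norm(large_centroids[alive, j, :] - p, axis=1)
            d_flip = np.linalg.norm(large_centroids[alive, jf, :] - p, axis=1)
            keep &= np.minimum(d_direct, d_flip) < d_rmax
        alive = alive[keep]
    return alive


def _assemble(
    S_S: list[SizedCluster],
    S_L: list[SizedCluster],
    merge_target: list[int | None],
    points: np.ndarray,
    align: bool,
):
    """Build candidates and noise from per-small-cluster merge decisions."""
    absorbed: dict[int, list[int]] = {}
    candidates: list[CandidateCluster] = []
    noise: set[int] = set()
    for s, tgt in zip(S_S, merge_target):
        if tgt is not None:
            absorbed.setdefault(tgt, []).extend(s.fiber_ids)
        elif s.size >= 3:
            candidates.append(
                CandidateCluster(key=s.key, fiber_ids=s.fiber_ids, centroid=s.centroid)
            )
        else:
            noise.update(s.fiber_ids)
    large_candidates = []
    for li, l in enumerate(S_L):
        ids = tuple(sorted(set(l.fiber_ids) | set(absorbed.get(li, ()))))
        cen = centroid(points[list(ids)], align=align) if li in absorbed else l.centroid
        large_candidates.append(CandidateCluster(key=l.key, fiber_ids=ids, centroid=cen))
    # large clusters first (their indices are the reassignment targets),
    # then surviving small clusters, preserving input order within each
    return large_candidates + candidates, noise


def reassign_small(
    S_S: list[SizedCluster],
    S_L: list[SizedCluster],
    t,
    d_rmax: float = D_RMAX,
    align: bool = True,
):
    """Merge small clusters into their nearest large cluster within d_rmax.

    One pass against the pre-merge large centroids (order-independent;
    small clusters never chain onto each other).  Ties in the nearest-
    neighbour search take the lowest large-cluster index.  Returns
    ``(candidates, noise_ids)``; merged large clusters carry centroids
    recomputed over their final membership.
    """
    points = t.points
    if not S_L:
        return _assemble(S_S, S_L, [None] * len(S_S), points, align)
    large_cents = np.stack([l.centroid for l in S_L])
    targets: list[int | None] = []
    for s in S_S:
        alive = pruning_filter_cascade(s.centroid, large_cents, d_rmax)
        tgt = None
        if alive.size:
            d = pairwise_min_distance(s.centroid[None], large_cents[alive])[0]
            best = int(np.argmin(d))  # lowest index on ties
            if d[best] < d_rmax:
                tgt = int(alive[best])
        targets.append(tgt)
    return _assemble(S_S, S_L, targets, points, align)


def reassign_small_bruteforce(
    S_S: list[SizedCluster],
    S_L: list[SizedCluster],
    t,
    d_rmax: float = D_RMAX,
    align: bool = True,
):
    """Reference implementation: every pairwise d_ME, no pruning."""
    points = t.points
    if not S_L:
        return _assemble(S_S, S_L, [None] * len(S_S), points, align)
    large_cents = np.stack([l.centroid for l in S_L])
    targets: list[int | None] = []
    for s in S_S:
        d = pairwise_min_distance(s.centroid[None], large_cents)[0]
        best = int(np.argmin(d))
        targets.append(best if d[best] < d_rmax else None)
    return _assemble(S_S, S_L, targets, points, align)
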