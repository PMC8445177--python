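"""Fiber distances, orientation-aligned centroids, and cluster dispersion.

Whole-brain tractograms carry no canonical streamline orientation: the same
curve may be stored forwards or backwards.  All fiber-to-fiber comparisons
therefore use the *minimum direct-flip* distance d_ME:

    d_P(a_i, b_i)  = ||a_i - b_i||                      (point distance)
    d_E(a, b)      = max_i d_P(a_i, b_i)                (direct)
    d_EF(a, b)     = d_E(a, flip(b))                    (flipped)
    d_ME(a, b)     = min(d_E, d_EF)

d_P and d_E are metrics; d_ME is symmetric and flip-invariant but does not
satisfy the triangle inequality in general.

A useful pruning bound: for any point position j (1-based),

    min(d_P(a_j, b_j), d_P(a_j, b_{22-j})) <= d_ME(a, b)

since d_ME realises one of the two correspondences and is a max over
positions under it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


__all__ = [
    "ClusterStats",
    "point_distance",
    "fiber_distance_direct",
    "fiber_distance_flipped",
    "fiber_distance_min",
    "pairwise_min_distance",
    "centroid",
    "cluster_stats",
]


def point_distance(a_i, b_i) -> float:
    """Euclidean distance between two 3D points (d_P)."""
    return float(np.linalg.norm(np.asarray(a_i, dtype=float) - np.asarray(b_i, dtype=float)))


def fiber_distance_direct(a, b) -> float:
    """Max over the 21 corresponding point distances (d_E)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.linalg.norm(a - b, axis=-1).max())


def fiber_distance_flipped(a, b) -> float:
    """d_E with one fiber reversed (d_EF)."""
    return fiber_distance_direct(a, np.asarray(b)[::-1])


def fiber_distance_min(a, b) -> float:
    """Minimum direct-flip distance d_ME = min(d_E, d_EF)."""
    return min(fiber_distance_direct(a, b), fiber_distance_flipped(a, b))


def pairwise_min_distance(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """d_ME between every fiber in ``A`` and every fiber in ``B``.

    Parameters
    ----------
    A : ndarray, shape (na, 21, 3)
    B : ndarray, shape (nb, 21, 3)

    Returns
    -------
    ndarray, shape (na, nb)
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    # (na, nb, 21) point distances under both correspondences
    diff = A[:, None, :, :] - B[None, :, :, :]
    d_e = np.linalg.norm(diff, axis=-1).max(axis=-1)
    diff_f = A[:, None, :, :] - B[None, :, ::-1, :]
    d_ef = np.linalg.norm(diff_f, axis=-1).max(axis=-1)
    return np.minimum(d_e, d_ef)


def _orient_to(fibers: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Flip each fiber when the flipped order is closer (d_E) to reference."""
    fibers = np.asarray(fibers, dtype=float)
    ref = np.asarray(reference, dtype=float)
    d_dir = np.linalg.norm(fibers - ref, axis=-1).max(axis=-1)
    d_flip = np.linalg.norm(fibers[:, ::-1, :] - ref, axis=-1).max(axis=-1)
    out = fibers.copy()
    mask = d_flip < d_dir
    out[mask] = out[mask, ::-1, :]
    return out


def centroid(fibers: np.ndarray, reference: np.ndarray | None = None,
             align: bool = True) -> np.ndarray:
    """Point-wise arithmetic mean of orientation-aligned member fibers.

    Each member is kept or flipped, whichever minimises its direct distance
    d_E to the reference (default: the first member), before averaging.
    With ``align=False`` the stored orientations are averaged as-is.
    """
    fibers = np.asarray(fibers, dtype=float)
    if fibers.ndim == 2:
        fibers = fibers[None]
    if fibers.shape[0] == 0:
        raise ValueError("centroid of an empty fiber set is undefined")
    if align:
        ref = fibers[0] if reference is None else np.asarray(reference, dtype=float)
        fibers = _orient_to(fibers, ref)
    return fibers.mean(axis=0)


@dataclass(frozen=True)
class ClusterStats:
    """Dispersion summary of one cluster.

    intra_distance : max member-to-centroid d_ME in mm (drives the optional
        70 mm post-filter); mean_dispersion : mean member-to-centroid d_ME
        in mm (the per-cluster dispersion term of the Davies-Bouldin index);
    size : member count.
    """

    intra_distance: float
    mean_dispersion: float
    size: int

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("cluster size must be >= 1")


def cluster_stats(fibers: np.ndarray, centroid_fiber: np.ndarray) -> ClusterStats:
    """Max and mean member-to-centroid d_ME plus the member count."""
    fibers = np.asarray(fibers, dtype=float)
    if fibers.ndim == 2:
        fibers = fibers[None]
    if fibers.shape[0] == 0:
        raise ValueError("cluster_stats of an empty fiber set is undefined")
    d = pairwise_min_distance(fibers, np.asarray(centroid_fiber)[None])[:, 0]
    return ClusterStats(
        intra_distance=float(d.max()),
        mean_dispersion=float(d.mean()),
        size=int(fibers.shape[0]),
    )
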