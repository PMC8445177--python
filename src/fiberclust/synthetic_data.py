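"""Ground-truth-labelled synthetic tractograms.

The generator plants ``n_bundles`` spatially coherent fiber bundles inside a
bounded box.  Each bundle has a smooth centerline — a cubic Bezier curve
whose control points are sampled in the box, rejection-sampled so that every
pair of centerlines is at least ``bundle_separation`` mm apart under the
orientation-invariant fiber distance d_ME.  Member fibers are the centerline
plus independent per-point Gaussian offsets (sd ``within_spread`` mm),
resampled to the standard 21 equidistant points.  A fraction
``flip_fraction`` of all fibers is stored in reversed point order, emulating
the arbitrary streamline orientation of real tractography.  Optional noise
fibers are independent random curves with ground-truth label -1.

Defaults mirror the end-to-end recovery experiment used throughout the test
suite: 20 bundles x 100 fibers, 1 mm spread, 20 mm separation, 30% flipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .fiber_model import N_POINTS, Tractogram, resample_fiber
from .clique_merge import FinalClustering

__all__ = ["SyntheticSpec", "generate_tractogram", "labels_to_reference"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic tractogram.

    bundle_separation is the minimum pairwise centerline d_ME in mm;
    within_spread the per-point Gaussian sd around the centerline in mm;
    noise_fraction the fraction of the total fiber count added as
    unstructured fibers (label -1).
    """

    n_bundles: int = 20
    fibers_per_bundle: int = 100
    bundle_separation: float = 20.0
    within_spread: float = 1.0
    flip_fraction: float = 0.3
    noise_fraction: float = 0.0
    box_size: float = 150.0
    curve_scale: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bundles < 1 or self.fibers_per_bundle < 1:
            raise ValueError("need at least one bundle with one fiber")
        if self.bundle_separation <= 0 or self.within_spread < 0:
            raise ValueError("separation must be positive, spread non-negative")
        for frac in (self.flip_fraction, self.noise_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


def _bezier(control: np.ndarray, n: int = 64) -> np.ndarray:
    """Evaluate a cubic Bezier curve at n parameter values."""
    t = np.linspace(0.0, 1.0, n)[:, None]
    p0, p1, p2, p3 = control
    return ((1 - t) ** 3 * p0 + 3 * (1 - t) ** 2 * t * p1
            + 3 * (1 - t) * t ** 2 * p2 + t ** 3 * p3)


def _random_curve(rng: np.random.Generator, box: float, scale: float) -> np.ndarray:
    """A 21-point random smooth curve: cubic Bezier with a start point in
    the box and subsequent control points a bounded walk from it."""
    start = rng.uniform(-box / 2, box / 2, size=3)
    steps = rng.normal(0.0, scale / 3.0, size=(3, 3))
    control = np.vstack([start, start + np.cumsum(steps, axis=0)])
    return resample_fiber(_bezier(control), N_POINTS)


def _min_dme_to(curve: np.ndarray, others: list[np.ndarray]) -> float:
    from .metrics import pairwise_min_distance

    if not others:
        return np.inf
    return float(pairwise_min_distance(curve[None], np.stack(others))[0].min())


def generate_tractogram(spec: SyntheticSpec, max_attempts: int = 5000):
    """Generate a labelled synthetic tractogram.

    Returns
    -------
    (Tractogram, ndarray of int)
        Fibers in randomly permuted order and the aligned ground-truth
        labels (bundle index, or -1 for noise fibers).

    Raises
    ------
    RuntimeError
        If the requested bundle separation cannot be met inside the box
        after ``max_attempts`` rejection-sampling attempts.
    """
    rng = np.random.default_rng(spec.seed)
    centerlines: list[np.ndarray] = []
    attempts = 0
    while len(centerlines) < spec.n_bundles:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {spec.n_bundles} centerlines at separation "
                f"{spec.bundle_separation} mm in a {spec.box_size} mm box "
                f"after {max_attempts} attempts; increase box_size"
            )
        attempts += 1
        cand = _random_curve(rng, spec.box_size, spec.curve_scale)
        if _min_dme_to(cand, centerlines) >= spec.bundle_separation:
            centerlines.append(cand)

    fibers: list[np.ndarray] = []
    labels: list[int] = []
    for b, cl in enumerate(centerlines):
        for _ in range(spec.fibers_per_bundle):
            f = cl + rng.normal(0.0, spec.within_spread, size=(N_POINTS, 3))
            fibers.append(resample_fiber(f, N_POINTS))
            labels.append(b)
    n_structured = len(fibers)
    n_noise = int(round(spec.noise_fraction * n_structured / max(1e-12, 1 - spec.noise_fraction))) \
        if spec.noise_fraction < 1 else 0
    for _ in range(n_noise):
        fibers.append(_random_curve(rng, spec.box_size, spec.curve_scale))
        labels.append(-1)

    points = np.stack(fibers)
    labels_arr = np.array(labels)
    n = points.shape[0]
    # store a random subset reversed
    n_flip = int(round(spec.flip_fraction * n))
    flip_idx = rng.choice(n, size=n_flip, replace=False)
    points[flip_idx] = points[flip_idx, ::-1, :]
    # shuffle fiber order so bundles are not contiguous on disk
    perm = rng.permutation(n)
    return Tractogram(points[perm], space_note="synthetic/mm"), labels_arr[perm]


def labels_to_reference(true_labels, fc: FinalClustering,
                        noise_handling: str = "exclude") -> float:
    """Chance-corrected agreement (adjusted Rand index) between planted
    labels and a recovered clustering.

    ``noise_handling='exclude'`` scores only fibers with a planted bundle
    label (true label != -1); ``'own_label'`` keeps noise fibers, treating
    planted noise and recovered noise each as one extra label.  Returns 1
    iff the partitions are identical up to relabelling, ~0 at chance level.
    """
    true_labels = np.asarray(true_labels)
    pred = fc.labels(true_labels.shape[0])
    if noise_handling == "exclude":
        mask = true_labels != -1
        if not mask.any():
            raise ValueError("no non-noise fibers to score")
        return float(adjusted_rand_score(true_labels[mask], pred[mask]))
    if noise_handling == "own_label":
        return float(adjusted_rand_score(true_labels, pred))
    raise ValueError("noise_handling must be 'exclude' or 'own_label'")
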