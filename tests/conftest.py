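"""Shared fixtures and helpers for the fiberclust test suite."""

from __future__ import annotations

import numpy as np
import pytest

from fiberclust.fiber_model import N_POINTS, Tractogram
from fiberclust.grouping import PreliminaryCluster
from fiberclust.reassignment import split_small_large


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_fibers(rng, n, scale=50.0):
    """n random (21, 3) fibers: smooth-ish random walks in a box."""
    starts = rng.uniform(-scale, scale, size=(n, 1, 3))
    steps = rng.normal(0, scale / 20, size=(n, N_POINTS, 3))
    return starts + np.cumsum(steps, axis=1)


def straight_fiber(direction=(1.0, 0.0, 0.0), origin=(0.0, 0.0, 0.0), length=20.0):
    """21 equidistant points on a straight segment."""
    t = np.linspace(0, length, N_POINTS)[:, None]
    return np.asarray(origin) + t * (np.asarray(direction) / np.linalg.norm(direction))


def make_reassignment_instance(rng, n_small=100, n_large=50, spread=0.5,
                               box=120.0):
    """A random step-3 instance: small (1-5 fiber) and large (6-12 fiber)
    preliminary clusters of coherent fibers, plus the tractogram.

    Cluster centerlines are random fibers in a box; cluster members jitter
    around them, so nearest-large distances straddle the 6 mm threshold.
    """
    prelim = []
    fibers = []
    next_id = 0
    sizes = np.concatenate([
        rng.integers(1, 6, size=n_small),
        rng.integers(6, 13, size=n_large),
    ])
    for ci, size in enumerate(sizes):
        center = random_fibers(rng, 1, scale=box / 2)[0]
        ids = []
        for _ in range(int(size)):
            f = center + rng.normal(0, spread, size=(N_POINTS, 3))
            if rng.random() < 0.3:
                f = f[::-1]
            fibers.append(f)
            ids.append(next_id)
            next_id += 1
        key = tuple(int(x) for x in rng.integers(0, 30, size=5))
        prelim.append(PreliminaryCluster(key=key, fiber_ids=tuple(ids)))
    t = Tractogram(np.stack(fibers))
    return prelim, t


def make_split_instance(rng, **kwargs):
    prelim, t = make_reassignment_instance(rng, **kwargs)
    S_S, S_L = split_small_large(prelim, t)
    return S_S, S_L, t
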