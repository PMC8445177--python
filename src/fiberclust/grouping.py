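"""Preliminary fiber clusters from identical membership keys (step 2).

Two fibers land in the same preliminary cluster exactly when their step-1
point-cluster labels agree at all five selected positions.  The grouping is
implemented as a stable lexicographic sort of the composite keys followed by
a segmented reduction (the sort-by-key / reduce-by-key pattern), so the
output order is deterministic: clusters are emitted in lexicographic key
order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .point_clustering import PointMembershipMatrix

__all__ = ["PreliminaryCluster", "group_by_membership"]


@dataclass(frozen=True)
class PreliminaryCluster:
    """A maximal set of fibers sharing one 5-label membership key."""

    key: tuple
    fiber_ids: tuple

    @property
    def size(self) -> int:
        return len(self.fiber_ids)


def group_by_membership(m: PointMembershipMatrix) -> list[PreliminaryCluster]:
    """Group fibers by identical membership rows.

    Returns one cluster per distinct row-key, sorted lexicographically by
    key; fiber ids within a cluster keep ascending order.  The clusters
    partition 0..N-1.
    """
    labels = m.labels
    n = labels.shape[0]
    # lexsort sorts by last key first; reverse columns for row-major lex order
    order = np.lexsort(labels.T[::-1])
    sorted_rows = labels[order]
    # segment boundaries where the key changes
    change = np.any(sorted_rows[1:] != sorted_rows[:-1], axis=1)
    starts = np.concatenate([[0], np.flatnonzero(change) + 1, [n]])
    clusters = []
    for a, b in zip(starts[:-1], starts[1:]):
        ids = np.sort(order[a:b])
        clusters.append(
            PreliminaryCluster(
                key=tuple(int(x) for x in sorted_rows[a]),
                fiber_ids=tuple(int(i) for i in ids),
            )
        )
    return clusters
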