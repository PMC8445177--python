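"""Clustering quality metrics: Davies-Bouldin index, coverage, histograms.

The Davies-Bouldin (DB) index averages, over clusters, the worst-case
ratio of summed dispersions to centroid separation:

    DB = (1/n) sum_i max_{j != i} (alpha_i + alpha_j) / d(c_i, c_j)

with alpha_i the mean member-to-centroid distance of cluster i and
d(c_i, c_j) the distance between centroids — here both measured with the
orientation-invariant fiber distance d_ME.  Lower is better.  A normalised
index DB_n = DB_reference / DB_method compares a method against a
reference clustering: DB_n > 1 means the method's DB is better (smaller)
than the reference's.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .clique_merge import FinalClustering
from .metrics import pairwise_min_distance

__all__ = [
    "QualityReport",
    "davies_bouldin",
    "normalized_db",
    "variance",
    "coverage_and_histograms",
    "quality_report",
]


def davies_bouldin(fc: FinalClustering) -> float:
    """DB index of a final clustering under d_ME.

    Requires at least two clusters and pairwise-distinct centroids
    (coincident centroids make the ratio undefined).
    """
    n = fc.n_clusters
    if n < 2:
        raise ValueError("Davies-Bouldin index requires at least 2 clusters")
    cents = np.stack([c.centroid for c in fc.clusters])
    alpha = np.array([c.stats.mean_dispersion for c in fc.clusters])
    d = pairwise_min_distance(cents, cents)
    iu, ju = np.where(np.triu(np.ones((n, n), dtype=bool), k=1) & (d == 0.0))
    if iu.size:
        raise ValueError(
            f"coincident centroids for clusters {int(iu[0])} and {int(ju[0])}: "
            "centroid distance is zero"
        )
    ratio = (alpha[:, None] + alpha[None, :]) / np.where(d > 0, d, np.inf)
    np.fill_diagonal(ratio, -np.inf)
    return float(ratio.max(axis=1).mean())


def normalized_db(db_reference: float, db_method: float) -> float:
    """DB_n = DB_reference / DB_method; > 1 means the method beats the
    reference."""
    if db_method == 0:
        raise ValueError("db_method must be nonzero")
    return db_reference / db_method


def variance(values) -> float:
    """Population variance (divide by n)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("variance of an empty sequence is undefined")
    mu = values.mean()
    return float(((values - mu) ** 2).sum() / values.size)


@dataclass
class QualityReport:
    """Quality summary of a final clustering."""

    n_clusters: int
    coverage_pct: float
    db: float | None = None
    size_hist: dict = field(default_factory=dict)
    intra_hist: dict = field(default_factory=dict)
    inter_hist: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _hist(values: np.ndarray, bins: int) -> dict:
    counts, edges = np.histogram(values, bins=bins)
    return {"counts": counts.tolist(), "edges": edges.tolist()}


def coverage_and_histograms(
    fc: FinalClustering,
    n_total: int,
    bins: int = 20,
    inter_mode: str = "all_pairs",
) -> QualityReport:
    """Coverage percentage plus size / intra / inter histograms.

    Coverage is 100 x (fibers in final clusters) / n_total.  The intra
    histogram bins per-cluster intra distances; the inter histogram bins
    centroid-pair d_ME over all pairs (default) or each centroid's
    nearest-neighbour distance (``inter_mode='nearest'``).
    """
    if inter_mode not in ("all_pairs", "nearest"):
        raise ValueError("inter_mode must be 'all_pairs' or 'nearest'")
    n_clustered = sum(c.size for c in fc.clusters)
    coverage = 100.0 * n_clustered / n_total if n_total else 0.0
    sizes = np.array([c.size for c in fc.clusters])
    intra = np.array([c.stats.intra_distance for c in fc.clusters])
    report = QualityReport(
        n_clusters=fc.n_clusters,
        coverage_pct=float(coverage),
        size_hist=_hist(sizes, bins) if sizes.size else {},
        intra_hist=_hist(intra, bins) if intra.size else {},
    )
    if fc.n_clusters >= 2:
        cents = np.stack([c.centroid for c in fc.clusters])
        d = pairwise_min_distance(cents, cents)
        if inter_mode == "all_pairs":
            iu, ju = np.triu_indices(fc.n_clusters, k=1)
            vals = d[iu, ju]
        else:
            np.fill_diagonal(d, np.inf)
            vals = d.min(axis=1)
        report.inter_hist = _hist(vals, bins)
    return report


def quality_report(fc: FinalClustering, n_total: int, bins: int = 20,
                   inter_mode: str = "all_pairs") -> QualityReport:
    """Full report: coverage/histograms plus the DB index when defined."""
    report = coverage_and_histograms(fc, n_total, bins=bins, inter_mode=inter_mode)
    if fc.n_clusters >= 2:
        try:
            report.db = davies_bouldin(fc)
        except ValueError:
            report.db = None
    return report
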