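"""End-to-end pipeline orchestration.

Chains the four clustering steps — per-position point clustering,
membership grouping, small-cluster reassignment, maximal-clique merging —
plus the optional intra-distance post-filter, and serialises the results.

Variant names follow the initialisation used in step 1: ``CkFFC`` (random),
``CkpFFC`` (farthest-first k-means++), ``CeFFC`` (k-means++ with centroid
retraction), and ``CefFFC`` (CeFFC plus the 70 mm intra-distance filter).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .clique_merge import (D_MMAX, FinalClustering, build_final_clusters,
                           filter_by_intra_distance)
from .evaluation import QualityReport, quality_report
from .fiber_model import Tractogram, write_tractogram
from .grouping import group_by_membership
from .point_clustering import DEFAULT_POSITIONS, fit_point_clusters
from .reassignment import D_RMAX, SMALL_THRESHOLD, reassign_small, split_small_large

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "variant_name"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass(frozen=True)
class PipelineConfig:
    """Full pipeline configuration.

    k_pc is the step-1 cluster count at the middle position (11), k_po at
    the other selected positions; d_rmax / d_mmax are the step-3 / step-4
    distance thresholds in mm; intra_filter, when not None, removes final
    clusters with intra-cluster distance above that many mm (70 in the
    filtered variant).
    """

    positions: tuple = DEFAULT_POSITIONS
    k_pc: int = 200
    k_po: int = 300
    init: str = "kpp_retract"
    r: float = 0.05
    small_threshold: int = SMALL_THRESHOLD
    d_rmax: float = D_RMAX
    d_mmax: float = D_MMAX
    intra_filter: float | None = None
    align_centroids: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if 11 not in tuple(self.positions):
            raise ValueError("positions must include the middle position 11")
        for name in ("k_pc", "k_po", "small_threshold"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("d_rmax", "d_mmax"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.intra_filter is not None and self.intra_filter <= 0:
            raise ValueError("intra_filter must be > 0 or None")


def variant_name(config: PipelineConfig) -> str:
    """Report label of the step-1 initialisation variant."""
    base = {"random": "CkFFC", "kpp": "CkpFFC", "kpp_retract": "CeFFC"}[config.init]
    if config.init == "kpp_retract" and config.intra_filter is not None:
        return "CefFFC"
    return base


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except (ValueError, RuntimeError) as exc:
                raise PipelineError(name, "stage-failure", str(exc)) from exc
            log.info("%s done in %.3f s", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def run_pipeline(t: Tractogram, config: PipelineConfig = PipelineConfig()):
    """Run steps 1-4 (+ optional intra filter) on a tractogram.

    Returns ``(FinalClustering, QualityReport)``.  Deterministic: identical
    tractogram, config and seed give identical outputs.
    """
    n = len(t)

    membership = _stage("step1-point-clustering")(fit_point_clusters)(
        t, positions=config.positions, k_middle=config.k_pc,
        k_other=config.k_po, init=config.init, r=config.r, seed=config.seed,
    )
    prelim = _stage("step2-grouping")(group_by_membership)(membership)
    log.info("step2: %d preliminary clusters from %d fibers", len(prelim), n)

    def _step3():
        S_S, S_L = split_small_large(
            prelim, t, small_threshold=config.small_threshold,
            align=config.align_centroids,
        )
        log.info("step3: %d small, %d large preliminary clusters", len(S_S), len(S_L))
        return reassign_small(S_S, S_L, t, d_rmax=config.d_rmax,
                              align=config.align_centroids)

    candidates, noise_ids = _stage("step3-reassignment")(_step3)()
    log.info("step3: %d candidate clusters, %d noise fibers",
             len(candidates), len(noise_ids))

    fc = _stage("step4-clique-merge")(build_final_clusters)(
        candidates, t, noise_ids,
        middle_column=membership.middle_column(),
        d_mmax=config.d_mmax, align=config.align_centroids,
        params={**asdict(config), "variant": variant_name(config),
                "version": __version__},
    )
    if config.intra_filter is not None:
        fc = _stage("intra-filter")(filter_by_intra_distance)(fc, config.intra_filter)
    log.info("final: %d clusters, %d noise fibers", fc.n_clusters, len(fc.noise_ids))
    report = quality_report(fc, n_total=n)
    return fc, report


def save_results(fc: FinalClustering, report: QualityReport, out_prefix: str,
                 centroid_format: str = "array") -> None:
    """Serialise a clustering: fiber-id lists (JSON), centroid tractogram,
    per-cluster stats table (CSV), quality report (JSON), run manifest."""
    with open(out_prefix + ".clusters.json", "w") as fh:
        json.dump(
            {
                "clusters": [sorted(c.fiber_ids) for c in fc.clusters],
                "noise_ids": sorted(fc.noise_ids),
            },
            fh,
        )
    ext = {"array": ".npy", "trk": ".trk", "bundles": ".bundles"}[centroid_format]
    if fc.clusters:
        cents = Tractogram(np.stack([c.centroid for c in fc.clusters]))
        write_tractogram(cents, out_prefix + ".centroids" + ext, centroid_format)
    pd.DataFrame(
        {
            "cluster_id": range(fc.n_clusters),
            "size": [c.size for c in fc.clusters],
            "intra_mm": [c.stats.intra_distance for c in fc.clusters],
            "mean_dispersion_mm": [c.stats.mean_dispersion for c in fc.clusters],
        }
    ).to_csv(out_prefix + ".stats.csv", index=False)
    report.to_json(out_prefix + ".report.json")
    with open(out_prefix + ".manifest.json", "w") as fh:
        json.dump(fc.params, fh, indent=2, default=str)
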