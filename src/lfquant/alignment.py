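"""Consensus retention time by clustering MS/MS scan times.

Alignment is performed after identification: every identified peptide is its
own landmark, so only identical peptides are ever aligned across injections
(a three-dimensional m/z - RT - MS/MS-identity alignment). All MS/MS scan
times of a peptide are collected; when their range exceeds a threshold
(default 3 min, the magnitude of typical LC retention drift) the times are
split into clusters at large gaps, and the weighted mean scan time of the
dominant cluster becomes the peptide's retention time.

Clustering is 1-D single-linkage gap splitting: deterministic, invariant to
input order, and for sorted points it yields the minimum number of clusters
such that no intra-cluster gap exceeds the gap parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import IdentificationEvent


@dataclass(frozen=True)
class ScanTimeObservation:
    run_id: str
    scan_time: float  # minutes
    weight: float


@dataclass
class ScanTimeSet:
    """All MS/MS scan-time observations of one peptide across injections."""

    peptide_key: str
    observations: list[ScanTimeObservation]

    def __post_init__(self) -> None:
        if not self.observations:
            raise ValueError(f"{self.peptide_key}: empty observation set")
        w = np.array([o.weight for o in self.observations])
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError(f"{self.peptide_key}: weights must be >= 0, not all zero")


@dataclass
class ScanTimeCluster:
    """One contiguous block of scan times; carries its members' data."""

    peptide_key: str
    indices: list[int]  # into the originating ScanTimeSet.observations
    times: np.ndarray
    weights: np.ndarray
    run_ids: list[str]

    @property
    def mean_time(self) -> float:
        return float(np.average(self.times, weights=self.weights))

    @property
    def time_range(self) -> float:
        return float(self.times.max() - self.times.min())

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


@dataclass(frozen=True)
class ConsensusRT:
    """A peptide's aligned retention time and the evidence behind it."""

    peptide_key: str
    rt: float  # minutes
    n_events: int
    n_runs: int
    n_clusters: int
    selected_cluster_fraction: float  # weight share of the selected cluster


def collect_scan_times(
    peptide_key: str,
    events: list[IdentificationEvent],
    weighting: str = "uniform",
) -> ScanTimeSet:
    """Gather one peptide's MS/MS scan times into a ScanTimeSet.

    ``weighting="uniform"`` gives every event weight 1; ``"confidence"``
    weights each event by its identification confidence.
    """
    if not events:
        raise ValueError("no events supplied")
    if weighting not in ("uniform", "confidence"):
        raise ValueError(f"unknown weighting {weighting!r}")
    bad = [e.peptide_key for e in events if e.peptide_key != peptide_key]
    if bad:
        raise ValueError(f"events for {bad[0]!r} mixed into set for {peptide_key!r}")
    obs = [
        ScanTimeObservation(
            e.run_id, e.scan_time, 1.0 if weighting == "uniform" else e.confidence
        )
        for e in events
    ]
    return ScanTimeSet(peptide_key, obs)


def cluster_scan_times(
    sts: ScanTimeSet, range_threshold: float = 3.0, gap: float = 1.0
) -> list[ScanTimeCluster]:
    """Partition a scan-time set into clusters.

    If the overall time range is within ``range_threshold`` no clustering is
    applied and a single cluster holds every observation. Otherwise the
    observations are sorted by time and split at every inter-observation gap
    larger than ``gap``. The partition is deterministic and invariant to the
    input order of observations.
    """
    times = np.array([o.scan_time for o in sts.observations])
    weights = np.array([o.weight for o in sts.observations])
    run_ids = [o.run_id for o in sts.observations]
    # canonical order: by time, ties broken by run then original index
    order = sorted(range(len(times)), key=lambda i: (times[i], run_ids[i], i))

    def make(block: list[int]) -> ScanTimeCluster:
        return ScanTimeCluster(
            sts.peptide_key,
            block,
            times[block],
            weights[block],
            [run_ids[i] for i in block],
        )

    if times.max() - times.min() <= range_threshold:
        return [make(order)]

    clusters: list[ScanTimeCluster] = []
    block = [order[0]]
    for i in order[1:]:
        if times[i] - times[block[-1]] > gap:
            clusters.append(make(block))
            block = [i]
        else:
            block.append(i)
    clusters.append(make(block))
    return clusters


def consensus_retention_time(
    clusters: list[ScanTimeCluster], selection: str = "max_weight"
) -> ConsensusRT:
    """Select the dominant cluster and return its weighted mean scan time.

    The cluster with the largest total weight wins; ties go to the earlier
    mean time. Minority clusters are reflected only in ``n_clusters`` and
    ``selected_cluster_fraction``.
    """
    if not clusters:
        raise ValueError("empty cluster list")
    if selection != "max_weight":
        raise ValueError(f"unknown selection rule {selection!r}")
    total = sum(c.total_weight for c in clusters)
    best = min(clusters, key=lambda c: (-c.total_weight, c.mean_time))
    all_runs = {r for c in clusters for r in c.run_ids}
    n_events = sum(len(c.indices) for c in clusters)
    return ConsensusRT(
        peptide_key=best.peptide_key,
        rt=best.mean_time,
        n_events=n_events,
        n_runs=len(all_runs),
        n_clusters=len(clusters),
        selected_cluster_fraction=best.total_weight / total,
    )


def align_events(
    events: list[IdentificationEvent],
    range_threshold: float = 3.0,
    gap: float = 1.0,
    weighting: str = "uniform",
) -> pd.DataFrame:
    """Run collect → cluster → consensus for every peptide in an event list.

    Returns a DataFrame with one row per peptide: peptide_key, rt_min,
    n_events, n_runs, n_clusters, selected_cluster_fraction.
    """
    by_pep: dict[str, list[IdentificationEvent]] = {}
    for e in events:
        by_pep.setdefault(e.peptide_key, []).append(e)
    rows = []
    for key in sorted(by_pep):
        sts = collect_scan_times(key, by_pep[key], weighting)
        clusters = cluster_scan_times(sts, range_threshold, gap)
        c = consensus_retention_time(clusters)
        rows.append(
            (key, c.rt, c.n_events, c.n_runs, c.n_clusters, c.selected_cluster_fraction)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "peptide_key",
            "rt_min",
            "n_events",
            "n_runs",
            "n_clusters",
            "selected_cluster_fraction",
        ],
    )
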