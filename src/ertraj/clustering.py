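"""Hierarchical clustering of trajectory frames on an RMSD matrix.

Frames are grouped by agglomerative clustering (scipy linkage on the
condensed RMSD matrix), cut either at a requested number of clusters or
at a distance threshold.  Major clusters are those with strictly more
than ``min_size`` members; each retained cluster is summarized by its
size, frame span, and a representative frame — the medoid, i.e. the real
frame minimizing the mean RMSD to the other members.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .rmsd import RMSDMatrix

__all__ = [
    "Cluster",
    "ClusterSet",
    "hierarchical_cluster",
    "filter_major_clusters",
    "representative_frame",
    "cluster_report",
]

logger = logging.getLogger(__name__)

LINKAGE_METHODS = ("single", "complete", "average")

#: Table-4-style report columns
REPORT_COLUMNS = (
    "Cluster Number",
    "Number of Structures",
    "Start Frame",
    "End Frame",
    "Representative Structure",
)


@dataclass
class Cluster:
    """One cluster of frames (all indices 1-based trajectory frames)."""

    id: int
    member_frames: np.ndarray
    representative_frame: int
    retained: bool = True

    @property
    def size(self) -> int:
        return len(self.member_frames)

    @property
    def start_frame(self) -> int:
        return int(self.member_frames.min())

    @property
    def end_frame(self) -> int:
        return int(self.member_frames.max())


@dataclass
class ClusterSet:
    """A partition of the matrix frames into clusters.

    ``assignments`` holds the cluster id per matrix position; clusters
    are numbered 1..k ordered by start frame, mirroring how major-cluster
    tables are usually printed.
    """

    assignments: np.ndarray
    clusters: list[Cluster]
    linkage: str
    cut_parameter: float
    min_size: int = 0
    frame_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def retained(self) -> list[Cluster]:
        return [c for c in self.clusters if c.retained]

    def labels_for_frames(self) -> np.ndarray:
        return self.assignments


def representative_frame(
    cluster_members: Sequence[int], matrix: RMSDMatrix
) -> int:
    """The medoid frame: the member minimizing the mean RMSD to all other
    members, ties broken by the lowest frame index."""
    members = np.asarray(list(cluster_members), dtype=int)
    if len(members) == 0:
        raise ValueError("cluster is empty")
    pos = np.array([matrix.position_of(m) for m in members])
    sub = matrix.values[np.ix_(pos, pos)]
    row_sums = sub.sum(axis=1)
    best = np.lexsort((members, row_sums))[0]
    return int(members[best])


def hierarchical_cluster(
    matrix: RMSDMatrix,
    linkage: str = "average",
    n_clusters: int | None = None,
    cut_distance: float | None = None,
) -> ClusterSet:
    """Agglomerative clustering of the matrix frames.

    Exactly one of ``n_clusters`` / ``cut_distance`` may be given; with
    neither, the tree is cut at 40% of the largest RMSD in the matrix.
    Every frame is assigned (min-size filtering happens later).
    """
    if linkage not in LINKAGE_METHODS:
        raise ValueError(f"linkage must be one of {LINKAGE_METHODS}")
    if n_clusters is not None and cut_distance is not None:
        raise ValueError("give n_clusters or cut_distance, not both")
    n = matrix.n
    if n_clusters is not None and not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in 1..{n}")
    if cut_distance is not None and cut_distance <= 0:
        raise ValueError("cut_distance must be positive")

    z = scipy_linkage(squareform(matrix.values, checks=False), method=linkage)
    if n_clusters is not None:
        flat = fcluster(z, t=n_clusters, criterion="maxclust")
        cut_parameter = float(n_clusters)
    else:
        if cut_distance is None:
            cut_distance = 0.4 * float(matrix.values.max())
            if cut_distance <= 0:  # all frames identical
                cut_distance = 1e-12
        flat = fcluster(z, t=cut_distance, criterion="distance")
        cut_parameter = float(cut_distance)

    # renumber clusters 1..k by start frame
    clusters: list[Cluster] = []
    order = []
    for cid in np.unique(flat):
        members = matrix.frame_indices[flat == cid]
        order.append((members.min(), cid, members))
    assignments = np.zeros(n, dtype=int)
    for new_id, (_, cid, members) in enumerate(sorted(
            order, key=lambda t: t[0]), start=1):
        assignments[flat == cid] = new_id
        clusters.append(Cluster(
            id=new_id,
            member_frames=np.sort(members),
            representative_frame=representative_frame(members, matrix),
        ))
    return ClusterSet(
        assignments=assignments,
        clusters=clusters,
        linkage=linkage,
        cut_parameter=cut_parameter,
        min_size=0,
        frame_indices=matrix.frame_indices.copy(),
    )


def filter_major_clusters(clusters: ClusterSet, min_size: int) -> ClusterSet:
    """Mark clusters with size strictly greater than ``min_size`` as
    retained ("more than N structures"); the rest stay in the assignments
    but are flagged unretained."""
    if min_size < 0:
        raise ValueError("min_size must be >= 0")
    new = [
        Cluster(c.id, c.member_frames.copy(), c.representative_frame,
                retained=c.size > min_size)
        for c in clusters.clusters
    ]
    if not any(c.retained for c in new):
        warnings.warn(
            f"no cluster exceeds min_size={min_size}; report will be empty",
            stacklevel=2,
        )
    return ClusterSet(
        assignments=clusters.assignments.copy(),
        clusters=new,
        linkage=clusters.linkage,
        cut_parameter=clusters.cut_parameter,
        min_size=min_size,
        frame_indices=clusters.frame_indices.copy(),
    )


def cluster_report(clusters: ClusterSet, path: str | Path) -> None:
    """CSV of retained clusters: number, size, start/end frame,
    representative frame."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(REPORT_COLUMNS)
        for rank, c in enumerate(
                sorted(clusters.retained, key=lambda c: c.start_frame),
                start=1):
            writer.writerow([rank, c.size, c.start_frame, c.end_frame,
                             c.representative_frame])
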