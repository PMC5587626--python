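"""Variance-informed DBSCAN spin-system grouping.

Peaks of a single list are clustered into spin systems with a DBSCAN in
which the Euclidean region query is replaced by a variance-normalized
distance and a chi-square-derived cutoff: peaks ``i`` and ``j`` are
neighbors when

    sqrt( sum_k ((peak_i[k] - peak_j[k]) / std[k])^2 ) <= sqrt(F^{-1}(p, df))

where the sum runs over the ``df`` comparable dimensions, ``std[k]`` comes
from self-registration analysis, and ``F^{-1}(p, df)`` is the upper-tail
(inverse survival) chi-square quantile at the configured p-value (default
1e-4).  This turns the DBSCAN radius into a statistical statement: a peak
joins a cluster only if its normalized squared distance is plausible under
the per-dimension variances.

Core points have at least ``min_points`` neighbors (the query peak itself
included, as in canonical DBSCAN); clusters grow by reachability from core
points; border points reachable from several clusters join the first one
discovered in file order (deterministic given input order — and the source
of the overlap-vs-split asymmetry in the evaluation metrics).  With the
default ``min_points = 2`` a glycine's single CA peak in an HN(CO)CACB
list legitimately remains unclustered.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import chi2 as _chi2

from .peaklist import Peak, PeakList

__all__ = [
    "GroupingConfig",
    "SpinSystemCluster",
    "GroupingResult",
    "membership_cutoff",
    "normalized_distance",
    "group",
]


@dataclass
class GroupingConfig:
    """Parameters of the grouping step.

    ``stds`` are the per-comparable-dimension standard deviations (ppm)
    supplied by self-registration analysis; ``p_value`` sets the chi-square
    cutoff; ``min_points`` is DBSCAN's core-point threshold (query peak
    included).
    """

    stds: tuple[float, ...]
    p_value: float = 1e-4
    min_points: int = 2

    def __post_init__(self) -> None:
        self.stds = tuple(float(s) for s in self.stds)
        if any(s <= 0 for s in self.stds):
            raise ValueError("stds must be positive")
        if not (0.0 < self.p_value < 1.0):
            raise ValueError("p_value must be in (0, 1)")
        if self.min_points < 2:
            raise ValueError("min_points must be >= 2")


@dataclass
class SpinSystemCluster:
    cluster_id: int
    member_indices: frozenset[int]
    tier: int = 1
    stds_used: tuple[float, ...] = ()

    def __len__(self) -> int:
        return len(self.member_indices)


@dataclass
class GroupingResult:
    clusters: list[SpinSystemCluster]
    unclustered: frozenset[int]

    def n_clustered(self) -> int:
        return sum(len(c) for c in self.clusters)

    def assignments(self) -> dict[int, int]:
        """peak index -> cluster_id for clustered peaks."""
        out = {}
        for c in self.clusters:
            for i in c.member_indices:
                out[i] = c.cluster_id
        return out


def membership_cutoff(p_value: float, df: int) -> float:
    """Cluster-membership cutoff: sqrt of the upper-tail chi-square quantile
    at ``p_value`` with ``df`` degrees of freedom."""
    if not (0.0 < p_value < 1.0):
        raise ValueError("p_value must be in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(np.sqrt(_chi2.isf(p_value, df)))


def normalized_distance(
    a: Peak, b: Peak, stds, comparable_dims
) -> float:
    """Root of the summed squared per-dimension z-differences between two
    peaks over the comparable dimensions."""
    stds = np.asarray(stds, dtype=float)
    if np.any(stds <= 0):
        raise ValueError("stds must be positive")
    dims = list(comparable_dims)
    da = np.array([a.shifts[d] for d in dims])
    db = np.array([b.shifts[d] for d in dims])
    return float(np.sqrt((((da - db) / stds) ** 2).sum()))


def group(pl: PeakList, cfg: GroupingConfig) -> GroupingResult:
    """Group the peaks of one list into spin-system clusters.

    DBSCAN over the variance-normalized comparable-dimension space with
    radius :func:`membership_cutoff`.  Returns disjoint clusters plus the
    unclustered peak indices; every peak lands in exactly one of the two.
    """
    df = pl.df
    if len(cfg.stds) != df:
        raise ValueError(f"expected {df} stds, got {len(cfg.stds)}")
    n = len(pl)
    if n < cfg.min_points:
        return GroupingResult(clusters=[], unclustered=frozenset(range(n)))
    cutoff = membership_cutoff(cfg.p_value, df)
    coords = np.array([pl.comparable_shifts(i) for i in range(n)]) / np.asarray(cfg.stds)
    tree = cKDTree(coords)
    neighborhoods = tree.query_ball_point(coords, r=cutoff)  # includes self

    labels = np.full(n, -1, dtype=int)  # -1 = unvisited/noise
    visited = np.zeros(n, dtype=bool)
    clusters: list[SpinSystemCluster] = []
    cid = 0
    for i in range(n):
        if visited[i]:
            continue
        visited[i] = True
        if len(neighborhoods[i]) < cfg.min_points:
            continue  # not core; may later join a cluster as a border point
        members = {i}
        labels[i] = cid
        queue = deque(sorted(neighborhoods[i]))
        while queue:
            q = queue.popleft()
            if labels[q] == -1:
                labels[q] = cid
                members.add(q)
            if visited[q]:
                continue
            visited[q] = True
            if len(neighborhoods[q]) >= cfg.min_points:  # q is core: expand
                queue.extend(sorted(neighborhoods[q]))
        clusters.append(
            SpinSystemCluster(
                cluster_id=cid,
                member_indices=frozenset(members),
                tier=1,
                stds_used=cfg.stds,
            )
        )
        cid += 1
    unclustered = frozenset(int(i) for i in np.nonzero(labels == -1)[0])
    return GroupingResult(clusters=clusters, unclustered=unclustered)
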