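"""Threshold clustering, homogeneity statistics and threshold optimization.

Clustering follows the OPTSIL scheme: agglomeration controlled by a distance
threshold T and a linkage fraction F in [0, 1].  Starting from singletons,
the pair of clusters with the smallest average inter-cluster distance among
all pairs passing the linkage test is merged repeatedly until no pair
qualifies.  The linkage test asks whether the fraction of inter-cluster
strain pairs at distance <= T reaches F; F = 0 means "at least one such
pair" (single linkage: the result equals connected components of the graph
{d <= T}), F = 1 requires every pair (complete linkage), intermediate F
interpolates.  Ties in the merge order are broken toward the pair whose
combined sorted member labels are lexicographically smallest, so results
are deterministic.

Partition agreement is measured by the adjusted Rand index.  "Clustering
consistency" scores how robust a threshold is to the linkage parameter:
for each within-species distance matrix the partitions at (T, F=0) and
(T, F=1) are compared; on perfectly ultrametric data they coincide at every
threshold and the score is 1.  The subspecies threshold is chosen as the
midpoint of the widest plateau of maximal mean consistency over a threshold
grid — non-ultrametric structure between the within- and between-subgroup
distance bands lowers consistency, and the surviving plateau sits in the
gap between the bands.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .ddh import DDHModel, distance_to_ddh
from .distance import DistanceMatrix

__all__ = [
    "Partition",
    "ClusterStats",
    "threshold_cluster",
    "cluster_stats",
    "partition_agreement",
    "optimize_against_reference",
    "clustering_consistency",
    "optimize_subspecies_threshold",
    "ConsistencyProfile",
]


@dataclass(frozen=True)
class Partition:
    """strain_id -> cluster index, with the (T, F) that produced it."""

    assignment: Mapping[str, int]
    T: float | None = None
    F: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignment", dict(self.assignment))
        idx = sorted(set(self.assignment.values()))
        if idx and idx != list(range(len(idx))):
            # renumber to contiguous indices ordered by smallest member label
            order: dict[int, str] = {}
            for sid, c in self.assignment.items():
                if c not in order or sid < order[c]:
                    order[c] = sid
            remap = {
                c: i for i, c in enumerate(sorted(order, key=order.__getitem__))
            }
            object.__setattr__(
                self,
                "assignment",
                {sid: remap[c] for sid, c in self.assignment.items()},
            )

    @classmethod
    def from_clusters(
        cls,
        clusters: Iterable[Iterable[str]],
        T: float | None = None,
        F: float | None = None,
    ) -> "Partition":
        assignment: dict[str, int] = {}
        for i, members in enumerate(clusters):
            for sid in members:
                if sid in assignment:
                    raise ValueError(f"strain {sid!r} assigned to two clusters")
                assignment[sid] = i
        return cls(assignment, T=T, F=F)

    @property
    def labels(self) -> list[str]:
        return sorted(self.assignment)

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def clusters(self) -> list[list[str]]:
        out: dict[int, list[str]] = {}
        for sid in sorted(self.assignment):
            out.setdefault(self.assignment[sid], []).append(sid)
        return [out[c] for c in sorted(out)]

    def same_up_to_relabeling(self, other: "Partition") -> bool:
        if set(self.assignment) != set(other.assignment):
            return False
        mine = {frozenset(c) for c in self.clusters()}
        theirs = {frozenset(c) for c in other.clusters()}
        return mine == theirs


def threshold_cluster(matrix: DistanceMatrix, T: float, F: float) -> Partition:
    """OPTSIL-style agglomeration at threshold T and linkage fraction F."""
    if T < 0:
        raise ValueError("T must be >= 0")
    if not 0.0 <= F <= 1.0:
        raise ValueError("F must lie in [0, 1]")
    labels = list(matrix.labels)
    v = matrix.values
    idx = {l: i for i, l in enumerate(labels)}
    clusters: list[list[str]] = [[l] for l in sorted(labels)]

    def link_ok(ca: list[str], cb: list[str]) -> tuple[bool, float]:
        ds = [v[idx[a], idx[b]] for a in ca for b in cb]
        n_le = sum(1 for d in ds if d <= T)
        avg = float(np.mean(ds))
        if F == 0.0:
            return n_le >= 1, avg
        return n_le / len(ds) >= F, avg

    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            ok, avg = link_ok(clusters[i], clusters[j])
            if not ok:
                continue
            key = (avg, tuple(sorted(clusters[i] + clusters[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        if best is None:
            break
        _, i, j = best
        merged = sorted(clusters[i] + clusters[j])
        clusters = [c for t, c in enumerate(clusters) if t not in (i, j)]
        clusters.append(merged)
        clusters.sort()
    return Partition.from_clusters(clusters, T=T, F=F)


@dataclass(frozen=True)
class ClusterStats:
    """Within-cluster distance statistics; singletons excluded from summaries."""

    sizes: tuple[int, ...]
    avg_within: tuple[float, ...]  # per cluster of size >= 2, cluster order
    max_within: tuple[float, ...]
    summary: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def has_multi_member_clusters(self) -> bool:
        return len(self.avg_within) > 0


def _lower_median(xs: Sequence[float]) -> float:
    """Median taking the lower of the two middles for even counts."""
    s = sorted(xs)
    return s[(len(s) - 1) // 2]


def cluster_stats(matrix: DistanceMatrix, partition: Partition) -> ClusterStats:
    if not set(partition.assignment) <= set(matrix.labels):
        raise ValueError("partition contains labels absent from the matrix")
    idx = {l: i for i, l in enumerate(matrix.labels)}
    v = matrix.values
    sizes, avgs, maxs = [], [], []
    for members in partition.clusters():
        sizes.append(len(members))
        if len(members) < 2:
            continue
        ds = [
            v[idx[a], idx[b]] for a, b in itertools.combinations(members, 2)
        ]
        avgs.append(float(np.mean(ds)))
        maxs.append(float(max(ds)))
    summary = {}
    for name, xs in (("avg_within", avgs), ("max_within", maxs)):
        if xs:
            summary[name] = {
                "min": min(xs),
                "median": _lower_median(xs),
                "max": max(xs),
            }
    return ClusterStats(tuple(sizes), tuple(avgs), tuple(maxs), summary)


def partition_agreement(p: Partition, q: Partition) -> float:
    """Adjusted Rand index between two partitions of the same strains."""
    if set(p.assignment) != set(q.assignment):
        raise ValueError("partitions cover different strain sets")
    labels = sorted(p.assignment)
    return float(
        adjusted_rand_score(
            [p.assignment[l] for l in labels], [q.assignment[l] for l in labels]
        )
    )


def default_threshold_grid(matrix: DistanceMatrix) -> list[float]:
    """Midpoints between consecutive unique off-diagonal distances,
    bracketed by a value below the minimum (all-singleton regime) and the
    maximum distance itself (at which every pair satisfies d <= T)."""
    uniq = np.unique(matrix.off_diagonal())
    grid = [float(uniq[0]) / 2.0]
    grid += [float((a + b) / 2.0) for a, b in zip(uniq, uniq[1:])]
    grid.append(float(uniq[-1]))
    return grid


def optimize_against_reference(
    matrix: DistanceMatrix,
    reference: Partition,
    T_grid: Sequence[float] | None = None,
    F_grid: Sequence[float] = (0.0, 0.5, 1.0),
) -> tuple[float, float, float, Partition, int]:
    """Exhaustive (T, F) grid search maximizing agreement with a reference.

    Ties resolve toward smaller T, then smaller F.  Returns
    (T, F, agreement, partition, n_clusters).
    """
    if len(set(reference.assignment)) < 2:
        raise ValueError("reference partition must cover at least 2 strains")
    if T_grid is None:
        T_grid = default_threshold_grid(matrix)
    if not list(T_grid) or not list(F_grid):
        raise ValueError("grids must be non-empty")
    best = None
    for T in sorted(T_grid):
        for F in sorted(F_grid):
            p = threshold_cluster(matrix, T, F)
            a = partition_agreement(p, reference)
            if best is None or a > best[2] + 1e-12:
                best = (T, F, a, p, p.n_clusters)
    return best


def clustering_consistency(
    matrices: Sequence[DistanceMatrix], T: float
) -> float:
    """Mean F=0 vs F=1 partition agreement at threshold T.

    Identical partitions score 1 even when the adjusted Rand index is
    undefined (all singletons or a single cluster).
    """
    if not matrices:
        raise ValueError("need at least one within-species matrix")
    scores = []
    for m in matrices:
        p0 = threshold_cluster(m, T, 0.0)
        p1 = threshold_cluster(m, T, 1.0)
        if p0.same_up_to_relabeling(p1):
            scores.append(1.0)
        else:
            scores.append(partition_agreement(p0, p1))
    return float(np.mean(scores))


@dataclass(frozen=True)
class ConsistencyProfile:
    """Result of the subspecies-threshold scan."""

    T_star: float | None
    ddh_star: float | None
    grid: tuple[float, ...]
    consistency: tuple[float, ...]
    ddh: tuple[float, ...]
    degenerate: bool  # plateau touches a grid end (no substructure signal)
    no_consistent_threshold: bool = False


def optimize_subspecies_threshold(
    matrices: Sequence[DistanceMatrix],
    model: DDHModel,
    T_grid: Sequence[float],
) -> ConsistencyProfile:
    """Pick the subspecies distance threshold by clustering consistency.

    Scans ``T_grid``, finds the maximal consistency value, and returns the
    midpoint of the widest maximal-consistency plateau (run of consecutive
    grid points at the maximum; width measured in T).  Plateaus touching a
    grid end are the trivial all-singleton / single-cluster regimes, not a
    signal about substructure, so interior plateaus take precedence; when
    only boundary plateaus exist the widest is reported with the
    ``degenerate`` flag set.  The full profile is returned for inspection.
    A flat-zero profile yields a "no consistent threshold" result rather
    than an exception.
    """
    grid = sorted(float(t) for t in T_grid)
    if not grid:
        raise ValueError("empty threshold grid")
    if any(t < 0 or t > 1 for t in grid):
        raise ValueError("thresholds must lie in [0, 1]")
    cons = [clustering_consistency(matrices, t) for t in grid]
    ddh = [distance_to_ddh(t, model) for t in grid]
    cmax = max(cons)
    if cmax <= 0.0:
        return ConsistencyProfile(
            None, None, tuple(grid), tuple(cons), tuple(ddh),
            degenerate=True, no_consistent_threshold=True,
        )
    # maximal runs of consecutive grid points achieving the maximum
    runs: list[tuple[int, int]] = []
    i = 0
    while i < len(grid):
        if cons[i] >= cmax - 1e-12:
            j = i
            while j + 1 < len(grid) and cons[j + 1] >= cmax - 1e-12:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    interior = [r for r in runs if r[0] > 0 and r[1] < len(grid) - 1]
    pool = interior or runs
    widest = max(pool, key=lambda r: (grid[r[1]] - grid[r[0]], -r[0]))
    lo, hi = grid[widest[0]], grid[widest[1]]
    t_star = (lo + hi) / 2.0
    degenerate = widest[0] == 0 or widest[1] == len(grid) - 1
    return ConsistencyProfile(
        t_star,
        distance_to_ddh(t_star, model),
        tuple(grid),
        tuple(cons),
        tuple(ddh),
        degenerate=degenerate,
    )
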