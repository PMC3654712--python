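"""Multi-level density-based single-linkage clustering with merge tracking.

The clustering sweeps an increasing schedule of distance thresholds
d1 < ... < dK.  At each level the single-linkage components of the encoded
points are formed (two points are connected iff their integer squared
distance is <= d^2) and a component is a *valid cluster* once the number of
sequences it holds — summing point multiplicities — reaches the density
parameter N.  Across levels three things can happen: new clusters are born,
existing clusters grow, and existing clusters merge.  Births and merges are
recorded into a forest (the merge tree); the leaves of that forest are the
final clusters, and the level at which each sequence first sat inside a
valid cluster (its *entry level*) separates core members from outliers.

Because every pairwise distance is evaluated exactly (integer arithmetic,
no approximate index), the result is a pure function of the multiset of
sequences: independent runs, any input order, give identical trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .encoding import EncodedPoint, point_matrix

DEFAULT_D_START = 3.317
DEFAULT_D_END = 7.141
DEFAULT_LEVELS = 23

_EDGE_BLOCK = 512


@dataclass(frozen=True)
class LevelSchedule:
    """Strictly increasing distance thresholds.

    ``squared`` is the authoritative representation: thresholds are applied
    by comparing exact integer squared distances against these values, so no
    floating-point square root ever participates in a comparison.
    """

    squared: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.squared:
            raise ValueError("schedule must contain at least one level")
        prev = 0.0
        for s in self.squared:
            if not math.isfinite(s) or s <= prev:
                raise ValueError(
                    "schedule levels must be finite, positive and strictly increasing"
                )
            prev = s

    @property
    def levels(self) -> tuple[float, ...]:
        """Distance values d_k (square roots of the squared thresholds)."""
        return tuple(math.sqrt(s) for s in self.squared)

    def __len__(self) -> int:
        return len(self.squared)

    @classmethod
    def linear_in_squared(
        cls,
        start: float = DEFAULT_D_START,
        end: float = DEFAULT_D_END,
        steps: int = DEFAULT_LEVELS,
    ) -> "LevelSchedule":
        """Default schedule: ``steps`` thresholds linear in squared distance.

        Squared distance is the algorithm's native integer scale, which is
        why the interpolation is linear there rather than in d.
        """
        if steps < 1:
            raise ValueError("steps must be >= 1")
        if steps == 1:
            return cls(squared=(float(start) ** 2,))
        grid = np.linspace(float(start) ** 2, float(end) ** 2, steps)
        return cls(squared=tuple(float(x) for x in grid))

    @classmethod
    def from_levels(cls, levels: Sequence[float]) -> "LevelSchedule":
        """Explicit list of distance values d_k."""
        return cls(squared=tuple(float(d) ** 2 for d in levels))

    def first_level_at_or_above(self, sqdist: float) -> int | None:
        """Smallest level index whose threshold admits ``sqdist``, else None."""
        for k, s in enumerate(self.squared):
            if sqdist <= s:
                return k
        return None


def default_schedule() -> LevelSchedule:
    return LevelSchedule.linear_in_squared()


@dataclass(frozen=True)
class DensityParams:
    """Density constraint: minimum sequence count N for a valid cluster."""

    min_cluster_size: int = 100

    def __post_init__(self) -> None:
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


class _UnionFind:
    __slots__ = ("parent", "rank")

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, x: int) -> int:
        p = self.parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:
            p[x], x = root, p[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1


@dataclass
class ClusterNode:
    """One lineage in the merge tree.

    A node is born either as a fresh valid component (a leaf) or as the
    parent created by a merge.  ``members`` tracks the current point set of
    a live lineage; when the lineage merges into a parent the set it held at
    the previous level is frozen as ``pre_merge_members``.
    """

    id: int
    birth_level: int
    members: frozenset[int]
    children: tuple[int, ...] = ()
    parent: int | None = None
    merge_level: int | None = None
    pre_merge_members: frozenset[int] | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class MergeTree:
    """The full record of a hierarchy run.

    ``entry_level`` maps point index -> level index at which the point first
    belonged to a valid cluster; points absent from it are noise.
    """

    points: list[EncodedPoint]
    schedule: LevelSchedule
    params: DensityParams
    nodes: dict[int, ClusterNode] = field(default_factory=dict)
    births: list[tuple[int, int]] = field(default_factory=list)
    events: list[tuple[int, tuple[int, ...], int]] = field(default_factory=list)
    entry_level: dict[int, int] = field(default_factory=dict)

    @property
    def leaves(self) -> list[int]:
        return sorted(nid for nid, n in self.nodes.items() if n.is_leaf)

    @property
    def roots(self) -> list[int]:
        return sorted(nid for nid, n in self.nodes.items() if n.parent is None)

    @property
    def n_clusters(self) -> int:
        """Final cluster count = number of leaves of the merge forest."""
        return len(self.leaves)

    def point_size(self, members: frozenset[int]) -> int:
        return sum(self.points[i].multiplicity for i in members)

    # -- exports ----------------------------------------------------------

    def to_newick(self) -> str:
        """Newick string: leaf labels C<id>, internal labels = merge level d."""
        levels = self.schedule.levels

        def render(nid: int) -> str:
            node = self.nodes[nid]
            if node.is_leaf:
                return f"C{node.id}"
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}){levels[node.birth_level]:.6g}"

        roots = self.roots
        if not roots:
            return ";"
        if len(roots) == 1:
            return render(roots[0]) + ";"
        return "(" + ",".join(render(r) for r in roots) + ")root;"

    def write_merge_log(self, path: str | Path) -> None:
        """TSV log of births and merges in level order."""
        levels = self.schedule.levels
        rows: list[tuple[int, str, str]] = []
        for lvl, nid in self.births:
            size = self.point_size(self.nodes[nid].members)
            rows.append((lvl, "birth", f"{nid}\t{size}\t"))
        for lvl, children, parent in self.events:
            size = self.point_size(self.nodes[parent].members)
            rows.append((lvl, "merge", f"{parent}\t{size}\t{','.join(map(str, children))}"))
        rows.sort(key=lambda r: (r[0], r[1], r[2]))
        with open(path, "w") as fh:
            fh.write("level_value\tevent\tcluster_id\tsize\tchildren\n")
            for lvl, ev, rest in rows:
                fh.write(f"{levels[lvl]:.6g}\t{ev}\t{rest}\n")


def _components(
    n: int, uf: _UnionFind
) -> dict[int, list[int]]:
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(uf.find(i), []).append(i)
    return comps


def _sorted_edges(X: np.ndarray, sq_max: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All point pairs with squared distance <= sq_max, sorted by (d2, i, j).

    Row-blocked so the distance matrix never materializes whole.
    """
    n = X.shape[0]
    norms = (X * X).sum(axis=1)
    d2_parts, i_parts, j_parts = [], [], []
    for i0 in range(0, n, _EDGE_BLOCK):
        i1 = min(i0 + _EDGE_BLOCK, n)
        block = norms[i0:i1, None] + norms[None, :] - 2 * (X[i0:i1] @ X.T)
        np.maximum(block, 0, out=block)
        ii, jj = np.nonzero(block <= sq_max)
        keep = (ii + i0) < jj  # upper triangle only
        d2_parts.append(block[ii[keep], jj[keep]])
        i_parts.append(ii[keep] + i0)
        j_parts.append(jj[keep])
    if not d2_parts:
        empty = np.zeros(0, dtype=np.int64)
        return empty, empty, empty
    d2 = np.concatenate(d2_parts)
    ei = np.concatenate(i_parts)
    ej = np.concatenate(j_parts)
    order = np.lexsort((ej, ei, d2))
    return d2[order], ei[order], ej[order]


def cluster_at_level(
    points: Sequence[EncodedPoint], d: float, min_cluster_size: int = 1
) -> list[frozenset[int]]:
    """Valid single-linkage components at one distance threshold.

    Returns the components (as frozensets of point indices) whose total
    sequence multiplicity reaches ``min_cluster_size``, sorted by smallest
    member index.  ``d`` may be ``math.inf``.
    """
    if min_cluster_size < 1:
        raise ValueError("min_cluster_size must be >= 1")
    if d < 0:
        raise ValueError("distance threshold must be >= 0")
    n = len(points)
    if n == 0:
        return []
    uf = _UnionFind(n)
    if math.isinf(d):
        for i in range(1, n):
            uf.union(0, i)
    else:
        X = point_matrix(points)
        _, ei, ej = _sorted_edges(X, d * d)
        for a, b in zip(ei, ej):
            uf.union(int(a), int(b))
    out = []
    for comp in _components(n, uf).values():
        if sum(points[i].multiplicity for i in comp) >= min_cluster_size:
            out.append(frozenset(comp))
    out.sort(key=min)
    return out


def run_hierarchy(
    points: Sequence[EncodedPoint],
    schedule: LevelSchedule | None = None,
    params: DensityParams | None = None,
) -> MergeTree:
    """Sweep the level schedule and build the merge tree.

    At each level the single-linkage components of the *full* point set are
    recomputed (edges are added incrementally to a union-find, which is
    exact because the thresholds increase).  For each component:

    * no live lineage inside, size >= N  -> birth of a new leaf;
    * exactly one live lineage inside    -> that lineage grows;
    * several live lineages inside       -> merge: each child's point set at
      the previous level is frozen and a new parent node takes over.

    Cluster ids are assigned in a canonical order — by level, then by the
    smallest sequence id in the component — so the tree is identical for any
    permutation of the input.
    """
    schedule = schedule or default_schedule()
    params = params or DensityParams()
    points = list(points)
    tree = MergeTree(points=points, schedule=schedule, params=params)
    n = len(points)
    if n == 0:
        return tree

    X = point_matrix(points)
    d2, ei, ej = _sorted_edges(X, schedule.squared[-1])
    uf = _UnionFind(n)
    live: dict[int, int] = {}  # live node id -> a representative point index
    next_id = 1
    edge_pos = 0

    for k, sq in enumerate(schedule.squared):
        while edge_pos < len(d2) and d2[edge_pos] <= sq:
            uf.union(int(ei[edge_pos]), int(ej[edge_pos]))
            edge_pos += 1

        comps = _components(n, uf)
        live_by_comp: dict[int, list[int]] = {}
        for nid, rep in live.items():
            live_by_comp.setdefault(uf.find(rep), []).append(nid)

        # canonical processing order: by smallest sequence id in the component
        ordered = sorted(
            comps.items(), key=lambda kv: min(points[i].members[0] for i in kv[1])
        )
        for root, comp in ordered:
            inside = sorted(live_by_comp.get(root, []))
            comp_set = frozenset(comp)
            if not inside:
                size = sum(points[i].multiplicity for i in comp)
                if size >= params.min_cluster_size:
                    node = ClusterNode(id=next_id, birth_level=k, members=comp_set)
                    tree.nodes[next_id] = node
                    tree.births.append((k, next_id))
                    live[next_id] = min(comp)
                    next_id += 1
                    for i in comp:
                        tree.entry_level.setdefault(i, k)
            elif len(inside) == 1:
                nid = inside[0]
                tree.nodes[nid].members = comp_set
                live[nid] = min(comp)
                for i in comp:
                    tree.entry_level.setdefault(i, k)
            else:
                for cid in inside:
                    child = tree.nodes[cid]
                    child.pre_merge_members = child.members
                    child.merge_level = k
                    del live[cid]
                parent = ClusterNode(
                    id=next_id,
                    birth_level=k,
                    members=comp_set,
                    children=tuple(inside),
                )
                tree.nodes[next_id] = parent
                for cid in inside:
                    tree.nodes[cid].parent = next_id
                tree.events.append((k, tuple(inside), next_id))
                live[next_id] = min(comp)
                next_id += 1
                for i in comp:
                    tree.entry_level.setdefault(i, k)
    return tree
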