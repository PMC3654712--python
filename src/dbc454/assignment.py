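"""Seed clusters, re-assignment and the final partition.

The leaves of the merge tree are the final clusters, but a leaf's lineage
keeps growing after its first merge under a different (internal) node, so
the members a leaf can claim directly are those it held *just before* its
first merge — its seed cluster.  Every sequence that entered the hierarchy
above the first merge of its branch is pulled back to the leaf whose seed
contains its nearest sequence (minimum exact squared distance over all seed
members).  Sequences never inside any valid cluster remain noise, and small
clusters can be pooled into the noise afterwards.

Sequences sharing one encoded point are assigned atomically: identical
vectors cannot be split between clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .encoding import (
    EncodedPoint,
    SequenceRecord,
    encode_sequence,
    pairwise_squared_distances,
    point_matrix,
)
from .hierarchy import MergeTree

#: Distinguished label for unclassified sequences.
NOISE = "NOISE"


@dataclass(frozen=True)
class SeedCluster:
    """A leaf's last state before its first merge (or final state if none)."""

    cluster_id: int
    members: frozenset[int]
    level_index: int


@dataclass
class Partition:
    """Final mapping of every sequence id to a cluster label or NOISE.

    ``entry_level`` holds the distance value d at which each classified
    sequence first joined a valid cluster; noise sequences have no entry.
    """

    assignment: dict[str, int | str]
    entry_level: dict[str, float] = field(default_factory=dict)

    def labels(self) -> list[int | str]:
        return sorted(
            {v for v in self.assignment.values() if v != NOISE}, key=str
        )

    def cluster_sizes(self) -> dict[int | str, int]:
        sizes: dict[int | str, int] = {}
        for label in self.assignment.values():
            if label != NOISE:
                sizes[label] = sizes.get(label, 0) + 1
        return sizes

    def n_noise(self) -> int:
        return sum(1 for v in self.assignment.values() if v == NOISE)

    def __len__(self) -> int:
        return len(self.assignment)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for sid in sorted(self.assignment):
            label = self.assignment[sid]
            lvl = self.entry_level.get(sid)
            rows.append(
                {
                    "sequence_id": sid,
                    "cluster_label": label,
                    "entry_level_value": "" if lvl is None else f"{lvl:.6g}",
                }
            )
        pd.DataFrame(rows, columns=["sequence_id", "cluster_label", "entry_level_value"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Partition":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        assignment: dict[str, int | str] = {}
        entry: dict[str, float] = {}
        for row in df.itertuples(index=False):
            label: int | str = row.cluster_label
            if label != NOISE:
                try:
                    label = int(label)
                except ValueError:
                    pass
            assignment[row.sequence_id] = label
            if row.entry_level_value != "":
                entry[row.sequence_id] = float(row.entry_level_value)
        return cls(assignment=assignment, entry_level=entry)


def identify_seeds(tree: MergeTree) -> list[SeedCluster]:
    """One seed per leaf of the merge tree.

    A leaf that merged keeps the member set frozen at the level before its
    first merge; a leaf that never merged keeps its final state.
    """
    seeds = []
    for nid in tree.leaves:
        node = tree.nodes[nid]
        if node.merge_level is not None:
            members = node.pre_merge_members
            level = node.merge_level - 1
        else:
            members = node.members
            level = len(tree.schedule) - 1
        assert members is not None
        seeds.append(SeedCluster(cluster_id=nid, members=members, level_index=level))
    return seeds


def reassign(tree: MergeTree, seeds: Sequence[SeedCluster]) -> Partition:
    """Build the final partition from the tree and its seed clusters.

    Points inside a seed keep that leaf's label.  Classified points outside
    every seed (they entered above the first merge of their branch) go to
    the leaf whose seed holds the nearest point; exact ties go to the
    smallest cluster id.  Unclassified points are NOISE.
    """
    levels = tree.schedule.levels
    point_label: dict[int, int | str] = {}
    for seed in seeds:
        for i in seed.members:
            point_label[i] = seed.cluster_id

    pending = [
        i for i in tree.entry_level if i not in point_label
    ]
    if pending:
        seed_pts: list[int] = []
        seed_lab: list[int] = []
        for seed in sorted(seeds, key=lambda s: s.cluster_id):
            for i in sorted(seed.members):
                seed_pts.append(i)
                seed_lab.append(seed.cluster_id)
        S = point_matrix([tree.points[i] for i in seed_pts])
        lab = np.asarray(seed_lab)
        Q = point_matrix([tree.points[i] for i in sorted(pending)])
        d2 = pairwise_squared_distances(Q, S)
        for row, i in enumerate(sorted(pending)):
            best = d2[row].min()
            # ties resolved to the smallest cluster id (seed_lab is sorted)
            point_label[i] = int(lab[d2[row] == best].min())

    assignment: dict[str, int | str] = {}
    entry: dict[str, float] = {}
    for i, point in enumerate(tree.points):
        label = point_label.get(i, NOISE)
        for sid in point.members:
            assignment[sid] = label
            if label != NOISE:
                entry[sid] = levels[tree.entry_level[i]]
    return Partition(assignment=assignment, entry_level=entry)


def filter_small_clusters(partition: Partition, min_size: int) -> Partition:
    """Pool every cluster with fewer than ``min_size`` sequences into NOISE."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    sizes = partition.cluster_sizes()
    small = {label for label, s in sizes.items() if s < min_size}
    assignment = {
        sid: (NOISE if label in small else label)
        for sid, label in partition.assignment.items()
    }
    entry = {
        sid: lvl
        for sid, lvl in partition.entry_level.items()
        if assignment[sid] != NOISE
    }
    return Partition(assignment=assignment, entry_level=entry)


def place_references(
    refs: Sequence[SequenceRecord],
    tree: MergeTree,
    partition: Partition,
    max_level_index: int | None = None,
) -> dict[str, tuple[int | str, float | None]]:
    """Attach reference sequences to the finished clustering.

    References never influence the clustering itself.  A reference is
    retained iff its distance to the nearest classified sequence is within
    the retention cutoff (by default the last, loosest schedule level); its
    entry level is the smallest schedule level admitting that distance and
    its label is the final cluster of that nearest sequence.  Everything
    else is rejected as noise.
    """
    schedule = tree.schedule
    if max_level_index is None:
        max_level_index = len(schedule) - 1
    cutoff_sq = schedule.squared[max_level_index]
    levels = schedule.levels

    classified_pts = []
    classified_labels = []
    for i, point in enumerate(tree.points):
        label = partition.assignment.get(point.members[0], NOISE)
        if label != NOISE:
            classified_pts.append(point)
            classified_labels.append(label)

    out: dict[str, tuple[int | str, float | None]] = {}
    if not classified_pts:
        return {r.id: (NOISE, None) for r in refs}
    C = point_matrix(classified_pts)
    lab = np.asarray(classified_labels)
    for rec in refs:
        q = encode_sequence(rec)[None, :]
        d2 = pairwise_squared_distances(q, C)[0]
        best = d2.min()
        if best > cutoff_sq:
            out[rec.id] = (NOISE, None)
            continue
        k = schedule.first_level_at_or_above(float(best))
        assert k is not None
        label = int(np.min(lab[d2 == best]))
        out[rec.id] = (label, levels[k])
    return out


def write_cluster_summary(
    tree: MergeTree,
    seeds: Sequence[SeedCluster],
    partition: Partition,
    path: str | Path,
    radii: Mapping[int | str, float] | None = None,
) -> None:
    """Per-cluster TSV: label, size, birth level, seed size, optional radius."""
    levels = tree.schedule.levels
    sizes = partition.cluster_sizes()
    seed_by_id = {s.cluster_id: s for s in seeds}
    rows = []
    for label in sorted(sizes, key=str):
        row = {
            "cluster_label": label,
            "size": sizes[label],
        }
        if isinstance(label, int) and label in tree.nodes:
            row["birth_level_value"] = f"{levels[tree.nodes[label].birth_level]:.6g}"
            seed = seed_by_id.get(label)
            row["seed_size"] = (
                tree.point_size(seed.members) if seed is not None else ""
            )
        else:
            row["birth_level_value"] = ""
            row["seed_size"] = ""
        if radii is not None:
            row["radius_percent"] = (
                f"{radii[label]:.4f}" if label in radii else ""
            )
        rows.append(row)
    cols = ["cluster_label", "size", "birth_level_value", "seed_size"]
    if radii is not None:
        cols.append("radius_percent")
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
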